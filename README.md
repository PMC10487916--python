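# mircna

Integrated copy-number / miRNA-expression analysis for triple-negative
breast cancer (TNBC) cohorts, as a tested, reusable Python pipeline.

TNBC tumours frequently carry large somatic copy-number alterations (CNAs),
and miRNA genes located inside gained or lost regions are candidates for
dosage-driven deregulation. `mircna` implements the full analysis chain a
tissue-profiling study of this kind needs:

1. **Aberration calling** from array-CGH probe tracks: a gain (loss) is a
   maximal run of ≥ 3 consecutive probes with per-probe log₂(test/reference)
   ≥ +0.25 (≤ −0.25). Calls are aggregated into per-cytoband penetrance
   (each case counts once per band and direction), and bands altered in at
   least 19% of cases are merged into recurrent regions.
2. **Differential expression** from NanoString-style raw counts:
   background subtraction (negative-control geometric mean), positive-control
   and codeset-content scaling, then per-miRNA two-sample *t*-tests on log₂
   values with Benjamini–Hochberg FDR (significant = *p* < 0.01 ∧ FDR < 0.05),
   plus average-linkage clustering of samples on 1 − Pearson *r*.
3. **Integration**, two ways: (a) direction concordance — an up-regulated
   miRNA inside a gained region or a down-regulated miRNA inside a lost
   region; (b) consensus target genes (predicted by ≥ 2 of 3 databases)
   intersected with the genes resident in recurrent regions, ranked by the
   number of targeting miRNAs. A DE-list comparison against an external
   cohort (shared miRNAs, direction agreement) is included.
4. **Validation statistics**: RT-qPCR relative quantification
   RQ = 2^(−ΔΔCt) with Ct exclusion limits (reference ≥ 31, target ≥ 35),
   ROC/AUC for tumour vs adjacent-non-tumour discrimination with a bootstrap
   CI, dichotomized clinical associations (Welch *t*, optional multivariate
   OLS), and Kaplan–Meier survival with a two-group log-rank test on a
   median expression split.

Because studies of archival FFPE tissue rarely deposit raw data, the
package ships a first-class **synthetic cohort generator**
(`mircna.synthetic`) that fabricates every input — probe tracks, count
matrix with control probes, annotations, target databases, qPCR and
clinical tables — with recorded ground truth, so every stage is testable by
recovery against known implants.

## Worked example

```sh
mircna run-all --out out --seed 1
```

runs the default desk-scale scenario (4 × 10 Mb chromosomes, 24 array
cases with 9 implanted segments each, 18 TNBC vs 32 control expression
samples, 200 miRNAs with 15% differentially expressed at ±2 log₂) and
prints:

```json
{
 "cna":        {"n_cna_calls": 220, "mean_calls_per_case": 9.17,
                "n_recurrent_regions": 7, "n_genes_in_regions": 92,
                "n_mirnas_in_regions": 41},
 "de":         {"n_endogenous": 200, "n_de": 32},
 "integration":{"n_de": 32, "n_mapped": 7, "n_concordant": 3,
                "mapped_percent": 21.9, "concordant_percent": 42.9,
                "n_intersection_genes": 9},
 "validation": {"auc": 0.9621, "logrank_p": 0.00497, "...": "..."}
}
```

Reading: the caller found 220 aberrations (≈ 9.2 per case, matching the 9
implanted per case); 7 cytoband runs were recurrent at ≥ 19% of cases; 32
of 200 miRNAs passed the dual DE cutoff; 7 of those lie inside recurrent
regions and 3 are direction-concordant with the copy-number change; 9
consensus target genes of the concordant miRNAs also sit in altered
regions; the qPCR driver miRNA separates tumour from adjacent tissue with
AUC 0.96 and its expression is associated with survival (log-rank
*p* ≈ 0.005, as implanted through the hazard model).

Per-stage TSVs (`cna_calls.tsv`, `recurrent_regions.tsv`, `de.tsv`,
`integration.tsv`, `gene_hits.tsv`, `rq.tsv`, `roc.tsv`,
`associations.tsv`, `survival_events.tsv`), a Newick dendrogram, the
implanted truth sidecar and a MANIFEST are written under `out/`. The same
stages are available individually (`mircna simulate | call-cna | de |
integrate | validate`) and as library functions.

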