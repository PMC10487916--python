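"""End-to-end orchestration: simulate → call CNAs → DE → integrate → validate.

``run_pipeline`` drives the whole analysis on synthetic inputs with known
truth: it writes every input table to disk, re-reads them through the same
readers a real dataset would use, executes each analysis stage, and emits
per-stage TSVs plus a structured JSON report of the headline counts (calls,
recurrent regions, DE features, mapped/concordant miRNAs, intersection
genes, AUCs, association and log-rank p-values).  The implanted truth is
written to a separate sidecar that no analysis stage reads; recovery scoring
against it lives in :func:`evaluate_against_truth`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from . import cna, expression, integration, io, synthetic
from .intervals import GenomicInterval

log = logging.getLogger("mircna")

_STREAM_DRIVER = 97


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


def _truth_to_json(truth: synthetic.SyntheticTruth) -> dict:
    return {
        "implanted_segments": [
            {
                "case_id": s.case_id,
                "chrom": s.interval.chromosome,
                "start": s.interval.start,
                "stop": s.interval.stop,
                "direction": s.direction,
                "amplitude": s.amplitude,
            }
            for s in truth.implanted_segments
        ],
        "de_mirnas": [[m, e] for m, e in truth.de_mirnas],
        "consensus_targets": {m: sorted(g) for m, g in sorted(truth.consensus_targets.items())},
        "survival_params": list(truth.survival_params) if truth.survival_params else None,
    }


def simulate_inputs(config: io.PipelineConfig, outdir: Path) -> synthetic.SyntheticTruth:
    """Generate and write every pipeline input plus the truth sidecar."""
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    genome = synthetic.generate_genome(
        config.n_chromosomes,
        config.bands_per_chromosome,
        config.n_genes,
        config.n_mirnas,
        seed=config.seed,
        chromosome_length=config.chromosome_length,
    )
    io.write_intervals(inputs / "cytobands.tsv", genome.cytobands)
    io.write_intervals(
        inputs / "genes.tsv", [(k, v) for k, v in genome.gene_annotations.items()]
    )
    io.write_intervals(
        inputs / "mirnas.tsv", [(k, v) for k, v in genome.mirna_annotations.items()]
    )

    tracks, truth_cna = synthetic.generate_acgh_profiles(
        genome,
        n_cases=config.n_acgh_cases,
        segments_per_case=config.segments_per_case,
        amplitude=config.amplitude,
        probe_spacing=config.probe_spacing,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    io.write_probe_tracks(inputs / "probes.tsv", tracks)

    matrix, truth_de = synthetic.generate_expression(
        genome,
        n_group_a=config.n_group_case,
        n_group_b=config.n_group_control,
        de_fraction=config.de_fraction,
        effect=config.de_effect,
        seed=config.seed,
    )
    io.write_expression(inputs / "counts.tsv", inputs / "groups.tsv", matrix)

    tables, truth_targets = synthetic.generate_target_dbs(
        genome,
        mirnas=list(genome.mirna_annotations),
        targets_per_mirna=config.targets_per_mirna,
        db_agreement=config.db_agreement,
        seed=config.seed,
    )
    io.write_target_tables(
        [inputs / f"targets_db{i + 1}.tsv" for i in range(3)], tables
    )

    # driver miRNA for the validation layer: the implanted miRNA with the
    # strongest up-regulation (falling back to strongest overall, then to the
    # first endogenous feature when nothing was implanted)
    if truth_de.de_mirnas:
        ups = [(m, e) for m, e in truth_de.de_mirnas if e > 0]
        pool = ups or truth_de.de_mirnas
        driver, driver_shift = max(pool, key=lambda me: abs(me[1]))
    else:
        driver, driver_shift = list(genome.mirna_annotations)[0], 0.0
    ct_records = synthetic.generate_ct_records(
        target_id=driver,
        n_tumor=config.n_tumor_qpcr,
        n_ant=config.n_ant_qpcr,
        delta_ct_shift=driver_shift,
        seed=config.seed,
    )
    io.write_ct_records(inputs / "ct.tsv", ct_records)

    rng = np.random.default_rng([_STREAM_DRIVER, config.seed])
    driver_expr = rng.standard_normal(config.n_patients)
    table, truth_surv = synthetic.generate_clinical(
        n_patients=config.n_patients,
        driver_expression=driver_expr,
        hazard_coef=config.hazard_coef,
        baseline_hazard=config.baseline_hazard,
        censor_month=config.censor_month,
        seed=config.seed,
    )
    table.insert(1, "driver_expression", np.round(driver_expr, 6))
    io.write_clinical(inputs / "clinical.tsv", table)

    truth = (
        truth_cna.merged_with(truth_de)
        .merged_with(truth_targets)
        .merged_with(truth_surv)
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(_truth_to_json(truth), fh, indent=1, sort_keys=True)
    return truth


def stage_call_cna(config: io.PipelineConfig, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    tracks = io.read_probe_tracks(inputs / "probes.tsv")
    bands = io.read_bed_like(inputs / "cytobands.tsv")
    bands = [(name, iv) for name, iv in bands]
    genes = io.read_annotations(inputs / "genes.tsv")
    mirnas = io.read_annotations(inputs / "mirnas.tsv")

    calls_by_case = {
        case_id: cna.call_aberrations(
            cna.ProbeTrack(case_id, df),
            min_probes=config.min_probes,
            gain_threshold=config.gain_threshold,
            loss_threshold=config.loss_threshold,
        )
        for case_id, df in tracks.items()
    }
    calls_df = pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "chrom": c.interval.chromosome,
                "start": c.interval.start,
                "stop": c.interval.stop,
                "size": c.interval.size,
                "direction": c.direction,
                "n_probes": c.n_probes,
                "mean_log2": round(c.mean_log2, 6),
            }
            for case_id in sorted(calls_by_case)
            for c in calls_by_case[case_id]
        ]
    )
    calls_df.to_csv(outdir / "cna_calls.tsv", sep="\t", index=False)

    penetrance = cna.aggregate_penetrance(calls_by_case, bands, n_cases=len(tracks))
    regions = cna.select_recurrent_regions(penetrance, min_frequency=config.min_frequency)
    regions_df = pd.DataFrame(
        [
            {
                "chrom": r.interval.chromosome,
                "cytoband": r.cytoband,
                "start": r.interval.start,
                "stop": r.interval.stop,
                "size": r.interval.size,
                "n_cases": r.n_cases,
                "percent": integration.round_half_away(100 * r.frequency),
                "direction": r.direction,
                "n_probes": r.n_probes,
            }
            for r in regions
        ]
    )
    regions_df.to_csv(outdir / "recurrent_regions.tsv", sep="\t", index=False)

    gene_hits = cna.map_features_to_regions(genes, regions)
    mirna_hits = cna.map_features_to_regions(mirnas, regions)
    n_calls = sum(len(v) for v in calls_by_case.values())
    return {
        "calls_by_case": calls_by_case,
        "regions": regions,
        "gene_hits": gene_hits,
        "mirna_hits": mirna_hits,
        "summary": {
            "n_cna_calls": n_calls,
            "mean_calls_per_case": round(n_calls / max(len(tracks), 1), 2),
            "n_recurrent_regions": len(regions),
            "n_genes_in_regions": len(gene_hits),
            "n_mirnas_in_regions": len(mirna_hits),
        },
    }


def stage_de(config: io.PipelineConfig, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    matrix = io.read_expression(inputs / "counts.tsv", inputs / "groups.tsv")
    normalized = expression.normalize(matrix)
    records, significant = expression.differential_expression(
        normalized, p_cutoff=config.p_cutoff, fdr_cutoff=config.fdr_cutoff
    )
    de_df = pd.DataFrame(
        [
            {
                "mirna": r.feature_id,
                "log2_fc": round(r.log2_fc, 5),
                "p_value": r.p_value,
                "fdr": r.fdr,
                "direction": r.direction,
                "significant": r in significant,
            }
            for r in records
        ]
    )
    de_df.to_csv(outdir / "de.tsv", sep="\t", index=False)

    newick = None
    if len(significant) >= 2:
        _, leaf_order, newick = expression.hierarchical_cluster(
            normalized, [r.feature_id for r in significant]
        )
        (outdir / "dendrogram.nwk").write_text(newick + "\n")
    return {
        "records": records,
        "significant": significant,
        "normalized": normalized,
        "summary": {"n_endogenous": len(records), "n_de": len(significant)},
    }


def stage_integrate(
    config: io.PipelineConfig, outdir: Path, de_significant, mirna_hits, gene_hits
) -> dict:
    inputs = outdir / "inputs"
    if not de_significant:
        summary = {
            "n_de": 0,
            "n_mapped": 0,
            "n_concordant": 0,
            "mapped_percent": 0.0,
            "concordant_percent": 0.0,
            "n_intersection_genes": 0,
        }
        pd.DataFrame(
            columns=["mirna", "log2_fc", "p_value", "fdr", "cytoband", "cna", "concordant"]
        ).to_csv(outdir / "integration.tsv", sep="\t", index=False)
        pd.DataFrame(columns=["gene", "n_mirnas", "mirnas", "cna_direction"]).to_csv(
            outdir / "gene_hits.tsv", sep="\t", index=False
        )
        return {"records": [], "gene_hits": [], "summary": summary}

    records, summary = integration.integrate(de_significant, mirna_hits)
    pd.DataFrame(
        [
            {
                "mirna": r.mirna_id,
                "log2_fc": round(r.log2_fc, 5),
                "de_direction": r.de_direction,
                "cytoband": r.region.cytoband,
                "cna": r.cna_direction,
                "concordant": r.concordant,
            }
            for r in records
        ]
    ).to_csv(outdir / "integration.tsv", sep="\t", index=False)

    # second approach: consensus targets of the concordant miRNAs vs CNA genes
    tables = io.read_target_tables([inputs / f"targets_db{i + 1}.tsv" for i in range(3)])
    concordant_ids = {
        integration.normalize_mirna_id(r.mirna_id) for r in records if r.concordant
    }
    tables = [
        t[t["mirna_id"].map(integration.normalize_mirna_id).isin(concordant_ids)]
        for t in tables
    ]
    gene_hit_rows: list[integration.GeneHit] = []
    if concordant_ids:
        consensus = integration.consensus_targets(tables, min_dbs=config.consensus_min_dbs)
        cna_gene_dirs = {
            gene: regions[0].direction for gene, regions in gene_hits.items()
        }
        if consensus:
            gene_hit_rows = integration.intersect_with_cna_genes(consensus, cna_gene_dirs)
    pd.DataFrame(
        [
            {
                "gene": h.gene_id,
                "n_mirnas": h.n_mirnas,
                "mirnas": ",".join(sorted(h.targeting_mirnas)),
                "cna_direction": h.cna_direction,
            }
            for h in gene_hit_rows
        ],
        columns=["gene", "n_mirnas", "mirnas", "cna_direction"],
    ).to_csv(outdir / "gene_hits.tsv", sep="\t", index=False)

    out_summary = {
        "n_de": summary.n_de,
        "n_mapped": summary.n_mapped,
        "n_concordant": summary.n_concordant,
        "mapped_percent": summary.mapped_percent,
        "concordant_percent": summary.concordant_percent,
        "n_intersection_genes": len(gene_hit_rows),
    }
    return {"records": records, "gene_hits": gene_hit_rows, "summary": out_summary}


def stage_validate(config: io.PipelineConfig, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    ct_records = io.read_ct_records(inputs / "ct.tsv")
    clin_table = io.read_clinical(inputs / "clinical.tsv")

    # ddCt quantification, calibrated to the mean ANT dCt
    ant_dcts = [
        float(np.mean(r.target_ct)) - float(np.mean(r.reference_ct))
        for r in ct_records
        if r.tissue == "ANT"
        and float(np.mean(r.reference_ct)) < clin.REFERENCE_CT_LIMIT
        and float(np.mean(r.target_ct)) < clin.TARGET_CT_LIMIT
    ]
    calibrator = float(np.mean(ant_dcts)) if ant_dcts else 0.0
    rq_results = [clin.relative_quantity(r, calibrator) for r in ct_records]
    rq_df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "target_id": r.target_id,
                "tissue": rec.tissue,
                "excluded": r.excluded,
                "reason": r.reason or "",
                "delta_ct": r.delta_ct if r.delta_ct is not None else "",
                "rq": r.rq if r.rq is not None else "",
            }
            for r, rec in zip(rq_results, ct_records)
        ]
    )
    rq_df.to_csv(outdir / "rq.tsv", sep="\t", index=False)

    kept = [
        (res, rec) for res, rec in zip(rq_results, ct_records) if not res.excluded
    ]
    scores = [res.rq for res, _ in kept]
    tissues = [rec.tissue for _, rec in kept]
    roc = clin.roc_auc(scores, tissues, positive_label="tumor", seed=config.seed)
    pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "one_minus_specificity": roc.one_minus_specificity,
        }
    ).to_csv(outdir / "roc.tsv", sep="\t", index=False)

    # clinical associations of the driver miRNA expression
    expr = pd.Series(
        clin_table["driver_expression"].to_numpy(), index=clin_table["patient_id"]
    )
    assoc_rows = []
    for variable in ["age", "tumor_size", "ki67", "p53", "bmi", "recurrence",
                     "distant_metastasis", "comorbidity", "htn", "grade", "stage",
                     "status"]:
        try:
            res = clin.associate(expr, clin_table, variable)
        except ValueError as exc:
            log.warning("association for %s skipped: %s", variable, exc)
            continue
        assoc_rows.append(
            {
                "variable": res.variable,
                "cutpoint": res.cutpoint if res.cutpoint is not None else "",
                "n": res.n,
                "mean_high": round(res.mean_high, 4),
                "mean_low": round(res.mean_low, 4),
                "p_value": res.p_value,
            }
        )
    assoc_df = pd.DataFrame(assoc_rows)
    assoc_df.to_csv(outdir / "associations.tsv", sep="\t", index=False)

    split = clin.median_split(expr.to_numpy())
    km = clin.km_logrank(clin_table, split)
    km.event_table.to_csv(outdir / "survival_events.tsv", sep="\t", index=False)

    return {
        "summary": {
            "n_rq_excluded": int(sum(r.excluded for r in rq_results)),
            "calibrator_delta_ct": round(calibrator, 4),
            "auc": round(roc.auc, 4),
            "auc_ci": [round(roc.ci_low, 4), round(roc.ci_high, 4)],
            "logrank_p": km.p_value,
            "association_p": {
                row["variable"]: row["p_value"] for row in assoc_rows
            },
        }
    }


def run_pipeline(config: io.PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages on a fresh synthetic scenario; return the report dict.

    Writes inputs, per-stage outputs, a truth sidecar, ``report.json`` and a
    MANIFEST.  On a stage failure the MANIFEST notes the failed stage and
    partial outputs are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}
    stage = "simulate"
    try:
        simulate_inputs(config, outdir)
        log.info("simulate: inputs written (seed=%d)", config.seed)

        stage = "call-cna"
        cna_out = stage_call_cna(config, outdir)
        report["stages"]["cna"] = cna_out["summary"]
        log.info("call-cna: %s", cna_out["summary"])

        stage = "de"
        de_out = stage_de(config, outdir)
        report["stages"]["de"] = de_out["summary"]
        log.info("de: %s", de_out["summary"])

        stage = "integrate"
        int_out = stage_integrate(
            config, outdir, de_out["significant"], cna_out["mirna_hits"], cna_out["gene_hits"]
        )
        report["stages"]["integration"] = int_out["summary"]
        log.info("integrate: %s", int_out["summary"])

        stage = "validate"
        val_out = stage_validate(config, outdir)
        report["stages"]["validation"] = val_out["summary"]
        log.info("validate: %s", val_out["summary"])
    except Exception as exc:
        _write_manifest(outdir, complete=False, failed_stage=stage)
        raise StageError(stage, str(exc)) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    _write_manifest(outdir, complete=True)
    return report


def _write_manifest(outdir: Path, complete: bool, failed_stage: str | None = None) -> None:
    lines = [f"complete: {str(complete).lower()}"]
    if failed_stage:
        lines.append(f"failed_stage: {failed_stage}")
    for f in sorted(p.relative_to(outdir).as_posix() for p in outdir.rglob("*") if p.is_file()):
        if f != "MANIFEST":
            lines.append(f"file: {f}")
    (outdir / "MANIFEST").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# truth-recovery scoring (used by tests and the acceptance harness, never by
# the analysis stages themselves)


def _probe_overlap_fraction(a: GenomicInterval, b: GenomicInterval, spacing: int) -> tuple[float, float]:
    """Reciprocal overlap fractions in probe counts for grid-aligned spans."""
    if a.chromosome != b.chromosome:
        return 0.0, 0.0
    lo, hi = max(a.start, b.start), min(a.stop, b.stop)
    if lo > hi:
        return 0.0, 0.0
    shared = (hi - lo) // spacing + 1
    n_a = (a.stop - a.start) // spacing + 1
    n_b = (b.stop - b.start) // spacing + 1
    return shared / n_a, shared / n_b


def segment_recovery(
    truth: synthetic.SyntheticTruth,
    calls_by_case: dict[str, list[cna.CnaCall]],
    probe_spacing: int,
    min_reciprocal: float = 0.5,
) -> float:
    """Fraction of implanted segments recovered by a direction-matched call
    with at least ``min_reciprocal`` reciprocal probe overlap."""
    if not truth.implanted_segments:
        return float("nan")
    n_hit = 0
    for seg in truth.implanted_segments:
        for call in calls_by_case.get(seg.case_id, []):
            if call.direction != seg.direction:
                continue
            fa, fb = _probe_overlap_fraction(seg.interval, call.interval, probe_spacing)
            if fa >= min_reciprocal and fb >= min_reciprocal:
                n_hit += 1
                break
    return n_hit / len(truth.implanted_segments)


def de_recovery(
    truth: synthetic.SyntheticTruth, significant: list[expression.DeRecord]
) -> tuple[float, float]:
    """(sensitivity, realized false-discovery fraction) vs implanted truth."""
    implanted = {m for m, e in truth.de_mirnas if e != 0}
    flagged = {r.feature_id for r in significant}
    sens = len(flagged & implanted) / len(implanted) if implanted else float("nan")
    fdr = len(flagged - implanted) / len(flagged) if flagged else 0.0
    return sens, fdr
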