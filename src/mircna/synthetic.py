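"""Synthetic cohort generators with recorded ground truth.

The analysis pipeline consumes five kinds of input: per-case array-CGH probe
tracks, a raw miRNA count matrix with control probes, genomic annotations
(cytobands, genes, miRNAs), miRNA→gene target-prediction tables, and a
clinical/survival table.  This module fabricates all five at desk scale with
the statistical structure the downstream stages assume, and records exactly
what was implanted (:class:`SyntheticTruth`) so every stage can be tested by
recovery against known truth rather than against opaque fixtures.

Defaults emulate the assay designs the pipeline targets: step-shaped
copy-number segments in Gaussian probe noise on a tiling oligo array;
log-normal NanoString-style counts with negative (background) and positive
(spike-in ladder) control probes and a mean shift on a chosen fraction of
features; three partially agreeing target databases; exponential survival
times whose hazard is log-linear in the expression of one driver miRNA.

Every generator is deterministic for a fixed seed.  Generators use distinct
RNG substreams so that calling two of them with the same seed does not
produce correlated draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .expression import ExpressionMatrix

# Fixed substream tags so the same user seed decorrelates across generators.
_STREAM_GENOME = 11
_STREAM_ACGH = 23
_STREAM_EXPR = 37
_STREAM_TARGETS = 53
_STREAM_CLINICAL = 71

GENE_LENGTH = 10_000
MIRNA_LENGTH = 100


@dataclass(frozen=True)
class ImplantedSegment:
    """One copy-number segment written into a synthetic probe track."""

    case_id: str
    interval: GenomicInterval
    direction: str  # "gain" | "loss"
    amplitude: float  # absolute log2 shift, > 0

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.amplitude == 0:
            raise ValueError("implanted segment amplitude must be nonzero")


@dataclass
class SyntheticTruth:
    """Everything a simulation implanted, for recovery testing downstream."""

    implanted_segments: list[ImplantedSegment] = field(default_factory=list)
    de_mirnas: list[tuple[str, float]] = field(default_factory=list)
    consensus_targets: dict[str, frozenset[str]] = field(default_factory=dict)
    survival_params: tuple[float, float] | None = None

    def merged_with(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            implanted_segments=self.implanted_segments + other.implanted_segments,
            de_mirnas=self.de_mirnas + other.de_mirnas,
            consensus_targets={**self.consensus_targets, **other.consensus_targets},
            survival_params=other.survival_params or self.survival_params,
        )


@dataclass
class GenomeModel:
    """A toy genome: chromosome lengths, cytobands and feature annotations.

    Cytobands within a chromosome are non-overlapping, sorted, and tile the
    chromosome exactly; every feature interval lies within its chromosome.
    """

    chromosomes: dict[str, int]
    cytobands: list[tuple[str, GenomicInterval]]
    gene_annotations: dict[str, GenomicInterval]
    mirna_annotations: dict[str, GenomicInterval]

    def validate(self) -> None:
        for name, iv in self.cytobands:
            if iv.stop > self.chromosomes[iv.chromosome]:
                raise ValueError(f"cytoband {name} exceeds chromosome bounds")
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for _, iv in self.cytobands:
            by_chrom.setdefault(iv.chromosome, []).append(iv)
        for chrom, ivs in by_chrom.items():
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.stop:
                    raise ValueError(f"overlapping/unsorted cytobands on {chrom}")
        for fid, iv in {**self.gene_annotations, **self.mirna_annotations}.items():
            if iv.chromosome not in self.chromosomes:
                raise ValueError(f"feature {fid} on unknown chromosome")
            if iv.stop > self.chromosomes[iv.chromosome]:
                raise ValueError(f"feature {fid} exceeds chromosome bounds")


def _band_names(n_bands: int) -> list[str]:
    """p/q band names in genomic order: p{k}..p1 then q1..q{m}."""
    n_p = n_bands // 2
    n_q = n_bands - n_p
    return [f"p{j}" for j in range(n_p, 0, -1)] + [f"q{j}" for j in range(1, n_q + 1)]


def generate_genome(
    n_chromosomes: int,
    bands_per_chromosome: int,
    n_genes: int,
    n_mirnas: int,
    seed: int,
    chromosome_length: int = 10_000_000,
) -> GenomeModel:
    """Build a uniform toy genome with equal-width cytobands.

    Genes (10 kb) and miRNAs (100 bp) are placed uniformly at random within
    chromosomes.  Band names follow the cytogenetic ``chr{i}p{j}/q{j}``
    convention, numbered outward from the centre of the chromosome.
    """
    if n_chromosomes < 1 or bands_per_chromosome < 1:
        raise ValueError("counts must be >= 1")
    if n_genes < 0 or n_mirnas < 0:
        raise ValueError("feature counts must be >= 0")
    rng = np.random.default_rng([_STREAM_GENOME, seed])
    chromosomes = {f"chr{i + 1}": chromosome_length for i in range(n_chromosomes)}

    cytobands: list[tuple[str, GenomicInterval]] = []
    for chrom, length in chromosomes.items():
        edges = np.linspace(0, length, bands_per_chromosome + 1).astype(int)
        for name, lo, hi in zip(_band_names(bands_per_chromosome), edges[:-1], edges[1:]):
            cytobands.append((f"{chrom}{name}", GenomicInterval(chrom, int(lo) + 1, int(hi))))

    def _place(n: int, width: int, prefix: str) -> dict[str, GenomicInterval]:
        out: dict[str, GenomicInterval] = {}
        chrom_names = list(chromosomes)
        for i in range(n):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            start = int(rng.integers(1, chromosomes[chrom] - width + 1))
            out[f"{prefix}{i + 1:04d}"] = GenomicInterval(chrom, start, start + width - 1)
        return out

    genome = GenomeModel(
        chromosomes=chromosomes,
        cytobands=cytobands,
        gene_annotations=_place(n_genes, GENE_LENGTH, "GENE"),
        mirna_annotations=_place(n_mirnas, MIRNA_LENGTH, "hsa-miR-s"),
    )
    genome.validate()
    return genome


def generate_acgh_profiles(
    genome: GenomeModel,
    n_cases: int,
    segments_per_case: int,
    amplitude: float = 0.5,
    probe_spacing: int = 10_000,
    noise_sd: float = 0.1,
    seed: int = 0,
    segment_probes: tuple[int, int] = (5, 15),
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Per-case probe tracks with step-shaped gain/loss segments in noise.

    Probes are laid at fixed spacing along each chromosome.  Within an
    implanted segment the log2 ratio is Normal(+amplitude, noise_sd) for a
    gain and Normal(-amplitude, noise_sd) for a loss; elsewhere it is
    Normal(0, noise_sd).  Implants within a case never overlap and always
    span at least three probes (segments that cannot are rejected).

    Returns one table per case (columns ``chrom, start, stop, log2_ratio``,
    sorted) and the truth record of every implant.
    """
    if amplitude < 0 or noise_sd < 0:
        raise ValueError("amplitude and noise_sd must be >= 0")
    if probe_spacing < 1:
        raise ValueError("probe_spacing must be >= 1")
    if segment_probes[0] < 3:
        raise ValueError("implanted segments must span at least 3 probes")
    if segments_per_case > 0 and amplitude == 0:
        raise ValueError("amplitude must be > 0 when implanting segments")
    rng = np.random.default_rng([_STREAM_ACGH, seed])

    probe_pos = {
        chrom: np.arange(1, length + 1, probe_spacing, dtype=np.int64)
        for chrom, length in genome.chromosomes.items()
    }
    chroms = list(genome.chromosomes)
    n_probes_total = {c: len(p) for c, p in probe_pos.items()}
    if segments_per_case > 0 and max(n_probes_total.values()) < segment_probes[1]:
        raise ValueError("chromosomes too short to fit requested segments")

    tables: dict[str, pd.DataFrame] = {}
    truth = SyntheticTruth()
    for k in range(n_cases):
        case_id = f"CASE{k + 1:02d}"
        # occupied probe-index ranges per chromosome, to keep implants disjoint
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        implants: list[tuple[str, int, int, str]] = []
        for _ in range(segments_per_case):
            for _try in range(1000):
                chrom = chroms[int(rng.integers(len(chroms)))]
                run = int(rng.integers(segment_probes[0], segment_probes[1] + 1))
                if run > n_probes_total[chrom]:
                    continue
                i0 = int(rng.integers(0, n_probes_total[chrom] - run + 1))
                i1 = i0 + run - 1
                # require a 1-probe gap so adjacent implants never merge
                if any(i0 <= b + 1 and a - 1 <= i1 for a, b in occupied[chrom]):
                    continue
                occupied[chrom].append((i0, i1))
                direction = "gain" if rng.random() < 0.5 else "loss"
                implants.append((chrom, i0, i1, direction))
                break
            else:
                raise ValueError("could not place non-overlapping segment; genome too small")

        frames = []
        for chrom in chroms:
            pos = probe_pos[chrom]
            log2 = rng.normal(0.0, noise_sd, size=len(pos)) if noise_sd > 0 else np.zeros(len(pos))
            for ch, i0, i1, direction in implants:
                if ch != chrom:
                    continue
                shift = amplitude if direction == "gain" else -amplitude
                log2[i0 : i1 + 1] += shift
                truth.implanted_segments.append(
                    ImplantedSegment(
                        case_id=case_id,
                        interval=GenomicInterval(chrom, int(pos[i0]), int(pos[i1])),
                        direction=direction,
                        amplitude=amplitude,
                    )
                )
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": pos,
                        "stop": pos,
                        "log2_ratio": log2,
                    }
                )
            )
        tables[case_id] = pd.concat(frames, ignore_index=True)
    return tables, truth


def generate_expression(
    genome: GenomeModel,
    n_group_a: int,
    n_group_b: int,
    de_fraction: float = 0.1,
    effect: float = 2.0,
    n_neg_controls: int = 6,
    n_pos_controls: int = 6,
    seed: int = 0,
    sigma: float = 1.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Raw count matrix with control rows and a mean-shifted DE subset.

    Endogenous counts are log-normal: per-feature baseline log2 abundance is
    Uniform(5, 12), per-sample log2 values are Normal(baseline, sigma), and a
    per-sample library-scale offset (Normal(0, 0.25) in log2) multiplies every
    endogenous and positive-control row.  Group A ("case") means are shifted
    by ±``effect`` log2 units on a ``de_fraction`` subset of features, with a
    random sign per feature.  Negative-control rows are unscaled low-level
    Poisson background; positive-control rows are a geometric spike-in ladder
    times the sample scale.
    """
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must be in [0, 1]")
    if n_group_a < 2 or n_group_b < 2:
        raise ValueError("group sizes must be >= 2")
    if n_neg_controls < 1 or n_pos_controls < 1:
        raise ValueError("at least one negative and one positive control required")
    rng = np.random.default_rng([_STREAM_EXPR, seed])

    mirnas = list(genome.mirna_annotations)
    n_feat = len(mirnas)
    samples = [f"TNBC{j + 1:02d}" for j in range(n_group_a)] + [
        f"CTRL{j + 1:02d}" for j in range(n_group_b)
    ]
    groups = pd.Series(
        ["case"] * n_group_a + ["control"] * n_group_b, index=samples, name="group"
    )
    n_samples = len(samples)

    baseline = rng.uniform(5.0, 12.0, size=n_feat)
    sample_scale = rng.normal(0.0, 0.25, size=n_samples)  # log2 library-size offset

    n_de = int(round(de_fraction * n_feat))
    de_idx = rng.choice(n_feat, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effects = np.zeros(n_feat)
    effects[de_idx] = signs * effect

    is_case = np.array([g == "case" for g in groups], dtype=float)
    log2_vals = (
        baseline[:, None]
        + effects[:, None] * is_case[None, :]
        + sample_scale[None, :]
        + rng.normal(0.0, sigma, size=(n_feat, n_samples))
    )
    endo = np.rint(np.exp2(log2_vals)).astype(np.int64)

    neg = rng.poisson(8.0, size=(n_neg_controls, n_samples)).astype(np.int64)
    pos_nominal = np.exp2(6.0 + np.arange(n_pos_controls))
    pos = np.rint(pos_nominal[:, None] * np.exp2(sample_scale)[None, :]).astype(np.int64)

    feature_ids = (
        mirnas
        + [f"NEG_{chr(ord('A') + i)}" for i in range(n_neg_controls)]
        + [f"POS_{chr(ord('A') + i)}" for i in range(n_pos_controls)]
    )
    counts = pd.DataFrame(
        np.vstack([endo, neg, pos]), index=feature_ids, columns=samples
    )
    feature_class = pd.Series(
        ["endogenous"] * n_feat
        + ["negative_control"] * n_neg_controls
        + ["positive_control"] * n_pos_controls,
        index=feature_ids,
        name="feature_class",
    )
    matrix = ExpressionMatrix(counts=counts, feature_class=feature_class, groups=groups)
    truth = SyntheticTruth(
        de_mirnas=[(mirnas[i], float(effects[i])) for i in sorted(de_idx)]
    )
    return matrix, truth


def generate_target_dbs(
    genome: GenomeModel,
    mirnas: list[str],
    targets_per_mirna: int = 30,
    db_agreement: float = 0.5,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], SyntheticTruth]:
    """Three partially agreeing miRNA→gene target-prediction tables.

    Each miRNA draws ``targets_per_mirna`` candidate genes; each candidate is
    a shared ("core") prediction listed in all three databases with
    probability ``db_agreement``, else a private prediction in exactly one
    database.  The truth consensus is the exhaustive two-of-three membership
    count over the generated tables, so it is exact by construction.
    """
    if not 0 <= db_agreement <= 1:
        raise ValueError("db_agreement must be in [0, 1]")
    unknown = set(mirnas) - set(genome.mirna_annotations)
    if unknown:
        raise ValueError(f"unknown miRNA ids: {sorted(unknown)}")
    genes = list(genome.gene_annotations)
    if targets_per_mirna > len(genes):
        raise ValueError("targets_per_mirna exceeds number of genes")
    rng = np.random.default_rng([_STREAM_TARGETS, seed])

    rows: list[list[tuple[str, str]]] = [[], [], []]
    membership: dict[tuple[str, str], int] = {}
    for mirna in mirnas:
        picked = rng.choice(len(genes), size=targets_per_mirna, replace=False)
        for gi in picked:
            gene = genes[int(gi)]
            if rng.random() < db_agreement:
                dbs = (0, 1, 2)
            else:
                dbs = (int(rng.integers(3)),)
            for d in dbs:
                rows[d].append((mirna, gene))
            membership[(mirna, gene)] = len(dbs)

    tables = [
        pd.DataFrame(r, columns=["mirna_id", "gene_id"]) for r in rows
    ]
    consensus: dict[str, set[str]] = {}
    for (mirna, gene), n in membership.items():
        if n >= 2:
            consensus.setdefault(mirna, set()).add(gene)
    truth = SyntheticTruth(
        consensus_targets={m: frozenset(g) for m, g in consensus.items()}
    )
    return tables, truth


def generate_ct_records(
    target_id: str,
    n_tumor: int,
    n_ant: int,
    delta_ct_shift: float = 2.0,
    seed: int = 0,
    replicate_sd: float = 0.2,
):
    """Triplicate RT-qPCR cycle thresholds for tumor and adjacent tissue.

    Reference-assay Ct is Normal(25, 1) per sample; the per-sample dCt
    (target minus reference) is Normal(5, 1.5) in adjacent non-tumor tissue
    and Normal(5 - ``delta_ct_shift``, 1.5) in tumor, so a positive shift
    means the target miRNA is up-regulated in tumor.  The 1.5-cycle
    between-sample spread reflects the biological and preservation
    variability of archival tissue.  Replicates scatter around the sample
    mean with sd ``replicate_sd``.
    """
    from .clinical import CtRecord  # local import: clinical does not import us

    if n_tumor < 1 or n_ant < 1:
        raise ValueError("need at least one sample per tissue")
    rng = np.random.default_rng([_STREAM_CLINICAL + 1, seed])
    records = []
    for tissue, n, dct_mean in (("tumor", n_tumor, 5.0 - delta_ct_shift), ("ANT", n_ant, 5.0)):
        for j in range(n):
            ref = rng.normal(25.0, 1.0)
            target = ref + rng.normal(dct_mean, 1.5)
            records.append(
                CtRecord(
                    sample_id=f"{'T' if tissue == 'tumor' else 'N'}{j + 1:02d}",
                    tissue=tissue,
                    target_id=target_id,
                    target_ct=tuple(np.round(target + rng.normal(0, replicate_sd, 3), 3)),
                    reference_ct=tuple(np.round(ref + rng.normal(0, replicate_sd, 3), 3)),
                )
            )
    return records


def generate_clinical(
    n_patients: int,
    driver_expression: np.ndarray,
    hazard_coef: float,
    baseline_hazard: float,
    censor_month: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Clinical table with exponential survival driven by one miRNA.

    Event times are exponential with per-patient hazard
    ``baseline_hazard * exp(hazard_coef * expression)`` (events per month),
    administratively censored at ``censor_month``.  All other clinical
    covariates (age, tumour size, grade, stage, Ki-67, p53, recurrence,
    distant metastasis, BMI, comorbidity and hypertension flags) are drawn
    independently, at marginals typical of a TNBC case series.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be > 0")
    if censor_month < 0:
        raise ValueError("censor_month must be >= 0")
    driver_expression = np.asarray(driver_expression, dtype=float)
    if driver_expression.shape != (n_patients,):
        raise ValueError("driver_expression must have one value per patient")
    rng = np.random.default_rng([_STREAM_CLINICAL, seed])

    hazard = baseline_hazard * np.exp(hazard_coef * driver_expression)
    event_time = rng.exponential(1.0 / hazard)
    follow_up = np.minimum(event_time, censor_month)
    deceased = event_time <= censor_month

    table = pd.DataFrame(
        {
            "patient_id": [f"PT{i + 1:03d}" for i in range(n_patients)],
            "age": np.clip(rng.normal(55.3, 10.6, n_patients), 25, 95).round(1),
            "tumor_size": np.clip(rng.normal(1.85, 1.25, n_patients), 0.1, None).round(2),
            "grade": rng.choice([2, 3], n_patients),
            "stage": rng.choice(["T1/T2", "T3/T4"], n_patients, p=[0.7, 0.3]),
            "ki67": np.clip(rng.normal(40, 25, n_patients), 0, 100).round(1),
            "p53": np.clip(rng.normal(35, 30, n_patients), 0, 100).round(1),
            "recurrence": rng.random(n_patients) < 0.31,
            "distant_metastasis": rng.random(n_patients) < 0.32,
            "bmi": np.clip(rng.normal(29.4, 6.7, n_patients), 15, None).round(1),
            "comorbidity": rng.random(n_patients) < 0.71,
            "htn": rng.random(n_patients) < 0.40,
            "status": np.where(deceased, "deceased", "alive"),
            "follow_up": follow_up.round(3),
        }
    )
    truth = SyntheticTruth(survival_params=(baseline_hazard, hazard_coef))
    return table, truth
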