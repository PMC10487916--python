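"""TSV/BED readers and writers and the pipeline configuration.

Canonical on-disk form is header-carrying TSV.  Interval files are accepted
in two dialects: ``one_based_tsv`` (the internal 1-based inclusive
convention, passed through) and ``bed`` (0-based half-open; converted on
read by start+1, stop unchanged).  Writers and readers round-trip every
in-memory type exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .clinical import CtRecord
from .expression import ExpressionMatrix
from .intervals import GenomicInterval


@dataclass
class PipelineConfig:
    """All tunable thresholds and synthetic-scenario sizes, with defaults.

    Thresholds default to the assay conventions the pipeline implements:
    runs of >= 3 probes at |log2| >= 0.25 for aberration calls, 19%
    recurrence frequency, dual DE cutoff p < 0.01 and FDR < 0.05, 2-of-3
    target-database consensus, and Ct exclusion at 31 (reference) / 35
    (target) cycles.
    """

    seed: int = 0
    # aberration calling
    min_probes: int = 3
    gain_threshold: float = 0.25
    loss_threshold: float = -0.25
    min_frequency: float = 0.19
    # differential expression
    p_cutoff: float = 0.01
    fdr_cutoff: float = 0.05
    # integration
    consensus_min_dbs: int = 2
    # synthetic scenario (desk-scale stand-in for a ~28-patient FFPE series)
    n_chromosomes: int = 4
    bands_per_chromosome: int = 12
    chromosome_length: int = 10_000_000
    n_genes: int = 400
    n_mirnas: int = 200
    n_acgh_cases: int = 24
    segments_per_case: int = 9
    amplitude: float = 0.5
    probe_spacing: int = 10_000
    noise_sd: float = 0.1
    n_group_case: int = 18
    n_group_control: int = 32
    de_fraction: float = 0.15
    de_effect: float = 2.0
    targets_per_mirna: int = 30
    db_agreement: float = 0.5
    n_tumor_qpcr: int = 22
    n_ant_qpcr: int = 12
    n_patients: int = 28
    hazard_coef: float = 0.8
    baseline_hazard: float = 0.02
    censor_month: float = 76.0

    def __post_init__(self) -> None:
        if not (self.gain_threshold > 0 > self.loss_threshold):
            raise ValueError("gain_threshold must be > 0 > loss_threshold")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not 0 < self.min_frequency <= 1:
            raise ValueError("min_frequency must be in (0, 1]")
        for name in ("p_cutoff", "fdr_cutoff", "de_fraction", "db_agreement"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.consensus_min_dbs not in (1, 2, 3):
            raise ValueError("consensus_min_dbs must be 1, 2 or 3")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# interval files


def read_bed_like(path: str | Path, dialect: str = "one_based_tsv") -> list[tuple[str, GenomicInterval]]:
    """Read (name, interval) rows from a BED-like file.

    Columns: chrom, start, stop[, name]; a header line is required for the
    TSV dialect and forbidden for BED.  The BED dialect converts 0-based
    half-open coordinates to 1-based inclusive (start+1, stop unchanged).
    """
    if dialect not in ("bed", "one_based_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start_line = 0
    if dialect == "one_based_tsv":
        start_line = 1  # header
    for lineno, line in enumerate(lines[start_line:], start=start_line + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        chrom, start_s, stop_s = parts[:3]
        name = parts[3] if len(parts) > 3 else ""
        try:
            start, stop = int(start_s), int(stop_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if dialect == "bed":
            start += 1
        out.append((name, GenomicInterval(chrom, start, stop)))
    return out


def write_intervals(path: str | Path, items: list[tuple[str, GenomicInterval]]) -> None:
    """Write (name, interval) rows in the 1-based TSV dialect."""
    df = pd.DataFrame(
        [(iv.chromosome, iv.start, iv.stop, name) for name, iv in items],
        columns=["chrom", "start", "stop", "name"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, GenomicInterval]:
    """Feature annotations: TSV with chrom, start, stop, name columns."""
    return {name: iv for name, iv in read_bed_like(path)}


# ---------------------------------------------------------------------------
# probe tracks


def write_probe_tracks(path: str | Path, tracks: dict[str, pd.DataFrame]) -> None:
    frames = []
    for case_id in sorted(tracks):
        df = tracks[case_id].copy()
        df.insert(0, "case_id", case_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_probe_tracks(path: str | Path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    required = {"case_id", "chrom", "start", "stop", "log2_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {
        str(case): grp.drop(columns="case_id").reset_index(drop=True)
        for case, grp in df.groupby("case_id", sort=True)
    }


# ---------------------------------------------------------------------------
# expression


def write_expression(path: str | Path, groups_path: str | Path, matrix: ExpressionMatrix) -> None:
    df = matrix.counts.copy()
    df.insert(0, "feature_class", matrix.feature_class)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")
    matrix.groups.rename_axis("sample_id").to_frame().to_csv(groups_path, sep="\t")


def read_expression(path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    df.index.name = None
    groups = pd.read_csv(groups_path, sep="\t", index_col="sample_id")["group"]
    groups.index.name = None
    feature_class = df.pop("feature_class")
    return ExpressionMatrix(counts=df, feature_class=feature_class, groups=groups)


# ---------------------------------------------------------------------------
# target tables


def write_target_tables(paths: list[str | Path], tables: list[pd.DataFrame]) -> None:
    for path, table in zip(paths, tables):
        table.to_csv(path, sep="\t", index=False)


def read_target_tables(paths: list[str | Path]) -> list[pd.DataFrame]:
    tables = []
    for path in paths:
        df = pd.read_csv(path, sep="\t")
        if not {"mirna_id", "gene_id"} <= set(df.columns):
            raise ValueError(f"{path}: expected mirna_id and gene_id columns")
        tables.append(df)
    return tables


# ---------------------------------------------------------------------------
# qPCR and clinical


def write_ct_records(path: str | Path, records: list[CtRecord]) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "tissue": r.tissue,
            "target_id": r.target_id,
            "rep1": r.target_ct[0],
            "rep2": r.target_ct[1],
            "rep3": r.target_ct[2],
            "ref_rep1": r.reference_ct[0],
            "ref_rep2": r.reference_ct[1],
            "ref_rep3": r.reference_ct[2],
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ct_records(path: str | Path) -> list[CtRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CtRecord(
            sample_id=row["sample_id"],
            tissue=row["tissue"],
            target_id=row["target_id"],
            target_ct=(row["rep1"], row["rep2"], row["rep3"]),
            reference_ct=(row["ref_rep1"], row["ref_rep2"], row["ref_rep3"]),
        )
        for _, row in df.iterrows()
    ]


def write_clinical(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
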