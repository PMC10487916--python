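"""Count normalization, differential expression and clustering.

Implements the three-step normalization used for hybridization-counting
(NanoString-style) miRNA panels — background subtraction against the
negative-control geometric mean, positive-control scaling, and codeset
content scaling against all endogenous features — followed by per-feature
two-sample t-tests with Benjamini–Hochberg FDR control and correlation-based
average-linkage hierarchical clustering of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

FEATURE_CLASSES = ("endogenous", "negative_control", "positive_control", "housekeeping")


@dataclass
class ExpressionMatrix:
    """Counts (features × samples) with per-row class and per-sample group.

    ``feature_class`` assigns each row one of endogenous / negative_control /
    positive_control / housekeeping; ``groups`` labels each sample column
    "case" or "control".  Normalization requires at least one negative and
    one positive control row.
    """

    counts: pd.DataFrame
    feature_class: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.feature_class.index):
            raise ValueError("feature_class index must match counts rows")
        if not set(self.counts.columns) == set(self.groups.index):
            raise ValueError("groups index must match counts columns")
        bad = set(self.feature_class) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be nonnegative")

    def rows(self, cls: str) -> pd.DataFrame:
        return self.counts.loc[self.feature_class == cls]

    @property
    def endogenous(self) -> pd.DataFrame:
        return self.rows("endogenous")


@dataclass(frozen=True)
class DeRecord:
    """One feature's differential-expression result (case minus control)."""

    feature_id: str
    log2_fc: float
    p_value: float
    fdr: float

    @property
    def direction(self) -> str:
        return "up" if self.log2_fc > 0 else "down"


def _gmean_positive(frame: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean; zero counts contribute as zero product."""
    return pd.Series(stats.gmean(np.asarray(frame, dtype=float), axis=0), index=frame.columns)


def normalize(matrix: ExpressionMatrix, subtract_background: bool = True) -> ExpressionMatrix:
    """Background-subtract and scale a raw count matrix, per sample.

    1. Subtract each sample's negative-control geometric mean from every
       count, flooring at 1 so downstream log transforms stay defined
       (skipped when ``subtract_background`` is False).
    2. Scale each sample by (grand mean of per-sample positive-control
       geometric means) / (this sample's positive-control geometric mean).
    3. Repeat the scaling of step 2 with all endogenous features as the
       reference set (codeset content normalization).

    The content factor of step 3 is not applied to the positive-control rows,
    so re-running steps 2–3 on the output is a no-op: both reference sets
    already have equal per-sample geometric means.
    """
    neg = matrix.rows("negative_control")
    pos = matrix.rows("positive_control")
    if neg.empty or pos.empty:
        raise ValueError("normalization requires negative and positive control rows")

    if subtract_background:
        background = _gmean_positive(neg)
        floored = (matrix.counts - background).clip(lower=1.0)
    else:
        floored = matrix.counts.astype(float)

    pos_g = _gmean_positive(floored.loc[pos.index])
    if (pos_g == 0).any():
        bad = pos_g.index[pos_g == 0].tolist()
        raise ValueError(f"zero positive-control geometric mean in samples: {bad}")
    pos_factor = pos_g.mean() / pos_g
    scaled = floored * pos_factor

    endo_mask = matrix.feature_class == "endogenous"
    endo_g = _gmean_positive(scaled.loc[endo_mask])
    content_factor = endo_g.mean() / endo_g
    is_pos = matrix.feature_class == "positive_control"
    out = scaled.mul(content_factor, axis=1)
    out.loc[is_pos] = scaled.loc[is_pos]
    return replace(matrix, counts=out)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: ExpressionMatrix,
    p_cutoff: float = 0.01,
    fdr_cutoff: float = 0.05,
    test: Literal["student", "welch"] = "student",
) -> tuple[list[DeRecord], list[DeRecord]]:
    """Per-feature two-sample t-test on log2 normalized endogenous counts.

    Values are log2(x + 1) transformed.  log2 fold change is
    mean(case) − mean(control); positive means higher in cases.  BH-FDR is
    computed across all endogenous features; the significant subset applies
    the dual cutoff p < ``p_cutoff`` and FDR < ``fdr_cutoff``.  Features with
    zero variance in both groups and equal means get p = 1 by convention.

    Returns (all records, significant subset), each ordered as in the matrix.
    """
    groups = matrix.groups
    case_ids = groups.index[groups == "case"]
    ctrl_ids = groups.index[groups == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("each group needs at least 2 samples")

    endo = matrix.endogenous
    log2 = np.log2(np.asarray(endo, dtype=float) + 1.0)
    a = log2[:, [endo.columns.get_loc(s) for s in case_ids]]
    b = log2[:, [endo.columns.get_loc(s) for s in ctrl_ids]]

    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    _, p = stats.ttest_ind(a, b, axis=1, equal_var=(test == "student"))
    # degenerate rows: no variance anywhere -> t undefined; p=1 if means equal
    p = np.where(np.isnan(p), np.where(log2_fc == 0, 1.0, 0.0), p)
    fdr = bh_fdr(p)

    records = [
        DeRecord(fid, float(fc), float(pv), float(q))
        for fid, fc, pv, q in zip(endo.index, log2_fc, p, fdr)
    ]
    significant = [r for r in records if r.p_value < p_cutoff and r.fdr < fdr_cutoff]
    return records, significant


def hierarchical_cluster(
    matrix: ExpressionMatrix, features: list[str]
) -> tuple[np.ndarray, list[str], str]:
    """Average-linkage clustering of samples on 1 − Pearson r distances.

    ``features`` selects the (normalized, typically significant) rows used to
    correlate samples.  Returns the SciPy linkage matrix, the leaf order as
    sample ids, and a Newick serialization of the dendrogram with merge
    heights as branch lengths.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 features to correlate samples")
    sub = np.log2(np.asarray(matrix.counts.loc[features], dtype=float) + 1.0)
    samples = list(matrix.counts.columns)
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sds = sub.std(axis=0)
    if (sds == 0).any():
        bad = [samples[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero variance across features in samples: {bad}")

    corr = np.corrcoef(sub.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaf_order = [samples[i] for i in hierarchy.leaves_list(linkage)]
    return linkage, leaf_order, _linkage_to_newick(linkage, samples)


def _linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick string."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = linkage[i - n]
        left, right = node(int(a)), node(int(b))
        bl_a = h - heights[int(a)]
        bl_b = h - heights[int(b)]
        heights[i] = h
        return f"({left}:{bl_a:.6g},{right}:{bl_b:.6g})"

    return node(n + len(linkage) - 1) + ";"
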