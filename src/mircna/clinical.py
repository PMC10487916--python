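"""Validation-layer statistics for RT-qPCR and clinical data.

Covers relative quantification from cycle thresholds (2^-ddCt with the
assay's Ct exclusion limits), ROC/AUC discrimination between tumor and
adjacent non-tumor tissue with a bootstrap confidence interval, a combined
multi-miRNA score, dichotomized clinical associations (Welch t-test, with a
multivariate linear-regression option), and Kaplan–Meier survival with a
two-group log-rank test on a median expression split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from sklearn.metrics import roc_auc_score, roc_curve

# Ct exclusion limits: reference (small-RNA normalizer) and target assays.
REFERENCE_CT_LIMIT = 31.0
TARGET_CT_LIMIT = 35.0

# Default dichotomization cutpoints for the continuous clinical variables.
DEFAULT_CUTPOINTS = {
    "age": 55.5,
    "tumor_size": 1.7,
    "bmi": 28.3,
    "ki67": 10.0,
    "p53": 10.0,
}


@dataclass(frozen=True)
class CtRecord:
    """Triplicate cycle thresholds for one sample/target pair."""

    sample_id: str
    tissue: str  # tumor | ANT
    target_id: str
    target_ct: tuple[float, float, float]
    reference_ct: tuple[float, float, float]

    def __post_init__(self) -> None:
        for reps, label in ((self.target_ct, "target"), (self.reference_ct, "reference")):
            if len(reps) != 3 or any(r is None or np.isnan(r) for r in reps):
                raise ValueError(
                    f"sample {self.sample_id}: {label} Ct requires 3 replicates"
                )
            if any(r <= 0 for r in reps):
                raise ValueError(f"sample {self.sample_id}: Ct values must be positive")


@dataclass(frozen=True)
class RqResult:
    sample_id: str
    target_id: str
    excluded: bool
    reason: str | None = None
    delta_ct: float | None = None
    rq: float | None = None


def relative_quantity(record: CtRecord, calibrator_delta_ct: float) -> RqResult:
    """2^-ddCt relative quantification with Ct exclusion rules.

    Replicates are averaged per channel.  A record is excluded when the
    reference mean Ct is >= 31 or the target mean Ct is >= 35 (boundary
    values excluded).  Otherwise dCt = target - reference,
    ddCt = dCt - calibrator dCt, RQ = 2^-ddCt.
    """
    target_mean = float(np.mean(record.target_ct))
    ref_mean = float(np.mean(record.reference_ct))
    if ref_mean >= REFERENCE_CT_LIMIT:
        return RqResult(record.sample_id, record.target_id, True, "reference Ct >= 31")
    if target_mean >= TARGET_CT_LIMIT:
        return RqResult(record.sample_id, record.target_id, True, "target Ct >= 35")
    delta_ct = target_mean - ref_mean
    ddct = delta_ct - calibrator_delta_ct
    return RqResult(
        record.sample_id, record.target_id, False, None, delta_ct, float(2.0 ** (-ddct))
    )


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray


def roc_auc(
    scores,
    labels,
    positive_label: str = "tumor",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> RocResult:
    """AUC with the positive class scoring high, plus a bootstrap 95% CI.

    The AUC is the Mann–Whitney probability that a random positive outscores
    a random negative, ties counting one half (equivalently the trapezoidal
    area under the empirical ROC curve).  The CI is the 2.5/97.5 percentile
    interval over seeded bootstrap resamples of the sample set; resamples
    with a single class are redrawn implicitly by being skipped.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lab == positive_label else 0 for lab in labels])
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thr = roc_curve(y, scores)

    rng = np.random.default_rng(seed)
    boots = []
    n = len(scores)
    while len(boots) < n_bootstrap:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.all() or not yb.any():
            continue
        boots.append(roc_auc_score(yb, scores[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(auc, float(lo), float(hi), thr, tpr, fpr)


def combine_scores(expression: pd.DataFrame) -> pd.Series:
    """Unweighted mean of per-feature z-scores (rows features, cols samples).

    Gives each miRNA equal weight on a common scale; a zero-variance feature
    cannot be standardized and is an error.
    """
    values = np.asarray(expression, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("combined score needs at least 2 features")
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = [expression.index[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance features: {bad}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.Series(z.mean(axis=0), index=expression.columns)


@dataclass(frozen=True)
class AssociationResult:
    variable: str
    cutpoint: float | None
    n: int
    mean_high: float
    mean_low: float
    p_value: float


def associate(
    expression: pd.Series,
    clinical: pd.DataFrame,
    variable: str,
    cutpoint: float | None = None,
) -> AssociationResult:
    """Welch two-sample t-test of expression between dichotomized strata.

    Continuous variables are split at ``cutpoint`` (default per-variable:
    age 55.5, tumour size 1.7 cm, BMI 28.3, Ki-67 and p53 10%), with the
    "high" stratum strictly above the cutpoint.  Boolean or two-level
    categorical variables use their levels directly.
    """
    aligned = clinical.set_index("patient_id").loc[expression.index]
    col = aligned[variable]
    if cutpoint is None and variable in DEFAULT_CUTPOINTS:
        cutpoint = DEFAULT_CUTPOINTS[variable]
    if cutpoint is not None:
        high_mask = col > cutpoint
    else:
        levels = sorted(col.unique(), key=str)
        if len(levels) != 2:
            raise ValueError(f"variable {variable} is not two-level and has no cutpoint")
        high_mask = col == levels[1]

    high = expression[high_mask.to_numpy()]
    low = expression[~high_mask.to_numpy()]
    if len(high) < 2 or len(low) < 2:
        raise ValueError(f"stratum of size < 2 for variable {variable}")
    t, p = stats.ttest_ind(high, low, equal_var=False)
    return AssociationResult(
        variable=variable,
        cutpoint=cutpoint,
        n=len(expression),
        mean_high=float(high.mean()),
        mean_low=float(low.mean()),
        p_value=float(p),
    )


def multivariate_association(
    expression: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """OLS of expression on clinical covariates with per-coefficient t-tests.

    Boolean and two-level categorical covariates are 0/1 encoded.  Returns a
    table with coefficient, standard error, t and p per covariate (plus the
    intercept).  A rank-deficient design is rejected with the offending
    columns named.
    """
    X = covariates.copy()
    for col in X.columns:
        if X[col].dtype == bool:
            X[col] = X[col].astype(float)
        elif X[col].dtype == object:
            levels = sorted(X[col].unique(), key=str)
            if len(levels) > 2:
                raise ValueError(f"covariate {col} has more than two levels")
            X[col] = (X[col] == levels[-1]).astype(float)
    X = X.astype(float)
    if len(expression) <= X.shape[1] + 1:
        raise ValueError("need more observations than covariates + 1")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        collinear = _collinear_columns(design)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    fit = sm.OLS(np.asarray(expression, dtype=float), design).fit()
    return pd.DataFrame(
        {
            "coef": fit.params,
            "stderr": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
        }
    )


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    cols: list[str] = []
    kept: list[int] = []
    mat = design.to_numpy()
    for j in range(mat.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(mat[:, trial]) < len(trial):
            cols.append(str(design.columns[j]))
        else:
            kept.append(j)
    return cols


def median_split(values) -> list[str]:
    """Label values 'high' when strictly above the median, else 'low'."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("median split needs at least 2 values")
    med = np.median(arr)
    labels = ["high" if v > med else "low" for v in arr]
    if all(lab == "low" for lab in labels):
        warnings.warn("all values at or below the median; split is degenerate")
    return labels


@dataclass
class KmLogrankResult:
    statistic: float
    p_value: float
    event_table: pd.DataFrame  # per event time: at-risk, observed, expected
    curves: dict[str, pd.DataFrame]  # group -> (time, survival)


def km_logrank(clinical: pd.DataFrame, group_labels) -> KmLogrankResult:
    """Kaplan–Meier curves per group and the two-group log-rank test.

    Deaths are records with status "deceased" at their follow-up time; all
    others are censored.  The log-rank chi-square (1 df) is computed from the
    observed and hypergeometric-expected event counts over the pooled risk
    sets at each distinct event time; the per-time tabulation is returned for
    inspection.
    """
    labels = pd.Series(list(group_labels), index=clinical.index)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    time = clinical["follow_up"].to_numpy(dtype=float)
    event = (clinical["status"] == "deceased").to_numpy()
    if (time == 0).all() and not event.any():
        raise ValueError("all records censored at time 0")

    g1 = (labels == groups[0]).to_numpy()
    event_times = np.unique(time[event])
    rows = []
    stat_num = 0.0
    var_sum = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & g1).sum()
        expected1 = d * n1 / n
        if n > 1:
            var_sum += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        stat_num += d1 - expected1
        rows.append(
            {
                "time": t,
                "at_risk": int(n),
                f"at_risk_{groups[0]}": int(n1),
                "events": int(d),
                f"observed_{groups[0]}": int(d1),
                f"expected_{groups[0]}": expected1,
            }
        )
    if var_sum > 0:
        statistic = stat_num**2 / var_sum
        p = float(stats.chi2.sf(statistic, df=1))
    else:
        statistic, p = 0.0, 1.0

    curves = {}
    for g in groups:
        mask = (labels == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(g))
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return KmLogrankResult(
        statistic=float(statistic),
        p_value=p,
        event_table=pd.DataFrame(rows),
        curves=curves,
    )
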