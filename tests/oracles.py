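"""Deliberately naive reference implementations used as independent oracles.

Everything here favours obviousness over speed: exhaustive window scans,
explicit pair counting, literal definitions.  These functions never share
code with the package under test.
"""

from __future__ import annotations

import numpy as np


def enumerate_runs(log2, min_probes, gain_threshold, loss_threshold):
    """All maximal qualifying runs by exhaustive window checking, O(n^2).

    Returns (start_index, end_index_inclusive, direction) tuples in scan
    order for one chromosome's probe vector.
    """
    n = len(log2)
    runs = []
    for direction, ok in (
        ("gain", lambda v: v >= gain_threshold),
        ("loss", lambda v: v <= loss_threshold),
    ):
        for i in range(n):
            for j in range(i, n):
                if not all(ok(log2[k]) for k in range(i, j + 1)):
                    continue
                maximal = (i == 0 or not ok(log2[i - 1])) and (
                    j == n - 1 or not ok(log2[j + 1])
                )
                if maximal and j - i + 1 >= min_probes:
                    runs.append((i, j, direction))
    runs.sort()
    return runs


def auc_pair_count(scores, labels, positive="tumor"):
    """Mann–Whitney AUC by explicit pair enumeration, ties counting half."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bh_stepup(p_values):
    """BH adjusted p-values straight from the definition.

    adjusted(i) = min over j with p(j) >= p(i) of m * p(j) / rank(j), capped
    at 1, computed via the sorted step-up form.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    for pos, idx in enumerate(order):
        rank = pos + 1
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(pos, m)
        ]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


def logrank_tabulation(times, events, in_group1):
    """Two-group log-rank by literal risk-set tabulation with Python loops.

    Returns (rows, statistic, variance_sum) where rows hold, per distinct
    event time: n at risk, n at risk in group 1, events, observed events in
    group 1, expected events in group 1.
    """
    records = list(zip(times, events, in_group1))
    event_times = sorted({t for t, e, _ in records if e})
    rows = []
    num = 0.0
    var = 0.0
    for t in event_times:
        at_risk = [r for r in records if r[0] >= t]
        n = len(at_risk)
        n1 = sum(1 for r in at_risk if r[2])
        d = sum(1 for r in records if r[0] == t and r[1])
        d1 = sum(1 for r in records if r[0] == t and r[1] and r[2])
        e1 = d * n1 / n
        rows.append((t, n, n1, d, d1, e1))
        num += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    statistic = num**2 / var if var > 0 else 0.0
    return rows, statistic, var


def average_linkage_heights(dist):
    """Merge heights of naive UPGMA agglomeration on a distance matrix."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = np.mean([[dist[i, j] for j in clusters[b]] for i in clusters[a]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


def consensus_2of3(tables, min_dbs=2):
    """Per-(miRNA, gene) membership count over three tables, kept if >= min."""
    out = {}
    pairs = set()
    for t in tables:
        for m, g in zip(t["mirna_id"], t["gene_id"]):
            pairs.add((m, g))
    for m, g in pairs:
        n = sum(
            (m, g) in set(zip(t["mirna_id"], t["gene_id"])) for t in tables
        )
        if n >= min_dbs:
            out.setdefault(m, set()).add(g)
    return out


def welch_t_p(x, y):
    """Welch statistic and Satterthwaite df evaluated from the formulas."""
    import math
    from scipy import stats as st

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * st.t.sf(abs(t), df)
    return t, p
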