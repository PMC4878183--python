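"""Statistical procedures for condition comparisons.

Per-cell fluorescence readouts of macrophage responses are heterogeneous
(some cells respond vigorously, others not at all), so the primary
two-group comparison is the Wilcoxon rank-sum test; Student's t-test is
provided for normally distributed readouts. Measurements acquired on
different days are made comparable by dividing each day's values by that
day's control median before pooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stack import ContractError

EXACT_LIMIT = 12  # full enumeration up to n_a + n_b of this size


class NormalizationError(ContractError):
    """Day normalization is impossible (missing or zero control median)."""


def day_normalize(
    table: pd.DataFrame,
    value_col: str = "value",
    condition_col: str = "condition",
    day_col: str = "day",
    metric_col: str | None = "metric",
    control_label: str = "control",
) -> pd.DataFrame:
    """Normalize each day's values to that day's control median, per metric.

    Returns a copy of the table with ``value_col`` divided by the matching
    day (and metric) control median. Raises :class:`NormalizationError`
    naming the day when a control median is missing or zero.
    """
    out = table.copy()
    group_cols = [day_col] if metric_col is None or metric_col not in table.columns else [day_col, metric_col]
    for key, idx in out.groupby(group_cols, sort=False).groups.items():
        sub = out.loc[idx]
        controls = sub.loc[sub[condition_col] == control_label, value_col]
        day = key[0] if isinstance(key, tuple) else key
        if controls.empty:
            raise NormalizationError(f"day {day!r}: no control rows to normalize against")
        med = float(controls.median())
        if med == 0:
            raise NormalizationError(f"day {day!r}: control median is zero")
        out.loc[idx, value_col] = sub[value_col] / med
    return out


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test: str
    n_a: int
    n_b: int


def _tie_corrected_sigma(ranks: np.ndarray, n_a: int, n_b: int) -> float:
    n = n_a + n_b
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return float(np.sqrt(max(var, 0.0)))


def rank_sum_test(a, b, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    The statistic is W, the sum of midranks of sample ``a`` in the pooled
    ordering. For ``n_a + n_b <= 12`` (or ``mode='exact'``) the two-sided p
    is computed by full enumeration of all C(n, n_a) assignments of the
    pooled midranks, conditioning on the observed ties:
    ``p = P(|W' - mu| >= |W - mu|)`` with ``mu = n_a (n+1) / 2`` (the
    permutation distribution of W is symmetric about mu, also under ties).
    Larger samples use the normal approximation with tie-corrected variance
    and a 0.5 continuity correction.

    Identical values across both samples give p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ContractError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks for ties
    w = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0

    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both samples; rank-sum p = 1")
        return TestResult(w, 1.0, "ranksum-degenerate", n_a, n_b)

    if mode not in ("auto", "exact", "normal"):
        raise ContractError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_LIMIT)

    if use_exact:
        if n > 16:
            raise ContractError(f"exact enumeration limited to n_a+n_b <= 16, got {n}")
        obs_dev = abs(w - mu) - 1e-9
        hits = 0
        for idx in combinations(range(n), n_a):
            w_perm = ranks[list(idx)].sum()
            if abs(w_perm - mu) >= obs_dev:
                hits += 1
        p = hits / comb(n, n_a)
        return TestResult(w, float(p), "ranksum-exact", n_a, n_b)

    sigma = _tie_corrected_sigma(ranks, n_a, n_b)
    if sigma == 0:
        warnings.warn("zero rank variance (heavy ties); rank-sum p = 1")
        return TestResult(w, 1.0, "ranksum-degenerate", n_a, n_b)
    # continuity correction shrinks the deviation toward the mean
    dev = max(abs(w - mu) - 0.5, 0.0)
    z = dev / sigma
    p = 2.0 * sps.norm.sf(z)
    return TestResult(w, float(min(p, 1.0)), "ranksum-normal", n_a, n_b)


def t_test(a, b) -> TestResult:
    """Two-sided pooled-variance Student's t-test.

    Degenerate samples (zero pooled variance) give p = 1 when the means are
    equal and p = 0 with a warning otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ContractError("t-test requires n >= 2 per sample")
    n_a, n_b = a.size, b.size
    sp2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n_a + n_b - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TestResult(0.0, 1.0, "t-degenerate", n_a, n_b)
        warnings.warn("zero pooled variance with unequal means; t-test p -> 0")
        return TestResult(float(np.sign(diff) * np.inf), 0.0, "t-degenerate", n_a, n_b)
    t = diff / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * sps.t.sf(abs(t), df=n_a + n_b - 2)
    return TestResult(float(t), float(p), "t", n_a, n_b)


def summary_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sd/√n, sample sd with ddof=1)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ContractError("SEM requires n >= 2")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def compare_conditions(
    table: pd.DataFrame,
    metric: str | None = None,
    group_a: str = "treatment",
    group_b: str = "control",
    test: str = "ranksum",
    value_col: str = "value",
    condition_col: str = "condition",
    metric_col: str = "metric",
    normalized: bool = False,
) -> pd.DataFrame:
    """Two-group comparison report over a measurement table.

    Runs the requested test per metric (or the single given metric) and
    returns one report row per metric: metric, n_a, n_b, statistic, p,
    test_used, normalized.
    """
    if metric is not None:
        metrics = [metric]
    elif metric_col in table.columns:
        metrics = list(table[metric_col].unique())
    else:
        metrics = [None]
    rows = []
    for m in metrics:
        sub = table if m is None else table[table[metric_col] == m]
        va = sub.loc[sub[condition_col] == group_a, value_col].to_numpy()
        vb = sub.loc[sub[condition_col] == group_b, value_col].to_numpy()
        res = rank_sum_test(va, vb) if test == "ranksum" else t_test(va, vb)
        rows.append(
            {
                "metric": m,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "statistic": res.statistic,
                "p": res.p_value,
                "test_used": res.test,
                "normalized": normalized,
            }
        )
    return pd.DataFrame(rows)
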