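"""Group-comparison statistics: chi-squared homogeneity, two-sample t,
percent-reduction summaries, iterative Grubbs outlier flagging and
ROI-pooled fraction summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import sem
from .neighborhood import TestResult


@dataclass(frozen=True)
class PercentChangeSummary:
    per_brain_percent: np.ndarray
    mean_percent: float
    sem_percent: float
    method: str


@dataclass(frozen=True)
class FractionSummary:
    """Per-nucleus double-positive fractions, pooled over ROIs per brain."""

    per_brain: pd.DataFrame  # columns: brain_id, nucleus, n_double, n_total, fraction
    per_nucleus: pd.DataFrame  # index nucleus: pooled counts, mean, sem, n_brains


def _validate_table(table: np.ndarray) -> np.ndarray:
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero row")
    if (obs.sum(axis=0) == 0).any():
        raise ValueError("contingency table has an all-zero column")
    return obs


def chi2_homogeneity(
    table: np.ndarray | pd.DataFrame, use_proportions: bool = False
) -> TestResult:
    """Chi-squared test of homogeneity on a groups × regions count table.

    Expected counts come from the row/column marginals; df =
    (rows−1)(cols−1); the p-value is the upper tail of the chi-squared
    distribution.  ``use_proportions`` rescales each row to sum to 100
    (relative cell numbers) before testing — a fidelity-comparison mode,
    not the default, since counts preserve the sampling theory.
    """
    obs = _validate_table(
        table.to_numpy() if isinstance(table, pd.DataFrame) else table
    )
    if use_proportions:
        obs = obs / obs.sum(axis=1, keepdims=True) * 100.0
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must all be > 0")
    return TestResult(statistic=float(chi2), p_value=float(p), df=float(df))


def ttest_two_sample(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    equal_var: bool = True,
) -> TestResult:
    """Unpaired two-sample two-tailed t-test (pooled variance by default;
    ``equal_var=False`` gives Welch's variant)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
    )


def percent_change(
    reference: Sequence[float],
    test: Sequence[float],
    method: str = "per_brain",
) -> PercentChangeSummary:
    """Percent reduction of the test group relative to the reference mean.

    ``per_brain`` (default): reduction_i = 1 − test_i / mean(reference) for
    each test brain, summarised as mean ± SEM of the per-brain percentages.
    ``ratio_of_means``: 1 − mean(test)/mean(reference), with a delta-method
    SEM propagated from the two group SEMs.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if len(ref) < 1 or len(tst) < 1:
        raise ValueError("each group needs n >= 1")
    mref = ref.mean()
    if mref == 0:
        raise ValueError("reference mean is 0; percent change undefined")
    if method == "per_brain":
        reductions = (1.0 - tst / mref) * 100.0
        return PercentChangeSummary(
            per_brain_percent=reductions,
            mean_percent=float(reductions.mean()),
            sem_percent=sem(reductions),
            method=method,
        )
    if method == "ratio_of_means":
        mtst = tst.mean()
        reduction = (1.0 - mtst / mref) * 100.0
        se_ref = sem(ref)
        se_tst = sem(tst)
        var = (se_tst / mref) ** 2 + (mtst * se_ref / mref**2) ** 2
        return PercentChangeSummary(
            per_brain_percent=np.array([reduction]),
            mean_percent=float(reduction),
            sem_percent=float(np.sqrt(var) * 100.0),
            method=method,
        )
    raise ValueError(f"unknown method {method!r}")


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha) from the t quantile."""
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))


def grubbs_outliers(
    values: Sequence[float], alpha: float = 0.05
) -> list[int]:
    """Iterative two-sided Grubbs test; returns original indices of outliers.

    Repeatedly computes G = max|x − mean| / SD on the remaining values,
    flags and removes the extreme point while G exceeds the critical value,
    and stops otherwise (or when fewer than 3 values remain).  All-equal
    input yields no outliers.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Grubbs test needs n >= 3")
    if not 0 < alpha <= 0.2:
        raise ValueError("alpha must be in (0, 0.2]")
    remaining = list(range(len(x)))
    flagged: list[int] = []
    while len(remaining) >= 3:
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i_max = int(dev.argmax())
        g = dev[i_max] / sd
        if g <= grubbs_critical_value(len(sub), alpha):
            break
        flagged.append(remaining.pop(i_max))
    return sorted(flagged)


def roi_fraction_summary(roi_counts: pd.DataFrame) -> FractionSummary:
    """Pool ROI counts within (brain, nucleus), then summarise across brains.

    ``roi_counts`` columns: ``brain_id, nucleus, roi, n_double, n_single``.
    Per (brain, nucleus) the double- and single-positive counts are summed
    over ROIs before dividing — fraction = Σdouble / (Σdouble + Σsingle) —
    so the result is invariant to ROI order and to splitting a ROI in two.
    """
    required = {"brain_id", "nucleus", "roi", "n_double", "n_single"}
    missing = required - set(roi_counts.columns)
    if missing:
        raise ValueError(f"roi_counts missing columns: {sorted(missing)}")
    pooled = (
        roi_counts.groupby(["brain_id", "nucleus"], sort=True)[["n_double", "n_single"]]
        .sum()
        .reset_index()
    )
    pooled["n_total"] = pooled["n_double"] + pooled["n_single"]
    zero = pooled[pooled["n_total"] == 0]
    if len(zero):
        pair = zero.iloc[0]
        raise ValueError(
            f"pooled total is 0 for brain {pair['brain_id']!r}, "
            f"nucleus {pair['nucleus']!r}"
        )
    pooled["fraction"] = pooled["n_double"] / pooled["n_total"]
    rows = []
    for nucleus, sub in pooled.groupby("nucleus", sort=True):
        fr = sub["fraction"].to_numpy()
        rows.append(
            {
                "nucleus": nucleus,
                "pooled_double": int(sub["n_double"].sum()),
                "pooled_total": int(sub["n_total"].sum()),
                "mean": fr.mean(),
                "sem": sem(fr),
                "n_brains": len(fr),
            }
        )
    return FractionSummary(
        per_brain=pooled,
        per_nucleus=pd.DataFrame(rows).set_index("nucleus"),
    )
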