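"""Fluorescence-assay reducer calling.

A strain is scored by the ratio of its mean fluorescence to the mean of an
abiotic medium control; ratios strictly above 5 call the strain a bilirubin
reducer. Supporting statistics are Welch two-sample t-tests on
log2-transformed raw fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PhenotypeCall",
    "fluorescence_ratio",
    "call_reducer",
    "log2_t_test",
    "call_table",
]

REDUCER_RATIO_THRESHOLD = 5.0


@dataclass(frozen=True)
class PhenotypeCall:
    strain_id: str
    ratio: float
    is_reducer: bool
    threshold: float = REDUCER_RATIO_THRESHOLD
    p_value: float | None = None

    def __post_init__(self):
        if self.is_reducer != (self.ratio > self.threshold):
            raise ValueError("is_reducer must equal (ratio > threshold)")


def fluorescence_ratio(sample_values, control_values, center: str = "mean") -> float:
    """Ratio of sample fluorescence to the abiotic control.

    Uses means of replicates by default (``center="median"`` available).
    """
    sample = np.asarray(sample_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if sample.size == 0 or control.size == 0:
        raise ValueError("sample and control value lists must be non-empty")
    agg = np.mean if center == "mean" else np.median
    c = float(agg(control))
    if c <= 0:
        raise ValueError("control center must be positive")
    return float(agg(sample)) / c


def call_reducer(ratio: float, threshold: float = REDUCER_RATIO_THRESHOLD) -> bool:
    """True iff ratio is strictly above the threshold (default 5)."""
    if ratio < 0:
        raise ValueError("fluorescence ratio cannot be negative")
    return ratio > threshold


def log2_t_test(
    group_a,
    group_b,
    alternative: str = "greater",
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test on log2-transformed values.

    Welch (unequal variance) by default. Returns ``(t, p, df)``; with
    ``alternative="greater"`` the p-value is P(T >= t).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("all values must be positive to log2-transform")
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    la, lb = np.log2(a), np.log2(b)
    if la.var(ddof=1) == 0 and lb.var(ddof=1) == 0:
        # degenerate replicates: a zero standard error breaks the t ratio
        df = float(a.size + b.size - 2)
        if la.mean() == lb.mean():
            return 0.0, 0.5 if alternative == "greater" else 1.0, df
        t = np.inf if la.mean() > lb.mean() else -np.inf
        p = 1.0 if (alternative == "greater" and t < 0) else 0.0
        return float(t), p, df
    scipy_alt = "greater" if alternative == "greater" else "two-sided"
    res = stats.ttest_ind(la, lb, equal_var=equal_var, alternative=scipy_alt)
    return float(res.statistic), float(res.pvalue), float(res.df)


def call_table(
    measurements: dict[str, list[float]],
    control_values,
    threshold: float = REDUCER_RATIO_THRESHOLD,
    with_p: bool = True,
) -> list[PhenotypeCall]:
    """Call every strain in a measurement table against one abiotic control."""
    calls = []
    for strain in sorted(measurements):
        values = measurements[strain]
        ratio = fluorescence_ratio(values, control_values)
        p = None
        if with_p and len(values) >= 2 and len(control_values) >= 2:
            _, p, _ = log2_t_test(values, control_values, alternative="greater")
        calls.append(
            PhenotypeCall(
                strain_id=strain,
                ratio=ratio,
                is_reducer=call_reducer(ratio, threshold),
                threshold=threshold,
                p_value=p,
            )
        )
    return calls
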