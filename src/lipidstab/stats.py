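"""Shared two-sample comparison core.

Both the native-MS stabilization assay and the steered-pull work comparison
reduce to a two-sided, two-sample location test on a handful of replicates.
This module wraps that single statistical step so the two assays cannot
drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = ["TwoSampleResult", "two_sample_ttest"]


@dataclass(frozen=True)
class TwoSampleResult:
    """Two-sided two-sample t-test outcome.

    ``delta`` is ``mean(a) - mean(b)`` for the two groups as passed;
    callers define the scientific sign convention.
    """

    delta: float
    t: float
    p: float
    df: float
    n_a: int
    n_b: int
    kind: str

    def summary(self) -> str:
        return (
            f"delta={self.delta:+.4g}  t={self.t:.4g}  p={self.p:.4g}  "
            f"df={self.df:.4g}  n={self.n_a}/{self.n_b}  ({self.kind})"
        )


def two_sample_ttest(a, b, kind: str = "student") -> TwoSampleResult:
    """Two-sided t-test between groups ``a`` and ``b``.

    Parameters
    ----------
    a, b
        Replicate measurements, at least 2 per group.
    kind
        ``"student"`` for the pooled equal-variance test (the conventional
        "two-tailed t-test" of small-n biophysics reporting) or ``"welch"``.

    The degenerate all-constant case (zero variance in both groups) is given
    the convention p=1 when the means are equal and p=0 otherwise, rather
    than propagating a 0/0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("replicate groups must be one-dimensional")
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group for a t-test")
    if kind not in ("student", "welch"):
        raise ValueError(f"unknown test kind: {kind!r}")

    delta = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if delta == 0.0:
            return TwoSampleResult(0.0, 0.0, 1.0, float(a.size + b.size - 2),
                                   a.size, b.size, kind)
        t = np.inf if delta > 0 else -np.inf
        return TwoSampleResult(delta, float(t), 0.0,
                               float(a.size + b.size - 2), a.size, b.size, kind)

    res = _sps.ttest_ind(a, b, equal_var=(kind == "student"))
    return TwoSampleResult(delta, float(res.statistic), float(res.pvalue),
                           float(res.df), a.size, b.size, kind)
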