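"""Two-sample comparison statistics for mutant-vs-control analyses.

A two-sample z-score on group summaries,

    Z = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b),

its one-sided normal p-value ``p = erfc(-Z/sqrt(2))/2``, and the standard
error of a Bernoulli proportion ``SE = sqrt(p(1-p)/N)`` used for
fold-formation frequencies.  Sample standard deviations use the n-1
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erfc

__all__ = [
    "GroupSummary",
    "z_score",
    "one_sided_p",
    "proportion_se",
    "compare_fold_counts",
    "stouffer_combined_p",
]


@dataclass
class GroupSummary:
    """Mean, sample SD (n-1 denominator), and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
        return cls(mean=float(x.mean()), sd=sd, n=len(x))


def z_score(a: GroupSummary, b: GroupSummary) -> float:
    """Two-sample z-score of group ``a`` against group ``b``.

    Antisymmetric under swapping groups.  A zero pooled variance with unequal
    means yields an explicit signed infinity.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    se2 = a.sd**2 / a.n + b.sd**2 / b.n
    diff = a.mean - b.mean
    if se2 == 0:
        if diff == 0:
            return 0.0
        return float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(se2))


def one_sided_p(z: float) -> float:
    """One-sided normal p-value, p = erfc(-Z/sqrt(2))/2; monotone in Z.

    Small p for strongly negative Z (group a below group b).
    """
    if not np.isfinite(z):
        return 1.0 if z > 0 else 0.0  # limits; callers handle inf explicitly
    return float(0.5 * erfc(-z / np.sqrt(2.0)))


def proportion_se(p_hat: float, N: int) -> float:
    """Standard error sqrt(p(1-p)/N) of an observed Bernoulli frequency."""
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError("p_hat must lie in [0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    return float(np.sqrt(p_hat * (1.0 - p_hat) / N))


def compare_fold_counts(
    outcomes_a: pd.DataFrame, outcomes_b: pd.DataFrame
) -> dict:
    """Compare mean fold counts of two outcome tables (column ``folds``).

    Returns mean folds per group, the two-sample Z of a against b, and the
    one-sided p for the hypothesis that group a forms fewer folds.
    """
    fa = np.asarray(outcomes_a["folds"], dtype=float)
    fb = np.asarray(outcomes_b["folds"], dtype=float)
    if len(fa) < 2 or len(fb) < 2:
        raise ValueError("each group needs at least two embryos")
    ga, gb = GroupSummary.from_values(fa), GroupSummary.from_values(fb)
    z = z_score(ga, gb)
    return {
        "mean_a": ga.mean,
        "mean_b": gb.mean,
        "z": z,
        "p": one_sided_p(z),
        "n_a": ga.n,
        "n_b": gb.n,
    }


def stouffer_combined_p(z_values) -> tuple[float, float]:
    """Stouffer combination of per-timepoint z-scores: Z = sum(Z_t)/sqrt(T).

    Returns ``(combined_z, one_sided_p)``; used for sustained differences
    between anisotropy curves sampled at multiple timepoints.
    """
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) == 0:
        raise ValueError("no finite z-scores to combine")
    zc = float(z.sum() / np.sqrt(len(z)))
    return zc, one_sided_p(zc)
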