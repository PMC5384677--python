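"""Effect-size conversions and the two-study fixed-effect comparator.

All inference in :mod:`snapmeta` happens on the Fisher-z scale, where a
sample correlation ``r`` from ``n`` observations is approximately normal
with mean ``atanh(rho)`` and variance ``1/(n - 3)``.  This module converts
the supported input modes (correlation + sample size, t-statistic with
group sizes, or two-group summary statistics) onto that scale and provides
the naive inverse-variance-weighted fixed-effect meta-analysis of a single
original/replication pair, which serves as the uncorrected comparator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "Study",
    "FixedEffectResult",
    "fisher_transform",
    "fisher_se",
    "d_to_r",
    "r_to_d",
    "t_to_d",
    "groups_to_d",
    "fixed_effect_meta",
]


def fisher_transform(r: float) -> float:
    """Fisher z-transform ``atanh(r)`` of a correlation coefficient.

    Parameters
    ----------
    r : float
        Correlation coefficient, ``|r| < 1``.

    Returns
    -------
    float
        The Fisher-z value, approximately normal with variance
        ``1/(n - 3)`` for a sample correlation on ``n`` observations.
    """
    if not abs(r) < 1:
        raise ValueError(f"correlation must satisfy |r| < 1, got {r}")
    return math.atanh(r)


def fisher_se(n: float) -> float:
    """Standard error ``1/sqrt(n - 3)`` of a Fisher-z correlation.

    ``n`` is the *total* sample size of the study and must be at least 4
    so the standard error is finite.
    """
    if n < 4:
        raise ValueError(f"total sample size must be >= 4, got {n}")
    return 1.0 / math.sqrt(n - 3)


def d_to_r(d: float) -> float:
    """Convert a standardized mean difference to a correlation.

    Uses the equal-group-size conversion ``r = d / sqrt(d^2 + 4)``.
    """
    if not math.isfinite(d):
        raise ValueError(f"d must be finite, got {d}")
    return d / math.sqrt(d * d + 4.0)


def r_to_d(r: float) -> float:
    """Inverse of :func:`d_to_r`: ``d = 2 r / sqrt(1 - r^2)``."""
    if not abs(r) < 1:
        raise ValueError(f"correlation must satisfy |r| < 1, got {r}")
    return 2.0 * r / math.sqrt(1.0 - r * r)


def t_to_d(t: float, n1: int, n2: int) -> float:
    """Standardized mean difference from a two-sample t statistic.

    ``d = t * sqrt(1/n1 + 1/n2)`` for group sizes ``n1`` and ``n2``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError(f"group sizes must be >= 2, got ({n1}, {n2})")
    return t * math.sqrt(1.0 / n1 + 1.0 / n2)


def groups_to_d(
    mean1: float, mean2: float, sd1: float, sd2: float, n1: int, n2: int
) -> float:
    """Cohen's d from two-group summaries, using the pooled SD."""
    if n1 < 2 or n2 < 2:
        raise ValueError(f"group sizes must be >= 2, got ({n1}, {n2})")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    pooled = math.sqrt(
        ((n1 - 1) * sd1 * sd1 + (n2 - 1) * sd2 * sd2) / (n1 + n2 - 2)
    )
    return (mean1 - mean2) / pooled


@dataclass(frozen=True)
class Study:
    """One study's effect on the Fisher-z correlation scale.

    Attributes
    ----------
    r : float
        Observed correlation, ``|r| < 1``.
    n : float
        Total sample size (``>= 4``).  May be non-integral when the study
        is reconstructed from a reported standard error.
    theta_hat : float
        ``atanh(r)``, the Fisher-z effect estimate.
    se : float
        ``1/sqrt(n - 3)``, the Fisher-z standard error.
    """

    r: float
    n: float
    theta_hat: float
    se: float

    def __post_init__(self) -> None:
        if not abs(self.r) < 1:
            raise ValueError(f"|r| must be < 1, got {self.r}")
        if self.n < 4:
            raise ValueError(f"n must be >= 4, got {self.n}")
        if self.se <= 0:
            raise ValueError("se must be positive")

    @classmethod
    def from_r_n(cls, r: float, n: float) -> "Study":
        """Build a study from a correlation and its total sample size."""
        return cls(r=r, n=n, theta_hat=fisher_transform(r), se=fisher_se(n))

    @classmethod
    def from_fisher(cls, theta_hat: float, se: float) -> "Study":
        """Build a study directly from Fisher-scale summaries.

        The implied correlation is ``tanh(theta_hat)`` and the implied
        (possibly non-integral) total sample size ``3 + 1/se^2``.
        """
        if se <= 0 or se > 1:
            raise ValueError(f"se must be in (0, 1] (n >= 4), got {se}")
        return cls(
            r=math.tanh(theta_hat),
            n=3.0 + 1.0 / (se * se),
            theta_hat=theta_hat,
            se=se,
        )

    @classmethod
    def from_t(cls, t: float, n1: int, n2: int) -> "Study":
        """Build a study from a two-sample t test (t, group sizes)."""
        return cls.from_r_n(d_to_r(t_to_d(t, n1, n2)), n1 + n2)

    @classmethod
    def from_d(cls, d: float, n: float) -> "Study":
        """Build a study from Cohen's d and the total sample size."""
        return cls.from_r_n(d_to_r(d), n)

    @classmethod
    def from_groups(
        cls, mean1: float, mean2: float, sd1: float, sd2: float, n1: int, n2: int
    ) -> "Study":
        """Build a study from two-group means, SDs, and group sizes."""
        return cls.from_d(groups_to_d(mean1, mean2, sd1, sd2, n1, n2), n1 + n2)

    def p_value(self, two_tailed: bool = True) -> float:
        """Normal-theory p-value of the Fisher-z test against zero effect."""
        z = abs(self.theta_hat) / self.se
        p = stats.norm.sf(z)
        return 2.0 * p if two_tailed else p


@dataclass(frozen=True)
class FixedEffectResult:
    """Inverse-variance-pooled estimate of a study pair.

    ``theta_hat``/``se`` are on the Fisher-z scale; ``r_hat`` and the
    confidence bounds are back-transformed to the correlation scale.
    """

    theta_hat: float
    se: float
    r_hat: float
    ci_low: float
    ci_high: float
    p_two_tailed: float


def fixed_effect_meta(
    original: Study, replication: Study, confidence: float = 0.95
) -> FixedEffectResult:
    """Fixed-effect meta-analysis of an original/replication pair.

    Pools the two Fisher-z estimates by inverse variance, tests the pooled
    estimate against zero with a normal z test, and back-transforms the
    point estimate and Wald interval endpoint-wise with ``tanh``.

    Note that this comparator ignores the selection of the original study
    on statistical significance and therefore overestimates the effect
    when publication bias is present; it is provided as the conventional
    baseline the corrected method is compared against.
    """
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    w_o = 1.0 / (original.se**2)
    w_r = 1.0 / (replication.se**2)
    pooled = (w_o * original.theta_hat + w_r * replication.theta_hat) / (w_o + w_r)
    se = 1.0 / math.sqrt(w_o + w_r)
    z_crit = stats.norm.ppf(0.5 + confidence / 2.0)
    p = 2.0 * stats.norm.sf(abs(pooled) / se)
    return FixedEffectResult(
        theta_hat=pooled,
        se=se,
        r_hat=math.tanh(pooled),
        ci_low=math.tanh(pooled - z_crit * se),
        ci_high=math.tanh(pooled + z_crit * se),
        p_two_tailed=p,
    )
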