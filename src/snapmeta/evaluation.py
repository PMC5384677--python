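"""Deterministic quantile-grid evaluation of the method's operating characteristics.

For a given true correlation ``rho`` and per-study sample size ``n``, the
joint sampling distribution of (significant original effect, replication
effect) is approximated by a G x G grid of equal-probability points:

* the original margin takes G equally spaced *conditional* cumulative
  probabilities of the normal distribution truncated at the one-sided
  critical value (only significant originals are published), mapped through
  the normal quantile function;
* the replication margin takes G equally spaced unconditional cumulative
  probabilities ``k/(G+1)``.

Each of the G^2 combinations carries mass ``1/G^2``.  Applying the
posterior computation to every combination yields expected posterior model
probabilities, the probability that a snapshot's posterior exceeds .25 or
.75, the probability of an inconclusive result (no snapshot above .75) and
the expectation of the correlation-scale fixed-effect estimate.

The evaluation is exact up to grid resolution and fully deterministic; it
is processed in row chunks so the working set stays bounded at the default
G = 5,000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import HYBRID, NAIVE, SnapshotSet, _log_plain_density, _log_truncated_density

__all__ = [
    "EvalCondition",
    "EvalResult",
    "original_quantile_grid",
    "replication_quantile_grid",
    "evaluate_condition",
]


@dataclass(frozen=True)
class EvalCondition:
    """One (true rho, per-study n) evaluation condition.

    ``alpha`` is the two-tailed significance level screened on the original
    study (i.e. one-tailed alpha/2 in the published direction), and
    ``grid_size`` the number of quantile points per margin.
    """

    rho: float
    n: float
    alpha: float = 0.05
    grid_size: int = 5000

    def __post_init__(self) -> None:
        if not -1 < self.rho < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if self.n < 4:
            raise ValueError(f"n must be >= 4, got {self.n}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")

    @property
    def theta(self) -> float:
        return math.atanh(self.rho)

    @property
    def se(self) -> float:
        return 1.0 / math.sqrt(self.n - 3)

    @property
    def theta_cv(self) -> float:
        """One-sided critical Fisher-z value of the alpha-level test."""
        return stats.norm.ppf(1.0 - self.alpha / 2.0) * self.se


@dataclass(frozen=True)
class EvalResult:
    """Operating characteristics of one evaluation condition.

    All per-method entries are arrays indexed like the snapshot set.
    ``fe_expected`` is the mean of the correlation-scale fixed-effect
    estimate over the grid; its excess over ``rho`` is the bias an
    uncorrected meta-analysis of the pair would incur.
    """

    condition: EvalCondition
    snapshots: SnapshotSet
    expected_pi: dict
    prob_exceed_25: dict
    prob_exceed_75: dict
    inconclusive: dict
    fe_expected: float


def original_quantile_grid(condition: EvalCondition) -> np.ndarray:
    """Equal-probability Fisher-z values of the *significant* original study.

    The sampling distribution of a published original effect is the normal
    distribution truncated below at the critical value.  With ``F`` the
    untruncated CDF at the true effect, the grid maps the conditional
    probabilities ``k/(G+1)`` to unconditional ones
    ``F(theta_cv) + k (1 - F(theta_cv)) / (G+1)`` and then through the
    normal quantile.  Under a true zero effect ``1 - F(theta_cv)`` equals
    alpha/2 and the probabilities run from ``1 - alpha/2 + alpha/2/(G+1)``
    up to ``1 - alpha/2 G/(G+1)``.
    """
    G = condition.grid_size
    th, se = condition.theta, condition.se
    k = np.arange(1, G + 1)
    mass_below = stats.norm.cdf((condition.theta_cv - th) / se)  # 1 - power
    p = mass_below + k / (G + 1) * (1.0 - mass_below)
    return th + se * stats.norm.ppf(p)


def replication_quantile_grid(condition: EvalCondition) -> np.ndarray:
    """Equal-probability Fisher-z values of the unconditional replication."""
    G = condition.grid_size
    k = np.arange(1, G + 1)
    return condition.theta + condition.se * stats.norm.ppf(k / (G + 1))


def _log_density_matrix(
    grid: np.ndarray,
    se: float,
    snapshots: SnapshotSet,
    theta_cv: float | None,
) -> np.ndarray:
    """(G, S) log densities of grid points at each snapshot theta."""
    theta = snapshots.theta
    if theta_cv is None:
        return _log_plain_density(grid[:, None], se, theta[None, :])
    return _log_truncated_density(grid[:, None], se, theta[None, :], theta_cv)


def evaluate_condition(
    condition: EvalCondition,
    snapshots: SnapshotSet = SnapshotSet(),
    methods: tuple = (HYBRID, NAIVE),
    chunk_size: int = 250,
) -> EvalResult:
    """Operating characteristics over the full G x G joint grid.

    Equal prior model probabilities are used throughout, matching the
    evaluation design.  Exceedance fractions use strict inequalities
    (``pi > .25``, ``pi > .75``); a pair is inconclusive when no snapshot
    exceeds .75.
    """
    for m in methods:
        if m not in (HYBRID, NAIVE):
            raise ValueError(f"unknown method {m!r}")
    S = len(snapshots)
    o_grid = original_quantile_grid(condition)
    r_grid = replication_quantile_grid(condition)
    se = condition.se

    log_fo = {}
    if HYBRID in methods:
        log_fo[HYBRID] = _log_density_matrix(o_grid, se, snapshots, condition.theta_cv)
    if NAIVE in methods:
        log_fo[NAIVE] = _log_density_matrix(o_grid, se, snapshots, None)
    log_fr = _log_density_matrix(r_grid, se, snapshots, None)

    sums = {m: np.zeros(S) for m in methods}
    n25 = {m: np.zeros(S) for m in methods}
    n75 = {m: np.zeros(S) for m in methods}
    n_inconcl = {m: 0.0 for m in methods}
    fe_sum = 0.0

    G = condition.grid_size
    for start in range(0, G, chunk_size):
        stop = min(start + chunk_size, G)
        for m in methods:
            log_lik = log_fo[m][start:stop, None, :] + log_fr[None, :, :]
            log_lik -= log_lik.max(axis=2, keepdims=True)
            pi = np.exp(log_lik)
            pi /= pi.sum(axis=2, keepdims=True)
            sums[m] += pi.sum(axis=(0, 1))
            n25[m] += (pi > 0.25).sum(axis=(0, 1))
            n75[m] += (pi > 0.75).sum(axis=(0, 1))
            n_inconcl[m] += (~(pi > 0.75).any(axis=2)).sum()
        # equal standard errors: the inverse-variance pooled Fisher-z is the mean
        fe_sum += np.tanh((o_grid[start:stop, None] + r_grid[None, :]) / 2.0).sum()

    total = float(G) * G
    return EvalResult(
        condition=condition,
        snapshots=snapshots,
        expected_pi={m: sums[m] / total for m in methods},
        prob_exceed_25={m: n25[m] / total for m in methods},
        prob_exceed_75={m: n75[m] / total for m in methods},
        inconclusive={m: n_inconcl[m] / total for m in methods},
        fe_expected=fe_sum / total,
    )
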