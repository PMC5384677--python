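"""Replication sample-size planning.

How many participants must a replication collect so that, if the true
effect equals a chosen snapshot, the posterior model probability of that
snapshot reaches a desired level ``a`` with probability ``b``?  The future
replication's Fisher-z estimate is integrated over an equal-probability
quantile grid of its (untruncated) sampling distribution at the snapshot,
while the original study — when incorporated — contributes its fixed,
significance-truncated density.  The required n is the smallest integer
with exceedance probability at least ``b``, found by geometric bracketing
and bisection with a linear verification of minimality at the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    NotSignificantError,
    SignificanceRule,
    SnapshotSet,
    _log_plain_density,
    _log_truncated_density,
)
from .transforms import Study

__all__ = ["SampleSizeSpec", "SampleSizeResult", "prob_reaching_threshold", "required_sample_size"]

_N_FLOOR = 4  # smallest n with a finite Fisher-z standard error


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the sample-size computation.

    ``a`` is the posterior model probability to reach (default .75,
    corresponding to a Bayes factor of 3 against the other snapshots) and
    ``b`` the desired probability of reaching it (default .8, akin to 80%
    power).  ``original`` may be ``None`` to plan a replication that
    ignores the original study.
    """

    original: Study | None = None
    alpha: float = 0.05
    a: float = 0.75
    b: float = 0.8
    snapshots: SnapshotSet = field(default_factory=SnapshotSet)
    grid_size: int = 5000
    n_max: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0 <= self.a < 1:
            raise ValueError(f"a must be in [0, 1), got {self.a}")
        if not 0 < self.b < 1:
            raise ValueError(f"b must be in (0, 1), got {self.b}")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.n_max < _N_FLOOR:
            raise ValueError("n_max must be >= 4")
        if self.original is not None:
            direction = -1 if self.original.theta_hat < 0 else 1
            rule = SignificanceRule(alpha=self.alpha, direction=direction)
            if not rule.is_significant(self.original):
                raise NotSignificantError(
                    "the original study must be statistically significant "
                    f"at alpha={self.alpha} to be incorporated"
                )


@dataclass(frozen=True)
class SampleSizeResult:
    """Required replication sample size per snapshot.

    ``required_n_with`` incorporates the original study's truncated
    density; ``required_n_without`` bases the posterior on the replication
    alone (``None`` entries when no original study was supplied make the
    "with" column unavailable, not the other way round).  ``at_floor``
    flags snapshots already satisfied at the minimum feasible n of 4, and
    ``unreachable`` snapshots for which the search cap was hit.
    """

    snapshots: SnapshotSet
    required_n_with: tuple
    required_n_without: tuple
    at_floor_with: tuple
    at_floor_without: tuple
    unreachable_with: tuple
    unreachable_without: tuple


def _log_original_vector(spec: SampleSizeSpec) -> np.ndarray | None:
    """Fixed per-snapshot log density contribution of the observed original."""
    if spec.original is None:
        return None
    o = spec.original
    # mirror a negative original so the positive snapshots refer to magnitudes
    direction = -1 if o.theta_hat < 0 else 1
    rule = SignificanceRule(alpha=spec.alpha, direction=direction)
    return _log_truncated_density(
        direction * o.theta_hat, o.se, spec.snapshots.theta, rule.critical_value(o.se)
    )


def prob_reaching_threshold(
    spec: SampleSizeSpec,
    snapshot_index: int,
    n_r: int,
    include_original: bool | None = None,
) -> float:
    """P(posterior of the chosen snapshot >= a) at replication size ``n_r``.

    The replication estimate is integrated over ``grid_size``
    equal-probability quantiles of N(snapshot theta, 1/(n_r - 3)).  When
    the original study is included, its observed value enters as a fixed
    (truncated-density) likelihood term; it is data, not integrated over.
    """
    if n_r < _N_FLOOR:
        raise ValueError(f"replication sample size must be >= {_N_FLOOR}, got {n_r}")
    if include_original is None:
        include_original = spec.original is not None
    log_fo = _log_original_vector(spec) if include_original else None
    if include_original and log_fo is None:
        raise ValueError("no original study supplied but include_original=True")
    return _prob_reach(spec, snapshot_index, n_r, log_fo)


def _prob_reach(
    spec: SampleSizeSpec, snapshot_index: int, n_r: int, log_fo: np.ndarray | None
) -> float:
    theta = spec.snapshots.theta
    if not 0 <= snapshot_index < len(theta):
        raise IndexError(f"snapshot index {snapshot_index} out of range")
    se = 1.0 / math.sqrt(n_r - 3)
    k = np.arange(1, spec.grid_size + 1)
    grid = theta[snapshot_index] + se * stats.norm.ppf(k / (spec.grid_size + 1))
    log_lik = _log_plain_density(grid[:, None], se, theta[None, :])
    if log_fo is not None:
        log_lik = log_lik + log_fo[None, :]
    log_lik -= log_lik.max(axis=1, keepdims=True)
    pi = np.exp(log_lik)
    pi /= pi.sum(axis=1, keepdims=True)
    return float((pi[:, snapshot_index] >= spec.a).mean())


def _search_minimal_n(f, b: float, n_max: int) -> tuple:
    """Smallest integer n >= 4 with f(n) >= b; (n, at_floor, unreachable)."""
    if f(_N_FLOOR) >= b:
        return _N_FLOOR, True, False
    lo, hi = _N_FLOOR, 2 * _N_FLOOR
    while f(hi) < b:
        if hi >= n_max:
            return n_max, False, True
        lo, hi = hi, min(2 * hi, n_max)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if f(mid) >= b:
            hi = mid
        else:
            lo = mid
    # bisection assumes monotone crossing; verify minimality linearly just below
    for m in range(max(_N_FLOOR, hi - 2), hi):
        if f(m) >= b:
            hi = m
            break
    return hi, False, False


def required_sample_size(spec: SampleSizeSpec) -> SampleSizeResult:
    """Required replication n per snapshot, with and without the original.

    The "with original" column is computed only when ``spec.original`` is
    present; its entries are ``None`` otherwise.
    """
    S = len(spec.snapshots)
    log_fo = _log_original_vector(spec)

    n_with, floor_with, unreach_with = [None] * S, [False] * S, [False] * S
    n_wo, floor_wo, unreach_wo = [None] * S, [False] * S, [False] * S
    for i in range(S):
        if log_fo is not None:
            n, fl, un = _search_minimal_n(
                lambda nr: _prob_reach(spec, i, nr, log_fo), spec.b, spec.n_max
            )
            n_with[i], floor_with[i], unreach_with[i] = n, fl, un
        n, fl, un = _search_minimal_n(
            lambda nr: _prob_reach(spec, i, nr, None), spec.b, spec.n_max
        )
        n_wo[i], floor_wo[i], unreach_wo[i] = n, fl, un

    return SampleSizeResult(
        snapshots=spec.snapshots,
        required_n_with=tuple(n_with),
        required_n_without=tuple(n_wo),
        at_floor_with=tuple(floor_with),
        at_floor_without=tuple(floor_wo),
        unreachable_with=tuple(unreach_with),
        unreachable_without=tuple(unreach_wo),
    )
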