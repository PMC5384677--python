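"""Snapshot posterior model probabilities for an original/replication pair.

The model: a common true effect theta underlies both studies, and theta is
one of a small ordered set of hypothesized values ("snapshots"; by default
the correlations 0, 0.1, 0.3 and 0.5 on the Fisher-z scale).  The original
study was published because it was statistically significant, so its
likelihood contribution is a normal density *truncated* at the critical
Fisher-z value of a two-tailed alpha-level test, one-sided in the observed
direction.  The replication's contribution is an untruncated normal
density.  Multiplying the two per-snapshot densities gives the joint
likelihood; normalizing likelihood-times-prior over snapshots gives the
posterior model probability of each hypothesized effect size.

The uncorrected variant ("naive"), which skips the truncation, is provided
for comparison only — it systematically favours too-large effects.

All density work is done in log space and exponentiated only at the
reporting boundary, so distant snapshots or very large samples do not
underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .transforms import Study

__all__ = [
    "SnapshotSet",
    "SignificanceRule",
    "PriorWeights",
    "PosteriorResult",
    "NotSignificantError",
    "DegenerateLikelihoodError",
    "truncated_original_density",
    "replication_density",
    "joint_likelihood",
    "posterior_probs",
    "reweight_posteriors",
    "priors_from_density",
    "posterior_matrix",
    "analyze_pair",
]

HYBRID = "hybrid"
NAIVE = "naive"

_DEFAULT_RHO = (0.0, 0.1, 0.3, 0.5)
_DEFAULT_LABELS = ("zero", "small", "medium", "large")


class NotSignificantError(ValueError):
    """The original study is not significant at the configured level.

    The bias correction conditions the original study's density on having
    passed the significance filter; it is undefined for a nonsignificant
    original.
    """


class DegenerateLikelihoodError(ValueError):
    """All prior-weighted likelihoods are zero (or underflow even in logs)."""


@dataclass(frozen=True)
class SnapshotSet:
    """Ordered hypothesized effect sizes on correlation and Fisher-z scales."""

    rho: tuple = _DEFAULT_RHO
    labels: tuple = _DEFAULT_LABELS

    def __post_init__(self) -> None:
        if len(self.rho) < 2:
            raise ValueError("need at least two snapshots")
        if len(self.labels) != len(self.rho):
            raise ValueError("labels and rho must have equal length")
        if any(not -1 < r < 1 for r in self.rho):
            raise ValueError("snapshot correlations must lie in (-1, 1)")
        if any(b <= a for a, b in zip(self.rho, self.rho[1:])):
            raise ValueError("snapshot correlations must be strictly increasing")

    @classmethod
    def from_rho(cls, rho: Sequence[float]) -> "SnapshotSet":
        """Snapshot set from correlations, with ``%g``-formatted labels."""
        return cls(rho=tuple(rho), labels=tuple(f"{r:g}" for r in rho))

    @property
    def theta(self) -> np.ndarray:
        """Fisher-z values ``atanh(rho)`` of the snapshots."""
        return np.arctanh(np.asarray(self.rho, dtype=float))

    def __len__(self) -> int:
        return len(self.rho)


@dataclass(frozen=True)
class SignificanceRule:
    """Two-tailed significance level and direction of the original effect.

    ``direction`` is +1 or -1; a negative original effect is handled by
    mirroring both studies (and keeping the positive snapshots), so that
    results refer to effect magnitudes.
    """

    alpha: float = 0.05
    direction: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")

    def critical_value(self, se: float) -> float:
        """Critical Fisher-z value (positive direction) for standard error se."""
        return stats.norm.ppf(1.0 - self.alpha / 2.0) * se

    def is_significant(self, study: Study) -> bool:
        """Whether the study is significant in ``direction`` (inclusive)."""
        return self.direction * study.theta_hat >= self.critical_value(study.se)


@dataclass(frozen=True)
class PriorWeights:
    """Nonnegative prior model weights, one per snapshot.

    Weights need not sum to one; equal weights encode the uniform
    encompassing prior under which the posterior reduces to normalized
    likelihoods.
    """

    p: tuple

    def __post_init__(self) -> None:
        arr = np.asarray(self.p, dtype=float)
        if arr.ndim != 1 or len(arr) < 2:
            raise ValueError("need one weight per snapshot (>= 2)")
        if (arr < 0).any() or not (arr > 0).any():
            raise ValueError("weights must be nonnegative with at least one > 0")

    @classmethod
    def equal(cls, k: int) -> "PriorWeights":
        return cls(p=(1.0,) * k)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)


@dataclass(frozen=True)
class PosteriorResult:
    """Per-snapshot joint likelihoods and posterior model probabilities."""

    likelihood: np.ndarray
    pi: np.ndarray
    method: str
    snapshots: SnapshotSet = field(default_factory=SnapshotSet)

    def as_dict(self) -> dict:
        return dict(zip(self.snapshots.labels, self.pi))


# ---------------------------------------------------------------------------
# densities


def _log_truncated_density(
    theta_obs: float, se: float, theta: np.ndarray, theta_cv: float
) -> np.ndarray:
    # log phi((obs-theta)/se)/se - log P(obs' >= cv | theta); the denominator
    # is the power of the alpha-level test at true effect theta.
    z = (np.asarray(theta_obs) - theta) / se
    log_power = stats.norm.logsf((theta_cv - theta) / se)
    return stats.norm.logpdf(z) - math.log(se) - log_power


def _log_plain_density(theta_obs: float, se: float, theta: np.ndarray) -> np.ndarray:
    return stats.norm.logpdf((np.asarray(theta_obs) - theta) / se) - math.log(se)


def truncated_original_density(
    original: Study, theta, rule: SignificanceRule = SignificanceRule()
):
    """Density of a significant original study's effect at hypothesized theta.

    Implements the normal density of the observed Fisher-z effect divided
    by the power of the significance test at true effect ``theta`` — i.e.
    the sampling density conditional on the study having been significant.
    Always at least as large as the untruncated density; exactly
    ``2/alpha`` times larger at ``theta = 0``.

    Raises
    ------
    NotSignificantError
        If the original study is not significant under ``rule``.
    """
    if not rule.is_significant(original):
        raise NotSignificantError(
            "original study is not statistically significant at "
            f"alpha={rule.alpha} in direction {rule.direction:+d}; the "
            "significance-corrected density is undefined for it"
        )
    d = rule.direction
    theta_arr = d * np.asarray(theta, dtype=float)
    out = np.exp(
        _log_truncated_density(
            d * original.theta_hat,
            original.se,
            theta_arr,
            rule.critical_value(original.se),
        )
    )
    return out if np.ndim(theta) else float(out)


def replication_density(replication: Study, theta):
    """Untruncated normal density of the replication's effect at theta."""
    out = np.exp(
        _log_plain_density(
            replication.theta_hat, replication.se, np.asarray(theta, dtype=float)
        )
    )
    return out if np.ndim(theta) else float(out)


# ---------------------------------------------------------------------------
# likelihood and posteriors


def _log_joint_likelihood(
    original: Study,
    replication: Study,
    snapshots: SnapshotSet,
    rule: SignificanceRule,
    method: str,
) -> np.ndarray:
    if method not in (HYBRID, NAIVE):
        raise ValueError(f"method must be '{HYBRID}' or '{NAIVE}', got {method!r}")
    d = rule.direction
    theta = snapshots.theta
    if method == HYBRID:
        if not rule.is_significant(original):
            raise NotSignificantError(
                "original study is not statistically significant at "
                f"alpha={rule.alpha}; the hybrid method requires a "
                "significant original study"
            )
        log_fo = _log_truncated_density(
            d * original.theta_hat,
            original.se,
            theta,
            rule.critical_value(original.se),
        )
    else:
        log_fo = _log_plain_density(d * original.theta_hat, original.se, theta)
    log_fr = _log_plain_density(d * replication.theta_hat, replication.se, theta)
    return log_fo + log_fr


def joint_likelihood(
    original: Study,
    replication: Study,
    snapshots: SnapshotSet = SnapshotSet(),
    rule: SignificanceRule = SignificanceRule(),
    method: str = HYBRID,
) -> np.ndarray:
    """Per-snapshot joint likelihood of the study pair.

    The product of the original study's density (truncated at the
    significance threshold for ``method='hybrid'``, untruncated for
    ``method='naive'``) and the replication's untruncated density,
    evaluated at each snapshot's Fisher-z value.
    """
    return np.exp(_log_joint_likelihood(original, replication, snapshots, rule, method))


def _posterior_from_log(
    log_lik: np.ndarray, priors: PriorWeights | None, k: int
) -> np.ndarray:
    w = PriorWeights.equal(k).array if priors is None else priors.array
    if len(w) != k:
        raise ValueError(f"expected {k} prior weights, got {len(w)}")
    with np.errstate(divide="ignore"):
        log_w = np.log(w)
    log_post = log_lik + log_w
    norm = logsumexp(log_post)
    if not np.isfinite(norm):
        raise DegenerateLikelihoodError(
            "all prior-weighted likelihoods are zero; the posterior is undefined"
        )
    return np.exp(log_post - norm)


def posterior_probs(
    likelihoods,
    priors: PriorWeights | None = None,
    method: str = HYBRID,
    snapshots: SnapshotSet = SnapshotSet(),
) -> PosteriorResult:
    """Posterior model probabilities from per-snapshot likelihoods.

    ``pi_x = p_x L_x / sum_y p_y L_y``; with equal priors this is the plain
    normalized likelihood.
    """
    lik = np.asarray(likelihoods, dtype=float)
    if (lik < 0).any():
        raise ValueError("likelihoods must be nonnegative")
    with np.errstate(divide="ignore"):
        log_lik = np.log(lik)
    pi = _posterior_from_log(log_lik, priors, len(lik))
    return PosteriorResult(likelihood=lik, pi=pi, method=method, snapshots=snapshots)


def reweight_posteriors(
    posteriors: PosteriorResult, priors: PriorWeights
) -> PosteriorResult:
    """Recompute posteriors under new prior weights without re-evaluating data.

    ``pi*_x = p_x pi_x / sum_y p_y pi_y`` where ``pi`` are equal-prior
    posteriors.  Equal weights are the identity map.
    """
    w = priors.array
    if len(w) != len(posteriors.pi):
        raise ValueError("one weight per snapshot required")
    num = w * posteriors.pi
    denom = num.sum()
    if denom <= 0:
        raise DegenerateLikelihoodError(
            "prior weights annihilate all posterior mass; reweighting undefined"
        )
    return PosteriorResult(
        likelihood=posteriors.likelihood,
        pi=num / denom,
        method=posteriors.method,
        snapshots=posteriors.snapshots,
    )


def priors_from_density(
    density: Callable[[np.ndarray], np.ndarray],
    snapshots: SnapshotSet = SnapshotSet(),
) -> PriorWeights:
    """Prior model weights read off a continuous encompassing prior.

    Evaluates the prior density on the Fisher-z scale at each snapshot and
    normalizes the values to sum to one.
    """
    vals = np.asarray(density(snapshots.theta), dtype=float)
    if vals.shape != (len(snapshots),):
        vals = np.array([float(density(t)) for t in snapshots.theta])
    if (vals < 0).any():
        raise ValueError("prior density must be nonnegative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("prior density is zero at every snapshot")
    return PriorWeights(p=tuple(vals / total))


def posterior_matrix(
    theta_o,
    se_o: float,
    theta_r,
    se_r: float,
    snapshots: SnapshotSet = SnapshotSet(),
    alpha: float = 0.05,
    method: str = HYBRID,
) -> np.ndarray:
    """Equal-prior posteriors for whole arrays of observed pairs at once.

    ``theta_o`` and ``theta_r`` are equal-length arrays of Fisher-z
    estimates sharing the standard errors ``se_o``/``se_r`` (positive
    direction assumed).  Returns an ``(n_pairs, n_snapshots)`` matrix; the
    workhorse behind Monte-Carlo cross-checks of the deterministic grids.
    """
    theta = snapshots.theta
    to = np.asarray(theta_o, dtype=float)[:, None]
    tr = np.asarray(theta_r, dtype=float)[:, None]
    if method == HYBRID:
        cv = stats.norm.ppf(1.0 - alpha / 2.0) * se_o
        log_fo = _log_truncated_density(to, se_o, theta[None, :], cv)
    elif method == NAIVE:
        log_fo = _log_plain_density(to, se_o, theta[None, :])
    else:
        raise ValueError(f"method must be '{HYBRID}' or '{NAIVE}', got {method!r}")
    log_lik = log_fo + _log_plain_density(tr, se_r, theta[None, :])
    log_lik -= log_lik.max(axis=1, keepdims=True)
    pi = np.exp(log_lik)
    pi /= pi.sum(axis=1, keepdims=True)
    return pi


def analyze_pair(
    original: Study,
    replication: Study,
    snapshots: SnapshotSet = SnapshotSet(),
    alpha: float = 0.05,
    priors: PriorWeights | None = None,
    method: str = HYBRID,
) -> PosteriorResult:
    """End-to-end snapshot analysis of one study pair.

    Infers the direction from the original effect's sign (mirroring both
    studies when it is negative, so snapshots refer to magnitudes), builds
    the joint likelihood in log space, and returns posterior model
    probabilities under ``priors`` (equal weights when omitted).
    """
    direction = -1 if original.theta_hat < 0 else 1
    rule = SignificanceRule(alpha=alpha, direction=direction)
    log_lik = _log_joint_likelihood(original, replication, snapshots, rule, method)
    pi = _posterior_from_log(log_lik, priors, len(snapshots))
    return PosteriorResult(
        likelihood=np.exp(log_lik), pi=pi, method=method, snapshots=snapshots
    )
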