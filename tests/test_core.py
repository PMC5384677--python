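import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from snapmeta import (
    DegenerateLikelihoodError,
    NotSignificantError,
    PriorWeights,
    SignificanceRule,
    SnapshotSet,
    Study,
    analyze_pair,
    joint_likelihood,
    posterior_probs,
    priors_from_density,
    replication_density,
    reweight_posteriors,
    truncated_original_density,
)

SNAPS = SnapshotSet()


@st.composite
def significant_pairs(draw):
    """Random valid pair whose original is significant at alpha = .05."""
    n_o = draw(st.integers(10, 500))
    n_r = draw(st.integers(10, 500))
    se_o = 1 / math.sqrt(n_o - 3)
    excess = draw(st.floats(0, 3))
    theta_o = (stats.norm.ppf(0.975) + excess) * se_o
    theta_r = draw(st.floats(-0.6, 0.8))
    return (
        Study.from_fisher(theta_o, se_o),
        Study.from_fisher(theta_r, 1 / math.sqrt(n_r - 3)),
    )


class TestDensities:
    def test_truncated_density_worked_example(self, maxwell_original):
        vals = truncated_original_density(maxwell_original, SNAPS.theta)
        assert vals == pytest.approx([13.252, 10.852, 3.894, 0.105], abs=2e-3)

    def test_replication_density_worked_example(self, maxwell_replication):
        vals = replication_density(maxwell_replication, SNAPS.theta)
        assert vals[:3] == pytest.approx([1.705, 5.096, 0.210], abs=2e-3)
        assert vals[3] < 5e-4

    def test_truncation_inflates_by_two_over_alpha_at_zero(self, maxwell_original):
        ratio = truncated_original_density(
            maxwell_original, 0.0
        ) / replication_density(maxwell_original, 0.0)
        assert ratio == pytest.approx(2 / 0.05, rel=1e-12)

    def test_truncated_approaches_untruncated_for_large_theta(self, maxwell_original):
        # power -> 1 far above the critical value, so the correction vanishes
        ratio = truncated_original_density(
            maxwell_original, 2.0
        ) / replication_density(maxwell_original, 2.0)
        assert ratio == pytest.approx(1.0, rel=1e-9)

    def test_truncated_density_always_inflates(self, maxwell_original):
        thetas = np.linspace(-1, 2, 50)
        trunc = truncated_original_density(maxwell_original, thetas)
        plain = replication_density(maxwell_original, thetas)
        assert (trunc >= plain).all()

    def test_replication_density_mode_and_symmetry(self, maxwell_replication):
        s = maxwell_replication
        assert replication_density(s, s.theta_hat) == pytest.approx(
            1 / (s.se * math.sqrt(2 * math.pi))
        )
        assert replication_density(s, s.theta_hat + 0.2) == pytest.approx(
            replication_density(s, s.theta_hat - 0.2)
        )

    def test_nonsignificant_original_is_rejected(self):
        weak = Study.from_r_n(0.05, 80)
        with pytest.raises(NotSignificantError):
            truncated_original_density(weak, 0.0)

    def test_rejection_sampling_oracle(self, maxwell_original):
        """The truncated density matches a histogram of significant-only draws."""
        o = maxwell_original
        rule = SignificanceRule()
        cv = rule.critical_value(o.se)
        rng = np.random.default_rng(20260930)
        draws = rng.normal(0.0, o.se, size=1_000_000)
        kept = draws[draws >= cv]
        lo, hi = o.theta_hat - 0.02, o.theta_hat + 0.02
        p_bin = (stats.norm.cdf(hi / o.se) - stats.norm.cdf(lo / o.se)) / 0.025
        frac = ((kept >= lo) & (kept < hi)).mean()
        se_mc = math.sqrt(p_bin * (1 - p_bin) / len(kept))
        assert abs(frac - p_bin) < 3 * se_mc
        # and the density value itself sits near the bin-averaged estimate
        assert frac / (hi - lo) == pytest.approx(
            truncated_original_density(o, 0.0), rel=0.05
        )


class TestJointLikelihood:
    def test_worked_example(self, maxwell_original, maxwell_replication):
        lik = joint_likelihood(maxwell_original, maxwell_replication)
        assert lik[1] == pytest.approx(55.304, abs=2e-3)
        assert lik[2] == pytest.approx(0.819, abs=2e-3)
        assert lik[3] < 5e-4

    def test_product_of_densities(self, maxwell_original, maxwell_replication):
        lik = joint_likelihood(maxwell_original, maxwell_replication)
        manual = truncated_original_density(
            maxwell_original, SNAPS.theta
        ) * replication_density(maxwell_replication, SNAPS.theta)
        assert lik == pytest.approx(manual, rel=1e-12)

    def test_hybrid_naive_ratio_is_inverse_power(
        self, maxwell_original, maxwell_replication
    ):
        rule = SignificanceRule()
        hybrid = joint_likelihood(maxwell_original, maxwell_replication, method="hybrid")
        naive = joint_likelihood(maxwell_original, maxwell_replication, method="naive")
        power = stats.norm.sf(
            (rule.critical_value(maxwell_original.se) - SNAPS.theta)
            / maxwell_original.se
        )
        assert hybrid / naive == pytest.approx(1 / power, rel=1e-10)


class TestPosteriors:
    def test_table1_hybrid(self, printed_original, printed_replication):
        res = analyze_pair(printed_original, printed_replication)
        assert res.pi[:3] == pytest.approx([0.287, 0.703, 0.010], abs=2e-3)
        assert res.pi[3] < 5e-4

    def test_table1_naive(self, printed_original, printed_replication):
        res = analyze_pair(printed_original, printed_replication, method="naive")
        assert res.pi[:3] == pytest.approx([0.063, 0.866, 0.071], abs=2e-3)

    def test_equal_likelihoods_give_uniform(self):
        res = posterior_probs([2.0, 2.0, 2.0, 2.0])
        assert res.pi == pytest.approx([0.25] * 4)

    def test_all_zero_likelihoods_rejected(self):
        with pytest.raises(DegenerateLikelihoodError):
            posterior_probs([0.0, 0.0, 0.0, 0.0])

    @pytest.mark.parametrize(
        "p0, expected",
        [(2.0, [0.446, 0.546, 0.008]), (6.0, [0.707, 0.289, 0.004])],
    )
    def test_table1_reweighting(self, printed_original, printed_replication, p0, expected):
        res = analyze_pair(printed_original, printed_replication)
        rw = reweight_posteriors(res, PriorWeights(p=(p0, 1, 1, 1)))
        assert rw.pi[:3] == pytest.approx(expected, abs=2e-3)
        assert rw.pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_weights_are_identity(self, printed_original, printed_replication):
        res = analyze_pair(printed_original, printed_replication)
        rw = reweight_posteriors(res, PriorWeights.equal(4))
        assert rw.pi == pytest.approx(res.pi, rel=1e-12)

    def test_degenerate_reweighting_rejected(self):
        res = posterior_probs([1.0, 0.0, 0.0, 0.0])
        with pytest.raises(DegenerateLikelihoodError):
            reweight_posteriors(res, PriorWeights(p=(0, 1, 1, 1)))

    def test_standard_normal_encompassing_prior(
        self, printed_original, printed_replication
    ):
        w = priors_from_density(stats.norm.pdf)
        assert w.array == pytest.approx([0.263, 0.261, 0.250, 0.226], abs=5e-4)
        res = analyze_pair(printed_original, printed_replication)
        rw = reweight_posteriors(res, w)
        assert rw.pi[:3] == pytest.approx([0.288, 0.702, 0.010], abs=2e-3)

    def test_uniform_prior_density_gives_equal_weights(self):
        w = priors_from_density(lambda th: np.ones_like(th))
        assert w.array == pytest.approx([0.25] * 4)


class TestProperties:
    @given(significant_pairs())
    def test_posteriors_normalized(self, pair):
        original, replication = pair
        for method in ("hybrid", "naive"):
            pi = analyze_pair(original, replication, method=method).pi
            assert ((pi >= 0) & (pi <= 1)).all()
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    @given(significant_pairs())
    def test_hybrid_favours_zero_over_naive(self, pair):
        original, replication = pair
        hybrid = analyze_pair(original, replication).pi
        naive = analyze_pair(original, replication, method="naive").pi
        assert hybrid[0] >= naive[0] - 1e-12

    @given(significant_pairs())
    def test_cumulative_shift_toward_smaller_effects(self, pair):
        # the 1/power reweighting shifts hybrid mass toward smaller snapshots,
        # so every cumulative prefix of the hybrid posterior dominates
        original, replication = pair
        hybrid = np.cumsum(analyze_pair(original, replication).pi)
        naive = np.cumsum(analyze_pair(original, replication, method="naive").pi)
        assert (hybrid >= naive - 1e-12).all()

    @given(significant_pairs())
    def test_sign_mirroring_invariance(self, pair):
        original, replication = pair
        mirrored = (
            Study.from_fisher(-original.theta_hat, original.se),
            Study.from_fisher(-replication.theta_hat, replication.se),
        )
        for method in ("hybrid", "naive"):
            direct = analyze_pair(original, replication, method=method).pi
            flipped = analyze_pair(*mirrored, method=method).pi
            assert flipped == pytest.approx(direct, rel=1e-10, abs=1e-12)

    def test_boundary_significance_accepted(self):
        se = 1 / math.sqrt(97)
        exactly = Study.from_fisher(stats.norm.ppf(0.975) * se, se)
        rule = SignificanceRule()
        assert rule.is_significant(exactly)
        truncated_original_density(exactly, 0.0)  # must not raise


class TestSnapshotSet:
    def test_default_thetas(self):
        assert SNAPS.theta == pytest.approx(
            [0.0, 0.10034, 0.30952, 0.54931], abs=5e-6
        )

    def test_custom_sets(self):
        s = SnapshotSet.from_rho([0.0, 0.2, 0.4])
        assert s.labels == ("0", "0.2", "0.4")
        with pytest.raises(ValueError):
            SnapshotSet.from_rho([0.3])
        with pytest.raises(ValueError):
            SnapshotSet.from_rho([0.3, 0.1])
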