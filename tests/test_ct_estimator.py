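import numpy as np
import pytest

from cttespike import (CoupledPairParams, EmbeddingConfig, EstimatorConfig,
                       build_sample_sets, estimate_te, estimate_te_4kl,
                       estimate_te_ct, kl_cross_entropy, kl_entropy,
                       radius_count, simulate_homogeneous_poisson)
from cttespike.ct_estimator import DegenerateDataError

from brute_oracle import brute_radius_count, brute_te, coupled_pair_true_te


class TestKLEntropy:
    def test_uniform_square_entropy_is_zero(self, rng):
        samples = rng.random((10_000, 2))
        assert abs(kl_entropy(samples, 5)) < 0.05

    def test_gaussian_entropy_closed_form(self, rng):
        samples = rng.normal(size=(10_000, 1))
        true = 0.5 * np.log(2 * np.pi * np.e)
        assert kl_entropy(samples, 5) == pytest.approx(true, abs=0.05)

    @pytest.mark.parametrize("norm", ["manhattan", "euclidean", "chebyshev"])
    def test_norm_invariance_of_entropy(self, rng, norm):
        samples = rng.normal(size=(5_000, 2))
        true = np.log(2 * np.pi * np.e)
        assert kl_entropy(samples, 4, norm=norm) == pytest.approx(true, abs=0.1)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateDataError):
            kl_entropy(np.zeros((50, 2)), 3)
        with pytest.raises(ValueError):
            kl_entropy(np.random.default_rng(0).random((10, 1)), 10)


class TestKLCrossEntropy:
    def test_matching_distributions_reduce_to_entropy(self, rng):
        ref = rng.random((8_000, 2))
        pts = rng.random((8_000, 2))
        assert kl_cross_entropy(pts, ref, 5) == pytest.approx(
            kl_entropy(ref, 5), abs=0.05)

    def test_shifted_gaussians_closed_form(self, rng):
        p = rng.normal(0.0, 1.0, size=(10_000, 1))
        q = rng.normal(1.0, 1.0, size=(10_000, 1))
        true = 0.5 * np.log(2 * np.pi * np.e) + 0.5  # H(p) + KL(p||q)
        assert kl_cross_entropy(p, q, 5) == pytest.approx(true, abs=0.05)

    def test_k_must_be_below_reference_size(self, rng):
        with pytest.raises(ValueError):
            kl_cross_entropy(rng.random((10, 1)), rng.random((5, 1)), 5)


class TestRadiusCount:
    def test_hand_cases(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.0]])
        assert radius_count([0.0], pts, 2.0, exclude_index=0) == (2, 2.0)
        assert radius_count([0.0], pts, 0.0, exclude_index=0) == (0, 0.0)

    def test_exclusion_window_removes_point(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.0]])
        wins = np.array([[10, 11], [0, 1], [10, 11], [10, 11]], dtype=float)
        count, dist = radius_count([0.0], pts, 2.0, point_windows=wins,
                                   anchor_window=np.array([[0.5, 2.0]]),
                                   exclude_index=0)
        assert (count, dist) == (1, 2.0)

    def test_matches_brute_force_on_random_data(self, rng):
        pts = rng.random((60, 3))
        wins = np.column_stack([np.arange(60.0), np.arange(60.0) + 2.5])
        anchor = pts[7]
        got = radius_count(anchor, pts, 0.4, point_windows=wins,
                           anchor_window=wins[7:8], exclude_index=None)
        want = brute_radius_count(anchor, pts, 0.4, point_wins=wins,
                                  anchor_win=wins[7:8])
        assert got == want


class TestEstimatorAgainstBruteForce:
    @pytest.mark.parametrize("variant", ["ct", "4kl"])
    @pytest.mark.parametrize("theiler", [True, False])
    def test_tree_search_equals_all_pairs(self, tiny_sets, variant, theiler):
        cfg = EstimatorConfig(k_global=4, variant=variant, theiler=theiler)
        fast = estimate_te(tiny_sets, cfg).te_rate
        slow = brute_te(tiny_sets, k=4, variant=variant, theiler=theiler)
        assert fast == pytest.approx(slow, abs=1e-10)

    @pytest.mark.parametrize("norm", ["euclidean", "chebyshev"])
    def test_other_norms_also_match(self, tiny_sets, norm):
        cfg = EstimatorConfig(k_global=3, variant="ct", norm=norm)
        fast = estimate_te(tiny_sets, cfg).te_rate
        slow = brute_te(tiny_sets, k=3, variant="ct", norm=norm)
        assert fast == pytest.approx(slow, abs=1e-10)


class TestEstimatorProperties:
    def test_rate_equals_mean_rate_times_mean_local(self, tiny_sets):
        est = estimate_te_ct(tiny_sets, EstimatorConfig(k_global=4))
        assert est.te_rate == pytest.approx(
            est.mean_rate * est.local_terms.mean(), rel=1e-12)
        assert est.n_samples == est.local_terms.size

    def test_radius_convention_cancels(self, tiny_sets):
        """Using distances vs diameters (2x) leaves the estimate unchanged."""
        for variant in ("ct", "4kl"):
            a = estimate_te(tiny_sets, EstimatorConfig(
                k_global=4, variant=variant, eps_scale=1.0)).te_rate
            b = estimate_te(tiny_sets, EstimatorConfig(
                k_global=4, variant=variant, eps_scale=2.0)).te_rate
            assert a == pytest.approx(b, abs=1e-12)

    def test_ct_reduces_to_4kl_when_counts_stay_at_k(self):
        """With geometry arranged so every in-radius count equals k_global,
        the shared-radius estimator coincides with the fixed-k one (the
        digamma corrections cancel exactly)."""
        from cttespike.embeddings import SampleSets
        cfg = EmbeddingConfig(l_X=1, l_Y=1)
        far = np.array([[1e6, 1e6 + 1.0]])  # windows never used (theiler off)
        sets = SampleSets(
            J_X=np.array([[0.0, 0.0], [1.0, 1.0]]),
            C_X=np.array([[0.0], [1.0]]),
            J_U=np.array([[0.5, 0.5], [50.0, 50.0]]),
            C_U=np.array([[0.5], [50.0]]),
            windows_JX=np.repeat(far, 2, 0), windows_CX=np.repeat(far, 2, 0),
            windows_JU=np.repeat(far, 2, 0), windows_CU=np.repeat(far, 2, 0),
            mean_rate=1.0, config=cfg)
        ct = estimate_te_ct(sets, EstimatorConfig(k_global=1, theiler=False))
        kl = estimate_te_4kl(sets, EstimatorConfig(k_global=1, theiler=False))
        assert ct.te_rate == pytest.approx(kl.te_rate, abs=1e-12)

    def test_k_too_large_rejected(self, tiny_sets):
        with pytest.raises(ValueError):
            estimate_te(tiny_sets, EstimatorConfig(k_global=10_000))


class TestGroundTruth:
    def test_filter_oracle_reproduces_reference_te(self):
        """The exact filtering oracle for the coupled pair gives the
        reference ground truth 0.5076 nats/time at the default params."""
        val = coupled_pair_true_te(CoupledPairParams(), n_events=20_000)
        assert val == pytest.approx(0.5076, abs=0.012)

    def test_ct_estimator_approaches_ground_truth(self):
        params = CoupledPairParams()
        from cttespike import simulate_coupled_pair
        y, x = simulate_coupled_pair(params, 20_000, 23)
        sets = build_sample_sets(
            x, y, (), EmbeddingConfig(l_X=3, l_Y=1, N_U=len(x)), seed=0)
        est = estimate_te_ct(sets, EstimatorConfig(k_global=4))
        assert est.te_rate == pytest.approx(0.5076, abs=0.08)
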