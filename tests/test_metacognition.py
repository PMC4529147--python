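import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressmeta import (
    DomainError,
    UndefinedAUCError,
    bin_confidence,
    calibration_metrics,
    permutation_null_auc,
    type2_roc,
)
from tests.conftest import pairwise_auc


class TestBinConfidence:
    def test_one_value_per_equal_width_bin(self):
        labels = bin_confidence([0.5, 0.6, 0.7, 0.8, 0.95], k=5, mode="equal_width")
        assert labels.tolist() == [1, 2, 3, 4, 5]

    def test_identical_confidences_share_a_bin(self):
        labels = bin_confidence([0.77] * 50, k=5, mode="equal_width")
        assert len(set(labels)) == 1

    def test_top_bin_closed_at_one(self):
        assert bin_confidence([1.0], k=5, mode="equal_width")[0] == 5

    def test_equal_count_balanced_occupancy(self, rng):
        conf = rng.uniform(0.5, 1.0, size=1000)
        labels = bin_confidence(conf, k=5, mode="equal_count")
        counts = np.bincount(labels)[1:]
        assert counts.tolist() == [200] * 5

    def test_equal_count_boundary_goes_to_lower_bin(self):
        conf = np.array([0.5, 0.6, 0.7, 0.8])  # k=2 -> interior edge at median 0.65
        labels = bin_confidence(conf, k=2, mode="equal_count")
        assert labels.tolist() == [1, 1, 2, 2]
        # a value exactly at the interior edge falls into the lower bin
        conf2 = np.array([0.5, 0.65, 0.7, 0.8])
        assert bin_confidence(conf2, k=2, mode="equal_count")[1] == 1

    @pytest.mark.parametrize("bad_k", [0, 1, -3])
    def test_k_floor(self, bad_k):
        with pytest.raises(DomainError):
            bin_confidence([0.6, 0.7], k=bad_k)

    def test_empty_input(self):
        with pytest.raises(DomainError):
            bin_confidence([], k=5)

    def test_unknown_mode(self):
        with pytest.raises(DomainError):
            bin_confidence([0.6], k=2, mode="quantile")


class TestType2ROC:
    def test_independence_null(self, rng):
        correct = rng.random(100_000) < 0.7
        confidence = rng.uniform(0.5, 1.0, size=100_000)
        roc = type2_roc(correct, confidence)
        assert roc.auc == pytest.approx(0.5, abs=0.01)

    def test_perfect_separation(self):
        correct = np.array([True] * 10 + [False] * 10)
        confidence = np.array([0.95] * 10 + [0.55] * 10)
        roc = type2_roc(correct, confidence, k=5)
        assert roc.auc == pytest.approx(1.0)
        assert roc.points[0] == (0.0, 0.0)
        assert roc.points[-1] == (1.0, 1.0)
        assert (0.0, 1.0) in roc.points

    def test_ten_trial_hand_computed_example(self):
        """Frozen value 0.72 from the exhaustive cumulative-count construction.

        correct conf {.9,.9,.8,.6,.55}, incorrect {.85,.7,.6,.55,.5}, k=5
        equal-width bins on [0.5,1]: cumulative (FA, hit) points sweeping
        liberal-ward are (0,.4),(.2,.6),(.4,.6),(.6,.8),(1,1); trapezoid
        over the anchored polyline = 0.72.
        """
        correct = np.array([True] * 5 + [False] * 5)
        conf = np.array([0.9, 0.9, 0.8, 0.6, 0.55, 0.85, 0.7, 0.6, 0.55, 0.5])
        roc = type2_roc(correct, conf, k=5, mode="equal_width")
        assert roc.auc == pytest.approx(0.72, abs=1e-12)
        expected = [(0, 0), (0, 0.4), (0.2, 0.6), (0.4, 0.6), (0.6, 0.8), (1, 1)]
        assert [(pytest.approx(x), pytest.approx(y)) for x, y in roc.points] == expected

    def test_counts_partition_trials(self, rng):
        correct = rng.random(500) < 0.7
        correct[:2] = [True, False]
        conf = rng.uniform(0.5, 1.0, 500)
        roc = type2_roc(correct, conf)
        assert roc.n_correct + roc.n_incorrect == 500

    @pytest.mark.parametrize("all_correct", [True, False])
    def test_undefined_auc_raises_with_participant(self, all_correct):
        correct = np.full(20, all_correct)
        conf = np.linspace(0.5, 1.0, 20)
        with pytest.raises(UndefinedAUCError) as exc:
            type2_roc(correct, conf, participant_id="p007")
        assert "p007" in str(exc.value)
        assert exc.value.participant_id == "p007"

    def test_matches_pairwise_oracle_with_per_value_bins(self, rng):
        """Exact equality when each distinct confidence value has its own bin."""
        k = 50
        centers = 0.5 + (np.arange(k) + 0.5) * 0.5 / k
        for _ in range(20):
            n = rng.integers(10, 51)
            conf = rng.choice(centers, size=n)
            correct = rng.random(n) < 0.7
            if correct.all() or not correct.any():
                continue
            roc = type2_roc(correct, conf, k=k, mode="equal_width")
            assert roc.auc == pytest.approx(pairwise_auc(correct, conf), abs=1e-12)

    def test_binned_auc_close_to_oracle_at_k5(self, rng):
        """Coarse k=5 binning stays within 0.05 of the bin-free oracle."""
        from stressmeta import ObserverParams, simulate_trials

        params = ObserverParams(sensitivity_scale=1.0, metacog_noise=0.5)
        t = simulate_trials(params, 0.545, 10_000, rng)
        correct, conf = t.correct.to_numpy(), t.confidence.to_numpy()
        roc = type2_roc(correct, conf, k=5)
        assert abs(roc.auc - pairwise_auc(correct, conf)) <= 0.05

    def test_invariance_under_monotone_transform_equal_count(self, rng):
        correct = rng.random(2000) < 0.7
        conf = rng.uniform(0.5, 1.0, 2000)
        correct[:2] = [True, False]
        a = type2_roc(correct, conf, k=5, mode="equal_count").auc
        transformed = 0.5 + (conf - 0.5) ** 2 * 2  # strictly increasing on [0.5,1]
        b = type2_roc(correct, transformed, k=5, mode="equal_count").auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_midpoint_trials_dilute_toward_half(self, rng):
        from stressmeta import ObserverParams, simulate_trials

        params = ObserverParams(sensitivity_scale=1.0)
        t = simulate_trials(params, 0.545, 2000, rng)
        correct, conf = t.correct.to_numpy(), t.confidence.to_numpy()
        auc_prev = type2_roc(correct, conf).auc
        for m in (100, 1000, 5000):
            c2 = np.concatenate([correct, np.ones(m, bool), np.zeros(m, bool)])
            conf2 = np.concatenate([conf, np.full(2 * m, 0.75)])
            auc = type2_roc(c2, conf2).auc
            assert 0.5 - 1e-12 <= auc <= auc_prev + 1e-12
            auc_prev = auc


class TestCalibrationMetrics:
    def test_well_calibrated_example(self):
        """Mean confidence .84 against accuracy .83 gives gap +.01."""
        correct = np.concatenate([np.ones(83, bool), np.zeros(17, bool)])
        confidence = np.full(100, 0.84)
        mean_conf, acc, gap = calibration_metrics(correct, confidence)
        assert mean_conf == pytest.approx(0.84)
        assert acc == pytest.approx(0.83)
        assert gap == pytest.approx(0.01)

    def test_perfect_confident_observer(self):
        mean_conf, acc, gap = calibration_metrics([True] * 10, [1.0] * 10)
        assert gap == 0.0

    def test_underconfident(self):
        correct = [True, True, True, False]
        mean_conf, acc, gap = calibration_metrics(correct, [0.5] * 4)
        assert gap == pytest.approx(-0.25)

    @given(
        n=st.integers(1, 200),
        p=st.floats(0.0, 1.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_gap_bounded(self, n, p, seed):
        r = np.random.default_rng(seed)
        correct = r.random(n) < p
        conf = r.uniform(0.5, 1.0, n)
        mean_conf, acc, gap = calibration_metrics(correct, conf)
        assert gap == pytest.approx(mean_conf - acc)
        assert -0.5 - 1e-12 <= gap <= 1.0 + 1e-12
        if acc >= 0.5:  # at or above 2IFC chance the gap is confined to +/- 0.5
            assert gap <= 0.5 + 1e-12


class TestPermutationNull:
    def test_zero_permutations(self, rng):
        out = permutation_null_auc([True, False], [0.6, 0.7], 0, rng)
        assert out.size == 0

    def test_null_mean_near_half(self, rng):
        correct = rng.random(1000) < 0.7
        correct[:2] = [True, False]
        conf = rng.uniform(0.5, 1.0, 1000)
        null = permutation_null_auc(correct, conf, 2000, rng)
        assert null.mean() == pytest.approx(0.5, abs=0.01)

    def test_deterministic_given_seed(self):
        correct = np.array([True, True, False, False, True])
        conf = np.array([0.9, 0.8, 0.7, 0.6, 0.55])
        a = permutation_null_auc(correct, conf, 50, np.random.default_rng(4))
        b = permutation_null_auc(correct, conf, 50, np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)

    def test_matches_direct_type2_roc_of_shuffled_labels(self, rng):
        """Cross-check the fast bincount path against the public type2_roc."""
        correct = rng.random(200) < 0.6
        correct[:2] = [True, False]
        conf = rng.uniform(0.5, 1.0, 200)
        seed_rng = np.random.default_rng(99)
        fast = permutation_null_auc(correct, conf, 20, seed_rng)
        check_rng = np.random.default_rng(99)
        slow = []
        for _ in range(20):
            # Generator.permutation(array) applies the same swap sequence as
            # permutation(n) does to arange(n), so conf[perm] reproduces the
            # implementation's shuffled bin labels elementwise
            perm = check_rng.permutation(len(conf))
            slow.append(type2_roc(correct, conf[perm], k=5).auc)
        np.testing.assert_allclose(fast, slow, atol=1e-12)
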