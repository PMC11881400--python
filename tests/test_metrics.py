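"""Metric suite: proper scores, binned calibration errors, AUC, t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemuq.metrics import (DegenerateTestError, MetricUndefinedError, accuracy,
                            auc, bce_loss, bin_stats, binned_ce,
                            brier_decomposition, brier_score, compare_models,
                            evaluate_model)


def ce_bruteforce(probs, y, n_bins, scheme):
    """Independent oracle: materialize bin membership lists explicitly."""
    probs = np.asarray(probs, float)
    y = np.asarray(y, float)
    n = len(probs)
    if scheme == "fixed_width":
        members = [[] for _ in range(n_bins)]
        for i in range(n):
            k = min(int(np.floor(probs[i] * n_bins)), n_bins - 1)
            members[k].append(i)
    else:
        order = list(np.argsort(probs, kind="stable"))
        base, extra = divmod(n, n_bins)
        rank_bin, start = {}, 0
        for b in range(n_bins):
            size = base + (1 if b < extra else 0)
            for i in order[start:start + size]:
                rank_bin[i] = b
            start += size
        # tied values share the bin of their first sorted occurrence
        first_bin = {}
        for i in order:
            first_bin.setdefault(probs[i], rank_bin[i])
        members = [[] for _ in range(n_bins)]
        for i in order:
            members[first_bin[probs[i]]].append(i)
    ce = 0.0
    for idx in members:
        if not idx:
            continue
        conf = float(np.mean(probs[idx]))
        acc = float(np.mean(y[idx]))
        ce += len(idx) * abs(acc - conf)
    return ce / n


class TestProperScores:
    @pytest.mark.parametrize("probs,y,expected", [
        ([1.0, 0.0, 1.0], [1, 0, 1], 0.0),
        ([0.5, 0.5], [1, 0], 0.25),
        ([0.8, 0.3], [1, 0], 0.065),
    ])
    def test_brier_hand_cases(self, probs, y, expected):
        assert brier_score(probs, y) == pytest.approx(expected, abs=1e-12)

    def test_bce_closed_forms(self):
        assert bce_loss([0.5, 0.5], [0, 1]) == pytest.approx(np.log(2), abs=1e-12)
        assert bce_loss([0.9], [0]) == pytest.approx(-np.log(0.1), abs=1e-12)
        # perfect predictions stay ~0 under clipping
        assert bce_loss([1.0, 0.0], [1, 0]) <= 1e-6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            brier_score([], [])


class TestRankingScores:
    def test_auc_cases(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5
        # exhaustive pair enumeration: 3 of 4 pairs won
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_auc_single_class_undefined(self):
        with pytest.raises(MetricUndefinedError):
            auc([0.2, 0.8], [1, 1])

    def test_auc_pair_enumeration_oracle(self, rng):
        probs = rng.random(40)
        y = (rng.random(40) < 0.4).astype(int)
        pos, neg = probs[y == 1], probs[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc(probs, y) == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_auc_monotone_invariance(self, rng):
        probs = rng.random(200)
        y = (rng.random(200) < 0.5).astype(int)
        assert auc(probs, y) == auc(1.0 / (1.0 + np.exp(-(5 * probs - 1))), y)

    def test_accuracy(self):
        assert accuracy([1.0, 0.0], [1, 0]) == 1.0
        assert accuracy([0.4, 0.4], [0, 0]) == 1.0
        assert accuracy([0.6, 0.4], [0, 1]) == 0.0


class TestBinnedCalibrationError:
    def test_hand_case_two_bins(self):
        ce, _ = binned_ce([0.1, 0.9], [0, 1], n_bins=2, scheme="fixed_width")
        assert ce == pytest.approx(0.1, abs=1e-12)

    def test_base_rate_predictor_perfectly_calibrated(self):
        y = np.array([1, 0, 0, 0, 1, 0, 0, 0])
        probs = np.full(8, y.mean())
        for scheme in ("fixed_width", "equal_count"):
            ce, _ = binned_ce(probs, y, n_bins=10, scheme=scheme)
            assert ce == pytest.approx(0.0, abs=1e-12)

    def test_equal_count_bin_sizes(self, rng):
        probs = rng.random(100)
        y = (rng.random(100) < 0.5).astype(int)
        bs = bin_stats(probs, y, n_bins=10, scheme="equal_count")
        assert (bs.counts == 10).all()

    def test_prob_one_lands_in_last_bin(self):
        bs = bin_stats([1.0, 0.0], [1, 0], n_bins=10)
        assert bs.counts[9] == 1 and bs.counts[0] == 1

    @pytest.mark.parametrize("scheme", ["fixed_width", "equal_count"])
    @pytest.mark.parametrize("n_bins", [1, 5, 10, 15])
    def test_matches_bruteforce_oracle(self, rng, scheme, n_bins):
        for _ in range(25):
            n = int(rng.integers(1, 200))
            probs = rng.random(n)
            y = (rng.random(n) < rng.random()).astype(int)
            ce, _ = binned_ce(probs, y, n_bins=n_bins, scheme=scheme)
            assert ce == pytest.approx(ce_bruteforce(probs, y, n_bins, scheme),
                                       abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60),
           st.integers(1, 12), st.booleans())
    def test_bruteforce_equivalence_property(self, probs, n_bins, equal_count):
        y = [(i * 7) % 3 == 0 for i in range(len(probs))]
        scheme = "equal_count" if equal_count else "fixed_width"
        ce, _ = binned_ce(probs, np.array(y, dtype=int), n_bins=n_bins, scheme=scheme)
        assert ce == pytest.approx(
            ce_bruteforce(probs, np.array(y, float), n_bins, scheme), abs=1e-12)


class TestBrierDecomposition:
    def test_single_bin_identity_exact(self, rng):
        probs = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        rel, res, unc = brier_decomposition(probs, y, n_bins=1)
        # single bin: conf and acc are global means; identity holds up to the
        # within-bin variance of the predictions
        assert res == pytest.approx(0.0, abs=1e-12)

    def test_constant_base_rate_prediction(self):
        y = np.array([1, 0, 1, 0])
        probs = np.full(4, 0.5)
        rel, res, unc = brier_decomposition(probs, y, n_bins=10)
        assert rel == pytest.approx(0.0, abs=1e-12)
        assert res == pytest.approx(0.0, abs=1e-12)
        assert rel - res + unc == pytest.approx(brier_score(probs, y), abs=1e-12)

    def test_murphy_identity_constant_within_bins(self, rng):
        # predictions constant within each fixed-width bin => exact identity
        levels = np.array([0.05, 0.15, 0.35, 0.65, 0.95])
        probs = levels[rng.integers(0, 5, size=400)]
        y = (rng.random(400) < probs).astype(int)
        rel, res, unc = brier_decomposition(probs, y, n_bins=10)
        assert rel - res + unc == pytest.approx(brier_score(probs, y), abs=1e-12)

    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0, 1])
        rel, res, unc = brier_decomposition(y.astype(float), y, n_bins=10)
        assert rel == pytest.approx(0.0, abs=1e-12)
        assert res == pytest.approx(unc, abs=1e-12)


class TestModelComparison:
    def test_zero_variance_paired_degenerate(self):
        with pytest.raises(DegenerateTestError):
            compare_models([1, 2, 3], [1, 2, 3], paired=True)

    def test_identical_unpaired(self):
        t, p = compare_models([1, 2, 3, 4], [1, 2, 3, 4], paired=False)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_paired_t_closed_form(self):
        a = np.array([2.1, 2.0, 2.2])
        b = np.array([1.0, 1.1, 0.9])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        t, p = compare_models(a, b, paired=True)
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert 0 < p < 0.05


class TestReport:
    def test_perfect_and_degenerate_reports(self):
        y = np.array([1, 0, 1, 0, 1, 0])
        rep = evaluate_model(y.astype(float), y)
        assert rep.brier == 0.0 and rep.ece == 0.0 and rep.auc == 1.0
        assert rep.bce < 1e-6
        rep2 = evaluate_model(np.full(6, 0.5), y)
        assert rep2.ece == 0.0 and rep2.ace == 0.0 and rep2.auc == 0.5

    def test_single_class_auc_nan_others_finite(self):
        rep = evaluate_model([0.2, 0.7, 0.4], [1, 1, 1])
        assert np.isnan(rep.auc)
        assert np.isfinite([rep.bce, rep.brier, rep.ece, rep.ace]).all()

    def test_fuzz_ranges(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 60))
            probs = rng.random(n)
            y = np.zeros(n, int)
            y[rng.integers(0, n)] = 1  # ensure both classes unless n==1
            rep = evaluate_model(probs, y)
            assert 0 <= rep.brier <= 1 and 0 <= rep.ece <= 1 and 0 <= rep.ace <= 1
            assert 0 <= rep.accuracy <= 1 and rep.bce >= 0
            if not np.isnan(rep.auc):
                assert 0 <= rep.auc <= 1

    def test_bins_frame_tidy(self, rng):
        probs = rng.random(100)
        y = (rng.random(100) < 0.5).astype(int)
        df = evaluate_model(probs, y).bins_frame()
        assert set(df["scheme"]) == {"fixed_width", "equal_count"}
        assert df.groupby("scheme")["n"].sum().eq(100).all()
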