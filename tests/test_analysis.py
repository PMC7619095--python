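import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from usvdend import analysis as an


def trial_set(trials, window=(0, 100), spont=(-500, 0)):
    return an.TrialSet(trials=[np.asarray(t, dtype=float) for t in trials],
                       window_ms=window, spont_window_ms=spont)


class TestPsth:
    def test_no_spikes_gives_zeros(self):
        ts = trial_set([[], []])
        rates, edges = an.psth(ts, 10)
        assert np.all(rates == 0)

    def test_counting(self):
        ts = trial_set([[5, 15]])
        rates, edges = an.psth(ts, 10)
        assert rates[0] == pytest.approx(100.0)
        assert rates[1] == pytest.approx(100.0)
        assert np.all(rates[2:] == 0)

    def test_integral_equals_mean_spike_count(self):
        rng = np.random.default_rng(0)
        ts = trial_set([np.sort(rng.uniform(0, 100, 17)) for _ in range(4)])
        rates, edges = an.psth(ts, 7)
        integral = np.sum(rates) * 7 / 1000
        assert integral == pytest.approx(17.0)


class TestSummationIndex:
    @pytest.mark.parametrize("r_a, r_b, r_ab, expected", [
        (10, 5, 10, 0.0),   # combined equals the stronger input: MAX
        (10, 5, 15, 1.0),   # combined equals the arithmetic sum
        (8, 4, 18, 2.5),    # supralinear
        (5, 10, 10, 0.0),   # symmetric under relabeling
    ])
    def test_values(self, r_a, r_b, r_ab, expected):
        assert an.summation_index(r_a, r_b, r_ab) == pytest.approx(expected)

    def test_zero_weak_response_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            an.summation_index(10, 0, 12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.floats(0.1, 100), hst.floats(0.1, 100), hst.floats(0, 200),
           hst.floats(0.1, 10))
    def test_symmetry_and_scale_invariance(self, r_a, r_b, r_ab, k):
        base = an.summation_index(r_a, r_b, r_ab)
        assert an.summation_index(r_b, r_a, r_ab) == pytest.approx(base)
        scaled = an.summation_index(k * r_a, k * r_b, k * r_ab)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestClassifySmi:
    @pytest.mark.parametrize("smi, expected", [
        (-0.3, an.MAX_LIKE), (0.0, an.MAX_LIKE), (0.5, an.SUBLINEAR),
        (1.0, an.AND_LIKE), (1.4, an.AND_LIKE), (np.inf, an.AND_LIKE)])
    def test_boundaries(self, smi, expected):
        assert an.classify_smi(smi) == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(hst.floats(-10, 10, allow_nan=False))
    def test_partition_no_gaps_no_overlap(self, smi):
        cls = an.classify_smi(smi)
        assert cls in (an.MAX_LIKE, an.SUBLINEAR, an.AND_LIKE)

    def test_configurable_boundary(self):
        assert an.classify_smi(0.9, and_boundary=0.8) == an.AND_LIKE


class TestInclusionFilter:
    def test_strong_responses_pass_significance_path(self):
        resp = [[10, 30, 50, 70], [12, 35, 55], [15, 40, 60, 80],
                [11, 33], [20, 45, 66], [9, 28, 47]]
        a = trial_set(resp)
        b = trial_set(resp)
        ab = trial_set(resp)
        ok, reason = an.inclusion_filter(a, b, ab)
        assert ok
        assert "spontaneous" in reason

    def test_subthreshold_pair_passes_combined_path(self):
        quiet = [[], [50], [], [], [30], []]
        strong = [[10, 30, 50], [12, 35, 60], [15, 40], [20, 44, 70],
                  [25, 48, 77], [8, 22, 39]]
        ok, reason = an.inclusion_filter(trial_set(quiet), trial_set(quiet),
                                         trial_set(strong))
        assert ok
        assert "1.25" in reason

    def test_all_spontaneous_excluded(self):
        quiet = [[], [], [], [], [], []]
        one = [[50], [], [], [], [], []]
        ok, _ = an.inclusion_filter(trial_set(one), trial_set(one),
                                    trial_set(one))
        assert not ok
        ok, _ = an.inclusion_filter(trial_set(quiet), trial_set(quiet),
                                    trial_set(quiet))
        assert not ok


class TestPitchSelectivity:
    @pytest.mark.parametrize("rates, expected", [
        ([5, 5, 5, 5], 0.0),
        ([1, 0, 0, 0], 1.0),
        ([2, 1, 0], 0.6),
    ])
    def test_values(self, rates, expected):
        assert an.pitch_selectivity(rates) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            an.pitch_selectivity([0, 0, 0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(hst.lists(hst.floats(0, 100), min_size=2, max_size=12))
    def test_bounded_in_unit_interval(self, rates):
        if not any(rates):
            return
        s = an.pitch_selectivity(rates)
        assert -1e-9 <= s <= 1 + 1e-9


class TestCrossAdaptation:
    def make(self, n_spikes):
        times = [list(np.linspace(5, 90, k)) for k in n_spikes]
        return trial_set(times)

    @pytest.mark.parametrize("fwd, rev, expected", [
        ((10, 9), (10, 8), "bidirectional"),   # 0.9 and 0.8
        ((10, 9), (10, 2), "asymmetric"),      # 0.9 and 0.2
        ((10, 3), (10, 1), "none"),            # 0.3 and 0.1
    ])
    def test_categories(self, fwd, rev, expected):
        out = an.cross_adaptation(self.make([fwd[0]] * 4),
                                  self.make([fwd[1]] * 4),
                                  self.make([rev[0]] * 4),
                                  self.make([rev[1]] * 4))
        assert out.category == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            an.cross_adaptation(self.make([0] * 3), self.make([1] * 3),
                                self.make([5] * 3), self.make([5] * 3))


class TestLotoVariability:
    def test_identical_trials_zero_sd(self):
        ts = trial_set([[10, 20, 30]] * 5)
        assert an.loto_smi_variability(ts, ts, ts) == pytest.approx(0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        def make(base):
            return trial_set([
                list(np.sort(rng.uniform(0, 100, base + k)))
                for k in (0, 1, 2, 0, 1)])
        a, b, ab = make(4), make(6), make(9)
        sd = an.loto_smi_variability(a, b, ab)
        doubled = [trial_set([np.concatenate([t, t + 0.01])
                              for t in ts.trials], ts.window_ms)
                   for ts in (a, b, ab)]
        sd2 = an.loto_smi_variability(*doubled)
        assert sd2 == pytest.approx(sd, rel=1e-6)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(2)
        sets = [trial_set([np.sort(rng.uniform(0, 100, rng.integers(2, 9)))
                           for _ in range(6)]) for _ in range(3)]
        sd = an.loto_smi_variability(*sets)
        # brute force: drop trial k, recount rates from raw spike times
        smis = []
        for k in range(6):
            rates = []
            for ts in sets:
                kept = [t for i, t in enumerate(ts.trials) if i != k]
                counts = [np.sum((t >= 0) & (t < 100)) for t in kept]
                rates.append(1000 * np.mean(counts) / 100)
            smis.append((rates[2] - max(rates[0], rates[1]))
                        / min(rates[0], rates[1]))
        assert sd == pytest.approx(np.std(smis, ddof=1))

    def test_too_few_trials_rejected(self):
        ts = trial_set([[1], [2]])
        with pytest.raises(ValueError):
            an.loto_smi_variability(ts, ts, ts)


class TestOptimalLag:
    def rec(self, lag, r_ab):
        return an.SmIRecord(r_a=10, r_b=5, r_ab=r_ab, smi=0, smi_class="",
                            lag_ms=lag)

    def test_single_record(self):
        r = self.rec(0, 10)
        assert an.optimal_lag([r]) is r

    def test_argmax_of_combined_response(self):
        recs = [self.rec(-10, 10), self.rec(0, 25), self.rec(10, 12)]
        assert an.optimal_lag(recs).lag_ms == 0

    def test_tie_breaks_toward_small_then_negative_lag(self):
        recs = [self.rec(-10, 20), self.rec(10, 20), self.rec(15, 19)]
        assert an.optimal_lag(recs).lag_ms == -10
        recs = [self.rec(-10, 20), self.rec(5, 20)]
        assert an.optimal_lag(recs).lag_ms == 5
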