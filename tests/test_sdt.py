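"""Signal-detection pipeline tests: exclusion, binning, rates, measures,
thresholds and time courses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tactsupp import (
    AmplitudeGrid,
    DesignSpec,
    PsychometricThreshold,
    assign_noise_bins,
    bin_amplitudes,
    compute_sdt_cells,
    corrected_rates,
    detection_threshold,
    detection_timecourse,
    exclude_cells,
    filter_trials,
    loglinear_rates,
    make_cohort,
    paper_like_observer,
    sdt_measures,
    simulate_cohort,
)
from tactsupp.exceptions import (
    EmptyCellError,
    InsufficientNoiseError,
    MustCorrectError,
    NoThresholdError,
    UnsupportedGridError,
)

from _oracles import norm_ppf, sdt_from_counts


def _trial_row(**kw):
    base = dict(
        trial_id=0, participant_id="p001", session_cue="cue-", block=0,
        movement="active", stimulus_present=True, amplitude_mm=0.05,
        stim_time_rel_go=900.0, movement_onset_rel_go=1000.0,
        movement_offset_rel_go=2000.0, stim_time_rel_onset=-100.0,
        response="yes", valid=True, exclusion_reason="",
    )
    base.update(kw)
    return base


class TestFilter:
    def _table(self):
        rows = [
            _trial_row(trial_id=0, stim_time_rel_onset=-150.0),
            _trial_row(trial_id=1, stim_time_rel_onset=20.0),
            _trial_row(trial_id=2, stim_time_rel_onset=-300.0),
            _trial_row(trial_id=3, stim_time_rel_onset=0.0),
            _trial_row(trial_id=4, stim_time_rel_onset=-400.0),
            _trial_row(trial_id=5, movement="baseline", stim_time_rel_go=700.0,
                       movement_onset_rel_go=np.nan, movement_offset_rel_go=np.nan,
                       stim_time_rel_onset=np.nan),
            _trial_row(trial_id=6, response="missing", valid=False),
            _trial_row(trial_id=7, movement_onset_rel_go=np.nan,
                       stim_time_rel_onset=np.nan),
            _trial_row(trial_id=8, stimulus_present=False, amplitude_mm=np.nan,
                       stim_time_rel_go=np.nan, stim_time_rel_onset=np.nan),
        ]
        return pd.DataFrame(rows)

    def test_window_rule(self):
        kept, _ = filter_trials(self._table())
        ids = set(kept["trial_id"])
        assert 0 in ids  # -150 ms: inside the window
        assert 1 not in ids  # after movement onset
        assert 2 in ids  # boundary -300 ms inclusive
        assert 3 not in ids  # at onset: excluded
        assert 4 not in ids  # earlier than -300 ms

    def test_step1_removes_failures(self):
        kept, _ = filter_trials(self._table())
        ids = set(kept["trial_id"])
        assert 6 not in ids  # missing response
        assert 7 not in ids  # movement trial without onset

    def test_baseline_and_catch_pass_untouched(self):
        kept, _ = filter_trials(self._table())
        ids = set(kept["trial_id"])
        assert 5 in ids and 8 in ids

    def test_accounting(self):
        table = self._table()
        kept, summary = filter_trials(table)
        assert summary["n_total"].sum() == len(table)
        assert (
            summary["n_kept"] + summary["n_step1"] + summary["n_step2"]
        ).equals(summary["n_total"])
        assert summary["n_kept"].sum() == len(kept)


class TestBinning:
    def test_default_partition_reproduces_printed_bin_means(self):
        scheme = bin_amplitudes(AmplitudeGrid.default())
        assert [round(m, 3) for m in scheme.bin_mean_amplitude] == [
            0.019, 0.044, 0.076, 0.107, 0.133,
        ]

    def test_third_bin_holds_middle_three_levels(self):
        scheme = bin_amplitudes(AmplitudeGrid.default())
        assert scheme.sizes == (2, 2, 3, 2, 2)
        assert [i for i, b in enumerate(scheme.level_bin) if b == 2] == [4, 5, 6]

    def test_partition_covers_grid(self):
        grid = AmplitudeGrid.default()
        scheme = bin_amplitudes(grid)
        assert len(scheme.level_bin) == grid.n_levels
        assert sorted(set(scheme.level_bin)) == list(range(scheme.n_bins))
        # contiguity: bin index is non-decreasing across the ordered grid
        assert list(scheme.level_bin) == sorted(scheme.level_bin)

    def test_wrong_grid_size_rejected(self):
        with pytest.raises(UnsupportedGridError):
            bin_amplitudes(AmplitudeGrid.literal_step(n_levels=10))

    def test_generic_binning_behind_flag(self):
        grid = AmplitudeGrid.literal_step(n_levels=9)
        scheme = bin_amplitudes(grid, sizes=(3, 3, 3))
        assert scheme.n_bins == 3

    @given(st.integers(5, 200), st.integers(2, 8))
    @settings(max_examples=50, deadline=None)
    def test_noise_split_near_equal(self, n, b):
        if n < b:
            return
        labels = assign_noise_bins(n, b, np.random.default_rng(0))
        sizes = np.bincount(labels, minlength=b)
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1

    def test_noise_split_examples(self):
        sizes = np.bincount(assign_noise_bins(66, 5, np.random.default_rng(1)))
        assert sorted(sizes) == [13, 13, 13, 13, 14]
        assert sorted(np.bincount(assign_noise_bins(5, 5, np.random.default_rng(2)))) == [1] * 5

    def test_noise_split_seeded_and_guarded(self):
        a = assign_noise_bins(66, 5, np.random.default_rng(9))
        b = assign_noise_bins(66, 5, np.random.default_rng(9))
        assert np.array_equal(a, b)
        with pytest.raises(InsufficientNoiseError):
            assign_noise_bins(4, 5, np.random.default_rng(0))


class TestRates:
    def test_perfect_accuracy_corrected(self):
        H, F, corrected = corrected_rates(66, 66, 0, 66)
        assert corrected
        assert H == pytest.approx(66.5 / 67)
        assert F == pytest.approx(0.5 / 67)

    def test_interior_rates_untouched(self):
        H, F, corrected = corrected_rates(30, 32, 1, 13)
        assert not corrected
        assert H == pytest.approx(0.9375)
        assert F == pytest.approx(1 / 13)

    def test_symmetric_boundary_corrected(self):
        H, F, corrected = corrected_rates(0, 10, 5, 10)
        assert corrected
        assert H == pytest.approx(0.5 / 11)
        assert F == pytest.approx(5.5 / 11)

    def test_empty_cell_rejected(self):
        with pytest.raises(EmptyCellError):
            corrected_rates(0, 0, 0, 5)

    def test_always_correct_mode(self):
        H, F, corrected = loglinear_rates(6, 12, 2, 13)
        assert corrected and H == pytest.approx(6.5 / 13) and F == pytest.approx(2.5 / 14)

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_containment_and_bounded_change(self, n_s, n_n, h, f):
        h, f = min(h, n_s), min(f, n_n)
        H, F, corrected = corrected_rates(h, n_s, f, n_n)
        assert 0.0 < H < 1.0 and 0.0 < F < 1.0
        if corrected:
            assert abs(H - h / n_s) <= 0.5 / (n_s + 1) + 1e-12
            assert abs(F - f / n_n) <= 0.5 / (n_n + 1) + 1e-12


class TestMeasures:
    def test_chance_performance(self):
        d, c, rel = sdt_measures(0.5, 0.5)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(rel)

    def test_against_quantile_oracle(self):
        d, c, _ = sdt_measures(0.9375, 1 / 13)
        assert d == pytest.approx(norm_ppf(0.9375) - norm_ppf(1 / 13), abs=1e-9)
        assert d == pytest.approx(2.960, abs=2e-3)
        assert c == pytest.approx(-0.054, abs=2e-3)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(max_examples=200, deadline=None)
    def test_swap_symmetry(self, H, F):
        # swapping H and F negates d'; c = -(z(H)+z(F))/2 is swap-invariant,
        # while negating BOTH rates (H -> 1-H, F -> 1-F) negates c
        d1, c1, _ = sdt_measures(H, F)
        d2, c2, _ = sdt_measures(F, H)
        assert d2 == pytest.approx(-d1, abs=1e-10)
        assert c2 == pytest.approx(c1, abs=1e-10)
        d3, c3, _ = sdt_measures(1 - H, 1 - F)
        assert c3 == pytest.approx(-c1, abs=1e-10)
        assert d3 == pytest.approx(-d1, abs=1e-10)

    @given(st.floats(0.05, 0.9), st.floats(0.02, 0.05), st.floats(0.01, 0.08))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, H, dH, F):
        d_lo, _, _ = sdt_measures(H, F)
        d_hi, _, _ = sdt_measures(min(H + dH, 0.999), F)
        assert d_hi > d_lo
        d_f, _, _ = sdt_measures(H, min(F + 0.05, 0.999))
        assert d_f < d_lo

    def test_boundary_rates_rejected(self):
        with pytest.raises(MustCorrectError):
            sdt_measures(1.0, 0.1)
        with pytest.raises(MustCorrectError):
            sdt_measures(0.5, 0.0)

    def test_oracle_equivalence_small_counts(self):
        # every count combination on up to 20 trials per cell
        for n in (1, 2, 5, 12, 20):
            for h in range(n + 1):
                for f in range(n + 1):
                    H, F, _ = corrected_rates(h, n, f, n)
                    d, c, _ = sdt_measures(H, F)
                    d0, c0 = sdt_from_counts(h, n, f, n)
                    assert d == pytest.approx(d0, abs=1e-9)
                    assert c == pytest.approx(c0, abs=1e-9)


class TestExclusion:
    def _cells(self):
        rows = []
        for pid, d in [("p001", 0.05), ("p002", 2.0), ("p003", 1.0)]:
            for b in range(5):
                rows.append(dict(participant_id=pid, movement="active",
                                 session_cue="cue-", bin_index=b, d_prime=d,
                                 c=0.2, relative_c=0.2 / d))
        rows[-1]["relative_c"] = 50.0  # one extreme bin for p003
        return pd.DataFrame(rows)

    def test_near_zero_dprime_condition_excluded(self):
        out = exclude_cells(self._cells())
        assert out.loc[out["participant_id"] == "p001", "excluded"].all()
        assert not out.loc[out["participant_id"] == "p002", "excluded"].any()

    def test_cell_level_mode(self):
        out = exclude_cells(self._cells(), level="cell")
        p3 = out[out["participant_id"] == "p003"]
        assert p3["excluded"].sum() == 1

    def test_relative_c_rule(self):
        cells = self._cells()
        cells.loc[cells["participant_id"] == "p002", "relative_c"] = 40.0
        out = exclude_cells(cells)
        assert out.loc[out["participant_id"] == "p002", "excluded"].all()


class TestThreshold:
    def test_interpolation_midpoint(self):
        rows = []
        for amp, k in [(1.0, 2), (2.0, 5), (3.0, 8)]:
            for i in range(10):
                rows.append(dict(stimulus_present=True, amplitude_mm=amp,
                                 response="yes" if i < k else "no"))
        thr = detection_threshold(pd.DataFrame(rows))
        assert thr == pytest.approx(2.0, abs=0.05)

    def test_recovers_generating_threshold(self):
        # observer p(yes) = Phi(20 a - 1): 50% point at 0.05 mm
        rng = np.random.default_rng(3)
        grid = np.asarray(AmplitudeGrid.default().levels)
        a = np.repeat(grid, 1000)
        from scipy.stats import norm as _n
        y = rng.random(a.size) < _n.cdf(20.0 * a - 1.0)
        est = PsychometricThreshold().fit(a, y.astype(float))
        assert est.method_ == "mle"
        assert est.threshold_ == pytest.approx(0.05, abs=0.003)

    def test_doubling_gain_halves_threshold(self):
        rng = np.random.default_rng(4)
        grid = np.asarray(AmplitudeGrid.default().levels)
        a = np.repeat(grid, 1000)
        from scipy.stats import norm as _n
        u = rng.random(a.size)
        t1 = PsychometricThreshold().fit(a, (u < _n.cdf(20 * a - 1)).astype(float)).threshold_
        t2 = PsychometricThreshold().fit(a, (u < _n.cdf(40 * a - 1)).astype(float)).threshold_
        assert t2 == pytest.approx(t1 / 2, rel=0.15)

    def test_uninformative_data_rejected(self):
        df = pd.DataFrame(dict(stimulus_present=[True] * 4,
                               amplitude_mm=[1.0, 2.0, 3.0, 4.0],
                               response=["yes"] * 4))
        with pytest.raises(NoThresholdError):
            detection_threshold(df)


class TestTimecourse:
    def test_single_bin_equals_overall_rate(self, small_cohort):
        t = small_cohort.trials
        tc = detection_timecourse(t, bin_edges_ms=np.array([-300.0, 0.0]))
        sel = (
            t["movement"].isin(["active", "passive"])
            & t["stimulus_present"]
            & (t["stim_time_rel_onset"] >= -300)
            & (t["stim_time_rel_onset"] < 0)
        )
        overall = (t.loc[sel, "response"] == "yes").mean()
        pooled = tc["detected"].sum() / tc["n"].sum()
        assert pooled == pytest.approx(overall)

    def test_unordered_edges_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            detection_timecourse(small_cohort.trials, bin_edges_ms=np.array([0.0, -300.0]))

    def test_constant_probability_within_binomial_ci(self):
        # time-constant detection probability: every bin's CI covers p
        model = paper_like_observer(lapse_rate=0.0, guess_rate=0.0)
        model.gain = {m: 1e-6 for m in ("baseline", "active", "passive")}
        model.criterion = {m: 0.5 for m in ("baseline", "active", "passive")}
        sim = simulate_cohort([model] * 6, DesignSpec(reps_per_amplitude=24), seed=61,
                              scheduling="iid")
        from scipy.stats import norm as _n
        p = _n.cdf(-0.5)
        tc = detection_timecourse(sim.trials)
        big = tc[tc["n"] >= 20]
        assert len(big) >= 6
        assert ((big["ci_low"] <= p) & (p <= big["ci_high"])).all()

    def test_earlier_sensitivity_drop_detected_earlier(self):
        # active sensitivity collapses 150 ms before onset, passive 50 ms
        def profile(movement, t):
            cut = -150.0 if movement == "active" else -50.0
            return 0.05 if t >= cut else 1.0

        hits = 0
        for s in range(10):
            models = make_cohort(6, seed=700 + s, lapse_rate=0.0, guess_rate=0.0)
            for m in models:
                m.gain_timecourse = profile
            sim = simulate_cohort(models, DesignSpec(reps_per_amplitude=24),
                                  seed=800 + s, scheduling="iid")
            tc = detection_timecourse(sim.trials, by=("movement",))
            first_drop = {}
            for mv, grp in tc.groupby("movement", observed=True):
                grp = grp.sort_values("bin_left_ms")
                half = (grp["rate"].max() + grp["rate"].min()) / 2
                below = grp[grp["rate"] <= half]
                first_drop[mv] = below["bin_left_ms"].min() if len(below) else np.inf
            if first_drop["active"] < first_drop["passive"]:
                hits += 1
        assert hits >= 9


class TestEndToEnd:
    def test_cells_schema_and_accounting(self, small_cells):
        assert {"d_prime", "c", "relative_c", "H", "F", "corrected"} <= set(
            small_cells.columns
        )
        assert small_cells["bin_index"].between(0, 4).all()
        assert ((small_cells["H"] > 0) & (small_cells["H"] < 1)).all()
        assert ((small_cells["F"] > 0) & (small_cells["F"] < 1)).all()
        # 6 participants x 3 movements x 2 cues x 5 bins
        assert len(small_cells) == 180

    def test_noise_counts_partition_catch_trials(self, small_cohort, small_cells):
        per_cond = small_cells.groupby(
            ["participant_id", "movement", "session_cue"], observed=True
        )["n_noise"].sum()
        assert (per_cond == 66).all()

    def test_seeded_noise_assignment_reproducible(self, small_cohort):
        a, _ = compute_sdt_cells(small_cohort.trials, seed=13)
        b, _ = compute_sdt_cells(small_cohort.trials, seed=13)
        assert a.equals(b)

    def test_excluded_condition_fraction_small_on_paper_like_cohort(self, small_cells):
        # the d'~0 / |relative c|>30 rule should fire on well under 1% of
        # condition cells for a paper-like cohort
        assert small_cells["excluded"].mean() < 0.01
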