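import numpy as np
import pytest
from scipy import stats

from boldwaves import (
    BinnedSeries,
    BoldRun,
    Segment,
    Signal1D,
    SurfaceGeometry,
    bin_by_gradient,
    bin_series,
    classify_run,
    classify_segment,
    count_waves,
    make_geometry,
    peak_table,
    segment_by_troughs,
    subject_wave_counts,
    wave_locked_average,
    wave_score_map,
)
from boldwaves.synthetic import SimConfig, simulate_run
from boldwaves.waves import PeakTable, WaveEvent

TR = 0.8


class TestBinning:
    def test_even_division(self):
        geom = SurfaceGeometry(pg_score=np.random.default_rng(0).normal(size=140))
        b = bin_by_gradient(geom, 70)
        occ = np.bincount(b.bin_of_vertex, minlength=70)
        assert np.all(occ == 2)

    def test_sign_flip_mirrors_bins(self, rng):
        scores = rng.normal(size=350)  # distinct with probability 1
        b1 = bin_by_gradient(SurfaceGeometry(pg_score=scores), 70)
        b2 = bin_by_gradient(SurfaceGeometry(pg_score=-scores), 70)
        np.testing.assert_array_equal(b2.bin_of_vertex, 69 - b1.bin_of_vertex)

    def test_sign_flip_mirrors_even_with_remainder(self, rng):
        # 2000 vertices over 70 bins: occupancies 28/29, laid out
        # palindromically so the mirror identity still holds exactly
        scores = rng.normal(size=2000)
        b1 = bin_by_gradient(SurfaceGeometry(pg_score=scores), 70)
        b2 = bin_by_gradient(SurfaceGeometry(pg_score=-scores), 70)
        np.testing.assert_array_equal(b2.bin_of_vertex, 69 - b1.bin_of_vertex)

    def test_occupancy_and_ordered_ranges(self, rng):
        scores = rng.normal(size=489)
        b = bin_by_gradient(SurfaceGeometry(pg_score=scores), 70)
        occ = np.bincount(b.bin_of_vertex, minlength=70)
        assert occ.max() - occ.min() <= 1
        tops = [scores[b.vertices_in(i)].max() for i in range(69)]
        bots = [scores[b.vertices_in(i + 1)].min() for i in range(69)]
        assert all(t <= b_ for t, b_ in zip(tops, bots))

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError):
            bin_by_gradient(SurfaceGeometry(pg_score=np.arange(10.0)), 11)


class TestBinSeries:
    def test_one_vertex_bins_and_groupby_oracle(self, rng):
        geom = SurfaceGeometry(pg_score=np.arange(5.0))
        run = BoldRun(rng.normal(size=(5, 20)), TR)
        b = bin_by_gradient(geom, 5)
        out = bin_series(run, b)
        np.testing.assert_allclose(out.data, run.data, atol=1e-12)
        geom2 = SurfaceGeometry(pg_score=rng.normal(size=60))
        run2 = BoldRun(rng.normal(size=(60, 15)), TR)
        b2 = bin_by_gradient(geom2, 6)
        out2 = bin_series(run2, b2)
        for i in range(6):
            np.testing.assert_allclose(
                out2.data[i], run2.data[b2.vertices_in(i)].mean(axis=0),
                atol=1e-12)

    def test_linearity(self, rng):
        geom = SurfaceGeometry(pg_score=rng.normal(size=40))
        b = bin_by_gradient(geom, 8)
        x, y = rng.normal(size=(2, 40, 12))
        lhs = bin_series(BoldRun(2 * x + y, TR), b).data
        rhs = 2 * bin_series(BoldRun(x, TR), b).data + bin_series(
            BoldRun(y, TR), b).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestSegmentation:
    def test_single_cycle_trough_to_trough(self):
        # sample ~2.75 cycles so two troughs are interior local minima
        t = np.arange(0, 44, TR)
        g = Signal1D(-np.cos(2 * np.pi * t / 16), TR)
        segs = segment_by_troughs(g)
        assert len(segs) == 1
        seg = segs[0]
        mid = (seg.start_frame + seg.end_frame) / 2
        assert abs(seg.gbold_peak_frame - mid) <= 1

    def test_monotone_ramp_has_no_segments(self):
        assert segment_by_troughs(Signal1D(np.arange(50.0), TR)) == []

    def test_matches_bruteforce_minima_scan(self, rng):
        t = np.arange(478) * TR
        g = (np.sin(2 * np.pi * 0.03 * t) + 0.6 * np.sin(2 * np.pi * 0.07 * t + 1)
             + 0.3 * np.sin(2 * np.pi * 0.011 * t + 2))
        troughs = [i for i in range(1, len(g) - 1)
                   if g[i] < g[i - 1] and g[i] < g[i + 1]]
        segs = segment_by_troughs(Signal1D(g, TR))
        assert [s.start_frame for s in segs] == troughs[:-1]
        assert [s.end_frame for s in segs] == troughs[1:]
        for s in segs:
            inner = g[s.start_frame:s.end_frame]
            assert g[s.gbold_peak_frame] == inner.max()
        # segments partition [first trough, last trough) without overlap
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end_frame == b.start_frame


def _bump(n, center, width=4.0, amp=1.0):
    t = np.arange(n, dtype=float)
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


class TestPeakTable:
    def test_zero_and_shifted_delays(self):
        n = 60
        gbold_course = _bump(n, 30)
        binned = BinnedSeries(np.vstack([gbold_course,
                                         np.roll(gbold_course, 2)]), TR)
        seg = Segment(5, 55, gbold_peak_frame=30)
        pt = peak_table(binned, seg)
        assert pt.delay_seconds[0] == pytest.approx(0.0)
        assert pt.delay_seconds[1] == pytest.approx(2 * TR)

    def test_matches_exhaustive_scan(self, rng):
        n = 80
        data = np.cumsum(rng.normal(size=(12, n)), axis=1)
        from scipy.ndimage import gaussian_filter1d
        data = gaussian_filter1d(data, 3.0, axis=1)
        binned = BinnedSeries(data, TR)
        seg = Segment(10, 70, gbold_peak_frame=40)
        pt = peak_table(binned, seg)
        for b in range(12):
            w = data[b, 10:70]
            local = [j for j in range(1, len(w) - 1)
                     if w[j] > w[j - 1] and w[j] > w[j + 1]]
            if not local:
                assert np.isnan(pt.delay_seconds[b])
            else:
                best = max(local, key=lambda j: w[j])
                assert pt.delay_seconds[b] == pytest.approx(
                    (10 + best - 40) * TR)

    def test_plateau_uses_earliest_frame(self):
        w = np.array([0, 1, 2, 2, 2, 1, 0], dtype=float)
        binned = BinnedSeries(w[None, :], TR)
        pt = peak_table(binned, Segment(0, 7, gbold_peak_frame=3))
        assert pt.delay_seconds[0] == pytest.approx((2 - 3) * TR)

    def test_involvement_fraction(self):
        pt = PeakTable(np.array([0.0, np.nan, 1.0, np.nan]))
        assert pt.involvement_fraction == pytest.approx(0.5)


def _delays(present_delays, n_bins=70):
    """PeakTable with given delays in the first bins, NaN elsewhere."""
    d = np.full(n_bins, np.nan)
    d[: len(present_delays)] = present_delays
    return PeakTable(d)


class TestClassification:
    seg = Segment(0, 100, gbold_peak_frame=50)

    def test_perfect_linear_delay_is_bottom_up(self):
        binning = bin_by_gradient(SurfaceGeometry(
            pg_score=np.arange(140.0)), 70)
        pt = PeakTable(np.linspace(-4, 4, 70))
        ev = classify_segment(pt, binning, self.seg)
        assert ev.label == "bottom_up"
        assert ev.r == pytest.approx(1.0)

    def test_reversed_gradient_is_top_down(self):
        binning = bin_by_gradient(SurfaceGeometry(
            pg_score=np.arange(140.0)), 70)
        pt = PeakTable(np.linspace(-4, 4, 70)[::-1].copy())
        ev = classify_segment(pt, binning, self.seg)
        assert ev.label == "top_down"
        assert ev.r == pytest.approx(-1.0)

    def test_involvement_boundary_80_percent(self):
        binning = bin_by_gradient(SurfaceGeometry(
            pg_score=np.arange(140.0)), 70)
        ev55 = classify_segment(_delays(np.linspace(-4, 4, 55)), binning, self.seg)
        assert ev55.label == "excluded_low_involvement"
        ev56 = classify_segment(_delays(np.linspace(-4, 4, 56)), binning, self.seg)
        assert ev56.label != "excluded_low_involvement"

    def test_constant_delays_no_propagation(self):
        binning = bin_by_gradient(SurfaceGeometry(
            pg_score=np.arange(140.0)), 70)
        ev = classify_segment(PeakTable(np.zeros(70)), binning, self.seg)
        assert ev.label == "no_propagation"

    def test_too_few_bins_degenerate(self):
        binning = bin_by_gradient(SurfaceGeometry(pg_score=np.arange(8.0)), 4)
        pt = PeakTable(np.array([0.0, 1.0, np.nan, np.nan]))
        ev = classify_segment(pt, binning, self.seg, involvement_threshold=0.1)
        assert ev.label == "excluded_low_involvement"

    def test_iid_delays_null_rate_matches_t_test(self, rng):
        # under exchangeable delays the p<0.01 rate should be ~1% and the
        # p-value itself should agree with a permutation null
        binning = bin_by_gradient(SurfaceGeometry(
            pg_score=np.arange(140.0)), 70)
        n_wave = 0
        n_trials = 400
        for _ in range(n_trials):
            pt = PeakTable(rng.normal(size=70))
            ev = classify_segment(pt, binning, self.seg)
            n_wave += ev.label in ("bottom_up", "top_down")
        assert n_wave / n_trials < 0.03

    def test_p_value_agrees_with_permutation_oracle_10_bins(self, rng):
        delays = rng.normal(size=10)
        positions = np.arange(10.0)
        r_obs = stats.pearsonr(delays, positions).statistic
        p_t = stats.pearsonr(delays, positions).pvalue
        perm = np.array([
            abs(stats.pearsonr(rng.permutation(delays), positions).statistic)
            for _ in range(4000)])
        p_perm = np.mean(perm >= abs(r_obs))
        assert p_t == pytest.approx(p_perm, abs=0.03)


class TestCountsAndAverages:
    def _event(self, label, start=10, end=30, peak=20):
        return WaveEvent(Segment(start, end, peak), 0.5, 0.001, label, 1.0)

    def test_count_waves(self):
        assert all(v == 0 for v in count_waves([]).values())
        events = [self._event("bottom_up"), self._event("bottom_up"),
                  self._event("top_down"), self._event("no_propagation"),
                  self._event("excluded_low_involvement")]
        counts = count_waves(events)
        assert counts["bottom_up"] == 2
        assert counts["top_down"] == 1
        assert sum(counts.values()) == len(events)

    def test_subject_counts_sum_and_rate_normalise(self):
        per_run = {"AP1": [self._event("bottom_up")] * 2,
                   "PA1": [self._event("bottom_up")] * 3}
        equal = subject_wave_counts(per_run, {"AP1": 360.0, "PA1": 360.0})
        assert equal["bottom_up"] == 5 and not equal["per_minute"]
        uneq = subject_wave_counts(per_run, {"AP1": 360.0, "PA1": 120.0})
        assert uneq["per_minute"]
        assert uneq["bottom_up"] == pytest.approx(5 / 8.0)  # 480 s = 8 min

    def test_wave_locked_average_single_and_bruteforce(self, rng):
        data = rng.normal(size=(6, 100))
        binned = BinnedSeries(data, TR)
        ev = self._event("bottom_up", 30, 60, 45)
        w = 4.0
        single = wave_locked_average(binned, [ev], w)
        k = int(round(w / TR))
        np.testing.assert_allclose(single.data, data[:, 45 - k:45 + k + 1],
                                   atol=1e-12)
        assert single.event_count == 1
        np.testing.assert_allclose(
            wave_locked_average(binned, [ev, ev], w).data, single.data,
            atol=1e-12)
        evs = [self._event("bottom_up", p - 10, p + 10, p) for p in (20, 50, 80)]
        multi = wave_locked_average(binned, evs, w)
        brute = np.mean([data[:, p - k:p + k + 1] for p in (20, 50, 80)], axis=0)
        np.testing.assert_allclose(multi.data, brute, atol=1e-12)

    def test_edge_events_dropped(self, rng):
        binned = BinnedSeries(rng.normal(size=(3, 50)), TR)
        ev = self._event("bottom_up", 0, 10, 2)
        with pytest.raises(ValueError):
            wave_locked_average(binned, [ev], window_seconds=8.0)


class TestScoreMap:
    def _averages(self, stack):
        from boldwaves.waves import WaveLockedAverage
        rel = np.arange(stack.shape[2]) * TR
        return [WaveLockedAverage(s, rel, 1) for s in stack]

    def test_constant_covariate_flagged(self, rng):
        stack = rng.normal(size=(8, 3, 5))
        r, p, ok = wave_score_map(self._averages(stack), np.ones(8))
        assert not ok and np.all(np.isnan(r))

    def test_covariate_equal_to_cell_gives_r_one(self, rng):
        stack = rng.normal(size=(10, 2, 3))
        cov = stack[:, 1, 2]
        r, p, ok = wave_score_map(self._averages(stack), cov)
        assert ok and r[1, 2] == pytest.approx(1.0)

    def test_matches_per_cell_bruteforce(self, rng):
        stack = rng.normal(size=(12, 3, 4))
        cov = rng.normal(size=12)
        ages = rng.normal(60, 4, size=12)
        from boldwaves import residualize_age
        r, p, ok = wave_score_map(self._averages(stack), cov, ages=ages)
        cov_adj = residualize_age(cov, ages)
        for b in range(3):
            for t in range(4):
                cell = residualize_age(stack[:, b, t], ages)
                res = stats.pearsonr(cell, cov_adj)
                assert r[b, t] == pytest.approx(res.statistic, abs=1e-10)
                assert p[b, t] == pytest.approx(res.pvalue, abs=1e-10)


class TestEquivariances:
    def _simulate(self, seed, n_vertices=280):
        cfg = SimConfig(n_vertices=n_vertices, event_rate_per_min=1.5)
        geom = make_geometry(n_vertices, 70, 14, seed=seed)
        rng = np.random.default_rng(seed)
        run, _, _, events = simulate_run(cfg, geom, rng)
        return cfg, geom, run, events

    def test_pg_negation_swaps_labels_exactly(self):
        cfg, geom, run, _ = self._simulate(seed=5)
        gbold = Signal1D(run.data.mean(axis=0), run.tr_seconds)
        flipped = SurfaceGeometry(pg_score=-geom.pg_score,
                                  parcel_id=geom.parcel_id,
                                  parcel_table=geom.parcel_table)
        swap = {"bottom_up": "top_down", "top_down": "bottom_up"}
        b1 = bin_by_gradient(geom, 70)
        b2 = bin_by_gradient(flipped, 70)
        ev1 = classify_run(bin_series(run, b1), gbold, b1)
        ev2 = classify_run(bin_series(run, b2), gbold, b2)
        assert len(ev1) == len(ev2)
        for a, b in zip(ev1, ev2):
            assert b.label == swap.get(a.label, a.label)
            if np.isfinite(a.r):
                assert abs(a.r) == pytest.approx(abs(b.r), abs=1e-12)
                assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_time_reversal_negates_delays_and_swaps_labels(self):
        # noise-free run with three strong events: the middle one is the
        # fully bounded segment under both time directions
        cfg = SimConfig(n_vertices=280, vertex_noise_sd=0.0,
                        event_rate_per_min=0.55)
        geom = make_geometry(280, 70, 14, seed=9)
        rng = np.random.default_rng(9)
        import pandas as pd
        events = pd.DataFrame({
            "center_s": [80.0, 190.0, 300.0],
            "direction": ["bottom_up"] * 3,
            "amplitude": [2.0] * 3,
        })
        run, _, _, _ = simulate_run(cfg, geom, rng, events=events)
        binning = bin_by_gradient(geom, 70)
        gbold = Signal1D(run.data.mean(axis=0), run.tr_seconds)
        fwd = classify_run(bin_series(run, binning), gbold, binning)
        rev_run = run.replace_data(run.data[:, ::-1].copy())
        rev_g = Signal1D(gbold.values[::-1].copy(), run.tr_seconds)
        rev = classify_run(bin_series(rev_run, binning), rev_g, binning)
        fwd_waves = [e for e in fwd if e.label == "bottom_up"]
        rev_waves = [e for e in rev if e.label == "top_down"]
        assert len(fwd_waves) >= 1
        assert len(rev_waves) == len(fwd_waves)
        assert all(a.r == pytest.approx(-b.r, abs=1e-9)
                   for a, b in zip(fwd_waves, reversed(rev_waves)))

    def test_noise_free_event_classified_with_near_perfect_r(self):
        cfg = SimConfig(n_vertices=280, vertex_noise_sd=0.0)
        geom = make_geometry(280, 70, 14, seed=2)
        import pandas as pd
        events = pd.DataFrame({
            "center_s": [80.0, 190.0, 300.0],
            "direction": ["bottom_up"] * 3,
            "amplitude": [2.0] * 3,
        })
        run, _, _, _ = simulate_run(cfg, geom, np.random.default_rng(2),
                                    events=events)
        binning = bin_by_gradient(geom, 70)
        gbold = Signal1D(run.data.mean(axis=0), run.tr_seconds)
        evs = classify_run(bin_series(run, binning), gbold, binning)
        waves = [e for e in evs if e.label == "bottom_up"]
        assert waves and max(e.r for e in waves) > 0.99
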