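"""Acquisition engine: AGC physics, trigger chain, timing, mode behavior."""

import numpy as np
import pytest

from hybridia.acquire import (
    AcqConfig,
    ScanRecord,
    accumulate,
    allocate_msx_fill,
    confirm_fragments,
    detect_in_ms1,
    id_loss_model,
    run_acquisition,
    run_surequant,
    scan_duration,
    time_budget,
)
from hybridia.synth import make_panel_run, make_plateau_run
from hybridia.targets import InclusionList
from .conftest import make_entry


class TestAccumulate:
    @pytest.mark.parametrize(
        "flux,max_it,agc,fill,counts",
        [
            (1e7, 116.0, 1e6, 100.0, 1e6),  # AGC-limited
            (1e3, 116.0, 1e6, 116.0, 116.0),  # time-limited
            (0.0, 116.0, 1e6, 116.0, 0.0),
        ],
    )
    def test_agc_contract(self, flux, max_it, agc, fill, counts):
        got_fill, got_counts = accumulate(flux, max_it, agc)
        assert got_fill == pytest.approx(fill)
        assert got_counts == pytest.approx(counts)


class TestMsxFillAllocation:
    def test_zero_flux_hits_the_time_cap(self, hybrid_cfg):
        it_is, it_endo = allocate_msx_fill(0.0, hybrid_cfg)
        assert it_is == pytest.approx(11.6)
        assert it_endo == pytest.approx(104.4)

    def test_abundant_is_gets_short_fill(self, hybrid_cfg):
        it_is, it_endo = allocate_msx_fill(1e8, hybrid_cfg)
        assert it_is < 1.1  # 0.1*1e6 charges at 1e8/s = 1 ms
        assert it_endo > 100.0

    @pytest.mark.parametrize("flux", [0.0, 1e4, 1e6, 1e8, 1e10])
    def test_budget_conserved(self, flux, hybrid_cfg):
        it_is, it_endo = allocate_msx_fill(flux, hybrid_cfg)
        assert it_is > 0 and it_endo > 0
        assert it_is + it_endo == pytest.approx(hybrid_cfg.msx_max_it)


class TestScanDuration:
    @pytest.mark.parametrize(
        "resolution,fill,expected",
        [(30000, 54.0, 0.064), (30000, 116.0, 0.116), (120000, 45.0, 0.256),
         (7500, 10.0, 0.016)],
    )
    def test_transient_vs_fill(self, resolution, fill, expected, hybrid_cfg):
        assert scan_duration(resolution, fill, hybrid_cfg) == pytest.approx(expected)

    def test_unknown_resolution_rejected(self, hybrid_cfg):
        with pytest.raises(ValueError, match="17500"):
            scan_duration(17500, 10.0, hybrid_cfg)

    def test_dia_cycle_time_is_0_96_s(self, hybrid_cfg):
        cycle = scan_duration(120000, 45.0, hybrid_cfg) + 11 * scan_duration(
            30000, 54.0, hybrid_cfg
        )
        assert cycle == pytest.approx(0.960)
        assert round(cycle) == 1


def _ms1_scan(peaks, fill_ms=10.0, start=600.0):
    mz = np.array([p[0] for p in peaks], float)
    counts = np.array([p[1] for p in peaks], float)
    order = np.argsort(mz)
    return ScanRecord("MS1", start, 0.256, [], [], mz[order], counts[order], 0,
                      fill_ms=fill_ms)


class TestDetectInMs1:
    def test_threshold_is_on_it_normalized_intensity(self, hybrid_cfg):
        entry = make_entry(rt_center=10.0)
        incl = InclusionList(entries=[entry], gradient_length=30.0)
        # 2000 counts in 10 ms -> 2e5 charges/s, above the 1e5 threshold
        ms1 = _ms1_scan([(500.0, 2000.0)])
        assert detect_in_ms1(ms1, incl, 600.0, {}, hybrid_cfg) == [entry]
        # 500 counts in 10 ms -> 5e4 charges/s, below threshold
        weak = _ms1_scan([(500.0, 500.0)])
        assert detect_in_ms1(weak, incl, 600.0, {}, hybrid_cfg) == []

    def test_rt_window_gates_detection(self, hybrid_cfg):
        entry = make_entry(rt_center=10.0, rt_halfwidth=1.0)
        incl = InclusionList(entries=[entry], gradient_length=30.0)
        ms1 = _ms1_scan([(500.0, 2000.0)])
        assert detect_in_ms1(ms1, incl, 20.0 * 60.0, {}, hybrid_cfg) == []

    def test_dynamic_exclusion_blocks_recent_triggers(self, hybrid_cfg):
        entry = make_entry()
        incl = InclusionList(entries=[entry], gradient_length=30.0)
        ms1 = _ms1_scan([(500.0, 2000.0)])
        excl = {entry.entry_id: 598.0}  # triggered 2 s ago
        assert detect_in_ms1(ms1, incl, 600.0, excl, hybrid_cfg) == []
        excl = {entry.entry_id: 594.0}  # 6 s ago, exclusion expired
        assert detect_in_ms1(ms1, incl, 600.0, excl, hybrid_cfg) == [entry]

    def test_nearest_peak_within_tolerance_wins(self, hybrid_cfg):
        entry = make_entry()
        incl = InclusionList(entries=[entry], gradient_length=30.0)
        # two peaks inside 10 ppm; the nearer, weaker one is the match
        ms1 = _ms1_scan([(500.0005, 500.0), (500.004, 50000.0)])
        assert detect_in_ms1(ms1, incl, 600.0, {}, hybrid_cfg) == []


class TestConfirmFragments:
    def _prm(self, frag_mzs):
        mz = np.asarray(sorted(frag_mzs), float)
        return ScanRecord("PRM_SURVEY", 600.0, 0.016, [(500.0, 1.0)], [],
                          mz, np.full(mz.size, 1000.0), 0)

    def test_enough_fragments_confirm(self, hybrid_cfg):
        entry = make_entry()  # fragments at 300, 400, ..., 800
        assert confirm_fragments(self._prm([300.0, 400.0, 500.0, 600.0]),
                                 entry, hybrid_cfg)
        assert not confirm_fragments(self._prm([300.0, 400.0]), entry, hybrid_cfg)

    def test_ppm_boundary_is_inclusive(self, hybrid_cfg):
        entry = make_entry()
        offset = [m * (1 + 10e-6) for m in (300.0, 400.0, 500.0)]
        assert confirm_fragments(self._prm(offset), entry, hybrid_cfg)
        beyond = [m * (1 + 10.8e-6) for m in (300.0, 400.0, 500.0)]
        assert not confirm_fragments(self._prm(beyond), entry, hybrid_cfg)


class TestHybridRun:
    def test_empty_inclusion_list_reduces_to_dia(self):
        run, _ = make_panel_run(2, gradient_length=3.0, seed=4)
        empty = InclusionList(entries=[], gradient_length=3.0)
        hybrid = run_acquisition(run, empty, AcqConfig(mode="hybrid"), seed=4)
        dia = run_acquisition(run, empty, AcqConfig(mode="dia"), seed=4)
        assert len(hybrid) == len(dia)
        for a, b in zip(hybrid, dia):
            assert a.scan_class == b.scan_class
            assert a.start == b.start
            assert np.array_equal(a.mz, b.mz)
            assert np.array_equal(a.intensity, b.intensity)

    def test_determinism_same_seed(self, small_panel):
        run, incl, cfg, scans = small_panel
        again = run_acquisition(run, incl, cfg, seed=11)
        assert len(again) == len(scans)
        for a, b in zip(scans, again):
            assert a.scan_class == b.scan_class and a.start == b.start
            assert np.array_equal(a.intensity, b.intensity)

    def test_causality_of_trigger_chain(self, small_panel):
        _, _, _, scans = small_panel
        by_cycle = {}
        for s in scans:
            by_cycle.setdefault(s.cycle_index, []).append(s)
        n_msx = 0
        for cycle_scans in by_cycle.values():
            classes = [s.scan_class for s in cycle_scans]
            assert classes[0] == "MS1"
            for i, s in enumerate(cycle_scans):
                if s.scan_class == "MSX":
                    n_msx += 1
                    prior = classes[:i]
                    assert "PRM_SURVEY" in prior and "MS1" in prior
        assert n_msx > 0  # targets did elute and trigger

    def test_dynamic_exclusion_spacing(self):
        run, incl = make_plateau_run(seed=3, plateau_s=60.0)
        cfg = AcqConfig(mode="hybrid")
        scans = run_acquisition(run, incl, cfg, seed=3)
        msx_times = [s.start for s in scans if s.scan_class == "MSX"]
        assert len(msx_times) >= 5
        assert np.min(np.diff(msx_times)) >= cfg.dynamic_exclusion

    def test_time_conservation_with_zero_overhead(self, small_panel):
        _, _, _, scans = small_panel
        total = sum(s.duration for s in scans)
        span = scans[-1].start + scans[-1].duration - scans[0].start
        assert total == pytest.approx(span, abs=1e-6)

    def test_msx_scans_carry_two_precursors_with_fills(self, small_panel):
        _, _, cfg, scans = small_panel
        msx = [s for s in scans if s.scan_class == "MSX"]
        for s in msx:
            assert len(s.precursors) == 2
            channels = {c for _, c, _ in s.precursors}
            assert channels == {"IS", "ENDO"}
            fills = [f for _, _, f in s.precursors]
            assert sum(fills) == pytest.approx(cfg.msx_max_it)


class TestSureQuant:
    def test_sensitive_scan_at_label_offset(self):
        run, incl = make_plateau_run(seed=2, plateau_s=30.0)
        cfg = AcqConfig(mode="surequant")
        scans = run_surequant(run, incl, cfg, seed=2)
        sens = [s for s in scans if s.scan_class == "SQ_SENSITIVE"]
        assert sens, "no sensitive scans triggered"
        entry = incl.entries[0]
        for s in sens:
            assert s.isolation[0][0] == pytest.approx(entry.endo_mz, abs=1e-6)
        surveys = [s for s in scans if s.scan_class == "SQ_SURVEY"]
        assert all(s.duration == pytest.approx(0.016) for s in surveys)

    def test_branchless_entry_rejected(self):
        run, _ = make_plateau_run(seed=2)
        bad = make_entry(label="V6", charge=3, seq="BADBRANCHK",
                         rt_center=2.0, rt_halfwidth=1.0)
        incl = InclusionList(entries=[bad], gradient_length=4.0)
        with pytest.raises(ValueError, match="BADBRANCHK"):
            run_surequant(run, incl, AcqConfig(mode="surequant"), seed=2)


class TestTimeBudget:
    def _scan(self, cls, start, dur):
        return ScanRecord(cls, start, dur, [], [], np.empty(0), np.empty(0), 0)

    def test_api_fraction_arithmetic(self):
        scans = [self._scan("DIA", i * 0.064, 0.064) for i in range(10)]
        scans += [self._scan("MSX", 1.0 + i * 0.116, 0.116) for i in range(5)]
        budget = time_budget(scans)
        assert budget["api_fraction"] == pytest.approx(580.0 / (640.0 + 580.0))
        assert budget["api_fraction"] + budget["dia_fraction"] == pytest.approx(1.0)
        assert budget["counts"] == {"DIA": 10, "MSX": 5}

    def test_dia_only_run_has_zero_api_fraction(self):
        scans = [self._scan("MS1", 0.0, 0.256)] + [
            self._scan("DIA", 0.3 + i * 0.064, 0.064) for i in range(11)
        ]
        assert time_budget(scans)["api_fraction"] == 0.0


class TestIdLossModel:
    def test_line_through_two_points(self):
        model = id_loss_model([(0.0, 0.0), (4.0, 12.5)])
        assert model.predict(8.0) == pytest.approx(25.0)
        assert model.predict(0.0) == pytest.approx(0.0)

    def test_duplicate_points_leave_line_unchanged(self):
        a = id_loss_model([(0.0, 0.0), (4.0, 12.5)])
        b = id_loss_model([(0.0, 0.0), (0.0, 0.0), (4.0, 12.5), (4.0, 12.5)])
        assert (a.slope, a.intercept) == pytest.approx((b.slope, b.intercept))

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            id_loss_model([(1.0, 2.0)])
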