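"""XIC assembly, injection-time correction, peak integration, S/N, ratios."""

import math

import numpy as np
import pytest

from hybridia.acquire import AcqConfig, ScanRecord
from hybridia.quant import (
    XICTrace,
    correct_injection_time,
    detect_peak,
    extract_xic,
    integrate,
    quantify_pair,
    snr,
)
from .conftest import make_entry


def _trace(rt, intensity, fill=None, channel="ENDO"):
    rt = np.asarray(rt, float)
    fill = np.full(rt.size, 100.0) if fill is None else np.asarray(fill, float)
    return XICTrace("t", channel, 400.0, rt, np.asarray(intensity, float), fill)


class TestInjectionTimeCorrection:
    @pytest.mark.parametrize("counts,fill,rate", [(1160.0, 116.0, 10.0),
                                                  (540.0, 54.0, 10.0)])
    def test_counts_per_ms(self, counts, fill, rate):
        assert correct_injection_time(counts, fill) == pytest.approx(rate)

    def test_scale_invariance(self):
        assert correct_injection_time(500.0, 50.0) == correct_injection_time(
            1000.0, 100.0
        )

    def test_nonpositive_fill_rejected(self):
        with pytest.raises(ValueError):
            correct_injection_time(100.0, 0.0)


class TestIntegrate:
    def test_triangle_area(self):
        # (0 s, 0), (1 s, 100), (2 s, 0) in raw counts -> 100 count*seconds
        tr = _trace([0.0, 1.0 / 60.0, 2.0 / 60.0], [0.0, 100.0, 0.0])
        assert integrate(tr, (0.0, 2.0 / 60.0), corrected=False) == pytest.approx(100.0)

    def test_gaussian_closed_form_within_1_percent(self):
        amp, sigma_s = 50.0, 6.0  # counts/ms, seconds
        dt = sigma_s / 3.0
        t = np.arange(-8 * sigma_s, 8 * sigma_s + dt / 2, dt)
        y = amp * np.exp(-0.5 * (t / sigma_s) ** 2)
        tr = _trace(10.0 + t / 60.0, y, fill=np.ones(t.size))
        area = integrate(tr, (float(tr.rt[0]), float(tr.rt[-1])), corrected=True)
        assert area == pytest.approx(amp * sigma_s * math.sqrt(2 * math.pi), rel=0.01)

    def test_zero_trace_and_inverted_boundaries(self):
        tr = _trace([0.0, 0.1, 0.2], [0.0, 0.0, 0.0])
        assert integrate(tr, (0.0, 0.2)) == 0.0
        with pytest.raises(ValueError, match="inverted"):
            integrate(tr, (0.2, 0.0))


class TestDetectPeak:
    def test_noiseless_gaussian_apex_within_one_interval(self):
        dt = 2.0 / 60.0
        rt = np.arange(8.0, 12.0, dt)
        y = 1000.0 * np.exp(-0.5 * ((rt - 10.01) / 0.1) ** 2)
        pk = detect_peak(_trace(rt, y), expected_rt=10.0, window=1.0)
        assert pk.found
        assert abs(pk.apex_rt - 10.01) <= dt

    def test_all_zero_trace_yields_no_peak(self):
        pk = detect_peak(_trace([0.0, 0.1, 0.2], [0.0, 0.0, 0.0]), 0.1, 0.2)
        assert not pk.found

    def test_second_disjoint_peak_ignored(self):
        rt = np.arange(0.0, 20.0, 0.1)
        y = 1000.0 * np.exp(-0.5 * ((rt - 5.0) / 0.2) ** 2)
        y += 5000.0 * np.exp(-0.5 * ((rt - 15.0) / 0.2) ** 2)
        pk = detect_peak(_trace(rt, y), expected_rt=5.0, window=2.0)
        assert pk.found
        assert abs(pk.apex_rt - 5.0) <= 0.1
        assert pk.boundaries[1] < 10.0  # second peak not swallowed

    def test_empty_trace(self):
        pk = detect_peak(_trace([], []), 5.0, 1.0)
        assert not pk.found


class TestSnr:
    def test_floor_when_baseline_is_silent(self):
        rt = np.arange(0.0, 2.0, 0.1)
        y = np.zeros(rt.size)
        y[10] = 100.0 * 100.0  # counts; fill 100 ms -> corrected 100/ms
        tr = _trace(rt, y)
        assert snr(tr, (0.9, 1.1)) == pytest.approx(100.0)

    def test_mad_based_noise(self):
        a = 10.0 / 1.4826  # out-of-peak deviations giving noise exactly 10
        rt = np.arange(0.0, 3.0, 0.1)
        y = np.zeros(rt.size)
        pattern = np.tile([a, 0.0, -a], 5)[:14]
        y[:14] = pattern * 100.0
        y[16:] = pattern * 100.0
        y[15] = 80.0 * 100.0
        tr = _trace(rt, y)
        assert snr(tr, (1.45, 1.55)) == pytest.approx(8.0, rel=1e-6)

    def test_scale_invariance_with_proportional_noise(self):
        rng = np.random.default_rng(0)
        rt = np.arange(0.0, 3.0, 0.1)
        base = 20.0 * np.abs(rng.normal(size=rt.size))
        base[15] = 1000.0
        tr1 = _trace(rt, base * 100.0)
        tr5 = _trace(rt, 5.0 * base * 100.0)
        assert snr(tr5, (1.45, 1.65)) == pytest.approx(
            snr(tr1, (1.45, 1.65)), rel=1e-9
        )


def _msx_scan(entry, t_s, is_counts, endo_counts, it_is=11.6, it_endo=104.4):
    """A synthetic MSx spectrum with both channels' fragment peaks."""
    mzs, counts = [], []
    for frag, c in zip(entry.match_fragments, is_counts):
        mzs.append(frag.mz)
        counts.append(c)
    for frag, c in zip(entry.match_fragments, endo_counts):
        mzs.append(entry.endo_fragment_mz(frag))
        counts.append(c)
    order = np.argsort(mzs)
    return ScanRecord(
        "MSX", t_s, 0.116,
        [(entry.is_peptide.precursor_mz, 1.0), (entry.endo_mz, 1.0)],
        [(entry.entry_id, "IS", it_is), (entry.entry_id, "ENDO", it_endo)],
        np.asarray(mzs)[order], np.asarray(counts, float)[order], 0,
    )


class TestExtractXic:
    def test_points_fills_and_summation(self, hybrid_cfg):
        entry = make_entry()
        shape = [0.2, 1.0, 0.4]
        scans = [
            _msx_scan(entry, 600.0 + 5.0 * i, [1000.0 * f] * 6, [100.0 * f] * 6)
            for i, f in enumerate(shape)
        ]
        tr = extract_xic(scans, entry, "IS", entry.match_fragments[0].mz)
        assert len(tr) == 3
        assert tr.intensity.tolist() == [200.0, 1000.0, 400.0]
        assert tr.fill.tolist() == [11.6] * 3
        endo = extract_xic(scans, entry, "ENDO",
                           entry.endo_fragment_mz(entry.match_fragments[0]))
        assert endo.fill.tolist() == [104.4] * 3

    def test_absent_target_yields_empty_trace(self, hybrid_cfg):
        entry = make_entry()
        other = make_entry(seq="OTHERPEPK")
        scans = [_msx_scan(other, 600.0, [100.0] * 6, [10.0] * 6)]
        tr = extract_xic(scans, entry, "IS", 300.0)
        assert len(tr) == 0

    def test_two_peaks_within_tolerance_are_summed(self, hybrid_cfg):
        entry = make_entry()
        scan = _msx_scan(entry, 600.0, [500.0] * 6, [0.0] * 6)
        # add a jittered twin of the first fragment peak, 3 ppm away
        mz0 = entry.match_fragments[0].mz
        scan.mz = np.append(scan.mz, mz0 * (1 + 3e-6))
        scan.intensity = np.append(scan.intensity, 250.0)
        order = np.argsort(scan.mz)
        scan.mz, scan.intensity = scan.mz[order], scan.intensity[order]
        tr = extract_xic([scan], entry, "IS", mz0)
        assert tr.intensity.tolist() == [750.0]


class TestQuantifyPair:
    def _scans(self, entry, ratio=0.1, n=7, spacing_s=5.0):
        center = entry.rt_center * 60.0
        times = center + spacing_s * (np.arange(n) - n // 2)
        out = []
        for t in times:
            f = math.exp(-0.5 * ((t - center) / 8.0) ** 2)
            is_counts = [1000.0 * f * w for w in (6, 5, 4, 3, 2, 1)]
            endo_counts = [c * ratio * (104.4 / 11.6) for c in is_counts]
            out.append(_msx_scan(entry, t, is_counts, endo_counts))
        return out

    def test_ratio_of_corrected_sums(self, hybrid_cfg):
        entry = make_entry()
        pair, _ = quantify_pair(self._scans(entry, ratio=0.1), entry, hybrid_cfg)
        assert pair.n_quantified_fragments == 6
        assert pair.quantified
        assert pair.ratio == pytest.approx(0.100, abs=1e-3)

    def test_too_few_quantifiable_fragments_flags_pair(self, hybrid_cfg):
        entry = make_entry()
        scans = self._scans(entry, ratio=0.1)
        for s in scans:
            # silence all but two ENDO fragments
            for frag in entry.match_fragments[2:]:
                emz = entry.endo_fragment_mz(frag)
                s.intensity[np.abs(s.mz - emz) < 1e-6] = 0.0
        pair, _ = quantify_pair(scans, entry, hybrid_cfg)
        assert pair.n_quantified_fragments == 2
        assert not pair.quantified

    def test_it_correction_makes_ratio_fill_independent(self, hybrid_cfg):
        entry = make_entry()
        # same underlying fluxes, different fill split: raw counts differ,
        # corrected ratio must not
        a = self._scans(entry, ratio=0.2)
        b = []
        for s in self._scans(entry, ratio=0.2):
            scale_is, scale_endo = 30.0 / 11.6, 86.0 / 104.4
            mz, inten = s.mz.copy(), s.intensity.copy()
            for frag in entry.match_fragments:
                inten[np.abs(mz - frag.mz) < 1e-6] *= scale_is
                emz = entry.endo_fragment_mz(frag)
                inten[np.abs(mz - emz) < 1e-6] *= scale_endo
            b.append(ScanRecord("MSX", s.start, s.duration, s.isolation,
                                [(entry.entry_id, "IS", 30.0),
                                 (entry.entry_id, "ENDO", 86.0)],
                                mz, inten, 0))
        ra, _ = quantify_pair(a, entry, hybrid_cfg)
        rb, _ = quantify_pair(b, entry, hybrid_cfg)
        assert rb.ratio == pytest.approx(ra.ratio, rel=1e-9)
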