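"""Transition-level quantification of targeted MSx streams.

For every IS/ENDO pair the pipeline assembles per-fragment extracted-ion
chromatograms (XICs) from the MSx scans, corrects each point for the
injection time its precursor actually received (counts -> counts per
millisecond, which removes the deliberate IS/ENDO fill asymmetry), finds and
integrates the chromatographic peak, and reports the ENDO/IS ratio over the
fragments quantifiable in both channels, together with per-channel
signal-to-noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .acquire import AcqConfig, ScanRecord
from .targets import FragmentIon, TargetEntry

logger = logging.getLogger(__name__)

#: Noise floor for S/N, in injection-time-corrected counts per millisecond.
SNR_EPSILON = 1.0
#: Boundary rule: peak edges where the smoothed trace drops below this
#: fraction of the apex.
BOUNDARY_FRACTION = 0.05


@dataclass
class XICTrace:
    """One fragment's intensity over retention time across MSx scans."""

    target_id: str
    channel: str  # 'IS' | 'ENDO'
    fragment_mz: float
    rt: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray  # raw counts
    fill: np.ndarray  # ms per point

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, float)
        self.intensity = np.asarray(self.intensity, float)
        self.fill = np.asarray(self.fill, float)
        if not (self.rt.size == self.intensity.size == self.fill.size):
            raise ValueError("rt, intensity and fill must have equal length")
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("rt must be strictly increasing")

    @property
    def corrected(self) -> np.ndarray:
        """Injection-time-corrected intensity, counts per millisecond."""
        return correct_injection_time(self.intensity, self.fill)

    def __len__(self) -> int:
        return int(self.rt.size)


@dataclass(frozen=True)
class PeakIntegration:
    """A detected chromatographic peak and its integral."""

    found: bool
    apex_rt: float  # minutes (nan when not found)
    apex_index: int
    boundaries: tuple[float, float]  # minutes
    area: float = 0.0  # corrected-intensity * seconds
    snr: float = 0.0


@dataclass
class PairQuant:
    """Quantification result for one IS/ENDO pair."""

    target_id: str
    fragment_areas: dict[float, tuple[float, float]]  # IS frag mz -> (endo, is)
    area_endo: float = 0.0
    area_is: float = 0.0
    ratio: float = float("nan")
    n_quantified_fragments: int = 0
    quantified: bool = False
    snr_endo: float = 0.0
    snr_is: float = 0.0
    ppfr: float = float("nan")  # filled by qc_stats
    dotpr: float = float("nan")  # filled by qc_stats


def correct_injection_time(intensity, fill):
    """Normalize raw counts by the fill time that produced them (counts/ms)."""
    fill_arr = np.asarray(fill, float)
    if np.any(fill_arr <= 0):
        raise ValueError("fill time must be positive")
    return np.asarray(intensity, float) / fill_arr


def extract_xic(
    msx_scans: Sequence[ScanRecord],
    entry: TargetEntry,
    channel: str,
    fragment_mz: float,
    tol_ppm: float = 10.0,
) -> XICTrace:
    """Assemble one fragment's XIC from the MSx scans of a target.

    One point per MSx scan that isolates the target's ``channel``; the point
    value is the summed counts of all peaks within ``tol_ppm`` of the
    fragment m/z (summing, rather than nearest-peak, is robust to mass
    jitter).  A target absent from the stream yields an empty trace.
    """
    rts, vals, fills = [], [], []
    for scan in msx_scans:
        if scan.scan_class not in ("MSX", "SQ_SENSITIVE"):
            continue
        fill = None
        for tid, ch, f in scan.precursors:
            if tid == entry.entry_id and ch == channel:
                fill = f
                break
        if fill is None:
            continue
        rts.append(scan.start / 60.0)
        vals.append(scan.counts_near(fragment_mz, tol_ppm))
        fills.append(fill)
    return XICTrace(entry.entry_id, channel, fragment_mz,
                    np.asarray(rts), np.asarray(vals), np.asarray(fills))


def _smooth3(x: np.ndarray) -> np.ndarray:
    if x.size < 3:
        return x.astype(float)
    out = np.convolve(x, np.ones(3) / 3.0, mode="same")
    # edge points: average of the available neighbours
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return out


def detect_peak(
    trace: XICTrace,
    expected_rt: float,
    window: float,
    boundary_fraction: float = BOUNDARY_FRACTION,
) -> PeakIntegration:
    """Find the chromatographic peak nearest the expected retention time.

    The apex is the maximum of the 3-point moving average inside
    ``expected_rt +/- window``; boundaries extend outward until the smoothed
    trace falls below ``boundary_fraction`` of the apex or starts rising
    again (a valley separating a neighbouring peak).
    """
    if len(trace) == 0:
        return PeakIntegration(False, float("nan"), -1, (float("nan"), float("nan")))
    y = _smooth3(trace.corrected)
    sel = np.abs(trace.rt - expected_rt) <= window
    if not np.any(sel) or float(np.max(y[sel])) <= 0:
        return PeakIntegration(False, float("nan"), -1, (float("nan"), float("nan")))
    idx_window = np.flatnonzero(sel)
    apex = int(idx_window[np.argmax(y[idx_window])])
    cutoff = boundary_fraction * y[apex]
    lo = apex
    while lo > 0 and y[lo - 1] >= cutoff and y[lo - 1] <= y[lo]:
        lo -= 1
    hi = apex
    while hi < y.size - 1 and y[hi + 1] >= cutoff and y[hi + 1] <= y[hi]:
        hi += 1
    return PeakIntegration(
        True, float(trace.rt[apex]), apex, (float(trace.rt[lo]), float(trace.rt[hi]))
    )


def integrate(
    trace: XICTrace, boundaries: tuple[float, float], corrected: bool = True
) -> float:
    """Trapezoidal area under the trace between the boundaries.

    Time is converted to seconds, so the unit is (corrected) counts x seconds.
    """
    lo, hi = boundaries
    if hi < lo:
        raise ValueError("inverted integration boundaries")
    sel = (trace.rt >= lo) & (trace.rt <= hi)
    if np.count_nonzero(sel) < 2:
        return 0.0
    y = trace.corrected if corrected else trace.intensity.astype(float)
    return float(np.trapezoid(y[sel], trace.rt[sel] * 60.0))


def snr(trace: XICTrace, boundaries: tuple[float, float]) -> float:
    """Apex corrected intensity over the MAD-based out-of-peak noise.

    Noise is 1.4826 x the median absolute deviation of corrected intensities
    outside the peak boundaries (>= 3 such points required, otherwise the
    floor applies alone), floored at ``SNR_EPSILON`` = 1 count/ms.
    """
    if len(trace) == 0:
        return 0.0
    y = trace.corrected
    lo, hi = boundaries
    inside = (trace.rt >= lo) & (trace.rt <= hi)
    apex = float(np.max(y[inside])) if np.any(inside) else float(np.max(y))
    out = y[~inside]
    noise = 0.0
    if out.size >= 3:
        noise = 1.4826 * float(np.median(np.abs(out - np.median(out))))
    return apex / max(noise, SNR_EPSILON)


def quantify_pair(
    msx_scans: Sequence[ScanRecord],
    entry: TargetEntry,
    cfg: AcqConfig,
    min_fragments: int | None = None,
) -> tuple[PairQuant, dict]:
    """Quantify one IS/ENDO pair from its MSx scans.

    A fragment is *quantifiable* when a peak is found in both channels; the
    pair ratio is the summed corrected ENDO area over the summed corrected
    IS area across quantifiable fragments, and the pair counts as quantified
    with at least ``min_fragments`` (default 3) of them.  Returns the
    :class:`PairQuant` plus the per-fragment traces/peaks for QC.
    """
    need = entry.min_fragments if min_fragments is None else min_fragments
    frag_areas: dict[float, tuple[float, float]] = {}
    detail: dict = {"is": {}, "endo": {}}
    sum_endo = sum_is = 0.0
    is_traces, endo_traces = [], []
    for frag in entry.match_fragments:
        is_tr = extract_xic(msx_scans, entry, "IS", frag.mz, cfg.mass_tol_ppm)
        en_tr = extract_xic(msx_scans, entry, "ENDO", entry.endo_fragment_mz(frag),
                            cfg.mass_tol_ppm)
        is_pk = detect_peak(is_tr, entry.rt_center, entry.rt_halfwidth)
        en_pk = detect_peak(en_tr, entry.rt_center, entry.rt_halfwidth)
        detail["is"][frag.mz] = (is_tr, is_pk)
        detail["endo"][frag.mz] = (en_tr, en_pk)
        is_traces.append(is_tr)
        endo_traces.append(en_tr)
        if is_pk.found and en_pk.found:
            a_is = integrate(is_tr, is_pk.boundaries, corrected=True)
            a_en = integrate(en_tr, en_pk.boundaries, corrected=True)
            if a_is > 0:
                frag_areas[frag.mz] = (a_en, a_is)
                sum_endo += a_en
                sum_is += a_is
    pair = PairQuant(target_id=entry.entry_id, fragment_areas=frag_areas)
    pair.n_quantified_fragments = len(frag_areas)
    pair.quantified = pair.n_quantified_fragments >= need
    if sum_is > 0:
        pair.area_endo, pair.area_is = sum_endo, sum_is
        pair.ratio = sum_endo / sum_is
    pair.snr_is = _summed_snr(is_traces, entry)
    pair.snr_endo = _summed_snr(endo_traces, entry)
    return pair, detail


def _summed_snr(traces: list[XICTrace], entry: TargetEntry) -> float:
    """S/N of the fragment-summed corrected trace for one channel."""
    traces = [t for t in traces if len(t) > 0]
    if not traces:
        return 0.0
    base = traces[0]
    total = np.sum([t.intensity for t in traces], axis=0)
    summed = XICTrace(base.target_id, base.channel, 0.0, base.rt, total, base.fill)
    pk = detect_peak(summed, entry.rt_center, entry.rt_halfwidth)
    if not pk.found:
        return 0.0
    return snr(summed, pk.boundaries)


def pair_table(pairs: Sequence[PairQuant]) -> "pd.DataFrame":
    """Long-format export of pair-level quantities."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "target_id": p.target_id,
                "ratio": p.ratio,
                "area_endo": p.area_endo,
                "area_is": p.area_is,
                "n_quantified_fragments": p.n_quantified_fragments,
                "quantified": p.quantified,
                "snr_endo": p.snr_endo,
                "snr_is": p.snr_is,
                "ppfr": p.ppfr,
                "dotpr": p.dotpr,
            }
            for p in pairs
        ]
    )
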