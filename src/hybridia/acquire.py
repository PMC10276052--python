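"""Acquisition engine: DIA, hybrid-DIA and SureQuant-style modes.

The hybrid mode intercalates a standard DIA cycle with spike-in-triggered
targeted scans:

1. precursors of heavy IS peptides are looked for in every MS1 scan (RT
   window + ppm tolerance + intensity threshold + dynamic exclusion);
2. detected IS precursors get one fast multiplexed PRM survey scan;
3. IS peptides whose predefined fragments are confirmed in the survey get a
   multiplexed MSx scan co-isolating the IS and its endogenous counterpart,
   with the fill-time budget split asymmetrically so the low-abundance ENDO
   channel receives most of the injection time;
4. the cycle then continues with the regular DIA windows.

Scan timing follows the Orbitrap parallelization contract: ion accumulation
for scan *n+1* proceeds during the transient of scan *n*, so each scan costs
``max(transient, total fill time)``.  With the default transient table the
standard DIA cycle (MS1 at 120k + 11 windows at 30k) takes 0.960 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .synth import GroundTruthRun, flux_at, sample_peak_list, scan_rng
from .targets import DiaWindowScheme, InclusionList, TargetEntry, plan_dia_windows

logger = logging.getLogger(__name__)

#: Orbitrap transient duration (ms) by resolution setting (at m/z 200).
TRANSIENT_MS: dict[int, float] = {7500: 16, 15000: 32, 30000: 64, 60000: 128, 120000: 256}

#: SureQuant branch table: heavy label -> allowed charge states.
SUREQUANT_BRANCHES: dict[str, tuple[int, ...]] = {
    "K8": (2, 3, 4),
    "R10": (2, 3, 4),
    "A4": (3,),
    "V6": (2,),
}

_CLASS_CODES = {"MS1": 1, "DIA": 2, "PRM_SURVEY": 3, "MSX": 4,
                "SQ_SURVEY": 5, "SQ_SENSITIVE": 6}


@dataclass(frozen=True)
class Ms1Config:
    resolution: int = 120000
    max_it: float = 45.0  # ms
    agc: float = 3e5  # charges (300% at 1e5 per 100%)
    range: tuple[float, float] = (350.0, 1400.0)


@dataclass(frozen=True)
class DiaConfig:
    scheme: DiaWindowScheme = field(
        default_factory=lambda: plan_dia_windows(472.0, 1143.0, 11, 1.0)
    )
    resolution: int = 30000
    max_it: float = 54.0  # ms
    agc: float = 1e6  # charges (1000%)


@dataclass(frozen=True)
class SurveyConfig:
    resolution: int = 7500
    max_it: float = 10.0  # ms per precursor


@dataclass(frozen=True)
class AcqConfig:
    """Every tolerance, threshold and timing parameter of one acquisition mode."""

    mode: str = "hybrid"  # 'dia' | 'hybrid' | 'surequant'
    mass_tol_ppm: float = 10.0
    intensity_threshold: float = 1e5  # IT-normalized counts (charges/second)
    msx_max_it: float = 116.0  # ms, shared IS+ENDO fill budget
    msx_agc: float = 1e6  # charges
    msx_resolution: int = 30000
    dynamic_exclusion: float = 5.0  # seconds
    min_fragments: int = 3
    prm_isolation_width: float = 1.0  # Th
    ms1: Ms1Config = field(default_factory=Ms1Config)
    dia: DiaConfig = field(default_factory=DiaConfig)
    survey: SurveyConfig = field(default_factory=SurveyConfig)
    sq_sensitive_resolution: int = 60000
    transient_ms: dict[int, float] = field(default_factory=lambda: dict(TRANSIENT_MS))
    interscan_overhead_ms: float = 0.0
    is_fill_fraction: float = 0.1  # share of budget/AGC reserved for the IS

    def __post_init__(self) -> None:
        if self.mode not in ("dia", "hybrid", "surequant"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for res in (self.ms1.resolution, self.dia.resolution, self.survey.resolution,
                    self.msx_resolution, self.sq_sensitive_resolution):
            if res not in self.transient_ms:
                raise ValueError(f"resolution {res} missing from transient table")
        if min(self.msx_max_it, self.ms1.max_it, self.dia.max_it, self.survey.max_it) <= 0:
            raise ValueError("all injection times must be positive")


@dataclass
class ScanRecord:
    """One acquired spectrum."""

    scan_class: str
    start: float  # seconds
    duration: float  # seconds
    isolation: list[tuple[float, float]]  # (center, width) pairs
    precursors: list[tuple[str, str, float]]  # (target id, channel, fill ms)
    mz: np.ndarray
    intensity: np.ndarray
    cycle_index: int
    fill_ms: float = 0.0  # scan-level fill (MS1/DIA)

    def peak_near(self, mz: float, tol_ppm: float) -> tuple[float, float] | None:
        """Nearest peak within ``tol_ppm`` of ``mz`` as (m/z, counts), or None."""
        if self.mz.size == 0:
            return None
        # tiny relative slack keeps the inclusive ppm boundary robust to
        # floating-point rounding of m/z values sitting exactly on it
        tol = mz * tol_ppm * 1e-6 * (1.0 + 1e-9)
        d = np.abs(self.mz - mz)
        i = int(np.argmin(d))
        if d[i] <= tol:
            return float(self.mz[i]), float(self.intensity[i])
        return None

    def counts_near(self, mz: float, tol_ppm: float) -> float:
        """Summed counts of all peaks within ``tol_ppm`` of ``mz``."""
        if self.mz.size == 0:
            return 0.0
        tol = mz * tol_ppm * 1e-6 * (1.0 + 1e-9)
        sel = np.abs(self.mz - mz) <= tol
        return float(self.intensity[sel].sum())


@dataclass
class TriggerEvent:
    """One trigger-chain decision, for the debug log."""

    clock: float  # seconds
    target_id: str
    stage: str  # 'detect' | 'confirm' | 'msx'
    accepted: bool
    reason: str


ExclusionTable = dict  # target id -> last confirmed-trigger clock (seconds)


# ---------------------------------------------------------------------------
# Timing and accumulation physics
# ---------------------------------------------------------------------------


def accumulate(flux: float, max_it: float, agc: float) -> tuple[float, float]:
    """AGC contract: fill until the charge target or the time cap is hit.

    Returns (fill time in ms, expected accumulated counts).
    """
    if flux < 0:
        raise ValueError("flux must be >= 0")
    if flux == 0:
        return max_it, 0.0
    fill = min(max_it, 1000.0 * agc / flux)
    return fill, flux * fill / 1000.0


def allocate_msx_fill(is_flux_estimate: float, cfg: AcqConfig) -> tuple[float, float]:
    """Split the MSx fill budget between IS and ENDO.

    The IS is abundant by construction, so it is capped at a small share of
    the budget (or the time needed to reach that share of the AGC target,
    whichever is less); all remaining fill time goes to the ENDO channel.
    """
    if is_flux_estimate < 0:
        raise ValueError("is_flux_estimate must be >= 0")
    cap = cfg.is_fill_fraction * cfg.msx_max_it
    if is_flux_estimate == 0:
        it_is = cap
    else:
        agc_time = 1000.0 * cfg.is_fill_fraction * cfg.msx_agc / is_flux_estimate
        it_is = min(cap, agc_time)
    it_is = max(it_is, 1e-3)  # keep both fills strictly positive
    return it_is, cfg.msx_max_it - it_is


def scan_duration(resolution: int, total_fill_ms: float, cfg: AcqConfig) -> float:
    """Scan cost in seconds: max(transient, fill) + inter-scan overhead."""
    if resolution not in cfg.transient_ms:
        raise ValueError(f"resolution {resolution} missing from transient table")
    return (max(cfg.transient_ms[resolution], total_fill_ms)
            + cfg.interscan_overhead_ms) / 1000.0


# ---------------------------------------------------------------------------
# Trigger decisions
# ---------------------------------------------------------------------------


def _ms1_peak_rate(ms1: ScanRecord, mz: float, tol_ppm: float) -> float:
    """IT-normalized intensity (charges/second) of the MS1 peak nearest ``mz``."""
    hit = ms1.peak_near(mz, tol_ppm)
    if hit is None or ms1.fill_ms <= 0:
        return 0.0
    return hit[1] / (ms1.fill_ms / 1000.0)


def detect_in_ms1(
    ms1: ScanRecord,
    inclusion: InclusionList,
    clock: float,
    excl: ExclusionTable,
    cfg: AcqConfig,
    log: list[TriggerEvent] | None = None,
) -> list[TargetEntry]:
    """Step 2 of the trigger chain: which IS precursors are present in MS1."""
    if ms1.scan_class != "MS1":
        raise ValueError("detect_in_ms1 requires an MS1 scan")
    t_min = clock / 60.0
    detected = []
    for entry in inclusion:
        lo, hi = entry.rt_window
        if not (lo <= t_min <= hi):
            continue
        last = excl.get(entry.entry_id)
        if last is not None and (clock - last) < cfg.dynamic_exclusion:
            if log is not None:
                log.append(TriggerEvent(clock, entry.entry_id, "detect", False,
                                        f"dynamic exclusion ({clock - last:.2f} s ago)"))
            continue
        rate = _ms1_peak_rate(ms1, entry.is_peptide.precursor_mz, cfg.mass_tol_ppm)
        ok = rate >= entry.intensity_threshold
        if log is not None:
            log.append(TriggerEvent(clock, entry.entry_id, "detect", ok,
                                    f"MS1 intensity {rate:.3g}"))
        if ok:
            detected.append(entry)
    return detected


def confirm_fragments(prm: ScanRecord, entry: TargetEntry, cfg: AcqConfig) -> bool:
    """Step 3 gate: are enough predefined IS fragments present in the survey scan?

    The ppm tolerance boundary is inclusive (|delta| <= tol counts as a match).
    """
    n = sum(
        1 for frag in entry.match_fragments
        if prm.peak_near(frag.mz, cfg.mass_tol_ppm) is not None
    )
    return n >= entry.min_fragments


# ---------------------------------------------------------------------------
# The acquisition loop
# ---------------------------------------------------------------------------


def _sample_scan(run, clock_s, window, it_s, seed_keys, ms_level=2):
    rng = scan_rng(*seed_keys)
    noiseless = not getattr(run, "shot_noise", True)
    return sample_peak_list(run, clock_s / 60.0, window, it_s, rng,
                            ms_level=ms_level, noiseless=noiseless)


def _total_flux(run: GroundTruthRun, t_min: float, window: tuple[float, float]) -> float:
    return sum(
        flux_at(sp, t_min, run.flux_per_fmol)
        for sp in run.species
        if window[0] <= sp.peptide.precursor_mz <= window[1]
    )


def _acquire_ms1(run, clock, cfg, seed, cycle) -> ScanRecord:
    t_min = clock / 60.0
    fill, _ = accumulate(_total_flux(run, t_min, cfg.ms1.range), cfg.ms1.max_it,
                         cfg.ms1.agc)
    keys = (seed, _CLASS_CODES["MS1"], int(round(clock * 1e6)) % (1 << 32))
    mz, counts = _sample_scan(run, clock, cfg.ms1.range, fill / 1000.0, keys, ms_level=1)
    dur = scan_duration(cfg.ms1.resolution, fill, cfg)
    return ScanRecord("MS1", clock, dur, [], [], mz, counts, cycle, fill_ms=fill)


def _acquire_dia(run, clock, window, cfg, seed, cycle) -> ScanRecord:
    t_min = clock / 60.0
    fill, _ = accumulate(_total_flux(run, t_min, window), cfg.dia.max_it, cfg.dia.agc)
    keys = (seed, _CLASS_CODES["DIA"], int(round(clock * 1e6)) % (1 << 32),
            int(round(sum(window) * 500)))
    mz, counts = _sample_scan(run, clock, window, fill / 1000.0, keys)
    dur = scan_duration(cfg.dia.resolution, fill, cfg)
    center, width = (window[0] + window[1]) / 2.0, window[1] - window[0]
    return ScanRecord("DIA", clock, dur, [(center, width)], [], mz, counts, cycle,
                      fill_ms=fill)


def _merge_peaks(parts):
    mz = np.concatenate([p[0] for p in parts]) if parts else np.empty(0)
    counts = np.concatenate([p[1] for p in parts]) if parts else np.empty(0)
    order = np.argsort(mz)
    return mz[order], counts[order]


def run_acquisition(
    run: GroundTruthRun,
    inclusion: InclusionList,
    cfg: AcqConfig,
    seed: int,
    trigger_log: list[TriggerEvent] | None = None,
) -> list[ScanRecord]:
    """Acquire a full run in ``cfg.mode`` and return the scan stream.

    Deterministic given (run, inclusion, cfg, seed).  In hybrid mode each
    cycle is MS1, an optional multiplexed PRM survey of all detected IS
    precursors, one MSx scan per confirmed IS/ENDO pair (inclusion-list
    order), then the DIA windows.
    """
    if cfg.mode == "surequant":
        return run_surequant(run, inclusion, cfg, seed, trigger_log)
    scans: list[ScanRecord] = []
    excl: ExclusionTable = {}
    clock = 0.0
    gradient_s = run.gradient_length * 60.0
    cycle = 0
    w = cfg.prm_isolation_width
    while clock < gradient_s:
        ms1 = _acquire_ms1(run, clock, cfg, seed, cycle)
        scans.append(ms1)
        ms1_clock = clock
        clock += ms1.duration
        if cfg.mode == "hybrid" and len(inclusion) > 0:
            detected = detect_in_ms1(ms1, inclusion, ms1_clock, excl, cfg, trigger_log)
            if detected:
                # one multiplexed PRM survey of all detected IS precursors
                centers = sorted({e.is_peptide.precursor_mz for e in detected})
                fill_each = cfg.survey.max_it
                parts = []
                for c in centers:
                    keys = (seed, _CLASS_CODES["PRM_SURVEY"],
                            int(round(clock * 1e6)) % (1 << 32), int(round(c * 1000)))
                    parts.append(_sample_scan(run, clock, (c - w / 2, c + w / 2),
                                              fill_each / 1000.0, keys))
                mz, counts = _merge_peaks(parts)
                total_fill = fill_each * len(centers)
                dur = scan_duration(cfg.survey.resolution, total_fill, cfg)
                prm = ScanRecord(
                    "PRM_SURVEY", clock, dur,
                    [(c, w) for c in centers],
                    [(e.entry_id, "IS", fill_each) for e in detected],
                    mz, counts, cycle,
                )
                scans.append(prm)
                clock += dur
                confirmed = []
                for e in detected:
                    ok = confirm_fragments(prm, e, cfg)
                    if trigger_log is not None:
                        trigger_log.append(TriggerEvent(
                            prm.start, e.entry_id, "confirm", ok,
                            "fragment match" if ok else "too few fragments"))
                    if ok:
                        confirmed.append(e)
                        # exclusion clock starts at the MS1 detection
                        excl[e.entry_id] = ms1_clock
                for e in confirmed:
                    flux_est = _ms1_peak_rate(ms1, e.is_peptide.precursor_mz,
                                              cfg.mass_tol_ppm)
                    it_is, it_endo = allocate_msx_fill(flux_est, cfg)
                    is_c = e.is_peptide.precursor_mz
                    en_c = e.endo_mz
                    keys_is = (seed, _CLASS_CODES["MSX"],
                               int(round(clock * 1e6)) % (1 << 32),
                               int(round(is_c * 1000)))
                    keys_en = (seed, _CLASS_CODES["MSX"],
                               int(round(clock * 1e6)) % (1 << 32),
                               int(round(en_c * 1000)))
                    parts = [
                        _sample_scan(run, clock, (is_c - w / 2, is_c + w / 2),
                                     it_is / 1000.0, keys_is),
                        _sample_scan(run, clock, (en_c - w / 2, en_c + w / 2),
                                     it_endo / 1000.0, keys_en),
                    ]
                    mz, counts = _merge_peaks(parts)
                    dur = scan_duration(cfg.msx_resolution, it_is + it_endo, cfg)
                    msx = ScanRecord(
                        "MSX", clock, dur,
                        [(is_c, w), (en_c, w)],
                        [(e.entry_id, "IS", it_is), (e.entry_id, "ENDO", it_endo)],
                        mz, counts, cycle,
                    )
                    scans.append(msx)
                    if trigger_log is not None:
                        trigger_log.append(TriggerEvent(
                            clock, e.entry_id, "msx", True,
                            f"fills IS {it_is:.1f} / ENDO {it_endo:.1f} ms"))
                    clock += dur
        for window in cfg.dia.scheme.windows:
            dia = _acquire_dia(run, clock, window, cfg, seed, cycle)
            scans.append(dia)
            clock += dia.duration
        cycle += 1
    return scans


def run_surequant(
    run: GroundTruthRun,
    inclusion: InclusionList,
    cfg: AcqConfig,
    seed: int,
    trigger_log: list[TriggerEvent] | None = None,
) -> list[ScanRecord]:
    """SureQuant-style acquisition: fast IS survey scans gate sensitive ENDO scans.

    Every inclusion entry must map onto one of the 8 label/charge branches
    (K8/R10 at 2+..4+, A4 at 3+, V6 at 2+); the sensitive scan isolates the
    label-offset (ENDO) m/z at high resolution with the full fill budget.
    """
    for e in inclusion:
        lab = e.is_peptide.label
        if not (isinstance(lab, str) and lab in SUREQUANT_BRANCHES
                and e.is_peptide.charge in SUREQUANT_BRANCHES[lab]):
            raise ValueError(
                f"entry {e.entry_id} does not fit any SureQuant branch "
                f"(label {lab!r}, charge {e.is_peptide.charge})"
            )
    scans: list[ScanRecord] = []
    excl: ExclusionTable = {}
    clock = 0.0
    gradient_s = run.gradient_length * 60.0
    cycle = 0
    w = cfg.prm_isolation_width
    while clock < gradient_s:
        ms1 = _acquire_ms1(run, clock, cfg, seed, cycle)
        scans.append(ms1)
        ms1_clock = clock
        clock += ms1.duration
        detected = detect_in_ms1(ms1, inclusion, ms1_clock, excl, cfg, trigger_log)
        for e in detected:
            c = e.is_peptide.precursor_mz
            fill = cfg.survey.max_it
            keys = (seed, _CLASS_CODES["SQ_SURVEY"],
                    int(round(clock * 1e6)) % (1 << 32), int(round(c * 1000)))
            mz, counts = _sample_scan(run, clock, (c - w / 2, c + w / 2),
                                      fill / 1000.0, keys)
            dur = scan_duration(cfg.survey.resolution, fill, cfg)
            survey = ScanRecord("SQ_SURVEY", clock, dur, [(c, w)],
                                [(e.entry_id, "IS", fill)], mz, counts, cycle)
            scans.append(survey)
            clock += dur
            if not confirm_fragments(survey, e, cfg):
                continue
            excl[e.entry_id] = ms1_clock
            en_c = e.endo_mz
            keys = (seed, _CLASS_CODES["SQ_SENSITIVE"],
                    int(round(clock * 1e6)) % (1 << 32), int(round(en_c * 1000)))
            fill_s = cfg.msx_max_it
            mz, counts = _sample_scan(run, clock, (en_c - w / 2, en_c + w / 2),
                                      fill_s / 1000.0, keys)
            dur = scan_duration(cfg.sq_sensitive_resolution, fill_s, cfg)
            scans.append(ScanRecord("SQ_SENSITIVE", clock, dur, [(en_c, w)],
                                    [(e.entry_id, "ENDO", fill_s)], mz, counts, cycle))
            clock += dur
        cycle += 1
    return scans


# ---------------------------------------------------------------------------
# Run-level accounting
# ---------------------------------------------------------------------------

API_CLASSES = ("PRM_SURVEY", "MSX", "SQ_SURVEY", "SQ_SENSITIVE")


def time_budget(scans: Sequence[ScanRecord]) -> dict:
    """Per-class scan counts/durations and the MS/MS time split (DIA vs API).

    Full (MS1) scans are excluded from the fraction denominators.
    """
    if not scans:
        raise ValueError("empty scan list")
    counts: dict[str, int] = {}
    seconds: dict[str, float] = {}
    for s in scans:
        counts[s.scan_class] = counts.get(s.scan_class, 0) + 1
        seconds[s.scan_class] = seconds.get(s.scan_class, 0.0) + s.duration
    api_t = sum(seconds.get(c, 0.0) for c in API_CLASSES)
    dia_t = seconds.get("DIA", 0.0)
    msms_t = api_t + dia_t
    return {
        "counts": counts,
        "seconds": seconds,
        "api_fraction": api_t / msms_t if msms_t > 0 else 0.0,
        "dia_fraction": dia_t / msms_t if msms_t > 0 else 0.0,
        "total_seconds": sum(seconds.values()),
    }


@dataclass(frozen=True)
class IdLossModel:
    """OLS line relating target density (targets/min) to % lost DIA identifications."""

    slope: float
    intercept: float

    def predict(self, targets_per_minute: float) -> float:
        return self.slope * targets_per_minute + self.intercept


def id_loss_model(observations: Sequence[tuple[float, float]]) -> IdLossModel:
    """Fit the identification-loss extrapolation line by ordinary least squares."""
    if len(observations) < 2:
        raise ValueError("need at least 2 observations")
    x = np.asarray([o[0] for o in observations], float)
    y = np.asarray([o[1] for o in observations], float)
    if np.ptp(x) == 0:
        raise ValueError("observations must span more than one target density")
    slope, intercept = np.polyfit(x, y, 1)
    return IdLossModel(float(slope), float(intercept))
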