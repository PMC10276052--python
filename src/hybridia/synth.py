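"""Synthetic ground-truth LC-MS runs.

The acquisition engine does not talk to an instrument; it samples a
:class:`GroundTruthRun` — a set of eluting species, each a precursor with a
Gaussian chromatographic profile, a known on-column amount and a fixed
relative fragmentation pattern.  Sampling converts ion flux (charges/second)
into detector counts over a finite injection time, with Poisson shot noise,
ppm-scale mass jitter and a chemical-noise background whose total intensity is
proportional to the isolation-window width — the mechanism by which narrow
targeted isolation out-performs wide DIA windows on signal-to-noise.

Two canned scenarios mirror common benchmark designs: a seven-peptide,
five-isotopologue dilution series (a system-suitability standard spanning
50 -> 0.0325 fmol on column) and an N-target spike-in panel with heavy IS
peptides at constant amount over log-uniform endogenous levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import yaml

from .targets import (
    FragmentIon,
    InclusionList,
    PeptideSpec,
    TargetEntry,
    compute_endo_mz,
)

#: Pierce-style dilution series: injected volume (µl) and stock concentration
#: of the trigger isotopologue (pmol/µl); 0.1 µl x 0.5 pmol/µl = 50 fmol.
PIERCE_INJECTION_UL = 0.1
PIERCE_TRIGGER_CONC_PMOL_PER_UL = 0.5
PIERCE_TRIGGER_FMOL = PIERCE_INJECTION_UL * PIERCE_TRIGGER_CONC_PMOL_PER_UL * 1000.0
#: On-column amounts of the four lower isotopologues, fmol.
PIERCE_ENDO_FMOL = (5.0, 0.5, 0.125, 0.0325)
#: Mass step between adjacent isotopologues (one A4-equivalent label), Da.
PIERCE_LABEL_STEP = 4.0070993


@dataclass(frozen=True)
class ElutionProfile:
    """Gaussian chromatographic peak."""

    apex_rt: float  # minutes
    sigma: float  # seconds
    apex_flux: float = 0.0  # charges/second at apex for a 1-fmol species

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class Species:
    """One eluting molecular species (a precursor with its fragments)."""

    peptide: PeptideSpec
    amount: float  # fmol on column
    elution: ElutionProfile
    fragment_pattern: tuple[float, ...]  # relative intensities, sum to 1
    channel: str  # 'IS' or 'ENDO'
    target_key: str  # entry_id of the TargetEntry this species belongs to

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be >= 0")
        pat = np.asarray(self.fragment_pattern, float)
        if pat.size != len(self.peptide.fragments):
            raise ValueError("fragment_pattern must match the fragment list")
        if np.any(pat < 0) or abs(pat.sum() - 1.0) > 1e-9:
            raise ValueError("fragment_pattern must be non-negative and sum to 1")


@dataclass
class GroundTruthRun:
    """Everything a simulated acquisition can observe."""

    gradient_length: float  # minutes
    species: list[Species]
    flux_per_fmol: float = 1e5  # charges/second at apex per fmol on column
    chemical_noise_rate: float = 50.0  # charges/second per Th of isolation width
    mz_jitter_ppm: float = 2.0
    seed: int = 0
    #: expected-value mode: disables shot noise, jitter and chemical noise
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if min(self.flux_per_fmol, self.chemical_noise_rate, self.mz_jitter_ppm, 0) < 0:
            raise ValueError("rates must be non-negative")
        for sp in self.species:
            if not (0 <= sp.elution.apex_rt <= self.gradient_length):
                raise ValueError(
                    f"species {sp.peptide.sequence} elutes outside the gradient"
                )


def flux_at(species: Species, t: float, flux_per_fmol: float = 1e5) -> float:
    """Total precursor ion flux (charges/second) of a species at time ``t`` (min)."""
    sigma_min = species.elution.sigma / 60.0
    z = (t - species.elution.apex_rt) / sigma_min
    return species.amount * flux_per_fmol * math.exp(-0.5 * z * z)


def scan_rng(seed: int, *stream_keys: int) -> np.random.Generator:
    """Deterministic child RNG for one scan.

    The stream is keyed by the root seed plus integer identifiers of the scan
    (class code, time in microseconds, window key), so the same scan draws the
    same noise regardless of the order scans are generated in.
    """
    keys = [int(seed) & 0x7FFFFFFF] + [int(k) & 0xFFFFFFFF for k in stream_keys]
    return np.random.default_rng(np.random.SeedSequence(keys))


def sample_peak_list(
    run: GroundTruthRun,
    t: float,
    mz_window: tuple[float, float],
    it_seconds: float,
    rng: np.random.Generator,
    ms_level: int = 2,
    channel_filter: str | None = None,
    readout_range: tuple[float, float] = (100.0, 1500.0),
    noiseless: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the centroid peak list one scan would observe.

    For MS1 the window selects precursors and the peaks are precursor ions;
    for MS2 the window is the quadrupole isolation and the peaks are the
    fragments of every species whose precursor falls inside it.  Expected
    counts are ``flux x injection time``; observed counts are Poisson draws;
    m/z values are jittered by ``mz_jitter_ppm``.  Chemical-noise peaks carry
    a total expected count of ``chemical_noise_rate x window width x it``.
    """
    if it_seconds <= 0:
        raise ValueError("it_seconds must be positive")
    lo, hi = mz_window
    mzs: list[float] = []
    counts: list[float] = []
    for sp in run.species:
        if channel_filter is not None and sp.channel != channel_filter:
            continue
        flux = flux_at(sp, t, run.flux_per_fmol)
        if flux <= 0:
            continue
        if ms_level == 1:
            pmz = sp.peptide.precursor_mz
            if lo <= pmz <= hi:
                mzs.append(pmz)
                counts.append(flux * it_seconds)
        else:
            if not (lo <= sp.peptide.precursor_mz <= hi):
                continue
            for frag, frac in zip(sp.peptide.fragments, sp.fragment_pattern):
                if frac <= 0:
                    continue
                mzs.append(frag.mz)
                counts.append(flux * frac * it_seconds)
    mz_arr = np.asarray(mzs, float)
    cnt_arr = np.asarray(counts, float)
    if not noiseless:
        cnt_arr = rng.poisson(cnt_arr).astype(float) if cnt_arr.size else cnt_arr
        if run.mz_jitter_ppm > 0 and mz_arr.size:
            mz_arr = mz_arr * (
                1.0 + rng.normal(0.0, run.mz_jitter_ppm * 1e-6, size=mz_arr.size)
            )
        # chemical noise: total expected counts proportional to isolation width
        noise_total = run.chemical_noise_rate * (hi - lo) * it_seconds
        if noise_total > 0:
            mean_per_peak = 20.0
            k = rng.poisson(noise_total / mean_per_peak)
            if k > 0:
                nm = rng.uniform(readout_range[0], readout_range[1], size=k)
                nc = rng.poisson(mean_per_peak, size=k).astype(float)
                keep = nc > 0
                mz_arr = np.concatenate([mz_arr, nm[keep]])
                cnt_arr = np.concatenate([cnt_arr, nc[keep]])
    keep = cnt_arr > 0
    mz_arr, cnt_arr = mz_arr[keep], cnt_arr[keep]
    order = np.argsort(mz_arr)
    return mz_arr[order], cnt_arr[order]


# ---------------------------------------------------------------------------
# Canned scenarios
# ---------------------------------------------------------------------------

_FRAG_PATTERN = (0.28, 0.22, 0.18, 0.13, 0.11, 0.08)

# Synthetic stand-in peptides for a 7-peptide system-suitability mix (the
# real kit sequences are proprietary); m/z values are plausible tryptic 2+.
_PIERCE_PEPTIDES = (
    ("SSYTPEPLAK", 541.78),
    ("GLIDEVTTAR", 611.84),
    ("VGDHFYSPK", 653.32),
    ("LATQSNEITIPVTFESR", 728.41),
    ("AVGAHLDVK", 791.93),
    ("TDLEKDIISDTSGDFR", 848.40),
    ("YVYVADVAAK", 919.98),
)


def _fragment_set(base_mz: float) -> tuple[FragmentIon, ...]:
    """Six synthetic singly charged y-ion m/z values for one peptide."""
    offsets = (175.119, 262.151, 375.235, 488.319, 601.403, 716.430)
    return tuple(
        FragmentIon(series="y", index=i + 2, charge=1, mz=base_mz / 2.0 + off, rank=i + 1)
        for i, off in enumerate(offsets)
    )


def make_pierce_series(
    seed: int,
    gradient_length: float = 31.0,
    sigma_s: float = 4.0,
    rt_halfwidth: float = 2.0,
) -> tuple[GroundTruthRun, InclusionList]:
    """A 7-peptide x 5-isotopologue dilution series.

    Each peptide appears as five co-eluting isotopologues: the most abundant
    (50 fmol on column) acts as the triggering IS, and the remaining four
    (5, 0.5, 0.125 and 0.0325 fmol) are modelled as the ENDO channels of four
    derived target entries, giving a 3+ order-of-magnitude dynamic range
    within single multiplexed scans.  Apexes are evenly spaced across the
    gradient; co-eluting isotopologues share one elution profile.
    """
    species: list[Species] = []
    entries: list[TargetEntry] = []
    n = len(_PIERCE_PEPTIDES)
    for i, (seqname, base_mz) in enumerate(_PIERCE_PEPTIDES):
        apex = gradient_length * (i + 1) / (n + 1)
        halfwidth = min(rt_halfwidth, apex, gradient_length - apex)
        elution = ElutionProfile(apex_rt=apex, sigma=sigma_s)
        trig_frags = _fragment_set(base_mz)
        trigger = PeptideSpec(
            sequence=seqname, charge=2, label="custom:0.0",
            precursor_mz=base_mz, fragments=trig_frags,
        )
        for j, amount in enumerate(PIERCE_ENDO_FMOL, start=1):
            delta = j * PIERCE_LABEL_STEP
            endo_mz = base_mz - delta / 2.0
            is_pep = PeptideSpec(
                sequence=seqname, charge=2, label=delta,
                precursor_mz=base_mz, fragments=trig_frags,
            )
            entry = TargetEntry(
                is_peptide=is_pep, endo_mz=endo_mz,
                rt_center=apex, rt_halfwidth=halfwidth,
            )
            entries.append(entry)
            endo_frags = tuple(
                FragmentIon(f.series, f.index, f.charge, entry.endo_fragment_mz(f), f.rank)
                for f in trig_frags
            )
            endo_pep = PeptideSpec(
                sequence=seqname, charge=2, label="none",
                precursor_mz=endo_mz, fragments=endo_frags,
            )
            species.append(
                Species(endo_pep, amount, elution, _FRAG_PATTERN, "ENDO", entry.entry_id)
            )
        # one physical trigger species, bookkept under the first entry's key
        species.append(
            Species(trigger, PIERCE_TRIGGER_FMOL, elution, _FRAG_PATTERN, "IS",
                    entries[-4].entry_id)
        )
    run = GroundTruthRun(gradient_length=gradient_length, species=species, seed=seed)
    return run, InclusionList(entries=entries, gradient_length=gradient_length)


def make_panel_run(
    n_targets: int,
    gradient_length: float = 60.0,
    endo_range: tuple[float, float] = (0.01, 10.0),
    seed: int = 0,
    sigma_s: float = 4.0,
    is_amount: float = 50.0,
    rt_halfwidth: float = 2.0,
) -> tuple[GroundTruthRun, InclusionList]:
    """An N-target spike-in panel: IS at constant amount, ENDO log-uniform.

    Apexes are evenly spaced over the gradient (a single target elutes at the
    midpoint); ENDO amounts are drawn log-uniformly over ``endo_range`` from
    the given seed.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = endo_range
    endo_amounts = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_targets))
    species: list[Species] = []
    entries: list[TargetEntry] = []
    labels = ("K8", "R10")
    charges = (2, 3)
    for i in range(n_targets):
        apex = gradient_length * (i + 1) / (n_targets + 1)
        halfwidth = min(rt_halfwidth, apex, gradient_length - apex)
        label, charge = labels[i % 2], charges[i % 2]
        base_mz = 480.0 + (i * 37.0) % 420.0
        frags = _fragment_set(base_mz)
        is_pep = PeptideSpec(
            sequence=f"PANELPEP{i:03d}K", charge=charge, label=label,
            precursor_mz=base_mz, fragments=frags,
        )
        entry = TargetEntry(
            is_peptide=is_pep,
            endo_mz=compute_endo_mz(base_mz, label, charge),
            rt_center=apex, rt_halfwidth=halfwidth,
        )
        entries.append(entry)
        elution = ElutionProfile(apex_rt=apex, sigma=sigma_s)
        species.append(
            Species(is_pep, is_amount, elution, _FRAG_PATTERN, "IS", entry.entry_id)
        )
        endo_frags = tuple(
            FragmentIon(f.series, f.index, f.charge, entry.endo_fragment_mz(f), f.rank)
            for f in frags
        )
        endo_pep = PeptideSpec(
            sequence=is_pep.sequence, charge=charge, label="none",
            precursor_mz=entry.endo_mz, fragments=endo_frags,
        )
        species.append(
            Species(endo_pep, float(endo_amounts[i]), elution, _FRAG_PATTERN, "ENDO",
                    entry.entry_id)
        )
    run = GroundTruthRun(gradient_length=gradient_length, species=species, seed=seed)
    return run, InclusionList(entries=entries, gradient_length=gradient_length)


def make_plateau_run(
    seed: int,
    plateau_s: float = 60.0,
    amount: float = 50.0,
    gradient_length: float = 4.0,
) -> tuple[GroundTruthRun, InclusionList]:
    """One target whose IS stays above the 1e5 trigger threshold continuously.

    The elution is a wide Gaussian whose above-threshold span is at least
    ``plateau_s`` seconds — used to exercise dynamic exclusion.
    """
    # span above threshold = 2 sigma sqrt(2 ln(amount*flux_per_fmol/1e5))
    fpf, thr = 1e5, 1e5
    span_factor = 2.0 * math.sqrt(2.0 * math.log(amount * fpf / thr))
    sigma = max(plateau_s / span_factor * 1.3, 1.0)  # 30% margin
    apex = gradient_length / 2.0
    base_mz = 622.33
    frags = _fragment_set(base_mz)
    is_pep = PeptideSpec(
        sequence="PLATEAUPEPK", charge=2, label="K8",
        precursor_mz=base_mz, fragments=frags,
    )
    entry = TargetEntry(
        is_peptide=is_pep, endo_mz=compute_endo_mz(base_mz, "K8", 2),
        rt_center=apex, rt_halfwidth=apex,
    )
    elution = ElutionProfile(apex_rt=apex, sigma=sigma)
    endo_frags = tuple(
        FragmentIon(f.series, f.index, f.charge, entry.endo_fragment_mz(f), f.rank)
        for f in frags
    )
    endo_pep = PeptideSpec(
        sequence="PLATEAUPEPK", charge=2, label="none",
        precursor_mz=entry.endo_mz, fragments=endo_frags,
    )
    species = [
        Species(is_pep, amount, elution, _FRAG_PATTERN, "IS", entry.entry_id),
        Species(endo_pep, 1.0, elution, _FRAG_PATTERN, "ENDO", entry.entry_id),
    ]
    run = GroundTruthRun(gradient_length=gradient_length, species=species, seed=seed)
    return run, InclusionList(entries=[entry], gradient_length=gradient_length)


# ---------------------------------------------------------------------------
# Serialization (reproducible runs from a text config)
# ---------------------------------------------------------------------------


def run_to_config(run: GroundTruthRun) -> str:
    """Serialize a ground-truth run to YAML."""
    doc = {
        "gradient_length": run.gradient_length,
        "flux_per_fmol": run.flux_per_fmol,
        "chemical_noise_rate": run.chemical_noise_rate,
        "mz_jitter_ppm": run.mz_jitter_ppm,
        "seed": run.seed,
        "species": [
            {
                "sequence": sp.peptide.sequence,
                "charge": sp.peptide.charge,
                "label": sp.peptide.label,
                "precursor_mz": sp.peptide.precursor_mz,
                "fragments": [
                    {"series": f.series, "index": f.index, "charge": f.charge,
                     "mz": f.mz, "rank": f.rank}
                    for f in sp.peptide.fragments
                ],
                "amount": sp.amount,
                "apex_rt": sp.elution.apex_rt,
                "sigma": sp.elution.sigma,
                "fragment_pattern": list(sp.fragment_pattern),
                "channel": sp.channel,
                "target_key": sp.target_key,
            }
            for sp in run.species
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def run_from_config(text: str) -> GroundTruthRun:
    doc = yaml.safe_load(text)
    species = []
    for s in doc["species"]:
        frags = tuple(
            FragmentIon(f["series"], f["index"], f["charge"], f["mz"], f["rank"])
            for f in s["fragments"]
        )
        pep = PeptideSpec(
            sequence=s["sequence"], charge=s["charge"], label=s["label"],
            precursor_mz=s["precursor_mz"], fragments=frags,
        )
        species.append(
            Species(
                pep, s["amount"],
                ElutionProfile(apex_rt=s["apex_rt"], sigma=s["sigma"]),
                tuple(s["fragment_pattern"]), s["channel"], s["target_key"],
            )
        )
    return GroundTruthRun(
        gradient_length=doc["gradient_length"],
        species=species,
        flux_per_fmol=doc["flux_per_fmol"],
        chemical_noise_rate=doc["chemical_noise_rate"],
        mz_jitter_ppm=doc["mz_jitter_ppm"],
        seed=doc["seed"],
    )
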