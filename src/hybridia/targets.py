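"""Peptide targets, inclusion lists and DIA window planning.

A hybrid-DIA method is driven by an inclusion list of heavy internal-standard
(IS) peptides, each paired with its endogenous (ENDO) counterpart.  The IS
carries a stable-isotope label (SILAC-style K8/R10, or the A4/V6 labels used
by commercial trigger-peptide kits), so IS and ENDO are chemically identical
and separated only by a fixed mass offset.  This module models those targets,
computes heavy/light m/z relationships from first-principles isotope masses,
plans the DIA isolation-window scheme, and reads/writes the tab-separated
inclusion-list format consumed by the acquisition engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Mass difference between the heavy and light isotope, in Da.
C13_C12 = 1.0033548
N15_N14 = 0.9970349

#: Mass deltas of the common heavy-label amino acids, in Da.
#: K8 = 6x13C + 2x15N, R10 = 6x13C + 4x15N, A4 = 3x13C + 1x15N,
#: V6 = 5x13C + 1x15N.
LABEL_DELTAS: dict[str, float] = {
    "none": 0.0,
    "K8": 6 * C13_C12 + 2 * N15_N14,
    "R10": 6 * C13_C12 + 4 * N15_N14,
    "A4": 3 * C13_C12 + 1 * N15_N14,
    "V6": 5 * C13_C12 + 1 * N15_N14,
}


def label_delta(label: str | float) -> float:
    """Mass delta (Da) of a heavy label.

    ``label`` is either one of the named labels in :data:`LABEL_DELTAS`,
    a ``"custom:<delta>"`` string, or a bare number (Da).
    """
    if isinstance(label, (int, float)):
        return float(label)
    if label in LABEL_DELTAS:
        return LABEL_DELTAS[label]
    if isinstance(label, str) and label.startswith("custom:"):
        return float(label.split(":", 1)[1])
    raise ValueError(f"unknown isotope label {label!r}")


def compute_endo_mz(is_mz: float, label: str | float, charge: int) -> float:
    """m/z of the light (endogenous) precursor given the heavy IS precursor.

    The heavy label adds ``label_delta(label)`` Da to the neutral mass, so at
    charge ``z`` the ENDO precursor sits ``delta / z`` Th below the IS.
    """
    if is_mz <= 0:
        raise ValueError("is_mz must be positive")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    delta = label_delta(label)
    if delta < 0:
        raise ValueError("label mass delta must be non-negative")
    return is_mz - delta / charge


@dataclass(frozen=True)
class FragmentIon:
    """A single fragment ion monitored for one peptide."""

    series: str  # 'y' or 'b'
    index: int
    charge: int
    mz: float
    rank: int  # 1 = most intense in the survey run

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")
        if self.charge < 1 or self.index < 1:
            raise ValueError("fragment index and charge must be >= 1")


@dataclass(frozen=True)
class PeptideSpec:
    """A precursor species: sequence, charge, label and monitored fragments."""

    sequence: str
    charge: int
    label: str | float = "none"
    precursor_mz: float = 0.0
    modifications: tuple[tuple[int, float], ...] = ()
    fragments: tuple[FragmentIon, ...] = ()

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        ranks = [f.rank for f in self.fragments]
        if len(set(ranks)) != len(ranks):
            raise ValueError("fragment ranks must be unique within a peptide")

    @property
    def label_delta(self) -> float:
        return label_delta(self.label)


@dataclass(frozen=True)
class TargetEntry:
    """One inclusion-list row: an IS peptide and its ENDO counterpart."""

    is_peptide: PeptideSpec
    endo_mz: float
    rt_center: float  # minutes
    rt_halfwidth: float  # minutes
    intensity_threshold: float = 1e5
    min_fragments: int = 3

    def __post_init__(self) -> None:
        if not (self.endo_mz < self.is_peptide.precursor_mz):
            raise ValueError("endo_mz must be below the heavy IS precursor m/z")
        n = len(self.match_fragments)
        if not (1 <= self.min_fragments <= n <= 6):
            raise ValueError(
                f"need 1 <= min_fragments <= n_fragments <= 6, got "
                f"min={self.min_fragments}, n={n}"
            )

    @property
    def match_fragments(self) -> tuple[FragmentIon, ...]:
        return self.is_peptide.fragments

    @property
    def entry_id(self) -> str:
        p = self.is_peptide
        lab = p.label if isinstance(p.label, str) else f"custom:{p.label:.6f}"
        return f"{p.sequence}/{p.charge}/{lab}"

    @property
    def rt_window(self) -> tuple[float, float]:
        return (self.rt_center - self.rt_halfwidth, self.rt_center + self.rt_halfwidth)

    def endo_fragment_mz(self, frag: FragmentIon) -> float:
        """Light-channel m/z of a monitored fragment.

        The label sits on the C-terminal residue, so every monitored (y-type)
        fragment shifts by the full label delta divided by its charge.
        """
        return frag.mz - self.is_peptide.label_delta / frag.charge


@dataclass
class InclusionList:
    """The target panel driving triggered acquisition."""

    entries: list[TargetEntry]
    gradient_length: float  # minutes

    def __post_init__(self) -> None:
        keys = [e.entry_id for e in self.entries]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise ValueError(f"duplicate inclusion-list entries: {sorted(dupes)}")
        for e in self.entries:
            lo, hi = e.rt_window
            if lo < 0 or hi > self.gradient_length:
                raise ValueError(
                    f"RT window of {e.entry_id} [{lo:.2f}, {hi:.2f}] lies outside "
                    f"the {self.gradient_length:.2f} min gradient"
                )

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def sorted_by_rt(self) -> list[TargetEntry]:
        return sorted(self.entries, key=lambda e: e.rt_center)


@dataclass(frozen=True)
class DiaWindowScheme:
    """An equal-width, overlapping DIA isolation-window scheme."""

    start_mz: float
    end_mz: float
    n_windows: int
    overlap: float
    windows: tuple[tuple[float, float], ...]

    @property
    def width(self) -> float:
        return self.windows[0][1] - self.windows[0][0]

    def to_text(self) -> str:
        return "\n".join(f"{lo:.4f}\t{hi:.4f}" for lo, hi in self.windows) + "\n"


def plan_dia_windows(
    start_mz: float, end_mz: float, n_windows: int, overlap: float = 0.0
) -> DiaWindowScheme:
    """Plan equal-width DIA windows with a fixed adjacent overlap.

    The common window width is ``w = (end - start + overlap) / n``; windows
    tile contiguously from ``start - overlap/2`` with step ``w - overlap``, so
    each adjacent pair shares exactly ``overlap`` Th.  For the standard
    scheme covering 472-1143 m/z with 11 windows and 1 Th overlap this gives
    the familiar 61.1 Da window width.
    """
    if end_mz <= start_mz:
        raise ValueError("end_mz must exceed start_mz")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    width = (end_mz - start_mz + overlap) / n_windows
    if width <= overlap:
        raise ValueError(
            f"degenerate scheme: window width {width:.4f} <= overlap {overlap:.4f}"
        )
    step = width - overlap
    first_low = start_mz - overlap / 2.0
    windows = tuple(
        (first_low + i * step, first_low + i * step + width) for i in range(n_windows)
    )
    return DiaWindowScheme(start_mz, end_mz, n_windows, overlap, windows)


# ---------------------------------------------------------------------------
# Inclusion-list file format (tab-separated, one header line)
# ---------------------------------------------------------------------------

_COLUMNS = (
    ["sequence", "charge", "label", "is_mz", "endo_mz", "rt_center", "rt_halfwidth"]
    + [f"frag{i}" for i in range(1, 7)]
    + ["threshold"]
)


def write_inclusion_list(inclusion: InclusionList, path) -> None:
    """Write the panel as tab-separated text (``input.txt`` convention)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# gradient_length_min={inclusion.gradient_length:.4f}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for e in inclusion.entries:
            p = e.is_peptide
            lab = p.label if isinstance(p.label, str) else f"custom:{p.label:.6f}"
            frags = [f"{f.mz:.4f}" for f in sorted(p.fragments, key=lambda f: f.rank)]
            frags += [""] * (6 - len(frags))
            row = [
                p.sequence,
                str(p.charge),
                lab,
                f"{p.precursor_mz:.4f}",
                f"{e.endo_mz:.4f}",
                f"{e.rt_center:.4f}",
                f"{e.rt_halfwidth:.4f}",
                *frags,
                f"{e.intensity_threshold:.4g}",
            ]
            fh.write("\t".join(row) + "\n")


def read_inclusion_list(path) -> InclusionList:
    """Parse a tab-separated inclusion list.

    A blank ``endo_mz`` is filled from the label via :func:`compute_endo_mz`.
    Fragment columns hold m/z only; ranks are assigned by column order and
    fragments are modelled as singly charged y-ions.
    """
    gradient = None
    entries: list[TargetEntry] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            if "gradient_length_min=" in ln:
                gradient = float(ln.split("=", 1)[1])
            continue
        if ln.strip():
            body.append(ln)
    if not body:
        raise ValueError("empty inclusion list file")
    header = body[0].split("\t")
    if header[:3] != _COLUMNS[:3]:
        raise ValueError(f"unrecognized inclusion list header: {header[:3]}")
    for rowno, ln in enumerate(body[1:], start=2):
        cells = ln.split("\t")
        cells += [""] * (len(_COLUMNS) - len(cells))
        try:
            sequence = cells[0]
            charge = int(cells[1])
            label: str | float = cells[2]
            is_mz = float(cells[3])
            endo_mz = float(cells[4]) if cells[4].strip() else compute_endo_mz(
                is_mz, label, charge
            )
            rt_center = float(cells[5])
            rt_halfwidth = float(cells[6])
            frag_mzs = [float(c) for c in cells[7:13] if c.strip()]
            threshold = float(cells[13]) if cells[13].strip() else 1e5
        except ValueError as exc:
            raise ValueError(f"row {rowno}: non-numeric field ({exc})") from None
        fragments = tuple(
            FragmentIon(series="y", index=i, charge=1, mz=mz, rank=i)
            for i, mz in enumerate(frag_mzs, start=1)
        )
        peptide = PeptideSpec(
            sequence=sequence,
            charge=charge,
            label=label,
            precursor_mz=is_mz,
            fragments=fragments,
        )
        entries.append(
            TargetEntry(
                is_peptide=peptide,
                endo_mz=endo_mz,
                rt_center=rt_center,
                rt_halfwidth=rt_halfwidth,
                intensity_threshold=threshold,
            )
        )
    if gradient is None:
        gradient = max(e.rt_center + e.rt_halfwidth for e in entries)
    return InclusionList(entries=entries, gradient_length=gradient)


# ---------------------------------------------------------------------------
# Building an inclusion list from survey-run chromatograms
# ---------------------------------------------------------------------------


@dataclass
class SurveyTarget:
    """Per-target survey-run fragment chromatograms used to build an entry."""

    is_peptide: PeptideSpec  # fragments here carry candidate m/z; ranks ignored
    endo_mz: float
    rt: np.ndarray  # minutes, shared by all fragment traces
    fragment_traces: Mapping[float, np.ndarray]  # fragment m/z -> intensity

    def summed(self) -> np.ndarray:
        return np.sum([np.asarray(v, float) for v in self.fragment_traces.values()], axis=0)


def build_inclusion_list(
    survey: Sequence[SurveyTarget],
    gradient_length: float,
    top_n: int = 6,
    rt_halfwidth: float = 2.0,
    noise_floor: float = 0.0,
) -> InclusionList:
    """Derive an inclusion list from survey-run XICs.

    The retention-time center is the apex of the summed fragment trace; the
    ``top_n`` fragments by apex intensity are kept and ranked (ties broken by
    ascending m/z).  Targets whose summed trace never rises above
    ``noise_floor`` are dropped with a warning.
    """
    entries = []
    for tgt in survey:
        total = tgt.summed()
        if total.size == 0 or float(np.max(total)) <= noise_floor:
            logger.warning(
                "target %s has no apex above the noise floor; dropped",
                tgt.is_peptide.sequence,
            )
            continue
        apex_idx = int(np.argmax(total))
        rt_center = float(tgt.rt[apex_idx])
        apex_int = {
            mz: float(np.asarray(trace, float)[apex_idx])
            for mz, trace in tgt.fragment_traces.items()
        }
        # sort by descending apex intensity, ties by ascending m/z
        ordered = sorted(apex_int.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        fragments = tuple(
            FragmentIon(series="y", index=rank, charge=1, mz=mz, rank=rank)
            for rank, (mz, _) in enumerate(ordered, start=1)
        )
        peptide = replace(tgt.is_peptide, fragments=fragments)
        entries.append(
            TargetEntry(
                is_peptide=peptide,
                endo_mz=tgt.endo_mz,
                rt_center=rt_center,
                rt_halfwidth=rt_halfwidth,
                min_fragments=min(3, len(fragments)),
            )
        )
    return InclusionList(entries=entries, gradient_length=gradient_length)
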