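"""Quality metrics, filtering, normalization and condition-level statistics.

Two spectral-library-free quality metrics gate targeted quantifications:

* **PPFR** (peptide-peak-found ratio): the fraction of monitored ENDO
  transitions with a detectable peak co-eluting with the IS consensus apex.
  Pairs pass with PPFR strictly above 0.5.
* **DOTPR** (dot-product ratio): cosine similarity between the ENDO and IS
  transition-area vectors — 1 when the two label channels fragment in
  identical proportions.  Pairs pass with DOTPR >= 0.5.

Together with the >= 3 quantifiable-fragments rule these form the standard
filter for reporting a pair.  The module also provides IS normalization with
an optional DIA-median loading correction, dilution-series reporting
(linearity, LLOQ, dynamic range) and Welch-t / Benjamini-Hochberg condition
statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .acquire import AcqConfig
from .quant import PairQuant, XICTrace, detect_peak, PeakIntegration

logger = logging.getLogger(__name__)

#: Minimum apex ion count for a transition to count as "found" in PPFR.
#: With ion counting, >= 10 ions is a >= 3-sigma excess over a near-zero
#: Poisson baseline; above that the MAD of the out-of-peak raw counts takes
#: over as the noise estimate.
PPFR_MIN_APEX_COUNTS = 10.0
#: Relative deviation of a sample's DIA median from the grand median above
#: which the second (loading) normalization step is recommended.
LOADING_BIAS_THRESHOLD = 0.2


@dataclass(frozen=True)
class QCRecord:
    """Pass/fail summary of one pair against the standard filters."""

    target_id: str
    ppfr: float
    dotpr: float
    n_quantified_fragments: int

    @property
    def pass_ppfr(self) -> bool:
        return self.ppfr > 0.5

    @property
    def pass_dotpr(self) -> bool:
        return self.dotpr >= 0.5

    @property
    def pass_quant(self) -> bool:
        return self.n_quantified_fragments >= 3

    @property
    def pass_all(self) -> bool:
        return self.pass_ppfr and self.pass_dotpr and self.pass_quant


def ppfr(
    pair: PairQuant,
    detail: Mapping,
    cfg: AcqConfig,
    cycle_time_s: float = 1.0,
) -> float:
    """Peptide-peak-found ratio of one pair.

    An ENDO transition counts as found when a peak is detected, its apex lies
    within one cycle time — or 1.5 XIC sampling intervals, whichever is
    larger — of the IS consensus apex (the median of the IS fragment
    apexes), and
    the apex raw ion count clears a Poisson-scale significance threshold
    (>= 3-sigma over the out-of-peak background, with a floor of
    :data:`PPFR_MIN_APEX_COUNTS` ions).  The sampling-interval term matters
    because dynamic exclusion spaces MSx points several cycles apart: an apex
    cannot be localized more finely than the points it was sampled on, the
    argmax of two near-equal points straddling the true apex flips by a full
    interval under shot noise, and an even-count median consensus can fall
    mid-interval — hence the 1.5-interval allowance.
    """
    is_apexes = [pk.apex_rt for _, pk in detail["is"].values() if pk.found]
    endo_items = list(detail["endo"].values())
    if not endo_items:
        return float("nan")
    if not is_apexes:
        return 0.0
    consensus = float(np.median(is_apexes))
    found = 0
    for trace, pk in endo_items:
        if not pk.found:
            continue
        samp_s = (float(np.median(np.diff(trace.rt))) * 60.0
                  if len(trace) > 1 else 0.0)
        tol_min = max(cycle_time_s, 1.5 * samp_s) / 60.0
        if abs(pk.apex_rt - consensus) > tol_min:
            continue
        raw = trace.intensity
        inside = (trace.rt >= pk.boundaries[0]) & (trace.rt <= pk.boundaries[1])
        apex_counts = float(np.max(raw[inside])) if np.any(inside) else 0.0
        out = raw[~inside]
        mad = 1.4826 * float(np.median(np.abs(out - np.median(out)))) if out.size >= 3 else 0.0
        if apex_counts >= max(PPFR_MIN_APEX_COUNTS, 3.0 * mad):
            found += 1
    return found / len(endo_items)


def dotpr(endo_areas: Sequence[float], is_areas: Sequence[float]) -> float:
    """Normalized dot product of the two channels' transition-area vectors."""
    a = np.asarray(endo_areas, float)
    b = np.asarray(is_areas, float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal-length vectors with >= 2 shared fragments")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        logger.warning("zero-norm transition-area vector; DOTPR set to 0")
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def qc_record(pair: PairQuant, detail: Mapping, cfg: AcqConfig,
              cycle_time_s: float = 1.0) -> QCRecord:
    """Compute both QC metrics for a quantified pair and fill them in."""
    p = ppfr(pair, detail, cfg, cycle_time_s)
    if len(pair.fragment_areas) >= 2:
        endo_v = [v[0] for v in pair.fragment_areas.values()]
        is_v = [v[1] for v in pair.fragment_areas.values()]
        d = dotpr(endo_v, is_v)
    else:
        d = float("nan")
    pair.ppfr, pair.dotpr = p, d
    return QCRecord(pair.target_id, p, d, pair.n_quantified_fragments)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_ratios(
    pairs_by_sample: Mapping[str, Sequence[PairQuant]],
    dia_medians: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """ENDO/IS ratios per target per sample, optionally loading-corrected.

    The primary normalization is the ENDO/IS ratio itself (the IS amount is
    constant by design).  When per-sample DIA median intensities are supplied,
    each sample's ratios are additionally divided by
    ``sample median / grand median``, cancelling a global loading bias that
    affects ENDO and DIA intensities but not the spiked IS.
    """
    rows = []
    grand = float(np.median(list(dia_medians.values()))) if dia_medians else None
    for sample, pairs in pairs_by_sample.items():
        factor = 1.0
        if dia_medians is not None:
            factor = dia_medians[sample] / grand
        for p in pairs:
            if not math.isfinite(p.ratio) or p.area_is <= 0:
                logger.warning("pair %s in sample %s has no IS area; dropped",
                               p.target_id, sample)
                continue
            rows.append({"sample": sample, "target_id": p.target_id,
                         "ratio": p.ratio / factor})
    return pd.DataFrame(rows, columns=["sample", "target_id", "ratio"])


def loading_bias_detected(dia_medians: Mapping[str, float],
                          threshold: float = LOADING_BIAS_THRESHOLD) -> bool:
    """Whether any sample's DIA median deviates enough to warrant correction."""
    med = np.asarray(list(dia_medians.values()), float)
    grand = float(np.median(med))
    return bool(np.any(np.abs(med / grand - 1.0) > threshold))


# ---------------------------------------------------------------------------
# Dilution-series reporting
# ---------------------------------------------------------------------------


@dataclass
class DilutionReport:
    """Accuracy/linearity summary of a dilution series."""

    levels: list[float]  # nominal fmol, descending
    recovered: dict[float, dict[str, float]]  # level -> peptide -> recovered fmol
    slope: float
    r_squared: float
    lloq: float | None  # fmol, None when not reached
    dynamic_range_log10: float

    @property
    def lloq_label(self) -> str:
        return "not reached" if self.lloq is None else f"{self.lloq:g} fmol"


def dilution_report(
    recovered_by_level: Mapping[float, Mapping[str, float]],
    tolerance: float = 0.3,
) -> DilutionReport:
    """Summarize recovery across a dilution series.

    ``recovered_by_level`` maps each nominal on-column amount (fmol) to the
    recovered amount per peptide.  The LLOQ is the smallest level at which it
    and every higher level recover within ``tolerance`` relative error for
    all peptides; the log-log regression uses every finite recovery.
    """
    levels = sorted(recovered_by_level, reverse=True)
    if len(levels) < 3:
        raise ValueError("need at least 3 dilution levels")
    xs, ys = [], []
    quantified_levels = []
    for lvl in levels:
        vals = [v for v in recovered_by_level[lvl].values() if np.isfinite(v) and v > 0]
        if vals:
            quantified_levels.append(lvl)
        xs.extend([lvl] * len(vals))
        ys.extend(vals)
    slope, intercept, r, *_ = stats.linregress(np.log10(xs), np.log10(ys))
    lloq = None
    for lvl in levels:  # descending; stop at the first failing level
        vals = list(recovered_by_level[lvl].values())
        ok = vals and all(
            np.isfinite(v) and abs(v / lvl - 1.0) <= tolerance for v in vals
        )
        if not ok:
            break
        lloq = lvl
    dr = (math.log10(max(quantified_levels) / min(quantified_levels))
          if len(quantified_levels) >= 2 else 0.0)
    return DilutionReport(
        levels=levels,
        recovered={lvl: dict(recovered_by_level[lvl]) for lvl in levels},
        slope=float(slope),
        r_squared=float(r ** 2),
        lloq=lloq,
        dynamic_range_log10=dr,
    )


# ---------------------------------------------------------------------------
# Condition-level statistics
# ---------------------------------------------------------------------------


def condition_stats(
    normalized: pd.DataFrame,
    design: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-target Welch t-test on log2 ratios between two conditions.

    ``normalized`` is the output of :func:`normalize_ratios`; ``design`` maps
    sample -> condition.  P-values are Benjamini-Hochberg adjusted within the
    contrast; contrasts with fewer than 2 replicates per condition are
    skipped with a warning.  Returns a table with log2 fold change, p and q
    per target.
    """
    df = normalized.copy()
    df["condition"] = df["sample"].map(design)
    conditions = sorted(df["condition"].dropna().unique())
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conditions}")
    a_name, b_name = conditions
    rows = []
    for target, sub in df.groupby("target_id"):
        a = np.log2(sub.loc[sub["condition"] == a_name, "ratio"].to_numpy())
        b = np.log2(sub.loc[sub["condition"] == b_name, "ratio"].to_numpy())
        if len(a) < 2 or len(b) < 2:
            logger.warning("target %s: <2 replicates in a condition; skipped", target)
            continue
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(b, a, equal_var=False)
        rows.append({"target_id": target,
                     "log2_fc": float(np.mean(b) - np.mean(a)),
                     "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows, columns=["target_id", "log2_fc", "t", "p"])
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = out["q"] < alpha
    else:
        out["q"] = []
        out["significant"] = []
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]
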