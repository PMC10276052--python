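# Methods

This note documents the models behind `hybridia`: what the simulator
emulates, how the acquisition engine schedules scans, how quantification and
quality control are defined, and where design choices were genuinely open.

## Ground-truth signal model

A run is a set of *species* — precursors with fixed fragment lists — each
with an on-column amount (fmol), a Gaussian elution profile (apex retention
time in minutes, peak sigma in seconds) and a relative fragmentation pattern
summing to 1. The instantaneous precursor ion flux is

    flux(t) = amount · flux_per_fmol · exp(−(t − apex)² / 2σ²)   [charges/s]

with `flux_per_fmol = 1e5` charges/s/fmol at apex by default. That scale
puts the 0.0325 fmol isotopologue of the dilution series at ~380 ions in a
116 ms fill — detectable but close to the counting floor, which is the
regime the method is designed for.

Sampling a scan converts flux to detector counts over the injection time:
expected counts = flux · IT, observed counts are Poisson draws, m/z values
receive 2 ppm Gaussian jitter, and a chemical-noise background contributes a
total expected count of `chemical_noise_rate · isolation width · IT`
(default 50 charges/s/Th), spread over random peaks across the read-out
range. Making background proportional to isolation width is the mechanism
that lets a 1 Th targeted isolation out-perform a 61 Da DIA window on
signal-to-noise; the linearity is verified by sampler tests.

Randomness is reproducible by construction: each scan derives its own RNG
stream from the root seed plus integer keys (scan class, clock time in µs,
window center), so identical seeds give bit-identical runs regardless of
generation order.

What the generator does **not** emulate: peak tailing (a Gaussian is the
simplest shape consistent with observed XICs; a tailing hook would go in
`ElutionProfile`), isotope envelopes (monoisotopic centroids only), ion
mobility, interferences that are mass-resolved at 10 ppm, and retention-time
drift between runs. Passing tests therefore demonstrate the correctness of
the scheduling and quantification logic under idealized chromatography, not
robustness to real-matrix effects.

## Canned scenarios

* **Dilution series** (`make_pierce_series`): 7 peptides × 5 co-eluting
  isotopologues at 50 / 5 / 0.5 / 0.125 / 0.0325 fmol (the 50 fmol species,
  0.1 µl of a 0.5 pmol/µl stock, is the trigger). The four lower
  isotopologues are represented as ENDO channels of four target entries that
  share the trigger IS but carry distinct label mass offsets (j·4.0070993 Da),
  which keeps inclusion-list keys unique. Peptide sequences and fragment m/z
  values are synthetic stand-ins — the commercial kit's sequences are not
  public — chosen as plausible tryptic 2+ precursors. Apexes are evenly
  spaced over a 31 min gradient (a 40 samples-per-day analytical gradient);
  peak sigma 4 s.
* **Spike-in panel** (`make_panel_run`): N IS/ENDO pairs, IS fixed at
  50 fmol, ENDO drawn log-uniformly (default 0.01–10 fmol) from the seed,
  apexes evenly spaced over a 60 min (20 SPD) gradient; a single target
  elutes at the midpoint.
* **Plateau** (`make_plateau_run`): one target whose IS stays above the
  trigger threshold continuously for a configurable span (realized as a wide
  Gaussian, since the elution model is Gaussian-only) — used to
  characterize dynamic exclusion.

## Acquisition engine

Scan timing follows the Orbitrap parallelization contract: ion accumulation
for the next scan proceeds during the current transient, so one scan costs
`max(transient, total fill) + overhead`, with the transient table
{7.5k: 16, 15k: 32, 30k: 64, 60k: 128, 120k: 256} ms and zero default
overhead. This table is a design choice, not a vendor datasheet value; it
reproduces the method's nominal 1 s DIA cycle (256 + 11·64 = 960 ms) and is
config-exposed. AGC semantics: fill = min(max IT, AGC target / flux); the
MS1 "300%" and DIA "1000%" normalized targets correspond to 3e5 and 1e6
charges (100% ≡ 1e5), the only convention consistent with the absolute
targeted-scan setting of 1e6.

Trigger chain per cycle: MS1 → detection (RT window, 10 ppm with inclusive
boundary, IT-normalized intensity ≥ 1e5 charges/s, dynamic exclusion 5 s) →
one multiplexed PRM survey of all detected IS precursors (7.5k, 10 ms per
precursor) → fragment confirmation (≥ 3 of ≤ 6 within 10 ppm) → one MSx scan
per confirmed pair in inclusion-list order → the DIA windows. The MS1
intensity threshold is compared on the injection-time-normalized scale
(counts ÷ fill time): raw counts would make triggering depend on how much
the MS1 fill was shortened by AGC in busy regions of the gradient, which
would defeat a fixed per-target threshold.

MSx fill allocation: the IS receives
`min(10% of the 116 ms budget, time to reach 10% of the 1e6 AGC target at
the flux estimated from the triggering MS1 peak)`, the ENDO receives the
rest; the split always sums to the budget. The 10% reservation is a policy
choice (`is_fill_fraction`, config-exposed): the real instrument's
per-precursor policy is not public, and corrected ratios are invariant to
the split (verified by a property test), so only sensitivity — not accuracy
— depends on it. MSx resolution is 30k, keeping the hybrid cycle near 1 s.
Dynamic exclusion is keyed to the MS1 detection that led to a *confirmed*
trigger; unconfirmed detections are not excluded, so a target is re-examined
on the next cycle.

The DIA window planner uses width = (range + overlap) / n, which yields the
standard 61.1 Da for 11 windows over 472–1143 m/z with 1 Th overlap; windows
tile contiguously from `start − overlap/2` with exactly the stated overlap
between neighbours. No convention simultaneously gives this width, exact
pairwise overlap, equal widths *and* coverage through `end`; the printed
width and exact overlap were kept, so the last window falls short of `end`
by (n−1)·overlap.

## Quantification

XICs take one point per MSx scan of the target (counts summed within 10 ppm
of the fragment m/z — summing rather than nearest-peak is robust to jitter),
with the per-precursor fill time attached. The injection-time correction is
counts ÷ fill (counts/ms). Peak detection: apex = maximum of a 3-point
moving average within the expected RT window; boundaries extend until the
smoothed trace drops below 5% of apex or turns back up (a valley).
Integration is trapezoidal over time in seconds; against an analytic
Gaussian it is accurate to 1% at a sampling interval of σ/3. S/N = apex
corrected intensity over 1.4826·MAD of the out-of-peak points, floored at
ε = 1 count/ms. A fragment is quantifiable when a peak is found in both
channels; the pair ratio is the ratio of summed corrected areas over
quantifiable fragments, and a pair needs ≥ 3 of them to count as quantified.
Because both channels are sampled in the *same* scans, the ratio is robust
to the sparse (exclusion-limited) sampling of the peak.

## Quality control

* **DOTPR** is cosine similarity between the ENDO and IS transition-area
  vectors over shared fragments (the metric is described in the field but
  not given a formula; cosine is the natural normalized dot product).
* **PPFR** is the fraction of monitored ENDO transitions "found": a peak is
  detected, its apex co-elutes with the IS consensus apex (median of the IS
  fragment apexes), and its apex ion count is significant. Two
  operationalizations here deserve comment, since the reference
  implementation's rule is proprietary:
  * *Co-elution tolerance* is one cycle time or 1.5 XIC sampling intervals,
    whichever is larger. Dynamic exclusion spaces MSx points several cycles
    apart; at that pitch the argmax of two near-equal points straddling the
    true apex flips by a full interval under shot noise, and an even-count
    median consensus falls mid-interval. 1.5 intervals is the smallest
    allowance that treats those cases as co-eluting while still failing a
    peak a full two intervals away.
  * *Significance* is tested on the raw ion-count scale: apex counts ≥
    max(10, 3·1.4826·MAD of out-of-peak raw counts). Ten ions is a ≥ 3σ
    excess over a near-zero Poisson baseline; a rate-scale floor (counts/ms)
    would impose an absolute abundance cutoff that rejects clean,
    statistically unambiguous peaks at the sub-fmol levels the method is
    designed to reach.
* Filters: PPFR strictly > 0.5, DOTPR ≥ 0.5, quantified fragments ≥ 3.

Normalization is ENDO/IS per pair; when per-sample DIA median intensities
are provided and any sample deviates > 20% from the grand median (the
"significant loading bias" rule, made explicit here), each sample's ratios
are divided by sample median / grand median, which exactly cancels a global
loading factor applied to ENDO and DIA but not the spiked IS. Condition
statistics use a Welch two-sample t-test on log2 ratios with
Benjamini–Hochberg adjustment — a standard unmoderated substitute for the
moderated test some downstream tools apply; moderation is out of scope.

The dilution report fits recovered vs nominal amounts in log–log space,
reports R², defines the lower limit of quantification as the smallest level
(contiguous from the top) at which every peptide recovers within 30%
relative error, and the dynamic range as the log10 span of quantified
levels. For the bundled series the *covered* range additionally counts the
50 fmol trigger species, which is measured in the same multiplexed scans as
the 0.0325 fmol level (log₁₀(50/0.0325) ≈ 3.19 orders).

## Problem sizes and numerical choices

The bundled benchmarks run at the scenario sizes above (7×5 species over
31 min; 20 targets over 60 min; ~0.96 s cycles, i.e. ~2–4·10⁴ scans per
run) and complete in seconds to a few minutes on one CPU. Tolerances used
in tests: 1e-9 for algebraic identities, 1% for integration and noiseless
ratio recovery, 20% for ratio recovery under the default noise model, 30%
for the LLOQ rule. Ties in fragment ranking break toward lower m/z; ppm
tolerances are inclusive at the boundary (with a 1e-9 relative slack so m/z
values sitting exactly on the boundary are not rejected by float rounding);
degenerate inputs (empty traces, all-zero traces, zero-norm vectors) return
explicit "not found"/0 results rather than raising.

## Known limitations

* The fill-time policy and the MSx resolution of real triggered-acquisition
  firmware are not public; both are config parameters here, and absolute
  sensitivities should not be read as instrument predictions.
* The S/N definition (MAD-based with a 1 count/ms floor) is one of many in
  use; comparisons with vendor software S/N values are qualitative.
* Single-run scope: no cross-run alignment, no protein roll-up, no missing
  value imputation, no DIA-based identification (the DIA stream is produced
  and split faithfully but only its medians feed the pipeline).
* Chemical noise is uniform in m/z; structured interferences (co-isolated
  peptides with matching fragments) are not modelled, so PPFR/DOTPR pass
  rates on clean simulations are upper bounds for real data.
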