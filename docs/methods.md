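# Methods

## The measurement model

Isotopic Ratio Outlier Analysis (IROA) grows two cultures of the same
organism on randomized-enrichment glucose: one at 95% ¹²C (so each carbon
position is ¹³C with probability q₁₂ = 0.05) and one at 95% ¹³C
(q₁₃ = 0.95). Extracts are mixed, derivatized for GC (methoximation, then
trimethylsilylation), and analyzed by GC/MS in chemical-ionization (CI)
and electron-ionization (EI) modes.

Because every biosynthesized carbon is an independent Bernoulli draw, the
isotopologue intensities of an n-carbon backbone follow Binomial(n, q)
within each channel. The mixed sample therefore shows two mirror-image
envelopes whose anchors — the all-¹²C peak M₀ and the all-¹³C peak Mₙ —
are separated by exactly n·Δ, with Δ = m(¹³C) − m(¹²C) = 1.0033548 Da.
The pair spacing reads out the backbone carbon count n; chemical
background and derivatization artifacts, which contain no biosynthesized
carbon, have no partner.

Two closed forms carry most of the workflow:

* **M₀₊₁/M₀ ratio.** The first binomial term gives
  n·q/(1−q); at q = 0.05 and n = 5 this is 0.263. Each trimethylsilyl
  (TMS) group adds a first-order natural-abundance M+1 carryover of
  8.54% of the anchor (9 H, 1 Si, 3 C of natural abundance), each
  methoxime 1.1% (one carbon). A 5-carbon, doubly silylated metabolite
  therefore shows 0.263 + 2×0.0854 ≈ 0.43.
* **Mₙ₊₁/Mₙ ratio.** On the ¹³C side the backbone is (nearly) saturated
  with ¹³C, so the M+1 satellite above Mₙ carries *only* the
  derivatization natural abundance — dividing the observed ratio by
  0.0854 and rounding yields the TMS count k directly.

The 8.54% per-TMS constant is the established workflow value; summing the
single-substitution probabilities of the group's atoms gives ≈8.1%, and
that abundance-derived alternative is exposed as
`tms_carryover_from_abundances()` for users who prefer it. The default
stays at 0.0854.

The carryover model is deliberately first-order (M+1 only). A full
natural-abundance convolution over all derivatization atoms would change
the M+2 region, which this workflow never inspects.

## Pair detection

`find_pairs` scans all ordered peak pairs of a mixed centroid spectrum.
A candidate (m₀, mₙ) is accepted when:

1. its spacing is within `mz_tol_ppm` (default 5 ppm, Orbitrap; 30 ppm in
   TOF mode) of an integer multiple n·Δ with n in `[n_min, n_max]`
   (default [2, 30]);
2. neither anchor is in the exclusion list or below the intensity floor;
3. the anchors look like envelope *ends*: a peak one Δ below m₀ reaching
   ≥25% of it, or one Δ above mₙ reaching ≥70% of it, marks the candidate
   as an interior satellite and disqualifies it (the 70% allowance leaves
   room for a legitimate 6-TMS carryover satellite of ~51%);
4. the anchor intensity ratio I(Mₙ)/I(M₀) lies within
   `anchor_ratio_bounds` (default 0.2–5). The anchors directly measure
   the ¹²C:¹³C channel mixing, which the experimenter sets near 1:1; an
   envelope satellite masquerading as an anchor produces an extreme
   ratio. Strongly unequal mixes require widening this window;
5. the observed satellite ratios, when the satellite peaks exist, are
   within `ratio_tol_factor` (default 2-fold) of the model expectation.
   The TMS count is unknown at this stage, so the hypothesis k ∈ [0, 6]
   that jointly best explains both ratios is used. For small n the two
   channels' satellites overlap (at n = 2, M₀₊₁ *is* Mₙ₋₁), so each
   expectation includes the other channel's binomial contribution scaled
   by the observed anchor ratio. Ratio checks are skipped — not failed —
   when the diagnostic peak is absent or an anchor is saturated
   (saturation clips M₀ and inflates the apparent ratio; such pairs are
   reported with a `saturated` flag instead of being vetted away).

Surviving candidates are assigned greedily by descending quality score so
each peak anchors at most one pair; score ties break by smaller spacing
residual, then larger n (a longer backbone explains more of the
envelope). The score is 0.5^Σ(dev/tol)², equal to 1 for an exact pair and
0.5 when a single diagnostic sits at its tolerance edge.

EI fragment search (`find_ei_pairs`) reuses the same machinery with
n ∈ [1, 20], a relaxed 15 ppm spacing tolerance (weak EI centroids sit a
few ppm off), no rejection on the ¹²C-side M+1 ratio (a fragment may
retain any number of TMS groups), and the ubiquitous unpaired silylation
ions (73.0468, 147.0654, configurable) barred from anchoring.

A cross-spectrum mode (`find_pairs_cross`) pairs separate ¹²C and ¹³C
runs matched by retention time within `rt_tol_min` (default 0.03 min);
the single-mixed-spectrum mode is primary because real mixed-extract
spectra show both envelope sides together.

## Chemical formula generation

`generate_formulas` enumerates every composition over {C, H, N, O, Si, S}
within per-element count ranges whose monoisotopic ion mass lies within a
ppm window of the measured m/z, sorted by |ppm| with ties broken by Hill
formula string. The recursion runs heaviest element first with
partial-mass pruning and resolves hydrogen in closed form; its output is
tested for exact equality (set *and* order) against full Cartesian
enumeration.

Conventions that matter for matching vendor elemental-composition
reports:

* masses are plain sums of monoisotopic atomic masses, with **no
  electron-mass correction**; the measured m/z is treated as the intact
  even-electron ion ([MH]⁺ for CI), so neutral-molecule hypotheses must
  add the proton's hydrogen before calling;
* the *reported* ppm deviation is computed against the theoretical mass
  rounded to 4 decimals (`FormulaCandidate.reported_ppm`), which is how
  such reports print it; the full-precision value is kept internally and
  used for ranking;
* no ring-double-bond-equivalent or parity filter is applied by default —
  the pure mass-window enumeration reproduces the worked example's
  candidate counts (8 at 30 ppm and 2 at 5 ppm for m/z 364.1793; 7 at
  30 ppm for 364.1863). An optional `rdbe_min` filter (Si counted as
  tetravalent carbon) exists for users who want chemical-plausibility
  pruning.

IROA evidence tightens the ranges (`iroa_constrained_ranges`): with
backbone count n and TMS hypothesis k ∈ [k_min, k_max], carbon spans
n + 3·k_min + m_mox … n + 3·k_max + m_mox and silicon spans k_min…k_max,
since each TMS contributes exactly three natural-abundance carbons and
one silicon, and each methoxime one carbon.

## Candidate scoring

Observed EI spectra are compared to externally predicted candidate
spectra (supplied as MSP or CSV; no fragment prediction is performed
here) with two similarity measures over greedily matched peaks within an
absolute m/z tolerance (default 0.005 Da, suitable for high-resolution
EI; set ~0.5 for nominal-mass predictions):

* **dot product** — cosine similarity with square-root intensity
  weighting by default (standard GC-EI practice; `weighting="none"`
  disables it). Unmatched peaks count toward the norms, so disjoint
  spectra score 0 and only near-identical spectra approach 1;
* **Jaccard** — |matched| / |union| of peaks.

Both are symmetric and scale-invariant; the cosine is cross-checked in
the test suite against an independent implementation (matchms
`CosineGreedy`).

`rank_candidates` orders isomeric candidates by (1) consistency of the
candidate's intact-ion formula with the IROA/CFG-derived formulas —
failures are demoted below all passing candidates; (2) fragment
carbon-count consistency: the fraction of observed EI pairs for which the
candidate predicts a co-located fragment whose *labeled* carbon count
(total C minus 3 per Si, the TMS carbons being natural-abundance) equals
the pair's n; (3) the dot-product score. When a prediction source
supplies no per-fragment formulas, carbon consistency is reported as
not-available and plain m/z co-location takes its place in the ordering,
so formula-less sources are neither penalized nor over-trusted.

## The simulator and what it does (not) emulate

`synthetic_data` generates mixed-sample spectra with a ground-truth
manifest. Per metabolite it plants both binomial envelopes (intensity
floor 10⁻⁴ of the base peak — below the plausible dynamic range), adds
the first-order derivatization M+1 on both anchors, then applies, in
order: per-peak multiplicative log-normal intensity noise (σ default
0.05 — enough to exercise the 2-fold ratio tolerances without swamping
them), Gaussian ppm jitter on m/z (1 ppm Orbitrap mode, 15 ppm TOF mode),
and optional saturation clipping with a `saturated` flag (TOF mode
defaults to the 1.8×10⁴ clip level at which such detectors visibly
distort the M₀₊₁/M₀ ratio). Artifact peaks are placed uniformly over the
m/z range with log-normal intensities; by default their positions are
re-drawn until they sit at least 3× the widest matching tolerance away
from any IROA-consistent spacing with existing peaks, so false-positive
statistics measure the detector, not the generator. An `adversarial`
mode disables that guard. The two channels mix 1:1 by default
(`mix_13c` scales the ¹³C side).

Simulated EI spectra plant a mirrored binomial pair per fragment (no
carryover — a fragment's TMS complement is not modeled) plus the unpaired
73/147 background ions.

The bundled fixture library contains four TMS-derivatized species with
formula-derived [MH]⁺ masses: glutamate-3TMS (n=5, ion C₁₄H₃₄NO₄Si₃,
364.1796), 5-oxoproline-2TMS (n=5, C₁₁H₂₄NO₃Si₂, 274.1289),
2,3-dihydroxyisovalerate-3TMS (n=5, C₁₄H₃₅O₄Si₃, 351.1843; EI fragments
131.0887/3C and 292.1350/2C) and isoleucine-2TMS (n=6; EI fragments
158/5C, 218/2C, 260/6C). EI fragment masses are monoisotopic masses of
plausible fragment ions; they are synthetic constructions for testing,
not library spectra.

What the simulator does **not** emulate: chromatographic peak shape and
scan-to-scan correlation, envelope overlap between co-eluting species
sharing peaks, real EI fragmentation chemistry, electron-mass effects,
and isotope fine structure. Passing recovery tests therefore demonstrate
the correctness of the pair logic and inference arithmetic under the
stated noise model, not performance on raw instrument data.

## Numerical choices and degenerate inputs

* Envelope equality is exact on offsets and tolerant (1e-9 relative) on
  intensities (`IsotopologueEnvelope.isclose`), since mirroring and
  complementary-q evaluation differ by floating-point rounding.
* `carbon_count` rounds the spacing to the nearest integer multiple of Δ
  and reports the residual in ppm of the heavy anchor; out-of-range n is
  a no-pair result, not an exception.
* Duplicate peaks (within 1e-6 Da) are rejected by the spectrum
  container; the simulator merges unresolvable peaks (< 2e-6 Da) before
  emission.
* Zero-intensity peaks are never emitted and never anchor.
* Empty spectra yield empty pair lists; an empty CFG result is a valid
  empty list; similarity scores require non-empty spectra.
* All randomness flows through a single seeded `numpy` generator per
  simulated spectrum; identical seeds give byte-identical output.

## Problem sizes used in the test suite

Statistical guarantees are exercised at desk scale: pair recovery over
100 single-metabolite spectra (≥95% exact-n recovery at 1 ppm jitter) and
100 artifact-only spectra (0 false pairs); formula-enumeration
equivalence against brute force on 100 random instances; Monte-Carlo
ratio convergence over 3000 replicates (3-standard-error band); MSP
round-trip over 100 simulated spectra. Instrument-level survey results
from real yeast extracts (hundreds of pairs per run) require raw
GC-Orbitrap data and are out of scope.

## Known limitations

* Overlapping envelopes that share peaks are not deconvolved; the
  greedy one-pair-per-peak assignment picks the best-scoring
  interpretation.
* The anchor-ratio window (0.2–5) trades false positives against support
  for strongly unequal channel mixing; widen it deliberately if mixing
  beyond 1:5.
* TMS-count inversion saturates at 6 groups and assumes the methoxime
  count is known (default 0).
* The mzML reader covers centroid MS1 scans with uncompressed or
  zlib-compressed float arrays only — by design, as the workflow's
  interchange formats are MSP and CSV.
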