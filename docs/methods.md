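# Methods

This note documents the models, algorithms, numerical choices and known
limitations of nmrkit, in the order data flows through the package.

## Signal model and simulator

The simulator (`nmrkit.simulate`) works in the first-order (weak-coupling)
limit. Each declared signal carries a chemical shift δ (ppm), a proton count,
and a list of couplings `(J, n_partners)`; its stick pattern is the iterated
convolution of the couplings (a coupling to *n* equivalent protons spreads
each stick over *n* + 1 positions spaced *J* Hz with binomial weights
C(n,k)/2ⁿ). Per signal the stick intensities sum to the proton count, so
integrals are exact by construction. The FID is the sum of complex
exponentials damped by a single T₂ (pure Lorentzian lineshape; Gaussian
lineshapes are out of scope), plus circular complex Gaussian noise with a
mandatory seed — every simulation is bit-reproducible.

Defaults emulate a routine 400 MHz proton acquisition: 4 kHz spectral width,
16k complex points, T₂ = 1 s (0.32 Hz natural linewidth), CDCl₃. Test and
acceptance conditions that need fully decayed FIDs (to keep truncation
ripple below the noise floor — with T₂ = 1 s a 4 s acquisition leaves ~1.7 %
sinc ripple around tall lines) acquire 64k points instead; the methods
below state the sizes used where they matter.

What the simulator does **not** emulate: strong coupling (except through the
closed-form AB oracle below), chemical-exchange or field-inhomogeneity
lineshape distortions, ¹³C satellites, solvent signals, baseline roll from
analog filters, and radiation damping. Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not robustness against
every artifact of real spectra.

`simulate_ab(Δν, J)` is the exact two-spin AB solution: with
C = √(Δν² + J²), lines sit at ±(C+J)/2 and ±(C−J)/2 about the centre with
intensities 1 ∓ J/C. It is validated against numerical diagonalization of
the two-spin Hamiltonian (in the test suite and the acceptance script) to
1e-10, and serves to generate second-order patterns the first-order engine
cannot produce — e.g. to exercise the "m" fallback of the classifier.

## Processing chain

Every operation is a named `FilterRecord`; `apply_chain` re-executes an
ordered chain from the raw FID deterministically. Time-domain filters must
precede the single Fourier transform, frequency-domain filters follow it;
disabled records are skipped. Because the spectrum is a pure function of
(raw FID, chain), editing a filter argument and re-running equals building
the edited chain directly, bit for bit — the reversibility contract.

Numerical conventions:

- **First-point halving.** The first FID sample is multiplied by 0.5 before
  the FT. This suppresses the constant offset a one-sided DFT otherwise
  assigns to the spectrum. Parseval's identity consequently holds against
  the *windowed* FID: Σ|s'|² = Σ|S|²/N with s'[0] = s[0]/2.
- **Zero-fill default**: twice the next power of two at or above the FID
  length — interpolation without excess.
- **Group delay** (Bruker digital filter) is recorded on import and
  compensated during the FT by a linear phase ramp of 360°·GRPDLY across the
  spectral width; the time-domain data are never modified.
- **Axis**: ppm descending left to right; angles are degrees everywhere;
  phase correction applies exp(i(φ₀ + φ₁·(x − pivot)/sw)) with the pivot
  defaulting to the tallest peak.
- **Exponential apodization** multiplies by exp(−π·lb·t), adding exactly
  `lb` Hz to a Lorentzian FWHM; the Gaussian window is
  exp(−(π·gb·t)²/(4 ln 2)) with FWHM `gb`.

### Automatic phase correction

`auto_phase` estimates (φ₀, φ₁) in three stages:

1. **Peak-phase measurement.** Strong peaks of the magnitude spectrum (at
   most the 12 strongest; height ≥ 10 % of the maximum with prominence above
   the noise) are located, and each peak's local phase is read from the
   complex data summed over a symmetric window (±3 magnitude-FWHM) weighted
   by the magnitude profile. The dispersive component is antisymmetric about
   the line centre and cancels in the sum; the magnitude weighting is the
   matched filter for the line shape, which empirically reduces the per-peak
   phase noise about three-fold versus an unweighted sum.
2. **Robust ramp fit.** A straight line through the peak phases versus
   normalized frequency, weighted by peak height, with two outlier-rejection
   passes (shoulder artifacts next to tall lines carry arbitrary phases).
   The fit is iterated three times on the re-phased data.
3. **Core-negativity polish.** Nelder–Mead refinement of the negative-area
   fraction of the real part restricted to the line cores (> 20 % of the
   tallest magnitude). At the correct phase the cores are purely absorptive
   and this objective sits on its zero plateau; including the wings or the
   noise floor would let the noise bias the optimum by several degrees,
   which is why a global negative-area or spectral-entropy objective was
   rejected: in controlled recovery experiments at SNR 100 such objectives
   mis-estimated φ₁ by up to ~20°, while the estimator above recovers
   dephasings of |φ₀| ≤ 45°, |φ₁| ≤ 90° to better than 3°.

The 180° ambiguity (all lines inverted) is resolved by requiring positive
total area. A spectrum whose tallest magnitude is below 8× the quadrature
noise raises "no signal to phase".

### Baseline correction

`polynomial` (default): iterative Chebyshev fit (degree 3, 10 iterations),
re-fitting on points below the current baseline plus two residual standard
deviations so signals are progressively excluded. `airpls` is provided as an
alternative (adaptive iteratively reweighted penalized least squares,
second-difference penalty, default λ = 1e6). The estimate is stored on the
spectrum for inspection.

## Signal analysis

**Noise** is estimated as 1.4826 × MAD of the pooled quietest decile of
32-point windows of the real part, divided by 0.74 — the selection bias of
taking the quietest decile, calibrated on pure Gaussian noise and stable
(±2 %) across spectrum sizes from 2k to 128k points.

**Peak picking** takes local maxima above `min_snr` × noise with the same
prominence requirement (otherwise noise wiggles riding on the tails of tall
lines all qualify), refines positions by three-point parabolic
interpolation, and measures FWHM from linearly interpolated half-height
crossings.

**Ranges** are contiguous supra-threshold regions: segments above the
picking threshold are merged when separated by less than `gap_hz`
(default 20 Hz — intra-multiplet gaps up to typical J values stay in one
range), then edges grow outward until the signal stays below 1× noise for 5
consecutive points (capped at the merge distance). A fixed point-count gap
alone is not resolution-independent: at fine digital resolution it splits
every multiplet, and in pure noise a 5-point sub-noise run occurs every few
tens of points so unbounded growth would never terminate.

**Multiplet classification** works on the picked peaks of a range:

1. *First-order matching* repeatedly extracts the smallest splitting (the
   spacing between the two lowest-frequency lines) as a doublet convolution
   factor. Overlapping sticks (the 1:2:1 centre of a triplet, etc.) are
   handled by intensity bookkeeping: a partner with matching intensity is
   consumed, a taller one is reduced. Extracted couplings are grouped
   (within `j_tol` = max(0.2 Hz, one digital-resolution bin)) and the group
   sizes map to letters (1 → d, 2 → t, … 6 → sept; larger → fail), largest
   J first, so a t is preferred over a dd with J₁ ≈ J₂ automatically.
   Intensity ratios must hold within 25 % relative.
2. *Deconvolution* (on failure, or on demand): a bounded least-squares fit
   of a sum of Lorentzians (≤ 12, initialized from the picked peaks with the
   median width) over the range. The fitted components are then partitioned:
   all set partitions (≤ 8 components) are searched for the assignment in
   which every group is itself a first-order pattern, preferring the fewest
   signals, then the fewest couplings. This is how two overlapping doublets
   of different intensity interleaved in one range resolve into two `d`
   signals with their own shifts and Js.
3. *Fallback*: multiplicity "m" centred on the intensity-weighted centroid.

An intrinsic ambiguity is worth stating: four equally intense lines at
±(J₁+J₂)/2, ±(J₁−J₂)/2 are *exactly* the pattern of one dd and also of two
equal doublets — no algorithm can distinguish them from one spectrum. The
classifier reports the single-signal reading (dd) in that case; the
two-doublet resolution engages when the intensities disagree.

**Integration** is trapezoidal with linear interpolation at fractional
endpoints (hence exactly additive over adjacent intervals). For precision
work at low SNR the Lorentzian fit areas (π·height·FWHM/2) are the better
estimator: a windowed integral's noise is set by the early FID samples and
cannot be reduced by apodization (which only correlates the spectral
noise), whereas the fitted areas are maximum-likelihood under the known
lineshape and tail-complete. Empirically, at per-line SNR 50 a windowed
integral of a 0.3 Hz line carries 2–4 % noise while the fitted area ratio
of the same data is reproducible to well under 1 %.

### Verification grid

The classifier is verified over {s, d, t, q, dd} × J ∈ {2, 4, 7, 10, 12,
16} Hz (dd pairs each J with J/2), each as a 2H multiplet at 3.7 ppm next
to a 1H reference singlet at 4.3 ppm: 400 MHz, 1 kHz spectral width, 64k
points (65 s acquisition, fully decayed), T₂ = 1 s, no apodization or
zero-filling, noise set so the *weakest* line of the pattern sits 50× above
the spectral noise, line separations ≥ 3× FWHM throughout. Under these
conditions classification is 100 % correct, J values from the fit path are
within a few mHz (tolerance: two digital-resolution bins = 0.031 Hz), and
fitted-area integrals match the 2:1 proton ratio to better than 2 %.

## JCAMP-DX

The reader handles label normalization (case, spaces, dashes), CRLF and a
UTF-8 BOM, compound LINK files, `$$` comments, AFFN and ASDF (SQZ/DIF/DUP)
tabular data, and NTUPLES blocks whose R/I pages assemble a complex FID.
DIF checkpoints — the first ordinate of a line repeating the last of the
previous line — are verified and raise with the line number on mismatch, as
do malformed numeric values. PEAK TABLE data are rejected explicitly. One
parsing subtlety: an unsigned exponent is not recognized inside data lines
("…E4" after a number is the SQZ digit 5 followed by 4; instrument writers
that use exponent notation write an explicit sign, and so does this
package's writer, which emits fixed-point x values and a space before the
first ordinate).

The writer emits a JCAMP-DX 5.01 header and only the `(X++(Y..Y))` tabular
form, AFFN or DIF/DUP with SQZ line starts and checkpoint verification
lines. The y factor maps the largest ordinate near 2¹⁵, so the
quantization error is bounded by y_factor/2 per point (relative ~3e-5).
Unknown and vendor-private labels pass through `ldrs` untouched.

## Bruker import

Only the raw time-domain layout is read: `acqus` (JCAMP-like ##$KEY= lines)
and `fid` (interleaved real/imaginary, int32 or float64 per DTYPA, little-
or big-endian per BYTORDA, TD values = 2 × complex points). TD inconsistent
with the file's byte length is an error stating both numbers. The synthetic
fixture writer mirrors the layout exactly and, for int32, stores a private
scale factor chosen so the peak amplitude maps near 2³⁰ (decoded amplitudes
within 1e-9 relative). Processed-data import (1r/1i) and other vendors are
out of scope.

## Molecules, canonical keys, topicity

V2000 molfiles are parsed by fixed columns with a whitespace fallback;
implicit hydrogens follow standard valences (C4, N3, O2, halogens 1, S
{2,4,6}, P {3,5}; N/P/O/S valence shifted by formal charge, C/B reduced by
|charge|). V3000 is rejected.

The canonical key is computed on a colored graph: node colors (element,
charge, isotope, total H count), edge labels the bond orders after ring
normalization — even-length cycles with strictly alternating single/double
bonds are relabelled 1.5, which makes the two Kekulé forms of an aromatic
ring indistinguishable without full aromaticity perception.
Weisfeiler–Lehman-style refinement is followed by individualization
backtracking; the lexicographically minimal certificate is the key, and the
set of leaves achieving it enumerates the automorphism group exactly (the
minimal leaves form a coset of the automorphism group). Tetrahedral parity
is appended as a renumbering-invariant descriptor: each flagged atom's
molfile parity is re-expressed against the canonical neighbor order via the
sign of the neighbor permutation, minimized over the automorphisms.

Hydrogen equivalence materializes implicit hydrogens as explicit leaf nodes
and takes orbits under the *configuration-respecting* automorphisms: a
permutation is admitted if it preserves every parity-flagged centre's
configuration, or inverts all of them (a mirror image — enantiotopic
protons are NMR-equivalent). A CH₂ carbon with no parity flag of its own is
treated as a prochiral test centre when an automorphism maps it to itself:
exchanging its two hydrogens is an odd local permutation, so in a molecule
with a genuine stereocentre the exchange is only available through
configuration-breaking maps and the two hydrogens fall into separate
classes, labelled diastereotopic. Limitations, stated deliberately: only
molfile tetrahedral parity is honored (no CIP ranking, no E/Z topicity),
prochiral centres mapped onto *different* atoms are not constrained (the
virtual-parity convention is not comparable across centres), and molecules
beyond 64 heavy atoms fall back to a refinement-only partition flagged
approximate. Answer checking compares canonical keys, constitution first,
then stereo if requested; an enantiomeric candidate returns `wrong_stereo`.

## Projects and exercises

A project file is one canonical JSON document (sorted keys, fixed
separators): numeric arrays are base64-encoded little-endian IEEE 754 with
declared dtype, so save → load → save is byte-identical and reloaded chains
re-execute to the stored spectra exactly. Unknown top-level keys are
preserved on re-save. Files without a version field, or with a newer major
version, are rejected explicitly. `import_any` dispatches by content (JSON
object / ##TITLE / V2000 counts line / Bruker directory), never by
extension alone.

Exercise sets mirror a folder hierarchy: a folder holding ≥ 1 JCAMP-DX
spectrum and exactly one molfile is a leaf; walking is lexicographic and
idempotent (re-runs are byte-identical). Student bundles contain the
spectra and the molecular formula but no byte of the solution molfile;
instructor bundles include the structure. Grading delegates to the
canonical-key comparison and never reveals the solution in the verdict.

## Acceptance script sizes

`scripts/acceptance.py` uses the same study conditions as the test suite:
32k-point singlet spectra for lineshape checks, 20 phase-recovery trials at
SNR 100, the 25-cell multiplet grid at 64k points, a 20×20 (Δν, J) AB grid,
1k/256-point format round trips, 100 renumberings × 4 molecules, and one
full exercise loop — about 5 s total on one core. All randomness derives
from `--seed`.
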