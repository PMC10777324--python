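# nmrkit

A headless Python toolkit for 1D NMR spectra, built for teaching and for
scripted analysis. It covers the full workflow a spectroscopist walks through
by hand:

- **Import**: JCAMP-DX files (AFFN and SQZ/DIF/DUP-compressed tabular data,
  NTUPLES blocks holding complex FIDs, compound LINK files) and Bruker raw
  directories (`acqus` + binary `fid`, int32/float64, both byte orders,
  group-delay metadata).
- **Processing** as a reversible *filter chain*: exponential/Gaussian
  apodization, zero-filling, Fourier transform, zero/first-order phase
  correction (manual or automatic), polynomial/airPLS baseline correction and
  ppm referencing. Every step is recorded as a named, parameterized
  `FilterRecord`; editing any argument and re-executing the chain from the raw
  FID reproduces the spectrum bit for bit.
- **Analysis**: robust noise estimation, peak picking with sub-bin
  interpolation, trapezoidal integration, and *ranges* — combined signal
  selection, integration and automatic multiplet analysis that classifies
  first-order patterns (s, d, t, q, quint, sext, sept and combinations such
  as dd), extracts J couplings, and resolves overlapping resonances by
  sum-of-Lorentzians deconvolution. Results render as a journal-style data
  string.
- **Structures**: MDL molfile (V2000) parsing, Hill-formula computation, a
  canonical structure key invariant under atom renumbering (with tetrahedral
  parity), and hydrogen-equivalence classes that recognize topicity —
  including diastereotopic CH₂ protons next to a stereocentre.
- **Workspaces**: a documented JSON project format that stores spectra, filter
  chains, analysis results, molecules and assignments losslessly
  (base64-encoded IEEE 754 arrays; save → load → save is byte-identical).
- **Teaching exercises**: turn a folder tree of JCAMP-DX spectra plus one
  solution molfile per leaf into a machine-readable exercise set with a table
  of contents, export student bundles with the solution redacted, and grade
  submitted structures (`correct` / `wrong_constitution` / `wrong_stereo`).
- **Simulation**: a first-order spin-system simulator (binomial stick
  patterns, Lorentzian lines, seeded complex Gaussian noise) provides ground
  truth for every stage, plus the exact closed-form AB two-spin system as an
  independent strong-coupling oracle.

## The model in brief

A signal with chemical shift δ (ppm) coupled to *n* equivalent protons with
scalar coupling *J* (Hz) splits into *n* + 1 lines with binomial intensities;
several couplings convolve. The FID is

```
s(t) = Σ_k w_k · exp(i 2π ν_k t) · exp(−t / T₂) + noise,
```

so each line is a Lorentzian of width FWHM = 1/(π T₂); exponential apodization
with line broadening `lb` adds `lb` Hz. The exact AB pattern for two strongly
coupled spins has lines at ±(C ± J)/2 about the centre with intensities
1 ∓ J/C, where C = √(Δν² + J²). Multiplet analysis inverts the first-order
construction by repeatedly extracting the smallest splitting; what does not
fit a single pattern is deconvolved into Lorentzian components and
re-analysed as a superposition of signals.

## Worked example

Simulate an ethanol-like ethyl pattern (OCH₂ quartet at 3.6 ppm, CH₃ triplet
at 1.2 ppm, J = 7 Hz) at 400 MHz, process it, and analyse the ranges:

```python
import nmrkit as nk

system = nk.SpinSystem(signals=(
    nk.SimSignal(3.6, 2, (nk.Coupling(7.0, 3),)),   # OCH2 quartet
    nk.SimSignal(1.2, 3, (nk.Coupling(7.0, 2),)),   # CH3 triplet
), t2_s=1.0)
config = nk.SimulationConfig(sfo1_mhz=400.0, sw_hz=4000.0, td=65536,
                             noise_sigma=0.02, seed=11, carrier_ppm=2.4)
fid = nk.simulate_fid(system, config)
spectrum = nk.apply_chain(fid, nk.standard_chain(lb_hz=0.0))
ranges = nk.detect_ranges(spectrum, min_snr=8)
nk.normalize_integrals(ranges, reference=1, n_protons=3)
for r in ranges:
    s = r.signals[0]
    print(f"{r.from_ppm:.3f}-{r.to_ppm:.3f} ppm  {s.multiplicity:>2}  "
          f"J = {[round(j, 2) for j in s.j_hz]}  {r.relative_integral:.2f} H")
print(nk.to_publication_string(spectrum, ranges))
```

prints

```
3.633-3.565 ppm   q  J = [7.0]  2.00 H
1.232-1.169 ppm   t  J = [7.0]  3.00 H
¹H NMR (400 MHz, CDCl₃) δ 3.60 (q, J = 7.0 Hz, 2H), 1.20 (t, J = 7.0 Hz, 3H).
```

— the quartet/triplet classification, the 7.0 Hz coupling and the 2:3 proton
ratio are all recovered from the synthetic data, and the last line is the
publication string ready for a lab report.

The same workflow is available from the shell:

```sh
nmrkit simulate --system ethyl.yaml --seed 11 -o ethyl.jdx
nmrkit ranges ethyl.jdx --min-snr 8
nmrkit exercise build my_exercises/
nmrkit grade --candidate answer.mol --solution solution.mol
```

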