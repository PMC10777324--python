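"""Reversible filter-chain processing for 1D NMR.

The pipeline mirrors the standard teaching workflow: apodization and
zero-filling act on the time-domain FID, a Fourier transform produces the
frequency-domain spectrum, and phase correction, baseline correction and
referencing act on the spectrum.  Every operation is recorded as a
:class:`FilterRecord`; a spectrum's state is fully defined by its originating
FID plus its ordered filter chain, so editing any filter argument and
re-executing the chain from the raw data reproduces, deterministically, the
spectrum that a freshly built chain would give.

Conventions (all documented in docs/methods.md): angles are degrees, the ppm
axis is strictly descending (high field to the right), the first FID point is
halved before the FT, and the default zero-fill target is twice the next power
of two above the FID length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "RawFid",
    "Spectrum1D",
    "FilterRecord",
    "FILTER_REGISTRY",
    "apodize_exponential",
    "apodize_gaussian",
    "zero_fill",
    "default_zero_fill_target",
    "fourier_transform",
    "phase_correct",
    "auto_phase",
    "baseline_correct",
    "reference_shift",
    "apply_chain",
    "standard_chain",
    "delta_hz",
]


@dataclass
class RawFid:
    """Complex time-domain acquisition with its metadata.

    ``carrier_ppm`` is the chemical shift of the carrier (spectrum centre);
    ``group_delay_pts`` records the digital-filter group delay of Bruker data
    (compensated as a first-order phase ramp during the FT, never silently
    applied to the time-domain points).
    """

    data: np.ndarray
    dwell_s: float
    sfo1_mhz: float
    sw_hz: float
    nucleus: str = "1H"
    solvent: str = ""
    carrier_ppm: float = 5.0
    group_delay_pts: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.complex128)
        if len(self.data) < 2:
            raise ValueError("FID must contain at least 2 points")
        if self.sw_hz <= 0 or self.sfo1_mhz <= 0:
            raise ValueError("sw_hz and sfo1_mhz must be positive")
        if not math.isclose(self.dwell_s, 1.0 / self.sw_hz, rel_tol=1e-9):
            raise ValueError("dwell_s must equal 1/sw_hz")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.data)) * self.dwell_s


@dataclass
class Spectrum1D:
    """Frequency-domain trace on a descending ppm grid, with provenance."""

    data: np.ndarray
    ppm_axis: np.ndarray
    sfo1_mhz: float
    sw_hz: float
    nucleus: str = "1H"
    solvent: str = ""
    reference_offset_ppm: float = 0.0
    chain: list["FilterRecord"] = field(default_factory=list)
    baseline_estimate: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.complex128)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        if len(self.ppm_axis) != len(self.data):
            raise ValueError("axis/data length mismatch")
        if len(self.ppm_axis) > 1 and not np.all(np.diff(self.ppm_axis) < 0):
            raise ValueError("ppm axis must be strictly descending")

    @property
    def real(self) -> np.ndarray:
        return self.data.real

    @property
    def digital_resolution_hz(self) -> float:
        return self.sw_hz / len(self.data)

    @property
    def digital_resolution_ppm(self) -> float:
        return self.digital_resolution_hz / self.sfo1_mhz

    def index_of_ppm(self, ppm: float) -> int:
        return int(np.argmin(np.abs(self.ppm_axis - ppm)))

    def ppm_to_frac_index(self, ppm: float) -> float:
        a = self.ppm_axis
        return float((a[0] - ppm) / (a[0] - a[-1]) * (len(a) - 1))


@dataclass
class FilterRecord:
    """One named, parameterized, re-executable processing step."""

    name: str
    params: dict = field(default_factory=dict)
    enabled: bool = True

    def __post_init__(self):
        if self.name not in FILTER_REGISTRY:
            raise ValueError(f"unknown filter {self.name!r}")
        FILTER_REGISTRY[self.name].validate(self.params)


# ---------------------------------------------------------------------------
# individual operations

def apodize_exponential(fid: RawFid, lb_hz: float) -> RawFid:
    """Multiply by ``exp(-pi * lb * t)``; adds ``lb_hz`` to the Lorentzian FWHM."""
    if not math.isfinite(lb_hz):
        raise ValueError("lb_hz must be finite")
    if lb_hz < 0:
        raise ValueError("lb_hz must be >= 0 (resolution enhancement is a different filter)")
    window = np.exp(-math.pi * lb_hz * fid.times_s)
    return replace(fid, data=fid.data * window)


def apodize_gaussian(fid: RawFid, gb_hz: float) -> RawFid:
    """Gaussian window ``exp(-(pi*gb*t)^2 / (4 ln 2))`` (FWHM ``gb_hz`` after FT)."""
    if not math.isfinite(gb_hz) or gb_hz < 0:
        raise ValueError("gb_hz must be finite and >= 0")
    t = fid.times_s
    window = np.exp(-((math.pi * gb_hz * t) ** 2) / (4.0 * math.log(2.0)))
    return replace(fid, data=fid.data * window)


def default_zero_fill_target(n: int) -> int:
    """Twice the next power of two >= n."""
    return 2 ** (math.ceil(math.log2(n)) + 1) if n > 1 else 2


def zero_fill(fid: RawFid, target_n: int | None = None) -> RawFid:
    if target_n is None:
        target_n = default_zero_fill_target(len(fid.data))
    if target_n < len(fid.data):
        raise ValueError(
            f"target_n={target_n} < FID length {len(fid.data)}; truncation is not zero-filling"
        )
    padded = np.zeros(target_n, dtype=np.complex128)
    padded[: len(fid.data)] = fid.data
    return replace(fid, data=padded)


def fourier_transform(fid: RawFid) -> Spectrum1D:
    """Discrete FT to a carrier-centred, descending-ppm spectrum.

    The first time-domain point is halved (suppresses the constant offset of
    the one-sided DFT) and any recorded group delay is compensated by a linear
    phase ramp of 360 deg * group_delay across the spectral width.
    """
    data = fid.data
    if not np.all(np.isfinite(data.real)) or not np.all(np.isfinite(data.imag)):
        raise ValueError("non-finite FID samples")
    d = data.copy()
    d[0] *= 0.5
    n = len(d)
    spec = np.fft.fftshift(np.fft.fft(d))
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=fid.dwell_s))  # ascending Hz
    if fid.group_delay_pts:
        spec = spec * np.exp(2j * math.pi * freqs * fid.group_delay_pts * fid.dwell_s)
    ppm = fid.carrier_ppm + freqs / fid.sfo1_mhz
    # NMR convention: ppm descending left to right
    return Spectrum1D(
        data=spec[::-1].copy(),
        ppm_axis=ppm[::-1].copy(),
        sfo1_mhz=fid.sfo1_mhz,
        sw_hz=fid.sw_hz,
        nucleus=fid.nucleus,
        solvent=fid.solvent,
    )


def phase_correct(
    spec: Spectrum1D, ph0_deg: float, ph1_deg: float, pivot_ppm: float | None = None
) -> Spectrum1D:
    """Apply zero/first-order phase: ``exp(i*(ph0 + ph1*(x - pivot)/sw_ppm))``."""
    if pivot_ppm is None:
        pivot_ppm = float(spec.ppm_axis[int(np.argmax(np.abs(spec.data)))])
    sw_ppm = spec.sw_hz / spec.sfo1_mhz
    phase = np.deg2rad(ph0_deg + ph1_deg * (spec.ppm_axis - pivot_ppm) / sw_ppm)
    out = replace(spec, data=spec.data * np.exp(1j * phase))
    out.chain = spec.chain + [
        FilterRecord("phase", {"ph0_deg": ph0_deg, "ph1_deg": ph1_deg, "pivot_ppm": pivot_ppm})
    ]
    return out


def _phase_array(spec: Spectrum1D, ph0: float, ph1: float, pivot_ppm: float) -> np.ndarray:
    sw_ppm = spec.sw_hz / spec.sfo1_mhz
    return np.deg2rad(ph0 + ph1 * (spec.ppm_axis - pivot_ppm) / sw_ppm)


def _negativity(real: np.ndarray) -> float:
    neg = real[real < 0]
    denom = float(np.sum(real**2)) or 1.0
    return float(np.sum(neg**2)) / denom


def auto_phase(spec: Spectrum1D, min_snr: float = 5.0,
               n_iter: int = 3) -> tuple[float, float]:
    """Estimate the (ph0, ph1) correction that yields pure absorption lines.

    Strategy: pick strong peaks in the magnitude spectrum and read each one's
    local phase with a matched-filter estimate (complex data weighted by the
    magnitude profile over a symmetric window — the dispersive part cancels,
    and the weighting is noise-optimal for the line shape); fit the ph0 + ph1
    ramp through the peak phases by intensity-weighted least squares with the
    pivot at the tallest peak, and iterate on the residual.  The sign
    ambiguity (all lines inverted) is resolved by requiring positive total
    area.  Returns the correction angles in degrees; applying them leaves the
    real part's negative-area fraction at a local minimum.

    Raises ``ValueError`` if no peak rises ``min_snr`` above the noise.
    """
    mag = np.abs(spec.data)
    # Gaussian noise scale from the quadrature components (phase-invariant)
    sigma = 0.5 * (_mad_noise(spec.data.real) + _mad_noise(spec.data.imag))
    if float(np.max(mag)) < 8.0 * sigma:
        raise ValueError("no signal to phase")
    noise = _mad_noise(mag)
    peak_idx = _strong_peaks(mag, noise * min_snr)
    if len(peak_idx) == 0:
        raise ValueError("no signal to phase")
    pivot_i = peak_idx[int(np.argmax(mag[peak_idx]))]
    pivot_ppm = float(spec.ppm_axis[pivot_i])
    sw_ppm = spec.sw_hz / spec.sfo1_mhz
    half = max(3, int(round(3.0 * _mag_fwhm_bins(mag, peak_idx))))
    x = (spec.ppm_axis[peak_idx] - pivot_ppm) / sw_ppm
    w = mag[peak_idx]

    ph0 = ph1 = 0.0
    data = spec.data
    for _ in range(n_iter):
        sums = np.empty(len(peak_idx), dtype=complex)
        for k, i in enumerate(peak_idx):
            lo, hi = max(0, i - half), i + half + 1
            sums[k] = np.sum(data[lo:hi] * mag[lo:hi])
        phases = np.angle(sums)
        ref = float(phases[int(np.argmax(w))])
        phases = ref + np.angle(np.exp(1j * (phases - ref)))
        if len(peak_idx) >= 2:
            slope, intercept = _robust_line_fit(x, phases, np.sqrt(w))
        else:
            slope, intercept = 0.0, phases[0]
        ph0 -= math.degrees(intercept)
        ph1 -= math.degrees(slope)
        data = spec.data * np.exp(1j * _phase_array(spec, ph0, ph1, pivot_ppm))

    # polish: minimize the negative-area fraction over the line cores
    # (> 20% of the tallest magnitude).  At the correct phase the cores are
    # purely absorptive and the objective sits on its zero plateau; wings and
    # noise floor are excluded because their negativity is noise-dominated
    # and would bias the optimum away from the true phase.
    strong = mag > 0.2 * float(np.max(mag))
    sig = spec.data[strong]
    sig_x = (spec.ppm_axis[strong] - pivot_ppm) / sw_ppm

    def objective(p):
        r = (sig * np.exp(1j * np.deg2rad(p[0] + p[1] * sig_x))).real
        return -float(r[r < 0].sum()) / float(np.abs(r).sum())

    res = minimize(objective, [ph0, ph1], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-14, "maxiter": 600})
    if res.fun <= objective([ph0, ph1]):
        ph0, ph1 = float(res.x[0]), float(res.x[1])

    # resolve the 180-degree ambiguity: total area must be positive
    r = (spec.data * np.exp(1j * _phase_array(spec, ph0, ph1, pivot_ppm))).real
    if np.sum(r) < 0:
        ph0 += 180.0
    ph0 = float(np.angle(np.exp(1j * math.radians(ph0))) * 180.0 / math.pi)
    return ph0, ph1


def _robust_line_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted straight-line fit with residual-based outlier rejection.

    Shoulder artifacts next to strong lines carry arbitrary phases; two
    rejection passes (> 3 x robust residual scale) keep them out of the ramp.
    """
    keep = np.ones(len(x), dtype=bool)
    slope = intercept = 0.0
    for _ in range(3):
        slope, intercept = np.polyfit(x[keep], y[keep], 1, w=w[keep])
        resid = y - (slope * x + intercept)
        scale = max(1.4826 * float(np.median(np.abs(resid[keep]))), math.radians(0.5))
        new_keep = np.abs(resid) <= 3.0 * scale
        if new_keep.sum() < 2 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return float(slope), float(intercept)


def _mag_fwhm_bins(mag: np.ndarray, peak_idx: np.ndarray) -> float:
    """Median half-height width (in bins) of the magnitude-spectrum peaks."""
    widths = []
    for i in peak_idx:
        half = mag[i] / 2.0
        j = i
        while j < len(mag) - 1 and mag[j] > half:
            j += 1
        k = i
        while k > 0 and mag[k] > half:
            k -= 1
        widths.append(j - k)
    return float(np.median(widths)) if widths else 3.0


def _mad_noise(values: np.ndarray) -> float:
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med))) or 1e-12


def _strong_peaks(mag: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of local maxima of ``mag`` above ``threshold``."""
    from scipy.signal import find_peaks

    idx, props = find_peaks(mag, height=max(threshold, float(np.max(mag)) * 0.10),
                            prominence=threshold)
    if len(idx) > 12:  # keep the strongest peaks only; noise bumps ruin the fit
        idx = idx[np.argsort(props["peak_heights"])[-12:]]
        idx.sort()
    return idx


def baseline_correct(
    spec: Spectrum1D,
    method: str = "polynomial",
    degree: int = 3,
    iterations: int = 10,
    lam: float = 1e6,
) -> Spectrum1D:
    """Subtract an estimated baseline from the real part.

    ``polynomial``: iterative Chebyshev fit of the given degree, re-fitting on
    the points that lie below the current baseline plus two residual standard
    deviations (signal exclusion), 10 iterations by default.
    ``airpls``: adaptive iteratively reweighted penalized least squares with
    smoothness ``lam``.  The estimate is stored in ``baseline_estimate``.
    """
    y = spec.data.real.astype(float)
    n = len(y)
    if method == "polynomial":
        if degree >= n:
            raise ValueError("polynomial degree must be smaller than the number of points")
        baseline = _iterative_poly_baseline(y, degree, iterations)
    elif method == "airpls":
        baseline = _airpls(y, lam=lam)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    out = replace(spec, data=spec.data - baseline)
    out.baseline_estimate = baseline
    out.chain = spec.chain + [
        FilterRecord("baseline", {"method": method, "degree": degree,
                                  "iterations": iterations, "lam": lam})
    ]
    return out


def _iterative_poly_baseline(y: np.ndarray, degree: int, iterations: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, len(y))
    mask = np.ones(len(y), dtype=bool)
    baseline = np.zeros(len(y))
    for _ in range(iterations):
        coeffs = np.polynomial.chebyshev.chebfit(x[mask], y[mask], degree)
        baseline = np.polynomial.chebyshev.chebval(x, coeffs)
        resid = y - baseline
        sigma = float(np.std(resid[mask]))
        new_mask = resid < 2.0 * sigma
        if new_mask.sum() <= degree + 1 or np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return baseline


def _airpls(y: np.ndarray, lam: float = 1e6, max_iter: int = 15) -> np.ndarray:
    from scipy import sparse
    from scipy.sparse.linalg import spsolve

    n = len(y)
    d = sparse.eye(n, format="csc")
    d = d[1:] - d[:-1]
    d = d[1:] - d[:-1]
    h = lam * (d.T @ d)
    w = np.ones(n)
    baseline = y.copy()
    for i in range(1, max_iter + 1):
        ws = sparse.diags(w, 0, shape=(n, n), format="csc")
        baseline = spsolve(ws + h, w * y)
        resid = y - baseline
        neg = resid[resid < 0]
        dssn = float(np.abs(neg).sum())
        if dssn < 1e-3 * float(np.abs(y).sum()):
            break
        w = np.where(resid >= 0, 0.0, np.exp(i * np.abs(resid) / (dssn or 1e-12)))
        w[0] = w[-1] = np.exp(i)
    return np.asarray(baseline)


def reference_shift(spec: Spectrum1D, peak_ppm: float, target_ppm: float) -> Spectrum1D:
    """Shift the ppm axis so the peak found nearest ``peak_ppm`` sits at ``target_ppm``."""
    i = spec.index_of_ppm(peak_ppm)
    lo, hi = max(0, i - 16), min(len(spec.data), i + 17)
    j = lo + int(np.argmax(spec.data.real[lo:hi]))
    shift = target_ppm - float(spec.ppm_axis[j])
    out = replace(spec, ppm_axis=spec.ppm_axis + shift,
                  reference_offset_ppm=spec.reference_offset_ppm + shift)
    out.chain = spec.chain + [
        FilterRecord("reference_shift", {"peak_ppm": peak_ppm, "target_ppm": target_ppm})
    ]
    return out


def delta_hz(spec: Spectrum1D, x1_ppm: float, x2_ppm: float) -> float:
    """Distance between two chemical shifts in Hz."""
    return abs(x1_ppm - x2_ppm) * spec.sfo1_mhz


# ---------------------------------------------------------------------------
# filter registry and chain execution

class _FilterSpec:
    def __init__(self, domain: str, required: tuple[str, ...], optional: tuple[str, ...] = ()):
        self.domain = domain  # "time" or "freq" or "ft"
        self.required = required
        self.optional = optional

    def validate(self, params: dict):
        unknown = set(params) - set(self.required) - set(self.optional)
        if unknown:
            raise ValueError(f"unknown filter parameters: {sorted(unknown)}")
        missing = set(self.required) - set(params)
        if missing:
            raise ValueError(f"missing filter parameters: {sorted(missing)}")


FILTER_REGISTRY: dict[str, _FilterSpec] = {
    "exponential_apodization": _FilterSpec("time", ("lb_hz",)),
    "gaussian_apodization": _FilterSpec("time", ("gb_hz",)),
    "zero_fill": _FilterSpec("time", (), ("target_n",)),
    "fourier_transform": _FilterSpec("ft", ()),
    "phase": _FilterSpec("freq", ("ph0_deg", "ph1_deg"), ("pivot_ppm",)),
    "baseline": _FilterSpec("freq", (), ("method", "degree", "iterations", "lam")),
    "reference_shift": _FilterSpec("freq", ("peak_ppm", "target_ppm")),
}


def apply_chain(fid: RawFid, chain: list[FilterRecord]) -> Spectrum1D:
    """Re-execute an ordered filter chain from raw data, deterministically.

    Time-domain filters must precede the single ``fourier_transform``;
    frequency-domain filters must follow it.  Disabled records are skipped.
    """
    n_ft = sum(1 for f in chain if f.name == "fourier_transform" and f.enabled)
    if n_ft > 1:
        raise ValueError("chain may contain at most one fourier_transform")
    state: RawFid | Spectrum1D = fid
    executed: list[FilterRecord] = []
    for rec in chain:
        if not rec.enabled:
            continue
        spec_info = FILTER_REGISTRY[rec.name]
        if spec_info.domain == "time":
            if isinstance(state, Spectrum1D):
                raise ValueError(f"time-domain filter {rec.name!r} after fourier_transform")
            state = _run_time_filter(state, rec)
        elif spec_info.domain == "ft":
            if isinstance(state, Spectrum1D):
                raise ValueError("duplicate fourier_transform")
            state = fourier_transform(state)
        else:
            if not isinstance(state, Spectrum1D):
                raise ValueError(f"frequency-domain filter {rec.name!r} before fourier_transform")
            state = _run_freq_filter(state, rec)
        executed.append(rec)
    if not isinstance(state, Spectrum1D):
        raise ValueError("chain must contain a fourier_transform")
    state.chain = list(chain)
    return state


def _run_time_filter(fid: RawFid, rec: FilterRecord) -> RawFid:
    if rec.name == "exponential_apodization":
        return apodize_exponential(fid, rec.params["lb_hz"])
    if rec.name == "gaussian_apodization":
        return apodize_gaussian(fid, rec.params["gb_hz"])
    if rec.name == "zero_fill":
        return zero_fill(fid, rec.params.get("target_n"))
    raise AssertionError(rec.name)


def _run_freq_filter(spec: Spectrum1D, rec: FilterRecord) -> Spectrum1D:
    if rec.name == "phase":
        return phase_correct(spec, rec.params["ph0_deg"], rec.params["ph1_deg"],
                             rec.params.get("pivot_ppm"))
    if rec.name == "baseline":
        return baseline_correct(spec, rec.params.get("method", "polynomial"),
                                rec.params.get("degree", 3),
                                rec.params.get("iterations", 10),
                                rec.params.get("lam", 1e6))
    if rec.name == "reference_shift":
        return reference_shift(spec, rec.params["peak_ppm"], rec.params["target_ppm"])
    raise AssertionError(rec.name)


def standard_chain(lb_hz: float = 0.3, target_n: int | None = None,
                   ph0_deg: float = 0.0, ph1_deg: float = 0.0) -> list[FilterRecord]:
    """The default teaching chain: apodize, zero-fill, FT, phase."""
    zf: dict = {} if target_n is None else {"target_n": target_n}
    return [
        FilterRecord("exponential_apodization", {"lb_hz": lb_hz}),
        FilterRecord("zero_fill", zf),
        FilterRecord("fourier_transform", {}),
        FilterRecord("phase", {"ph0_deg": ph0_deg, "ph1_deg": ph1_deg}),
    ]
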