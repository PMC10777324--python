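"""Synthetic 1D NMR data with known ground truth.

The generator builds FIDs from declared spin systems in the first-order
(weak-coupling) limit: each signal's stick pattern is the iterated convolution
of its scalar couplings (n equivalent partner protons split a line into n+1
components with binomial intensities), every stick rings as a complex
exponential damped with the common T2, and complex circular Gaussian noise is
added with a mandatory seed.  The exact two-spin AB system, whose four-line
pattern deviates from first order, is available in closed form as an
independent oracle (:func:`simulate_ab`).

Defaults emulate a routine 400 MHz proton acquisition: 4 kHz spectral width,
16k acquired complex points, T2 = 1 s (0.32 Hz natural linewidth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .processing import (
    FilterRecord,
    RawFid,
    apply_chain,
    standard_chain,
)

__all__ = [
    "Coupling",
    "SimSignal",
    "SpinSystem",
    "SimulationConfig",
    "simulate_fid",
    "simulate_spectrum",
    "simulate_ab",
    "sigma_for_snr",
    "make_exercise_fixture",
    "ETHANOL_MOLFILE",
]


@dataclass(frozen=True)
class Coupling:
    """Scalar coupling to ``n_partners`` equivalent protons."""

    j_hz: float
    n_partners: int = 1

    def __post_init__(self):
        if self.j_hz <= 0:
            raise ValueError("J must be positive")
        if self.n_partners < 1:
            raise ValueError("n_partners must be >= 1")


@dataclass(frozen=True)
class SimSignal:
    delta_ppm: float
    n_protons: int = 1
    couplings: tuple[Coupling, ...] = ()

    def __post_init__(self):
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")
        object.__setattr__(self, "couplings", tuple(self.couplings))


@dataclass(frozen=True)
class SpinSystem:
    """A set of first-order signals sharing one T2 (Lorentzian lineshape)."""

    signals: tuple[SimSignal, ...]
    t2_s: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "signals", tuple(self.signals))
        if self.t2_s <= 0:
            raise ValueError("t2_s must be positive")

    def sticks(self, sfo1_mhz: float, carrier_ppm: float) -> tuple[np.ndarray, np.ndarray]:
        """All (frequency offset Hz, intensity) sticks relative to the carrier.

        Per signal the intensities sum to ``n_protons`` (conservation).
        """
        freqs: list[float] = []
        weights: list[float] = []
        for sig in self.signals:
            offsets = np.array([0.0])
            w = np.array([1.0])
            for c in sig.couplings:
                n = c.n_partners
                ks = np.arange(n + 1)
                pat_off = (ks - n / 2.0) * c.j_hz
                pat_w = np.array([math.comb(n, k) for k in ks], dtype=float) / 2.0**n
                offsets = (offsets[:, None] + pat_off[None, :]).ravel()
                w = (w[:, None] * pat_w[None, :]).ravel()
            centre = (sig.delta_ppm - carrier_ppm) * sfo1_mhz
            freqs.extend(centre + offsets)
            weights.extend(sig.n_protons * w)
        return np.asarray(freqs), np.asarray(weights)


@dataclass(frozen=True)
class SimulationConfig:
    sfo1_mhz: float = 400.0
    sw_hz: float = 4000.0
    td: int = 16384
    noise_sigma: float = 0.0
    seed: int = 0
    carrier_ppm: float = 5.0
    nucleus: str = "1H"
    solvent: str = "CDCl3"

    def __post_init__(self):
        if self.td < 64:
            raise ValueError("td must be >= 64")


def simulate_fid(sys: SpinSystem, cfg: SimulationConfig) -> RawFid:
    """Build the first-order FID of ``sys`` under ``cfg``.

    Deterministic for a fixed seed.  Raises ``ValueError`` if any line falls
    outside the spectral window.
    """
    freqs, weights = sys.sticks(cfg.sfo1_mhz, cfg.carrier_ppm)
    if np.any(np.abs(freqs) > cfg.sw_hz / 2.0):
        worst = float(freqs[np.argmax(np.abs(freqs))])
        raise ValueError(f"signal at {worst:+.1f} Hz falls outside sw = {cfg.sw_hz} Hz")
    dwell = 1.0 / cfg.sw_hz
    t = np.arange(cfg.td) * dwell
    fid = np.zeros(cfg.td, dtype=np.complex128)
    decay = np.exp(-t / sys.t2_s)
    for f, w in zip(freqs, weights):
        fid += w * np.exp(2j * math.pi * f * t)
    fid *= decay
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        fid += cfg.noise_sigma * (rng.standard_normal(cfg.td) + 1j * rng.standard_normal(cfg.td))
    return RawFid(
        data=fid,
        dwell_s=dwell,
        sfo1_mhz=cfg.sfo1_mhz,
        sw_hz=cfg.sw_hz,
        nucleus=cfg.nucleus,
        solvent=cfg.solvent,
        carrier_ppm=cfg.carrier_ppm,
    )


def simulate_spectrum(sys: SpinSystem, cfg: SimulationConfig,
                      chain: list[FilterRecord] | None = None):
    """Convenience: simulate and run the standard processing chain."""
    fid = simulate_fid(sys, cfg)
    return apply_chain(fid, chain if chain is not None else standard_chain(lb_hz=0.0))


def sigma_for_snr(sys: SpinSystem, cfg: SimulationConfig, target_snr: float,
                  chain: list[FilterRecord] | None = None) -> float:
    """Time-domain noise sigma giving the requested spectral peak SNR.

    The tallest peak height of the noiseless processed spectrum is divided by
    ``target_snr`` to obtain the frequency-domain noise standard deviation;
    white time-domain noise of variance ``sigma^2`` per quadrature maps to a
    frequency-domain standard deviation of ``sigma * sqrt(sum w_k^2)`` where
    ``w`` is the effective window (apodization, first-point halving).
    """
    base = simulate_spectrum(sys, SimulationConfig(**{**cfg.__dict__, "noise_sigma": 0.0}),
                             chain)
    height = float(np.max(base.data.real))
    lb = 0.0
    for rec in (chain or standard_chain(lb_hz=0.0)):
        if rec.name == "exponential_apodization" and rec.enabled:
            lb = rec.params["lb_hz"]
    t = np.arange(cfg.td) / cfg.sw_hz
    w = np.exp(-math.pi * lb * t)
    w[0] *= 0.5
    gain = math.sqrt(float(np.sum(w**2)))
    return height / (target_snr * gain)


def simulate_ab(delta_nu_hz: float, j_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form AB (strongly coupled two-spin) four-line pattern.

    With ``C = sqrt(delta_nu^2 + J^2)`` the lines sit at offsets
    ``+-(C + J)/2`` and ``+-(C - J)/2`` about the centre; the outer lines have
    intensity ``1 - J/C``, the inner lines ``1 + J/C``.  Limits: ``delta_nu
    -> 0`` gives a singlet (outer intensities vanish), ``J -> 0`` gives two
    equal singlets at ``+-delta_nu/2``.
    """
    if delta_nu_hz < 0 or j_hz < 0:
        raise ValueError("delta_nu_hz and j_hz must be >= 0")
    c = math.hypot(delta_nu_hz, j_hz)
    offsets = np.array([-(c + j_hz) / 2, -(c - j_hz) / 2, (c - j_hz) / 2, (c + j_hz) / 2])
    if c == 0.0:
        intensities = np.array([0.0, 2.0, 2.0, 0.0])
    else:
        r = j_hz / c
        intensities = np.array([1 - r, 1 + r, 1 + r, 1 - r])
    return offsets, intensities


# ---------------------------------------------------------------------------
# exercise fixtures

ETHANOL_MOLFILE = """ethanol
  nmrkit

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.2500    1.2990    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
"""


def make_exercise_fixture(exercises, cfg: SimulationConfig, out: str | Path) -> None:
    """Write a folder tree of JCAMP-DX spectra + solution molfiles.

    ``exercises`` is an iterable of ``(relative_path, SpinSystem, molfile_text)``
    tuples; each becomes one leaf folder holding ``spectrum.jdx`` (the
    processed spectrum, DIF/DUP-compressed) and ``solution.mol``, consumable
    by :func:`nmrkit.exercises.build_toc`.  Byte-deterministic for a fixed
    seed.
    """
    from . import jcampdx

    out = Path(out)
    for rel, sys, molfile in exercises:
        folder = out / rel
        folder.mkdir(parents=True, exist_ok=True)
        spec = simulate_spectrum(sys, cfg, standard_chain(lb_hz=0.2))
        block = jcampdx.JcampBlock(
            title=rel.replace("/", " / "),
            data_type="NMR SPECTRUM",
            x_units="PPM",
            x_first=float(spec.ppm_axis[0]),
            x_last=float(spec.ppm_axis[-1]),
            n_points=len(spec.data),
            data=spec.data.real,
        )
        block.ldrs[".OBSERVEFREQUENCY"] = f"{cfg.sfo1_mhz:.2f}"
        block.ldrs[".OBSERVENUCLEUS"] = "^" + cfg.nucleus
        block.ldrs[".SOLVENTNAME"] = cfg.solvent
        (folder / "spectrum.jdx").write_text(
            jcampdx.write_jcamp(block, compression="dif_dup"), encoding="ascii"
        )
        (folder / "solution.mol").write_text(molfile, encoding="ascii")
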