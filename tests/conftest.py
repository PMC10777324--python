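"""Shared fixtures: programmatically generated molfiles and simulated spectra."""

from __future__ import annotations

import numpy as np
import pytest

import nmrkit as nk


def make_molfile(elements, bonds, parities=None, charges=None, title="fixture"):
    """Build a minimal column-aligned V2000 molfile.

    ``bonds`` is a list of (a1, a2, order) with 0-based indices; ``parities``
    and ``charges`` map atom index to molfile parity flag / formal charge.
    """
    parities = parities or {}
    charges = charges or {}
    lines = [title, "  nmrkit", ""]
    lines.append(f"{len(elements):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for i, el in enumerate(elements):
        par = parities.get(i, 0)
        lines.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {el:<3} 0  0{par:3d}  0  0  0  0  0  0  0  0  0"
        )
    for a, b, order in bonds:
        lines.append(f"{a + 1:3d}{b + 1:3d}{order:3d}  0")
    for i, chg in charges.items():
        lines.append(f"M  CHG  1 {i + 1:3d} {chg:3d}")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def ethanol():
    return nk.parse_molfile(nk.simulate.ETHANOL_MOLFILE)


@pytest.fixture(scope="session")
def benzene_kekule_a():
    return nk.parse_molfile(make_molfile(
        ["C"] * 6, [(0, 1, 2), (1, 2, 1), (2, 3, 2), (3, 4, 1), (4, 5, 2), (5, 0, 1)]
    ))


@pytest.fixture(scope="session")
def benzene_kekule_b():
    return nk.parse_molfile(make_molfile(
        ["C"] * 6, [(0, 1, 1), (1, 2, 2), (2, 3, 1), (3, 4, 2), (4, 5, 1), (5, 0, 2)]
    ))


@pytest.fixture(scope="session")
def dimethoxybenzene():
    # 1,4-dimethoxybenzene: ring C0..C5, OMe on C0 and C3
    return nk.parse_molfile(make_molfile(
        ["C"] * 6 + ["O", "C", "O", "C"],
        [(0, 1, 2), (1, 2, 1), (2, 3, 2), (3, 4, 1), (4, 5, 2), (5, 0, 1),
         (0, 6, 1), (6, 7, 1), (3, 8, 1), (8, 9, 1)],
    ))


@pytest.fixture(scope="session")
def butanol_r():
    # 2-butanol, stereocentre at C1 (CH3-C*(OH)-CH2-CH3)
    return nk.parse_molfile(make_molfile(
        ["C", "C", "C", "C", "O"],
        [(0, 1, 1), (1, 2, 1), (2, 3, 1), (1, 4, 1)], parities={1: 1},
    ))


@pytest.fixture(scope="session")
def butanol_s():
    return nk.parse_molfile(make_molfile(
        ["C", "C", "C", "C", "O"],
        [(0, 1, 1), (1, 2, 1), (2, 3, 1), (1, 4, 1)], parities={1: 2},
    ))


@pytest.fixture(scope="session")
def dimethyl_ether():
    return nk.parse_molfile(make_molfile(["C", "O", "C"], [(0, 1, 1), (1, 2, 1)]))


# ---------------------------------------------------------------------------
# simulated spectra (session-scoped: several tests share them)

ETHYL_SYSTEM = nk.SpinSystem(signals=(
    nk.SimSignal(3.6, 2, (nk.Coupling(7.0, 3),)),
    nk.SimSignal(1.2, 3, (nk.Coupling(7.0, 2),)),
), t2_s=1.0)


@pytest.fixture(scope="session")
def ethyl_spectrum():
    """Ethyl q/t pattern at spectral SNR ~100, fully decayed acquisition."""
    cfg0 = nk.SimulationConfig(sfo1_mhz=400, sw_hz=4000, td=65536, seed=1, carrier_ppm=2.4)
    sigma = nk.sigma_for_snr(ETHYL_SYSTEM, cfg0, 100)
    cfg = nk.SimulationConfig(sfo1_mhz=400, sw_hz=4000, td=65536, noise_sigma=sigma,
                              seed=1, carrier_ppm=2.4)
    return nk.simulate_spectrum(ETHYL_SYSTEM, cfg)


@pytest.fixture(scope="session")
def singlet_spectrum():
    """One singlet at 2.500 ppm, SNR ~100."""
    sys = nk.SpinSystem(signals=(nk.SimSignal(2.5, 1),), t2_s=1.0)
    cfg0 = nk.SimulationConfig(sfo1_mhz=400, sw_hz=2000, td=32768, seed=2, carrier_ppm=2.5)
    sigma = nk.sigma_for_snr(sys, cfg0, 100)
    cfg = nk.SimulationConfig(sfo1_mhz=400, sw_hz=2000, td=32768, noise_sigma=sigma,
                              seed=2, carrier_ppm=2.5)
    return nk.simulate_spectrum(sys, cfg)
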