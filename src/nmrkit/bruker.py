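"""Direct import of Bruker raw-data directories (``acqus`` + binary ``fid``).

Only the time-domain layout is read: ``acqus`` is a JCAMP-like parameter file
and ``fid`` holds interleaved real/imaginary values, int32 or float64
(``DTYPA``), little- or big-endian (``BYTORDA``).  The digital-filter group
delay (``GRPDLY``) is recorded on the returned FID and compensated later by
the processing module's phase ramp — never silently applied to the data.

:func:`make_bruker_fixture` writes a minimal directory in the same layout so
the reader can be exercised against synthetic data with known ground truth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .processing import RawFid

__all__ = ["BrukerParams", "read_bruker", "make_bruker_fixture"]


@dataclass
class BrukerParams:
    """Acquisition parameters from ``acqus`` (Bruker conventions).

    ``td`` counts real+imaginary values, so the FID holds ``td/2`` complex
    points.
    """

    td: int
    sw_h: float
    sfo1: float
    o1: float = 0.0
    byte_order: str = "little"
    data_type: str = "int32"
    grpdly: float | None = None
    nucleus: str = "1H"
    solvent: str = ""
    scale: float = 1.0

    def __post_init__(self):
        if self.td <= 0 or self.td % 2:
            raise ValueError(f"TD must be even and positive, got {self.td}")
        if self.sw_h <= 0:
            raise ValueError("SW_h must be positive")
        if self.sfo1 <= 0:
            raise ValueError("SFO1 must be positive")


def _parse_acqus(text: str) -> dict[str, str]:
    params: dict[str, str] = {}
    for m in re.finditer(r"^##\$?([A-Za-z0-9_]+)=\s*(.*)$", text, re.MULTILINE):
        params[m.group(1).upper()] = m.group(2).strip()
    return params


def read_params(directory: str | Path) -> BrukerParams:
    directory = Path(directory)
    acqus = directory / "acqus"
    if not acqus.exists():
        raise FileNotFoundError(f"missing parameter file: {acqus}")
    raw = _parse_acqus(acqus.read_text(errors="replace"))

    def fval(key: str, default: float | None = None) -> float:
        if key not in raw:
            if default is None:
                raise ValueError(f"acqus is missing ##${key}=")
            return default
        return float(raw[key])

    dtypa = int(fval("DTYPA", 0))
    grpdly = fval("GRPDLY", -1.0)
    return BrukerParams(
        td=int(fval("TD")),
        sw_h=fval("SW_H"),
        sfo1=fval("SFO1"),
        o1=fval("O1", 0.0),
        byte_order="big" if int(fval("BYTORDA", 0)) else "little",
        data_type="float64" if dtypa == 2 else "int32",
        grpdly=None if grpdly < 0 else grpdly,
        nucleus=raw.get("NUC1", "1H").strip("<>"),
        solvent=raw.get("SOLVENT", "").strip("<>"),
        scale=fval("NMRKITSCALE", 1.0),
    )


def read_bruker(directory: str | Path) -> RawFid:
    """Read ``acqus`` + ``fid`` into a :class:`~nmrkit.processing.RawFid`.

    Raises ``FileNotFoundError`` naming the missing file, or ``ValueError``
    stating both numbers when TD is inconsistent with the fid byte length.
    """
    directory = Path(directory)
    params = read_params(directory)
    fid_path = directory / "fid"
    if not fid_path.exists():
        raise FileNotFoundError(f"missing data file: {fid_path}")
    blob = fid_path.read_bytes()
    dtype = np.dtype(np.int32 if params.data_type == "int32" else np.float64)
    dtype = dtype.newbyteorder("<" if params.byte_order == "little" else ">")
    expect = params.td * dtype.itemsize
    if len(blob) != expect:
        raise ValueError(
            f"fid holds {len(blob)} bytes but TD={params.td} "
            f"({params.data_type}) requires {expect}"
        )
    values = np.frombuffer(blob, dtype=dtype).astype(np.float64) * params.scale
    data = values[0::2] + 1j * values[1::2]
    return RawFid(
        data=data,
        dwell_s=1.0 / params.sw_h,
        sfo1_mhz=params.sfo1,
        sw_hz=params.sw_h,
        nucleus=params.nucleus,
        solvent=params.solvent,
        carrier_ppm=params.o1 / params.sfo1,
        group_delay_pts=params.grpdly,
    )


def make_bruker_fixture(directory: str | Path, fid: RawFid,
                        data_type: str = "int32",
                        byte_order: str = "little") -> None:
    """Write a minimal Bruker-layout directory readable by :func:`read_bruker`.

    int32 storage records a private ``##$NMRKITSCALE`` factor chosen so the
    maximum amplitude maps near 2^30, keeping the decoded amplitudes within
    int32 quantization of the originals.
    """
    if data_type not in ("int32", "float64"):
        raise ValueError(f"unsupported data_type {data_type!r}")
    if byte_order not in ("little", "big"):
        raise ValueError(f"unsupported byte_order {byte_order!r}")
    if len(fid.data) == 0:
        raise ValueError("empty FID")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    interleaved = np.empty(2 * len(fid.data), dtype=np.float64)
    interleaved[0::2] = fid.data.real
    interleaved[1::2] = fid.data.imag
    scale = 1.0
    if data_type == "int32":
        peak = float(np.max(np.abs(interleaved))) or 1.0
        scale = peak / 2**30
        stored = np.round(interleaved / scale).astype(np.int32)
        dtype = np.dtype(np.int32)
    else:
        stored = interleaved
        dtype = np.dtype(np.float64)
    dtype = dtype.newbyteorder("<" if byte_order == "little" else ">")
    (directory / "fid").write_bytes(stored.astype(dtype).tobytes())

    lines = [
        "##TITLE=nmrkit synthetic Bruker fixture",
        "##JCAMP-DX=5.0",
        "##DATA TYPE=Parameter Values",
        f"##$TD= {2 * len(fid.data)}",
        f"##$SW_h= {fid.sw_hz!r}",
        f"##$SFO1= {fid.sfo1_mhz!r}",
        f"##$O1= {fid.carrier_ppm * fid.sfo1_mhz!r}",
        f"##$BYTORDA= {1 if byte_order == 'big' else 0}",
        f"##$DTYPA= {2 if data_type == 'float64' else 0}",
        f"##$GRPDLY= {fid.group_delay_pts if fid.group_delay_pts is not None else -1}",
        f"##$NUC1= <{fid.nucleus}>",
        f"##$SOLVENT= <{fid.solvent}>",
        f"##$NMRKITSCALE= {scale!r}",
        "##END=",
    ]
    (directory / "acqus").write_text("\n".join(lines) + "\n", encoding="ascii")
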