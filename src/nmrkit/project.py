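"""Workspace serialization: spectra, filter chains, molecules, assignments.

A project is one JSON document ("nmrkit project", schema version 1).  Numeric
arrays are stored losslessly as base64-encoded little-endian IEEE 754 bytes
with a declared dtype, so a saved spectrum reloads bit-for-bit and the stored
filter chain re-executes from the stored raw FID to exactly the stored
spectrum.  Serialization is canonical (sorted keys, fixed float formatting):
save -> load -> save is byte-identical.  Unknown top-level keys found in a
file are preserved and re-emitted on save.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import jcampdx
from .analysis import Range, Signal
from .molecule import Molecule, parse_molfile
from .processing import FilterRecord, RawFid, Spectrum1D

__all__ = [
    "Project",
    "ProjectSpectrum",
    "Assignment",
    "ProjectError",
    "save_project",
    "load_project",
    "import_any",
]

SCHEMA_VERSION = 1
_KNOWN_KEYS = {"format", "version", "spectra", "molecules", "assignments", "display"}


class ProjectError(ValueError):
    pass


@dataclass
class ProjectSpectrum:
    id: str
    raw: RawFid | None = None
    spectrum: Spectrum1D | None = None
    chain: list[FilterRecord] = field(default_factory=list)
    ranges: list[Range] = field(default_factory=list)


@dataclass
class Assignment:
    spectrum_id: str
    range_index: int
    signal_index: int
    molecule_id: str
    atom_indices: list[int]


@dataclass
class Project:
    version: int = SCHEMA_VERSION
    spectra: list[ProjectSpectrum] = field(default_factory=list)
    molecules: list[tuple[str, Molecule]] = field(default_factory=list)
    assignments: list[Assignment] = field(default_factory=list)
    display: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def spectrum(self, spectrum_id: str) -> ProjectSpectrum:
        for s in self.spectra:
            if s.id == spectrum_id:
                return s
        raise KeyError(spectrum_id)


# ---------------------------------------------------------------------------
# array codec

def _encode_array(arr: np.ndarray) -> dict:
    arr = np.ascontiguousarray(arr)
    dtype = "<c16" if np.iscomplexobj(arr) else "<f8"
    return {
        "dtype": dtype,
        "b64": base64.b64encode(arr.astype(dtype).tobytes()).decode("ascii"),
    }


def _decode_array(obj: dict) -> np.ndarray:
    return np.frombuffer(base64.b64decode(obj["b64"]), dtype=obj["dtype"]).copy()


# ---------------------------------------------------------------------------
# to/from JSON document

def _fid_to_doc(fid: RawFid) -> dict:
    return {
        "data": _encode_array(fid.data),
        "dwell_s": fid.dwell_s,
        "sfo1_mhz": fid.sfo1_mhz,
        "sw_hz": fid.sw_hz,
        "nucleus": fid.nucleus,
        "solvent": fid.solvent,
        "carrier_ppm": fid.carrier_ppm,
        "group_delay_pts": fid.group_delay_pts,
    }


def _fid_from_doc(doc: dict) -> RawFid:
    return RawFid(
        data=_decode_array(doc["data"]),
        dwell_s=doc["dwell_s"],
        sfo1_mhz=doc["sfo1_mhz"],
        sw_hz=doc["sw_hz"],
        nucleus=doc["nucleus"],
        solvent=doc["solvent"],
        carrier_ppm=doc["carrier_ppm"],
        group_delay_pts=doc["group_delay_pts"],
    )


def _spectrum_to_doc(spec: Spectrum1D) -> dict:
    return {
        "data": _encode_array(spec.data),
        "ppm_axis": _encode_array(spec.ppm_axis),
        "sfo1_mhz": spec.sfo1_mhz,
        "sw_hz": spec.sw_hz,
        "nucleus": spec.nucleus,
        "solvent": spec.solvent,
        "reference_offset_ppm": spec.reference_offset_ppm,
    }


def _spectrum_from_doc(doc: dict) -> Spectrum1D:
    return Spectrum1D(
        data=_decode_array(doc["data"]),
        ppm_axis=_decode_array(doc["ppm_axis"]).real.astype(float),
        sfo1_mhz=doc["sfo1_mhz"],
        sw_hz=doc["sw_hz"],
        nucleus=doc["nucleus"],
        solvent=doc["solvent"],
        reference_offset_ppm=doc["reference_offset_ppm"],
    )


def _range_to_doc(r: Range) -> dict:
    return {
        "from_ppm": r.from_ppm,
        "to_ppm": r.to_ppm,
        "absolute_integral": r.absolute_integral,
        "relative_integral": r.relative_integral,
        "signals": [
            {
                "delta_ppm": s.delta_ppm,
                "multiplicity": s.multiplicity,
                "j_hz": list(s.j_hz),
                "assigned_atoms": list(s.assigned_atoms),
            }
            for s in r.signals
        ],
    }


def _range_from_doc(doc: dict) -> Range:
    r = Range(
        from_ppm=doc["from_ppm"],
        to_ppm=doc["to_ppm"],
        absolute_integral=doc["absolute_integral"],
        relative_integral=doc["relative_integral"],
    )
    r.signals = [
        Signal(
            delta_ppm=s["delta_ppm"],
            multiplicity=s["multiplicity"],
            j_hz=list(s["j_hz"]),
            assigned_atoms=list(s["assigned_atoms"]),
        )
        for s in doc["signals"]
    ]
    return r


def project_to_doc(p: Project) -> dict:
    _validate(p)
    doc = {
        "format": "nmrkit-project",
        "version": p.version,
        "spectra": [
            {
                "id": s.id,
                "raw": _fid_to_doc(s.raw) if s.raw is not None else None,
                "spectrum": _spectrum_to_doc(s.spectrum) if s.spectrum is not None else None,
                "chain": [
                    {"name": f.name, "params": f.params, "enabled": f.enabled}
                    for f in s.chain
                ],
                "ranges": [_range_to_doc(r) for r in s.ranges],
            }
            for s in p.spectra
        ],
        "molecules": [{"id": mid, "molfile": mol.source_molfile} for mid, mol in p.molecules],
        "assignments": [
            {
                "spectrum_id": a.spectrum_id,
                "range_index": a.range_index,
                "signal_index": a.signal_index,
                "molecule_id": a.molecule_id,
                "atom_indices": list(a.atom_indices),
            }
            for a in p.assignments
        ],
        "display": p.display,
    }
    doc.update(p.extra)
    return doc


def doc_to_project(doc: dict) -> Project:
    if "version" not in doc:
        raise ProjectError("unversioned project file")
    version = doc["version"]
    if not isinstance(version, int) or version > SCHEMA_VERSION:
        raise ProjectError(
            f"project schema version {version!r} is newer than supported ({SCHEMA_VERSION})"
        )
    spectra = []
    for s in doc.get("spectra", []):
        spectra.append(
            ProjectSpectrum(
                id=s["id"],
                raw=_fid_from_doc(s["raw"]) if s.get("raw") else None,
                spectrum=_spectrum_from_doc(s["spectrum"]) if s.get("spectrum") else None,
                chain=[
                    FilterRecord(f["name"], dict(f["params"]), f["enabled"])
                    for f in s.get("chain", [])
                ],
                ranges=[_range_from_doc(r) for r in s.get("ranges", [])],
            )
        )
    molecules = [(m["id"], parse_molfile(m["molfile"])) for m in doc.get("molecules", [])]
    assignments = [
        Assignment(
            spectrum_id=a["spectrum_id"],
            range_index=a["range_index"],
            signal_index=a["signal_index"],
            molecule_id=a["molecule_id"],
            atom_indices=list(a["atom_indices"]),
        )
        for a in doc.get("assignments", [])
    ]
    extra = {k: v for k, v in doc.items() if k not in _KNOWN_KEYS}
    return Project(
        version=version,
        spectra=spectra,
        molecules=molecules,
        assignments=assignments,
        display=doc.get("display", {}),
        extra=extra,
    )


def _validate(p: Project) -> None:
    spectrum_ids = {s.id for s in p.spectra}
    molecule_ids = {mid for mid, _ in p.molecules}
    if len(spectrum_ids) != len(p.spectra):
        raise ProjectError("duplicate spectrum ids")
    for a in p.assignments:
        if a.spectrum_id not in spectrum_ids:
            raise ProjectError(f"assignment references unknown spectrum {a.spectrum_id!r}")
        if a.molecule_id not in molecule_ids:
            raise ProjectError(f"assignment references unknown molecule {a.molecule_id!r}")
        s = p.spectrum(a.spectrum_id)
        if not (0 <= a.range_index < len(s.ranges)):
            raise ProjectError("assignment references missing range")
        if not (0 <= a.signal_index < len(s.ranges[a.range_index].signals)):
            raise ProjectError("assignment references missing signal")


def save_project(p: Project, path: str | Path) -> None:
    """Write the project as canonical JSON (raises before writing on dangling links)."""
    doc = project_to_doc(p)
    text = json.dumps(doc, sort_keys=True, separators=(",", ":"), allow_nan=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


def load_project(path: str | Path) -> Project:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ProjectError(f"not a valid project file: {exc}") from exc
    if not isinstance(doc, dict):
        raise ProjectError("not a valid project file: top level is not an object")
    return doc_to_project(doc)


# ---------------------------------------------------------------------------
# universal import

def import_any(path: str | Path) -> Project:
    """Content-sniffing import: JCAMP-DX, Bruker directory, molfile, or project.

    The result is always a :class:`Project`.
    """
    path = Path(path)
    if path.is_dir():
        if (path / "acqus").exists() and (path / "fid").exists():
            from .bruker import read_bruker

            fid = read_bruker(path)
            return Project(spectra=[ProjectSpectrum(id=path.name, raw=fid)])
        raise ProjectError(
            f"{path} is not a Bruker raw directory (acqus + fid); "
            "supported inputs: JCAMP-DX file, Bruker directory, molfile, project JSON"
        )
    text = path.read_text(encoding="utf-8", errors="replace")
    stripped = text.lstrip("﻿ \t\r\n")
    if stripped.startswith("{"):
        return load_project(path)
    if stripped.startswith("##"):
        return _import_jcamp(text, path.stem)
    if "V2000" in text or "M  END" in text:
        return Project(molecules=[(path.stem, parse_molfile(text))])
    raise ProjectError(
        f"unrecognized content in {path}; supported inputs: JCAMP-DX file, "
        "Bruker directory, molfile, project JSON"
    )


def _import_jcamp(text: str, name: str) -> Project:
    blocks = jcampdx.parse_jcamp(text)
    spectra = []
    for k, block in enumerate(blocks):
        sid = name if len(blocks) == 1 else f"{name}:{k}"
        spectra.append(_block_to_entry(block, sid))
    return Project(spectra=spectra)


def _block_to_entry(block: jcampdx.JcampBlock, sid: str) -> ProjectSpectrum:
    sfo1 = float(block.ldr(".OBSERVEFREQUENCY", "400") or 400)
    nucleus = (block.ldr(".OBSERVENUCLEUS", "^1H") or "^1H").lstrip("^")
    solvent = block.ldr(".SOLVENTNAME", "") or ""
    if np.iscomplexobj(block.data):
        n = block.n_points
        duration = abs(block.x_last - block.x_first)
        dwell = duration / (n - 1) if n > 1 and duration else 1e-4
        sw = 1.0 / dwell
        fid = RawFid(
            data=block.data,
            dwell_s=dwell,
            sfo1_mhz=sfo1,
            sw_hz=sw,
            nucleus=nucleus,
            solvent=solvent,
        )
        return ProjectSpectrum(id=sid, raw=fid)
    data = np.asarray(block.data, dtype=float)
    axis = block.x_axis
    if block.x_units.upper() == "HZ":
        axis = axis / sfo1
    if len(axis) > 1 and axis[0] < axis[-1]:
        axis = axis[::-1].copy()
        data = data[::-1].copy()
    sw_hz = abs(axis[0] - axis[-1]) * sfo1 if len(axis) > 1 else 1.0
    spec = Spectrum1D(
        data=data.astype(np.complex128),
        ppm_axis=axis,
        sfo1_mhz=sfo1,
        sw_hz=sw_hz,
        nucleus=nucleus,
        solvent=solvent,
    )
    return ProjectSpectrum(id=sid, spectrum=spec)
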