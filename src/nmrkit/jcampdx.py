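"""JCAMP-DX reading and writing for 1D NMR data.

Supports the tabular ``(X++(Y..Y))`` form in AFFN (plain numbers) and in the
ASDF compressed encodings (SQZ, DIF, DUP), compound (LINK) files with multiple
blocks, and ``##NTUPLES`` blocks holding the separate real/imaginary pages of a
complex FID.  DIF checkpoints (the first y of a line repeating the last y of
the previous line) are verified during decoding.

Written output uses a JCAMP-DX 5.01 header and only the ``(X++(Y..Y))``
tabular form, either uncompressed (AFFN) or DIF/DUP-compressed.  Unknown and
vendor-private labels (``##$FOO``) are preserved verbatim in
:attr:`JcampBlock.ldrs` and otherwise ignored.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "JcampBlock",
    "JcampError",
    "parse_jcamp",
    "write_jcamp",
]


class JcampError(ValueError):
    """Raised for malformed or unsupported JCAMP-DX content."""


@dataclass
class JcampBlock:
    """One JCAMP-DX data block.

    ``data`` holds the decoded series: a real ``float64`` array for ordinary
    ``##XYDATA`` blocks, a ``complex128`` array when assembled from the R/I
    pages of an ``##NTUPLES`` FID block.  Decoded y values equal the stored
    integers times ``y_factor`` — quantization is explicit, never hidden.
    """

    title: str = ""
    data_type: str = ""
    ldrs: dict[str, str] = field(default_factory=dict)
    x_units: str = ""
    y_factor: float = 1.0
    x_first: float = 0.0
    x_last: float = 0.0
    n_points: int = 0
    data: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def x_axis(self) -> np.ndarray:
        """Arithmetic x progression from ``x_first`` to ``x_last``."""
        return np.linspace(self.x_first, self.x_last, self.n_points)

    def ldr(self, label: str, default: str | None = None) -> str | None:
        return self.ldrs.get(_normalize_label(label), default)


# ---------------------------------------------------------------------------
# label handling

def _normalize_label(label: str) -> str:
    # JCAMP labels are case-insensitive; spaces, dashes, underscores ignored.
    # Private labels keep their leading "$".
    label = label.strip()
    private = label.startswith("$")
    core = re.sub(r"[ \-_/]", "", label.lstrip("$")).upper()
    return ("$" + core) if private else core


# ---------------------------------------------------------------------------
# ASDF / AFFN token stream

_SQZ = {c: v for v, c in enumerate("@ABCDEFGHI")}
_SQZ.update({c: -(v + 1) for v, c in enumerate("abcdefghi")})
_DIF = {c: v for v, c in enumerate("%JKLMNOPQR")}
_DIF.update({c: -(v + 1) for v, c in enumerate("jklmnopqr")})
_DUP = {c: v + 1 for v, c in enumerate("STUVWXYZ")}
_DUP["s"] = 9

# exponent requires an explicit sign: an unsigned "E4" after a number is the
# SQZ pseudo-digit for 5 followed by a 4, not an exponent
_AFFN_RE = re.compile(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]\d+)?")


def _tokenize_data_line(line: str, lineno: int):
    """Yield ('affn'|'sqz'|'dif'|'dup', value) tokens from one data line."""
    i = 0
    n = len(line)
    while i < n:
        c = line[i]
        if c in " \t,;":
            i += 1
            continue
        if c in _SQZ or c in _DIF or c in _DUP:
            if c in _SQZ:
                mode, lead = "sqz", _SQZ[c]
            elif c in _DIF:
                mode, lead = "dif", _DIF[c]
            else:
                mode, lead = "dup", _DUP[c]
            j = i + 1
            while j < n and line[j].isdigit():
                j += 1
            digits = line[i + 1 : j]
            value = lead
            if digits:
                mag = int(digits)
                base = abs(lead) * 10 ** len(digits) + mag
                value = -base if (lead < 0) else base
                if lead == 0 and mode != "dup":
                    value = mag
            i = j
            yield mode, value
        elif c in "+-.0123456789":
            m = _AFFN_RE.match(line, i)
            if not m:
                raise JcampError(f"malformed numeric value on line {lineno}: {line[i:i+12]!r}")
            i = m.end()
            yield "affn", float(m.group(0))
        elif c == "?":
            i += 1
            yield "affn", math.nan
        else:
            raise JcampError(f"malformed numeric line {lineno}: unexpected character {c!r}")


def _decode_xydata(lines: list[tuple[int, str]], y_factor: float) -> np.ndarray:
    """Decode ``(X++(Y..Y))`` data lines into a float array of y values.

    ``lines`` are (lineno, text) pairs.  Verifies DIF checkpoints: when a line
    ends in DIF (or DUP-of-DIF) mode, the first y of the next line repeats the
    last y and is dropped after comparison.
    """
    ys: list[float] = []
    in_dif = False  # whether previous line ended in DIF mode
    for lineno, line in lines:
        line = line.split("$$", 1)[0].rstrip()
        if not line.strip():
            continue
        tokens = list(_tokenize_data_line(line, lineno))
        if not tokens:
            continue
        # first token is the x value (AFFN or SQZ per standard); drop it.
        tokens.pop(0)
        first_y = True
        last_mode = None
        last_inc = 0
        for mode, value in tokens:
            if mode == "dup":
                if last_mode is None:
                    raise JcampError(f"DUP with no preceding value on line {lineno}")
                for _ in range(value - 1):
                    if last_mode == "dif":
                        ys.append(ys[-1] + last_inc)
                    else:
                        ys.append(ys[-1])
                continue
            if mode == "dif":
                if not ys:
                    raise JcampError(f"DIF with no previous y on line {lineno}")
                y = ys[-1] + value
                last_inc = value
            else:
                y = float(value)
            if first_y and in_dif:
                # checkpoint: must repeat last y of previous line
                if mode == "dif":
                    raise JcampError(f"line {lineno} starts in DIF mode after DIF line")
                if ys and abs(y - ys[-1]) > 0.5:
                    raise JcampError(
                        f"DIF checkpoint mismatch on line {lineno}: "
                        f"expected {ys[-1]}, got {y}"
                    )
                first_y = False
                last_mode = mode
                continue
            first_y = False
            ys.append(y)
            last_mode = mode
        in_dif = last_mode == "dif" or (last_mode == "dup" and in_dif)
    return np.asarray(ys, dtype=float) * y_factor


# ---------------------------------------------------------------------------
# parsing

def _split_ldrs(text: str):
    """Split a JCAMP document into (lineno, label, value-lines) records."""
    if text.startswith("﻿"):
        text = text[1:]
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    records = []
    current = None
    for lineno, raw in enumerate(lines, start=1):
        if raw.startswith("##"):
            if current is not None:
                records.append(current)
            label, _, value = raw[2:].partition("=")
            current = [lineno, label, [value.strip()]]
        elif current is not None:
            current[2].append(raw)
        # text before the first ## is ignored
    if current is not None:
        records.append(current)
    return records


def _parse_float(value: str, default: float = 0.0) -> float:
    value = value.split("$$")[0].strip()
    if not value:
        return default
    try:
        return float(value)
    except ValueError:
        return default


def parse_jcamp(text: str) -> list[JcampBlock]:
    """Parse a JCAMP-DX document into data blocks.

    Compound (LINK) files yield one block per nested data block.  Raises
    :class:`JcampError` on malformed numeric content, DIF checkpoint
    mismatches, or unsupported data classes (e.g. PEAK TABLE).
    """
    records = _split_ldrs(text)
    if not any(_normalize_label(r[1]) == "TITLE" for r in records):
        raise JcampError("no ##TITLE= record found")

    blocks: list[JcampBlock] = []
    stack: list[dict] = []

    def close_block(blk: dict):
        if blk.get("is_link"):
            return
        blocks.append(_finish_block(blk))

    for lineno, label, value_lines in records:
        norm = _normalize_label(label)
        if norm == "TITLE":
            stack.append({
                "title": value_lines[0],
                "ldrs": {},
                "data": [],
                "ntuples": None,
            })
            stack[-1]["ldrs"]["TITLE"] = value_lines[0]
            continue
        if not stack:
            continue
        blk = stack[-1]
        if norm == "END":
            stack.pop()
            close_block(blk)
            continue
        if norm == "DATATYPE" and value_lines[0].strip().upper() == "LINK":
            blk["is_link"] = True
        if norm in ("XYDATA", "DATATABLE"):
            blk.setdefault("tables", []).append(
                (norm, value_lines[0], lineno, value_lines[1:], _line_numbers(lineno, value_lines))
            )
        elif norm == "PAGE":
            blk.setdefault("pages", []).append(value_lines[0].strip())
        elif norm == "PEAKTABLE":
            raise JcampError("unsupported data class: PEAK TABLE")
        else:
            blk["ldrs"][norm] = "\n".join(value_lines).strip()

    while stack:  # tolerate missing trailing ##END=
        blk = stack.pop()
        close_block(blk)
    return blocks


def _line_numbers(start: int, value_lines: list[str]) -> list[int]:
    return list(range(start, start + len(value_lines)))


def _finish_block(blk: dict) -> JcampBlock:
    ldrs = blk["ldrs"]
    out = JcampBlock(
        title=blk["title"],
        data_type=ldrs.get("DATATYPE", ""),
        ldrs=dict(ldrs),
        x_units=ldrs.get("XUNITS", ""),
    )
    tables = blk.get("tables", [])
    if not tables:
        return out

    is_ntuples = "NTUPLES" in ldrs or any(t[0] == "DATATABLE" for t in tables)
    if is_ntuples:
        return _finish_ntuples(blk, out)

    norm_kind, variable_list, lineno, body, linenos = tables[0]
    if "PEAK" in variable_list.upper():
        raise JcampError("unsupported data class: PEAK TABLE")
    y_factor = _parse_float(ldrs.get("YFACTOR", "1"), 1.0)
    x_factor = _parse_float(ldrs.get("XFACTOR", "1"), 1.0)
    out.y_factor = y_factor
    out.x_first = _parse_float(ldrs.get("FIRSTX", "0"))
    out.x_last = _parse_float(ldrs.get("LASTX", "0"))
    n_points = int(_parse_float(ldrs.get("NPOINTS", "0")))
    data = _decode_xydata(list(zip(linenos[1:], body)), y_factor)
    if n_points and len(data) != n_points:
        raise JcampError(
            f"##NPOINTS={n_points} but decoded {len(data)} y values"
        )
    out.n_points = len(data)
    out.data = data
    del x_factor  # x values come from FIRSTX/LASTX; per-line x only checked
    return out


def _finish_ntuples(blk: dict, out: JcampBlock) -> JcampBlock:
    """Assemble a complex FID from the R/I pages of an NTUPLES block."""
    ldrs = blk["ldrs"]

    def split_list(label: str) -> list[str]:
        raw = ldrs.get(label, "")
        return [v.strip() for v in raw.replace("\n", ",").split(",") if v.strip()]

    symbols = split_list("SYMBOL")
    factors = split_list("FACTOR")
    firsts = split_list("FIRST")
    lasts = split_list("LAST")
    var_dims = split_list("VARDIM")

    def column(values: list[str], sym: str, default: str) -> str:
        try:
            return values[symbols.index(sym)]
        except (ValueError, IndexError):
            return default

    pages = blk.get("pages", [])
    tables = blk.get("tables", [])
    page_data: dict[str, np.ndarray] = {}
    for page_desc, (kind, varlist, lineno, body, linenos) in zip(pages, tables):
        # variable list like "(X++(R..R)), XYDATA"
        m = re.search(r"\(X\+\+\((\w)\.\.\1\)\)", varlist)
        ysym = m.group(1) if m else "Y"
        y_factor = float(column(factors, ysym, "1") or 1)
        page_data[page_desc.split("=")[-1].strip()] = _decode_xydata(
            list(zip(linenos[1:], body)), y_factor
        )

    keys = sorted(page_data)
    if len(keys) == 2:
        real, imag = page_data[keys[0]], page_data[keys[1]]
        if len(real) != len(imag):
            raise JcampError("NTUPLES R and I pages have different lengths")
        out.data = real + 1j * imag
    elif len(keys) == 1:
        out.data = page_data[keys[0]]
    else:
        raise JcampError(f"NTUPLES block with {len(keys)} pages not supported")
    out.n_points = len(out.data)
    out.x_first = float(column(firsts, "X", "0") or 0)
    out.x_last = float(column(lasts, "X", "0") or 0)
    out.y_factor = float(column(factors, "R", "1") or 1)
    if not out.x_last and var_dims:
        n = int(float(column(var_dims, "X", "0") or 0))
        if n:
            out.x_last = out.x_first + (n - 1)
    return out


# ---------------------------------------------------------------------------
# writing

def _encode_affn(xs: np.ndarray, ints: np.ndarray) -> list[str]:
    lines = []
    i = 0
    n = len(ints)
    per_line = 8
    while i < n:
        chunk = ints[i : i + per_line]
        lines.append(_fmt(xs[i]) + " " + " ".join(str(int(v)) for v in chunk))
        i += per_line
    return lines


def _sqz_str(v: int) -> str:
    s = str(abs(v))
    lead = int(s[0])
    table = "@ABCDEFGHI" if v >= 0 else "@abcdefghi"
    return table[lead] + s[1:]


def _dif_str(v: int) -> str:
    s = str(abs(v))
    lead = int(s[0])
    table = "%JKLMNOPQR" if v >= 0 else "%jklmnopqr"
    return table[lead] + s[1:]


def _dup_str(count: int) -> str:
    s = str(count)
    lead = int(s[0])
    return "STUVWXYZ"[lead - 1] + s[1:] if lead < 9 else "s" + s[1:]


def _encode_difdup(xs: np.ndarray, ints: np.ndarray, width: int = 72) -> list[str]:
    """DIF/DUP encoding with SQZ line starts and checkpoint line openings."""
    lines: list[str] = []
    n = len(ints)
    i = 0
    while i < n:
        parts = [_fmt(xs[i]) + " ", _sqz_str(int(ints[i]))]
        length = len(parts[0]) + len(parts[1]) + 1
        j = i + 1
        tokens: list[str] = []
        while j < n:
            diff = int(ints[j]) - int(ints[j - 1])
            # count duplicates of this difference
            run = 1
            while j + run < n and int(ints[j + run]) - int(ints[j + run - 1]) == diff:
                run += 1
            tok = _dif_str(diff)
            if run > 1:
                tok += _dup_str(run)
            if length + len(tok) > width:
                break
            tokens.append(tok)
            length += len(tok)
            j += run
        lines.append("".join([parts[0], parts[1]] + tokens))
        if j >= n:
            if tokens:
                # line ended in DIF mode: emit the final checkpoint line
                lines.append(_fmt(xs[n - 1]) + " " + _sqz_str(int(ints[n - 1])))
            break
        # next line re-emits ints[j-1] as its SQZ checkpoint; a line that held
        # no DIF token at all continues with fresh data instead
        i = j - 1 if tokens else j
    return lines


def _fmt(x: float) -> str:
    # fixed-point only: an exponent "E" would be ambiguous with the SQZ digit
    # for 5 when an ASDF y value follows the x immediately
    s = f"{float(x):.6f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-0") else "0"


def _fmt_header(x: float) -> str:
    # header LDR values sit on their own line; keep full precision
    return repr(float(x))


def write_jcamp(block: JcampBlock, compression: str = "none") -> str:
    """Serialize a :class:`JcampBlock` to JCAMP-DX text.

    ``compression`` is ``"none"`` (AFFN) or ``"dif_dup"``.  Complex data are
    written as an NTUPLES block with separate real/imaginary pages.  Output
    re-parses to a block whose data match the input within one ``y_factor``
    quantization step.
    """
    if compression not in ("none", "dif_dup"):
        raise ValueError(f"unknown compression {compression!r}")
    data = np.asarray(block.data)
    if data.size and not np.all(np.isfinite(data if not np.iscomplexobj(data) else np.abs(data))):
        raise JcampError("non-finite data values cannot be written")
    if np.iscomplexobj(data):
        return _write_ntuples(block, data, compression)
    return _write_xydata(block, data.astype(float), compression)


def _choose_y_factor(values: np.ndarray) -> float:
    peak = float(np.max(np.abs(values))) if values.size else 0.0
    if peak == 0.0:
        return 1.0
    return peak / 32767.0


def _emit_series(xs, ints, compression):
    if compression == "dif_dup":
        return _encode_difdup(xs, ints)
    return _encode_affn(xs, ints)


def _header_ldrs(block: JcampBlock, extra: dict[str, str]) -> list[str]:
    lines = [f"##TITLE={block.title}", "##JCAMP-DX=5.01"]
    emitted = {"TITLE", "JCAMPDX"}
    for label, value in extra.items():
        lines.append(f"##{label}={value}")
        emitted.add(_normalize_label(label))
    skip = emitted | {
        "XYDATA", "DATATABLE", "END", "NPOINTS", "FIRSTX", "LASTX",
        "XFACTOR", "YFACTOR", "NTUPLES", "PAGE", "SYMBOL", "VARDIM",
        "FACTOR", "FIRST", "LAST", "VARNAME", "VARTYPE", "VARFORM",
        "UNITS", "ENDNTUPLES", "MINY", "MAXY", "FIRSTY",
    }
    for label, value in sorted(block.ldrs.items()):
        if _normalize_label(label) in skip:
            continue
        prefix = "##$" if label.startswith("$") else "##"
        lines.append(f"{prefix}{label.lstrip('$')}={value}")
    return lines


def _write_xydata(block: JcampBlock, data: np.ndarray, compression: str) -> str:
    n = len(data)
    y_factor = _choose_y_factor(data)
    ints = np.round(data / y_factor).astype(np.int64)
    xs = np.linspace(block.x_first, block.x_last, n) if n > 1 else np.array([block.x_first])
    lines = _header_ldrs(block, {
        "DATA TYPE": block.data_type or "NMR SPECTRUM",
        "XUNITS": block.x_units or "PPM",
        "YUNITS": "ARBITRARY UNITS",
        "XFACTOR": "1",
        "YFACTOR": _fmt_header(y_factor),
        "FIRSTX": _fmt_header(block.x_first),
        "LASTX": _fmt_header(block.x_last),
        "NPOINTS": str(n),
    })
    lines.append("##XYDATA=(X++(Y..Y))")
    lines.extend(_emit_series(xs, ints, compression))
    lines.append("##END=")
    return "\n".join(lines) + "\n"


def _write_ntuples(block: JcampBlock, data: np.ndarray, compression: str) -> str:
    n = len(data)
    xs = np.linspace(block.x_first, block.x_last, n) if n > 1 else np.array([block.x_first])
    rf = _choose_y_factor(data.real)
    imf = _choose_y_factor(data.imag)
    r_ints = np.round(data.real / rf).astype(np.int64)
    i_ints = np.round(data.imag / imf).astype(np.int64)
    dx = (block.x_last - block.x_first) / (n - 1) if n > 1 else 1.0
    lines = _header_ldrs(block, {
        "DATA TYPE": block.data_type or "NMR FID",
        "DATA CLASS": "NTUPLES",
    })
    lines += [
        f"##NTUPLES={block.data_type or 'NMR FID'}",
        "##VAR_NAME=TIME, FID/REAL, FID/IMAG",
        "##SYMBOL=X, R, I",
        "##VAR_TYPE=INDEPENDENT, DEPENDENT, DEPENDENT",
        "##VAR_FORM=AFFN, ASDF, ASDF",
        f"##VAR_DIM={n}, {n}, {n}",
        f"##UNITS={block.x_units or 'SECONDS'}, ARBITRARY UNITS, ARBITRARY UNITS",
        f"##FACTOR=1, {_fmt_header(rf)}, {_fmt_header(imf)}",
        f"##FIRST={_fmt_header(block.x_first)}, {_fmt_header(data.real[0]) if n else 0}, "
        f"{_fmt_header(data.imag[0]) if n else 0}",
        f"##LAST={_fmt_header(block.x_last)}, {_fmt_header(data.real[-1]) if n else 0}, "
        f"{_fmt_header(data.imag[-1]) if n else 0}",
        "##PAGE=N=1",
        f"##DATA TABLE=(X++(R..R)), XYDATA",
    ]
    lines.extend(_emit_series(xs, r_ints, compression))
    lines += ["##PAGE=N=2", "##DATA TABLE=(X++(I..I)), XYDATA"]
    lines.extend(_emit_series(xs, i_ints, compression))
    lines += ["##END NTUPLES=" + (block.data_type or "NMR FID"), "##END="]
    del dx
    return "\n".join(lines) + "\n"
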