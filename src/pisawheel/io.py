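"""Peak-list file formats: TSV (canonical) and Sparky assignment lists.

TSV is the interchange format for both spectral spaces:

    HSQC:  residue  h_ppm  n_ppm
    SLF:   residue  shift_ppm  coupling_khz

with an empty residue field for unassigned peaks.  Values are written at
fixed precision so write → read → write is byte-stable.  Sparky-style
lists (``Y47N-H  121.3  8.02``, w1 = ¹⁵N, w2 = ¹H) are read-only.
"""

from __future__ import annotations

import re
from pathlib import Path

from .csp import HNPeak
from .oriented_nmr import SLFPeak

__all__ = ["read_peaklist", "write_peaklist", "sniff_dialect"]

_HN_HEADER = ["residue", "h_ppm", "n_ppm"]
_SLF_HEADER = ["residue", "shift_ppm", "coupling_khz"]

# e.g. "Y47N-H", "Y47N-HN", "Y188N-H"
_SPARKY_LABEL = re.compile(r"^([A-Z])(\d+)N-HN?$")


def sniff_dialect(path: str | Path) -> str:
    """Guess 'tsv' or 'sparky' from the first non-blank line."""
    for line in Path(path).read_text().splitlines():
        tok = line.split()
        if not tok:
            continue
        if tok[0].lower() in ("residue",):
            return "tsv"
        if tok[0].lower() == "assignment":
            return "sparky"
        if _SPARKY_LABEL.match(tok[0]):
            return "sparky"
        return "tsv"
    raise ValueError(f"{path}: empty peak list")


def read_peaklist(path: str | Path, kind: str | None = None,
                  dialect: str | None = None) -> list[HNPeak] | list[SLFPeak]:
    """Read a peak list into typed peaks.

    ``kind`` is 'hn' or 'slf'; for TSV it is inferred from the header.
    Sparky lists are always HSQC-type ('hn').  Malformed lines raise with
    the offending line number.
    """
    path = Path(path)
    dialect = dialect or sniff_dialect(path)
    if dialect == "sparky":
        if kind not in (None, "hn"):
            raise ValueError("sparky lists hold H/N assignments only (kind='hn')")
        return _read_sparky(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    return _read_tsv(path, kind)


def _read_sparky(path: Path) -> list[HNPeak]:
    peaks: list[HNPeak] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        tok = line.split()
        if not tok or tok[0].lower() == "assignment":
            continue
        m = _SPARKY_LABEL.match(tok[0])
        if not m or len(tok) < 3:
            raise ValueError(f"{path}:{ln}: malformed sparky line: {line!r}")
        try:
            w1, w2 = float(tok[1]), float(tok[2])
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: non-numeric shift: {line!r}") from e
        peaks.append(HNPeak(h_ppm=w2, n_ppm=w1, residue=int(m.group(2))))
    if not peaks:
        raise ValueError(f"{path}: no peaks found")
    return peaks


def _read_tsv(path: Path, kind: str | None) -> list[HNPeak] | list[SLFPeak]:
    lines = path.read_text().splitlines()
    rows = [ln for ln in lines if ln.strip()]
    if not rows:
        raise ValueError(f"{path}: empty peak list")
    header = rows[0].split("\t")
    if header == _HN_HEADER:
        file_kind = "hn"
    elif header == _SLF_HEADER:
        file_kind = "slf"
    else:
        raise ValueError(
            f"{path}:1: unrecognized TSV header {header!r}; expected "
            f"{_HN_HEADER} or {_SLF_HEADER}"
        )
    if kind is not None and kind != file_kind:
        raise ValueError(f"{path}: header says kind={file_kind!r}, caller "
                         f"requested {kind!r}")
    peaks = []
    for ln, line in enumerate(rows[1:], start=2):
        tok = line.split("\t")
        if len(tok) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields: "
                             f"{line!r}")
        try:
            residue = int(tok[0]) if tok[0] != "" else None
            a, b = float(tok[1]), float(tok[2])
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: malformed line: {line!r}") from e
        if file_kind == "hn":
            peaks.append(HNPeak(h_ppm=a, n_ppm=b, residue=residue))
        else:
            peaks.append(SLFPeak(shift_ppm=a, coupling_khz=b, residue=residue))
    if not peaks:
        raise ValueError(f"{path}: no peaks found")
    return peaks


def write_peaklist(peaks: list[HNPeak] | list[SLFPeak],
                   path: str | Path) -> None:
    """Write peaks as canonical TSV (fixed 6-decimal precision)."""
    if not peaks:
        raise ValueError("cannot write an empty peak list")
    lines = []
    if isinstance(peaks[0], HNPeak):
        lines.append("\t".join(_HN_HEADER))
        for p in peaks:
            r = "" if p.residue is None else str(p.residue)
            lines.append(f"{r}\t{p.h_ppm:.6f}\t{p.n_ppm:.6f}")
    else:
        lines.append("\t".join(_SLF_HEADER))
        for p in peaks:
            r = "" if p.residue is None else str(p.residue)
            lines.append(f"{r}\t{p.shift_ppm:.6f}\t{p.coupling_khz:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
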