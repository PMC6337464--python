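"""Fixed-width parsing of PDB entries into typed section rowsets.

A PDB entry is a block of 80-column records; the first six columns name the
record type.  This module slices the five supported record types (ATOM,
HETATM, SHEET, HELIX, SEQRES) at the 1-based column positions of the wwPDB
format v3.3 dialect used by ``*.ent`` files, converts fields to their
semantic types, and returns an ordered :class:`pandas.DataFrame` rowset with
a fixed column schema.  Every row is supplemented with the entry's protein
identifier and, for coordinate records, the model number, so that rowsets
from many entries can be aggregated without losing provenance.

Files are decoded as Latin-1: PDB files are ASCII in practice and Latin-1
never raises, so a stray byte cannot abort an extraction run.
"""

from __future__ import annotations

import enum
import gzip
import math
import os
import zlib
from dataclasses import dataclass, fields as dc_fields
from typing import Any, BinaryIO, Callable, Iterable, Union

import pandas as pd

from .errors import CompressionError, MalformedLineError

__all__ = [
    "SectionKind",
    "AtomRow",
    "SheetRow",
    "HelixRow",
    "SeqresRow",
    "read_entry_text",
    "derive_protein_id",
    "parse_section_line",
    "extract_section",
    "section_columns",
]

GZIP_MAGIC = b"\x1f\x8b"

#: In-memory missing value for optional numeric fields; serialized as an
#: empty CSV field.
NULL = None


class SectionKind(enum.Enum):
    """The five PDB record sections the extractor supports."""

    ATOM = "ATOM"
    HETATM = "HETATM"
    SHEET = "SHEET"
    HELIX = "HELIX"
    SEQRES = "SEQRES"

    @classmethod
    def coerce(cls, value: "SectionKind | str") -> "SectionKind":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError:
            raise ValueError(
                f"unsupported section {value!r}; expected one of "
                f"{[k.name for k in cls]}"
            ) from None


@dataclass
class AtomRow:
    """One ATOM or HETATM coordinate record with entry/model context."""

    proteinId: str
    modelId: int
    recordName: str
    serial: int
    atomName: str
    altLoc: str
    resName: str
    chainId: str
    resSeq: int
    iCode: str
    x: float
    y: float
    z: float
    occupancy: float | None
    tempFactor: float | None
    element: str
    charge: str


@dataclass
class SheetRow:
    """One SHEET record locating a β-strand and its registration."""

    proteinId: str
    strand: int
    sheetId: str
    numStrands: int
    initResName: str
    initChainId: str
    initSeqNum: int
    initICode: str
    endResName: str
    endChainId: str
    endSeqNum: int
    endICode: str
    sense: int
    curAtom: str
    curResName: str
    curChainId: str
    curResSeq: int | None
    curICode: str
    prevAtom: str
    prevResName: str
    prevChainId: str
    prevResSeq: int | None
    prevICode: str


@dataclass
class HelixRow:
    """One HELIX record locating an α-helix."""

    proteinId: str
    serNum: int
    helixId: str
    initResName: str
    initChainId: str
    initSeqNum: int
    initICode: str
    endResName: str
    endChainId: str
    endSeqNum: int
    endICode: str
    helixClass: int
    comment: str
    length: int | None


@dataclass
class SeqresRow:
    """One SEQRES record: up to thirteen residue names of one chain."""

    proteinId: str
    serNum: int
    chainId: str
    numRes: int
    resName1: str = ""
    resName2: str = ""
    resName3: str = ""
    resName4: str = ""
    resName5: str = ""
    resName6: str = ""
    resName7: str = ""
    resName8: str = ""
    resName9: str = ""
    resName10: str = ""
    resName11: str = ""
    resName12: str = ""
    resName13: str = ""


# ---------------------------------------------------------------------------
# field tables: (name, first column, last column, converter, mandatory)
# columns are 1-based inclusive per the wwPDB v3.3 format description
# ---------------------------------------------------------------------------

def _text(s: str) -> str:
    return s.strip()


def _int(s: str) -> int:
    return int(s)


def _float(s: str) -> float:
    return float(s)


def _opt_int(s: str) -> int | None:
    s = s.strip()
    return int(s) if s else NULL


def _opt_float(s: str) -> float | None:
    s = s.strip()
    return float(s) if s else NULL


_FieldSpec = tuple[str, int, int, Callable[[str], Any], bool]

_ATOM_FIELDS: list[_FieldSpec] = [
    ("recordName", 1, 6, _text, True),
    ("serial", 7, 11, _int, True),
    ("atomName", 13, 16, _text, True),
    ("altLoc", 17, 17, _text, False),
    ("resName", 18, 20, _text, True),
    ("chainId", 22, 22, _text, False),
    ("resSeq", 23, 26, _int, True),
    ("iCode", 27, 27, _text, False),
    ("x", 31, 38, _float, True),
    ("y", 39, 46, _float, True),
    ("z", 47, 54, _float, True),
    ("occupancy", 55, 60, _opt_float, False),
    ("tempFactor", 61, 66, _opt_float, False),
    ("element", 77, 78, _text, False),
    ("charge", 79, 80, _text, False),
]

_SHEET_FIELDS: list[_FieldSpec] = [
    ("strand", 8, 10, _int, True),
    ("sheetId", 12, 14, _text, True),
    ("numStrands", 15, 16, _int, True),
    ("initResName", 18, 20, _text, True),
    ("initChainId", 22, 22, _text, False),
    ("initSeqNum", 23, 26, _int, True),
    ("initICode", 27, 27, _text, False),
    ("endResName", 29, 31, _text, True),
    ("endChainId", 33, 33, _text, False),
    ("endSeqNum", 34, 37, _int, True),
    ("endICode", 38, 38, _text, False),
    ("sense", 39, 40, _int, True),
    ("curAtom", 42, 45, _text, False),
    ("curResName", 46, 48, _text, False),
    ("curChainId", 50, 50, _text, False),
    ("curResSeq", 51, 54, _opt_int, False),
    ("curICode", 55, 55, _text, False),
    ("prevAtom", 57, 60, _text, False),
    ("prevResName", 61, 63, _text, False),
    ("prevChainId", 65, 65, _text, False),
    ("prevResSeq", 66, 69, _opt_int, False),
    ("prevICode", 70, 70, _text, False),
]

_HELIX_FIELDS: list[_FieldSpec] = [
    ("serNum", 8, 10, _int, True),
    ("helixId", 12, 14, _text, True),
    ("initResName", 16, 18, _text, True),
    ("initChainId", 20, 20, _text, False),
    ("initSeqNum", 22, 25, _int, True),
    ("initICode", 26, 26, _text, False),
    ("endResName", 28, 30, _text, True),
    ("endChainId", 32, 32, _text, False),
    ("endSeqNum", 34, 37, _int, True),
    ("endICode", 38, 38, _text, False),
    ("helixClass", 39, 40, _int, True),
    ("comment", 41, 70, _text, False),
    ("length", 72, 76, _opt_int, False),
]

_SEQRES_FIELDS: list[_FieldSpec] = [
    ("serNum", 8, 10, _int, True),
    ("chainId", 12, 12, _text, False),
    ("numRes", 14, 17, _int, True),
] + [
    (f"resName{i + 1}", 20 + 4 * i, 22 + 4 * i, _text, False)
    for i in range(13)
]

_FIELDS_BY_KIND: dict[SectionKind, list[_FieldSpec]] = {
    SectionKind.ATOM: _ATOM_FIELDS,
    SectionKind.HETATM: _ATOM_FIELDS,
    SectionKind.SHEET: _SHEET_FIELDS,
    SectionKind.HELIX: _HELIX_FIELDS,
    SectionKind.SEQRES: _SEQRES_FIELDS,
}

_ROW_CLASS: dict[SectionKind, type] = {
    SectionKind.ATOM: AtomRow,
    SectionKind.HETATM: AtomRow,
    SectionKind.SHEET: SheetRow,
    SectionKind.HELIX: HelixRow,
    SectionKind.SEQRES: SeqresRow,
}

# last column of the last mandatory field, per kind
_MIN_LINE_LEN: dict[SectionKind, int] = {
    kind: max(end for _, _, end, _, mandatory in specs if mandatory)
    for kind, specs in _FIELDS_BY_KIND.items()
}


def section_columns(kind: SectionKind | str) -> list[str]:
    """Column schema (ordered names) of the rowset for *kind*."""
    kind = SectionKind.coerce(kind)
    return [f.name for f in dc_fields(_ROW_CLASS[kind])]


# ---------------------------------------------------------------------------
# entry-level helpers
# ---------------------------------------------------------------------------

def read_entry_text(source: Union[str, os.PathLike, BinaryIO]) -> str:
    """Read one PDB entry as text, inflating gzip transparently.

    Compression is detected by the two gzip magic bytes, never by file
    extension, so misnamed files are handled correctly.  Plain text passes
    through unchanged.

    Raises :class:`CompressionError` for corrupt or truncated gzip streams.
    """
    if hasattr(source, "read"):
        data = source.read()
    else:
        with open(source, "rb") as fh:
            data = fh.read()
    if data[:2] == GZIP_MAGIC:
        try:
            data = gzip.decompress(data)
        except (OSError, EOFError, zlib.error) as exc:
            raise CompressionError(f"corrupt gzip stream: {exc}") from exc
    return data.decode("latin-1")


def derive_protein_id(entry_text: str, fallback: str) -> str:
    """Return the entry's 4-character idCode, or *fallback* when absent.

    The idCode sits at columns 63-66 of the HEADER record and is
    normalized to uppercase (PDB identifiers are case-insensitive).
    """
    for line in entry_text.splitlines():
        if line.startswith("HEADER"):
            id_code = line[62:66].strip()
            if id_code:
                return id_code.upper()
            break
    return fallback


def parse_section_line(
    line: str,
    kind: SectionKind | str,
    context: tuple[str, int] = ("", 1),
    line_number: int | None = None,
):
    """Parse one record line of section *kind* into its typed row.

    *context* is the ``(proteinId, modelId)`` pair the entry-level scan
    tracks; modelId is only meaningful for coordinate records.  Fields are
    sliced at fixed columns, trimmed, and converted; optional numeric fields
    that are blank map to the in-memory null.

    Raises :class:`MalformedLineError` when the line is shorter than its
    last mandatory column or a mandatory numeric field does not parse.
    """
    kind = SectionKind.coerce(kind)
    protein_id, model_id = context
    stripped = line.rstrip("\r\n")
    if len(stripped.rstrip()) < _MIN_LINE_LEN[kind]:
        raise MalformedLineError(
            f"{kind.name} record shorter than mandatory column "
            f"{_MIN_LINE_LEN[kind]}",
            line_number=line_number,
            line=stripped,
        )
    padded = stripped.ljust(80)
    values: dict[str, Any] = {"proteinId": protein_id}
    if _ROW_CLASS[kind] is AtomRow:
        values["modelId"] = model_id
    for name, first, last, convert, mandatory in _FIELDS_BY_KIND[kind]:
        raw = padded[first - 1:last]
        try:
            values[name] = convert(raw)
        except ValueError:
            raise MalformedLineError(
                f"field {name!r} of {kind.name} record does not parse: "
                f"{raw.strip()!r}",
                line_number=line_number,
                line=stripped,
            ) from None
    row = _ROW_CLASS[kind](**values)
    if isinstance(row, AtomRow) and not (
        math.isfinite(row.x) and math.isfinite(row.y) and math.isfinite(row.z)
    ):
        raise MalformedLineError(
            "non-finite coordinates", line_number=line_number, line=stripped
        )
    return row


def _record_name_matches(line: str, kind: SectionKind) -> bool:
    return line[:6].strip() == kind.value


def extract_section(
    entry_text: str,
    kind: SectionKind | str,
    fallback_id: str = "",
    strict: bool = True,
) -> pd.DataFrame:
    """Extract every record of section *kind* from one entry.

    Returns an ordered rowset (one row per matching line, in file order)
    with the fixed column schema of the section.  ``MODEL n`` / ``ENDMDL``
    records update the model context for coordinate rows; entries without
    MODEL records are model 1.  Non-matching lines are skipped.

    In strict mode a malformed matching line raises
    :class:`MalformedLineError`; in lenient mode it is skipped and counted
    in ``result.attrs["malformedLinesSkipped"]``.
    """
    kind = SectionKind.coerce(kind)
    protein_id = derive_protein_id(entry_text, fallback_id)
    model_id = 1
    rows: list[Any] = []
    skipped = 0
    for lineno, line in enumerate(entry_text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            try:
                model_id = int(line[10:14])
            except ValueError:
                model_id += 1
            continue
        if record != kind.value:
            continue
        try:
            rows.append(
                parse_section_line(line, kind, (protein_id, model_id), lineno)
            )
        except MalformedLineError:
            if strict:
                raise
            skipped += 1
    df = rows_to_frame(rows, kind)
    df.attrs["malformedLinesSkipped"] = skipped
    return df


def rows_to_frame(rows: Iterable[Any], kind: SectionKind | str) -> pd.DataFrame:
    """Assemble typed rows into the section's fixed-schema DataFrame."""
    kind = SectionKind.coerce(kind)
    columns = section_columns(kind)
    data = [[getattr(r, c) for c in columns] for r in rows]
    df = pd.DataFrame(data, columns=columns)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
    # nullable integer columns keep an integer face in CSV output
    for col in ("curResSeq", "prevResSeq", "length"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df
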