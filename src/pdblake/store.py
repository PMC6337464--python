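"""Sequential-file storage: build, partition and stream END-delimited records.

A *sequential file* is a plain concatenation of many PDB entries, each
terminated by its END record.  Concatenation is a pure byte-level operation
(the file is bit-exact with ``cat`` of members that already end with END),
so building one costs almost nothing, while downstream extraction can treat
each member entry as one unit of work without re-opening thousands of small
files.

The store enforces a maximum record size (default 4 MiB of decompressed
text): member entries above the cap are rejected at build time, and inputs
above the cap are routed to individual extraction by
:func:`partition_inputs`.  Iteration is streaming — memory never holds more
than one record plus one line.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO, Iterator, Union

from .errors import OversizeRecordError, TrailingDataError
from .reader import GZIP_MAGIC, read_entry_text

__all__ = [
    "StoreConfig",
    "EntryRecord",
    "decompressed_size",
    "partition_inputs",
    "concat_entries",
    "iter_records",
]

#: 4 MiB — the per-record cap of the extraction engine.
DEFAULT_MAX_RECORD_SIZE = 4 * 2**20

#: advisory size at which a sequential file is cut (entry boundaries only)
DEFAULT_TARGET_FILE_SIZE = 64 * 2**20


@dataclass
class StoreConfig:
    """Sizing and compression policy for sequential files.

    maxRecordSize is measured on decompressed text, because records are
    parsed decompressed.  targetFileSize is advisory: files are cut at the
    first entry boundary past it.
    """

    max_record_size: int = DEFAULT_MAX_RECORD_SIZE
    target_file_size: int = DEFAULT_TARGET_FILE_SIZE
    compress: bool = False

    def __post_init__(self) -> None:
        if self.max_record_size <= 0:
            raise ValueError("max_record_size must be positive")
        if self.target_file_size <= 0:
            raise ValueError("target_file_size must be positive")


@dataclass
class EntryRecord:
    """One complete PDB entry cut out of a sequential file."""

    index: int
    text: str
    byte_size: int


def _is_end_line(line: str) -> bool:
    # a line whose first token is exactly END terminates a record;
    # ENDMDL is a distinct record type and never does
    token = line.split(None, 1)
    return bool(token) and token[0] == "END"


def _ends_with_end(text: str) -> bool:
    for line in reversed(text.splitlines()):
        if line.strip():
            return _is_end_line(line)
    return False


def decompressed_size(path: Union[str, os.PathLike]) -> int:
    """Byte size of a file's decompressed content (streaming for gzip)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic != GZIP_MAGIC:
        return path.stat().st_size
    total = 0
    with gzip.open(path, "rb") as gz:
        while chunk := gz.read(1 << 20):
            total += len(chunk)
    return total


def partition_inputs(
    paths: list[Union[str, os.PathLike]],
    config: StoreConfig | None = None,
) -> tuple[list[Path], list[Path]]:
    """Split inputs into (small, large) around the record-size cap.

    Small files (decompressed size ≤ cap) are candidates for concatenation
    into sequential files; large ones must be extracted individually.  The
    two lists are disjoint and together cover the input, in input order.
    """
    config = config or StoreConfig()
    small: list[Path] = []
    large: list[Path] = []
    for p in paths:
        p = Path(p)
        if decompressed_size(p) <= config.max_record_size:
            small.append(p)
        else:
            large.append(p)
    return small, large


def normalize_entry(text: str) -> str:
    """Ensure an entry ends with a newline-terminated END record."""
    if not text.endswith("\n"):
        text += "\n"
    if not _ends_with_end(text):
        text += "END\n"
    return text


def _open_seq_output(path: Path, compress: bool) -> BinaryIO:
    if compress:
        # fixed mtime and no embedded name: identical input => identical bytes
        return gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"),
                             mtime=0)
    return open(path, "wb")


def concat_entries(
    paths: list[Union[str, os.PathLike]],
    config: StoreConfig | None = None,
    out_dir: Union[str, os.PathLike] = ".",
    prefix: str = "sequential",
) -> list[Path]:
    """Concatenate small PDB entries into one or more sequential files.

    Entries are appended verbatim, in input order; an END line is appended
    to any entry lacking one, so iteration always recovers the members.
    Output files are cut at entry boundaries once they pass
    ``config.target_file_size``, and are gzipped whole when
    ``config.compress`` is set.

    Raises :class:`OversizeRecordError` naming any input whose decompressed
    size exceeds the record cap.
    """
    config = config or StoreConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".ent.gz" if config.compress else ".ent"

    outputs: list[Path] = []
    sink: BinaryIO | None = None
    written = 0

    def open_next() -> BinaryIO:
        path = out_dir / f"{prefix}-{len(outputs):04d}{suffix}"
        outputs.append(path)
        return _open_seq_output(path, config.compress)

    try:
        for p in paths:
            text = normalize_entry(read_entry_text(p))
            blob = text.encode("latin-1")
            if len(blob) > config.max_record_size:
                raise OversizeRecordError(
                    f"{p}: entry is {len(blob)} bytes, exceeds record cap "
                    f"of {config.max_record_size}"
                )
            if sink is None:
                sink = open_next()
                written = 0
            sink.write(blob)
            written += len(blob)
            if written >= config.target_file_size:
                sink.close()
                sink = None
    finally:
        if sink is not None:
            sink.close()
    return outputs


def iter_records(
    source: Union[str, os.PathLike, BinaryIO],
    config: StoreConfig | None = None,
    strict: bool = True,
) -> Iterator[EntryRecord]:
    """Stream the member entries of a sequential file.

    Records are cut at lines whose first token is exactly ``END``
    (``ENDMDL`` never terminates a record).  Blank lines between records
    are tolerated and ignored.  Memory stays bounded by one record plus one
    line.

    Raises :class:`OversizeRecordError` if a record outgrows the cap before
    its END, and — in strict mode — :class:`TrailingDataError` when
    non-blank text follows the last END; in lenient mode that trailing
    block is yielded as a final record.
    """
    config = config or StoreConfig()
    if hasattr(source, "read"):
        stream: BinaryIO = source  # type: ignore[assignment]
        close = False
    else:
        stream = open(source, "rb")
        close = True
    try:
        head = stream.read(2)
        rest = io.BufferedReader(_Prepend(head, stream))  # type: ignore[arg-type]
        text_stream = gzip.open(rest, "rt", encoding="latin-1") \
            if head == GZIP_MAGIC \
            else io.TextIOWrapper(rest, encoding="latin-1")
        index = 0
        buffer: list[str] = []
        size = 0
        for line in text_stream:
            if not buffer and not line.strip():
                continue  # blank padding between records
            buffer.append(line)
            size += len(line.encode("latin-1"))
            if size > config.max_record_size:
                raise OversizeRecordError(
                    f"record {index} exceeds cap of "
                    f"{config.max_record_size} bytes before its END",
                    index=index,
                )
            if _is_end_line(line):
                yield EntryRecord(index, "".join(buffer), size)
                index += 1
                buffer = []
                size = 0
        if buffer:
            if strict:
                raise TrailingDataError(
                    f"{size} bytes of non-blank data after the last END "
                    f"delimiter (record {index})"
                )
            yield EntryRecord(index, normalize_entry("".join(buffer)), size)
    finally:
        if close:
            stream.close()


class _Prepend(io.RawIOBase):
    """Raw stream that replays sniffed magic bytes before the real stream."""

    def __init__(self, head: bytes, stream: BinaryIO):
        self._head = head
        self._stream = stream

    def readable(self) -> bool:
        return True

    def readinto(self, b) -> int:
        if self._head:
            n = min(len(b), len(self._head))
            b[:n] = self._head[:n]
            self._head = self._head[n:]
            return n
        data = self._stream.read(len(b))
        b[: len(data)] = data
        return len(data)
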