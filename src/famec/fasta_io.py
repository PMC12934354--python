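"""Byte-exact FASTA reading and writing.

The codec's lossless contract requires restoring input files byte for byte,
so this module captures formatting metadata that sequence-oriented parsers
normally discard: per-file sequence line width (or explicit per-record line
breaks when widths are irregular), line-ending style (LF/CRLF), presence of
a terminating newline, verbatim header bytes, and letter case of residues.

Sequence content is kept as raw bytes; nothing is interpreted beyond line
structure, so arbitrary IUPAC symbols, gaps and soft-masking survive a round
trip unchanged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import MalformedInputError

__all__ = [
    "SequenceRecord",
    "FastaFile",
    "CaseMask",
    "read_fasta_bytes",
    "read_collection",
    "write_fasta_bytes",
    "write_collection",
    "split_case",
    "apply_case",
]


@dataclass
class SequenceRecord:
    """One FASTA entry: verbatim header bytes (without '>') and residues.

    Residues are the concatenation of the record's sequence lines with line
    terminators removed; letter case is preserved.
    """

    header: bytes
    residues: bytes

    def __post_init__(self) -> None:
        if b"\n" in self.header or b"\r" in self.header:
            raise ValueError("header must not contain end-of-line bytes")
        if b"\n" in self.residues or b"\r" in self.residues:
            raise ValueError("residues must not contain end-of-line bytes")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FastaFile:
    """A parsed FASTA file plus the metadata needed to rewrite it exactly.

    ``line_length`` is the common sequence line width when it is consistent
    throughout the file, else ``None`` ("irregular"); irregular files carry
    explicit per-record line lengths in ``line_breaks`` and are replayed
    verbatim on write.
    """

    path: str
    records: list[SequenceRecord] = field(default_factory=list)
    line_length: int | None = None
    line_breaks: list[list[int]] | None = None  # per record, when irregular
    crlf: bool = False
    trailing_newline: bool = True
    empty: bool = False  # a genuinely zero-byte file

    @property
    def raw_size(self) -> int:
        return len(write_fasta_bytes(self))


@dataclass
class CaseMask:
    """Run-length encoding of lowercase (soft-masked) stretches of a record.

    Runs alternate between lower and upper case and cover the record exactly;
    ``first_lower`` gives the case of the first run. An empty record has no
    runs.
    """

    run_lengths: list[int]
    first_lower: bool

    def total(self) -> int:
        return sum(self.run_lengths)


# ---------------------------------------------------------------------------
# reading


def read_fasta_bytes(data: bytes, path: str = "<bytes>") -> FastaFile:
    """Parse FASTA bytes into a :class:`FastaFile`.

    Raises :class:`MalformedInputError` when the first non-empty line does
    not start with '>', or when LF and CRLF line endings are mixed.
    """
    if data == b"":
        return FastaFile(path=path, records=[], line_length=None, line_breaks=[],
                         crlf=False, trailing_newline=False, empty=True)

    trailing_newline = data.endswith(b"\n")
    parts = data.split(b"\n")
    if trailing_newline:
        parts = parts[:-1]
    n_terminated = len(parts) if trailing_newline else len(parts) - 1

    crlf_flags = [parts[i].endswith(b"\r") for i in range(n_terminated)]
    if any(crlf_flags) and not all(crlf_flags):
        raise MalformedInputError("mixed LF/CRLF line endings", path=path)
    crlf = bool(crlf_flags) and all(crlf_flags)
    lines = [p[:-1] if (i < n_terminated and crlf) else p for i, p in enumerate(parts)]

    # Locate the first non-empty line; it must be a header.
    offset = 0
    eol = 2 if crlf else 1
    first = None
    for i, ln in enumerate(lines):
        if ln != b"":
            first = i
            break
        offset += len(ln) + eol
    if first is None or not lines[first].startswith(b">"):
        raise MalformedInputError("missing '>' on first non-empty line",
                                  path=path, offset=offset)
    if first != 0:
        raise MalformedInputError("blank lines before the first record",
                                  path=path, offset=0)

    records: list[SequenceRecord] = []
    line_breaks: list[list[int]] = []
    cur_header: bytes | None = None
    cur_chunks: list[bytes] = []
    cur_lens: list[int] = []

    def flush() -> None:
        if cur_header is None:
            return
        records.append(SequenceRecord(cur_header, b"".join(cur_chunks)))
        line_breaks.append(list(cur_lens))

    for ln in lines:
        if ln.startswith(b">"):
            flush()
            cur_header = ln[1:]
            cur_chunks = []
            cur_lens = []
        else:
            cur_chunks.append(ln)
            cur_lens.append(len(ln))
    flush()

    return FastaFile(path=path, records=records,
                     line_length=_uniform_width(line_breaks),
                     line_breaks=line_breaks, crlf=crlf,
                     trailing_newline=trailing_newline)


def _uniform_width(line_breaks: list[list[int]]) -> int | None:
    """The common line width, or None when the file is irregular.

    A file is uniform when one width L reproduces every record by chunking:
    all non-terminal lines equal L and each terminal line is in (0, L].
    Files whose records are all single-line adopt the longest line as L.
    """
    non_terminal: set[int] = set()
    terminal: list[int] = []
    for lens in line_breaks:
        if not lens:
            continue
        non_terminal.update(lens[:-1])
        terminal.append(lens[-1])
    if len(non_terminal) > 1:
        return None
    if non_terminal:
        width = next(iter(non_terminal))
    elif terminal:
        width = max(terminal)
    else:
        return None  # no sequence lines at all
    if any(t == 0 or t > width for t in terminal):
        return None
    return width


def read_collection(paths: list[str | os.PathLike], root: str | None = None) -> list[FastaFile]:
    """Read FASTA files preserving order; paths are stored relative to *root*
    (or verbatim when *root* is None)."""
    out = []
    for p in paths:
        p = os.fspath(p)
        with open(p, "rb") as fh:
            data = fh.read()
        rel = os.path.relpath(p, root) if root is not None else p
        out.append(read_fasta_bytes(data, path=rel.replace(os.sep, "/")))
    return out


# ---------------------------------------------------------------------------
# writing


def write_fasta_bytes(f: FastaFile) -> bytes:
    """Serialize a :class:`FastaFile` back to bytes (inverse of reading)."""
    if f.empty and not f.records:
        return b""
    eol = b"\r\n" if f.crlf else b"\n"
    lines: list[bytes] = []
    for ri, rec in enumerate(f.records):
        lines.append(b">" + rec.header)
        res = rec.residues
        if f.line_length is not None:
            width = f.line_length
            for i in range(0, len(res), width):
                lines.append(res[i:i + width])
        else:
            lens = f.line_breaks[ri] if f.line_breaks is not None else [len(res)]
            pos = 0
            for ll in lens:
                lines.append(res[pos:pos + ll])
                pos += ll
    body = eol.join(lines)
    if f.trailing_newline:
        body += eol
    return body


def write_collection(files: list[FastaFile], destination: str | os.PathLike) -> list[str]:
    """Write files under *destination*, refusing path traversal; returns the
    written absolute paths."""
    dest = os.path.abspath(os.fspath(destination))
    written = []
    for f in files:
        target = os.path.abspath(os.path.join(dest, f.path))
        if os.path.commonpath([dest, target]) != dest:
            raise MalformedInputError("path escapes destination root", path=f.path)
        os.makedirs(os.path.dirname(target), exist_ok=True)
        with open(target, "wb") as fh:
            fh.write(write_fasta_bytes(f))
        written.append(target)
    return written


# ---------------------------------------------------------------------------
# case handling


def split_case(residues: bytes) -> tuple[bytes, CaseMask]:
    """Uppercase *residues* and return the mask that restores the original.

    The mask is minimal: adjacent runs always differ in case.
    """
    if not residues:
        return b"", CaseMask([], False)
    arr = np.frombuffer(residues, dtype=np.uint8)
    lower = (arr >= 97) & (arr <= 122)
    change = np.flatnonzero(np.diff(lower.view(np.int8)))
    bounds = np.concatenate(([0], change + 1, [len(arr)]))
    run_lengths = np.diff(bounds).tolist()
    return residues.upper(), CaseMask(run_lengths, bool(lower[0]))


def apply_case(upper: bytes, mask: CaseMask) -> bytes:
    """Invert :func:`split_case`."""
    if mask.total() != len(upper):
        raise ValueError("case mask does not cover the residues")
    if not mask.run_lengths:
        return upper
    out = bytearray(upper)
    pos = 0
    is_lower = mask.first_lower
    for length in mask.run_lengths:
        if is_lower:
            out[pos:pos + length] = upper[pos:pos + length].lower()
        pos += length
        is_lower = not is_lower
    return bytes(out)
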