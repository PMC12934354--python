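"""The on-disk archive container.

Layout (all integers unsigned LEB128 varints, documented in
docs/FORMAT.md): magic ``FAMC``, one version byte, a JSON parameter block,
a JSON file table (path, record count, raw size, 64-bit content hash), a
stream directory (id, raw length, flag-bit count, compressed length per
stream), then the stream payloads, each compressed independently with the
LZMA backend. Listing reads only the header; nothing before the payloads
depends on them, so content listing never decompresses sequence data.
"""

from __future__ import annotations

import fnmatch
import json
import lzma
import os

from .approx_codec import CodecConfig, decode_collection, encode_collection
from .errors import (CorruptArchiveError, DuplicatePathError, HashMismatchError,
                     NotFoundError, TruncatedArchiveError)
from .fasta_io import FastaFile, write_collection, write_fasta_bytes
from .util import read_varint, write_varint

__all__ = ["MAGIC", "VERSION", "STREAM_IDS", "pack", "unpack", "compress",
           "decompress", "list_contents", "extract", "append", "repack"]

MAGIC = b"FAMC"
VERSION = 1

STREAM_IDS = ["literals", "flags", "offsets", "lengths", "gaps_delta",
              "extents", "gap_lengths", "packed", "pack_lengths",
              "headers", "meta"]

# per-stream payload codec: raw-format LZMA2 (headerless; the preset lives
# in the archive's parameter block), or stored verbatim when smaller
CODEC_STORED = 0
CODEC_LZMA = 1


def _filters(preset: int) -> list[dict]:
    # pb=0/lc=0 suits the streams here (varints, flags, small-alphabet
    # literals) better than the text-oriented defaults
    return [{"id": lzma.FILTER_LZMA2, "preset": preset | lzma.PRESET_EXTREME,
             "pb": 0, "lc": 0}]


def _compress_payload(raw: bytes, preset: int) -> tuple[int, bytes]:
    blob = lzma.compress(raw, format=lzma.FORMAT_RAW, filters=_filters(preset))
    if len(blob) >= len(raw):
        return CODEC_STORED, raw
    return CODEC_LZMA, blob


def _decompress_payload(blob: bytes, codec: int, raw_len: int, preset: int,
                        name: str) -> bytes:
    if codec == CODEC_STORED:
        raw = blob
    elif codec == CODEC_LZMA:
        try:
            raw = lzma.decompress(blob, format=lzma.FORMAT_RAW,
                                  filters=_filters(preset))
        except lzma.LZMAError as exc:
            raise CorruptArchiveError(
                f"stream {name!r} fails to decompress: {exc}") from None
    else:
        raise CorruptArchiveError(f"unknown payload codec {codec}")
    if len(raw) != raw_len:
        raise CorruptArchiveError(
            f"stream {name!r} decompressed to {len(raw)} bytes, expected {raw_len}")
    return raw


def _json_block(obj) -> bytes:
    payload = json.dumps(obj, sort_keys=True, separators=(",", ":")).encode()
    codec, blob = _compress_payload(payload, 6)
    out = bytearray()
    out.append(codec)
    write_varint(out, len(payload))
    write_varint(out, len(blob))
    out += blob
    return bytes(out)


def pack(streams, table: list[dict], cfg: CodecConfig, *,
         flag_bits: int | None = None) -> bytes:
    """Serialize finalized streams plus metadata into archive bytes."""
    raw = streams.finalized() if hasattr(streams, "finalized") else dict(streams)
    bits = streams.flag_bits if hasattr(streams, "flag_bits") else flag_bits
    out = bytearray()
    out += MAGIC
    out.append(VERSION)
    out += _json_block(cfg.to_dict())
    out += _json_block(table)
    payloads = []
    directory = bytearray()
    write_varint(directory, len(STREAM_IDS))
    for sid, name in enumerate(STREAM_IDS):
        data = raw[name]
        codec, blob = _compress_payload(data, cfg.backend_preset)
        write_varint(directory, sid)
        write_varint(directory, codec)
        write_varint(directory, len(data))
        write_varint(directory, bits if name == "flags" else 0)
        write_varint(directory, len(blob))
        payloads.append(blob)
    out += directory
    for blob in payloads:
        out += blob
    return bytes(out)


def _parse_header(archive: bytes):
    """Parse everything before the payloads; returns
    (params_dict, table, directory, payload_offset)."""
    if len(archive) < 5:
        raise TruncatedArchiveError("archive shorter than its magic")
    if archive[:4] != MAGIC:
        raise CorruptArchiveError("bad magic: not a famec archive")
    version = archive[4]
    if version > VERSION:
        raise CorruptArchiveError(
            f"archive version {version} is ahead of this implementation")
    pos = 5

    def block(pos):
        if pos >= len(archive):
            raise TruncatedArchiveError("JSON block extends past end of archive")
        codec = archive[pos]
        raw_len, pos = read_varint(archive, pos + 1)
        comp_len, pos = read_varint(archive, pos)
        if pos + comp_len > len(archive):
            raise TruncatedArchiveError("JSON block extends past end of archive")
        data = _decompress_payload(archive[pos:pos + comp_len], codec,
                                   raw_len, 6, "metadata")
        try:
            obj = json.loads(data)
        except json.JSONDecodeError as exc:
            raise CorruptArchiveError(f"undecodable metadata block: {exc}") from None
        return obj, pos + comp_len

    params, pos = block(pos)
    table, pos = block(pos)
    n_streams, pos = read_varint(archive, pos)
    directory = []
    for _ in range(n_streams):
        sid, pos = read_varint(archive, pos)
        codec, pos = read_varint(archive, pos)
        raw_len, pos = read_varint(archive, pos)
        bits, pos = read_varint(archive, pos)
        comp_len, pos = read_varint(archive, pos)
        if sid >= len(STREAM_IDS):
            raise CorruptArchiveError(f"unknown stream id {sid}")
        directory.append((STREAM_IDS[sid], codec, raw_len, bits, comp_len))
    return params, table, directory, pos


def unpack(archive: bytes):
    """Inverse of :func:`pack`: returns (raw streams, flag_bits, table, cfg)."""
    params, table, directory, pos = _parse_header(archive)
    preset = int(params.get("backend_preset", 6))
    raw = {}
    flag_bits = 0
    for name, codec, raw_len, bits, comp_len in directory:
        if pos + comp_len > len(archive):
            raise TruncatedArchiveError(
                f"payload of stream {name!r} is truncated")
        raw[name] = _decompress_payload(archive[pos:pos + comp_len], codec,
                                        raw_len, preset, name)
        if name == "flags":
            flag_bits = bits
        pos += comp_len
    if pos != len(archive):
        raise CorruptArchiveError(f"{len(archive) - pos} trailing bytes after payloads")
    missing = [n for n in STREAM_IDS if n not in raw]
    if missing:
        raise CorruptArchiveError(f"archive lacks streams: {missing}")
    try:
        cfg = CodecConfig(**params)
    except (TypeError, ValueError) as exc:
        raise CorruptArchiveError(f"invalid codec parameters: {exc}") from None
    return raw, flag_bits, table, cfg


# ---------------------------------------------------------------------------
# high-level operations


def compress(files: list[FastaFile], cfg: CodecConfig | None = None) -> bytes:
    """Encode a collection into archive bytes."""
    cfg = cfg or CodecConfig()
    streams, table = encode_collection(files, cfg)
    return pack(streams, table, cfg)


def _decode_all(archive: bytes, cfg_override: CodecConfig | None = None):
    raw, flag_bits, table, cfg = unpack(archive)
    files = decode_collection(raw, flag_bits, table, cfg)
    return files, table, cfg

def _verify(files: list[FastaFile], table: list[dict],
            only: set[str] | None = None) -> None:
    import hashlib
    by_path = {e["path"]: e for e in table}
    for f in files:
        if only is not None and f.path not in only:
            continue
        digest = hashlib.blake2b(write_fasta_bytes(f), digest_size=8).hexdigest()
        if digest != by_path[f.path]["hash"]:
            raise HashMismatchError(f.path)


def decompress(archive: bytes) -> list[FastaFile]:
    """Full decode with per-file content verification."""
    files, table, _ = _decode_all(archive)
    _verify(files, table)
    return files


def list_contents(archive: bytes) -> list[dict]:
    """File table (paths, record counts, raw sizes) from the header alone;
    sequence payloads are never decompressed."""
    _, table, _, _ = _parse_header(archive)
    return [dict(e) for e in table]


def _select(table: list[dict], selector) -> list[str]:
    paths = [e["path"] for e in table]
    if isinstance(selector, str):
        chosen = fnmatch.filter(paths, selector)
        if not chosen:
            import difflib
            near = difflib.get_close_matches(selector, paths, n=3)
            hint = f"; close matches: {near}" if near else ""
            raise NotFoundError(f"selector {selector!r} matches no file{hint}")
        return chosen
    missing = [s for s in selector if s not in paths]
    if missing or not selector:
        raise NotFoundError(f"paths not in archive: {missing or selector}")
    return list(selector)


def extract(archive: bytes, selector, destination: str | os.PathLike) -> list[str]:
    """Restore the files matched by *selector* (glob string or path list)
    under *destination*, byte-exact. Decoding replays the reference buffer
    over all prior contigs, so mid-collection extraction is correct albeit
    not faster than a full pass."""
    files, table, _ = _decode_all(archive)
    chosen = set(_select(table, selector))
    picked = [f for f in files if f.path in chosen]
    _verify(picked, table, only=chosen)
    return write_collection(picked, destination)


def append(archive: bytes, new_files: list[FastaFile]) -> bytes:
    """Add files to an existing archive.

    Duplicate paths are rejected before any decoding work; the existing
    collection is then decoded to rebuild the reference state and the whole
    collection is re-encoded with the archive's own parameters.
    """
    _, _, table, cfg = unpack(archive)
    existing = {e["path"] for e in table}
    for f in new_files:
        if f.path in existing:
            raise DuplicatePathError(f"path already in archive: {f.path!r}")
    if not new_files:
        return archive
    files, table, cfg = _decode_all(archive)
    _verify(files, table)
    return compress(files + list(new_files), cfg)


def repack(archive: bytes, new_cfg: CodecConfig) -> bytes:
    """Re-encode the archived collection under different parameters."""
    files, table, _ = _decode_all(archive)
    _verify(files, table)
    return compress(files, new_cfg)
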