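"""Approximate-match encoding and decoding of contigs.

A contig is serialized into logical streams (Fig.-style architecture):
matched intervals become a MATCH_MARK in the literals stream with their
lengths and (explicit or delta-derived) reference offsets in side streams;
the surroundings are coded relative to the reference wherever profitable:

* encoding in gaps — a nonempty region between two adjacent same-diagonal
  forward matches is aligned base-by-base with its equal-length reference
  counterpart: a 0 flag per matching base, a 1 flag plus an exclusive
  mismatch code per mismatching base;
* adjacent encoding — outside gaps, relative coding extends from a match
  boundary into the unmatched neighborhood, driven by a mismatch scoring
  automaton (initial score Y, ±100/x per base, termination at 100 %); the
  boundary base is a guaranteed mismatch and is coded without a flag;
* the exclusive mismatch matrix maps each mismatching base, given its
  reference base, to {0,1,2} (transitions first, then the A/T partner), with
  3 escaping a raw non-ACGT byte.

Every byte of the original residues is recoverable: regions not worth
relative coding stay as raw literals, and block markers keep the literal
stream self-describing for the decoder.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .dna import A, C, G, T, BASE2BITS, acgt_mask, is_acgt_byte, map_to_acgt, revcomp_bytes
from .errors import CorruptArchiveError
from .fasta_io import CaseMask, FastaFile, SequenceRecord, apply_case, split_case, write_fasta_bytes
from .match_model import LinkTracker, compute_links, gap_breaks_filter
from .mem_index import FORWARD, Match, ReferenceBuffer, select_matches, update_reference
from .util import BitReader, BitWriter, VarintReader, encode_varints, write_varint

__all__ = ["CodecConfig", "MismatchMatrix", "EncodingStreams", "StreamCursors",
           "ESCAPE", "MATCH_MARK", "SEQ_MARK",
           "mismatch_code", "mismatch_decode", "encode_gap", "encode_adjacent",
           "encode_contig", "decode_contig", "encode_collection", "decode_collection"]

# literal-stream byte assignments: codes 0-3, then block markers, all disjoint
# from residue bytes; '%' kept as the match mark
CODE_MAX = 3
ESCAPE = 3
SEQ_MARK = 0x04
LEFT_MARK = 0x05
RIGHT_MARK = 0x06
GAP_MARK = 0x07
ESC = 0x08
PACK_MARK = 0x09  # long ACGT run stored 2-bit-packed in the packed stream
MATCH_MARK = 0x25  # '%'

_RESERVED = frozenset({0, 1, 2, 3, SEQ_MARK, LEFT_MARK, RIGHT_MARK,
                       GAP_MARK, ESC, PACK_MARK, MATCH_MARK})

# raw ACGT runs at least this long are 2-bit packed; shorter runs stay as
# text so the escape machinery and LZMA handle them
_PACK_MIN_RUN = 64

_BITS2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _acgt_runs(arr: np.ndarray, min_run: int):
    """Maximal runs of ACGT bytes in *arr* of at least *min_run* bases,
    as (start, end) pairs."""
    if len(arr) < min_run:
        return
    mask = acgt_mask(arr)
    edges = np.flatnonzero(np.diff(mask.view(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [len(arr)]))
    for i in range(len(bounds) - 1):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if mask[s] and e - s >= min_run:
            yield s, e


def _pack2bit(arr: np.ndarray) -> bytes:
    """4 bases per byte, first base in the low bits; zero-padded tail."""
    bits = BASE2BITS[arr].astype(np.uint8)
    pad = (-len(bits)) % 4
    if pad:
        bits = np.concatenate([bits, np.zeros(pad, dtype=np.uint8)])
    q = bits.reshape(-1, 4)
    packed = q[:, 0] | (q[:, 1] << 2) | (q[:, 2] << 4) | (q[:, 3] << 6)
    return packed.tobytes()


def _unpack2bit(data: bytes, n_bases: int) -> bytes:
    arr = np.frombuffer(data, dtype=np.uint8)
    out = np.empty((len(arr), 4), dtype=np.uint8)
    out[:, 0] = arr & 3
    out[:, 1] = (arr >> 2) & 3
    out[:, 2] = (arr >> 4) & 3
    out[:, 3] = (arr >> 6) & 3
    return _BITS2BASE[out.reshape(-1)[:n_bases]].tobytes()


@dataclass
class CodecConfig:
    """All tunable codec parameters and per-technique ablation switches.

    ``score_initial`` (Y) and ``score_step_x`` (x) parameterize the adjacent
    encoding automaton: the per-base penalty/bonus is 100/x percent and
    encoding terminates at a 100 % score. ``gap_breaks_max`` is the strict
    upper bound on lengths the gap-breaks filter may remove;
    ``corr_window`` bounds how many matches may sit between corresponding
    matches. ``ref_extend_threshold`` is the matched-base fraction below
    which a contig joins the reference buffer.
    """

    k: int = 16
    min_match_length: int = 16
    sampling: int = 1
    score_initial: int = 25
    score_step_x: int = 10
    gap_breaks_max: int = 256
    corr_window: int = 64
    ref_extend_threshold: float = 0.5
    ref_cap: int = 1 << 28
    backend_preset: int = 6
    use_gaps_delta: bool = True
    use_gap_breaks: bool = True
    use_gap_encoding: bool = True
    use_adjacent: bool = True
    use_mismatch_matrix: bool = True

    def __post_init__(self) -> None:
        if self.k < 8 or self.min_match_length < self.k:
            raise ValueError("need k >= 8 and min_match_length >= k")
        if not 1 <= self.score_step_x:
            raise ValueError("score_step_x must be >= 1")
        if not 0 <= self.score_initial <= 100:
            raise ValueError("score_initial must be a percentage in [0, 100]")
        if not 0.0 <= self.ref_extend_threshold <= 1.0:
            raise ValueError("ref_extend_threshold must be in [0, 1]")

    # integer scoring in units of percent·x keeps the automaton exact for
    # any x: step 100/x percent -> 100 units, threshold -> 100*x units
    @property
    def score_threshold_units(self) -> int:
        return 100 * self.score_step_x

    @property
    def score_initial_units(self) -> int:
        return self.score_initial * self.score_step_x

    def to_dict(self) -> dict:
        return asdict(self)


class MismatchMatrix:
    """Exclusive mismatch encoding matrix over {A,C,G,T}.

    For each reference base the three other bases map bijectively onto
    {0,1,2}: 0 is the transition partner (A<->G, C<->T), 1 the A/T member of
    the remaining pair, 2 the last base — transitions and AT-richness get
    the cheap codes. Non-ACGT contig bytes use ESCAPE (3) followed by the
    raw byte.
    """

    _TRANSITION = {A: G, G: A, C: T, T: C}

    def __init__(self) -> None:
        self.encode_map: dict[tuple[int, int], int] = {}
        self.decode_map: dict[tuple[int, int], int] = {}
        for r in (A, C, G, T):
            ordered = [self._TRANSITION[r]]
            rest = [b for b in (A, C, G, T) if b != r and b != ordered[0]]
            at = [b for b in rest if b in (A, T)]
            other = [b for b in rest if b not in (A, T)]
            ordered += at + other
            for code, b in enumerate(ordered):
                self.encode_map[(r, b)] = code
                self.decode_map[(r, code)] = b

    def code(self, ref_base: int, contig_base: int) -> int:
        if contig_base == ref_base:
            raise ValueError("mismatch codes are exclusive: bases are equal")
        if not is_acgt_byte(ref_base):
            raise ValueError("reference base must be ACGT")
        if not is_acgt_byte(contig_base):
            return ESCAPE
        return self.encode_map[(ref_base, contig_base)]

    def decode(self, ref_base: int, code: int) -> int:
        try:
            return self.decode_map[(ref_base, code)]
        except KeyError:
            raise CorruptArchiveError(
                f"invalid mismatch code {code} for reference base {chr(ref_base)}"
            ) from None


MATRIX = MismatchMatrix()


def mismatch_code(ref_base: int | str, contig_base: int | str) -> int:
    """Module-level convenience over the shipped matrix."""
    if isinstance(ref_base, str):
        ref_base = ord(ref_base)
    if isinstance(contig_base, str):
        contig_base = ord(contig_base)
    return MATRIX.code(ref_base, contig_base)


def mismatch_decode(ref_base: int | str, code: int) -> int:
    if isinstance(ref_base, str):
        ref_base = ord(ref_base)
    return MATRIX.decode(ref_base, code)


# ---------------------------------------------------------------------------
# streams


class EncodingStreams:
    """The logical output streams an encoder fills, per collection."""

    def __init__(self) -> None:
        self.literals = bytearray()
        self.flags = BitWriter()
        self.offsets: list[int] = []    # (ref_start << 1) | strand, explicit only
        self.lengths: list[int] = []    # length - min_match_length
        self.gaps_delta: list[int] = []
        self.extents: list[int] = []    # adjacency truncation entries
        self.gap_lengths: list[int] = []  # one length per gap-coded region
        self.packed = bytearray()       # 2-bit-packed long ACGT literal runs
        self.pack_lengths: list[int] = []
        self.headers = bytearray()
        self.meta = bytearray()         # varint-coded per-file/record metadata

    def emit_literal(self, byte: int) -> None:
        self.literals.append(byte)

    def meta_varint(self, value: int) -> None:
        write_varint(self.meta, value)

    def emit_raw(self, data: bytes) -> None:
        """Top-level raw residues.

        Long pure-ACGT stretches are stored 2-bit packed in the dedicated
        packed stream (announced by PACK_MARK); everything else goes to the
        literals verbatim, with reserved byte values ESC-escaped.
        """
        pos = 0
        arr = np.frombuffer(data, dtype=np.uint8)
        for start, end in _acgt_runs(arr, _PACK_MIN_RUN):
            self._emit_text(data[pos:start])
            self.literals.append(PACK_MARK)
            self.pack_lengths.append(end - start)
            self.packed += _pack2bit(arr[start:end])
            pos = end
        self._emit_text(data[pos:])

    def _emit_text(self, data: bytes) -> None:
        for b in data:
            if b in _RESERVED:
                self.literals.append(ESC)
            self.literals.append(b)

    def finalized(self) -> dict[str, bytes]:
        return {
            "literals": bytes(self.literals),
            "flags": self.flags.getvalue(),
            "offsets": encode_varints(self.offsets),
            "lengths": encode_varints(self.lengths),
            "gaps_delta": encode_varints(self.gaps_delta),
            "extents": encode_varints(self.extents),
            "gap_lengths": encode_varints(self.gap_lengths),
            "packed": bytes(self.packed),
            "pack_lengths": encode_varints(self.pack_lengths),
            "headers": bytes(self.headers),
            "meta": bytes(self.meta),
        }

    @property
    def flag_bits(self) -> int:
        return self.flags.n_bits


class StreamCursors:
    """Sequential read cursors over unpacked streams, for decoding."""

    def __init__(self, raw: dict[str, bytes], flag_bits: int):
        self.literals = raw["literals"]
        self.lit_pos = 0
        self.flags = BitReader(raw["flags"], flag_bits)
        self.offsets = VarintReader(raw["offsets"], "offsets")
        self.lengths = VarintReader(raw["lengths"], "lengths")
        self.gaps_delta = VarintReader(raw["gaps_delta"], "gaps_delta")
        self.extents = VarintReader(raw["extents"], "extents")
        self.gap_lengths = VarintReader(raw["gap_lengths"], "gap_lengths")
        self.packed = raw["packed"]
        self.packed_pos = 0
        self.pack_lengths = VarintReader(raw["pack_lengths"], "pack_lengths")
        self.headers = raw["headers"]
        self.head_pos = 0
        self.meta = VarintReader(raw["meta"], "meta")

    def next_packed(self, n_bases: int) -> bytes:
        n_bytes = (n_bases + 3) // 4
        if self.packed_pos + n_bytes > len(self.packed):
            raise CorruptArchiveError("packed stream exhausted")
        chunk = self.packed[self.packed_pos:self.packed_pos + n_bytes]
        self.packed_pos += n_bytes
        return _unpack2bit(chunk, n_bases)

    def next_literal(self) -> int:
        if self.lit_pos >= len(self.literals):
            raise CorruptArchiveError(
                f"literals stream exhausted at offset {self.lit_pos}")
        b = self.literals[self.lit_pos]
        self.lit_pos += 1
        return b

    def next_header(self) -> bytes:
        end = self.headers.find(b"\n", self.head_pos)
        if end < 0:
            raise CorruptArchiveError("headers stream exhausted")
        h = self.headers[self.head_pos:end]
        self.head_pos = end + 1
        return h


# ---------------------------------------------------------------------------
# reference-neighborhood geometry


class _RefView:
    """Cached byte view of the reference with neighborhood lookups."""

    _COMP = {A: T, T: A, C: G, G: C}

    def __init__(self, reference: ReferenceBuffer):
        self._ref = reference
        self.refresh()

    def refresh(self) -> None:
        self.bases = self._ref.bases
        self.n = len(self.bases)

    def neighbor(self, m: Match, side: str, i: int) -> int:
        """Expected contig byte at neighborhood offset i (0 = boundary base)."""
        if m.strand == FORWARD:
            pos = m.ref_start - 1 - i if side == "left" else m.ref_end + i
            return self.bases[pos]
        # reverse complement: contig-left maps past ref_end, contig-right
        # before ref_start, both complemented
        pos = m.ref_end + i if side == "left" else m.ref_start - 1 - i
        return self._COMP[self.bases[pos]]

    def avail(self, m: Match, side: str) -> int:
        """How many neighborhood bytes exist on *side* before a reference
        boundary."""
        if m.strand == FORWARD:
            return m.ref_start if side == "left" else self.n - m.ref_end
        return self.n - m.ref_end if side == "left" else m.ref_start


# ---------------------------------------------------------------------------
# gap encoding


def encode_gap(contig_seg: bytes, ref_seg: bytes, streams: EncodingStreams,
               use_matrix: bool = True) -> None:
    """Relative coding of a gap against its equal-length reference
    counterpart: flag 0 per match, flag 1 plus a mismatch code per mismatch.

    The first gap base needs no flag: the match to its left is maximal at
    its right edge, so that base is a guaranteed mismatch.
    """
    if len(contig_seg) != len(ref_seg):
        raise ValueError("gap and reference counterpart must have equal length")
    if not contig_seg:
        return
    if contig_seg[0] == ref_seg[0]:
        raise ValueError("first gap base must mismatch (flank not maximal?)")
    _emit_mismatch(streams, ref_seg[0], contig_seg[0], use_matrix)
    for cb, rb in zip(contig_seg[1:], ref_seg[1:]):
        if cb == rb:
            streams.flags.append(0)
        else:
            streams.flags.append(1)
            _emit_mismatch(streams, rb, cb, use_matrix)


def _emit_mismatch(streams: EncodingStreams, ref_base: int, contig_base: int,
                   use_matrix: bool) -> None:
    if not use_matrix:
        streams.emit_literal(contig_base)
        return
    code = MATRIX.code(ref_base, contig_base)
    streams.emit_literal(code)
    if code == ESCAPE:
        streams.emit_literal(contig_base)


def _read_base(cur: StreamCursors, ref_base: int, use_matrix: bool) -> int:
    """Read one mismatching base from the literals (code or raw byte)."""
    b = cur.next_literal()
    if not use_matrix:
        return b
    if b == ESCAPE:
        return cur.next_literal()
    return MATRIX.decode(ref_base, b)


def decode_gap(length: int, ref_seg: bytes, cur: StreamCursors,
               use_matrix: bool = True) -> bytes:
    if length == 0:
        return b""
    out = bytearray()
    out.append(_read_base(cur, ref_seg[0], use_matrix))
    for i in range(1, length):
        if cur.flags.read() == 0:
            out.append(ref_seg[i])
        else:
            out.append(_read_base(cur, ref_seg[i], use_matrix))
    return bytes(out)


# ---------------------------------------------------------------------------
# adjacent encoding


def encode_adjacent(contig: bytes, boundary: int, direction: int,
                    refview: _RefView, m: Match, side: str, span_limit: int,
                    cfg: CodecConfig, streams: EncodingStreams) -> int:
    """Score-bounded relative coding of a match's unmatched neighborhood.

    *boundary* is the contig index of the guaranteed-mismatch base touching
    the match; *direction* is -1 (left side, processed right-to-left) or +1.
    *span_limit* is how many further bases may be consumed after the
    boundary base. Emits the boundary code (flagless), then one flag (and a
    code on mismatch) per base; stops at a 100 % score or at the span limit,
    recording which in the extents stream. Returns the number of bases
    consumed beyond the boundary one.
    """
    _emit_mismatch(streams, refview.neighbor(m, side, 0), contig[boundary],
                   cfg.use_mismatch_matrix)
    score = cfg.score_initial_units
    threshold = cfg.score_threshold_units
    extent = 0
    by_score = score >= threshold
    while not by_score and extent < span_limit:
        cb = contig[boundary + direction * (extent + 1)]
        rb = refview.neighbor(m, side, extent + 1)
        if cb == rb:
            streams.flags.append(0)
            score = max(0, score - 100)
        else:
            streams.flags.append(1)
            _emit_mismatch(streams, rb, cb, cfg.use_mismatch_matrix)
            score = min(threshold, score + 100)
        extent += 1
        by_score = score >= threshold
    streams.extents.append(0 if by_score else extent + 1)
    return extent


def _probe_adjacent(contig: bytes, boundary: int, direction: int,
                    refview: _RefView, m: Match, side: str, span_limit: int,
                    cfg: CodecConfig) -> tuple[int, int]:
    """Dry-run of the scoring automaton: (extent, mismatches beyond the
    boundary base). Used by the encoder to decide whether a block pays."""
    score = cfg.score_initial_units
    threshold = cfg.score_threshold_units
    extent = mism = 0
    while score < threshold and extent < span_limit:
        cb = contig[boundary + direction * (extent + 1)]
        rb = refview.neighbor(m, side, extent + 1)
        if cb == rb:
            score = max(0, score - 100)
        else:
            mism += 1
            score = min(threshold, score + 100)
        extent += 1
    return extent, mism


def decode_adjacent(refview: _RefView, m: Match, side: str, cfg: CodecConfig,
                    cur: StreamCursors) -> bytes:
    """Inverse of :func:`encode_adjacent`; returns the decoded bases in
    processing order (boundary base first)."""
    out = bytearray()
    out.append(_read_base(cur, refview.neighbor(m, side, 0),
                          cfg.use_mismatch_matrix))
    entry = cur.extents.read()
    score = cfg.score_initial_units
    threshold = cfg.score_threshold_units
    extent = 0
    while ((entry > 0 and extent < entry - 1)
           or (entry == 0 and score < threshold)):
        rb = refview.neighbor(m, side, extent + 1)
        if cur.flags.read() == 0:
            out.append(rb)
            score = max(0, score - 100)
        else:
            out.append(_read_base(cur, rb, cfg.use_mismatch_matrix))
            score = min(threshold, score + 100)
        extent += 1
    return bytes(out)


# ---------------------------------------------------------------------------
# contig encode / decode


# adjacency blocks and gap blocks carry fixed overhead (marker, boundary
# code, extent/length varint); the encoder emits them only where the probe
# says relative coding beats raw literals under the backend
_ADJ_MIN_EXTENT = 16


def _adjacency_pays(extent: int, mism: int) -> bool:
    return extent >= _ADJ_MIN_EXTENT and 4 * mism <= extent


def _encode_right_adjacency(contig: bytes, a: int, b: int, lm: Match,
                            refview: _RefView, cfg: CodecConfig,
                            streams: EncodingStreams) -> int:
    """Try right-side adjacent encoding of *lm* into [a, b); returns the new
    region start after any consumed bases."""
    if not (cfg.use_adjacent and lm is not None and a < b):
        return a
    avail = refview.avail(lm, "right")
    if avail < 1 or contig[a] == refview.neighbor(lm, "right", 0):
        return a  # no guaranteed mismatch at the boundary (e.g. trimmed match)
    span = min(b - a - 1, avail - 1)
    if not _adjacency_pays(*_probe_adjacent(contig, a, +1, refview, lm,
                                            "right", span, cfg)):
        return a
    streams.emit_literal(RIGHT_MARK)
    ext = encode_adjacent(contig, a, +1, refview, lm, "right", span, cfg, streams)
    return a + 1 + ext


def encode_contig(contig: bytes, reference: ReferenceBuffer, refview: _RefView,
                  cfg: CodecConfig, streams: EncodingStreams) -> list[Match]:
    """Encode one uppercased contig against the current reference state.

    Returns the final selected match list (used for the reference-extension
    decision). Appends to every logical stream; the literal segment ends
    with SEQ_MARK.
    """
    matches: list[Match] = []
    if len(reference) >= cfg.k and len(contig) >= cfg.k:
        mems = reference.find_mems(contig, cfg.min_match_length)
        matches = select_matches(mems, cfg.min_match_length)
        if cfg.use_gap_breaks:
            def _worth_removing(a: Match, mid: Match, b: Match) -> bool:
                # the freed region will be coded in-gap against the local
                # counterpart; removal pays only when the match's own span
                # codes in clearly fewer bits than the match entry it frees
                seg = contig[a.contig_end:b.contig_start]
                ref_seg = refview.bases[a.ref_end:a.ref_end + len(seg)]
                mism = sum(1 for cb, rb in zip(seg, ref_seg) if cb != rb)
                if 2 * mism > len(seg):
                    return False
                off = mid.contig_start - a.contig_end
                mid_seg = seg[off:off + mid.length]
                mid_ref = ref_seg[off:off + mid.length]
                mid_mism = sum(1 for cb, rb in zip(mid_seg, mid_ref)
                               if cb != rb)
                return mid.length + 4 * mid_mism <= 40

            matches = gap_breaks_filter(matches, cfg.gap_breaks_max,
                                        cfg.corr_window,
                                        removable=_worth_removing)
    n = len(matches)
    if cfg.use_gaps_delta:
        _, deltas, explicit = compute_links(matches, cfg.corr_window)
    else:
        deltas, explicit = [0] * n, [True] * n

    pos = 0
    for i, m in enumerate(matches):
        a, b = pos, m.contig_start
        lm = matches[i - 1] if i else None
        # a gap is structural (region between corresponding adjacent
        # matches) whether or not encoding-in-gaps is enabled; adjacent
        # encoding never reaches into one
        is_gap = (lm is not None and a < b
                  and lm.strand == FORWARD and m.strand == FORWARD
                  and lm.diagonal == m.diagonal)
        gap_coded = False
        if is_gap and cfg.use_gap_encoding:
            ref_seg = refview.bases[lm.ref_end:lm.ref_end + (b - a)]
            mism = sum(1 for cb, rb in zip(contig[a:b], ref_seg) if cb != rb)
            # relative coding of a gap pays only while mismatches are the
            # minority; denser gaps (e.g. bases of a filtered-out match)
            # stay as raw literals
            gap_coded = 2 * mism <= (b - a)
        if gap_coded:
            streams.emit_literal(GAP_MARK)
            streams.gap_lengths.append(b - a)
            encode_gap(contig[a:b], ref_seg, streams, cfg.use_mismatch_matrix)
            streams.lengths.append(m.length - cfg.min_match_length)
            if explicit[i]:
                streams.offsets.append((m.ref_start << 1) | m.strand)
        elif is_gap:
            # still a structural gap: adjacent encoding stays out of it
            streams.lengths.append(m.length - cfg.min_match_length)
            if explicit[i]:
                streams.offsets.append((m.ref_start << 1) | m.strand)
            streams.emit_raw(contig[a:b])
        else:
            a = _encode_right_adjacency(contig, a, b, lm, refview, cfg, streams)
            left_len = 0
            left_ok = (cfg.use_adjacent and explicit[i] and a < b
                       and refview.avail(m, "left") >= 1
                       and contig[b - 1] != refview.neighbor(m, "left", 0))
            if left_ok:
                span = min(b - a - 1, refview.avail(m, "left") - 1)
                left_ok = _adjacency_pays(
                    *_probe_adjacent(contig, b - 1, -1, refview, m, "left",
                                     span, cfg))
            if left_ok:
                streams.emit_literal(LEFT_MARK)
                streams.lengths.append(m.length - cfg.min_match_length)
                streams.offsets.append((m.ref_start << 1) | m.strand)
                ext = encode_adjacent(contig, b - 1, -1, refview, m, "left",
                                      span, cfg, streams)
                left_len = 1 + ext
            else:
                streams.lengths.append(m.length - cfg.min_match_length)
                if explicit[i]:
                    streams.offsets.append((m.ref_start << 1) | m.strand)
            streams.emit_raw(contig[a:b - left_len])
        if not gap_coded:
            # a gap block implies its right match; no separate mark needed
            streams.emit_literal(MATCH_MARK)
        if cfg.use_gaps_delta and i < n - 1:
            streams.gaps_delta.append(deltas[i])
        pos = m.contig_end

    a = _encode_right_adjacency(contig, pos, len(contig),
                                matches[-1] if matches else None,
                                refview, cfg, streams)
    streams.emit_raw(contig[a:])
    streams.emit_literal(SEQ_MARK)
    return matches


def decode_contig(cur: StreamCursors, refview: _RefView,
                  cfg: CodecConfig) -> bytes:
    """Inverse of :func:`encode_contig`: consume exactly the tokens one
    contig produced and return its uppercased residues."""
    out = bytearray()
    matches: list[Match] = []
    tracker = LinkTracker()
    left_buf: bytes | None = None
    pending: tuple[int, int, int] | None = None  # (length, ref_start, strand)

    def arrive_match() -> None:
        """Pop and materialize the next match (explicit, link-derived, or
        the one announced by a left-adjacency block)."""
        nonlocal left_buf, pending
        if cfg.use_gaps_delta and matches:
            d = cur.gaps_delta.read()
            prev = matches[-1]
            if d > 0:
                if prev.strand != FORWARD:
                    raise CorruptArchiveError(
                        "gaps-delta link from a reverse-strand match")
                tracker.add(len(matches) - 1, prev.diagonal, d,
                            prev.contig_end)
        if pending is not None:
            length, ref_start, strand = pending
            pending = None
        else:
            length = cur.lengths.read() + cfg.min_match_length
            ref_start, strand = None, FORWARD
        cs = len(out) + (len(left_buf) if left_buf else 0)
        fired = tracker.on_match(cs, cs + length)
        if ref_start is None:
            if fired is not None:
                ref_start = fired[1] + cs
            else:
                v = cur.offsets.read()
                ref_start, strand = v >> 1, v & 1
        elif fired is not None:
            raise CorruptArchiveError(
                "gaps-delta link fired on an explicitly-offset match")
        if ref_start < 0 or ref_start + length > refview.n:
            raise CorruptArchiveError("match offset outside the reference")
        if left_buf is not None:
            out.extend(left_buf[::-1])
            left_buf = None
        seg = refview.bases[ref_start:ref_start + length]
        out.extend(seg if strand == FORWARD else revcomp_bytes(seg))
        matches.append(Match(cs, ref_start, length, strand))

    while True:
        b = cur.next_literal()
        if b == SEQ_MARK:
            if left_buf is not None or pending is not None:
                raise CorruptArchiveError("record ends inside an adjacency block")
            if cfg.use_gaps_delta and tracker.unresolved():
                raise CorruptArchiveError(
                    "gaps-delta link points past the record's match list")
            return bytes(out)
        if b == ESC:
            out.append(cur.next_literal())
            continue
        if b == PACK_MARK:
            out.extend(cur.next_packed(cur.pack_lengths.read()))
            continue
        if b == MATCH_MARK:
            arrive_match()
            continue
        if b == LEFT_MARK:
            if pending is not None or left_buf is not None:
                raise CorruptArchiveError("nested left-adjacency block")
            length = cur.lengths.read() + cfg.min_match_length
            v = cur.offsets.read()
            ref_start, strand = v >> 1, v & 1
            m = Match(0, ref_start, length, strand)  # contig_start not needed
            left_buf = decode_adjacent(refview, m, "left", cfg, cur)
            pending = (length, ref_start, strand)
            continue
        if b == RIGHT_MARK:
            if not matches or left_buf is not None or pending is not None:
                raise CorruptArchiveError("right-adjacency block without a match")
            out.extend(decode_adjacent(refview, matches[-1], "right", cfg, cur))
            continue
        if b == GAP_MARK:
            if not matches or left_buf is not None or pending is not None:
                raise CorruptArchiveError("gap block without a preceding match")
            lm = matches[-1]
            if lm.strand != FORWARD:
                raise CorruptArchiveError("gap block after a reverse-strand match")
            g = cur.gap_lengths.read()
            ref_seg = refview.bases[lm.ref_end:lm.ref_end + g]
            if len(ref_seg) != g:
                raise CorruptArchiveError("gap extends past the reference")
            out.extend(decode_gap(g, ref_seg, cur, cfg.use_mismatch_matrix))
            arrive_match()  # a gap is always followed by its right match
            continue
        if b <= CODE_MAX or b in (LEFT_MARK, RIGHT_MARK, GAP_MARK):
            raise CorruptArchiveError(
                f"unknown byte {b:#x} in literals at offset {cur.lit_pos - 1}")
        out.append(b)


# ---------------------------------------------------------------------------
# collection encode / decode


def _file_flags(f: FastaFile) -> int:
    irregular = f.line_length is None
    return (int(f.crlf) | (int(f.trailing_newline) << 1)
            | (int(f.empty) << 2) | (int(irregular) << 3))


def encode_collection(files: list[FastaFile], cfg: CodecConfig
                      ) -> tuple[EncodingStreams, list[dict]]:
    """Encode a whole collection; returns the filled streams and the file
    table (path, record count, raw size, content hash)."""
    import hashlib

    streams = EncodingStreams()
    ref = ReferenceBuffer(cfg.k, cfg.sampling, cfg.ref_cap)
    refview = _RefView(ref)
    table: list[dict] = []
    seen_paths: set[str] = set()
    for f in files:
        if f.path in seen_paths:
            raise ValueError(f"duplicate path in collection: {f.path!r}")
        seen_paths.add(f.path)
        data = write_fasta_bytes(f)
        table.append({
            "path": f.path,
            "n_records": len(f.records),
            "raw_size": len(data),
            "hash": hashlib.blake2b(data, digest_size=8).hexdigest(),
        })
        streams.meta_varint(_file_flags(f))
        streams.meta_varint(0 if f.line_length is None else f.line_length)
        streams.meta_varint(len(f.records))
        for ri, rec in enumerate(f.records):
            streams.headers += rec.header + b"\n"
            upper, mask = split_case(rec.residues)
            matches = encode_contig(upper, ref, refview, cfg, streams)
            streams.meta_varint(len(upper))
            streams.meta_varint((len(mask.run_lengths) << 1)
                                | int(mask.first_lower))
            for rl in mask.run_lengths:
                streams.meta_varint(rl)
            if f.line_length is None:
                lens = f.line_breaks[ri] if f.line_breaks else []
                streams.meta_varint(len(lens))
                for ll in lens:
                    streams.meta_varint(ll)
            appended = update_reference(upper, matches, ref,
                                        cfg.ref_extend_threshold)
            streams.meta_varint(int(appended))
            if appended:
                refview.refresh()
    return streams, table


def decode_collection(raw: dict[str, bytes], flag_bits: int,
                      table: list[dict], cfg: CodecConfig) -> list[FastaFile]:
    """Replay the encoder's decisions and restore every file."""
    cur = StreamCursors(raw, flag_bits)
    ref = ReferenceBuffer(cfg.k, cfg.sampling, cfg.ref_cap, indexed=False)
    refview = _RefView(ref)
    files: list[FastaFile] = []
    for entry in table:
        fflags = cur.meta.read()
        crlf = bool(fflags & 1)
        trailing = bool(fflags & 2)
        empty = bool(fflags & 4)
        irregular = bool(fflags & 8)
        line_length = cur.meta.read()
        n_records = cur.meta.read()
        if n_records != entry["n_records"]:
            raise CorruptArchiveError(
                f"record count mismatch for {entry['path']!r}")
        records: list[SequenceRecord] = []
        line_breaks: list[list[int]] = []
        for _ in range(n_records):
            header = cur.next_header()
            try:
                upper = decode_contig(cur, refview, cfg)
            except IndexError as exc:  # stream damage steering past a boundary
                raise CorruptArchiveError(
                    f"stream inconsistency while decoding {entry['path']!r}"
                ) from exc
            res_len = cur.meta.read()
            if res_len != len(upper):
                raise CorruptArchiveError(
                    f"decoded length mismatch in {entry['path']!r}")
            v = cur.meta.read()
            n_runs, first_lower = v >> 1, bool(v & 1)
            runs = [cur.meta.read() for _ in range(n_runs)]
            try:
                residues = apply_case(upper, CaseMask(runs, first_lower))
            except ValueError as exc:
                raise CorruptArchiveError(
                    f"invalid case mask in {entry['path']!r}") from exc
            if irregular:
                n_lines = cur.meta.read()
                line_breaks.append([cur.meta.read() for _ in range(n_lines)])
            if cur.meta.read():
                ref.append(map_to_acgt(upper))
                refview.refresh()
            records.append(SequenceRecord(header, residues))
        files.append(FastaFile(
            path=entry["path"], records=records,
            line_length=None if irregular else line_length,
            line_breaks=line_breaks if irregular else None,
            crlf=crlf, trailing_newline=trailing, empty=empty))
    return files
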