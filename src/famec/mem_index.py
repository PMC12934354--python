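"""Reference buffer and maximal-exact-match (MEM) finding.

The reference buffer is an append-only {A,C,G,T} byte string seeded by the
first dissimilar contig of a run and extended whenever a later contig shows
too little similarity to it. Matching uses a sampled k-mer anchor index over
the reference: every contig k-mer is looked up, anchors are grouped by
diagonal and extended bidirectionally to maximality. Both the forward strand
and the reverse complement of the contig are scanned; reverse hits are
mapped back to forward contig coordinates.

Non-ACGT bytes (N runs, IUPAC ambiguity codes) never match: reference bytes
are strictly ACGT, so byte equality fails at any such contig position, and
k-mers containing them are not anchored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dna import BASE2BITS, acgt_mask, complement, map_to_acgt
from .errors import ReferenceCapError

__all__ = ["Match", "FORWARD", "REVCOMP", "ReferenceBuffer",
           "find_mems", "select_matches", "update_reference"]

FORWARD = 0
REVCOMP = 1


@dataclass(frozen=True)
class Match:
    """One exact match between a contig interval and the reference.

    Forward: ``contig[contig_start:contig_start+length] ==
    reference[ref_start:ref_start+length]``. Reverse: the contig segment
    equals the reverse complement of the reference segment. Coordinates are
    0-based, half-open.
    """

    contig_start: int
    ref_start: int
    length: int
    strand: int = FORWARD

    @property
    def contig_end(self) -> int:
        return self.contig_start + self.length

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def diagonal(self) -> int | None:
        """ref_start − contig_start for forward matches, None for reverse."""
        return self.ref_start - self.contig_start if self.strand == FORWARD else None


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit k-mer codes and validity mask for every window start of *arr*."""
    n = len(arr)
    if n < k:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    bits = BASE2BITS[arr]
    invalid = (bits == 255).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(invalid)))
    valid = (csum[k:] - csum[:-k]) == 0
    windows = np.lib.stride_tricks.sliding_window_view(
        bits.astype(np.uint64), k)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    codes = (windows * powers).sum(axis=1, dtype=np.uint64)
    return codes, valid


def _expand_ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate arange(s, s+c) for each (s, c) pair, vectorized."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    rep = np.repeat(starts, counts)
    off = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    return rep + off


class _IndexBlock:
    """Sorted k-mer codes and their reference positions for one extension."""

    __slots__ = ("codes", "positions")

    def __init__(self, codes: np.ndarray, positions: np.ndarray):
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.positions = positions[order]


class ReferenceBuffer:
    """Append-only reference with a sampled k-mer anchor index.

    A position p is indexed when ``p % sampling == 0`` and the k bytes at p
    are all ACGT. The index grows in blocks as the buffer is extended; the
    buffer bytes themselves never mutate.
    """

    def __init__(self, k: int = 24, sampling: int = 1, cap: int = 1 << 28,
                 indexed: bool = True):
        if k < 8:
            raise ValueError("k must be >= 8")
        if sampling < 1:
            raise ValueError("sampling must be >= 1")
        self.k = k
        self.sampling = sampling
        self.cap = cap
        self.indexed = indexed  # decoders replay the buffer without an index
        self._arr = np.empty(0, dtype=np.uint8)
        self._blocks: list[_IndexBlock] = []

    def __len__(self) -> int:
        return len(self._arr)

    @property
    def bases(self) -> bytes:
        return self._arr.tobytes()

    def append(self, chunk: bytes) -> None:
        """Extend the buffer and index the new region (including windows that
        straddle the old/new junction)."""
        if not chunk:
            return
        if len(self._arr) + len(chunk) > self.cap:
            raise ReferenceCapError(self.cap)
        new = np.frombuffer(chunk, dtype=np.uint8)
        if not acgt_mask(new).all():
            raise ValueError("reference chunks must be strictly ACGT")
        old_len = len(self._arr)
        self._arr = np.concatenate([self._arr, new])
        if not self.indexed:
            return
        # index windows starting in [start, len - k]
        start = max(0, old_len - self.k + 1)
        region = self._arr[start:]
        codes, valid = _kmer_codes(region, self.k)
        pos = np.flatnonzero(valid) + start
        if self.sampling > 1:
            pos = pos[pos % self.sampling == 0]
        if len(pos):
            self._blocks.append(_IndexBlock(codes[pos - start], pos.astype(np.int64)))

    def indexed_positions(self) -> np.ndarray:
        """All indexed reference positions, sorted (diagnostics/testing)."""
        if not self._blocks:
            return np.empty(0, dtype=np.int64)
        return np.sort(np.concatenate([b.positions for b in self._blocks]))

    # -- anchor lookup -----------------------------------------------------

    def _anchors(self, codes: np.ndarray, valid: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        """All (contig_pos, ref_pos) anchor pairs for the given contig codes."""
        cpos_all: list[np.ndarray] = []
        rpos_all: list[np.ndarray] = []
        q = np.flatnonzero(valid)
        if len(q) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qcodes = codes[q]
        for block in self._blocks:
            left = np.searchsorted(block.codes, qcodes, side="left")
            right = np.searchsorted(block.codes, qcodes, side="right")
            counts = right - left
            hit = counts > 0
            if not hit.any():
                continue
            ridx = _expand_ranges(left[hit], counts[hit])
            cpos_all.append(np.repeat(q[hit], counts[hit]))
            rpos_all.append(block.positions[ridx])
        if not cpos_all:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(cpos_all), np.concatenate(rpos_all)

    # -- extension ---------------------------------------------------------

    def _extend_right(self, carr: np.ndarray, cp: int, rp: int) -> int:
        """Longest common run of carr[cp:] and reference[rp:], chunked scan."""
        ref = self._arr
        limit = min(len(carr) - cp, len(ref) - rp)
        done = 0
        while done < limit:
            step = min(256, limit - done)
            eq = carr[cp + done:cp + done + step] == ref[rp + done:rp + done + step]
            if eq.all():
                done += step
            else:
                return done + int(np.argmin(eq))
        return done

    def _extend_left(self, carr: np.ndarray, cp: int, rp: int) -> int:
        ref = self._arr
        limit = min(cp, rp)
        done = 0
        while done < limit:
            step = min(256, limit - done)
            eq = (carr[cp - done - step:cp - done]
                  == ref[rp - done - step:rp - done])
            if eq.all():
                done += step
            else:
                return done + int(np.argmin(eq[::-1]))
        return done

    def _strand_mems(self, carr: np.ndarray, min_len: int) -> list[tuple[int, int, int]]:
        """Maximal matches of carr against the reference (forward sense)."""
        codes, valid = _kmer_codes(carr, self.k)
        cpos, rpos = self._anchors(codes, valid)
        if len(cpos) == 0:
            return []
        diag = rpos - cpos
        order = np.lexsort((cpos, diag))
        out = []
        cur_diag = None
        cur_end = -1
        for idx in order:
            cp = int(cpos[idx])
            d = int(diag[idx])
            if d == cur_diag and cp < cur_end:
                continue  # inside the previously extended run on this diagonal
            rp = int(rpos[idx])
            left = self._extend_left(carr, cp, rp)
            right = self._extend_right(carr, cp, rp)
            start, length = cp - left, left + right
            cur_diag, cur_end = d, cp + right
            if length >= min_len:
                out.append((start, rp - left, length))
        return out

    def find_mems(self, contig: bytes, min_len: int) -> list[Match]:
        """Maximal exact matches of *contig* on both strands, sorted by
        contig_start (ties: longer first, forward before reverse, lower
        ref_start)."""
        if min_len < self.k:
            raise ValueError("min_len must be >= k (anchors would miss matches)")
        if not self._blocks or len(contig) < self.k:
            return []
        carr = np.frombuffer(contig, dtype=np.uint8)
        matches = [Match(cs, rs, ln, FORWARD)
                   for cs, rs, ln in self._strand_mems(carr, min_len)]
        rc = complement(carr)[::-1].copy()
        n = len(carr)
        for cs_rc, rs, ln in self._strand_mems(rc, min_len):
            matches.append(Match(n - cs_rc - ln, rs, ln, REVCOMP))
        matches.sort(key=lambda m: (m.contig_start, -m.length, m.strand, m.ref_start))
        # drop duplicates (several anchors can reach the same maximal run)
        seen = set()
        unique = []
        for m in matches:
            key = (m.contig_start, m.ref_start, m.length, m.strand)
            if key not in seen:
                seen.add(key)
                unique.append(m)
        return unique


def find_mems(contig: bytes, reference: ReferenceBuffer, min_len: int) -> list[Match]:
    return reference.find_mems(contig, min_len)


def select_matches(mems: list[Match], min_len: int) -> list[Match]:
    """Greedy left-to-right selection of a disjoint, ordered match subset.

    Earlier-starting (and, at ties, longer) matches win; later overlapping
    matches are trimmed on the contig side and dropped when trimmed below
    *min_len*. Abutting forward matches on one diagonal are merged back into
    a single match.
    """
    out: list[Match] = []
    end = 0
    for m in sorted(mems, key=lambda m: (m.contig_start, -m.length,
                                         m.strand, m.ref_start)):
        if m.contig_start < end:
            trim = end - m.contig_start
            if m.length - trim < min_len:
                continue
            rs = m.ref_start + trim if m.strand == FORWARD else m.ref_start
            m = Match(m.contig_start + trim, rs, m.length - trim, m.strand)
        if (out and m.strand == FORWARD and out[-1].strand == FORWARD
                and out[-1].contig_end == m.contig_start
                and out[-1].ref_end == m.ref_start):
            prev = out.pop()
            m = Match(prev.contig_start, prev.ref_start,
                      prev.length + m.length, FORWARD)
        out.append(m)
        end = m.contig_end
    return out


def update_reference(contig_upper: bytes, selected: list[Match],
                     reference: ReferenceBuffer, threshold: float = 0.5) -> bool:
    """Append the contig to the reference when its matched-base fraction is
    strictly below *threshold*; returns the decision (replayed by the
    decoder). Non-ACGT bytes are mapped to 'A' before appending."""
    if len(contig_upper) == 0:
        return False
    coverage = sum(m.length for m in selected) / len(contig_upper)
    if coverage < threshold:
        reference.append(map_to_acgt(contig_upper))
        return True
    return False
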