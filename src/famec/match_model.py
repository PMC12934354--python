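"""Structural relations among a contig's selected matches.

Corresponding matches are forward-strand matches on one diagonal
(ref_start − contig_start equal), so the contig distance between them equals
the reference distance. Three techniques hang off this notion:

* the gap-breaks filter drops short matches sandwiched between mutually
  corresponding neighbors, so the whole region is coded as one gap;
* gaps-delta coding stores, instead of a match's reference offset, the
  number of gaps (nonempty inter-match regions) to its nearest subsequent
  corresponding match — the decoder rederives the offset from the diagonal;
* matches that correspond to an earlier match contribute no entry to the
  offsets stream at all.

When counting gaps for match i, intervening matches already derivable from a
source earlier than i are transparent: their flanking regions merge into one
gap. The encoder commits a link only when a decoder replaying these rules
would resolve exactly the intended target; otherwise the offset is stored
explicitly. :class:`LinkTracker` is that replay, shared in spirit by both
sides (the encoder simulates it once per candidate link; the decoder runs it
online).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CorruptArchiveError
from .mem_index import FORWARD, Match

__all__ = ["detect_corresponding", "gap_breaks_filter", "compute_links",
           "gaps_delta_encode", "gaps_delta_decode", "LinkTracker"]


def detect_corresponding(matches: list[Match], window: int = 64) -> list[int | None]:
    """For each match, the index of its nearest subsequent corresponding
    match, or None.

    Two matches correspond when both are forward-strand, share a diagonal,
    and fewer than *window* other matches lie between them in the list.
    """
    n = len(matches)
    links: list[int | None] = [None] * n
    for i in range(n):
        d = matches[i].diagonal
        if d is None:
            continue
        for j in range(i + 1, min(n, i + window + 1)):  # j - i - 1 < window
            if matches[j].diagonal == d:
                links[i] = j
                break
    return links


def gap_breaks_filter(matches: list[Match], max_len: int = 256,
                      window: int = 64, removable=None) -> list[Match]:
    """Drop short matches that interrupt a gap between corresponding matches.

    A match shorter than *max_len* is removed when its two list neighbors
    are corresponding to each other while the match itself refers elsewhere
    (a different diagonal, or the reverse strand); its bases rejoin the
    surrounding gap and are coded by encoding-in-gaps. A short match on the
    *same* diagonal as its neighbors is part of the corresponding chain and
    is kept. One pass over the original list (no fixed-point iteration).

    *removable*, when given, is an extra encoder-side predicate called as
    ``removable(prev, mid, nxt)``; it lets the caller veto removals whose
    freed bases would code poorly against the local reference counterpart.
    """
    n = len(matches)
    keep = [True] * n
    for i in range(1, n - 1):
        if matches[i].length >= max_len:
            continue
        a, b = matches[i - 1], matches[i + 1]
        if (a.strand == FORWARD and b.strand == FORWARD
                and a.diagonal == b.diagonal and window > 1
                and matches[i].diagonal != a.diagonal):
            if removable is not None and not removable(a, matches[i], b):
                continue
            keep[i] = False
    return [m for m, k in zip(matches, keep) if k]


@dataclass
class _Pending:
    src: int
    diagonal: int
    delta: int
    count: int
    last_end: int


class LinkTracker:
    """Online resolution of gaps-delta links while matches arrive in order.

    Feed every match via :meth:`on_match`; register a source's delta via
    :meth:`add`. A pending link's counter increments when a non-transparent
    match arrives after a nonempty region; the link fires when the counter
    reaches its delta, resolving that match's diagonal.
    """

    def __init__(self) -> None:
        self._pending: list[_Pending] = []

    def add(self, src: int, diagonal: int, delta: int, src_end: int) -> None:
        if delta <= 0:
            return
        self._pending.append(_Pending(src, diagonal, delta, 0, src_end))

    def on_match(self, contig_start: int, contig_end: int) -> tuple[int, int] | None:
        """Returns (source index, diagonal) when a link fires here, else None."""
        fired: _Pending | None = None
        for link in self._pending:  # kept in ascending source order
            if fired is not None and fired.src < link.src:
                continue  # this match is transparent for later sources
            if contig_start > link.last_end:
                link.count += 1
            link.last_end = contig_end
            if fired is None and link.count == link.delta:
                fired = link
        if fired is None:
            return None
        self._pending.remove(fired)
        return fired.src, fired.diagonal

    def unresolved(self) -> int:
        return len(self._pending)


def compute_links(matches: list[Match], window: int = 64
                  ) -> tuple[list[int | None], list[int], list[bool]]:
    """Commit decodable correspondence links for an ordered match list.

    Returns ``(links, deltas, explicit)``: per-match nearest-successor link
    target (or None), the gaps-delta value per match (0 = no link; the last
    match never gets one), and whether each match's reference offset must be
    stored explicitly (True unless the match is some committed link's
    target).
    """
    n = len(matches)
    nearest = detect_corresponding(matches, window)
    resolved_by: list[int | None] = [None] * n
    links: list[int | None] = [None] * n
    deltas = [0] * n
    for i in range(n - 1):
        j = nearest[i]
        if j is None:
            continue
        # decoder-style walk from i to j
        count = 0
        last_end = matches[i].contig_end
        incremented_at_j = False
        for m in range(i + 1, j + 1):
            if resolved_by[m] is not None and resolved_by[m] < i:
                continue  # transparent for source i
            inc = matches[m].contig_start > last_end
            if inc:
                count += 1
            last_end = matches[m].contig_end
            if m == j:
                incremented_at_j = inc
        if not incremented_at_j:
            continue  # a replaying decoder would fire early; keep j explicit
        links[i] = j
        deltas[i] = count
        resolved_by[j] = i
    explicit = [resolved_by[j] is None for j in range(n)]
    return links, deltas, explicit


def gaps_delta_encode(matches: list[Match], window: int = 64
                      ) -> tuple[list[int], list[int]]:
    """Encode reference offsets as (explicit offsets, gaps-delta values).

    The offsets list holds ref_start for matches not corresponding to any
    preceding encoded match; the delta list has one value per match except
    the last (0 = no subsequent corresponding match).
    """
    _, deltas, explicit = compute_links(matches, window)
    offsets = [m.ref_start for m, e in zip(matches, explicit) if e]
    return offsets, deltas[:-1] if matches else []


def gaps_delta_decode(offsets: list[int], deltas: list[int],
                      skeleton: list[tuple[int, int]]) -> list[int]:
    """Recover every match's ref_start from the two streams.

    *skeleton* gives (contig_start, length) for each match in order — the
    information a decoder reads off the literal stream. Raises
    :class:`CorruptArchiveError` on inconsistent streams.
    """
    tracker = LinkTracker()
    offsets_it = iter(offsets)
    out: list[int] = []
    n = len(skeleton)
    if n > 1 and len(deltas) < n - 1:
        raise CorruptArchiveError("gaps-delta stream too short")
    for idx, (cs, length) in enumerate(skeleton):
        if idx >= 1:
            d = deltas[idx - 1]
            prev_cs, prev_len = skeleton[idx - 1]
            tracker.add(idx - 1, out[idx - 1] - prev_cs, d, prev_cs + prev_len)
        fired = tracker.on_match(cs, cs + length)
        if fired is not None:
            out.append(fired[1] + cs)
        else:
            try:
                out.append(next(offsets_it))
            except StopIteration:
                raise CorruptArchiveError(
                    "offsets stream exhausted before all matches resolved"
                ) from None
    if tracker.unresolved():
        raise CorruptArchiveError("gaps-delta link points past the match list")
    if next(offsets_it, None) is not None:
        raise CorruptArchiveError("offsets stream has surplus entries")
    return out
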