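"""Synthetic genome collections with the redundancy structure the codec exploits.

A collection is a set of descendants of one random ancestor, each carrying
point mutations, short indels, reverse-complemented inversions, segment
translocations and runs of N — the variation classes that shape real
assembly collections. Files can be fragmented into contigs, soft-masked
(lowercase runs) and written at mixed line widths so that the whole I/O and
codec stack is exercised without any external dataset.

Everything is driven by one explicit seed through ``numpy`` generators;
identical parameters always produce identical collections.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .dna import ACGT, complement
from .fasta_io import FastaFile, SequenceRecord

__all__ = ["MutationModel", "make_ancestor", "mutate", "make_collection"]


@dataclass
class MutationModel:
    """Per-genome mutation intensities.

    Rates are per base (``snp_rate``, ``indel_rate``) or expected events per
    genome (``inversion_rate``, ``rearrange_rate``, ``n_run_rate``); lengths
    are mean lengths in bases of geometric/exponential event sizes.
    """

    snp_rate: float = 0.01
    ts_tv_ratio: float = 3.0  # transition:transversion bias of substitutions
    indel_rate: float = 0.0005
    indel_len: float = 3.0
    inversion_rate: float = 1.0
    inversion_len: float = 400.0
    rearrange_rate: float = 0.5
    n_run_rate: float = 1.0
    n_run_len: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("indel_len", "inversion_len", "n_run_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def make_ancestor(length: int, gc: float = 0.5, seed: int = 0) -> SequenceRecord:
    """An i.i.d. random genome with the requested GC fraction."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = rng.choice(np.frombuffer(ACGT, dtype=np.uint8), size=length, p=probs)
    return SequenceRecord(header=b"ancestor", residues=bases.tobytes())


def _geometric_len(rng: np.random.Generator, mean: float) -> int:
    return int(rng.geometric(min(1.0, 1.0 / mean)))


def _mutate_array(seq: np.ndarray, model: MutationModel,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply all mutation classes to a copy of *seq* (uint8 ACGT array)."""
    seq = seq.copy()
    n = len(seq)
    if n == 0:
        return seq
    alphabet = np.frombuffer(ACGT, dtype=np.uint8)

    # translocations: cut a segment and reinsert it elsewhere
    for _ in range(rng.poisson(model.rearrange_rate)):
        if len(seq) < 10:
            break
        seg_len = min(_geometric_len(rng, model.inversion_len), len(seq) // 2)
        start = int(rng.integers(0, len(seq) - seg_len + 1))
        seg = seq[start:start + seg_len].copy()
        rest = np.concatenate([seq[:start], seq[start + seg_len:]])
        at = int(rng.integers(0, len(rest) + 1))
        seq = np.concatenate([rest[:at], seg, rest[at:]])

    # inversions: reverse complement a segment in place
    for _ in range(rng.poisson(model.inversion_rate)):
        if len(seq) < 10:
            break
        seg_len = min(max(2, _geometric_len(rng, model.inversion_len)), len(seq))
        start = int(rng.integers(0, len(seq) - seg_len + 1))
        seq[start:start + seg_len] = complement(seq[start:start + seg_len])[::-1]

    # substitutions: transition-biased (HKY-like); P(transition) = R/(R+1)
    hits = np.flatnonzero(rng.random(len(seq)) < model.snp_rate)
    if hits.size:
        r = model.ts_tv_ratio
        p_ts = r / (r + 1.0)
        # alphabet is ACGT: transitions are A<->G (0<->2) and C<->T (1<->3)
        cur = np.searchsorted(alphabet, seq[hits])
        u = rng.random(hits.size)
        new = np.where(u < p_ts, (cur + 2) % 4,            # transition
                       np.where(u < p_ts + (1 - p_ts) / 2,  # two transversions
                                (cur + 1) % 4, (cur + 3) % 4))
        seq[hits] = alphabet[new]

    # indels: geometric lengths, insertion or deletion with equal odds
    n_events = rng.poisson(model.indel_rate * len(seq))
    if n_events:
        pieces: list[np.ndarray] = []
        positions = np.sort(rng.integers(0, len(seq), size=n_events))
        prev = 0
        for pos in positions:
            pos = int(pos)
            if pos < prev:
                continue
            length = _geometric_len(rng, model.indel_len)
            if rng.random() < 0.5:  # insertion
                pieces.append(seq[prev:pos])
                pieces.append(rng.choice(alphabet, size=length))
                prev = pos
            else:  # deletion
                pieces.append(seq[prev:pos])
                prev = min(len(seq), pos + length)
        pieces.append(seq[prev:])
        seq = np.concatenate(pieces)

    # runs of N (assembly gaps)
    for _ in range(rng.poisson(model.n_run_rate)):
        if len(seq) == 0:
            break
        run = min(_geometric_len(rng, model.n_run_len), len(seq))
        start = int(rng.integers(0, len(seq) - run + 1))
        seq[start:start + run] = ord("N")

    return seq


def _soft_mask(seq: np.ndarray, rng: np.random.Generator,
               events: float = 3.0, mean_len: float = 120.0) -> np.ndarray:
    seq = seq.copy()
    for _ in range(rng.poisson(events)):
        if len(seq) == 0:
            break
        run = min(_geometric_len(rng, mean_len), len(seq))
        start = int(rng.integers(0, len(seq) - run + 1))
        low = seq[start:start + run]
        upper = (low >= 65) & (low <= 90)
        low[upper] += 32
        seq[start:start + run] = low
    return seq


def mutate(ancestor: SequenceRecord, model: MutationModel, *,
           seed: int | None = None, name: str = "genome",
           n_contigs: int = 1, line_length: int = 60,
           soft_mask: bool = False) -> FastaFile:
    """One mutated descendant of *ancestor*, optionally fragmented into contigs."""
    if len(ancestor.residues) == 0:
        raise ValueError("ancestor must be non-empty")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    seq = _mutate_array(np.frombuffer(ancestor.residues, dtype=np.uint8), model, rng)
    if soft_mask:
        seq = _soft_mask(seq, rng)

    n_contigs = max(1, min(n_contigs, len(seq)))
    if n_contigs > 1:
        cuts = np.sort(rng.choice(np.arange(1, len(seq)), size=n_contigs - 1,
                                  replace=False))
        bounds = np.concatenate(([0], cuts, [len(seq)]))
    else:
        bounds = np.array([0, len(seq)])

    records = []
    for ci in range(len(bounds) - 1):
        chunk = seq[bounds[ci]:bounds[ci + 1]].tobytes()
        header = f"{name}_contig{ci + 1} synthetic len={len(chunk)}".encode()
        records.append(SequenceRecord(header, chunk))
    return FastaFile(path=f"{name}.fa", records=records, line_length=line_length,
                     crlf=False, trailing_newline=True)


def make_collection(n_genomes: int, model: MutationModel, *,
                    ancestor_length: int = 100_000, gc: float = 0.30,
                    max_contigs: int = 3, soft_mask: bool = True,
                    line_lengths: tuple[int, ...] = (60, 70, 80)) -> list[FastaFile]:
    """A seeded collection of *n_genomes* descendants of one ancestor.

    Line widths cycle through *line_lengths* so the collection mixes
    formatting dialects; contig counts and soft-masking vary per genome.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    ss = np.random.SeedSequence(model.seed)
    anc_seed, *child_seeds = [int(s.generate_state(1)[0] % (2**31))
                              for s in ss.spawn(n_genomes + 1)]
    ancestor = make_ancestor(ancestor_length, gc=gc, seed=anc_seed)
    files = []
    for gi in range(n_genomes):
        rng = np.random.default_rng(child_seeds[gi])
        n_contigs = int(rng.integers(1, max_contigs + 1))
        f = mutate(ancestor, model, seed=child_seeds[gi], name=f"genome{gi + 1:03d}",
                   n_contigs=n_contigs,
                   line_length=line_lengths[gi % len(line_lengths)],
                   soft_mask=soft_mask and gi % 2 == 0)
        files.append(f)
    return files
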