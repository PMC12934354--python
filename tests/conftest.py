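import numpy as np
import pytest

from famec.fasta_io import FastaFile, SequenceRecord
from famec.synthetic import MutationModel, make_collection


@pytest.fixture
def small_collection():
    """A quick mixed-feature collection: SNPs, indels, inversions, N runs,
    soft-masking, several line widths and contig counts."""
    model = MutationModel(seed=11, snp_rate=0.02, indel_rate=0.001,
                          inversion_rate=2.0, inversion_len=150,
                          rearrange_rate=1.0, n_run_rate=2.0)
    return make_collection(5, model, ancestor_length=6000)


@pytest.fixture
def single_record_file():
    return FastaFile(path="one.fa",
                     records=[SequenceRecord(b"one", b"ACGTACGTACGT" * 10)],
                     line_length=60)


def brute_force_mems(contig: bytes, reference: bytes, min_len: int):
    """Independent maximal-exact-match enumeration by diagonal scanning.

    For every diagonal of the (contig x reference) grid, walk the equality
    vector and report maximal runs of length >= min_len; repeat on the
    reverse complement of the contig and map coordinates back. No k-mers,
    no anchoring, no extension — just exhaustive run enumeration.
    """
    comp = bytes.maketrans(b"ACGT", b"TGCA")

    def runs_forward(query: bytes):
        q = np.frombuffer(query, dtype=np.uint8)
        r = np.frombuffer(reference, dtype=np.uint8)
        valid_q = np.isin(q, np.frombuffer(b"ACGT", dtype=np.uint8))
        found = []
        for d in range(-len(q) + 1, len(r)):
            q_lo = max(0, -d)
            q_hi = min(len(q), len(r) - d)
            if q_hi - q_lo < min_len:
                continue
            seg_q = q[q_lo:q_hi]
            seg_r = r[q_lo + d:q_hi + d]
            eq = (seg_q == seg_r) & valid_q[q_lo:q_hi]
            # maximal runs of True
            padded = np.concatenate(([False], eq, [False]))
            edges = np.flatnonzero(np.diff(padded.view(np.int8)))
            for s, e in zip(edges[::2], edges[1::2]):
                if e - s >= min_len:
                    found.append((q_lo + int(s), q_lo + d + int(s), int(e - s)))
        return found

    fwd = [(cs, rs, ln, 0) for cs, rs, ln in runs_forward(contig)]
    rc = contig.translate(comp)[::-1]
    n = len(contig)
    rev = [(n - cs - ln, rs, ln, 1) for cs, rs, ln in runs_forward(rc)]
    return sorted(fwd + rev)
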