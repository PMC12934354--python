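"""Reference buffer, k-mer index and MEM finding against a brute-force oracle."""

import numpy as np
import pytest

from conftest import brute_force_mems
from famec.dna import revcomp_bytes
from famec.errors import ReferenceCapError
from famec.mem_index import (FORWARD, REVCOMP, Match, ReferenceBuffer,
                             select_matches, update_reference)


def _mk_ref(seq: bytes, k=8, sampling=1) -> ReferenceBuffer:
    ref = ReferenceBuffer(k=k, sampling=sampling)
    ref.append(seq)
    return ref


def _random_dna(rng, n, p_n=0.0) -> bytes:
    bases = rng.choice(np.frombuffer(b"ACGTN", dtype=np.uint8), size=n,
                       p=[(1 - p_n) / 4] * 4 + [p_n])
    return bases.tobytes()


class TestIndex:
    def test_indexed_position_count(self):
        ref = _mk_ref(b"ACGT" * 10, k=8)
        assert len(ref.indexed_positions()) == 40 - 8 + 1

    def test_n_everywhere_gives_empty_index(self):
        ref = ReferenceBuffer(k=8)
        with pytest.raises(ValueError):
            ref.append(b"ACGNACGNACGNACGN")  # reference must be ACGT

    def test_sampling_grid(self):
        seq = np.random.default_rng(1).choice(
            np.frombuffer(b"ACGT", dtype=np.uint8), size=100).tobytes()
        ref = _mk_ref(seq, k=8, sampling=4)
        expected = [p for p in range(0, 100 - 8 + 1) if p % 4 == 0]
        assert ref.indexed_positions().tolist() == expected

    def test_append_only_growth(self):
        ref = _mk_ref(b"ACGTACGTAC")
        ref.append(b"GGGG")
        assert ref.bases == b"ACGTACGTACGGGG"

    def test_cap_enforced(self):
        ref = ReferenceBuffer(k=8, cap=10)
        with pytest.raises(ReferenceCapError):
            ref.append(b"A" * 11)


class TestFindMems:
    def test_identical_sequences_single_forward_match(self):
        seq = _random_dna(np.random.default_rng(0), 300)
        ref = _mk_ref(seq, k=16)
        mems = ref.find_mems(seq, 16)
        assert Match(0, 0, len(seq), FORWARD) in mems

    def test_reverse_complement_contig(self):
        seq = _random_dna(np.random.default_rng(1), 300)
        ref = _mk_ref(seq, k=16)
        mems = ref.find_mems(revcomp_bytes(seq), 16)
        assert Match(0, 0, len(seq), REVCOMP) in mems

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_random(self, seed):
        """Finder equals exhaustive diagonal-run enumeration, both strands."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 500))
        m = int(rng.integers(50, 500))
        # small alphabet chunks stitched from the reference make matches likely
        ref_seq = _random_dna(rng, n)
        pieces = []
        total = 0
        while total < m:
            if rng.random() < 0.6 and n > 30:
                s = int(rng.integers(0, n - 20))
                ln = int(rng.integers(10, 40))
                frag = ref_seq[s:s + ln]
                if rng.random() < 0.3:
                    frag = revcomp_bytes(frag)
            else:
                frag = _random_dna(rng, int(rng.integers(5, 25)), p_n=0.1)
            pieces.append(frag)
            total += len(frag)
        contig = b"".join(pieces)[:m]
        ref = _mk_ref(ref_seq, k=8)
        got = sorted((mm.contig_start, mm.ref_start, mm.length, mm.strand)
                     for mm in ref.find_mems(contig, 10))
        expected = brute_force_mems(contig, ref_seq, 10)
        assert got == expected

    def test_maximality(self):
        rng = np.random.default_rng(3)
        ref_seq = _random_dna(rng, 400)
        contig = ref_seq[50:150] + b"N" + ref_seq[200:260]
        ref = _mk_ref(ref_seq, k=8)
        for m in ref.find_mems(contig, 10):
            if m.strand != FORWARD:
                continue
            cs, rs, ln = m.contig_start, m.ref_start, m.length
            assert contig[cs:cs + ln] == ref_seq[rs:rs + ln]
            if cs > 0 and rs > 0:
                assert (contig[cs - 1] != ref_seq[rs - 1]
                        or contig[cs - 1] not in b"ACGT")
            if cs + ln < len(contig) and rs + ln < len(ref_seq):
                assert (contig[cs + ln] != ref_seq[rs + ln]
                        or contig[cs + ln] not in b"ACGT")

    def test_determinism(self):
        rng = np.random.default_rng(4)
        ref_seq = _random_dna(rng, 300)
        contig = ref_seq[10:200] + _random_dna(rng, 50)
        ref = _mk_ref(ref_seq, k=8)
        assert ref.find_mems(contig, 12) == ref.find_mems(contig, 12)


class TestSelect:
    def test_disjoint_input_unchanged(self):
        ms = [Match(0, 0, 20), Match(30, 50, 20)]
        assert select_matches(ms, 10) == ms

    def test_overlap_trimmed_and_dropped(self):
        # second overlaps by 5: trimmed on the contig side
        ms = [Match(0, 0, 20), Match(15, 100, 20)]
        out = select_matches(ms, 10)
        assert out == [Match(0, 0, 20), Match(20, 105, 15)]
        # trimmed below min_len: dropped
        ms = [Match(0, 0, 20), Match(15, 100, 12)]
        assert select_matches(ms, 10) == [Match(0, 0, 20)]

    def test_random_instances_disjoint_ordered_trimmed(self):
        """Selected matches are pairwise disjoint, ordered, and each is a
        (possibly left-trimmed) input match never shorter than min_len."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            ms = [Match(int(rng.integers(0, 80)), int(rng.integers(0, 200)),
                        int(rng.integers(10, 40)),
                        int(rng.integers(0, 2)))
                  for _ in range(int(rng.integers(0, 8)))]
            out = select_matches(ms, 10)
            end = -1
            for m in out:
                assert m.contig_start >= end
                assert m.length >= 10
                end = m.contig_end
            # output never covers contig positions no input match covered
            covered = set()
            for o in ms:
                covered.update(range(o.contig_start, o.contig_end))
            for m in out:
                assert set(range(m.contig_start, m.contig_end)) <= covered

    def test_empty(self):
        assert select_matches([], 10) == []

    def test_abutting_same_diagonal_merged(self):
        ms = [Match(0, 10, 20), Match(15, 25, 20)]
        assert select_matches(ms, 10) == [Match(0, 10, 35)]


class TestUpdateReference:
    def test_first_contig_appended(self):
        ref = ReferenceBuffer(k=8)
        assert update_reference(b"ACGTACGTACGT", [], ref)
        assert len(ref) == 12

    def test_fully_covered_not_appended(self):
        ref = _mk_ref(b"ACGTACGTACGT")
        n0 = len(ref)
        assert not update_reference(b"ACGTACGT", [Match(0, 0, 8)], ref)
        assert len(ref) == n0

    def test_threshold_is_strict(self):
        ref = _mk_ref(b"ACGTACGTACGT")
        contig = b"ACGTACGTAC"  # 10 bases, 5 covered = exactly 0.5
        assert not update_reference(contig, [Match(0, 0, 5)], ref, threshold=0.5)

    def test_non_acgt_mapped_on_append(self):
        ref = ReferenceBuffer(k=8)
        update_reference(b"ACGTNNNNACGT", [], ref)
        assert ref.bases == b"ACGTAAAAACGT"
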