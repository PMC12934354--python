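# famec

**famec** is a lossless compressor for collections of FASTA files
(multi-FASTA genome collections). It is aimed at people who store or ship
many closely related assemblies — bacterial isolate collections, pan-genome
panels, strain surveys — where genomes differ by point mutations, short
indels, inversions and rearrangements, and general-purpose compressors waste
space re-describing near-identical sequence.

## The method

famec is a *reference-buffer relative* codec. The first contigs of a run
seed an append-only reference buffer **R** over {A,C,G,T}; every later
contig is factored into **maximal exact matches** (MEMs) against R, on the
direct strand and the reverse complement. A contig whose matched-base
fraction falls below a threshold (default 0.5) is itself appended to R, so
the buffer grows to capture the collection's diversity. The decoder replays
the same decisions, so no index or reference is stored in the archive.

Around the exact matches, four techniques turn the match skeleton into an
*approximate-match* encoding:

- **Exclusive mismatch matrix.** A substituted base, given its reference
  base *r*, is one of only three possibilities; famec maps it to a code in
  {0,1,2} — 0 for the transition partner (A↔G, C↔T), then the A/T member of
  the remaining pair — so the transition-rich, AT-rich mutations common in
  real genomes get the cheapest codes. Code 3 escapes a raw non-ACGT byte.
- **Encoding in gaps.** *Corresponding matches* are forward matches on one
  diagonal (equal `ref_start − contig_start`), so the nonempty region (the
  *gap*) between two adjacent corresponding matches has an equal-length
  reference counterpart. Gap bases are coded relative to it: a flag bit per
  base, plus a mismatch code on disagreement. The first gap base is a
  guaranteed mismatch (the left match is maximal) and needs no flag.
- **Adjacent encoding.** Outside gaps, relative coding extends from a match
  boundary into the unmatched neighborhood under a mismatch scoring
  automaton: the score starts at Y = 25 %, moves ±100/x % per base
  (x = 10 ⇒ 10 % steps), is floored at 0 and terminates coding at 100 %.
  The boundary base is again a flagless known mismatch.
- **Gap-breaks filter** (< 256 bases by default): a short match that refers
  to a distant reference region but interrupts a gap between corresponding
  matches is dropped, and its bases are coded in-gap.
- **Gaps-delta coding.** A match corresponding to an earlier match needs no
  stored reference offset: the encoder stores only the number of gaps to
  its nearest subsequent corresponding match (within a 64-match window),
  and the decoder rederives the offset from the shared diagonal.

The resulting logical streams (literals, mismatch flags, match offsets and
lengths, gaps delta, …) are each compressed with an LZMA backend into a
single archive that supports fast listing, selective decompression,
appending and repacking. Every technique can be disabled independently
(`--no-gaps-delta`, `--no-gap-breaks`, `--no-gap-encoding`,
`--no-adjacent`, `--no-mismatch-matrix`) for ablation studies.

Losslessness is byte-level: line widths (uniform or irregular), LF/CRLF
endings, trailing-newline state, soft-masking case, headers, N runs and
arbitrary IUPAC symbols all round-trip exactly, verified by a per-file
64-bit content hash.

## Worked example

Generate a small synthetic collection (5 genomes of 20 kb, 1 % SNPs plus
indels, inversions and N runs), compress it, list it, and restore one file:

```text
$ famec synth -o genomes -n 5 --length 20000 --seed 7
$ famec -v c genomes/ -o collection.famc
5 files, 101931 -> 9138 bytes (ratio 11.15)
$ famec l collection.famc
genome001.fa    2 records       20420 bytes
genome002.fa    3 records       20402 bytes
genome003.fa    1 records       20281 bytes
genome004.fa    3 records       20446 bytes
genome005.fa    3 records       20382 bytes
$ famec d collection.famc -o restored -s 'genome003.fa'
$ cmp genomes/genome003.fa restored/genome003.fa && echo BYTE-IDENTICAL
BYTE-IDENTICAL
```

The reported ratio is raw input bytes over archive bytes: the 102 kB
collection fits in 9.1 kB because only the first genome is stored in full —
each later genome costs roughly its mutation count, not its length. Larger
collections amortize the reference better (10 × 100 kb genomes at 1 % SNPs
compress beyond 20×). Listing reads only the archive header; selective
decompression replays the reference buffer internally and writes just the
requested files, byte-identical to a full extraction.

The same operations are available in Python:

```python
from famec import CodecConfig, compress, decompress, read_collection

files = read_collection(["a.fa", "b.fa"])
blob = compress(files, CodecConfig())          # bytes of the archive
restored = decompress(blob)                    # list of FastaFile, verified
```

## Format

The container layout is specified bit-exactly in
[docs/FORMAT.md](docs/FORMAT.md); the science and the numerical choices are
documented in [docs/methods.md](docs/methods.md).
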