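# Methods

This note records how famec's codec is defined, the parameters that matter,
what the synthetic data generator does and does not emulate, and the design
decisions taken where more than one reasonable construction existed.

## Reference-buffer relative compression

The codec factors each contig into maximal exact matches (MEMs) against an
append-only reference buffer over {A,C,G,T}. The buffer starts empty; any
contig whose selected matches cover less than `ref_extend_threshold`
(default 0.5, strict `<`) of its bases is appended to the buffer after
uppercasing and mapping non-ACGT bytes to `A`. The first contig of a run is
therefore always appended, which subsumes "the first genome is the initial
reference" as a special case. The decoder reproduces the buffer by replaying
a stored per-record extension flag; an explicit flag (one varint per record)
was preferred over decoder-side recomputation so that the invariant
"encoder buffer == decoder buffer" never depends on floating-point or
rounding agreement. Matching against mapped bytes is sound because match
equality is always checked against the stored buffer bytes, never against
the original residues.

### MEM finding

Matches are found with a k-mer anchor index over the reference (every
position whose k bytes are ACGT, subsampled by `sampling`) and maximal
bidirectional extension of each anchor along its diagonal; the reverse
complement of the contig is scanned separately and hits are mapped back to
forward contig coordinates. With `sampling = 1` the finder is exact: every
maximal match of length ≥ `min_match_length ≥ k` contains an indexed
reference k-mer, and the test suite checks equality with a brute-force
diagonal-scanning enumerator on hundreds of random instances (both
strands, N-breaks included). With `sampling > 1` only matches of length
≥ `k + sampling − 1` are guaranteed. Non-ACGT bytes break matches
naturally: the reference contains none, so byte equality fails at any such
contig position.

Defaults are `k = 16`, `min_match_length = 16`. The shorter anchor (versus
the 20–30 range typical of genome matchers) is deliberate: at desk scale
(reference buffers of 10^5–10^7 bases) random 16-mer collisions are rare,
and the shorter minimum keeps inter-SNP runs as cheap exact matches instead
of flag-coded gap bases. On very large collections a larger `k` trades
sensitivity for speed and index size.

Overlapping candidate matches are resolved greedily left to right,
preferring the longest match at each start (ties: forward strand, lower
reference offset); later matches are trimmed on the contig side and dropped
below the minimum length. Abutting forward matches on one diagonal are
re-merged. Greedy selection does not maximize covered bases in every
configuration, but it is deterministic, order-stable and preserves the
right-edge maximality that the gap and adjacency coders rely on (a match's
right edge is never created by trimming).

## Approximate-match encoding

Four techniques extend the exact-match skeleton; each is a boolean switch
in `CodecConfig`, and the decoder is entirely marker-driven, so any
combination decodes with the same machinery.

**Exclusive mismatch matrix.** For reference base *r* the three possible
substituting bases map bijectively to {0,1,2}: code 0 is the transition
partner (A↔G, C↔T), code 1 the A/T member of the remaining pair, code 2 the
last base. This fixes code(T, G) = 2 and makes transitions — the majority
class of real point mutations — and AT-enrichment cheapest. Code 3 is an
escape followed by the raw byte, used for N and other IUPAC symbols. The
matrix is static; per-genome adaptation was deliberately not implemented.

**Encoding in gaps.** A *gap* is the nonempty contig region between two
adjacent forward matches on one diagonal; diagonal equality gives it an
equal-length reference counterpart. Gap bases are coded with one flag bit
(0 = equal) and a mismatch code on disagreement. The first gap base is
coded flaglessly: the left flank is maximal at its right edge, so that base
is a guaranteed mismatch. The symmetric trick at the gap's last base is
*not* used, because the right flank may owe its left edge to overlap
trimming, and the decoder cannot know whether the guarantee holds.

**Adjacent encoding.** Outside gaps, relative coding extends from a match
boundary into the unmatched neighborhood, starting with a flagless known
mismatch, under the mismatch scoring automaton: score starts at
`score_initial` = 25 %, each mismatch adds and each match subtracts
100/`score_step_x` percent (x = 10 ⇒ 10 % steps), the score is floored at 0
and capped at 100 %, and reaching 100 % terminates the region. Scores are
held internally in integer units of (percent × x), so the automaton is
exact for any x ≥ 1 with no divisibility requirement. Reverse-complement
matches participate with the neighborhood geometry flipped and
complemented.

Because the encoder can stop early at a span boundary the decoder cannot
infer (a contig end, a previous match, a region edge), every adjacency
block writes one entry to a truncation side-stream: 0 means "terminated by
score" (the decoder replays the automaton from the flags), any other value
is the consumed extent + 1. A per-block entry was chosen over entries only
for truncated blocks because the decoder has no independent way to know
which blocks are truncated.

Left-side adjacency is only applied to matches whose reference offset is
stored explicitly. A delta-derived match resolves its offset from its
contig position, which is not yet known while its left block is being
decoded; restricting left blocks to explicit matches breaks that cycle at
negligible cost, since delta-derived matches are almost always preceded by
a gap, where adjacency does not apply anyway.

**Gap-breaks filter.** A match shorter than `gap_breaks_max` (default 256,
strict `<`) whose two list neighbors are corresponding to each other is
removed when it refers elsewhere — a different diagonal or the reverse
strand — and its bases are coded in-gap. A short match *on its neighbors'
own diagonal* is chain structure and is kept; removing it would convert
cheap exact-match bases into flag-coded gap bases for no gain. The filter
runs once over the original list (no fixed-point iteration), and
correspondence is recomputed afterwards.

**Gaps-delta coding.** Each match links to its nearest subsequent
corresponding match if fewer than `corr_window` = 64 other matches lie
between them. A linked target's reference offset is never stored; instead
the source match's delta value counts the gaps (maximal nonempty
inter-match regions) up to the target, ignoring intervening matches that
were themselves resolved from a source earlier than the current match —
such matches are transparent and their flanking regions merge. Delta 0
means "no link"; the last match of a record emits no delta. Correspondence
is restricted to forward-strand matches, because "equal distances in contig
and reference" is exactly diagonal equality and has no analogue across
strands.

The encoder commits a link only after simulating the decoder's counting
walk and confirming it fires exactly at the intended target (it can fail
to, e.g. when all regions between are empty); otherwise the offset is
stored explicitly. The decoder runs the same walk online (`LinkTracker`),
and encode/decode inversion is property-tested on tens of thousands of
randomized match lists that include abutting matches, reverse-strand
members and shared diagonals.

### Encoder policy versus stream mechanism

The literal stream is self-describing (block markers announce adjacency,
gap, packed-run and match tokens), which separates *mechanism* — the block
formats above, always decodable — from *policy* — when the encoder chooses
to emit a block. famec's encoder gates blocks on profitability under the
LZMA backend: adjacency blocks require a probed extent ≥ 16 with mismatches
≤ ¼ of it; gap regions are relatively coded only while mismatches are at
most half the bases (denser regions, e.g. the freed bases of a filtered-out
match, stay as raw literals); gap-break removals additionally require the
removed match's own span to code cheaply against the local counterpart.
These thresholds are encoder heuristics, not format parameters: changing
them changes archive size, never decodability. With techniques disabled the
corresponding marker simply never appears — except that a structural gap
still excludes adjacency even when in-gap coding is off, since gaps are
defined by correspondence, not by how they are coded.

Long raw ACGT runs (≥ 64 bases, notably the reference-seeding first
genome) are stored 2-bit packed in a dedicated stream; DNA at ~2 bits/base
beats what a byte-oriented LZMA achieves on the text form.

## Container and backend

Streams are compressed independently with raw-format LZMA2 (`pb=0, lc=0`,
preset `backend_preset`, extreme mode) — one general-purpose LZMA-class
backend for every stream — and stored verbatim when compression would
expand them. Match lengths are stored as `length − min_match_length`;
offsets carry the strand in their low bit; integers are unsigned LEB128.
Each archived file records a 64-bit blake2b content hash, verified on
extraction: some stream damage necessarily decodes to *wrong* output
rather than a parse error, and the hash converts that into a typed failure
naming the file. Appending and repacking decode the whole collection and
re-encode it (full reference replay); correctness over speed.

## Byte-exact FASTA handling

Uniform line widths are stored as one integer per file (a file is uniform
when one width reproduces every record by chunking); otherwise explicit
per-record line lengths are kept, so irregular and blank-line-containing
files still round-trip exactly. CRLF/LF style and trailing-newline state
are per-file flags; mixed line endings within one file are rejected as
malformed rather than silently normalized. Headers are stored verbatim;
soft-masking is a per-record alternating run-length case mask.

## The synthetic generator

`famec.synthetic` produces collections of descendants of one i.i.d. random
ancestor. Per genome it applies, in order: segment translocations,
reverse-complement inversions, transition-biased substitutions (HKY-like,
ts/tv ratio 3), geometric indels, and runs of N; files are optionally
fragmented into contigs, soft-masked in runs, and written at cycling line
widths. Everything is driven by `numpy` generators spawned from one seed.

The standard study collection is 10 genomes of 100 kb at 30 % GC — sized
like a large bacterial plasmid or a manageable slice of a bacterial
chromosome, with the GC content of *Campylobacter*-like AT-rich organisms —
at 1 % substitution divergence. What passing tests on such data show:
byte-exact losslessness across the mutation classes and formatting
dialects, correct strand handling, and that each coding technique pays for
itself under the stated conditions. What they do not show: behavior on
real pan-genome panels (gene gain/loss, mobile elements, repeat families,
contamination), on multi-megabase chromosomes where index memory and
encode throughput dominate, or on protein FASTA. Ratios on real bacterial
collections are typically far higher than on these synthetics, because
real isolate genomes share long identical tracts while the generator
scatters mutations uniformly.

## Degenerate inputs and tie-breaks

Empty files, empty records, records shorter than `k`, and collections of
one file are all legal and round-trip. Contigs shorter than `k` or matched
before the buffer holds `k` bases are emitted as literals. Ties in match
selection are broken deterministically (earliest start, longest, forward
strand, lowest reference offset), and the whole pipeline is
deterministic: identical inputs and parameters give identical archive
bytes, which the suite asserts.

## Known limitations

- Single-threaded; decode replays every prior contig, so selective
  extraction is correct but not sublinear in collection size.
- No random access to an individual contig without reference replay.
- The reference buffer is capped (`ref_cap`, default 256 MiB) and the
  k-mer index lives in memory; collections far beyond that need a larger
  cap and correspondingly more memory.
- One LZMA-class backend serves all streams; no PPMd-style context-mixing
  backend is provided.
- Gzipped input, FASTQ and alignment formats are out of scope.
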