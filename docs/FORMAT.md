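# famec archive format (version 1)

All multi-byte integers are unsigned LEB128 varints. All offsets are
0-based. A *payload codec* byte is 0 (stored verbatim) or 1 (raw-format
LZMA2, `pb=0, lc=0`, preset taken from the archive's `backend_preset`
parameter, extreme mode; no xz container, no checksum — integrity is
covered by per-file content hashes).

```
archive :=
  magic            4 bytes        "FAMC"
  version          u8             1
  params_block     json_block     codec parameters (CodecConfig fields)
  table_block      json_block     file table (see below)
  n_streams        varint
  directory        n_streams * dir_entry
  payloads         concatenated stream payloads, directory order

json_block :=
  codec            u8             payload codec (0 stored / 1 lzma)
  raw_len          varint         uncompressed JSON length
  comp_len         varint
  payload          comp_len bytes

dir_entry :=
  stream_id        varint         index into the stream list below
  codec            u8 varint      payload codec
  raw_len          varint         uncompressed stream length in bytes
  flag_bits        varint         bit count (nonzero only for "flags")
  comp_len         varint         payload length in bytes
```

The file table is a JSON array of objects
`{"path", "n_records", "raw_size", "hash"}` where `hash` is the hex
blake2b-64 of the original file bytes. Listing an archive needs only the
header; no sequence stream is touched.

## Streams

| id | name        | content |
|----|-------------|---------|
| 0  | literals    | per-record literal segment (grammar below) |
| 1  | flags       | mismatch flag bits, little-endian packed |
| 2  | offsets     | varints `(ref_start << 1) | strand` for explicit matches |
| 3  | lengths     | varints `match_length − min_match_length`, one per match |
| 4  | gaps_delta  | varints, one per match except each record's last |
| 5  | extents     | adjacency truncation entries (0 = score-terminated, else extent+1) |
| 6  | gap_lengths | varints, one per gap-coded region |
| 7  | packed      | 2-bit packed long ACGT literal runs (4 bases/byte, low bits first, each run zero-padded to a byte) |
| 8  | pack_lengths| varints, run length in bases per PACK_MARK |
| 9  | headers     | record header bytes, `\n`-terminated, in record order |
| 10 | meta        | per-file/record formatting metadata varints |

## Literal-stream grammar (per record)

Reserved byte values: codes 0–3, SEQ_MARK 0x04, LEFT_MARK 0x05,
RIGHT_MARK 0x06, GAP_MARK 0x07, ESC 0x08, PACK_MARK 0x09,
MATCH_MARK 0x25 ('%'). Any residue byte colliding with these is written as
ESC + byte.

```
record   := item* SEQ_MARK
item     := raw-byte | ESC byte
          | PACK_MARK                      (run length from pack_lengths)
          | MATCH_MARK                     (one match; streams 2-4)
          | RIGHT_MARK known mismatches    (right adjacency of last match)
          | LEFT_MARK  known mismatches raw* MATCH_MARK
                                           (left adjacency, then the raw
                                            remainder, then the match)
          | GAP_MARK   known mismatches    (gap region; length from
                                            gap_lengths; implies the match
                                            that follows — no MATCH_MARK)
known    := code 0-3 | raw base            (the boundary/first-gap base,
                                            flagless; code 3 is followed by
                                            one raw byte; with the matrix
                                            ablated a raw base byte appears
                                            instead of a code)
```

Adjacency blocks consume one `extents` entry and are driven by the scoring
automaton replayed from the flag bits; gap regions consume one
`gap_lengths` entry and one flag bit per base after the first.

## Per-record metadata (stream 10)

Per file: flags varint (bit0 CRLF, bit1 trailing newline, bit2 empty file,
bit3 irregular widths), line width varint (0 when irregular), record count.
Per record, after its literal segment: residue length; case-mask header
`(n_runs << 1) | first_is_lower` followed by the run lengths; for irregular
files the explicit per-record line lengths; finally the
reference-extension flag (1 = the decoder must append the record's
uppercased, ACGT-mapped residues to the reference buffer).
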