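# Methods

## Model and procedure

The codec treats a genome as a one-line text `T` of length `t` over the
fixed, ordered alphabet `A,C,G,T,N`. `T` is cut into `⌈t/w⌉`
non-overlapping windows of length `w`; the trailing window keeps its
natural length `t mod w` and is labelled and binned like any other (its
length is recovered from `t` in the archive header, so no padding is ever
introduced). Each window is summarised by the multiset of code lengths a
Huffman tree assigns to its base frequencies, formatted as
`<symbols>_<digits>` (e.g. `GATC_1233`) and truncated to the `k`
shortest-code symbols. Windows sharing a label are concatenated, in order
of appearance, into one bin; each bin is compressed independently by a
general-purpose backend; the per-window label stream `L` is entropy-coded;
and everything is framed into a single archive carrying `w`, `k`, `t`, the
alphabet, the backend id and a SHA-256 of `T`. Decompression inverts each
stage and refuses to return text that fails the checksum.

The premise is empirical: window-scale base composition in real genomes is
locally skewed, and compositionally similar regions recur at distances far
beyond the reach of LZ windows. Binning is a permutation of `T` (plus the
recipe `L` to undo it) chosen so that a codec's local redundancy detection
operates within compositionally homogeneous, repeat-enriched blocks.

## Labelling: canonical construction and tie-breaks

Only code lengths matter, never codewords, so the Huffman construction is
fixed to be fully deterministic: merge the two lowest-weight nodes,
breaking ties by lower weight first, then earlier creation order; leaves
are created in alphabet order before any internal node. Three further
choices close gaps the worked examples leave open:

* **Single-symbol windows.** A one-leaf tree would need a 0-bit code; we
  assign length 1 (a real emitted code needs at least one bit), so `A_1`
  is well defined.
* **Absent symbols** never appear in a label: two windows with different
  present-symbol sets never share a full-length label.
* **Label ordering** is (code length ascending, frequency descending,
  alphabet order). This makes truncation consistent — the label at `k1 <
  k2` is a prefix (symbols and digits) of the label at `k2` — and is
  verified against the printed example ordering (`GATC_1233` with T
  before C requires the frequency tie-break to precede alphabet order).

With five symbols the maximum code length is 4, so one digit per symbol
suffices; an alphabet with more than ten symbols would need delimited
digits, which the format does not implement.

## Archive format and the label stream

The container uses little-endian fixed-width integers and length-prefixed
strings; the exact layout is documented in `ostdna/container.py`. `L` is
coded with a canonical Huffman code over label ids assigned in
first-appearance order, using the same tie rules as window labelling; both
sides derive the codewords from the stored code lengths, and a
single-label stream stores only its entry count (empty payload, recorded
code length 0). Bins are keyed and written in first-appearance order, so
identical input and parameters yield byte-identical archives. Decoding
validates magic, version, counts, Kraft equality of the stored lengths,
zero padding after the final codeword, cursor conservation during
reassembly, and finally the SHA-256 — tampering surfaces as a structural
corruption error or a checksum mismatch, never as silently wrong output.

The lossless-FASTA sidecar (headers, per-record line lengths, soft-mask
case intervals, dropped non-ACGTN characters with insertion points, and
whether the file ended in a newline) is serialised as compact JSON,
compressed with the same backend, and stored in a trailing flagged slot of
the archive. Dropped characters are recorded at their insertion point in
final-text coordinates and re-inserted right-to-left on restore, which
keeps adjacent dropped characters in their original order. The
benchmarking ("paper") mode instead deletes headers, newlines, lowercase
bases and non-ACGTN characters outright and stores nothing.

## Backends

Bins are compressed by pluggable codecs with library-default settings,
single-threaded: `identity` (id 0), `deflate` (1), `bzip2` (2), `xz` (3),
and — when their modules are importable — `zstd` (4) and `brotli` (5).
Numeric ids are frozen in the header for compatibility. The identity
backend exists for exact overhead accounting: with it, archive size equals
`t` plus the coded `L` plus fixed framing, byte for byte.

## Synthetic genomes

The generator emulates exactly the two motivating observations and
nothing else. A genome is a concatenation of segments (length uniform in
500–2000) whose base probabilities are drawn from a symmetric
Dirichlet(α=0.3) over A,C,G,T — small α gives strongly skewed segments.
Twenty repeat families are planted: each is one random 2 kb master copied
three times at starts ≥ 100 kb apart (rejection sampling; overlap between
any two planted copies is also forbidden, and infeasible configurations
raise an error rather than silently degrade), each copy independently
point-mutated at 1 %. N-runs (assembly gaps) are overlaid last at a rate
of 1e-5 runs per base with lengths 10–100, skipping planted repeats so
unmutated copies remain exact substrings. The default length is 10 Mb.
Randomness is numpy's PCG64 seeded explicitly, so output is byte-stable
across platforms.

What this model omits — and what passing tests therefore do not show —
includes GC isochores, transposon families with indel divergence,
chromosome-scale composition gradients, and any sequencing artefacts.
The benefit measurements characterise the codec under the stated regime,
not on arbitrary real assemblies, though the mechanism they exercise
(distant similar windows pooled before compression) is the same one real
repeats provide.

## Evaluation choices

Compression ratio is 100 × compressed/original in percent, lower better.
Ratios are computed on full archive bytes (header and coded `L`
included), the honest end-to-end cost; the bins-only byte count is also
reported for comparison with pipelines that keep per-bin files without a
container. Every ratio reported by `evalbench` comes from a run whose
round trip was verified first. Wall times and MB/s speeds are recorded
but never asserted (hardware-dependent). The sweep grid defaults to
window lengths 25–10,000 and label lengths 1–5; the best cell is the
minimum ratio with ties to smaller `w`, then smaller `k`. The CLI
defaults (`w=250`, `k=2`, bzip2) are the best bundled-backend cell of
that grid on the benchmarking protocol this package follows.

Problem sizes in the shipped tests and the acceptance script are chosen
for a single CPU: ten 10 Mb genomes for the benefit comparison, 1000
fuzzed texts up to 10 kb for losslessness, ~53k exhaustive count multisets
(counts ≤ 20; Huffman cost depends only on the multiset) plus 10^4 random
tables for the optimality oracle. The oracle is independent of the
implementation: it enumerates every Kraft-equality code-length profile
for ≤ 5 symbols and applies the rearrangement inequality.

## Known limitations

* Window length is fixed per run; adaptive/variable windows and nested
  sub-binning are out of scope.
* `L` is coded per entry; run-length coding could beat it on genomes with
  long homogeneous stretches and is not explored.
* The archive is single-member, unencrypted, and not seekable.
* Non-DNA alphabets work in principle but the label format caps the
  alphabet at ten symbols, and only `A,C,G,T,N` is exercised.
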