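# Methods

This note documents the models and numerical choices behind duplexkit: how
consensus calling is defined, what the simulator does and does not emulate,
and where the design was genuinely open.

## Family construction

A read pair's barcode is the pair of 12-bp tags at the start of its two
mates (α from mate 1, β from mate 2), order-normalised into a 24-bp
*canonical barcode* by plain string comparison: `α+β` if `α ≤ β`, else
`β+α`. The physical order is kept as a separate field (`AB`/`BA`) and
identifies the strand. The tag and the following 5-bp constant linker are
removed from both mates before any alignment.

Grouping is by exact barcode match. Tags containing `N` are kept verbatim —
such reads simply found their own families and are eliminated by the
family-size threshold downstream. A tag tie (`α == β`) is labelled `AB`;
this makes grouping deterministic at the cost of the strand-swap symmetry in
that measure-zero case. Reads shorter than tag + linker + 1 are rejected and
counted.

## Family alignment

Reads within one strand family are near-identical — they differ by scattered
polymerase/sequencer errors — so a general-purpose MSA is unnecessary. The
built-in aligner is a center-star progressive alignment: the longest read is
the center (ties broken by input order), every other read is globally
aligned to it (edlib's Needleman–Wunsch), and the pairwise alignments are
merged on the center's coordinates, one insertion block per center position
sized to the largest insertion observed there, insertions left-aligned
within the block. The construction guarantees that each row degaps to its
input read exactly and that no column is all-gap, and it is deterministic.
An optional backend shells out to MAFFT (`--backend mafft`) for users who
prefer a full MSA; the builtin backend is the reference behaviour for tests.

Gap positions in a row carry a sentinel in the gapped quality string, never
a real Phred value.

## Consensus calling

**Column rule.** Characters (gaps included) whose quality passes the
threshold (default Phred 20) vote; the character with *strictly more than
half* of the counted votes is the consensus, otherwise `N`. "Majority" is
deliberately > 50 %, not plurality. If nothing passes the filter the call is
`N`. Columns whose consensus is a gap are removed from the output sequence.

**Gap quality.** A gap inherits a quality from its row's context: up to four
nearest real bases on each side, the neighbour at rank distance d (1 =
nearest) weighted `5 − d` (i.e. 4, 3, 2, 1), weights renormalised near
sequence ends; a row with no real base scores 0. The "eight nearest,
linearly decreasing" shape is fixed by the method; the constants 4…1 and the
end-of-read renormalisation are this package's choice and are pinned by unit
tests.

**SSCS.** Called per (canonical barcode, tag order, mate) group with at
least `min_reads` (default 3) members. The production path is vectorised
(numpy byte matrices); a brute-force per-column tally written independently
serves as its oracle in the test suite (1,000 random families).

**DCS.** The two opposite-strand SSCSs of a fragment are aligned with a
local Smith–Waterman and reconciled column-wise: agreement keeps the base,
two distinct bases give the two-base IUPAC code, and any pairing involving a
gap or an `N` gives `N` — ignorance is never outvoted. Columns outside the
local alignment are excluded; when the alignment truncates an SSCS the event
is logged. Mates swap across strands (opposite tag order means opposite
physical strand), so DCS mate 1 reconciles SSCS(AB, mate 1) with
SSCS(BA, mate 2).

**Smith–Waterman.** Gotoh affine-gap local alignment, default scores
match +1, mismatch −1, gap open −2, gap extend −1 (a length-g gap costs
`open + (g−1)·extend`). The method's source does not fix these constants, so
they are exposed as parameters. `N` scores as a mismatch against everything,
including `N`. Traceback ties break deterministically diagonal > up > left,
and the optimum cell is the first maximal cell in row-major order. The fill
is numba-compiled; an independent pure-Python textbook DP is the oracle (500
random pairs).

**Trimming.** `remove` drops a sequence whose non-ACGT fraction exceeds the
threshold (default 0.3). `trim` walks a window (default 10 bp) in from each
end, cutting until the window's ambiguous fraction is within the threshold
and the boundary base itself is unambiguous; an interior window over the
threshold truncates the sequence at that point. Consensus FASTA can be
converted to FASTQ at a fixed quality (default Phred 40), since consensi
carry no per-base qualities of their own.

## Simulator

The simulator emulates a duplex experiment at the level the analysis sees:

- Fragments: uniform start and strand on a linear reference (default 600 bp;
  the singleton experiments use 400 bp with 100-bp reads).
- The amplified molecule is `α + linker + insert + rc(linker) + rc(β)` with
  fresh random 12-bp tags per fragment and the constant linker `TGACT` (only
  the linker's length matters; the sequence is configurable). Errors are
  applied to this whole molecule, so tags corrupt at the same rate as the
  insert and artifactual singleton families arise mechanistically rather
  than by a bolted-on model.
- Family size per fragment is drawn from a discretised log-normal
  (σ = 0.55) shifted to put its mode at nine reads — the shape of observed
  duplex family-size distributions — with the singleton mass exposed as a
  parameter (default 1.20 %). The experiments that hold the "starting
  distribution" fixed draw one realized assignment with an *exact* singleton
  count and reuse it across conditions.
- Read genealogy: backward coalescent from the last PCR cycle (default 30).
  At each cycle c, open lineages are shuffled and successive disjoint pairs
  merge with probability `2^−c`; survivors of the last merge round attach
  uniformly to the two first-cycle daughter molecules, which are the
  fragment's physical strands and fix each read's tag order. The pairing
  scheme (shuffle + disjoint successive pairs) realises the stated pairwise
  probability without quadratic work; it is this package's choice and is
  validated against the analytic merge-cycle distribution for two lineages.
- Errors: on a branch spanning k cycles each base mutates with per-base
  per-cycle probability 0.001 (default); a mutation is an indel with
  probability 0.15 (insertion/deletion equiprobable, geometric length with
  extension probability 0.3) and otherwise a substitution to a uniformly
  chosen different base. Descendants inherit ancestral mutations; each leaf
  gets one extra error round for the sequencing reaction.
- Reads: the first `read_length` bases of the final molecule and of its
  reverse complement (swapped for the second daughter), all qualities fixed
  at Phred 40.

What it does **not** emulate: quality-score profiles (qualities are
constant), GC/coverage bias, adapter read-through, chimeras/heteroduplexes,
or polymerase error spectra (errors are uniform). Tests passing on
simulated data therefore demonstrate the correctness of the grouping,
alignment, consensus and accounting logic under the stated error model —
not robustness to every artefact of real libraries.

A truth-based pileup helper places each DCS on the reference by aligning it
(edlib, infix mode) against its fragment's recorded origin window, oriented
through the fragment's strand and tag order. Alignment-based placement
tolerates the indels that strand-fixed PCR errors leave in consensus
sequences, exactly as read mapping would; mapping itself is outside this
package's scope, but with the origin known a windowed pairwise alignment
suffices. Only A/C/G/T calls on match/mismatch columns are counted —
`N` and IUPAC ambiguity codes are never counted as alleles.

## Barcode-error model

`r = 1 − (1−E)^l` is used three ways: per-base rate over a 24-bp barcode;
per-stage rate over 31 stages (30 PCR cycles + 1 sequencing reaction — the
stage count is this package's documented assumption) to produce the
cumulative per-base rate; and inverted,
`E = 1 − (1−r)^(1/l)`, to estimate the cumulative rate from the observed
singleton-family fraction `singletons / total read pairs`. The expected
family count for n fragments sequenced into m pairs is `n + round(m·r)`
(half-up). Two simplifying assumptions are kept deliberately: every
erroneous barcode is unique, and errors occur only within tags. The
inversion is exact in the r → E → r direction (tested to 1e−12); the
E → r → E direction is ill-conditioned when r approaches 1 and is not a
contract.

## Site filtering

Minor allele frequency is the second-most-frequent allele's count over
depth (ties by count then alphabet). Strand bias is
`SB = |b/(a+b) − d/(c+d)| / ((b+d)/N)` over major (a, c) and minor (b, d)
counts on the two strands: 0 for balanced support, invariant under strand
relabelling, growing with imbalance, undefined (filter-failing) when a
strand has no coverage, and 0 when there is no minor allele. Several
strand-bias statistics exist in the literature with these properties; this
one is pinned in code and only its qualitative contract is asserted.
Default filters: MAF ≥ 0.5 %, SB < 1, depth ≥ 0 (the mitochondrial analyses
this supports used a 10,000× DCS floor, configurable via `depth_min`).
Positions are 1-based in all site tables.

## Problem sizes used in the test suite

The two simulation studies run scaled down, with fixed seeds: the spike-in
mixing experiment uses a synthetic 16.6-kb reference, 21 injected variants
(pairwise spacing ≥ 600 bp), a 1:100 mix of 1,000 mutant + 100,000 reference
fragments at error rate 0.001, asserting that every injected variant is
recovered among DCS alleles and that no uninjected site reaches the
injected sites' minimum frequency; the error-rate/singleton experiment uses
10,000 fragments for the exact zero-error check and 3,000 fragments per
rate for the monotonicity check across {0, 0.0005, 0.001}. The full-scale
protocol (25 M fragments, 1:10,000 mix) is supported by the same code path
but is not exercised by the test suite.

## Known limitations

- Exact-match grouping only; no mismatch-tolerant barcode clustering.
- Consensus sequences carry no posterior per-base qualities.
- The center-star aligner is built for near-identical reads; highly
  divergent families (which should not occur under exact barcode grouping)
  would be better served by the MAFFT backend.
- An indel fixed early on one strand produces an `N` column and, near read
  boundaries, a shifted/truncated DCS — visible in the simulator's
  truth-based comparisons; such sequences are skipped by the truth pileup.
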