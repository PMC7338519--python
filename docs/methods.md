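# Methods

This note documents the models and procedures implemented in `fernplast`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that make
results reproducible.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open; GenBank and GFF3 conversion
(1-based inclusive) happens only at the I/O boundary. Circular genomes are
first-class: an interval may wrap the origin, and scanners that need linear
sequence unroll the circle internally (never in the data model). `N` is a
legal base that pairs with and matches nothing; ORFs may contain interior
`N` (translated as `X`), but no start or stop codon can contain one.

## Inverted-repeat detection and quadripartite partition

The two IR copies of a plastome satisfy `seq[x] == complement(seq[c - x])`
for a fixed anti-diagonal constant `c`. The detector indexes all k-mers
(k = 21 by default), finds positions whose reverse complement recurs, groups
the resulting seed pairs by `c` (substitutions between the copies do not
move a pair off its anti-diagonal, so one IR yields one group), and extends
the seeded core outward and inward. Extension scores +1 per complementary
pair and −5 per mismatch and stops when the running score falls 30 below its
maximum (X-drop); the boundary is placed at the score maximum, which by
construction trims trailing mismatches. A candidate qualifies if its copies
do not overlap, its length is ≥ `min_ir_len` (default 1,000 bp; configurable
down to 100 bp for toys) and its mismatch count is at most
`max_mismatch_frac × length` (default 1%). Ties between maximal candidates
are broken by fewer mismatches, then smaller start coordinate.

The mismatch penalty and drop threshold were chosen so that, on repeats whose
copies diverge at ≈1%, crossing an isolated substitution costs little while
continuing into unrelated flanking sequence (75% mismatch density) is
unprofitable within a few bases; with a −5 penalty, moving a boundary one
mismatch outward requires six chance complementary pairs (probability 4⁻⁶).
When the copies are expected to diverge at rate 2·µ (genome-wide substitution
rate µ hits each copy independently), the budget should be set to about twice
that divergence; the package default of 1% suits the near-identical copies of
real plastomes, where intramolecular recombination homogenizes the IRs.

The partition assigns the longer single-copy arc between the copies as LSC
(tie: the arc containing position 0), walks the circle as LSC → IRb → SSC →
IRa, and validates that the four regions tile it exactly with
`span(IRa) = span(IRb)`.

## ORF scanning

An ORF runs from a start codon (ATG only by default) to the next in-frame
stop of the bacterial/plastid code (table 11), on either strand in any
frame; when several starts share a stop only the 5′-most (longest) is
reported. Both published thresholds are applied conjunctively — length
strictly greater than 303 bp *and* more than 100 aa — which at codon
granularity coincide at ≥ 306 nt / ≥ 101 aa. `nt_len` counts start through
stop inclusive, so `nt_len = 3·(aa_len + 1)`.

Internally, codons are scored vectorially (base-4 codon values), stops and
starts located per frame, and the 5′-most start after each previous stop
found by binary search. Circular sequences are unrolled to two copies plus
two bases — enough for any stop to see a full circle of upstream context —
and hits are grouped per physical stop codon, which enforces the 5′-most
rule around the origin. ORFs longer than the genome (no stop anywhere on the
circle in frame) are not reported.

## Stem-loop scanning

A stem-loop is a pair of exactly reverse-complementary arms (Watson–Crick
only, no G·U; mismatch budget 0 by default) separated by a loop. Defaults
follow the 5 bp stem / 5 bp loop / 20 bp total convention, with loop length
bounded by 100 bp — cassette-terminal palindromes are compact hairpins, and
an unbounded loop would make "palindrome" meaningless at genome scale; the
bound is a parameter, not a claim. A reported hairpin is *maximal*: the stem
can be extended neither outward nor inward by one more pair, regardless of
whether the extension would still satisfy the loop minimum. All maximal
hairpins are reported, including overlapping ones; downstream consumers
filter by window.

The scanner slices by inner-pair distance `d = loop + 1`: for each `d` it
vectorizes the innermost-pair predicate and the first `min_stem` outward
pairs over all positions, applies the inward-maximality mask, and finishes
survivors (rare in random sequence: ≈ 4^-min_stem per position·distance)
with explicit outward extension. This is fast enough for whole plastomes.
A positive mismatch budget switches to direct enumeration, intended for
short sequences. The test oracle instead builds the full pair matrix and a
run-length recurrence over anti-diagonals — a deliberately different route.

## MORFFO homology search and context classification

Queries are searched on both target strands by exact k-mer seeding (k = 12),
clustering of seeds by diagonal and position, ungapped X-drop extension
(match +1, mismatch −2, drop 20) to size a window, and an optimal affine-gap
local alignment (Gotoh; gap of length g costs 4 + g) over the window.
Redundant hits (>50% overlap on the target, per query and strand) keep only
the highest score. A hit must span at least 100 alignment columns — the
published locus rule — and at least 70% identity; the identity floor is this
package's addition, deliberately more conservative than the length rule
alone, because a bare 100-column floor admits junk alignments at permissive
scoring. Whether the 100 bp rule means alignment columns or ungapped match
length is not specified by convention; alignment columns are used.

Hits are grouped into loci by the annotated context of their midpoints (gene
name, or `geneA-geneB` spacer name, else `unplaced`), because counts of
interest are loci, not hits. A locus is *tRNA-flanked* when at least one of
the two genes immediately flanking the merged hit region is a tRNA (a
stricter both-ends mode is available), and *stem-loop-flanked* when a
qualifying hairpin intersects the ±50 bp window around **each** end of the
merged region. Fractions in the context summary are always computed from
counts, never assumed.

Note that at the default 5/5/20 hairpin thresholds random sequence contains
roughly one qualifying hairpin per ~11 bp of scan, so the both-ends flag has
limited specificity at a 50 bp window; it is reported as the convention
requires, and the per-locus table carries the actual flanking hairpins so
stricter post-filters can be applied.

The in-repo Smith–Waterman (numba-compiled, full matrices, traceback by
score recomputation) serves as the optimality oracle for the windowed
search; its scores are independently cross-checked against Biopython's
local `PairwiseAligner` in the test suite.

## Pairwise identity with region masking

Identity is defined over the columns of a global alignment: match, mismatch,
or gap; gap columns count as differences (they can optionally be excluded).
The definition matters — published identity figures are method-dependent —
so it is fixed and stated rather than inferred: match +1, mismatch −1, a gap
of length g costs 5 + g, and `pct = 100 · matches / counted columns`
reported to 2 decimals. A column is masked when **either** of its two genome
positions lies inside a masked region (a named IGS, a gene, or explicit
coordinates); masked columns leave both numerator and denominator. Masking
both genomes' copies of a hotspot spacer yields the "variation ignored"
contrast.

`exact-dp` mode is the optimal global affine alignment (Biopython's
PairwiseAligner), capped at 10⁸ DP cells. `anchor-chain` mode takes k = 19
mers unique in both genomes, chains the longest collinear subsequence,
merges same-diagonal runs, and aligns inter-anchor segments with the exact
DP — so it equals `exact-dp` whenever the anchors are correct, which the
equivalence suite checks on random diverged pairs. Inter-anchor segments
above 2.5×10⁷ cells (only heavily diverged hotspots in full-size genomes)
fall back to an edit-distance path (edlib); such segments are precisely the
ones masked in the analyses that matter. Circular genomes are rotated to a
shared anchor gene (default `rrn16`) before alignment; the rotation is
undone in the column→position maps, so masks are specified in original
coordinates.

## Flow-cytometry 1C estimation

Fluorescence is proportional to DNA content, so
`1C = (sample mode / reference mode) × standard` with the *N. tabacum*
standard 5.18 (the value is carried through in the unit convention of the
cited standard; no unit conversion is attempted). Peak positions are modes
of a Gaussian KDE (Silverman bandwidth by default, 4096-point grid over the
padded event range); the mode is preferred to the mean as it is insensitive
to debris tails. The `n_peaks` highest-density modes are returned in
ascending intensity; in a mixed reference+sample table the lowest mode is
the reference. Peak CV is computed from the events nearest each mode within
`max(2·bandwidth, 10% of the mode)` — a pure ±2-bandwidth window grossly
underestimates CV when the KDE bandwidth is much narrower than the peak.
Estimates are reported to 2 decimals; replicates aggregate as mean ± sample
standard deviation (ddof = 1, sd = 0 for n = 1), so identical replicates
reproduce a "± 0.00" display while the unrounded sd is also reported.

## The synthetic-data generator

The generator is the package's ground truth and defines the conditions under
which everything is tested:

- **Genomes**: 150 kb circle (LSC + IRb + SSC + IRa, IRa ending at the
  origin), GC 38%, IR drawn from 10–25 kb unless fixed, SSC 21 kb — the
  envelope of real filmy-fern plastomes (144–161 kb, GC 37.5–38.6%, IR
  10.5–24.9 kb). IRa is the exact reverse complement of IRb. A standard gene
  set (tRNAs `trnH/trnE/trnG/trnV-GAC/trnP`, rRNA `rrn16`, CDSs including
  `rps12`, `ndhF`, `ndhA`) is laid out with even spacers except a fixed
  2,200 bp `rrn16–trnV-GAC` spacer, the unexpanded length of the hotspot in
  real genomes. Genes are placed only in single-copy regions.
- **Guard bases**: two base pairs at each planted-structure boundary are set
  to non-complementary values (a base can never pair with itself), so the
  planted IR and the cassette stem-loops are also the *maximal* structures —
  otherwise chance pairings would shift truth coordinates in a quarter of
  simulations and boundary recovery could not be asserted exactly.
- **Cassettes**: terminal stem-loops (arm 8, loop 9, total 25 — comfortably
  above the 5/5/20 floor) around a long ORF (default 400 aa, within the
  101–1,274 aa envelope of reported cassette ORFs) built from sense codons
  with an all-frame stop block immediately upstream, pinning the ORF 5′ end.
  The clean cassette is emitted as the homology query. With
  `planted_identity < 1`, substitutions hit only the cassette interior —
  the terminal palindromes are the element's conserved recognition
  structures and are left intact.
- **Divergence**: substitutions first (per-site Bernoulli; a substituted
  base always changes), then indels (length 1–3), then the hotspot
  insertion at the spacer midpoint; features are remapped through a
  breakpoint table and truth coordinates refer to the mutated genome. The
  default contrast pair uses 1.8% background substitutions and a diverged
  (+30%) and expanded (+3–5 kb) hotspot, emulating the published
  whole-sequence ≈93% vs hotspot-ignored ≈98% pattern qualitatively.
- **Flow**: Gaussian mixture at specified ratios and CVs over a reference
  peak at 100 a.u., plus a uniform debris floor (5%). Ratios 3.12 and 2.87
  reproduce 1C magnitudes of ≈16.16 and ≈14.87 against the 5.18 standard.

Non-realisms, stated plainly: background sequence is i.i.d. per base (no
dinucleotide structure, no repeats beyond the IR), genes are random sequence
(only their annotations matter), the IRs carry no genes, and divergence has
no transition/transversion or rate heterogeneity structure. Passing tests
therefore demonstrate algorithmic correctness against known truth — exact
coordinate recovery, threshold behaviour, rate recovery — not performance on
the compositional idiosyncrasies of real plastomes. Real-data use goes
through the same GenBank/GFF3 readers and the same parameters.

## Problem sizes and determinism

The test suite validates scanners against exhaustive oracles on 1,000 random
sequences (500 bp for stem-loops, 10 kb for ORFs), boundary recovery on 100
planted 150 kb genomes (mutation-free and at 0.5% substitutions, the latter
with the mismatch budget at twice the expected arm divergence, per the rule
above), cassette recovery on 100 planted + 100 null genomes, aligner
equivalence on 50 pairs, and 1C recovery on 200 simulations; the acceptance
script runs the full study once at the default conditions. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
reports contain no timestamps, and a fixed seed reproduces every output file
byte for byte.

## Known limitations

- The IR detector assumes substitution-only divergence between copies (one
  anti-diagonal); an indel between the copies splits the seed group and
  would shorten the reported repeat. Real plastome IRs are homogenized
  enough that this is rarely limiting.
- Wrapping (origin-crossing) IRs are not detected; the simulator never
  generates them and real records are conventionally linearized with the
  IRa at the end.
- `anchor-chain` equals exact DP only while unique-k-mer anchors are
  uniformly correct; above ~15% divergence anchor scarcity degrades it.
- The homology search reports non-redundant local hits, not a spliced
  co-linear chain per query; a cassette fragmented by large insertions
  appears as multiple hits in one locus (which the locus grouping absorbs).
- Flow-cytometry estimation assumes well-separated peaks; G2/endopolyploid
  peaks and non-linear instrument response are out of scope.
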