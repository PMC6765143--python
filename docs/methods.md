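# Methods

## Motif algebra

A telomere motif is a primitive circular word over {A,C,G,T}, stored on the
G-strand. Primitivity means the unit is not a whole repetition of a shorter
word — formally, its smallest weak period does not properly divide its
length. (The weak period p of a string s is the smallest p with
s[i] = s[i+p] wherever both are defined; rotations of a primitive unit can
carry a non-dividing weak period shorter than the unit, e.g. GTTAGG with
weak period 5, and are still primitive.) Identity and hashing use the
lexicographically minimal rotation; display uses the rotation starting
immediately 3' of the longest circular G-run (ties go to the smallest
candidate string), which reproduces the conventional spellings TTAGGG,
TTTAGGG, CTCGGTTATGGG, TTCAGG, TTTTTTAGGG and so on without a lookup table.
Units with no G fall back to the canonical rotation.

The minimal-template permutation set of an L-bp motif with extension e is
the set of distinct (L+e)-mers of the doubled C-strand unit: exactly L
strings for e < L. The default e = 1 encodes the biological constraint that
a functional template must exceed one repeat unit by at least the anchor
nucleotide.

## Template inference and its intrinsic ambiguity

`predict_telomere_motif` takes the smallest weak period p of the template
within [min_unit, max_unit] (defaults 5 and 15: one unit below the smallest
plant telomere unit of 6 bp, and covering the 12-bp onion unit with slack),
requires at least one nucleotide of overhang, and reports the unit
template[0:p], its reverse-complement motif, the span n/p in units, and the
anchor (n − p below two units, n mod p above). Periods below min_unit raise
a degenerate-template error; no usable period raises a no-periodic-template
error.

This rule is a maximum-parsimony choice and cannot be infallible: a window
of length L+1 cut from an L-unit repeat is, with probability roughly
4^-(e+1) summed over shorter candidate periods, *also* a perfect window of
a different, shorter unit (AAGTAGCTAA is simultaneously a 1-nt-overhang
window of CTACTTTAG and of AAGTAGCT). Measured over random primitive motifs
of 5–15 nt with 1–6 nt overhangs, about 1.3% of windows are ambiguous in
this sense. The test suite therefore asserts that every prediction is a
valid circular-repeat explanation of its template and that mismatches occur
only on such ambiguous windows; longer overhangs resolve the ambiguity
exponentially fast. `enumerate_compatible_motifs` sidesteps the commitment
entirely by reporting every maximal p-periodic window for every p in range
(windows whose unit is a whole repetition of a shorter unit are skipped —
the shorter period already reports that motif); mixed-type templates
produce several entries.

## Screening

Matching is exact, case-normalized, over the full unwrapped sequence, so a
permutation split across FASTA line wraps is still found (an improvement
over line-based text search). The default is sense-strand only, matching
stranded RNA-seq assemblies; `strand_mode="both"` covers unstranded ones.
Windows containing N never match. Transcript ids must be unique within a
dataset; collisions across datasets are fine (assembler ids recur between
runs) because candidates are namespaced by dataset.

## Cross-species comparison

The aligner is a full Smith–Waterman/Gotoh dynamic program with affine gaps
under BLASTN-style scoring (match +2, mismatch −3, a k-base gap costs
5 + 2k), searched over both strands of the subject; traceback ties prefer
diagonal, then vertical, then horizontal moves, and among equal-scoring end
cells the smallest (row, column) wins. There is no word seeding: candidate
transcripts are hundreds of nucleotides, so the O(nm) program is exact and
fast enough (a compiled kernel performs the score-only pass; full traceback
runs only for pairs that clear the score threshold). Sequences above 100 kb
are rejected — this is a transcript-scale aligner. An optional exact k-mer
prefilter exists for very large candidate sets but is off by default.

A hit passes when score ≥ 40, identity ≥ 0.70 (gap columns count in the
denominator) and aligned length ≥ 40 nt. These acceptance thresholds are
declared defaults, not inferred ones: raw-score acceptance replaces E-value
statistics, which would require Karlin–Altschul calibration the method does
not otherwise need. A relaxed mode (match +1, mismatch −1, halved score
cutoff) recovers deeply diverged orthologs in query-driven extension; each
extension hit is annotated with whether the target contains a periodic
template window, standing in for manual inspection of conserved regions.

Presence classification marks a candidate present in another dataset when
any candidate there yields a passing hit; rows are classed shared_in_all,
shared_in_some or unique. Ortholog groups are single-linkage connected
components over passing hits; the final candidate set is the groups whose
members span every dataset. Consensus identity uses per-column majority
over non-gap residues (ties alphabetical, all-gap columns stay gaps), with
per-sequence identity computed over that sequence's non-gap columns; a
mean-of-all-pairs variant is exposed alongside since "pairwise identity to
a consensus" admits both readings.

## Annotation

Template-domain candidates are periodic windows filtered for span ≥ 9/7
units (one unit plus a 2-nt anchor on a 7-bp repeat), C-strand unit
C-content ≥ 0.25 and ≥ 3 distinct bases, ranked by span then 5'-position.
Chance windows in C-rich tracts can outrank a real template, so all
candidates are reported as features with rank annotations — cross-species
conservation, not periodicity alone, settles the true template.
Compositional regions use 15-nt sliding windows (G ≥ 0.5, C ≥ 0.5,
A+T ≥ 0.8, all overridable); qualifying windows are merged into maximal
intervals, trimmed of terminal bases outside the composition class, and
scored by the best full window inside (or the interval's own fraction when
shorter than one window).

Promoter elements are found with log-odds base-2 PWMs built from
user-supplied equal-length site alignments with pseudocount 0.5 against a
uniform background; no promoter matrices ship as ground truth, since no
machine-readable site alignment underlies the published logos. A literal
TATAAA matcher (≤ 1 mismatch, flagged heuristic) covers the no-sites case.
Promoter scans run on upstream genomic context only; the Pol III terminator
— the first run of ≥ 4 T within 200 nt — on downstream context only. End
support counts reads containing the transcript's terminal k-mer (k = 20,
either orientation, optional fuzzy matching); note a read must reach the
transcript end exactly, so even deep uniform coverage yields modest counts.
GFF3 output is 1-based inclusive and byte-deterministic for fixed inputs.

## TRAP and TRF

TRAP products are parsed greedily after locating the substrate primer
(≤ 1 mismatch): each unit-length window is matched against all rotations of
the G-strand unit, accepting ≤ 1 mismatch per unit, ties keeping the
previous phase; parsing stops at the reverse complement of the reverse
primer or the end, and the decomposition must reconstruct the input exactly
(enforced as a type invariant). Global DP decomposition is out of scope.
Ladder periodicity is the modal gap between successive distinct product
lengths, ties toward the smaller gap. The TRF weighted median weights each
band by intensity/size by default (molar correction — longer fragments bind
proportionally more probe); raw-intensity weighting is a flag, since the
underlying convention is not uniquely fixed in the literature. The median
is the smallest size whose cumulative normalized weight reaches 0.5.

## Synthetic data

The simulator emulates the statistical structure of a comparative TR
screen. Defaults: 4 datasets; one planted 240-nt TR per dataset derived
from a common ancestral transcript by i.i.d. substitutions at rate 0.15 per
copy, with the template protected (a TR with a decayed template would
neither be found by a template-driven screen nor make a functional
telomerase RNA); 500 decoys per dataset, 200–600 nt, uniform base
composition, 10% of them given one random minimal-template permutation.
The planted architecture is 5' G-rich (20 nt at 85% G), template (1.5 units
of TTAGGG by default), conserved box (25 nt), C-rich (20 nt at 85% C) and
AT-rich tail (15 nt at 90% A+T), with random spacers to length. Gene
context plants a USE (consensus TCCCACATCG), TATAAA and a T6 terminator at
fixed offsets. TRAP products use synthetic primers (real primer sequences
are assay configuration, not built in) and truncated-geometric unit counts;
TRF profiles discretize a log-normal of known median. All randomness flows
from one mandatory seed through a single generator; identical specs give
byte-identical files.

What the simulator does not model: indels and rearrangements between
orthologs, assembly fragmentation and chimeras, realistic transcript
sequence composition, coverage biases or sequencing errors. Passing the
planted-recovery tests shows the pipeline's logic is correct under its own
assumptions, not that the thresholds are tuned for any particular real
dataset.

## Problem sizes used in the test suite

The end-to-end check runs the full default bed (4 × 501 transcripts,
~1.5 × 10^4 candidate alignments) in well under two minutes on one core;
the aligner is verified against an independent reference implementation on
all 260 100 ordered pairs of {A,C}-strings up to length 8 and against a
pure path-enumeration oracle on all pairs up to length 3; TRAP parsing is
checked on 1000 simulated products. Identity-to-consensus of the recovered
family is asserted within ±0.05 of the 85% regime implied by 15% per-copy
divergence.

## Known limitations

- Template inference commits to the shortest compatible period; use
  `enumerate_compatible_motifs` when the unit length is uncertain.
- No E-values; score/identity/length acceptance is explicit and tunable but
  uncalibrated.
- Alignments are consumed, not produced: consensus-identity functions
  expect an externally computed MSA (or the simulator's gapless families).
- IUPAC-degenerate motifs and RNA secondary structure are out of scope.
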