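# telokit

Toolkit for discovering telomerase RNA (TR) candidates in assembled
transcriptomes and predicting the telomere repeat they would synthesize.

## The problem

The RNA subunit of telomerase carries the template that the reverse
transcriptase (TERT) copies into telomere DNA. TRs diverge so quickly in
length and sequence that homology search alone rarely finds them; the one
predictable part is the template region, which must contain a circular
permutation of the C-strand of the telomere repeat, elongated by at least
one nucleotide so the telomere 3' end can anneal before elongation. That
single constraint supports a comparative screen:

1. **Permutations** — for an L-bp telomere motif, enumerate all L distinct
   (L+1)-mers of the doubled C-strand unit ("minimal template regions").
   For TTAGGG these are the six 7-mers CCCTAAC, CCTAACC, CTAACCC, TAACCCT,
   AACCCTA, ACCCTAA; for a 12-bp motif they are 13-mers.
2. **Screen** — pull out every transcript in each species' assembly that
   contains any permutation. This is deliberately permissive; telomere-like
   k-mers are common, so thousands of decoys survive.
3. **Cross-compare** — align all candidates across species all-to-all
   (Smith–Waterman, BLASTN-style scoring: reward +2, penalty −3, gap open
   5, gap extend 2) and classify each candidate by the datasets in which it
   has passing hits. Only transcripts with homologs in *all* datasets —
   connected components spanning every species — survive as the final TR
   candidate set. True TR orthologs share conserved architecture; decoys do
   not recur across species.
4. **Predict** — infer each candidate's template domain as a maximal
   periodic window, take its repeat unit, and reverse-complement it: that
   is the telomere motif this telomerase would synthesize. A template of
   length n with unit period p spans n/p repeat units with an n−p anchor.
5. **Annotate** — locate the conserved TR gene elements: 5' G-rich region,
   template domain, C-rich and AT-rich regions, and in genomic context the
   Pol III promoter elements (USE, TATA box, via user-built PWMs) and the
   poly-T terminator. Read end-support counts back TSS/TTS calls.

Companion utilities decompose sequenced TRAP (telomere repeat amplification
protocol) products into primer + repeat units, estimate ladder periodicity,
and compute weighted-median telomere length from TRF (terminal restriction
fragment) intensity profiles.

A seeded simulator generates the whole test bed — transcript sets with one
planted TR family among hundreds of decoys, TR genes with promoter context,
reads, TRAP products and TRF profiles — so every stage is testable without
any external data.

## Worked example

Permutations of the human-type motif, and motif prediction from two
template regions:

```
$ telokit permutations --motif TTAGGG --ext 1
AACCCTA
ACCCTAA
CCCTAAC
CCTAACC
CTAACCC
TAACCCT

$ telokit predict-motif --template CTAAACCCT
CTAAACCCT	TTTAGGG	7	2	1.2857142857142858

$ telokit predict-motif --template AACCGAGCCCATAACCGA --json
{"template": "AACCGAGCCCATAACCGA", "motif": "CTCGGTTATGGG", "period": 12, "anchor_nt": 6, "span_units": 1.5}
```

The TSV columns are template, predicted motif, period, anchor and span:
`CTAAACCCT` repeats with period 7, so its unit `CTAAACC` reverse-complements
to the Arabidopsis-type repeat TTTAGGG, with 2 nt of anchor overhang; the
18-nt template spans 1.5 units of the 12-bp onion-type repeat CTCGGTTATGGG.

A full in-silico screen on synthetic data:

```
$ telokit simulate --seed 11 --n-datasets 3 --decoys 40 --out-dir sim
wrote 3 dataset(s) to sim
$ telokit scan --motif TTAGGG --fasta sim/species1.fasta \
      --fasta sim/species2.fasta --fasta sim/species3.fasta --out-dir screen
{"species1": {"total": 41, "candidates": 5}, "species2": {"total": 41, "candidates": 4}, "species3": {"total": 41, "candidates": 11}}
$ telokit crosslink --candidates screen/species1.candidates.fasta \
      --candidates screen/species2.candidates.fasta \
      --candidates screen/species3.candidates.fasta --out-dir cross
18 groups, 1 in the final set
```

The one group spanning all three species is exactly the planted TR family
(`cross/final_set.fasta`); the decoys that leaked through the permutation
screen drop out at the cross-species step.

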