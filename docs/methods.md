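# Methods

## Overview

`nrscout` finds sequence present in de novo assemblies but missing from a
reference genome, places it on the reference by flanking-sequence
anchoring, classifies it as insertion / alternate allele / ambiguous, and
profiles its repeat content and transcription potential.  This note
documents the models and the numerical and design choices, and what the
synthetic benchmarks do and do not demonstrate.

## Alignment engine

All stages consume alignments through one contract, the `AlignmentBlock`
(query/target half-open intervals, strand, matches, columns, gap opens,
score; identity = 100·matches/columns).  Two routes produce blocks:

* `align_pair_dp` — exact affine-gap Smith–Waterman (Biopython's C
  implementation) with a deterministic tie-break (fewest gap opens, then
  smallest target start).  A cell cap (default 25 M) bounds memory; larger
  problems are refused with a pointer to the seeded engine.
* `local_align` — k-mer seed → chain → stitch.  Exact seed matches
  (default k = 15; seeds with ambiguous bases never index; seeds occurring
  more than 256 times are dropped) are merged into maximal exact diagonal
  runs, chained greedily (gaps ≤ 500 bp, diagonal drift bounded by what an
  affine gap within the x-drop could produce), stitched (small equal-length
  gaps by direct comparison, others by global DP), and extended at the ends
  window-by-window.  End extension is gapless-first with an indel probe
  (register-shifted comparison) that triggers gapped DP only when needed.

Two post-processing steps give the engine the property the workflow relies
on — that a divergent stretch embedded in near-identical context surfaces
as its *own low-identity block* rather than being absorbed:

* **Homogeneity segmentation.**  A chained block with identity ≥ 90% is
  scanned (100-column smoothing) for sustained low-identity runs (≥ 250
  columns, run identity < 87%); runs are cut out as separate blocks.  Cut
  positions are refined by a changepoint that scores each column with the
  log-likelihood ratio of the high regime (p≈0.995) against the run's own
  match rate — matches are weak evidence, mismatches strong
  counter-evidence, so boundaries land on the real junction rather than
  the smoothing midpoint.
* **Tail trimming.**  Block ends whose trailing run is clearly foreign
  (smoothed identity < 90%, run mean < 80%) are trimmed at the same kind
  of changepoint; during extension, marginal score gains from a divergent
  tail (e.g. the shared motif backbone at a tandem-array junction) are
  given back when the tail's match rate is below 0.75 and the sacrifice is
  ≤ 10 score units.

The thresholds (window 100, run 250, 87 / 80 / 90) were chosen so that
uniformly divergent alignments — where there is no changepoint to find —
are never fragmented; the engine-versus-exact-DP sweep (random pairs,
0–20% divergence) is part of the benchmark suite.

For very small problems (query × target ≤ the DP cap) the engine falls
back to exact DP when seeding finds nothing better: short sequences near
20% divergence can lack any exact 15-mer.

E-values use the Karlin–Altschul model E = K·m·n·e^(−λS) with the standard
ungapped parameters for +1/−2 scoring (λ = 1.28, K = 0.46), configurable.

## Extraction cascade

Stage order is fixed: uncovered-harvest → subtract-back → repeat masking →
merge/length-filter → subtract-back → merge/length-filter, with per-stage
counts logged.  A base counts as covered only by blocks of identity ≥ 90%;
coverage by an 89% block leaves it harvestable.  Merged intervals
re-include the gap bases so every candidate is a contiguous assembly
substring — flank anchoring depends on this.  Masking removes only simple
repeats, low complexity and microsatellites; TE-class intervals stay.

## Placement

Flanks are the up-to-1 kb of assembly sequence immediately outside the
candidate's source interval (≥ 200 bp required).  "Near-perfect" anchoring
is quantified as: gapless best block, identity ≥ 98%, covering ≥ 95% of
the flank; these and the flank length are configuration, not inference.
Consistency requires one chromosome and strand, correct order, and a
reference span ≤ 1 Mb; a negative span up to 20 bp (target-site
duplication / microhomology) is clamped to a zero-length interval.

Breakends are refined by a junction changepoint: because qualifying flank
blocks are gapless, the columns around the inner end are in register with
the reference, and the concatenation [flank tail | NRS head] is scored
against the reference with the high-versus-divergent log-likelihood ratio,
the divergent-side match probability estimated from the variant-side
columns themselves.  Shifts are capped at 25 bp.  Finally, breakends are
voted across up to four redundancy-cluster siblings (the same variant
carried by other assemblies): a background substitution adjacent to a
junction is private to one carrier, so the majority recovers the shared
junction.  Residual inexactness is dominated by junctions that are
genuinely ambiguous at the sequence level (a variant whose first bases
happen to match the reference continuation).

## Classification

Insertion iff reference span ≤ 20 bp (microhomology slop; "simply
introducing" sequence is not otherwise quantified).  Alternate iff span
≥ 400 bp, best local DP identity < 90% or no alignment at all (score below
the engine minimum — "0% identity" is represented as *no alignment* and
satisfies the divergence criterion), and length ratio within [1/3, 3]
inclusive.  Spans in (20, 400) are ambiguous by definition.  The ratio is
documented as len(NRS)/span; the symmetric bounds make the orientation
immaterial.

## Annotation

The tandem detector defines a position as covered at period p when some
window of length max(24, 3p) containing it has ≤ 10% mismatching
self-comparisons seq[i] ≠ seq[i−p]; maximal covered runs are reported with
the smallest covering period.  These thresholds are package choices (no
detector is prescribed for novel sequence); the window formulation makes
the detector exactly reproducible by a brute-force (start, period) scan,
which the benchmark suite exploits.

Internal TE content is base-union coverage of alignments (identity ≥ 80%)
against a TE consensus library; the synthetic cohorts ship toy Alu-like
(300 bp) and L1-like (6 kb) consensi.  Flank TE content comes from the
reference repeat track over the 5 kb windows each side (clipped at
chromosome ends); flank tandem content is the detector's coverage of the
actual flank sequence, unioned with annotated simple-repeat intervals.

Read support re-defines mapping quality as a uniqueness margin: a read
placement counts only when the best gapless seed-vote placement beats the
second-best by ≥ 10 score units, the mates are in FR orientation on one
target within insert bounds (50–1000 bp).  A proper pair contributes two
mapped reads (configurable).  A quality pass-through filter drops reads
< 80 bp or with > 50% of bases below Q20 before mapping.  CPM is
count·10⁶ / total properly-paired mapped reads of the sample.

## Synthetic cohorts

The generator's defaults define the standard benchmark: a 2 Mb reference
(GC 0.41) with 40 Alu-like and 3 L1-like copies, 30 simple-repeat arrays,
20 genes with CDS and 2 N-gaps; four derived assemblies carrying 30
insertions (300–3000 bp), 20 alternate alleles (target identity 60–85%,
length ratio 0.5–2, reference span 1.2–2 kb, half with tandem-repeat
architecture), 10 simple-repeat decoys, 5 contaminant contigs and gap
fillers; two ape-like outgroups (1.5% divergence, carrying ~30% of
events); an EST database from transcribed events; and three RNA-seq
samples at 20× over transcribed events (100 bp pairs, 300 ± 30 insert,
0.1% error).  Carriers are drawn per event (P = 0.6, ≥ 1); with population
groups configured, events are group-private and carriers drawn within the
group (P = 0.8).

Design choices that matter for interpreting results:

* **Background divergence is substitution-only (0.1%).**  Real assemblies
  contain indels; a single flank indel would make an anchoring alignment
  gapped and hence at best unlocalized under the strict no-gap rule.
  Passing placement benchmarks therefore demonstrates breakpoint logic,
  not robustness to indel-rich flanks.
* **Junction disambiguation.**  Planted sequences' terminal bases are
  forced to differ from the adjacent reference bases (for tandem-repeat
  alternates, the mutated alternate motif always differs at position 0),
  so every planted breakpoint has a unique coordinate representation and
  "exact breakend" is well defined.  Real rearrangements often carry
  microhomology, where exactness is representation-dependent.
* **Alternate-allele construction.**  Non-tandem alternates are evolved
  from (a prefix of, or an extension of) the reference allele by iterated
  substitution with a bisection on the rate until exact-DP identity enters
  target ± 1 (capped at 8 rounds with a seed-stable closest-candidate
  fallback; heavily diverged targets can leave only short residual local
  alignments, in which case the measured identity is recorded as
  realized).  The planted length is floored at span/3 + 300 so that
  boundary trimming cannot push a recovered allele outside the
  length-ratio window.  Tandem-architecture alternates share a 16–30 bp
  motif between the two alleles, with the alternate motif mutated to the
  target identity; alternate tandem fractions are drawn U(0.4, 1) and the
  reference-allele fraction follows ref = 0.8·alt + N(0, 0.05), the
  association the annotation stage is benchmarked on.
* **Decoys versus tandem alternates.**  Decoys use 1–6 bp motifs and are
  annotated in the per-assembly repeat track (lifted through the event
  coordinate map), so masking removes them; tandem-architecture alternates
  use ≥ 16 bp motifs, are not annotated, and survive — mirroring a
  workflow in which simple-repeat annotation is removed while longer-motif
  arrays inside retained sequence are kept.
* **Gap fillers** replace reference N-runs in every assembly and are
  expected to surface as unlocalized, in-gap placements.

Every byte of output is a function of (spec, seed); RNG streams are
per-component so adding one component does not reshuffle the others.

## Benchmark scales and expectations

The standard cohort (2 Mb, 4 assemblies) runs the full pipeline in a few
minutes on one core; the population-structure benchmark uses a 0.8 Mb
reference with two groups of five assemblies.  These scales were chosen to
exercise every stage, including repeat-induced seed multi-mapping, while
keeping the whole benchmark suite runnable interactively.  Expected
outcomes under the default conditions: insertion and alternate recovery at
or near 100% of recoverable events (insertions shorter than the 400 bp
length rule are planted but unrecoverable by design), classification
accuracy ~100%, breakend exactness ~98–100%, zero decoy/contaminant
leakage, presence matrices equal to the planted sharing matrices, and PC1
of the occurrence matrix separating the two populations.

## Known limitations

* No spliced alignment; RNA-seq support uses unspliced paired placement,
  adequate only because simulated transcripts are the planted sequences
  themselves.
* The engine's block segmentation assumes a two-regime (high/divergent)
  structure; alignments with gradual identity drift are not split.
* Placement requires ≥ 200 bp of flank; candidates at contig ends are at
  best unlocalized.
* CD-HIT's exact clustering heuristics are not reproduced; the greedy
  longest-first contract with the same identity/coverage-of-shorter
  semantics is implemented directly.
* PCA centers features (standard PCA) — occurrence matrices are not
  scaled, and no population-genetic statistics beyond PCA are provided.
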