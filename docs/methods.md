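# Methods

`barcodekit` re-implements, as a tested library, the computational core of a
DNA-barcode evaluation study: given multi-FASTA files of candidate marker
sequences (ITS2, ITS, *rbcL*, *matK*, *psbA-trnH*, or any user marker) whose
headers carry an identifier and a Latin binomial, it quantifies how well each
marker separates and identifies species, and how markers combine.  This note
records the models, the parameter choices that matter, and the places where
the underlying methodology is ambiguous and a decision had to be made.

## Quality filtering

Download hygiene follows the standard GenBank-mining rules: drop sequences
shorter than 100 bp (strict inequality: 100 bp is kept), with more than 15
`N` symbols (15 is kept), or from unnamed species (token `sp.` anywhere in
the binomial, case-insensitive; `cf.` and `aff.` qualifiers are named and
kept).  Removal precedence is short → ambiguous → unnamed, each record
counted once under the first matching rule, so filter reports are
deterministic.  Lengths are counted on ungapped sequence so aligned and
unaligned input filter identically.

## Distances

Genetic distances use the Kimura 2-parameter model,

d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

with P and Q the transition (A↔G, C↔T) and transversion proportions among
comparable sites.  Sites with a gap or non-ACGT symbol on either sequence of
a pair are excluded pair-by-pair (complete-pair deletion), which matches the
pairwise-alignment workflow and maximises usable sites; the deletion policy
is recorded in the matrix metadata.  Saturated pairs (a non-positive log
argument) and pairs with no comparable sites are *undefined*: stored as NA,
excluded from every downstream mean/minimum/maximum, and counted.

Two alignment routes feed the distance: `pairwise-global` (default,
self-contained) aligns each pair with an affine-gap Needleman–Wunsch
(match +1, mismatch −2, gap open −5, extend −2 by default — megablast-like,
all configurable; deterministic diagonal→up→left tie-breaking), and
`pre-aligned` accepts an upstream multiple alignment.  The routes agree
exactly whenever the input is gap-free and equal-length with the identity
alignment optimal.  Ambiguity codes score as a match when their IUPAC sets
intersect.

## Divergence metrics

Six summaries characterise the barcoding gap.  Intra-specific, over species
with ≥ 2 individuals: the pooled mean conspecific distance; θ, the mean of
per-species means (removing unequal-sampling bias); and the mean coalescent
depth (per-species maximum).  Inter-specific, over genera with ≥ 2 species:
the pooled mean congeneric heterospecific distance; θ′, the mean of
per-genus means (removing unequal-species-count bias); and the mean of
per-genus minimum inter-specific distances.  Two readings were genuinely
open and are decided as follows: inter-specific pairs are individual-level
record pairs (not species representatives), and θ′ is computed over
heterospecific pairs only — a flag (`include_conspecific`) switches to the
all-pairs-within-genus variant.

## Marker comparison (Wilcoxon signed-rank)

Markers are compared on paired per-genus mean inter-specific distances over
the genera qualifying under both markers.  The test statistic is W+ with the
two-sided normal approximation z = (W+ − n(n+1)/4) / √(n(n+1)(2n+1)/24),
zero differences dropped, midranks for ties, and deliberately **no**
continuity correction and **no** tie correction: this exact variant
reproduces the published per-marker p-values from their printed (W+, n) —
e.g. n = 8, W+ = 36 gives z = 2.5205, p ≈ 0.0117.  (One published row,
n = 4 with W+ = 3, prints 0.4615 where this procedure gives 0.4652 and the
exact tie-free p is 0.625; no standard variant we tried reproduces it, and
it is not asserted.)  An exact-null p (n ≤ 25) is computed by the
generating-polynomial count of the sign-flip distribution — mathematically
identical to enumerating all 2ⁿ assignments, with midranks handled by
doubling — and serves as the internal cross-check: exhaustively over every
(W, n) with n in 10–25, the approximation is within 0.0096 of the exact p
whenever the exact p ≤ 0.1; near the null's centre the discreteness gap can
reach 0.05 at n = 10.  No multiple-testing adjustment is applied across
marker pairs.

## Species identification

Two methods.  *BLAST1*: assign the query to the species of its best local
alignment hit — exact Smith–Waterman scores (no heuristic seeding, so
rankings are reproducible).  *Nearest distance*: best = minimal K2P
distance, undefined distances ranking below all defined ones.  The default
evaluation is **self-inclusive** (the query's own record stays in the
reference set) with **ties as failures**: a query whose optimal hits span
more than one species is "ambiguous" and counted incorrect.  This pairing of
conventions is forced by the published per-genus arithmetic — a genus of 57
sequences over 55 species scoring 96.5% is only consistent if self-matching
is allowed and cross-species identical sequences fail — and leave-one-out is
provided as the stricter alternative.  Genus-level success requires all
optimal hits to share the query's genus.

The traffic-light combination rule evaluates a set of markers on the samples
sequenced for *all* members (intersection); a sample is identified if *any*
member identifies it.  Combination success is therefore never below any
member's success on the common-sample set.

## Contaminant screen

A Plan7-style profile HMM (match states from alignment columns with gap
fraction < 0.5; insert/delete states; background-emitting flanks; uniform
local entry over match states and a fixed exit probability τ = 0.05) is
trained on a curated alignment of the contaminant family with Laplace
pseudocounts (weight 1), and sequences are scored by the forward algorithm
as log₂ odds against an i.i.d. background.

The screening cutoff is calibrated per profile: half the minimum forward
score of the training sequences.  A fixed 0-bit cutoff on the raw log-odds
was considered and rejected after measurement: the forward score sums over
the full alignment-path ensemble, and that ensemble's entropy lifts even
unrelated 200-nt sequences to roughly −13 ± 8 bits (about 60 bits above
their best single path), so the sign of the log-odds misflags a few percent
of genuine sequences.  Anchoring the cutoff to the training family's own
scores (in the spirit of curated per-family bit-score thresholds) separates
cleanly: training-like contaminants score within a factor of the training
scores while sequences from a family 1.0 substitutions/site away (≈ 55%
observed column divergence) score near or below zero.  An absolute
threshold, the gap-column threshold, and the pseudocount remain knobs.  The
screen's contract is behaviour with respect to its own training profile; no
claim is made of equivalence to any particular curated fungal filter.

## Synthetic data

The simulator generates genera → species → individuals on star phylogenies
at every rank: a uniform root, genus ancestors at `genus_branch` = 0.15
expected substitutions/site, species ancestors at `inter_branch` = 0.05,
individuals at `intra_branch` = 0.005, all under the K2P process with
κ = 2.0 and exact closed-form site transition probabilities.  Defaults
emulate a small herbarium survey (≈ 20 genera, 1–4 species each, 1–3
individuals, ≈ 250 bp marker): conspecific divergence ≈ 1%, congeneric
heterospecific divergence ≈ 11%, in the range typical of nuclear spacer
markers.  Star topologies and exact site probabilities are deliberate —
every expected pairwise divergence is the sum of the separating branch
lengths, which is what parameter-recovery checks need.  Cross-species
identical sequence pairs can be planted (species-disjoint, congeneric),
making expected identification failures exactly 2k records.  Contaminants
evolve from a second root a configurable divergence from the plant root.
All randomness derives from one seed through named sub-streams, so outputs
are byte-reproducible and adding operations never perturbs existing ones.

What the simulator does **not** model: indels (all output is trivially
aligned), rate variation across sites, non-star topologies, paralogy/ITS2
copy variation, sequencing error, or taxonomic misannotation.  Passing tests
therefore demonstrate correctness of the statistics and decision rules under
a clean substitution process, not robustness to real-data pathologies.

## Problem sizes and numerics

Test and acceptance runs use desk-scale datasets chosen to make every
expectation analytic: tens of genera and a few hundred sites for
identification and gap checks; 100 sister-species pairs at 10,000 sites for
parameter recovery (mean pairwise K2P within 3 standard errors of
2 × `inter_branch`); 1,000 random aligned pairs for the distance oracle;
50 labelled records for screen separation; 20 replicates for
combination-monotonicity and gap-detection rates.  Score ties in
identification use a 10⁻⁹ tolerance; alignment traceback uses 10⁻⁶ (scores
are small sums of scheme values).  Forward/Viterbi recursions run in log
space with the delete-chain as a log-sum-exp / max-plus prefix scan.

## Known limitations

- The pairwise-global distance route is quadratic per pair and pure
  numpy; it is meant for datasets of hundreds, not tens of thousands.
- The Smith–Waterman surrogate is not claimed to reproduce BLAST scores or
  E-values, only similarity rankings on unambiguous cases.
- Exact signed-rank p-values are limited to n ≤ 25 (beyond that the normal
  approximation is accurate in the decision region anyway).
- The screen's calibrated cutoff assumes the training alignment is a
  reasonably homogeneous family sample; a heterogeneous training set would
  lower the cutoff and loosen the screen.
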