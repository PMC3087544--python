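# barcodekit

Evaluation toolkit for plant DNA barcode markers.

DNA barcoding assigns specimens to species from a short standardised locus
(for flowering plants, the usual candidates are ITS2, ITS, *rbcL*, *matK*
and *psbA-trnH*).  Whether a locus works for a given taxon hangs on the
*barcoding gap* — how far inter-specific divergence sits above
intra-specific variation — and on how often a simple best-hit rule returns
the right species.  `barcodekit` implements that whole evaluation as a
reusable pipeline for anyone comparing candidate markers on a plant family:

- **Quality filtering** of taxonomy-annotated FASTA (minimum length 100 bp,
  at most 15 `N`s, unnamed "sp." taxa dropped) with auditable filter
  reports and dataset composition summaries.
- **K2P distances** — d = −½ ln(1−2P−Q) − ¼ ln(1−2Q) with P/Q the
  transition/transversion proportions — from built-in pairwise global
  alignment or a supplied multiple alignment, with explicit handling of
  undefined (saturated/no-overlap) pairs.
- **Six divergence metrics**: pooled intra-specific mean, θ (per-species
  means averaged), mean coalescent depth; pooled inter-specific mean, θ′
  (per-genus means averaged), mean per-genus minimum inter-specific
  distance.
- **Wilcoxon signed-rank comparison** of markers on paired per-genus
  divergences (two-sided normal approximation without continuity
  correction, plus an exact-enumeration p for n ≤ 25).
- **Species identification**: BLAST1-style best local-alignment hit and
  nearest-K2P-distance assignment, self-inclusive or leave-one-out, ties
  counted as failures; success rates at species and genus level, overall
  and per genus; traffic-light marker combinations.
- **Profile-HMM contaminant screen** (e.g. fungal ITS2 in plant data):
  Plan7-style match/insert/delete profile trained from a curated alignment,
  forward-algorithm log-odds scoring with a per-profile calibrated cutoff.
- **A sequence simulator** that generates genus/species/individual
  hierarchies under the K2P process with known truth — including planted
  cross-species identical sequences — so every stage is testable without
  downloads.

## Worked example

Simulate a two-marker-style dataset with one planted cross-species
identical pair, compute distances, and evaluate identification:

```bash
barcodekit simulate --seed 7 --n-genera 6 --species-per-genus 2 \
    --cross-species-identicals 1 --out demo.fasta --truth-out truth.tsv
barcodekit distances demo.fasta --mode pre-aligned --out d.tsv
barcodekit identify demo.fasta --method distance --matrix d.tsv
barcodekit metrics demo.fasta d.tsv --marker DEMO
```

which prints

```
wrote 24 records to demo.fasta
wrote d.tsv (24 records, 0 undefined pairs)
marker   method    mode            n_queries  species_rate  genus_rate
unknown  distance  self-inclusive  24         91.7          100.0
marker  avg_inter  theta_prime  min_inter  avg_intra  theta   avg_coalescent_depth ...
DEMO    0.0973     0.0973       0.0838     0.0170     0.0170  0.0170
```

Read: 24 sequences (6 genera × 2 species × 2 individuals); the planted
identical pair makes exactly its 2 members unidentifiable at species level,
so species success is 22/24 = 91.7% while every query still lands in the
right genus.  Congeneric species diverge by ≈ 0.10 substitutions/site
against ≈ 0.017 within species — the minimum inter-specific distance
(0.084) sits well above the intra-specific mean, a clear barcoding gap.

The same operations are available as a library (`barcodekit.simulate`,
`barcodekit.k2p`, `barcodekit.identify`, ...), and `barcodekit run-all
config.yaml` drives the full pipeline (filter → distances → metrics →
signed-rank tests → identification → combinations → screen) from one YAML
config, writing TSV/JSON artifacts plus a provenance record.

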