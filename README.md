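# barcode-librarian

Evaluation toolkit for DNA-barcode reference libraries, built around the
workflow used to assess curated COI libraries of taxonomically difficult
insect groups (the motivating case is Afrotropical hoverflies, Syrphidae):
given an aligned set of ~658 bp COI barcodes with voucher, species, genus
and subfamily labels, the package answers the practical question *"how well
does this library identify its own specimens, and which taxa does it flag
for further taxonomic work?"*

## What it computes

- **QC and haplotypes** — minimum-length and stop-codon filtering under the
  invertebrate mitochondrial code; collapsing identical sequences into
  haplotypes (`library_io`).
- **K2P distances** — Kimura 2-parameter distances with pairwise deletion,

  `d = -½ ln(1 - 2P - Q) - ¼ ln(1 - 2Q)`,

  where `P` and `Q` are the transition and transversion proportions over
  comparable sites; pooled intraspecific vs congeneric-interspecific
  partitions, per-species summaries with nearest neighbours, low-divergence
  species pairs, and the specimens-vs-haplotypes Spearman correlation
  (`distances`).
- **Barcode gap & threshold** — cumulative-error curves
  `total_error(t) = Pr(intra > t) + Pr(inter ≤ t)`, the best-compromise
  threshold `t*` minimising them (interval midpoint on ties), and true-gap
  detection (`max_intra < min_inter`) per dataset / subfamily / genus
  (`gap_threshold`).
- **Identification success** — leave-one-out Best Match and Best Close
  Match criteria with TP / ambiguous / FP / FN / TN bookkeeping, singleton
  species excluded as queries but kept as references (`identification`).
- **Trees and clusters** — neighbor-joining on the K2P matrix, alignment-
  column bootstrap support, and a minimal-clade-cover test of whether each
  nominal species forms a single cluster on the outgroup-rooted tree
  (`njtree`).
- **Synthetic libraries** — a K80 simulator over a genus/species/individual
  hierarchy with known ground truth, including singleton species, species
  pairs at near-zero divergence, cryptic splits, and shared haplotypes
  (`synthetic`), so the whole pipeline is testable offline.

## Worked example

The numbered scripts under `analysis/` run the complete study on a
simulated library (26 genera, ~100 nominal species, ~560 barcodes) and
write their tables under `results/`:

```
$ python analysis/01_simulate_library.py --seed 1
library: 560 ingroup barcodes, 103 nominal species (34 singletons), 1 outgroup

$ python analysis/02_distance_analysis.py
pooled intraspecific mean K2P  = 0.0092 (n = 1973 pairs, max 0.0789)
pooled congeneric mean K2P     = 0.0681 (n = 4489 pairs)
99/103 species lie > 0.03 from their nearest neighbour
low-divergence pair: Genus01 species01 vs Genus01 species02 (mean 0.0048, ...)
haplotypes track sampling effort: Spearman R_s = 0.967, t = 31.21, N = 69

$ python analysis/04_identification.py
526 queries (34 singleton-species sequences excluded as queries, kept as references)
BM: 95.4% correct, 21 ambiguous, 3 incorrect
misidentifications are confined to the low-divergence labels: Genus01 ...

$ python analysis/05_tree_clusters.py --bootstrap 100 --seed 2
64/69 multi-specimen species form single clusters on the outgroup-rooted NJ tree
```

Reading: intraspecific divergence (≈0.009) sits an order of magnitude below
congeneric divergence (≈0.068), so most species identify perfectly; the few
failures are exactly the planted pathologies — the near-zero-divergence
species pair attracts ambiguous/false-positive matches, and the cryptic
split and shared haplotype break single-cluster monophyly — which is how a
real library audit flags taxa deserving revision.

The same stages are available programmatically (`barcode_librarian.run`
with a `RunConfig`) and as a CLI (`barcode-librarian simulate|qc|distances|
threshold|identify|tree|run`).

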