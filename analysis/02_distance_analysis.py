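#!/usr/bin/env python
"""K2P distance structure of the study library.

Computes all pairwise K2P distances, collapses haplotypes, and reports the
pooled intraspecific and congeneric-interspecific means, the per-species
summaries (with nearest-neighbour distances), the low-divergence species
pairs, and the specimens-vs-haplotypes rank correlation.
"""

import argparse
from pathlib import Path

import pandas as pd

from barcode_librarian.distances import (
    distance_matrix,
    low_divergence_pairs,
    partition,
    species_summaries,
    species_summaries_frame,
    specimens_vs_haplotypes_correlation,
)
from barcode_librarian.library_io import collapse_haplotypes, read_library

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--library", type=Path, default=Path("results/library"))
parser.add_argument("--out", type=Path, default=Path("results/distances"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

library = read_library(args.library / "library.fasta", args.library / "library.tsv")
matrix = distance_matrix(library)
matrix.to_long_frame().to_csv(args.out / "distances_long.tsv", sep="\t", index=False)

[pooled] = partition(matrix, library, "dataset")
print(f"pooled intraspecific mean K2P  = {pooled.intra_mean:.4f} "
      f"(n = {pooled.intraspecific.size} pairs, max {pooled.intraspecific.max():.4f})")
print(f"pooled congeneric mean K2P     = {pooled.inter_mean:.4f} "
      f"(n = {pooled.congeneric_interspecific.size} pairs)")

haplotypes = collapse_haplotypes(library.ingroup())
summaries = species_summaries(matrix, library, haplotypes)
sdf = species_summaries_frame(summaries)
sdf.to_csv(args.out / "species_summaries.tsv", sep="\t", index=False)
n_far = (sdf["nn_distance"] > 0.03).sum()
print(f"{n_far}/{len(sdf)} species lie > 0.03 from their nearest neighbour")
high = sdf[sdf["max_intra"] > 0.03]
if len(high):
    print(f"high (> 0.03) maximum intraspecific divergence in: "
          f"{', '.join(high['species'])} (candidate cryptic species)")

pairs = low_divergence_pairs(matrix, library, cutoff=0.03)
pd.DataFrame([vars(p) for p in pairs]).to_csv(
    args.out / "low_divergence_pairs.tsv", sep="\t", index=False
)
for p in pairs:
    print(f"low-divergence pair: {p.species_a} vs {p.species_b} "
          f"(mean {p.mean:.4f}, min {p.min:.4f}, max {p.max:.4f})")

rs, t, n = specimens_vs_haplotypes_correlation(haplotypes)
print(f"haplotypes track sampling effort: Spearman R_s = {rs:.3f}, "
      f"t = {t:.2f}, N = {n} multi-specimen species")
print(f"mean haplotypes per multi-specimen species = "
      f"{haplotypes.mean_haplotypes_per_species():.2f}")
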