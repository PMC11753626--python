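#!/usr/bin/env python
"""Impute missing calls, summarise within-population diversity, and build
the modified Rogers distance matrix over all populations.

Prints the Hs / NbMono range across the panel and writes the distance
matrix in both the TSV dialect and PHYLIP square format.
"""

from pathlib import Path

from bulkadmix import diversity, io

OUT = Path("results/analysis")


def main() -> None:
    freqs = io.read_matrix(OUT / "frequencies.tsv")
    complete = diversity.impute_missing(freqs)
    io.write_matrix(complete, OUT / "frequencies_imputed.tsv")

    stats = diversity.diversity_stats(complete)
    stats.to_csv(OUT / "diversity.tsv", sep="\t", index_label="population")
    top = stats.sort_values("Hs", ascending=False).head(3)
    low = stats.sort_values("Hs").head(3)
    print(f"Hs range {stats['Hs'].min():.4f}-{stats['Hs'].max():.4f} "
          f"(mean {stats['Hs'].mean():.4f}); "
          f"NbMono range {stats['NbMono'].min()}-{stats['NbMono'].max()}")
    print("most diverse populations:\n", top.to_string())
    print("least diverse populations:\n", low.to_string())

    d = diversity.mrd_matrix(complete)
    io.write_distance_matrix(d, OUT / "mrd.tsv")
    io.write_phylip_distance(d, OUT / "mrd.phylip")
    off = d.to_numpy()[~(d.to_numpy() == 0)]
    print(f"MRD over {d.shape[0]} populations: min {off.min():.4f}, "
          f"median {float(sorted(off)[len(off) // 2]):.4f}, max {off.max():.4f}")


if __name__ == "__main__":
    main()
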