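#!/usr/bin/env python
"""Structure analysis of the MRD matrix: PCoA axes, neighbor-joining
tree, and Ward dendrogram, with a check that Ward at k = K recovers the
simulated reference groups.
"""

from pathlib import Path

import pandas as pd

from bulkadmix import io, structure

OUT = Path("results/analysis")
DATA = OUT / "data"


def main() -> None:
    d = io.read_distance_matrix(OUT / "mrd.tsv")

    res = structure.pcoa(d)
    res.coordinates.to_csv(OUT / "pcoa_coordinates.tsv", sep="\t", index_label="population")
    pd.DataFrame({"eigenvalue": res.eigenvalues, "pct_variance": res.pct_variance}).to_csv(
        OUT / "pcoa_eigenvalues.tsv", sep="\t", index_label="axis"
    )
    pcts = ", ".join(f"Axis {i + 1}: {p:.1f}%" for i, p in enumerate(res.pct_variance[:4]))
    print(f"PCoA variance explained — {pcts}")

    tree = structure.neighbor_joining(d)
    structure.write_newick(tree, OUT / "nj.nwk")
    print(f"NJ tree over {len(structure.leaf_names(tree))} populations -> {OUT / 'nj.nwk'}")

    z = structure.ward_linkage(d)
    structure.linkage_table(z, labels=list(d.index)).to_csv(
        OUT / "ward_linkage.tsv", sep="\t", index=False
    )

    labels = io.read_labels(DATA / "reference_labels.tsv")
    k = labels.nunique()
    found = pd.Series(structure.cluster_labels(z, k), index=d.index)
    ref_found = found[found.index.isin(labels.index)]
    purity = (
        ref_found.groupby(labels[ref_found.index]).agg(lambda s: s.value_counts().iloc[0])
    ).sum() / len(ref_found)
    print(f"Ward cut at k={k}: reference-group purity {purity:.1%}")


if __name__ == "__main__":
    main()
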