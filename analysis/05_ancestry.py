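#!/usr/bin/env python
"""Supervised ancestry assignment and recovery scoring.

Builds the group mean frequency matrix from the labelled reference
populations, expresses every population as a sum-to-one non-negative
mixture of the groups, and — because the queries are simulated — scores
the recovered proportions against the ground truth.
"""

from pathlib import Path

import numpy as np

from bulkadmix import ancestry, diversity, io

OUT = Path("results/analysis")
DATA = OUT / "data"


def main() -> None:
    freqs = io.read_matrix(OUT / "frequencies_imputed.tsv")
    labels = io.read_labels(DATA / "reference_labels.tsv")
    ref_ids = [p for p in freqs.index if p in labels.index]
    G = ancestry.group_mean_frequencies(freqs.loc[ref_ids], labels)
    props, summary = ancestry.assign_panel(freqs, G)
    io.write_proportions(props, OUT / "ancestry_proportions.tsv")
    summary.to_csv(OUT / "main_groups.tsv", sep="\t", index_label="population")

    n_main = int(summary["mainly_assigned"].sum())
    print(f"assigned {len(props)} populations to {G.shape[0]} groups; "
          f"{n_main} are mainly (>50%) assigned to one group")

    # reference self-assignment
    ref_summary = summary.loc[ref_ids]
    self_acc = (ref_summary["main_group"] == labels[ref_ids]).mean()
    print(f"reference self-assignment accuracy: {self_acc:.1%}")

    # query recovery against the simulated truth
    truth = io.read_proportions(DATA / "true_proportions.tsv")
    est = props.loc[truth.index, truth.columns].to_numpy()
    tru = truth.to_numpy()
    mae = np.abs(est - tru).mean()
    acc = (est.argmax(axis=1) == tru.argmax(axis=1)).mean()
    print(f"query landraces: proportion MAE {mae:.4f}, main-group accuracy {acc:.1%}")
    worst = np.abs(est - tru).mean(axis=1).argmax()
    print(f"hardest landrace: {truth.index[worst]} "
          f"(true {np.round(tru[worst], 2)}, est {np.round(est[worst], 2)})")


if __name__ == "__main__":
    main()
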