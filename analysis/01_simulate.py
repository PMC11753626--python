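#!/usr/bin/env python
"""Generate the synthetic bulk-genotyping study all later steps analyse.

Seven ancestral genetic groups, five reference populations per group
drifted around their group means, and fourteen query landraces (seven
unadmixed, seven Dirichlet-admixed) sampled as 15-plant DNA bulks and
read out as noisy FIR signals, plus two controlled-pool sets for the
calibration step. Everything is written as delimited text under
results/analysis/data/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bulkadmix import io, synthetic

SEED = 42
K, L = 7, 1000
REFS_PER_GROUP = 5
N_ADMIXED = 7

OUT = Path("results/analysis/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    group_means, ref_freqs, labels = synthetic.simulate_reference_panel(
        K=K, L=L, n_populations_per_group=REFS_PER_GROUP, drift=50, seed=SEED
    )
    rng = np.random.default_rng(SEED + 1)
    props = np.vstack([np.eye(K), rng.dirichlet(np.ones(K), size=N_ADMIXED)])
    truth = synthetic.simulate_admixed_landraces(
        group_means, props, n_individuals=15, seed=SEED + 2
    )
    bulk = pd.DataFrame(
        [t.bulk_freqs for t in truth],
        index=[t.landrace_id for t in truth],
        columns=group_means.columns,
    )
    fir = synthetic.simulate_fir(bulk, noise_sd=0.03, seed=SEED + 3)
    fir = synthetic.inject_missing(fir, rate=0.02, seed=SEED + 4)
    reference = synthetic.simulate_inbred_reference(list(group_means.columns), cluster_sd=0.03)
    cal, val = synthetic.simulate_controlled_pools(n_snps=1000, seed=SEED + 5)

    io.write_matrix(group_means, OUT / "group_means_true.tsv", index_label="group")
    io.write_matrix(ref_freqs, OUT / "reference_frequencies.tsv")
    io.write_labels(labels, OUT / "reference_labels.tsv")
    io.write_matrix(fir, OUT / "query_fir.tsv")
    io.write_inbred_reference(reference, OUT / "inbred_reference.tsv")
    io.write_pool_set(cal, OUT / "pools_calibration.tsv")
    io.write_pool_set(val, OUT / "pools_validation.tsv")
    truth_df = pd.DataFrame(props, index=[t.landrace_id for t in truth],
                            columns=group_means.index)
    io.write_proportions(truth_df, OUT / "true_proportions.tsv")

    print(f"simulated {K} groups x {L} loci; {len(ref_freqs)} reference populations, "
          f"{len(truth)} query landraces ({K} pure + {N_ADMIXED} admixed)")
    print(f"query FIR missing rate: {fir.isna().to_numpy().mean():.3%}")
    print(f"wrote study tables to {OUT}")


if __name__ == "__main__":
    main()
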