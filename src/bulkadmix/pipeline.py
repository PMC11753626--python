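"""Configuration-driven orchestration of the full bulk-genotyping analysis.

Stage order is fixed: (simulate or load) -> frequency estimation from
FIR (bypassed when frequencies are supplied directly) -> imputation ->
diversity statistics and modified Rogers distances -> PCoA / neighbor
joining / Ward -> supervised ancestry assignment. All randomness flows
from the single config seed, so an identical config yields identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry, bulkfreq, diversity, io, structure, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_recovery", "load_config"]


@dataclass
class PipelineConfig:
    """Everything one run needs; ``mode`` is ``simulate`` or ``load``.

    In load mode either ``freqs_path`` (frequencies ready-made) or
    ``fir_path`` + ``reference_path`` + ``model_path`` (estimate first)
    must be given, along with ``labels_path`` splitting reference
    populations (labelled) from queries (absent from the label table).
    """

    mode: str = "simulate"
    out_dir: str = "results/run"
    seed: int = 0
    # simulate-mode generator settings (the study conditions)
    K: int = synthetic.DEFAULT_K
    L: int = 1000
    n_populations_per_group: int = 5
    n_queries: int = 10
    drift: float = synthetic.DEFAULT_DRIFT
    n_individuals: int = synthetic.DEFAULT_N_INDIVIDUALS
    noise_sd: float = synthetic.DEFAULT_NOISE_SD
    beta0: float = synthetic.DEFAULT_BETA0
    beta1: float = synthetic.DEFAULT_BETA1
    missing_rate: float = synthetic.DEFAULT_MISSING_RATE
    calibration_grid: tuple = tuple(np.round(np.arange(0.1, 0.95, 0.1), 2))
    calibration_n_snps: int = 1000
    # estimation / assignment settings
    fixation_threshold: float = bulkfreq.DEFAULT_FIXATION_THRESHOLD
    cluster_z: float = bulkfreq.DEFAULT_CLUSTER_Z
    mono_tol: float = 0.0
    ridge_lambda: float = 0.0
    main_assignment_threshold: float = 0.5
    # load-mode inputs
    freqs_path: str | None = None
    fir_path: str | None = None
    reference_path: str | None = None
    model_path: str | None = None
    labels_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"mode must be 'simulate' or 'load', got {self.mode!r}")
        if self.mode == "load":
            for p in filter(None, [self.freqs_path, self.fir_path, self.reference_path,
                                   self.model_path, self.labels_path]):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            if self.freqs_path is None and self.fir_path is None:
                raise ValueError("load mode needs freqs_path or fir_path")
            if self.labels_path is None:
                raise ValueError("load mode needs labels_path for the reference groups")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config, rejecting unknown keys before any stage runs."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    bad = sorted(set(raw) - known)
    if bad:
        raise ValueError(f"unknown config keys: {bad}")
    if "calibration_grid" in raw:
        raw["calibration_grid"] = tuple(raw["calibration_grid"])
    return PipelineConfig(**raw)


def summarize_recovery(
    truth: list[synthetic.SimulatedLandrace],
    proportions: pd.DataFrame,
    freq_estimates: pd.DataFrame | None = None,
) -> dict:
    """Truth-vs-estimate metrics for simulated queries, matched by ID.

    Reports the mean absolute error of estimated frequencies against the
    realised bulk frequencies, the mean absolute ancestry-proportion
    error per landrace, and main-group accuracy (fraction of landraces
    whose top estimated group is the top true group).
    """
    ids = [t.landrace_id for t in truth]
    missing = [i for i in ids if i not in proportions.index]
    if missing:
        raise ValueError(f"landraces absent from proportion table: {missing[:10]}")
    true_a = np.array([t.true_proportions for t in truth])
    est_a = proportions.loc[ids].to_numpy()
    prop_mae = float(np.abs(true_a - est_a).mean())
    accuracy = float((true_a.argmax(axis=1) == est_a.argmax(axis=1)).mean())
    out = {
        "proportion_mae": prop_mae,
        "main_group_accuracy": accuracy,
        "n_landraces": len(ids),
    }
    if freq_estimates is not None:
        bad = [i for i in ids if i not in freq_estimates.index]
        if bad:
            raise ValueError(f"landraces absent from frequency estimates: {bad[:10]}")
        bulk = np.array([t.bulk_freqs for t in truth])
        est_f = freq_estimates.loc[ids].to_numpy()
        keep = ~np.isnan(est_f)
        out["frequency_mae"] = float(np.abs(est_f[keep] - bulk[keep]).mean())
    return out


def _simulate_inputs(cfg: PipelineConfig, rng_seed: int) -> dict:
    """Generate the full study: reference panel, queries, pools, FIR."""
    group_means, ref_freqs, labels = synthetic.simulate_reference_panel(
        cfg.K, cfg.L, cfg.n_populations_per_group, cfg.drift, seed=rng_seed
    )
    rng = np.random.default_rng(rng_seed + 1)
    # half pure, half Dirichlet-admixed queries
    props = []
    for i in range(cfg.n_queries):
        if i % 2 == 0:
            a = np.zeros(cfg.K)
            a[i // 2 % cfg.K] = 1.0
        else:
            a = rng.dirichlet(np.ones(cfg.K))
        props.append(a)
    truth = synthetic.simulate_admixed_landraces(
        group_means, np.array(props), cfg.n_individuals, seed=rng_seed + 2
    )
    bulk = pd.DataFrame(
        [t.bulk_freqs for t in truth],
        index=[t.landrace_id for t in truth],
        columns=group_means.columns,
    )
    fir = synthetic.simulate_fir(bulk, cfg.beta0, cfg.beta1, cfg.noise_sd, seed=rng_seed + 3)
    fir = synthetic.inject_missing(fir, cfg.missing_rate, seed=rng_seed + 4)
    reference = synthetic.simulate_inbred_reference(
        list(group_means.columns), cfg.beta0, cfg.beta1, cluster_sd=max(cfg.noise_sd, 1e-3)
    )
    cal, val = synthetic.simulate_controlled_pools(
        cfg.calibration_grid, cfg.calibration_n_snps, cfg.beta0, cfg.beta1,
        cfg.noise_sd, seed=rng_seed + 5,
    )
    return {
        "group_means": group_means,
        "ref_freqs": ref_freqs,
        "labels": labels,
        "truth": truth,
        "query_fir": fir,
        "reference": reference,
        "pools": (cal, val),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the analysis end to end; returns the run report (also
    written to ``<out_dir>/report.json`` along with all stage outputs)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in dataclasses.asdict(cfg).items()}}

    # ------------------------------------------------------ inputs
    truth = None
    if cfg.mode == "simulate":
        sim = _simulate_inputs(cfg, cfg.seed)
        truth = sim["truth"]
        labels = sim["labels"]
        ref_freqs = sim["ref_freqs"]
        model = bulkfreq.fit_calibration(*sim["pools"], fixation_threshold=cfg.fixation_threshold)
        query_freqs, calls = bulkfreq.estimate_frequencies(
            sim["query_fir"], sim["reference"], model, z=cfg.cluster_z
        )
        freqs = pd.concat([ref_freqs, query_freqs])
        report["calibration"] = bulkfreq.calibration_report(model)
        io.write_matrix(ref_freqs, out / "reference_frequencies.tsv")
        io.write_matrix(sim["query_fir"], out / "query_fir.tsv")
        io.write_inbred_reference(sim["reference"], out / "inbred_reference.tsv")
        io.write_labels(labels, out / "reference_labels.tsv")
        model.to_json(out / "calibration_model.json")
    else:
        labels = io.read_labels(cfg.labels_path)
        if cfg.freqs_path is not None:
            freqs = io.read_matrix(cfg.freqs_path)
        else:
            fir = io.read_matrix(cfg.fir_path)
            reference = io.read_inbred_reference(cfg.reference_path)
            model = bulkfreq.CalibrationModel.from_json(cfg.model_path)
            est, calls = bulkfreq.estimate_frequencies(fir, reference, model, z=cfg.cluster_z)
            report["calibration"] = bulkfreq.calibration_report(model)
            freqs = est
    io.validate_frequency_matrix(freqs)
    io.write_matrix(freqs, out / "frequencies.tsv")
    report["inputs"] = {
        "n_populations": int(freqs.shape[0]),
        "n_loci": int(freqs.shape[1]),
        "n_reference": int(labels.index.isin(freqs.index).sum()),
    }

    # ------------------------------------------------------ impute + diversity
    complete = diversity.impute_missing(freqs)
    stats = diversity.diversity_stats(complete, mono_tol=cfg.mono_tol)
    stats.to_csv(out / "diversity.tsv", sep="\t", index_label="population")
    report["diversity"] = {
        "mean_Hs": float(stats["Hs"].mean()),
        "mean_NbMono": float(stats["NbMono"].mean()),
    }

    # ------------------------------------------------------ distance + structure
    d = diversity.mrd_matrix(complete)
    io.write_distance_matrix(d, out / "mrd.tsv")
    io.write_phylip_distance(d, out / "mrd.phylip")
    ord_res = structure.pcoa(d)
    ord_res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t", index_label="population")
    pd.DataFrame(
        {"eigenvalue": ord_res.eigenvalues, "pct_variance": ord_res.pct_variance}
    ).to_csv(out / "pcoa_eigenvalues.tsv", sep="\t", index_label="axis")
    tree = structure.neighbor_joining(d)
    structure.write_newick(tree, out / "nj.nwk")
    z = structure.ward_linkage(d)
    structure.linkage_table(z, labels=list(d.index)).to_csv(
        out / "ward_linkage.tsv", sep="\t", index=False
    )
    report["structure"] = {
        "top_eigenvalues": [float(v) for v in ord_res.eigenvalues[:5]],
        "top_pct_variance": [float(v) for v in ord_res.pct_variance[:5]],
        "newick_path": str(out / "nj.nwk"),
    }

    # ------------------------------------------------------ ancestry
    ref_ids = [p for p in complete.index if p in labels.index]
    G = ancestry.group_mean_frequencies(complete.loc[ref_ids], labels)
    acfg = ancestry.AssignmentConfig(
        ridge_lambda=cfg.ridge_lambda, main_assignment_threshold=cfg.main_assignment_threshold
    )
    props, summary = ancestry.assign_panel(complete, G, acfg)
    io.write_proportions(props, out / "ancestry_proportions.tsv")
    summary.to_csv(out / "main_groups.tsv", sep="\t", index_label="population")
    report["ancestry"] = {
        "proportions_path": str(out / "ancestry_proportions.tsv"),
        "n_mainly_assigned": int(summary["mainly_assigned"].sum()),
    }

    # ------------------------------------------------------ recovery (simulate only)
    if truth is not None:
        report["recovery"] = summarize_recovery(truth, props, freqs)
        truth_df = pd.DataFrame(
            [t.true_proportions for t in truth],
            index=[t.landrace_id for t in truth],
            columns=G.index,
        )
        io.write_proportions(truth_df, out / "true_proportions.tsv")

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
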