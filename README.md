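# bulkadmix

Genetic-diversity analysis of crop landrace panels genotyped as **DNA
bulks** on SNP arrays: one pooled DNA sample per population (here 15
plants), one array hybridisation, and per-SNP fluorescent intensity
ratios (FIR) instead of individual genotypes. The package estimates
population B-allele frequencies from the FIR signal, measures diversity
and genetic distance between populations, and assigns each landrace to
reference ancestral groups — the standard workflow for placing
unstudied landraces (e.g. North-African maize) relative to established
germplasm groups.

For population *i* with B-allele frequencies *p<sub>il</sub>* over *L*
biallelic loci, the core quantities are:

- **Calibration / estimation.** FIR relates to frequency through a
  logistic link; a unique model `logit(fir) = β₀ + β₁·f` is fitted by
  least squares on controlled pools of known frequency and inverted to
  estimate `f̂ = clamp((logit(fir) − β₀)/β₁, 0, 1)`. A cell is called
  monomorphic (and snapped to 0/1) only when its FIR falls inside the
  matching inbred homozygote FIR cluster *and* `f̂` is within 5% of
  fixation.
- **Diversity.** Expected heterozygosity `Hs = mean_l 2p(1−p)` and the
  count of monomorphic loci (NbMono).
- **Modified Rogers distance.**
  `MRD(x, y) = sqrt( Σ_l (p_xl − p_yl)² / L ) ∈ [0, 1]`,
  computed after imputing missing calls by locus means; it is Euclidean,
  so principal coordinate analysis needs no correction.
- **Structure.** PCoA (Gower double-centering), Saitou–Nei
  neighbor joining (Newick export) and Ward hierarchical clustering
  (ward.D2 convention) on the MRD matrix.
- **Ancestry.** Each population's frequency vector is expressed as a
  mixture of the K group mean vectors *G* by solving
  `min_a ‖f − Gᵀa‖² + λ‖a‖²  s.t.  Σa_k = 1, a_k ≥ 0`,
  a convex QP whose coefficients are read as percentages of belonging.

A synthetic-study generator (Beta ancestral frequencies,
Balding–Nichols drift, binomial 15-plant bulk sampling, logistic FIR
link with Gaussian noise, controlled pools, MCAR missingness) makes the
whole pipeline testable end to end with known ground truth.

## Worked example

The `analysis/` drivers run a complete synthetic study — 7 ancestral
groups × 1000 SNPs, 35 reference populations, 14 query landraces
(7 unadmixed, 7 admixed) as 15-plant bulks with FIR noise sd 0.03 and
2% missing calls:

```sh
python analysis/01_simulate.py
python analysis/02_calibrate_and_estimate.py
python analysis/03_diversity_distance.py
python analysis/04_structure.py
python analysis/05_ancestry.py
```

which prints, among other things:

```
held-out MAE 2.92% (within the 3% budget)
Hs range 0.2323-0.4378 (mean 0.2725); NbMono range 7-235
MRD over 49 populations: min 0.0640, median 0.4948, max 0.5227
PCoA variance explained — Axis 1: 17.9%, Axis 2: 17.0%, Axis 3: 16.3%, Axis 4: 15.5%
Ward cut at k=7: reference-group purity 100.0%
reference self-assignment accuracy: 100.0%
query landraces: proportion MAE 0.0117, main-group accuracy 100.0%
```

Read: the FIR calibration predicts held-out pool frequencies within
2.92% on average; admixed groups (drift 50) sit at roughly equal MRD
(~0.49) so the seven PCoA axes share the variance; Ward clustering and
supervised assignment both recover the simulated group structure, and
the recovered admixture coefficients are within ~1 percentage point of
the truth per group on average. Outputs (frequency matrices, Hs/NbMono
table, MRD in TSV + PHYLIP, PCoA coordinates, Newick tree, Ward
linkage, ancestry percentages) land under `results/analysis/`.

The same pipeline is available as a CLI
(`bulkadmix run --config cfg.yaml`, plus stage-wise `simulate`,
`calibrate`, `estimate`, `distance`, `structure`, `assign`) driven by a
YAML config, and as a library (`bulkadmix.run_pipeline`).

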