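# Methods

## The measurement model

A DNA bulk pools equal leaf mass from *n* plants of one open-pollinated
population and is hybridised once to a biallelic SNP array. The only
per-SNP observable is the fluorescent intensity ratio (FIR), the
allele-B share of two-channel fluorescence in [0, 1]. We model FIR as a
logistic function of the bulk's true B-allele frequency *f*,

    fir = expit(β₀ + β₁ f) + ε,   ε ~ N(0, σ²), clamped to [0, 1],

with one global (β₀, β₁) across SNPs. Defaults β₀ = −3, β₁ = 6 place
the homozygote clusters near 0.05 and 0.95 and make the link symmetric
about f = 0.5; σ = 0.03 is the working FIR noise level. The exact
transform from raw X/Y intensities to FIR is not modelled — any
monotone ratio in [0, 1] works, because calibration absorbs the link.

### Two-step frequency estimation

1. **Monomorphism test.** Per locus, inbred homozygote lines define FIR
   clusters (mean_A ± sd_A, mean_B ± sd_B; orientation convention
   mean_A < mean_B, references violating it are flipped on load). A
   bulk cell is called mono_A when its FIR lies within z·sd (default
   z = 3) of the A cluster **and** its calibrated frequency estimate is
   below the fixation threshold t (default 0.05); symmetrically for
   mono_B. The conjunction makes snapping conservative: no cell whose
   estimate is in [t, 1−t] is ever set to 0 or 1. Whether the test is
   applied per locus or globally was an open choice; per-locus is used.
2. **Calibration.** On controlled pools of known frequency, least
   squares of logit(fir) (FIR clamped to [1e-6, 1−1e-6]) on the known
   f, restricted to pools strictly inside (0, 1); the fit requires at
   least two distinct interior frequencies. Estimation inverts the fit,
   `f̂ = clamp((logit(fir) − β̂₀)/β̂₁, 0, 1)`; a negative fitted slope
   triggers an orientation flip (the model then reads 1 − FIR) so that
   β̂₁ > 0 always. This parameterization is the exact inverse of the
   generative link, so the noiseless round trip is identity; regressing
   on the logit-FIR scale also puts the (FIR-scale, Gaussian) noise on
   the response side of the regression. Held-out accuracy is summarised
   as the mean absolute error on a second, independently seeded pool
   set; under the default design (9 pools at 0.1…0.9, 1000 SNPs each,
   σ = 0.03) it sits just under 3%. Missing FIR yields missing
   frequency, never 0.

## Synthetic studies

The generator is the package's ground-truth source, not a fixture:

- **Groups.** K group mean frequencies per locus i.i.d. Beta(0.5, 0.5)
  (U-shaped, as for ascertained array SNPs); member populations drift
  around their group mean p as Beta(p·c, (1−p)·c) — Balding–Nichols
  with concentration c (`drift`, default 50, i.e. Fst ≈ 1/c ≈ 0.02
  within groups; c → ∞ collapses members onto the mean).
- **Landraces.** True frequencies are simplex mixtures of group means;
  a bulk of n = 15 diploid plants contributes a Binomial(2n, f)/2n
  draw per locus, so bulk frequencies live on the 1/30 lattice. Equal
  DNA contribution per plant is assumed.
- **Missingness** is injected completely at random (default 2%); the
  real mechanism of failed calls is unknown and not modelled.
- All randomness flows through `numpy.random.default_rng(seed)`:
  outputs are bit-reproducible per seed.

What passing tests therefore do **not** show: robustness to per-SNP
link heterogeneity, linkage disequilibrium, unequal plant contribution
to the bulk, or informative missingness — none of which the generator
emulates.

## Diversity and distance

Hs = mean over loci of 2p(1−p); NbMono counts loci at exact fixation
(p ∈ {0, 1}) by default, because upstream snapping produces exact 0/1;
a `mono_tol` widens the band for sensitivity analysis. Hs is computed
on the post-imputation matrix by default, with an `ignore_missing`
mode. Missing cells are imputed by the observed locus mean (an
all-missing locus gets 0.5 and a logged warning, keeping shapes stable
on small inputs).

The modified Rogers distance for biallelic loci reduces to
`sqrt(Σ(p_x − p_y)²/L)`: the 1/(2L) two-allele normalisation folds into
1/L because the A-allele difference mirrors the B-allele difference.
This keeps d ≤ 1 exactly and makes MRD Euclidean.

## Structure

- **PCoA**: Gower double-centering of −½D², symmetric
  eigendecomposition; only positive eigenvalues produce axes and enter
  the percent-variance denominator (no Lingoes/Cailliez correction —
  MRD needs none; eigenvalues below a 1e-12 relative floor are treated
  as null). Sign indeterminacy is resolved by orienting each axis so
  its largest-magnitude score is positive.
- **Neighbor joining**: plain Saitou–Nei with the Q-criterion.
  BIONJ-style variance weighting is deliberately out of scope: on
  additive matrices the two coincide, and plain NJ has a clean
  brute-force oracle. Q-ties break on the lexicographically smallest
  index pair, so output is deterministic given input order. Negative
  branch estimates are clamped to zero with the deficit moved to the
  sibling, preserving pairwise totals. Trees serialise to standard
  Newick (labels with metacharacters quoted).
- **Ward**: scipy's `linkage(…, "ward")` on the distance matrix, i.e.
  the Lance–Williams recursion on squared distances (hclust "ward.D2").
  Squared input was an open choice; it is taken because Ward's
  criterion is variance-based. Verified in tests against an exhaustive
  agglomeration oracle for N ≤ 6.

## Ancestry assignment

Group mean matrix G: unweighted mean of labelled reference populations
per group and locus. Each query solves
`min_a ‖f − Gᵀa‖² + λ‖a‖²` subject to Σa = 1, a ≥ 0, as a K-dimensional
reduced quadratic (Gram matrix precomputed, scaled by 1/L) via SLSQP
with analytic gradients (ftol 1e-14); the solution is clipped at 0 and
renormalised, so rows sit on the simplex within 1e-8. Non-negativity is
enforced by default because the coefficients are reported as
percentages of belonging; `nonneg=False` drops it (closed-form KKT
solve) for comparison with a sum-to-one-only regression. The ridge
weight defaults to 0 — the penalty form is exposed but not needed when
K ≪ L. Queries are solved independently; ties in the main-group label
break by group order and are logged. Duplicate identical group rows
with λ = 0 make the optimum non-unique; the deterministic solver path
then fixes a representative and a warning is logged.

## Pipeline

Stage order is fixed: inputs (simulate or load) → FIR-to-frequency
estimation (bypassed when frequencies are supplied directly) →
imputation → Hs/NbMono + MRD → PCoA/NJ/Ward → ancestry. One seed feeds
every stage, so identical configs give byte-identical outputs; unknown
config keys abort before any stage runs. In simulate mode the run
report additionally scores recovery (frequency MAE vs the realised bulk
frequencies, proportion MAE, main-group accuracy) against the
generator's truth.

## Problem sizes

The bundled analyses and tests run at desk scale by design: panels of
3–7 groups × 200–1000 loci, 12–49 populations, pools of 9 × 1000 SNPs,
and 10-seed replication for stochastic checks. These sizes keep every
statistical margin comfortable (Monte-Carlo error well under the
asserted tolerances) while the full suite completes in well under a
minute per module.

## Known limitations

- One global calibration assumes a homogeneous link across SNPs; real
  arrays show per-SNP cluster geometry, which the upstream SNP
  suitability filtering (not re-implemented here) is meant to remove.
- The monomorphism rule's z-window (z = 3) is a convention; the
  original cluster-comparison rule it stands in for is unspecified.
- MRD/PCoA/NJ/Ward operate on point estimates of frequency; estimation
  noise is not propagated into distances.
- No unsupervised admixture: the reference groups are fixed inputs, and
  no uncertainty (bootstrap/SE) accompanies the assignment percentages.
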