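# Methods

`namscreen` implements a five-cell-type new-approach-methodology (NAM)
workflow for rapid chemical hazard characterization: concentration–response
point-of-departure (POD) estimation, ToxPi aggregation and ranking,
unsupervised grouping scored by the Fowlkes–Mallows index, supervised
chemical-class prediction, and margin-of-exposure (MoE) screening. Because
real screen data of this kind are plate-level measurements that cannot be
bundled with a software package, the package includes a synthetic screen
generator with exact ground truth; every stage is validated against that
truth.

## Concentration–response model and POD

Each chemical × phenotype series is modelled with a four-parameter logistic
(Hill) curve on log10 concentration,

    f(c) = bottom + (top − bottom) / (1 + (EC50 / c)^h),

fitted by bounded least squares (`scipy.optimize.least_squares`, trust
region reflective, analytic Jacobian) to all replicate wells without
pre-averaging. Wells at concentration 0 (vehicle controls) observe the
`bottom` asymptote directly and are included in the residual vector; this
anchors the baseline near 100% of control. Without the anchor the
free-floating baseline drifts by a few percent on noisy flat series, which
is enough for |f(c) − 100| to exceed the benchmark everywhere and to turn a
quarter of truly inactive curves into spurious, extremely low PODs.

Parameter bounds: EC50 ∈ [1e−4, 1e4] µM, Hill slope ∈ [0.3, 8],
asymptotes ∈ [−100, 400]% of control. Three starts seed the EC50 at the
lowest, median and highest tested concentration; the lowest residual sum of
squares wins. The fitted curve is monotone by construction, so the
benchmark crossing below is unique when it exists.

The POD is the lowest concentration at which the fitted curve departs from
the vehicle mean by one vehicle standard deviation (a benchmark response
anchored to assay noise). It is found by a 256-point log-grid scan followed
by Brent root-finding on the bracketing interval. σ_v is the plate-matched
vehicle SD per phenotype, rescaled by normalization to % of control, which
matches the scope of the plate normalization itself. Censoring rules:

- no crossing within (0, 100 µM] → POD right-censored at the highest tested
  concentration (100 µM); censored PODs are retained, never dropped;
- crossing below the extrapolation floor of 1e−3 µM (one decade under the
  lowest tested concentration) → POD reported at the floor and flagged
  `below_range` rather than extrapolated further;
- σ_v = 0 (degenerate controls) → error, the benchmark is undefined.

When the optimizer fails to converge, a nonparametric fallback interpolates
concentration-wise mean responses linearly on log10 concentration to locate
the crossing.

Assay QC covers five parameters: replicate-well variance of both negative
controls (CV ≤ 15% passes), vehicle-vs-medium difference (Welch test,
passing when p > 0.05), intra-plate and inter-plate replicate correlation
(≥ 0.8 passes), and the positive-control EC50 falling in a configured
window. Checks whose data are absent are reported `not-evaluable`, never
silently passed. Functional-vs-cytotoxicity sensitivity is compared with a
one-sided Mann–Whitney test per cell type and pooled; censored PODs enter
at the censoring bound, which is conservative for the one-sided
alternative.

## ToxPi aggregation

Per phenotype, PODs are inversely scaled to [0, 1]: the lowest POD in the
dataset maps to 1 (highest bioactivity), the highest to 0, censored PODs to
exactly 0, and intermediate values interpolate on log10 POD (the default,
natural for a five-decade concentration series; linear interpolation is
retained for sensitivity analysis). Phenotypes with fewer than two distinct
finite PODs carry no information and are scored all-0 with a warning.
Slice scores are unweighted means of the member phenotype scores of each
cell type; the overall score is the equally-weighted mean of the five slice
scores (weights configurable, must sum to 1). Ranking is by descending
overall score with ties broken lexicographically by chemical id. Scaling
implies the overall score is monotone under POD improvement: lowering any
single POD of a chemical can never lower that chemical's overall score
(verified by randomized perturbation tests).

## Grouping and the Fowlkes–Mallows index

Chemicals are clustered agglomeratively from any numeric feature matrix.
The default bioactivity features are −log10 POD with censored values at
their bound. Distances are 1 − Pearson correlation between chemical rows
(range [0, 2], deliberately not clipped) or Euclidean; linkages are average
or Ward. A constant feature vector has no defined correlation and receives
maximal dissimilarity 1 with a logged warning. The tree is cut into k
groups (k = 5 when evaluating against the five reference classes; free
parameter otherwise).

Correspondence to the reference classing uses the Fowlkes–Mallows index.
With contingency counts m_ij between partitions, Tk = Σ m_ij² − n,
Pk = Σ (row sums)² − n, Qk = Σ (column sums)² − n, and B = Tk / √(Pk·Qk);
B = 1 iff the partitions are identical up to relabeling. Significance
against the null of random label assignment comes either from the
closed-form permutation moments of Tk or from an explicit permutation test
(p = (1 + #{B_perm ≥ B_obs}) / (n_perm + 1)). The variance of Tk was derived
from pair-overlap combinatorics — splitting E[Tk²] over identical,
one-shared-item, and disjoint pairs of item pairs:

    Var(Tk) = 2 Pk Qk / (n(n−1)) + 4 Pk′ Qk′ / (n(n−1)(n−2))
            + (Pk² − 2Pk − 4Pk′)(Qk² − 2Qk − 4Qk′) / (n(n−1)(n−2)(n−3))
            − (Pk Qk / (n(n−1)))²,  Pk′ = Σ nᵢ(nᵢ−1)(nᵢ−2),

and validated against exhaustive enumeration of all relabelings at
n = 4, 6, 8 (exact agreement) and against permutation z-scores at n = 30
(within ~1%). This derivation-first approach exists because transcription
errors in this formula are easy to make and hard to notice; the permutation
oracle is the arbiter.

## Supervised classification

Class prediction uses a random forest (500 bagged, √p-feature-subsampled
trees by default, no depth cap) under 5-fold cross-validation repeated over
50 random splits. Folds are stratified as far as class sizes allow: each
class's members are shuffled and dealt round-robin from a random offset, so
classes with ≥ 5 members spread evenly and a 2-member class (the smallest
reference class) never has both members in the same fold — a held-out
member always has a training instance. Confusion counts are summed over
repeats (matrix total = n × repeats). The accuracy null re-runs the full
cross-validation on uniformly permuted labels. Feature importance is
permutation importance on held-out folds — the mean decrease in test-fold
accuracy when one feature's values are shuffled — which is model-agnostic
and out-of-sample; top-k ties break by feature name.

## Risk characterization

The surrogate NAM POD per chemical is the minimum non-censored POD within a
scope (one cell type, or all combined — so the combined surrogate is ≤
every per-cell-type surrogate). All-censored chemicals yield a censored
surrogate that propagates as a lower bound. In vitro PODs (µM) convert to
administered equivalent doses via AED = POD / Css, where Css is the
supplied steady-state plasma concentration per 1 mg/kg/day oral dose
(upper-95th-percentile toxicokinetic variability); kinetics are assumed
linear and the toxicokinetic modelling itself is consumed as an input
table, not computed. MoE = AED / exposure; MoE < 100 (strict inequality,
so exactly 100 is not flagged) marks potential concern. Zero exposure gives
an infinite MoE, never flagged. For censored surrogates the MoE is a lower
bound; the default conservative mode flags when the bound is below the
benchmark. Conservatism against in vivo PODs is summarized as log10(NAM/in
vivo) ratios, the fraction strictly above the in vivo value
(unconservative), and the fraction of those within 10-fold. Units are
declared on every output row and checked on every paired comparison;
mismatches raise.

## Synthetic screen generator

The generator emulates the screen the analysis assumes: 42 chemicals in 5
classes (7 inorganics, 5 PAHs, 20 pesticides, 8 other industrial chemicals,
2 phthalates), five cell types (iPSC-derived hepatocytes, neurons,
cardiomyocytes and endothelial cells, plus HUVECs) with 41 phenotypes in
total (5/10/9/8/9 per cell type, functional and cytotoxicity categories;
counts are configurable), concentrations 100/10/1/0.1/0.01 µM, 3 treatment
replicates, 16 vehicle wells per plate (one plate per cell type), and
Gaussian well noise with SD 10% of control by default — enough wells per
plate for QC statistics to be estimable. One master seed feeds
`numpy.random.SeedSequence` splitting, one substream per plate plus one for
the ground truth, so cell-type subsets reproduce independently.

Chemical classes act through shared mechanisms, so class structure is
drawn at two levels. Per class × phenotype: whether the phenotype responds
(probability = the class's per-cell-type `activity_probability`), the
response direction (80% decreasing by default), and a shared log10 EC50
offset. Per chemical: membership fidelity (95% chance of responding on a
class-responsive phenotype), sporadic background activity elsewhere (2%),
and an individual log10 EC50 residual. The shared offset carries 80% of the
log10 EC50 variance (`phenotype_consistency`); potencies are drawn on log10
EC50 because the tested range spans five decades. Without the shared level,
class members would be independent random vectors and no clustering method
could recover classes from correlation distances — the two-level draw is
what makes class signatures well-separated, and is also how real chemical
classes behave. Active curves are vehicle-anchored (bottom = 100) with
effect sizes of 45–85% of control, keeping responses well clear of the 10%
noise floor, and Hill slopes uniform on [0.8, 3].

The default class signatures plant the qualitative structure the pipeline
is meant to resolve: inorganics broadly potent in all five cell types
(log10 EC50 ≈ −0.5), pesticides selectively potent in cardiomyocytes
(≈ −1.0) with moderate neuronal activity, PAHs acting on neurons,
industrial chemicals on the two endothelial models, and phthalates showing
moderate hepatocyte/cardiomyocyte activity.

What the generator does not emulate: plate-position effects and
edge-well artifacts, non-monotone (e.g., hormetic) responses,
heteroscedastic or correlated well noise, partial solubility and
concentration-series truncation, and any resemblance between a named
chemical and its real-world potency. Passing tests therefore demonstrate
the correctness and internal consistency of the analysis machinery under
the stated statistical assumptions — not field performance on real screens,
where class signatures are weaker and noise is structured.

The closed-form POD of a true curve (the oracle the fitted pipeline is
tested against) inverts the Hill function: c = EC50 / (|top − 100|/σ − 1)^(1/h),
censored when the asymptotic effect does not exceed σ.

## Numerical and design choices

- Root-finding tolerances: Brent to xtol 1e−12; POD oracle agreement is
  asserted to 1e−3 relative, fitted-vs-true recovery to a median
  |Δlog10 POD| < 0.25 at 10% noise.
- Degenerate inputs: all-identical vehicle wells (σ_v = 0) and zero vehicle
  means raise typed errors; all-censored phenotypes score 0 in ToxPi with a
  warning; single-member classes refuse cross-validation with an
  instruction to merge or drop.
- Determinism: every stochastic stage takes an explicit seed; identical
  seeds reproduce measurement tables, confusion matrices, importance ranks
  and permutation p-values bitwise.
- Problem sizes: the test suite computes one full 42-chemical POD table
  (1,722 curve fits) shared across tests; planted-structure recovery checks
  use 5 cross-validation repeats with 100-tree forests and a 99-permutation
  label null, and the Fowlkes–Mallows permutation test uses 1,999 relabelings
  (the smallest attainable p with the add-one estimator is 1/(n_perm + 1),
  so 999 permutations cannot resolve p < 0.001).
- The packaged toxicokinetic/exposure table is synthetic: invented, plausibly
  scaled values for 16 chemicals that exercise the risk stage end to end.

## Known limitations

- The 1-SD benchmark ties the POD to assay noise; between-plate differences
  in vehicle variability move PODs accordingly.
- Censored PODs at the range bound enter bioactivity feature vectors and
  rank-sum contrasts at that bound; with many censored values the contrasts
  are conservative rather than exact.
- Permutation feature importance divides credit among correlated features;
  planted single-feature signals rank correctly, but correlated feature
  blocks share importance.
- The generator's classes are balanced in mechanism strength; real
  reference classes (e.g., two phthalates) are hard to cluster simply
  because they are small, and the small-class behaviour seen here (the
  2-member class is the usual misclassification victim) mirrors that.
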