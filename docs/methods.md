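# Methods

## The model

`qolnet` treats a set of questionnaire scales measured on one cohort as
jointly latent-Gaussian: observed scores arise from a multivariate normal
vector through monotone per-scale margins, and the object of inference is
the latent precision matrix Θ, displayed as the partial-correlation
network w_ij = −Θ_ij/√(Θ_ii Θ_jj).  An absent edge means the two scales
are conditionally independent given all others; a present edge is a
candidate direct interaction.  The model is cross-sectional and
undirected: it cannot orient effects, and an edge can also reflect a
shared latent cause or semantic overlap between scales.  Networks are
estimated separately at each time point; the longitudinal structure
enters only through subject pairing in the resampling procedures.

### Mixed correlations

Multi-item scales (7+ distinct observed values) are treated as interval
data; scales with fewer than 7 distinct observed values — in practice
the single-item EORTC scales with 4 levels — as ordinal.  Pairwise
correlations are Pearson (continuous–continuous), polyserial
(continuous–ordinal) or polychoric (ordinal–ordinal).  The polychoric and
polyserial estimators are two-step: thresholds are fixed at inverse
standard-normal CDF values of the marginal cumulative proportions, then
the latent correlation alone maximizes the bivariate-normal likelihood by
bounded scalar search on (−0.999, 0.999) with tolerance 1e−6.  Two-step
estimation is standard practice and essentially indistinguishable from
full ML at the cohort sizes targeted here (n ≈ 500).  Zero-count cells
enter the likelihood as-is (no continuity correction) — estimates come
from the other cells; a configurable +0.5 correction is not applied by
default to keep the likelihood unmodified.

The assembled matrix need not be positive semidefinite (each pair is
estimated separately).  Eigenvalues below 1e−8 are clipped to that floor
and the matrix rescaled to a unit diagonal; the repair event and the
pre-repair minimum eigenvalue are recorded.  This one-shot clipping is
not the exact nearest-correlation projection, but stays close to it (the
alternating-projections algorithm serves as the test oracle) and is what
comparable network pipelines apply.

### EBIC-glasso

The glasso objective log det Θ − tr(SΘ) − λΣ_{i≠j}|Θ_ij| (diagonal
unpenalized) is solved by block coordinate descent on the working
covariance W, each column a lasso subproblem solved by coordinate-wise
soft thresholding; exact zeros in Θ come directly from the soft
threshold.  Solutions satisfy the KKT conditions to ~1e−6 at default
tolerance.  The penalty path has 100 log-spaced values from
λ_max = max|S_ij| (empty model) down to λ_max/100, fitted large-to-small
with warm starts; λ is selected by

    EBIC = −n (log det Θ − tr(SΘ)) + E log n + 4 γ E log p,  γ = 0.5.

γ = 0.5 is the conventional value: it suppresses most spurious edges at
the cost of missing some genuinely weak ones.  Edge weights are the
partial correlations of the *penalized* precision (no refit), matching
the convention of reporting regularized partial correlations.  n in the
EBIC is the subject count even when S contains polychoric entries — the
Gaussian likelihood is then an approximation, a known and accepted one in
this pipeline family.

### Centrality, communities

Strength is Σ|w|; closeness is 1/Σ distances with edge distance 1/|w|
(disconnected ⇒ closeness 0, keeping a total order for z-scores);
betweenness counts geodesics through a node, tied geodesics split
fractionally (Brandes convention — the plain count is ambiguous under
ties).  Communities are sought on |w| (modularity is defined for
non-negative weights; the estimated networks contain a minority of
negative edges) by three algorithms — exact integer-programming
modularity maximization (used up to 16 nodes; a simulated-annealing run
stands in beyond that), spinglass annealing, and 4-step walktrap — and
the partition with the highest Newman modularity Q is reported, with
Q < 0.3 flagged as weak structure.

### Stability and accuracy

Case-dropping bootstrap: B replicates spread evenly over a drop grid
(default 5%…75% in 5% steps; the source procedure's grid is not
published, so it is a config key), each re-running the *entire*
correlation + glasso pipeline; the stability curve is the Pearson
correlation between original and replicate edge-weight vectors (zeros
included; identical vectors count as correlation 1).  CS(cor = 0.7) is
the largest grid proportion at which — and below which — at least 95% of
replicates correlate ≥ 0.7 with the original; CS ≥ 0.25 is the
conventional interpretability floor, CS > 0.5 preferred.  Nonparametric
bootstrap (resampling subjects with replacement, B = 1000 by default)
gives per-edge 2.5/97.5% quantile intervals, and pairwise difference
tests declare two edges (or node strengths) different when the bootstrap
interval of their difference excludes zero, deliberately without
multiple-testing correction.  Resampling is always at subject level, so
the two time points of a subject are kept or dropped together.  Failed
replicates (e.g. a degenerate resampled contingency table) are dropped
and counted, erroring out above a 5% failure rate.

### Temporal comparison

The dependent-samples permutation test: under the null of equal
networks, a subject's (M0, M12) score-vector pair is exchangeable, so
each permutation swaps the pair independently per subject with
probability 1/2 and re-estimates both networks with the identical
pipeline.  Statistics: structure M = max|w1 − w2| over edges, global
strength |Σ|w1| − Σ|w2||, per-edge and per-node-strength absolute
differences (uncorrected).  p-values use the add-one convention
(1 + #{perm ≥ obs})/(1 + iterations) and are never exactly zero; 5000
iterations and a conservative α = 0.005 are the defaults.  The
dependent-data variant is heuristic — it has not been formally validated
— which the conservative α partially offsets; the package's own
calibration check (below) shows near-nominal type-I error for the
structure statistic under a paired null.  The difference network is the
entrywise |w1| − |w2| (positive = the association weakened from first to
second input; antisymmetric under swapping inputs); display thresholds
(0.05 for networks, 0.04 for differences) affect export only.

## The synthetic-data generator

`make_precision_spec` draws a sparse symmetric precision matrix: uniform
random support at the requested density, magnitudes uniform in
(0.25, 0.45) with 75% negative precision entries (≙ positive partial
correlations, the dominant sign among questionnaire scales), an
eigenvalue shift to enforce SPD and rescaling to a unit diagonal.  The
implied true partial correlations land mostly in ±(0.12, 0.30),
matching the magnitude range of published questionnaire networks.

`generate_cohort` draws per-subject latent vectors from the implied
correlation matrix; the two time points share one network and are paired
coordinate-wise with correlation `subject_corr` (default 0.5, a typical
one-year retest correlation for QoL scales; the trial reports no value,
so it is a free parameter).  Margins: continuous scales use a clipped
normal whose pre-clip mean/SD are moment-matched so the *post-clip*
distribution hits the published per-timepoint mean/SD — scales with
means near a bound correctly show ceiling effects; ordinal scales use
equal-probability standard-normal cuts onto equispaced reporting values.
Missingness is MCAR at a fixed expected cell rate (default 4%).  Each
subject has a dedicated child random stream spawned from the root seed,
so enlarging the cohort never changes earlier subjects' draws.

What the generator does *not* emulate: skewed non-Gaussian latent
dependence, informative (MAR/MNAR) missingness, item-level response
processes, intervention effects, or drift in the network between time
points.  Passing recovery/calibration tests therefore demonstrates
correctness of the estimation machinery under the latent-Gaussian model,
not robustness to violations of it.

## Preprocessing choices

Symptom and depression scales are reflected about their range maximum
(100, or 39 for the depression sum score) so higher always means better;
reversal precedes imputation (the source analysis does not state the
order; Spearman-based screening is insensitive to it up to sign).
Copy-mean imputation: interior gaps get within-subject linear
interpolation plus the population-mean shape correction; leading/trailing
gaps copy the nearest observation plus the population mean shift.
Population means use observed values only (no feedback through imputed
cells), making the procedure idempotent.  With two time points all
missingness reduces to the edge rule; the interior rule is implemented
and tested for T ≥ 3.  Imputed values are clipped to the scale range
(configurable), and imputed cells on ordinal scales are snapped to the
nearest attainable level so a 4-level scale keeps its ordinal
classification after imputation.  A subject missing a scale at every
time point falls back to the per-timepoint population mean (strict mode
available).

Node selection averages |rho| across the two time points and keeps
scales strictly above 0.3 (published screening tables have all-positive
correlations, so signed-vs-absolute averaging is unobservable there; the
absolute value is used for symmetry).  BH adjustment is applied within
each time point's family of scale-vs-target tests.

## Problem sizes in the shipped checks

The test-suite simulations run at the cohort's scale, n = 487 and 15
nodes: edge-support recovery averages 20 generator seeds; the
permutation-test calibration uses 200 Monte-Carlo repetitions of 250
permutations with all-continuous margins and a 30-point penalty path
(path floor λ_max/20) — calibration of a permutation scheme is invariant
to those estimator settings since observed and permuted data go through
the identical pipeline; bootstrap checks use B = 200 with the same
shortened path.  `scripts/acceptance.py` uses B = 200 and 500
permutations for the pipeline demonstration.  Full-scale defaults
(B = 1000, 5000 permutations, 100-point path) remain the package
defaults.

## Known limitations

- Polychoric standard errors are not computed (point estimates only).
- The glasso assumes the repaired mixed correlation matrix behaves like a
  Gaussian sample correlation; with many coarse ordinal scales the EBIC's
  effective sample size is optimistic.
- Community detection on |w| discards edge signs; signed-modularity
  variants are not implemented.
- The dependent NCT variant is heuristic (see above).
- Betweenness stability is computed but known to be the least stable
  index; interpret only when its CS clears 0.25.
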