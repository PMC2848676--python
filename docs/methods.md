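# Methods

`flumeflux` re-implements, as a tested library, an analysis chain that links
fine-scale flow heterogeneity in experimental stream flumes to biofilm
bacterial beta diversity and to the rate and molecular diversity of
dissolved-organic-carbon (DOC) uptake.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
generator does and does not emulate.

## The experimental system being modeled

Six 40-m streamside flumes share one water source, mean velocity
(7.6 cm s⁻¹, residence time 8.8 min) and mean depth (6.7 cm), but differ in
bedform height and therefore in the spatial variability of near-bed flow.
Heterogeneity is quantified as `SD_Rxyz`, the spatial standard deviation of
the node-wise time-mean 3-D speed, rising from 1.6 to 6.3 cm s⁻¹ across the
six flumes.  Biofilms assemble from a common inoculum in four bedform
microhabitats (upstream face, crest, downstream face, trough); communities
are fingerprinted (T-RFLP, one OTU per terminal-fragment size), glucose and
leaf-leachate DOC are injected into recirculating mode and their decay
monitored, and the inflow and residual DOC pools are characterized by
negative-mode FTICR mass spectrometry.

## Flow statistics

Per node, from the (u, v, w) time series:

* `R_xyz = mean_t sqrt(u² + v² + w²)` — time-mean speed (node means, not
  pooled instantaneous values, enter the spatial SD);
* `TKE = (var(u) + var(v) + var(w)) / 2` with population variances
  (long, stationary series);
* `TI = sqrt((var(u)+var(v)+var(w))/3) / R_xyz` — RMS fluctuation over mean
  speed.  `R_xyz = 0` with nonzero fluctuation would leave TI undefined; it
  is returned as NaN with a flag, never as infinity.

`SD_Rxyz` uses the sample (n−1) SD across nodes — a small spatial sample —
while within-series variances are population moments; neither convention is
dictated by the source material, so the velocimetry-standard pairing was
chosen.  Residence time is flume length over mean velocity.

## Diversity

Hill numbers `D_q = (Σ p_i^q)^(1/(1−q))` (limit `exp(H)` at q = 1) express
diversity as effective species counts; q = 0 is richness, q = 2 inverse
Simpson.  Gamma diversity comes from the equal-weight pooled community,
alpha from the generalized mean of within-community sums (`exp` of mean
Shannon entropy at q = 1), and beta = gamma/alpha is the effective number of
distinct communities among the four microhabitats.  The identity
gamma = alpha·beta holds to 1e-9 for every q and is property-tested.  Equal
community weights reflect the balanced microhabitat design; unequal weights
are accepted only at q ∈ {0, 1} where the multiplicative decomposition
remains exact.  Evenness is reported both as Hill evenness `D₁/S` and
Pielou's `ln D₁ / ln S`.  Zero abundances never enter entropy sums.

T-RFLP peak tables are reduced with the fragment-size window 30–900 bp and
a 2% of-maximum height threshold before normalization; both are
configurable.  Core-taxon filtering (taxa present in every flume, or every
microhabitat) turns the analysis into a conservative evenness-only
comparison among widespread taxa; rows are renormalized after filtering.
Partitions are computed per sampling date and averaged; partitioning pooled
tables instead is available by grouping upstream of the call.

## Uptake kinetics

First-order loss in recirculation gives `ln c(t) = ln c0 − k t`; k is the
negative OLS slope (closed-form, unit-invariant), and the mass transfer
coefficient is `v_f = k · h̄` with `h̄` the recirculating volume per wetted
area, approximated by mean water depth (6.7 cm) and configurable per flume.
k ≤ 0 (no net uptake) is legal and flagged.  Biofilm-free controls are
reported alongside biofilm runs, not subtracted by default; a
`control_correct` helper provides the net value when wanted.

## FTICR-MS processing

Ions are assumed deprotonated ([M−H]⁻): neutral mass = m/z + proton mass.
Formula assignment searches all CHONS compositions under the caps C ≤ 100,
O ≤ 80, N ≤ 5, S ≤ 1, requiring non-negative integer DBE
(`1 + C − H/2 + N/2`, i.e. H+N even), H/C ∈ [0.3, 2.5] and O/C ≤ 1.2 —
standard validity filters, all configurable.  The candidate with smallest
|mass error| wins; ties break toward fewer heteroatoms and are flagged
ambiguous.  Default tolerance 1 ppm.  The search is vectorized over the
(C, O) grid per (N, S) block and is verified in the tests against an
unpruned full-grid enumeration and by exact-mass round trips at 0.2 ppm.

The aromaticity index uses the modified form
`AI = (1 + C − O/2 − S − H/2) / (C − O/2 − N − S)`, clamped to 0 for
non-positive denominators or negative values (half of oxygen treated as
carbonyl-like).

Analysis is restricted to compounds present in the inflow and in **every**
residual sample (matching by nearest m/z within a ppm window, so unassigned
peaks are tracked too); this guards against in-flume production and
sensitivity artifacts.  Compound-specific mass transfer inverts the
first-order relation on intensities:
`v_f = (h̄/T) · ln(I_inflow / I_residual)` with T the recirculation
duration (6 h default).  With intensities normalized over the shared set
(the relative-availability convention, default) every compound's v_f is
shifted by a per-flume constant — v_f is then removal *relative to the pool
average* and negative values mean slower-than-average removal.  Slopes,
SDs and distance matrices are invariant to that constant; raw-intensity
ratios (`intensity_norm="none"`) give absolute values.  Pool diversity is
Shannon entropy of relative intensities with evenness `H/ln n`.

## Regression machinery

Per-flume compound-v_f models regress v_f on inflow relative intensity,
O:C, H:C, aromaticity, nitrogen presence and neutral mass.  Hierarchical
partitioning decomposes the full-model R² into per-predictor independent
contributions by averaging, over hierarchy levels, the mean R² gain from
adding the predictor to every subset of the others (all 2^k subset models;
equal to the average over all k! orderings, which the tests verify by
enumeration).  ΣI_j = R²_full exactly.  The coefficient of variation uses a
percentile bootstrap CI (simplest defensible choice; BCa not offered).

## Distance-matrix inference

Metavariables are small dissimilarity matrices among the six flumes:
z-scored Euclidean for mixed-unit variables, Bray-Curtis for compositional
tables, plain Euclidean for the unit-sum-normalized compound-v_f vectors.
Default declarations: HET = {SD_Rxyz}; BETA = {beta, q=1}; DOCUSE =
normalized compound-v_f vectors; DOCDIV = {slope(v_f ~ rI_inflow), SD(v_f)};
DOCMT = {bulk DOC v_f}; GLCMT = {glucose v_f per biofilm age}; COMP =
Bray-Curtis among flume-pooled communities.

The Mantel statistic is the Pearson correlation of upper triangles; with
six objects all 6! = 720 simultaneous row/column permutations are
enumerated, so P is exact, one-tailed (greater), counts the identity, and
has a discrete floor of 1/720.  The partial Mantel statistic is the
first-order partial correlation; its null permutes the residuals of A's
triangle regressed on the control's (arranged back into matrix form and
permuted object-wise — Legendre's recommendation; raw permutation available
by flag).  The Bonferroni family defaults to the number of tests in the
emitted table.

Path analysis treats the Mantel correlation matrix as a correlation
structure over a user-declared DAG: per endogenous node,
`β = R_XX⁻¹ R_Xy`, error variance `(1 − R_yX β)·100%`.  Edge significance
randomizes **all** involved matrices independently and recomputes β;
P = share of randomizations (observed included) with |β_perm| ≥ |β_obs|.
The default DAG regresses beta diversity and glucose mass transfer on flow
heterogeneity, resource-use diversity on heterogeneity + beta diversity,
and DOC mass transfer on heterogeneity + resource-use diversity — the
minimal hypothesis chain from physical forcing through biodiversity to
function; it is configurable because the choice of edges is a scientific
hypothesis, not a package decision.  UPGMA (average linkage) clusters the
resource-use matrix.

## Synthetic data generator

The generator is first-class, tested code; its defaults encode the study
design: 6 flumes, `SD_Rxyz` targets 1.6 → 6.3 cm s⁻¹ (evenly spaced — only
the endpoints are known), mean velocity 7.6 cm s⁻¹, depth 6.7 cm, 4
microhabitats × 4 dates, a 76-OTU regional pool with per-flume richness
drawn around 26 (SD 13), 361 shared DOC compounds, 6-h recirculation,
glucose at biofilm ages 12/18/23 d and DOC at 24 d.  One global seed feeds
per-stream/per-flume `SeedSequence` spawn keys, so streams regenerate
independently and fixed seeds are bit-identical.

* **Flow**: node-mean speeds are gamma-shaped (right-skewed, positive even
  at SD close to the mean) and affinely standardized to the exact target
  mean and SD; per-node turbulent series are rescaled to their assigned
  node speed.  A target SD ≥ mean velocity is unreachable under
  non-negativity and raises.  Default grid 80 nodes × 60 time steps with
  turbulence intensity 0.15 — a deliberate scale-down of a 50-Hz
  velocimeter record that leaves every spatial statistic intact.
* **Communities**: geometric-series regional pool (ratio 0.92); per-flume
  support drawn abundance-weighted; microhabitat centers are log-space
  perturbations of the flume center whose *direction* is a fixed property
  of the habitat type (shared across flumes) and whose magnitude is
  `0.15 · SD_Rxyz`, standardized with abundance weights so each flume
  realizes exactly its designed divergence; composite samples are Dirichlet
  draws with concentration 1000.  The concentration keeps within-flume
  sampling noise below the designed between-flume signal, which the
  monotone-gradient contract of the generator requires; realized beta is
  then strictly monotone along the gradient for the large majority of seeds
  and in expectation always.
* **Decay**: `c(t) = c0 · e^(−kt) · (1 + ε)`, ε ~ N(0, 0.02) —
  multiplicative relative error, as analytical chemistry scatter scales
  with concentration.  True rates rise linearly with heterogeneity
  (glucose: 0.15 + 0.05·SD h⁻¹ scaled by age; DOC: 0.04 + 0.012·SD h⁻¹;
  controls 0.01 h⁻¹), placing v_f in the cm h⁻¹ range typical of labile
  vs. semi-labile solutes.
* **Peak lists**: compounds are sampled from the valid CHONS grid (mass
  150–800 Da, ≥3 ppm apart); inflow intensities are lognormal(0, 1.2).
  True compound v_f = 0.30 + b·rI + 0.25·O:C − 0.15·AI + N(0, 0.05) cm h⁻¹
  with the rI coefficient b = 160 − 18·SD_Rxyz — the weakening of the
  availability dependence along the gradient.  Residual intensities invert
  the mass-transfer relation exactly; unshared peaks (25 inflow-only, 14
  per-residual) exercise the shared-set filter and are kept ≥5 ppm away
  from shared compounds.

What the generator does **not** emulate: hydrodynamics (no Navier-Stokes,
no spatial autocorrelation of the velocity field), sequence-level 16S
structure, chromatogram baselines, isotope patterns, instrument drift or
calibration error, and within-flume replication of uptake experiments
(replicate-level noise magnitudes are free parameters — the source study
does not report them).  Passing tests therefore demonstrate that the
estimators recover known truth under the designed signal and noise, not
that real electropherograms or spectra are processed robustly.

## Numerical and scale choices

* Full Mantel enumeration is limited to n ≤ 8 objects; larger problems use
  the sampled mode (identity always counted).
* The pipeline's default path-permutation count is 10⁴ (the full
  10⁵ used for publication-grade inference is one config key away); with six flumes one
  full run takes well under a minute on a single core.
* Ties in permutation statistics are compared with a 1e-12 slack so the
  identity permutation is never lost to floating-point jitter.
* Degenerate inputs raise informative errors rather than returning NaN:
  constant distance triangles, zero-variance z-scores, all-zero
  Bray-Curtis pairs, single-species evenness, nonpositive concentrations
  before the log transform.

## Known limitations

* The exact TI formula, the volume-to-area accounting behind h̄, the
  FTICR tolerance/validity limits and the metavariable column memberships
  of the original study are not public; each is implemented as the
  field-standard choice and exposed as configuration.
* Hierarchical partitioning is capped at 12 predictors (2^k fits).
* Mantel-based path coefficients are descriptive decompositions of the
  correlation structure, not maximum-likelihood structural equation fits.
* Compound matching is by m/z proximity only; isomers are one compound.
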