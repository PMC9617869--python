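# Methods

This note documents the models and numerical choices behind `dynconn`:
what each stage computes, which parameters matter and why their defaults
were chosen, what the synthetic cohort generator does and does not
emulate, and the known limitations.

## Synthetic cohort model

Each subject's BOLD matrix is a piecewise-stationary Gaussian process. A
latent state sequence z(t) ∈ {1, …, k} evolves as a first-order Markov
chain at volume (TR) resolution — not at window resolution — so sliding
windows can straddle state changes exactly as windowed estimation does
on real data. Volume t is drawn as x(t) ~ N(0, Σ_{z(t)}) plus isotropic
observation noise with SD `noise_sd` (default 0.2, i.e. 4% variance
inflation on unit-variance signals: visible but not dominant).

**State covariances.** Correlation targets are set per network pair
(within/between defaults plus named block overrides) and assembled into
a block-structured correlation matrix per state. The default two states
encode the canonical case–control contrast: state 1 is hypoconnected
(within-network 0.15, default-mode coupling to other networks −0.2,
fronto-parietal to sensory −0.15) and state 2 is hyperconnected
(within 0.5, between 0.25, sensorimotor/visual blocks 0.5–0.6). A matrix
that is not positive-definite is repaired by diagonal loading with a
smallest-eigenvalue floor of 1e-6 followed by rescaling to unit diagonal
— equivalent to uniform shrinkage of all off-diagonal targets, which
preserves the block structure; construction fails loudly (naming the
offending blocks) if the required shrinkage exceeds 50%, because the
planted structure would no longer resemble the targets.

**Group dynamics.** The two-state transition matrices are parameterized
by the target stationary occupancy and mean dwell time (in volumes) of
state 1: patients 0.756 / 61.5, controls 0.672 / 41.0. For a two-state
chain these two numbers identify the matrix (mean dwell of state 1 is
1/p₁₂ and occupancy is p₂₁/(p₁₂+p₂₁)), so the planted group effect —
patients persist in the hypoconnected state, dwell longer in it, and
transition less — follows directly from the chain.

**Symptom link.** One designated default-mode node (index 0 by default)
carries a per-patient state contrast v ∈ [0, 1]: its state-1 coupling
row is interpolated toward its state-2 (hub) row as v shrinks, followed
by the same PD repair. At v = 0 the node keeps its strong hub profile in
both states — it is "locked in", its thresholded-graph metrics barely
fluctuate across windows, and its CV is low; at v = 1 it has the full
between-state contrast and a high CV. This parameterization was chosen
because proportional thresholding makes graph metrics depend on a
node's standing *relative to the rest of the network* within each
window: simply scaling a node's couplings down does not reduce its
temporal variability (a weakly coupled node drops in and out of the
retained edge set and fluctuates strongly), whereas pinning the node to
a consistently central profile does. Empirically the Spearman
correlation between v and the measured CV of the node's eigenvector
centrality is ≈ 0.6–0.8 at the default dimensions. Controls have v = 1,
so patients (v uniform on [0, 1]) also show reduced average variability
at this node. Severity scores are generated with a linear-in-rank link:
the standardized rank of v is mixed with Gaussian noise to hit a target
correlation (`symptom_effect`, default −0.5), so Spearman-based recovery
is unbiased in expectation. PANSS-style totals and subscales are affine
transforms of the same severity factor.

**What the generator does not emulate.** No hemodynamic response
convolution, scanner drift, physiological noise, motion artifacts, or
spatial structure within nodes; within-state covariance is exactly
stationary. Passing tests therefore demonstrate that the pipeline
recovers planted state structure and effects under its own model
assumptions — they do not certify behavior under real-data violations
of those assumptions (autocorrelated noise, gradual state drift,
non-Gaussian signals).

## Windowing

Default window width 22 TR sliding by 1 TR; a 30 TR / 2 TR configuration
is exposed for window-length sensitivity analysis. Windows are
rectangular by default (the common toolbox default); a Gaussian taper is
available and is applied as observation weights in a weighted Pearson
correlation. Correlations are clustered untransformed; a Fisher r-to-z
flag and a within-window linear detrend flag exist for sensitivity
checks and are off by default. A zero-variance node within a window has
its correlations set to 0 (with a warning counter on the result) rather
than aborting the subject, so flat channels degrade visibly but
gracefully.

## State analysis

k-means uses k-means++ initialization, 20 restarts, relative tolerance
1e-6, at most 500 iterations, and an explicit seed. Model order is the
silhouette-maximizing k over 2…10; the "elbow" is operationalized as the
largest discrete second difference of the SSE curve (an inflection needs
a computable definition) and a warning is logged when the two criteria
disagree — the silhouette k wins because it is the sharper criterion on
well-separated states. Fits that leave a cluster empty (fewer distinct
windows than k) are retried with a fresh seed and then fail loudly.

States are relabeled by ascending centroid mean edge value, making
"state 1 = hypoconnected" an invariant of the fitted model rather than
an accident of initialization. A state a subject never visits has
fractional time 0 and mean dwell 0 (not missing), keeping per-subject
feature vectors complete for the classifier; dwell times are reported in
window counts and include all subjects in group averages.

## Dynamic topology

Thresholding keeps the m = round(K/100 · N(N−1)/2) strongest strictly
positive off-diagonal weights, ties broken by lexicographic node-pair
order for bit-reproducibility. Defining the budget against all possible
pairs (rather than the count of positive edges, which varies by window)
gives comparable densities across windows — the premise of integrating
across a sparsity grid. If fewer positive edges exist they are all kept
and the graph is flagged. Retained weights are the raw correlations.

Efficiency metrics use edge length 1/weight and Dijkstra shortest
paths; unreachable pairs contribute 0, so values stay comparable across
windows with different components. The clustering coefficient is
Onnela's weighted formulation (weights normalized by the matrix maximum,
geometric-mean triangle intensity, nodes of degree < 2 contribute 0),
averaged over nodes. Eigenvector centrality is the leading eigenvector
by power iteration (max 10,000 iterations) on the matrix shifted by its
largest row sum — the shift leaves eigenvectors unchanged, makes the
iteration monotone (no ±λ oscillation on bipartite-like graphs), and the
stopping rule is residual-based (‖Wx − λx‖ ≤ 1e-10·λ), which bounds the
eigenvector error by tolerance divided by the relative spectral gap.
The result is nonnegative with unit Euclidean norm; an empty graph
yields the zero vector. On a disconnected graph the mass concentrates on
the dominant component by design.

AUC across the sparsity grid is the trapezoidal integral in percent
units. The CV across windows uses the sample SD (denominator W−1) over
the mean and is flagged undefined (NaN) when |mean| < 1e-12; undefined
CVs are imputed fold-locally in the classifier and excluded pairwise in
group statistics.

## Group statistics

The permutation statistic is the difference of group means (a pooled-t
variant is available behind a flag); p-values use the add-one estimator
(#{|perm| ≥ |obs|} + 1)/(n_perm + 1), which is never exactly zero.
Default 10,000 permutations. FDR families: the five state
characteristics form one family; each nodal map (nodal efficiency,
eigenvector centrality) is corrected as its own family; the two global
CVs form a fourth. Symptom correlations are run only on features
surviving the FDR-corrected group comparison, in patients, as Spearman
partial correlations: x and y are rank-transformed (average ranks),
residualized on the raw covariates (age, sex coded 0/1, education) with
an intercept, and the Pearson correlation of residuals is tested with a
t approximation on n − #covariates − 2 degrees of freedom; nominal
α = 0.05, uncorrected, as these analyses are descriptive. Demographic
checks use a Pearson chi-square without continuity correction (sex) and
pooled-variance two-sample t-tests (age, education).

## Classification

Linear SVC with C = 1 and no class weighting (groups are near-balanced;
no hyperparameter search is performed, so LOOCV estimates are not
optimistically tuned). Within every LOOCV fold and using the training
fold only: NaN features are imputed with the training median, features
are ranked by one-way ANOVA F score (epsilon-guarded for zero
within-group variance) and the top ⌈fraction·p⌉ kept, then z-scored by
training statistics. Patients are the positive class; AUC uses decision
values. The feature fraction is swept from 1% to 100% in 1% steps, and
the chosen fraction is the smallest whose accuracy is within one
fold-error (1/n) of the maximum — the most parsimonious model
statistically indistinguishable from the best, which guards against
picking a large, overfit feature set. Consensus features are those
selected in every fold; their reported weights are means of the
standardized-feature SVC coefficients across folds, ranked by absolute
value. Significance comes from rerunning the entire selection + LOOCV
pipeline under permuted labels.

## Problem sizes in the test suite and acceptance script

The default study conditions are 20 patients + 20 controls, 20 nodes in
4 networks, 190 volumes — dimensions at which every stage's behavior is
measurable in minutes while preserving the windows-per-subject and
group-dynamics structure of a full-scale study; node count and network
assignment scale to 264/13 by configuration. The acceptance script uses
10,000 permutations for group tests, 999 for each of 1,000 null
datasets in the type-I calibration, and 199 label permutations for the
classifier (each of which reruns the full LOOCV); the planted symptom
correlation is additionally recovered on a 200-patient cohort, where
the sampling error of a correlation is small. All randomness flows from
the single `--seed` argument through `numpy.random.SeedSequence`.

## Known limitations

* Sliding-window Pearson correlation is the only dFC estimator; wavelet,
  dynamic-conditional-correlation, and phase-based estimators are out of
  scope.
* The state model is k-means on pooled windows; no hidden-Markov or
  per-subject state estimation (the Markov chain lives only in the
  generator).
* Graph metrics cover efficiency, Onnela clustering, and eigenvector
  centrality on positive weighted graphs; binary variants,
  small-worldness, and modularity are not implemented.
* ROI extraction assumes atlas coordinates in the image affine's output
  space and uses voxel-center-in-sphere membership; no resampling or
  partial-volume weighting.
* The classifier has no external-cohort validation path; LOOCV on one
  cohort is known to have high variance at these sample sizes.
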