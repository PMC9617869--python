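# dynconn

Dynamic functional connectivity (dFC) analysis of resting-state fMRI for
case–control studies: sliding-window connectivity, k-means brain-state
identification, state temporal metrics, dynamic graph topology,
permutation-based group inference with FDR control, symptom correlation,
and individual-level classification — plus a synthetic cohort generator
that plants the statistical structure the analysis assumes, so the whole
pipeline is testable end to end without any imaging data.

The package is aimed at neuroimaging researchers studying time-varying
brain network organization in clinical populations (the default
configuration emulates a first-episode psychosis case–control design),
and at methodologists who want a fully seeded, parameter-recoverable
reference implementation of the standard dFC state / dynamic-topology
workflow.

## The analysis

**Sliding-window dFC.** Each subject's T×N region-of-interest BOLD matrix
is segmented into overlapping windows of width *w* TR sliding by *s* TR
(defaults *w* = 22, *s* = 1; a *w* = 30, *s* = 2 validation configuration is
one config flag away). Window *j* covers volumes [*js*, *js* + *w*) and
yields an N×N Pearson correlation matrix, giving
W = ⌊(T − w)/s⌋ + 1 matrices per subject (169 for T = 190, w = 22, s = 1).

**Brain states.** The upper triangles of all windows from all subjects
are pooled and clustered with k-means (Euclidean distance, k-means++
initialization, 20 restarts). The number of states k is chosen by the
maximum mean silhouette coefficient over k = 2…10, with the elbow of the
sum of squared errors (largest discrete second difference) reported
alongside. States are relabeled by ascending centroid mean connectivity,
so state 1 is always the hypoconnected state. Per subject, three
temporal metrics summarize the window-ordered state sequence: fractional
time (proportion of windows per state), mean dwell time (mean
consecutive-run length, in windows), and number of transitions.

**Dynamic topology.** Each windowed matrix is thresholded to a sparse
weighted graph keeping the strongest K% of positive connections
(K ∈ {5, 10, 15, 20}); four metrics are computed per window and sparsity —
global efficiency, mean (Onnela) weighted clustering coefficient, nodal
efficiency, and nodal eigenvector centrality — then integrated across the
sparsity grid (trapezoidal AUC). The coefficient of variation (SD/mean)
of each AUC across windows quantifies temporal variability; high CV
means strongly fluctuating topology.

**Inference and classification.** Group differences in the dynamic
features use a two-sided label-permutation test on the difference of
group means (10,000 permutations by default) with Benjamini–Hochberg FDR
within feature families; symptom associations use Spearman partial
correlations controlling age, sex, and education. A linear support
vector classifier with leave-one-out cross-validation, fold-local
F-score feature selection, and a 1–100% feature-fraction sweep evaluates
whether the dynamic features separate patients from controls at the
individual level; its accuracy is benchmarked against label
permutations.

**Synthetic cohorts.** The generator draws each subject's latent
connectivity state sequence from a group-specific two-state Markov chain
at volume resolution and samples volumes from state-specific Gaussian
covariances (plus isotropic noise). Patients persist longer in the
hypoconnected state, and one designated default-mode node carries a
planted, symptom-linked dynamic range. Ground truth (state sequences,
stationary occupancies, planted effects) is recorded for
parameter-recovery testing.

## Worked example

```python
import dynconn as dc

cfg = dc.default_config(n_patients=10, n_controls=10, seed=7)
subjects, truth = dc.simulate_cohort(cfg)

params = dc.WindowParams(width_tr=22, step_tr=1)
dfc = {ts.subject_id: dc.sliding_window_fc(ts, params) for ts in subjects}
X, sids = dc.stack_window_vectors(dfc.values())
model = dc.fit_states(X, k=2, seed=7, subject_ids=sids)

occ = dc.occurrence_frequency(model)
print(f"state 1 (hypoconnected) occupies {100*occ[0]:.1f}% of all windows")
for ts in subjects[:2]:
    m = dc.state_metrics(model.labels_for(ts.subject_id), 2)
    print(f"{ts.subject_id} ({ts.group}): fractional time "
          f"{m.fractional_time.round(2)}, mean dwell {m.mean_dwell.round(1)}, "
          f"transitions {m.n_transitions}")

td = dc.subject_topo_dynamics(dfc[subjects[0].subject_id])
print(f"{subjects[0].subject_id}: CV of global efficiency "
      f"{td.cv_global_efficiency:.3f}, CV of nodal EC at node 0 "
      f"{td.cv_eigenvector_centrality[0]:.3f}")
```

prints

```
state 1 (hypoconnected) occupies 69.1% of all windows
sub-P000 (patient): fractional time [0.98 0.02], mean dwell [165.   4.], transitions 1
sub-P001 (patient): fractional time [0.81 0.19], mean dwell [68.5 32. ], transitions 2
sub-P000: CV of global efficiency 0.125, CV of nodal EC at node 0 0.541
```

The occupancy line says the weakly connected state dominates the pooled
windows; the per-subject lines show the three temporal metrics (this
patient barely leaves state 1); the last line is the temporal
variability of the graph metrics that enters the group statistics and
the classifier.

The same stages are available from the shell:

```bash
dynconn simulate --out cohort/ --n-patients 20 --n-controls 20 --seed 1
dynconn run-all --cohort cohort/ --out results/ --seed 1
```

`run-all` writes `state_metrics.tsv`, `topo_dynamics.tsv`,
`group_comparisons.tsv`, `correlations.tsv`, a classification report with
`fraction_curve.tsv` and `consensus_features.tsv`, and a
`run_manifest.json` that records every parameter and seed needed to
reproduce the run byte-for-byte.

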