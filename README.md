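# lamdec

Laminar analysis of columnar V1 recordings: current-source-density (CSD)
layer assignment, single-neuron orientation-tuning metrics, and
depth-resolved population decoding of stimulus orientation.

## The problem

High-density probes record hundreds of neurons spanning every layer of a
single cortical column. Within one penetration this makes it possible to
ask where along the depth axis stimulus information is strongest: do the
input layers (4C), which receive thalamic drive, carry a better orientation
code than superficial (2/3) and deep (5/6) layers — and if so, is that due
to weaker noise correlations or to more reliable single neurons?

`lamdec` implements that analysis as a tested, reusable pipeline:

1. **Layer assignment** — stimulus-triggered LFP, averaged over groups of
   four channels, differentiated twice along the probe with the five-point
   stencil `CSD_i = −(φ_{i−2} − 2φ_i + φ_{i+2})/(2h)²`, smoothed across
   depth (σ = 120 µm). The lower boundary of the major current sink marks
   the 4C–5/6 border; the remaining compartment borders (2/3, 4A/B, 4C,
   5/6; mean thicknesses 650/311/281/489 µm) follow by thickness offsets.
2. **Single-neuron metrics** — responsiveness gate (two-tailed t-test vs
   the inter-stimulus interval, p < 0.01, plus a 3 spikes/s floor), optimal
   eye/SF selection, maximum rate, modulation ratio F1/F0, direction and
   orientation indices, Hanning-smoothed tuning curves fitted with the von
   Mises form `y = a0 + a1·exp(a2(cos 2(x − a3) − 1))` (R² > 0.7 gate),
   bandwidth with the 180° sentinel, and the windowed Fano factor
   (var/mean of spike counts in 100 ms windows).
3. **Decoding** — subpopulations of 10 depth-adjacent neurons, labelled by
   their centre depth; all 153 pairwise discriminations of the 18
   orientations; five classifier families (logistic regression, LDA,
   Gaussian naive Bayes, RBF-SVM, random forest) under stratified 10-fold
   cross-validation with a 6-fold inner search of the regularisation
   constant; trial-shuffling and single-neuron controls; neuron-dropping
   curves; and orientation sensitivity (1/Δθ_min at the 60% threshold).
4. **Statistics** — Kruskal–Wallis and two-tailed Wilcoxon comparisons
   across compartments, the Fano-factor vs accuracy correlation, and
   running-window kurtosis of metric profiles across depth.

A synthetic-session generator (`lamdec.synth`) produces fully specified
columnar or non-columnar sessions — von Mises tuning, gamma-Poisson counts
realising layer-dependent Fano factors, simple/complex temporal
modulation, optional within-compartment noise correlations, and a dipole
LFP whose sink ends at the 4C–5/6 border — so the whole pipeline is
testable end to end without any recorded data. See `docs/methods.md` for
models, conventions and limitations.

## Worked example

```python
import numpy as np, lamdec

cfg = lamdec.SessionConfig(n_neurons=48, sf_set=(2.0,),
                           reps_per_direction=5, seed=7)
session = lamdec.generate_session(cfg)

model = lamdec.estimate_laminar_model(
    session.lfp, session.trials["onset"].values[:30])
print("4C-5/6 border: %.0f um" % model.boundary_46)

metrics = lamdec.compute_metrics(session, model)
print("mean Fano by compartment:",
      metrics.groupby("compartment").fano.mean().round(2).to_dict())

pop = lamdec.build_response_matrix(
    session, neurons=np.flatnonzero(metrics.responsive.values))
subs = lamdec.build_subpopulations(pop.depths, model, k=10, stride=2)
res = lamdec.decode_subpopulations(
    pop, subs, lamdec.DecodeConfig(outer_folds=5, seed=0), families=("LDA",))
print(res.groupby("compartment").accuracy.mean().round(3))
```

prints

```
4C-5/6 border: 1230 um
mean Fano by compartment: {'2/3': 1.53, '4A/B': 1.4, '4C': 1.25, '5/6': 1.57}
compartment
2/3     0.825
4A/B    0.846
4C      0.864
5/6     0.844
```

The CSD chain recovers the planted 4C–5/6 border (truth 1242 µm) within
one channel group; the Fano estimates track the planted per-compartment
targets (1.87/1.62/1.28/1.94, read slightly low at 5 repeats per
condition); and the layer with the most reliable neurons — 4C, lowest
Fano factor — decodes orientation best (86.4% mean pairwise accuracy vs
82.5% in layer 2/3), even though every compartment has identically tuned
neurons in this synthetic column.

## Command line

Each stage is also a subcommand (`simulate`, `layers`, `tuning`,
`decode`, `ndc`, `sensitivity`, `report`, `validate`), driven by a
YAML/JSON config; stages reuse cached upstream artifacts and a manifest
records the configuration hash and seeds:

```sh
lamdec run --config run.yaml --out results/
lamdec validate results/session.h5
```

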