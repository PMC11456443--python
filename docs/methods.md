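# Methods

This note documents the models, conventions and numerical choices behind
`lamdec`: a pipeline that assigns laminar compartments from current-source
density (CSD), measures single-neuron orientation tuning, and compares
orientation decoding across cortical depth in columnar V1-like recordings.

## The recording model

A *session* holds sorted single units (spike times per trial, depth below
pia in micrometers), a trial table (drift direction 0–350° in 10° steps,
spatial frequency, eye, onset; 1 s stimulus + 0.25 s blank), and a
multi-channel LFP block (20 µm contact pitch, 2500 Hz). Cortical depth is
divided into four laminar compartments — 2/3, 4A/B, 4C, 5/6 — with mean
thicknesses 650, 311, 281 and 489 µm and half-open depth intervals
`[upper, lower)`; a depth exactly on a boundary belongs to the deeper
compartment.

## Synthetic session generator

The generator exists so every downstream stage is testable without any
recorded data. It emulates the statistical structure the analysis assumes,
not the biophysics.

**Orientation tuning.** Each unit's mean rate is a von Mises function of
drift direction,

    r(θ) = a0 + a1 · exp(a2 (cos 2(θ − a3) − 1)) · (1 + b cos(θ − a3)) / (1 + b),

with baseline a0 ≈ 4.5 spikes/s, amplitude a1 ≈ 23.5 spikes/s,
concentration a2 ≈ 3 and direction bias b (the direction index at zero
baseline). Defaults were chosen to give peak rates near 30 spikes/s,
median orientation index ≈ 0.7 and raw half-bandwidth ≈ 15–19°, the regime
reported for macaque V1. In *columnar* sessions the preferred orientation
is shared across depth (configurable jitter); in *non-columnar* sessions it
drifts monotonically by 120° across the probe.

**Spike counts.** Counts are drawn independently in the ten 100 ms windows
tiling the stimulus period. Each window count is negative binomial
(gamma-Poisson) with dispersion solved from the unit's Fano-factor target
at that window's mean (`var = µ + µ²/r`); a target of 1 is exactly Poisson
and targets below 1 are realised by binomial thinning of a regular count.
Because the windows are independent and share the Fano factor, the summed
trial count carries the same Fano factor — the planted value is recovered
at both the windowed and the whole-trial scale. Per-compartment defaults
are 1.87 (2/3), 1.62 (4A/B), 1.28 (4C) and 1.94 (5/6).

**Temporal structure.** Spike times are placed by inverse-CDF sampling of
a rate profile modulated at the grating temporal frequency, taken as drift
speed (2 deg/s) × spatial frequency. The modulation-depth parameter is the
target F1/F0: 0 gives a flat (complex-cell) profile, values ≤ 1 an offset
cosine, values up to π/2 a clipped or fully rectified cosine (the clip
depth is solved numerically from the target). Spontaneous Poisson activity
at the baseline rate fills the inter-stimulus blank so the responsiveness
gate has a baseline to test against.

**Noise correlations.** Within-compartment correlations are imposed by
Gaussian-copula trial *reordering*: per condition, a shared latent with
weight √r plus independent noise defines per-unit trial ranks, and each
unit's trials are reordered to follow its ranks. This preserves every
marginal distribution — and therefore the planted Fano factors — exactly,
induces mean pairwise count correlation ≈ r, and is removed by independent
within-condition shuffling. A multiplicative shared gain would have been
simpler to calibrate but inflates count variance, corrupting the planted
Fano structure that the study conditions pivot on.

**LFP.** The stimulus-locked LFP is a dipole forward model: a current sink
spanning layer 4C with an equal-width balanced source below, temporal
kernel a Gaussian transient peaking 60 ms after onset. The potential is
the (detrended) double integral of the prescribed CSD, so the estimation
chain should recover the sink's lower boundary — the 4C–5/6 border — up to
discretisation. The LFP block covers a configurable number of onsets
(default 30); the triggered average needs no more.

**What the generator does not emulate.** No membrane or network dynamics,
no waveforms, no eye movements, no adaptation or slow drift, no
stimulus-dependent correlation structure, and no relationship between
firing rate and Fano factor beyond the planted compartment profile.
Passing tests therefore demonstrate that the *pipeline* measures what it
claims under the assumed statistics, not that those statistics exhaust
real recordings.

## Layer assignment

LFP channels are averaged in groups of four (80 µm pitch), triggered
averages are differentiated twice along depth with the five-contact
stencil `CSD_i = −(φ_{i−2} − 2φ_i + φ_{i+2})/(2h)²` (conductivity set to 1;
two bins lost per edge), and smoothed along depth with a Gaussian of
σ = 120 µm (edge handling: zero padding, so mass is conserved away from
edges). The major sink is the most negative bin of the time-averaged CSD
in a 30–100 ms response window; it must exceed 3 robust (MAD-scaled)
deviations, otherwise "no sink" is raised. The sink→source zero crossing
below it, linearly interpolated (plateaus resolve to the shallower depth),
is the 4C–5/6 border; a ±1-group manual adjustment is exposed. Remaining
boundaries follow by offsetting compartment thicknesses. Alternative
five-point stencils differ only by a constant factor, which cannot move a
zero crossing.

## Single-neuron metrics

All rates use the stimulus period offset by a fixed 50 ms response
latency; the same offset starts the decoding window, keeping the two
analyses consistent. Per unit: a two-tailed t-test of per-trial stimulus
rates against inter-stimulus rates (responsive iff p < 0.01 *and* the best
condition reaches 3 spikes/s); the optimal eye/SF maximises the direction
curve (ties → lower SF, then first eye); DI and OI are the standard
response contrasts; F1/F0 is twice the Fourier magnitude at the grating
temporal frequency over the mean rate. Orientation curves average
opposite drift directions (most units respond near-equally to both),
are smoothed by circular convolution with a unit-sum raised-cosine kernel
(half width at half height 20°, nine 10° taps, endpoints zero), and
fitted with the von Mises form by multi-start nonlinear least squares
(starts at the six highest bins; preferred angle reported mod 180°).
Bandwidth is the closed-form flank offset where the fitted curve drops to
criterion × peak — criterion 1/√2 by default with 1/2 behind a switch, as
both conventions circulate — and 180° when the curve never drops below
criterion. The Fano factor averages var/mean of counts (n−1 variance)
over non-overlapping 100 ms windows and stimulus conditions, excluding
zero-mean windows.

Two estimator caveats, documented rather than hidden: (i) the smoothing
kernel broadens tuning before fitting, so fitted bandwidths have a floor
of ≈ 18.6° (the kernel's own fitted width) regardless of the true width;
(ii) the windowed Fano estimator is a small-sample ratio and reads a few
percent low at 5–10 repeats per condition — it is unbiased to within 10%
at ≥ 500 repeats, which is what the recovery tests check.

## Decoding

Responses are mean spike counts in the 50–1050 ms window, restricted to
the optimal spatial frequency, normalised per neuron by the session
maximum (a max statistic; the leakage this induces across folds is
negligible and documented), with orientation labels pooling opposite
directions. Subpopulations are sliding windows of k = 10 depth-adjacent
units (stride 1 by default); the centre depth — the mean of the two middle
units — assigns the compartment. All C(18,2) = 153 orientation pairs are
decoded with stratified 10-fold cross-validation; logistic regression
(L2, liblinear) and RBF-SVM select C from an 11-point grid 10⁻⁶…10⁴ by
6-fold inner validation on each training fold (ties → smaller C; the best
C is refit on the full fold); LDA uses the least-squares solver with
automatic (Ledoit-Wolf) covariance shrinkage; Gaussian NB and random
forest (100 trees, √p features, bootstrap) run at defaults. LDA and NB
use closed-form implementations whose predictions are verified in the
test suite to match the corresponding scikit-learn estimators exactly;
the other families are scikit-learn. Fold assignment is seeded per
(subpopulation, pair).

Controls: *shuffled* decoders permute each neuron's training trials
independently within each orientation (testing is un-shuffled);
*single-neuron* decoders are the k = 1 case. Neuron-dropping curves
sample up to 200 distinct combinations per population size and decode all
pairs with LDA. Sensitivity expresses pair accuracy against angular
difference (10–90°, both neighbours averaged) per reference orientation;
Δθ_min is the first linear crossing of 60%, clamped at 10° when already
above threshold and floored at 90° when never reached (both conventions
explicit config); sensitivity = 1/Δθ_min.

## Statistics

Kruskal–Wallis (tie-corrected, df = groups − 1) for omnibus compartment
comparisons; two-tailed Wilcoxon rank-sum (unpaired) and signed-rank
(paired) follow-ups, exact below n = 25 and normal-approximated with
continuity correction above; identical paired vectors return p = 1 by
convention. The Fano–accuracy correlation is Pearson by default (Spearman
available). Running kurtosis uses the Pearson (non-excess) convention in
sliding 100 µm depth windows, skipping windows with fewer than 4 values.

## Reference experiment sizes

The mechanism experiment (`lamdec.experiments.run_mechanism`) uses a
96-unit columnar session, 10 repeats per direction, one spatial frequency,
in which compartments differ *only* in their planted Fano factors: tuning
parameters are identical across units, the column is perfectly tight (no
preference scatter), direction bias is fixed at 0.1 and no correlations
are planted. This isolates response reliability as the only systematic
laminar difference. LDA and NB are evaluated on the full stride-2
subpopulation profile at 10 folds, unshuffled, shuffled and in
single-neuron mode; LogR/SVM/RF are evaluated on the two purest windows
per compartment (all members inside the compartment, nearest its
midpoint) with 5 outer / 3 inner folds, a 3-point C grid and 25 trees.
Chance calibration uses a 200-trial label-permuted set at the full
protocol settings.

With compartments differing only in Fano factor, the expected 4C margin
over the next-best compartment is small — roughly 0.5–2% mean accuracy at
these sizes — so an individual random session can occasionally invert two
compartments by sampling noise alone; the reference experiment pins the
session seed, and across-seed behaviour is discussed above. The paper-
scale margins arise from real neurons that differ in more than Fano
factor.

## Known limitations

- Fitted bandwidths are kernel-broadened (floor ≈ 18.6°); comparisons
  across compartments remain valid, absolute values read high.
- The windowed Fano estimator is biased a few percent low at few repeats.
- The copula correlation calibration is exact only up to rank-mapping
  attenuation (< 5% for counts with means ≳ 10).
- The synthetic LFP is a single stationary dipole; multi-sink CSD
  profiles, impedance artefacts and volume-conduction effects are absent.
- No multi-class (18-way) decoding, no temporal decoding, no spike
  sorting, no histology processing.
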