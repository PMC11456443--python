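"""Reference experiments: the synthetic study conditions and their analyses.

These functions bundle the package's end-to-end checks at desk scale:

* ``run_mechanism`` — the reliability mechanism: a columnar session whose
  laminar compartments differ *only* in their planted Fano factors
  (2/3: 1.87, 4A/B: 1.62, 4C: 1.28, 5/6: 1.94).  Layer 4C subpopulations are
  expected to decode orientation best, the ordering should survive
  training-set trial shuffling and single-neuron decoding, and subpopulation
  accuracy should correlate negatively with mean Fano factor.
* ``chance_calibration`` — label-permuted decoding sits at 50% for every
  classifier family.
* ``boundary_recovery`` — the CSD chain recovers a planted sink boundary.
* ``tuning_recovery`` — von Mises parameter recovery and the windowed Fano
  estimator against planted targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .csd import estimate_laminar_model
from .decode import (DecodeConfig, build_response_matrix,
                     build_subpopulations, decode_pair, decode_subpopulations,
                     single_neuron_decode)
from .stats import ff_performance_correlation
from .synth import (NeuronSpec, SessionConfig, Trial, generate_session,
                    sample_trial_counts)
from .tuning import compute_metrics, fano_factor

COMPARTMENTS = ("2/3", "4A/B", "4C", "5/6")


def mechanism_session_config(seed: int, n_neurons: int = 96,
                             reps: int = 10) -> SessionConfig:
    """Columnar session in which compartments differ only in Fano factor.

    A single tight orientation column (no preference scatter), one spatial
    frequency and eye, identical tuning parameters for every unit and weak,
    uniform direction bias, so that the planted per-compartment Fano factors
    are the only systematic difference between laminar compartments.
    """
    return SessionConfig(
        n_neurons=n_neurons, reps_per_direction=reps, sf_set=(2.0,),
        eye_conditions=("mono",), columnar=True, columnar_jitter_sd=0.0,
        param_jitter=0.0, uniform_selectivity=True,
        direction_bias_range=(0.1, 0.1), noise_corr=0.0, seed=seed)


def _mechanism_decode_config(seed: int) -> DecodeConfig:
    # desk-scale settings for the expensive families (5 outer / 3 inner
    # folds, 3-point C grid, 25 trees); LDA/NB run at the full 10 folds
    return DecodeConfig(outer_folds=5, inner_folds=3,
                        c_grid=(1e-3, 1e-1, 1e1), n_trees=25, seed=seed)


def _pure_windows(subs, member_compartments, per_compartment=2):
    """The purest windows (all members in one compartment), nearest the
    compartment midpoints, ``per_compartment`` each."""
    chosen = []
    for comp in COMPARTMENTS:
        pure = [s for s in subs
                if s.compartment == comp
                and all(c == comp for c in member_compartments(s))]
        mid = np.median([s.center_depth for s in pure]) if pure else None
        pure.sort(key=lambda s: abs(s.center_depth - mid))
        chosen.extend(pure[:per_compartment])
    return chosen


def run_mechanism(seed: int, n_neurons: int = 96, reps: int = 10,
                  heavy_families: bool = True) -> dict:
    """Full mechanism experiment; returns compartment accuracy tables.

    LDA and NB are evaluated densely (stride-2 subpopulation profile,
    10-fold CV, unshuffled and shuffled, plus single-neuron mode); the
    costlier LogR/SVM/RF families are evaluated on the two purest windows
    per compartment with reduced fold counts.
    """
    cfg = mechanism_session_config(seed, n_neurons, reps)
    session = generate_session(cfg)
    model = estimate_laminar_model(
        session.lfp, session.trials["onset"].values[: cfg.n_lfp_trials])
    metrics = compute_metrics(session, model)
    responsive = np.flatnonzero(metrics["responsive"].values)
    pop = build_response_matrix(session, neurons=responsive)
    subs = build_subpopulations(pop.depths, model, k=10, stride=2)
    comps_true = np.array(session.true_compartments)

    def members(s):
        return comps_true[pop.neuron_indices[s.indices]]

    dense_cfg = DecodeConfig(outer_folds=10, seed=seed)
    out: dict = {"seed": seed, "model": model.to_dict()}

    res = decode_subpopulations(pop, subs, dense_cfg, families=("LDA", "NB"))
    res_sh = decode_subpopulations(pop, subs, dense_cfg,
                                   families=("LDA", "NB"), shuffle=True)
    out["dense"] = res
    out["dense_shuffled"] = res_sh
    out["compartment_mean"] = (res.groupby(["algorithm", "compartment"])
                               ["accuracy"].mean().unstack())
    out["compartment_mean_shuffled"] = (
        res_sh.groupby(["algorithm", "compartment"])["accuracy"]
        .mean().unstack())

    single = single_neuron_decode(pop, model, dense_cfg,
                                  families=("LDA", "NB"))
    out["single_neuron"] = single
    out["single_neuron_mean"] = (single.groupby(["algorithm", "compartment"])
                                 ["accuracy"].mean().unstack())

    # Fano factor vs accuracy across subpopulations (LDA)
    ff = metrics.set_index("neuron")["fano"]
    sub_ff = np.array([float(np.nanmean(
        ff.reindex(pop.neuron_indices[s.indices]).values)) for s in subs])
    lda = res[res["algorithm"] == "LDA"]
    sub_acc = lda.groupby("subpopulation")["accuracy"].mean().values
    out["ff_accuracy"] = ff_performance_correlation(sub_ff, sub_acc)
    out["subpop_ff"] = sub_ff
    out["subpop_acc"] = sub_acc

    if heavy_families:
        picked = _pure_windows(subs, members, per_compartment=2)
        heavy = decode_subpopulations(pop, picked,
                                      _mechanism_decode_config(seed),
                                      families=("LogR", "SVM", "RF"))
        out["heavy"] = heavy
        out["heavy_mean"] = (heavy.groupby(["algorithm", "compartment"])
                             ["accuracy"].mean().unstack())
        # the cheap families on the same windows, completing the
        # five-family comparison table
        cheap = decode_subpopulations(pop, picked, dense_cfg,
                                      families=("LDA", "NB"))
        out["five_family_mean"] = pd.concat([heavy, cheap]).groupby(
            ["algorithm", "compartment"])["accuracy"].mean().unstack()
    out["metrics"] = metrics
    return out


def chance_calibration(seed: int, n_trials: int = 200,
                       n_neurons: int = 10) -> dict[str, float]:
    """Label-permuted decoding accuracy per family on one synthetic pair."""
    rng = np.random.default_rng(seed)
    spec = NeuronSpec(depth=500.0, preferred_direction=90.0,
                      tuning_amplitude=23.5, baseline=4.5,
                      tuning_concentration=3.0, direction_bias=0.1,
                      modulation_ratio_target=0.0, fano_target=1.5,
                      optimal_sf=2.0)
    trial = Trial(90.0, 2.0, "mono", 0.0)
    X = np.array([[sample_trial_counts(spec, trial, rng).sum()
                   for _ in range(n_neurons)] for _ in range(n_trials)],
                 dtype=float)
    X /= X.max(axis=0)
    y = rng.permutation(np.repeat([0, 90], n_trials // 2))
    cfg = DecodeConfig(seed=seed)
    return {fam: decode_pair(X, y, fam, cfg, seed=seed)
            for fam in ("LogR", "LDA", "NB", "SVM", "RF")}


def boundary_recovery(seed: int, sink_bottom: float = 1200.0) -> dict:
    """Noiseless dipole forward model -> CSD chain -> boundary error (um)."""
    from .synth import synthesize_lfp
    cfg = SessionConfig(seed=seed)
    onsets = np.arange(10) * 1.25
    lfp = synthesize_lfp(cfg, (sink_bottom - 281.0, sink_bottom), onsets)
    model = estimate_laminar_model(lfp, onsets)
    return {"true": sink_bottom, "estimated": model.boundary_46,
            "error": abs(model.boundary_46 - sink_bottom)}


def tuning_recovery(seed: int, n_reps: int = 500) -> dict:
    """Parameter recovery: noiseless von Mises fit and Fano estimation."""
    from .tuning import fit_von_mises
    rng = np.random.default_rng(seed)
    theta = np.arange(0.0, 180.0, 10.0)
    a0, a1, a2, a3 = 4.0, 20.0, 2.5, float(rng.uniform(0, 180))
    curve = a0 + a1 * np.exp(a2 * (np.cos(2 * np.deg2rad(theta - a3)) - 1.0))
    fit = fit_von_mises(curve, theta)
    d_a3 = abs((fit.a3 - a3 + 90.0) % 180.0 - 90.0)
    ff_est = {}
    trial = Trial(90.0, 2.0, "mono", 0.0)
    for target in (1.0, 1.3, 1.9):
        spec = NeuronSpec(depth=0.0, preferred_direction=90.0,
                          tuning_amplitude=0.0, baseline=20.0,
                          tuning_concentration=2.0, direction_bias=0.0,
                          modulation_ratio_target=0.0, fano_target=target,
                          optimal_sf=2.0)
        counts = np.array([sample_trial_counts(spec, trial, rng)
                           for _ in range(n_reps)])
        ff_est[target] = fano_factor([counts])
    return {"a3_error_deg": d_a3, "r_squared": fit.r_squared,
            "fano_estimates": ff_est}
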