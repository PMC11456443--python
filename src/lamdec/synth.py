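"""Synthetic columnar recording sessions.

Generates fully specified sessions with the statistical structure the laminar
analysis assumes: depth-stratified neurons with von Mises orientation tuning,
layer-dependent Fano factors realised by a gamma-Poisson (negative binomial)
count model, simple/complex temporal modulation at the grating temporal
frequency, optional within-compartment noise correlations, and a stimulus-locked
LFP dipole whose current sink ends at the 4C-5/6 border.

Spike counts are drawn independently per 100 ms window; a sum of independent
negative binomial counts sharing a common Fano factor keeps that Fano factor,
so the planted value is recovered both at the windowed and the whole-trial
scale.  Correlations are imposed by Gaussian-copula trial reordering within
each stimulus condition, which preserves every marginal (hence the Fano
factors) exactly and is removed by independent within-condition shuffling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("2/3", "4A/B", "4C", "5/6")

#: mean compartment thicknesses (um) for layers 2/3, 4A/B, 4C, 5/6
DEFAULT_THICKNESSES = (650.0, 311.0, 281.0, 489.0)

#: per-compartment Fano factor defaults (2/3, 4A/B, 4C, 5/6)
DEFAULT_FANO = (1.87, 1.62, 1.28, 1.94)

N_FANO_WINDOWS = 10          # 100 ms windows tiling the 1 s stimulus period
DRIFT_SPEED = 2.0            # deg/s drift of the grating


class Trial(NamedTuple):
    direction: float         # deg in [0, 360)
    sf: float                # cycles/deg
    eye: str
    onset: float             # s


@dataclass
class SessionConfig:
    """Parameters of a synthetic columnar (or non-columnar) session."""

    n_neurons: int = 96
    depth_range: tuple[float, float] = (0.0, 1731.0)
    compartment_thicknesses: tuple[float, ...] = DEFAULT_THICKNESSES
    columnar: bool = True
    reps_per_direction: int = 5
    sf_set: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    eye_conditions: tuple[str, ...] = ("mono",)
    seed: int = 0
    fano_by_compartment: tuple[float, ...] = DEFAULT_FANO
    noise_corr: float = 0.0
    stim_duration: float = 1.0
    isi: float = 0.25
    latency: float = 0.05
    pref_orientation: float | None = None     # deg; None -> drawn
    columnar_jitter_sd: float = 5.0           # deg circular SD when columnar
    noncolumnar_drift: float = 120.0          # deg drift across depth otherwise
    n_lfp_trials: int = 30
    lfp_fs: float = 2500.0
    lfp_channel_pitch: float = 20.0
    lfp_noise_sd: float = 0.0
    balanced_depths: bool = True              # equal neuron counts per compartment
    param_jitter: float = 1.0                 # scales between-neuron parameter spread
    uniform_selectivity: bool = False         # compartment-independent DI / simple fraction
    direction_bias_range: tuple[float, float] | None = None   # overrides DI range

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.compartment_thicknesses):
            raise ValueError("compartment thicknesses must be positive")
        if self.reps_per_direction < 2:
            raise ValueError("reps_per_direction must be >= 2")
        span = self.depth_range[1] - self.depth_range[0]
        if span < sum(self.compartment_thicknesses):
            raise ValueError("depth_range does not cover all compartments")
        if not 0.0 <= self.noise_corr <= 0.5:
            raise ValueError("noise_corr must lie in [0, 0.5]")

    @property
    def true_boundaries(self) -> np.ndarray:
        """Depths (um) of 2/3|4A/B, 4A/B|4C, 4C|5/6 and 5/6|WM borders."""
        return self.depth_range[0] + np.cumsum(self.compartment_thicknesses)

    @property
    def boundary_46(self) -> float:
        return float(self.true_boundaries[2])

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list, indent=1)


@dataclass
class NeuronSpec:
    """Generative parameters of one synthetic unit."""

    depth: float                       # um below pia
    preferred_direction: float         # deg in [0, 360)
    tuning_amplitude: float            # spikes/s above baseline at preference
    baseline: float                    # spikes/s
    tuning_concentration: float        # kappa of the von Mises profile
    direction_bias: float              # [0, 1]; direction index at zero baseline
    modulation_ratio_target: float     # F1/F0; simple if > 1
    fano_target: float
    optimal_sf: float                  # cycles/deg
    optimal_eye: str = "mono"
    sf_bandwidth_oct: float = 1.2
    eye_gain: float = 0.4              # attenuation at the non-optimal eye
    compartment: str = ""

    def __post_init__(self) -> None:
        if self.tuning_amplitude < 0 or self.baseline < 0:
            raise ValueError("rates must be >= 0")
        if self.fano_target <= 0:
            raise ValueError("fano_target must be > 0")
        if not 0.0 <= self.direction_bias <= 1.0:
            raise ValueError("direction_bias must lie in [0, 1]")

    def mean_rate(self, direction: float, sf: float, eye: str) -> float:
        """Trial-averaged firing rate (spikes/s) for one stimulus condition."""
        d = np.deg2rad(direction - self.preferred_direction)
        ori = np.exp(self.tuning_concentration * (np.cos(2.0 * d) - 1.0))
        dir_f = (1.0 + self.direction_bias * np.cos(d)) / (1.0 + self.direction_bias)
        sf_f = np.exp(-(np.log2(sf / self.optimal_sf)) ** 2
                      / (2.0 * self.sf_bandwidth_oct ** 2))
        eye_f = 1.0 if eye == self.optimal_eye else self.eye_gain
        return float(self.baseline + self.tuning_amplitude * ori * dir_f * sf_f * eye_f)


@dataclass
class LfpBlock:
    data: np.ndarray            # channels x samples, uV
    channel_depths: np.ndarray  # um, ascending
    fs: float                   # Hz


@dataclass
class Session:
    """One synthetic recording: spike trains, trial table and LFP block."""

    config: SessionConfig
    neurons: list[NeuronSpec]
    spikes: list[list[np.ndarray]]      # [neuron][trial] -> absolute times (s)
    trials: pd.DataFrame                # direction, sf, eye, onset
    lfp: LfpBlock | None = None
    true_compartments: list[str] = field(default_factory=list)

    @property
    def depths(self) -> np.ndarray:
        return np.array([n.depth for n in self.neurons])

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def trial_tuples(self) -> list[Trial]:
        return [Trial(r.direction, r.sf, r.eye, r.onset)
                for r in self.trials.itertuples()]


# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------

def build_stimulus_schedule(cfg: SessionConfig,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Pseudorandom trial order over 36 directions x SFs x eyes.

    Every (direction, sf, eye) condition appears exactly ``reps_per_direction``
    times.  Directions run 0-350 deg in 10 deg steps; each 1 s presentation is
    followed by a 0.25 s blank.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    directions = np.arange(0, 360, 10, dtype=float)
    rows = [(d, sf, eye)
            for d in directions
            for sf in cfg.sf_set
            for eye in cfg.eye_conditions
            for _ in range(cfg.reps_per_direction)]
    order = rng.permutation(len(rows))
    period = cfg.stim_duration + cfg.isi
    out = pd.DataFrame([rows[i] for i in order],
                       columns=["direction", "sf", "eye"])
    out["onset"] = np.arange(len(out)) * period
    return out


# ---------------------------------------------------------------------------
# temporal intensity profile (simple/complex modulation)
# ---------------------------------------------------------------------------

_RECTIFIED_RATIO = np.pi / 2.0   # F1/F0 of a half-wave rectified sine


@lru_cache(maxsize=256)
def _clip_depth_for_ratio(target: float) -> float:
    """Modulation depth m' such that max(0, 1 + m' cos) has F1/F0 = target."""
    from scipy.optimize import brentq

    x = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)

    def ratio(m):
        c = np.maximum(0.0, 1.0 + m * np.cos(x))
        return 2.0 * np.mean(c * np.cos(x)) / np.mean(c)

    if target >= _RECTIFIED_RATIO - 1e-3:
        return np.inf
    return float(brentq(lambda m: ratio(m) - target, 1.0, 1e4))


def temporal_intensity(m_target: float, freq: float, t: np.ndarray) -> np.ndarray:
    """Unit-mean rate modulation profile on [0, 1] s.

    ``m_target`` is the asymptotic F1/F0: 0 gives a flat (complex-cell)
    profile, values <= 1 an offset cosine, values up to pi/2 a clipped or
    fully rectified cosine.
    """
    if m_target <= 1e-9 or freq <= 0:
        return np.ones_like(t)
    phase = 2.0 * np.pi * freq * t
    if m_target <= 1.0:
        prof = 1.0 + m_target * np.cos(phase)
    else:
        m = _clip_depth_for_ratio(min(m_target, _RECTIFIED_RATIO))
        if np.isinf(m):
            prof = np.maximum(0.0, np.cos(phase))
        else:
            prof = np.maximum(0.0, 1.0 + m * np.cos(phase))
    mean = prof.mean()
    return prof / mean if mean > 0 else np.ones_like(t)


def _condition_profile(spec: NeuronSpec, trial: Trial,
                       duration: float = 1.0,
                       n_windows: int = N_FANO_WINDOWS):
    """Per-window expected counts and the fine intensity grid for one condition."""
    rate = spec.mean_rate(trial.direction, trial.sf, trial.eye)
    if rate < 0:
        raise ValueError("negative mean rate")
    freq = DRIFT_SPEED * trial.sf
    grid = np.linspace(0.0, duration, 2001)
    intensity = temporal_intensity(spec.modulation_ratio_target, freq, grid)
    cdf = np.concatenate([[0.0], np.cumsum((intensity[1:] + intensity[:-1]) / 2.0
                                           * np.diff(grid))])
    total = cdf[-1]
    if total <= 0:
        weights = np.full(n_windows, 1.0 / n_windows)
        cdf = grid / duration
        total = 1.0
    else:
        edges = np.linspace(0.0, duration, n_windows + 1)
        cum = np.interp(edges, grid, cdf) / total
        weights = np.diff(cum)
    mu_w = rate * duration * weights
    return mu_w, grid, cdf / total


# ---------------------------------------------------------------------------
# count noise model
# ---------------------------------------------------------------------------

def _draw_count(mu: float, fano: float, rng: np.random.Generator) -> int:
    if mu < 0:
        raise ValueError("negative mean")
    if mu == 0:
        return 0
    if abs(fano - 1.0) < 1e-9:
        return int(rng.poisson(mu))
    if fano > 1.0:
        r = mu / (fano - 1.0)
        return int(rng.negative_binomial(r, r / (r + mu)))
    # fano < 1: binomial thinning of a (randomised-round) regular count
    q = 1.0 - fano
    n_f = mu / q
    n = int(np.floor(n_f)) + int(rng.random() < (n_f - np.floor(n_f)))
    return int(rng.binomial(n, q)) if n > 0 else 0


def sample_trial_counts(spec: NeuronSpec, trial: Trial,
                        rng: np.random.Generator,
                        n_windows: int = N_FANO_WINDOWS) -> np.ndarray:
    """Spike counts in the ``n_windows`` 100 ms windows of one trial.

    Each window count is negative binomial (gamma-Poisson) with dispersion
    solved from the neuron's Fano target at that window's mean; windows are
    independent, so the summed trial count carries the same Fano factor.
    Targets below 1 are realised by binomial thinning of a regular process;
    a target of exactly 1 reduces to Poisson.
    """
    mu_w, _, _ = _condition_profile(spec, trial, n_windows=n_windows)
    return np.array([_draw_count(m, spec.fano_target, rng) for m in mu_w])


def render_spike_times(counts, spec: NeuronSpec, trial: Trial,
                       rng: np.random.Generator,
                       latency: float = 0.05,
                       duration: float = 1.0) -> np.ndarray:
    """Place spike counts as times within the stimulus response period.

    ``counts`` may be a scalar (placed over the whole period) or a per-window
    vector from :func:`sample_trial_counts`.  Placement follows the neuron's
    temporal intensity (sinusoidal at the grating temporal frequency for
    simple-cell specs, uniform for complex specs) by inverse-CDF sampling, so
    the measured F1/F0 approaches ``modulation_ratio_target``.
    """
    _, grid, cdf = _condition_profile(spec, trial, duration=duration)
    counts = np.atleast_1d(np.asarray(counts, dtype=int))
    if counts.sum() == 0:
        return np.empty(0)
    if counts.size == 1:
        u = rng.random(int(counts[0]))
    else:
        edges = np.linspace(0.0, duration, counts.size + 1)
        cum = np.interp(edges, grid, cdf)
        parts = [rng.uniform(cum[w], cum[w + 1], size=int(c))
                 for w, c in enumerate(counts) if c > 0]
        u = np.concatenate(parts)
    times = np.interp(u, cdf, grid)
    return np.sort(trial.onset + latency + times)


# ---------------------------------------------------------------------------
# noise correlations
# ---------------------------------------------------------------------------

def correlation_permutation(counts: np.ndarray, r_target: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Trial-reordering (one permutation per neuron) inducing ~r_target.

    Gaussian-copula rank matching: a latent shared across neurons with weight
    sqrt(r) plus independent noise defines per-neuron trial ranks; each
    neuron's counts are reordered to follow its ranks.  ``perm[t, j]`` is the
    source trial whose data neuron ``j`` receives on trial ``t``.
    """
    if not 0.0 <= r_target <= 0.5:
        raise ValueError("r_target must lie in [0, 0.5]")
    n_trials, n_neurons = counts.shape
    perm = np.tile(np.arange(n_trials)[:, None], (1, n_neurons))
    if r_target == 0.0 or n_neurons < 2 or n_trials < 2:
        return perm
    z = rng.standard_normal(n_trials)
    eps = rng.standard_normal((n_trials, n_neurons))
    u = np.sqrt(r_target) * z[:, None] + np.sqrt(1.0 - r_target) * eps
    for j in range(n_neurons):
        dest = np.argsort(u[:, j])          # trials in rank order of the latent
        src = np.argsort(counts[:, j])      # counts ascending
        perm[dest, j] = src
    return perm


def impose_noise_correlations(counts: np.ndarray, r_target: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Reorder same-condition trials per neuron to induce pairwise correlation.

    Marginal distributions (hence means and Fano factors) are preserved
    exactly; mean pairwise spike-count correlation approaches ``r_target``.
    """
    perm = correlation_permutation(counts, r_target, rng)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = counts[perm[:, j], j]
    return out


# ---------------------------------------------------------------------------
# LFP forward model
# ---------------------------------------------------------------------------

def synthesize_lfp(cfg: SessionConfig,
                   sink_depth_range: tuple[float, float],
                   onsets: Sequence[float],
                   amplitude: float = 50.0,
                   noise_sd: float | None = None,
                   rng: np.random.Generator | None = None) -> LfpBlock:
    """Stimulus-locked dipole LFP: a sink over ``sink_depth_range`` with a
    balanced return source of equal width directly below.

    The potential is the double integral of the prescribed current-source
    density, so the CSD estimator recovers a sink whose lower boundary (the
    sink-to-source reversal) sits at ``sink_depth_range[1]``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if noise_sd is None:
        noise_sd = cfg.lfp_noise_sd
    z0, z1 = sink_depth_range
    d_lo, d_hi = cfg.depth_range
    if not (d_lo <= z0 < z1 <= d_hi):
        raise ValueError("sink range outside depth range")
    depths = np.arange(d_lo, d_hi, cfg.lfp_channel_pitch)
    width = z1 - z0
    csd = np.zeros_like(depths)
    csd[(depths >= z0) & (depths < z1)] = -1.0                  # sink
    csd[(depths >= z1) & (depths < min(z1 + width, d_hi))] = 1.0  # source
    # potential: phi'' = -csd  (double cumulative integral, detrended)
    h = cfg.lfp_channel_pitch
    phi = np.cumsum(np.cumsum(-csd)) * h * h
    trend = phi[0] + (phi[-1] - phi[0]) * np.linspace(0, 1, len(phi))
    phi = (phi - trend) / max(np.abs(phi - trend).max(), 1e-30)

    onsets = np.asarray(onsets, dtype=float)
    dur = (onsets.max() if len(onsets) else 0.0) + cfg.stim_duration + cfg.isi
    n_samp = int(np.ceil(dur * cfg.lfp_fs))
    drive = np.zeros(n_samp)
    k_t = np.arange(0.0, 0.15, 1.0 / cfg.lfp_fs)
    kernel = np.exp(-0.5 * ((k_t - 0.06) / 0.015) ** 2)   # evoked transient
    for on in onsets:
        i0 = int(round(on * cfg.lfp_fs))
        seg = kernel[: max(0, min(len(kernel), n_samp - i0))]
        drive[i0:i0 + len(seg)] += seg
    data = (amplitude * phi[:, None] * drive[None, :]).astype(np.float32)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)
    return LfpBlock(data=data, channel_depths=depths, fs=cfg.lfp_fs)


# ---------------------------------------------------------------------------
# full session generator
# ---------------------------------------------------------------------------

def _draw_neuron_specs(cfg: SessionConfig, rng: np.random.Generator) -> tuple[list[NeuronSpec], list[str]]:
    bounds = np.concatenate([[cfg.depth_range[0]], cfg.true_boundaries])
    if cfg.balanced_depths:
        per = np.full(4, cfg.n_neurons // 4)
        per[: cfg.n_neurons % 4] += 1
        depths = np.concatenate([rng.uniform(bounds[c], bounds[c + 1], per[c])
                                 for c in range(4)])
    else:
        depths = rng.uniform(cfg.depth_range[0], cfg.true_boundaries[-1],
                             cfg.n_neurons)
    depths = np.sort(depths)
    comp_idx = np.clip(np.searchsorted(cfg.true_boundaries, depths,
                                       side="right"), 0, 3)
    base_ori = (cfg.pref_orientation if cfg.pref_orientation is not None
                else rng.uniform(0.0, 180.0))
    span = cfg.true_boundaries[-1] - cfg.depth_range[0]
    specs, comps = [], []
    for depth, ci in zip(depths, comp_idx):
        comp = COMPARTMENTS[ci]
        if cfg.columnar:
            ori = base_ori + rng.normal(0.0, cfg.columnar_jitter_sd)
        else:
            ori = base_ori + cfg.noncolumnar_drift * (depth - cfg.depth_range[0]) / span
        direction = (ori + 180.0 * rng.integers(0, 2)) % 360.0
        jit = cfg.param_jitter
        if cfg.uniform_selectivity:
            simple_p, bias_lo, bias_hi = 0.45, 0.1, 0.5
        else:
            simple_p = 0.6 if comp == "4C" else 0.3
            bias_lo, bias_hi = (0.05, 0.3) if comp == "4C" else (0.1, 0.5)
        if cfg.direction_bias_range is not None:
            bias_lo, bias_hi = cfg.direction_bias_range
        bias_mid = 0.5 * (bias_lo + bias_hi)
        bias = bias_mid + jit * (rng.uniform(bias_lo, bias_hi) - bias_mid)
        is_simple = rng.random() < simple_p
        m_target = (rng.uniform(1.0, 1.5) if is_simple
                    else rng.uniform(0.0, 0.3))
        specs.append(NeuronSpec(
            depth=float(depth),
            preferred_direction=float(direction),
            tuning_amplitude=float(23.5 * rng.lognormal(0.0, 0.3 * jit)),
            baseline=float(4.5 * rng.lognormal(0.0, 0.25 * jit)),
            tuning_concentration=float(3.0 * rng.lognormal(0.0, 0.25 * jit)),
            direction_bias=float(bias),
            modulation_ratio_target=float(m_target),
            fano_target=float(cfg.fano_by_compartment[ci]
                              * rng.lognormal(0.0, 0.05 * jit)),
            optimal_sf=float(rng.choice(cfg.sf_set)),
            optimal_eye=str(rng.choice(cfg.eye_conditions)),
            compartment=comp,
        ))
        comps.append(comp)
    return specs, comps


def generate_session(cfg: SessionConfig) -> Session:
    """Build a complete session: schedule, spike trains, correlations, LFP."""
    rng = np.random.default_rng(cfg.seed)
    specs, comps = _draw_neuron_specs(cfg, rng)
    trials = build_stimulus_schedule(cfg, rng)
    trial_tuples = [Trial(r.direction, r.sf, r.eye, r.onset)
                    for r in trials.itertuples()]
    n_trials = len(trial_tuples)

    window_counts = np.zeros((len(specs), n_trials, N_FANO_WINDOWS), dtype=int)
    for j, spec in enumerate(specs):
        for t, tr in enumerate(trial_tuples):
            window_counts[j, t] = sample_trial_counts(spec, tr, rng)

    if cfg.noise_corr > 0:
        comp_arr = np.array(comps)
        groups = trials.groupby(["direction", "sf", "eye"]).indices
        for comp in COMPARTMENTS:
            members = np.flatnonzero(comp_arr == comp)
            if len(members) < 2:
                continue
            for idx in groups.values():
                idx = np.asarray(idx)
                totals = window_counts[members][:, idx].sum(axis=2).T
                perm = correlation_permutation(totals, cfg.noise_corr, rng)
                for k, j in enumerate(members):
                    window_counts[j, idx] = window_counts[j, idx[perm[:, k]]]

    spikes: list[list[np.ndarray]] = []
    isi_rate_window = (cfg.latency + cfg.stim_duration, cfg.stim_duration + cfg.isi)
    for j, spec in enumerate(specs):
        per_trial = []
        for t, tr in enumerate(trial_tuples):
            evoked = render_spike_times(window_counts[j, t], spec, tr, rng,
                                        latency=cfg.latency,
                                        duration=cfg.stim_duration)
            # spontaneous activity in the inter-stimulus blank
            isi_len = isi_rate_window[1] - isi_rate_window[0]
            n_spont = rng.poisson(spec.baseline * isi_len)
            spont = tr.onset + rng.uniform(*isi_rate_window, size=n_spont)
            per_trial.append(np.sort(np.concatenate([evoked, spont])))
        spikes.append(per_trial)

    bounds = cfg.true_boundaries
    lfp = synthesize_lfp(cfg, (float(bounds[1]), float(bounds[2])),
                         trials["onset"].values[: cfg.n_lfp_trials],
                         noise_sd=cfg.lfp_noise_sd, rng=rng)
    return Session(config=cfg, neurons=specs, spikes=spikes, trials=trials,
                   lfp=lfp, true_compartments=comps)
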