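"""Single-neuron functional metrics.

Per neuron: visual-responsiveness gate (two-tailed t-test against the
inter-stimulus interval plus a 3 spikes/s floor), optimal eye/SF selection,
maximum evoked rate, modulation ratio F1/F0, direction and orientation
indices, Hanning-smoothed orientation tuning, von Mises fit with R^2 gate,
tuning bandwidth (with the 180 deg sentinel) and windowed Fano factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synth import DRIFT_SPEED, Session
from .csd import LaminarModel, assign_neuron_layer

SQRT_HALF = 1.0 / np.sqrt(2.0)   # Ringach-convention bandwidth criterion


# ---------------------------------------------------------------------------
# responsiveness and condition selection
# ---------------------------------------------------------------------------

def responsiveness_gate(stim_rates, isi_rates, max_rate: float,
                        alpha: float = 0.01, min_rate: float = 3.0) -> bool:
    """True iff stimulus rates differ from ISI rates (two-tailed t-test,
    p < alpha) and the best condition reaches ``min_rate`` spikes/s."""
    stim = np.asarray(stim_rates, dtype=float)
    isi = np.asarray(isi_rates, dtype=float)
    if len(stim) < 2 or len(isi) < 2:
        raise ValueError("need at least 2 trials in each period")
    if max_rate < min_rate:
        return False
    if np.var(stim) == 0 and np.var(isi) == 0:
        return stim.mean() != isi.mean()
    _, p = stats.ttest_ind(stim, isi)
    return bool(p < alpha)


def select_optimal_condition(mean_rates: pd.DataFrame) -> tuple[str, float]:
    """(eye, sf) whose direction curve attains the highest response.

    ``mean_rates`` has columns eye, sf, direction, rate.  Ties resolve to the
    lower spatial frequency, then the first eye in table order.
    """
    if len(mean_rates) == 0:
        raise ValueError("no conditions")
    peak = (mean_rates.groupby(["eye", "sf"], sort=False)["rate"]
            .max().reset_index())
    best = peak["rate"].max()
    tied = peak[peak["rate"] == best].sort_values("sf", kind="stable")
    row = tied.iloc[0]
    return str(row["eye"]), float(row["sf"])


# ---------------------------------------------------------------------------
# selectivity indices
# ---------------------------------------------------------------------------

def direction_index(resp_pref: float, resp_opp: float) -> float:
    """(pref - opposite) / (pref + opposite); NaN when both are zero."""
    if resp_pref < 0 or resp_opp < 0:
        raise ValueError("rates must be nonnegative")
    s = resp_pref + resp_opp
    return np.nan if s == 0 else (resp_pref - resp_opp) / s


def orientation_index(resp_pref: float, resp_orth: float) -> float:
    """(pref - orthogonal) / (pref + orthogonal); NaN when both are zero."""
    return direction_index(resp_pref, resp_orth)


# ---------------------------------------------------------------------------
# modulation ratio
# ---------------------------------------------------------------------------

def modulation_ratio(spike_times, temporal_freq: float,
                     duration: float = 1.0) -> float:
    """F1/F0 at the grating temporal frequency.

    ``spike_times`` is a list of per-trial arrays of times relative to the
    response-window start.  F0 is the mean rate (DC of the cycle-resolved
    response); F1 is twice the magnitude of the Fourier component at
    ``temporal_freq`` per unit time.
    """
    trials = [np.asarray(t) for t in spike_times]
    n_trials = len(trials)
    total = sum(len(t) for t in trials)
    if total == 0 or n_trials == 0:
        return np.nan
    t_all = np.concatenate(trials)
    f0 = total / (n_trials * duration)
    f1 = 2.0 * np.abs(np.exp(-2j * np.pi * temporal_freq * t_all).sum()) \
        / (n_trials * duration)
    return f1 / f0


# ---------------------------------------------------------------------------
# tuning curve smoothing and fit
# ---------------------------------------------------------------------------

def hanning_kernel(hwhh: float = 20.0, spacing: float = 10.0) -> np.ndarray:
    """Unit-sum raised-cosine kernel with half width at half height ``hwhh``.

    Full support is 4*hwhh (endpoints zero); at +-hwhh the kernel equals half
    its centre value.
    """
    half_support = 2.0 * hwhh
    offsets = np.arange(-half_support, half_support + spacing / 2, spacing)
    k = 0.5 * (1.0 + np.cos(np.pi * offsets / half_support))
    return k / k.sum()


def smooth_tuning(curve, hwhh: float = 20.0, spacing: float = 10.0) -> np.ndarray:
    """Circular convolution of a tuning curve with the Hanning kernel."""
    y = np.asarray(curve, dtype=float)
    k = hanning_kernel(hwhh, spacing)
    half = len(k) // 2
    ext = np.concatenate([y[-half:], y, y[:half]])
    return np.convolve(ext, k, mode="valid")


@dataclass
class VonMisesFit:
    """y(x) = a0 + a1 * exp(a2 * (cos(2x - 2*a3) - 1)), x in degrees."""

    a0: float
    a1: float
    a2: float
    a3: float          # preferred angle, reported mod 180
    r_squared: float
    valid: bool = True

    def predict(self, x_deg) -> np.ndarray:
        x = np.deg2rad(np.asarray(x_deg, dtype=float))
        mu = np.deg2rad(self.a3)
        return self.a0 + self.a1 * np.exp(self.a2 * (np.cos(2 * x - 2 * mu) - 1.0))


def _vm(x_deg, a0, a1, a2, a3):
    x = np.deg2rad(x_deg)
    return a0 + a1 * np.exp(a2 * (np.cos(2 * x - 2 * np.deg2rad(a3)) - 1.0))


def fit_von_mises(curve, theta_deg=None) -> VonMisesFit:
    """Nonlinear least squares with a multi-start over the preferred angle.

    A flat curve yields a1 ~ 0 and r_squared = 0 without error; total
    non-convergence flags the fit invalid.
    """
    y = np.asarray(curve, dtype=float)
    x = (np.asarray(theta_deg, dtype=float) if theta_deg is not None
         else np.arange(0.0, 180.0, 180.0 / len(y)))
    if np.any(y < 0):
        raise ValueError("responses must be nonnegative")
    span = y.max() - y.min()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if span == 0:
        return VonMisesFit(float(y.mean()), 0.0, 1.0, float(x[0]), 0.0)
    best = None
    for a3_start in x[np.argsort(y)[::-1][:6]]:
        p0 = [max(y.min(), 1e-6), max(span, 1e-6), 2.0, float(a3_start)]
        try:
            popt, _ = optimize.curve_fit(
                _vm, x, y, p0=p0,
                bounds=([0.0, 0.0, 1e-3, -360.0], [np.inf, np.inf, 60.0, 720.0]),
                maxfev=5000)
        except RuntimeError:
            continue
        ss_res = float(np.sum((y - _vm(x, *popt)) ** 2))
        if best is None or ss_res < best[0]:
            best = (ss_res, popt)
    if best is None:
        return VonMisesFit(np.nan, np.nan, np.nan, np.nan, np.nan, valid=False)
    ss_res, (a0, a1, a2, a3) = best
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return VonMisesFit(float(a0), float(a1), float(a2), float(a3 % 180.0),
                       float(r2))


def bandwidth(fit: VonMisesFit, criterion: float = SQRT_HALF) -> float:
    """Half the angular separation between the flanks where the fitted curve
    first drops to ``criterion`` x peak; 180 if it never does.

    Closed form at the von Mises parameterisation: the flank offset solves
    exp(a2 (cos 2d - 1)) = q with q = (criterion*(a0+a1) - a0)/a1, giving
    d = 0.5 * arccos(1 + ln(q)/a2).
    """
    if not fit.valid:
        return np.nan
    peak = fit.a0 + fit.a1
    if fit.a1 <= 0 or peak <= 0:
        return 180.0
    q = (criterion * peak - fit.a0) / fit.a1
    q_min = np.exp(-2.0 * fit.a2)      # deepest relative drop of the curve
    if q <= q_min:
        return 180.0
    if q >= 1.0:
        return 0.0
    return float(np.rad2deg(0.5 * np.arccos(1.0 + np.log(q) / fit.a2)))


# ---------------------------------------------------------------------------
# Fano factor
# ---------------------------------------------------------------------------

def fano_factor(window_counts) -> float:
    """Mean of var/mean across 100 ms windows and stimulus conditions.

    ``window_counts`` is a sequence over conditions of (trials x windows)
    count arrays; windows with zero mean are excluded.  Returns NaN when
    every window has zero mean.
    """
    ratios = []
    for cond in window_counts:
        c = np.asarray(cond, dtype=float)
        if c.shape[0] < 2:
            raise ValueError("need at least 2 trials per condition")
        means = c.mean(axis=0)
        variances = c.var(axis=0, ddof=1)
        keep = means > 0
        ratios.extend(variances[keep] / means[keep])
    return float(np.mean(ratios)) if ratios else np.nan


# ---------------------------------------------------------------------------
# whole-session metrics table
# ---------------------------------------------------------------------------

def _counts_in_window(spike_times: np.ndarray, start: float, stop: float) -> int:
    return int(np.searchsorted(spike_times, stop) - np.searchsorted(spike_times, start))


def _window_count_matrix(session: Session, neuron: int, trial_idx, latency: float):
    """Trials x (10 windows) counts over the offset stimulus period."""
    dur = session.config.stim_duration
    edges = np.linspace(0.0, dur, 11)
    rows = []
    for t in trial_idx:
        on = session.trials["onset"].iat[t] + latency
        st = session.spikes[neuron][t]
        rows.append([_counts_in_window(st, on + a, on + b)
                     for a, b in zip(edges[:-1], edges[1:])])
    return np.asarray(rows)


def compute_metrics(session: Session, model: LaminarModel | None = None,
                    criterion: float = SQRT_HALF,
                    latency: float | None = None) -> pd.DataFrame:
    """Per-neuron metrics table (one row per unit).

    Columns: depth, compartment, responsive, max_rate, modulation_ratio, di,
    oi, pref_direction, pref_orientation, bandwidth, r_squared, fano,
    optimal_sf, optimal_eye.
    """
    cfg = session.config
    lat = cfg.latency if latency is None else latency
    dur = cfg.stim_duration
    onsets = session.trials["onset"].values
    isi_len = cfg.isi - lat
    rows = []
    for j in range(session.n_neurons):
        stim_rates = np.array([
            _counts_in_window(session.spikes[j][t], onsets[t] + lat,
                              onsets[t] + lat + dur) / dur
            for t in range(len(onsets))])
        isi_rates = np.array([
            _counts_in_window(session.spikes[j][t], onsets[t] + lat + dur,
                              onsets[t] + dur + cfg.isi) / isi_len
            for t in range(len(onsets))])
        table = session.trials.assign(rate=stim_rates)
        means = (table.groupby(["eye", "sf", "direction"], sort=True)["rate"]
                 .mean().reset_index())
        eye, sf = select_optimal_condition(means)
        cond = means[(means["eye"] == eye) & (means["sf"] == sf)]
        curve36 = cond.sort_values("direction")["rate"].to_numpy()
        dirs36 = cond.sort_values("direction")["direction"].to_numpy()

        sm36 = smooth_tuning(curve36)
        pref_i = int(np.argmax(sm36))          # ties -> smaller angle
        pref_dir = float(dirs36[pref_i])
        opp_i = (pref_i + len(curve36) // 2) % len(curve36)
        max_rate = float(curve36[pref_i])
        di = direction_index(curve36[pref_i], curve36[opp_i])

        n_ori = len(curve36) // 2
        curve18 = 0.5 * (curve36[:n_ori] + curve36[n_ori:])
        pref_ori_i = pref_i % n_ori
        orth_i = (pref_ori_i + n_ori // 2) % n_ori
        oi = orientation_index(curve18[pref_ori_i], curve18[orth_i])

        sm18 = smooth_tuning(curve18)
        fit = fit_von_mises(sm18)
        bw = bandwidth(fit, criterion)

        pref_trials = np.flatnonzero(
            (session.trials["eye"] == eye) & (session.trials["sf"] == sf)
            & (session.trials["direction"] == pref_dir))
        rel = [session.spikes[j][t] - (onsets[t] + lat) for t in pref_trials]
        rel = [r[(r >= 0) & (r < dur)] for r in rel]
        mr = modulation_ratio(rel, DRIFT_SPEED * sf, duration=dur)

        cond_trials = session.trials[(session.trials["eye"] == eye)
                                     & (session.trials["sf"] == sf)]
        groups = [np.flatnonzero((session.trials["direction"] == d)
                                 & (session.trials["eye"] == eye)
                                 & (session.trials["sf"] == sf))
                  for d in np.unique(cond_trials["direction"])]
        ff = fano_factor([_window_count_matrix(session, j, g, lat)
                          for g in groups if len(g) >= 2])

        responsive = responsiveness_gate(stim_rates, isi_rates, max_rate)
        depth = session.neurons[j].depth
        comp = assign_neuron_layer(depth, model) if model is not None else ""
        rows.append(dict(neuron=j, depth=depth, compartment=comp,
                         responsive=responsive, max_rate=max_rate,
                         modulation_ratio=mr, di=di, oi=oi,
                         pref_direction=pref_dir,
                         pref_orientation=pref_dir % 180.0,
                         bandwidth=bw, r_squared=fit.r_squared, fano=ff,
                         optimal_sf=sf, optimal_eye=eye))
    return pd.DataFrame(rows)
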