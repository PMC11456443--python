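"""Depth-resolved pairwise orientation decoding.

Subpopulations of k depth-adjacent neurons are scored on every pairwise
discrimination of the 18 orientations (153 binary problems) with five
classifier families — logistic regression (L2), LDA (lsqr + automatic
shrinkage), Gaussian naive Bayes, RBF-kernel SVM and random forest — under
stratified outer cross-validation with an inner-fold search of the
regularisation constant for LogR and SVM.  Controls: independent trial
shuffling of the training folds (destroys noise correlations) and
single-neuron decoding (k = 1).  Derivatives: neuron-dropping curves and the
interpolated 60%-threshold orientation sensitivity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .csd import LaminarModel, assign_neuron_layer
from .synth import Session

FAMILIES = ("LogR", "LDA", "NB", "SVM", "RF")

#: 11 log-spaced regularisation constants searched for LogR and SVM
DEFAULT_C_GRID = tuple(np.logspace(-6, 4, 11))


@dataclass
class DecodeConfig:
    families: tuple[str, ...] = FAMILIES
    outer_folds: int = 10
    inner_folds: int = 6
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_trees: int = 100
    window: tuple[float, float] = (0.05, 1.05)   # s after stimulus onset
    k: int = 10
    stride: int = 1
    seed: int = 0


@dataclass
class PopulationResponse:
    """Normalized trial x neuron spike counts with orientation labels."""

    X: np.ndarray                # trials x neurons, per-neuron max = 1
    y: np.ndarray                # orientation labels, deg in {0,...,170}
    depths: np.ndarray           # um, one per retained neuron
    neuron_indices: np.ndarray   # indices into the source session
    trial_indices: np.ndarray

    def subset(self, cols) -> "PopulationResponse":
        cols = np.asarray(cols)
        return PopulationResponse(self.X[:, cols], self.y, self.depths[cols],
                                  self.neuron_indices[cols], self.trial_indices)


@dataclass
class Subpopulation:
    indices: np.ndarray     # neuron indices, depth order
    center_depth: float
    compartment: str


def build_response_matrix(session: Session,
                          window: tuple[float, float] = (0.05, 1.05),
                          sf: float | None = None,
                          eye: str | None = None,
                          neurons=None) -> PopulationResponse:
    """Spike counts in the stimulation window, per-neuron max-normalized.

    Trials are restricted to one spatial frequency / eye (the subpopulation's
    optimal condition); orientation labels pool opposite drift directions
    (direction mod 180).  Neurons whose maximum count is zero are excluded.
    """
    trials = session.trials
    if sf is None:
        sfs = trials["sf"].unique()
        if len(sfs) > 1:
            raise ValueError("session has several SFs; pass the optimal one")
        sf = float(sfs[0])
    if eye is None:
        eyes = trials["eye"].unique()
        if len(eyes) > 1:
            raise ValueError("session has several eyes; pass the optimal one")
        eye = str(eyes[0])
    sel = np.flatnonzero((trials["sf"] == sf) & (trials["eye"] == eye))
    if len(sel) == 0:
        raise ValueError("no trials at the requested condition")
    onsets = trials["onset"].values[sel]
    if window[1] <= window[0]:
        raise ValueError("empty count window")
    if window[1] > session.config.stim_duration + session.config.isi:
        raise ValueError("count window extends outside the trial")
    idx = np.arange(session.n_neurons) if neurons is None else np.asarray(neurons)
    counts = np.empty((len(sel), len(idx)))
    for c, j in enumerate(idx):
        for r, t in enumerate(sel):
            st = session.spikes[j][t]
            a, b = onsets[r] + window[0], onsets[r] + window[1]
            counts[r, c] = np.searchsorted(st, b) - np.searchsorted(st, a)
    maxima = counts.max(axis=0)
    keep = maxima > 0
    if not keep.all():
        warnings.warn("%d neuron(s) with zero max count excluded"
                      % int((~keep).sum()))
    X = counts[:, keep] / maxima[keep]
    y = (trials["direction"].values[sel] % 180.0).astype(int)
    depths = session.depths[idx][keep]
    return PopulationResponse(X=X, y=y, depths=depths,
                              neuron_indices=idx[keep], trial_indices=sel)


def build_subpopulations(depths, model: LaminarModel, k: int = 10,
                         stride: int = 1) -> list[Subpopulation]:
    """Sliding windows of ``k`` depth-adjacent neurons.

    The window's center depth (mean of the two middle neurons for even k)
    determines its compartment.  Fewer than ``k`` neurons yields an empty
    list with a warning.
    """
    depths = np.asarray(depths, dtype=float)
    order = np.argsort(depths, kind="stable")
    n = len(depths)
    if n < k:
        warnings.warn("fewer than k=%d neurons; no subpopulations" % k)
        return []
    subs = []
    for start in range(0, n - k + 1, stride):
        idx = order[start:start + k]
        d = depths[idx]
        if k % 2 == 0:
            center = 0.5 * (d[k // 2 - 1] + d[k // 2])
        else:
            center = d[k // 2]
        subs.append(Subpopulation(indices=idx, center_depth=float(center),
                                  compartment=str(assign_neuron_layer(center, model))))
    return subs


# ---------------------------------------------------------------------------
# classifier backends
# ---------------------------------------------------------------------------


class _FastLDA:
    """Closed-form binary LDA, lsqr solver with Ledoit-Wolf shrinkage.

    Mirrors ``LinearDiscriminantAnalysis(solver='lsqr', shrinkage='auto')``:
    the within-class covariance is the prior-weighted sum of per-class
    Ledoit-Wolf estimates, w = S^-1 (mu1 - mu0) and the intercept carries the
    log prior ratio.  Predictions agree with the sklearn estimator; this path
    only strips per-call validation overhead for the inner decoding loops.
    """

    @staticmethod
    def _lw_cov(Xg):
        # Ledoit-Wolf shrinkage on standardized features, rescaled back
        scale = Xg.std(axis=0)
        scale[scale == 0] = 1.0
        X = (Xg - Xg.mean(axis=0)) / scale
        n, p = X.shape
        emp = X.T @ X / n
        mu = np.trace(emp) / p
        delta_ = np.sum(emp ** 2)
        beta_ = np.sum((X ** 2).T @ (X ** 2))
        beta = (beta_ / n - delta_) / (n * p)
        delta = (delta_ - 2.0 * mu * np.trace(emp) + p * mu ** 2) / p
        shrink = 0.0 if (p == 1 or beta <= 0 or delta <= 0) \
            else min(beta, delta) / delta
        s = (1.0 - shrink) * emp
        s[np.diag_indices(p)] += shrink * mu
        return scale[:, None] * s * scale[None, :]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        k0, k1 = self.classes_
        X0, X1 = X[y == k0], X[y == k1]
        n = len(X)
        p0, p1 = len(X0) / n, len(X1) / n
        S = p0 * self._lw_cov(X0) + p1 * self._lw_cov(X1)
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        self.coef_ = np.linalg.lstsq(S, mu1 - mu0, rcond=None)[0]
        self.intercept_ = (-0.5 * (mu1 + mu0) @ self.coef_
                           + np.log(p1 / p0))
        return self

    def predict(self, X):
        score = np.asarray(X, dtype=float) @ self.coef_ + self.intercept_
        return np.where(score > 0, self.classes_[1], self.classes_[0])


class _FastNB:
    """Closed-form Gaussian naive Bayes matching ``GaussianNB`` defaults
    (variance floor 1e-9 relative to the largest feature variance)."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        eps = 1e-9 * np.var(X, axis=0).max()
        self.theta_ = np.stack([X[y == k].mean(axis=0) for k in self.classes_])
        self.var_ = np.stack([X[y == k].var(axis=0) for k in self.classes_]) + eps
        self.priors_ = np.array([(y == k).mean() for k in self.classes_])
        return self

    def predict(self, X):
        idx = gaussian_nb_predict(X, self.theta_, self.var_, self.priors_)
        return self.classes_[idx]


def make_classifier(family: str, C: float = 1.0, n_trees: int = 100,
                    random_state: int | None = None, fast: bool = True):
    if family == "LogR":
        # L2 penalty (the default) with the liblinear solver: fast on the
        # small dense binary problems decoded here
        return LogisticRegression(C=C, solver="liblinear",
                                  random_state=random_state)
    if family == "LDA":
        return (_FastLDA() if fast
                else LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"))
    if family == "NB":
        return _FastNB() if fast else GaussianNB()
    if family == "SVM":
        return SVC(C=C, kernel="rbf", random_state=random_state)
    if family == "RF":
        return RandomForestClassifier(n_estimators=n_trees,
                                      max_features="sqrt", bootstrap=True,
                                      random_state=random_state)
    raise ValueError("unknown classifier family %r" % family)


def gaussian_nb_predict(X, means, variances, priors) -> np.ndarray:
    """Closed-form Gaussian naive Bayes posterior argmax.

    ``means``/``variances`` are (classes x features); ties resolve to the
    lower class index (argmax keeps the first maximum).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    means = np.asarray(means, dtype=float)
    var = np.asarray(variances, dtype=float)
    if np.any(var <= 0):
        var = np.maximum(var, 1e-9 * max(var.max(), 1.0))
    log_post = np.log(np.asarray(priors, dtype=float))[None, :] + np.sum(
        -0.5 * np.log(2 * np.pi * var[None, :, :])
        - (X[:, None, :] - means[None, :, :]) ** 2 / (2 * var[None, :, :]),
        axis=2)
    return np.argmax(log_post, axis=1)


def shuffle_training_trials(X: np.ndarray, y: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """Independently permute each neuron's trials within each label.

    Per-class marginals per neuron are unchanged; cross-neuron correlations
    are destroyed.  Applied to training folds only.
    """
    out = X.copy()
    for label in np.unique(y):
        rows = np.flatnonzero(y == label)
        for j in range(X.shape[1]):
            out[rows, j] = X[rng.permutation(rows), j]
    return out


def _needs_c_search(family: str) -> bool:
    return family in ("LogR", "SVM")


def _select_C(X, y, family: str, cfg: DecodeConfig, seed: int) -> float:
    """Best C on the log grid by inner stratified CV; ties -> smaller C."""
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(cfg.inner_folds, counts.min()))
    if n_splits < 2:
        return 1.0
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best_c, best_acc = None, -1.0
    for C in cfg.c_grid:
        correct = total = 0
        for tr, te in folds:
            clf = make_classifier(family, C=C, n_trees=cfg.n_trees,
                                  random_state=seed)
            clf.fit(X[tr], y[tr])
            correct += int((clf.predict(X[te]) == y[te]).sum())
            total += len(te)
        acc = correct / total
        if acc > best_acc:
            best_acc, best_c = acc, C
    return best_c


def decode_pair(X, y, family: str, cfg: DecodeConfig,
                seed: int, shuffle: bool = False) -> float:
    """Cross-validated accuracy of one binary orientation discrimination."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("degenerate single-class input")
    n_splits = int(min(cfg.outer_folds, counts.min()))
    if n_splits < cfg.outer_folds:
        warnings.warn("reducing folds to %d (smallest class)" % n_splits)
    if n_splits < 2:
        raise ValueError("not enough trials per class for cross-validation")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    correct = total = 0
    for tr, te in skf.split(X, y):
        Xtr, ytr = X[tr], y[tr]
        if shuffle:
            Xtr = shuffle_training_trials(Xtr, ytr, rng)
        C = (_select_C(Xtr, ytr, family, cfg, seed)
             if _needs_c_search(family) else 1.0)
        clf = make_classifier(family, C=C, n_trees=cfg.n_trees,
                              random_state=seed)
        clf.fit(Xtr, ytr)
        correct += int((clf.predict(X[te]) == y[te]).sum())
        total += len(te)
    return correct / total


def _pair_seed(base: int, a: int, b: int, tag: int = 0) -> int:
    ss = np.random.SeedSequence([int(base), int(a), int(b), int(tag)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def pairwise_decode(pop: PopulationResponse, family: str,
                    cfg: DecodeConfig | None = None,
                    shuffle: bool = False, seed_tag: int = 0,
                    max_dtheta: float | None = None) -> pd.DataFrame:
    """Accuracy for every orientation pair (153 pairs for 18 orientations).

    Fold assignment is seeded per (subpopulation tag, pair) so results are
    reproducible independently of evaluation order.  ``max_dtheta`` restricts
    the enumeration to pairs within a given angular distance (degrees).
    """
    cfg = cfg or DecodeConfig()
    oris = np.unique(pop.y)
    rows = []
    for a, b in itertools.combinations(oris, 2):
        if max_dtheta is not None and min(b - a, 180 - (b - a)) > max_dtheta:
            continue
        mask = (pop.y == a) | (pop.y == b)
        acc = decode_pair(pop.X[mask], pop.y[mask], family, cfg,
                          seed=_pair_seed(cfg.seed, a, b, seed_tag),
                          shuffle=shuffle)
        rows.append(dict(ori_a=int(a), ori_b=int(b), accuracy=acc))
    return pd.DataFrame(rows)


def decode_subpopulations(pop: PopulationResponse,
                          subpops: list[Subpopulation],
                          cfg: DecodeConfig | None = None,
                          families=None, shuffle: bool = False,
                          max_dtheta: float | None = None) -> pd.DataFrame:
    """Tidy table: subpopulation x family x orientation pair accuracy."""
    cfg = cfg or DecodeConfig()
    families = families or cfg.families
    # map session neuron index -> column of pop.X
    col_of = {j: c for c, j in enumerate(pop.neuron_indices)}
    frames = []
    for s_id, sub in enumerate(subpops):
        cols = [col_of[j] for j in sub.indices if j in col_of]
        view = pop.subset(cols)
        for family in families:
            df = pairwise_decode(view, family, cfg, shuffle=shuffle,
                                 seed_tag=s_id, max_dtheta=max_dtheta)
            df.insert(0, "subpopulation", s_id)
            df.insert(1, "center_depth", sub.center_depth)
            df.insert(2, "compartment", sub.compartment)
            df.insert(3, "algorithm", family)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def single_neuron_decode(pop: PopulationResponse, model: LaminarModel,
                         cfg: DecodeConfig | None = None,
                         families=("LDA",)) -> pd.DataFrame:
    """Pairwise decoding from individual neurons (k = 1 subpopulations)."""
    subs = [Subpopulation(indices=np.array([c]), center_depth=float(d),
                          compartment=str(assign_neuron_layer(d, model)))
            for c, d in enumerate(pop.depths)]
    # neuron_indices of the view must match the constructed subpops
    view = PopulationResponse(pop.X, pop.y, pop.depths,
                              np.arange(pop.X.shape[1]), pop.trial_indices)
    return decode_subpopulations(view, subs, cfg, families=families)


# ---------------------------------------------------------------------------
# neuron-dropping curves
# ---------------------------------------------------------------------------

def _distinct_combinations(n: int, size: int, reps: int,
                           rng: np.random.Generator):
    from math import comb
    total = comb(n, size)
    if total <= reps:
        return [np.array(c) for c in itertools.combinations(range(n), size)]
    seen, out = set(), []
    while len(out) < reps:
        c = tuple(sorted(rng.choice(n, size=size, replace=False).tolist()))
        if c not in seen:
            seen.add(c)
            out.append(np.array(c))
    return out


def neuron_dropping_curve(pop: PopulationResponse, n_grid,
                          cfg: DecodeConfig | None = None,
                          reps: int = 200, family: str = "LDA",
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Mean pairwise accuracy vs population size for one compartment's pool.

    For each n, up to ``reps`` distinct neuron combinations (all of them when
    fewer exist) are decoded over every orientation pair with the LDA family.
    """
    cfg = cfg or DecodeConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    n_avail = pop.X.shape[1]
    rows = []
    for n in n_grid:
        if n > n_avail:
            continue
        combos = _distinct_combinations(n_avail, int(n), reps, rng)
        for c_id, cols in enumerate(combos):
            df = pairwise_decode(pop.subset(cols), family, cfg,
                                 seed_tag=10_000 + c_id)
            rows.append(dict(n=int(n), combination=c_id,
                             mean_accuracy=float(df["accuracy"].mean()),
                             n_combinations=len(combos)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# decoding sensitivity
# ---------------------------------------------------------------------------

def sensitivity(pair_accuracy: pd.DataFrame, threshold: float = 0.60,
                clamp_at_smallest: bool = True,
                floor_at_largest: bool = True) -> pd.DataFrame:
    """Interpolated minimum discriminable orientation difference per reference.

    For each reference orientation, accuracy is expressed against the angular
    difference (10..90 deg, both neighbours averaged) and the first linear
    crossing of ``threshold`` gives dtheta_min; sensitivity = 1/dtheta_min.
    Performance already above threshold at 10 deg clamps dtheta_min to 10;
    never reaching it floors dtheta_min at 90.
    """
    need = {"ori_a", "ori_b", "accuracy"}
    if not need.issubset(pair_accuracy.columns):
        raise ValueError("pair table must have ori_a, ori_b, accuracy")
    oris = np.unique(pair_accuracy[["ori_a", "ori_b"]].values)
    acc = {}
    for row in pair_accuracy.itertuples():
        acc.setdefault((row.ori_a, row.ori_b), []).append(row.accuracy)
    rows = []
    for ref in oris:
        dthetas = np.arange(10, 91, 10)
        mean_acc = np.full(len(dthetas), np.nan)
        for i, dt in enumerate(dthetas):
            vals = []
            for other in ((ref + dt) % 180, (ref - dt) % 180):
                key = (min(ref, other), max(ref, other))
                if key in acc and other != ref:
                    vals.extend(acc[key])
            if vals:
                mean_acc[i] = np.mean(vals)
        if np.any(np.isnan(mean_acc)):
            raise ValueError("missing dtheta grid for reference %s" % ref)
        if mean_acc[0] >= threshold and clamp_at_smallest:
            dmin = 10.0
        else:
            dmin = None
            for i in range(len(dthetas) - 1):
                lo, hi = mean_acc[i], mean_acc[i + 1]
                if lo < threshold <= hi:
                    dmin = dthetas[i] + (threshold - lo) / (hi - lo) * 10.0
                    break
            if dmin is None:
                dmin = 90.0 if floor_at_largest else np.nan
        rows.append(dict(reference=int(ref), dtheta_min=float(dmin),
                         sensitivity=1.0 / dmin))
    return pd.DataFrame(rows)
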