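"""Pipeline orchestration: simulate -> layers -> tuning -> decode -> report.

Each stage is idempotent: it writes its artifact into the output directory
and is skipped when the artifact already exists (unless forced).  A manifest
records the configuration, its hash, the seeds and the stage list, which is
sufficient to reproduce every output table exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .csd import LaminarModel, estimate_laminar_model
from .decode import (DecodeConfig, build_response_matrix,
                     build_subpopulations, decode_subpopulations,
                     neuron_dropping_curve, sensitivity)
from .io import read_session_hdf5, read_session_npz, write_session_hdf5
from .stats import ff_performance_correlation, omnibus_compare
from .synth import DEFAULT_THICKNESSES, SessionConfig, generate_session
from .tuning import compute_metrics

log = logging.getLogger("lamdec")

CSV_FMT = "%.10g"   # fixed float format -> byte-identical reruns


@dataclass
class RunConfig:
    """All pipeline knobs; defaults follow the study protocol."""

    session: SessionConfig = field(default_factory=SessionConfig)
    session_path: str | None = None        # load instead of simulating
    latency: float = 0.05                  # s, response latency offset
    window: tuple[float, float] = (0.05, 1.05)
    k: int = 10                            # subpopulation size
    stride: int = 1
    families: tuple[str, ...] = ("LogR", "LDA", "NB", "SVM", "RF")
    outer_folds: int = 10
    inner_folds: int = 6
    c_grid: tuple[float, ...] = tuple(np.logspace(-6, 4, 11))
    n_trees: int = 100
    ndc_reps: int = 200
    ndc_grid: tuple[int, ...] = (1, 2, 4, 8)
    sensitivity_threshold: float = 0.60
    thickness_offsets: tuple[float, ...] = DEFAULT_THICKNESSES
    seed: int = 0
    out_dir: str = "lamdec_out"

    def decode_config(self) -> DecodeConfig:
        return DecodeConfig(families=self.families,
                            outer_folds=self.outer_folds,
                            inner_folds=self.inner_folds,
                            c_grid=self.c_grid, n_trees=self.n_trees,
                            window=self.window, k=self.k, stride=self.stride,
                            seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "session" in d and isinstance(d["session"], dict):
            s = dict(d["session"])
            for key in ("depth_range", "compartment_thicknesses", "sf_set",
                        "eye_conditions", "fano_by_compartment"):
                if key in s:
                    s[key] = tuple(s[key])
            d["session"] = SessionConfig(**s)
        for key in ("families", "c_grid", "ndc_grid", "thickness_offsets",
                    "window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def validate_session(path) -> list[str]:
    """Schema/domain checks on a stored session; empty list means valid."""
    path = Path(path)
    problems: list[str] = []
    try:
        session = (read_session_npz(path) if path.suffix == ".npz"
                   else read_session_hdf5(path))
    except Exception as exc:   # corrupted container
        return ["container: failed to load (%s)" % exc]
    depths = session.depths
    if not np.all(np.isfinite(depths)):
        problems.append("neurons/depth: non-finite value")
    d = session.trials["direction"].values
    if np.any((d < 0) | (d > 350) | (d % 10 != 0)):
        problems.append("trials/direction: values must be multiples of 10 in [0, 350]")
    onsets = session.trials["onset"].values
    if np.any(np.diff(onsets) <= 0):
        problems.append("trials/onset: onsets must strictly increase")
    n_trials = len(session.trials)
    for j, per_trial in enumerate(session.spikes):
        if len(per_trial) != n_trials:
            problems.append("neurons[%d]: spike lists misaligned with trials" % j)
            break
    if session.lfp is not None and np.any(np.diff(session.lfp.channel_depths) <= 0):
        problems.append("lfp/channel_depths: must strictly increase")
    return problems


def _exists(path: Path, force: bool) -> bool:
    return path.exists() and not force


def run_pipeline(cfg: RunConfig, force: bool = False,
                 stages=("simulate", "layers", "tuning", "decode",
                         "ndc", "sensitivity", "report")) -> dict:
    """Execute the pipeline; returns a manifest of produced artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    session_path = out / "session.h5"
    if "simulate" in stages:
        if cfg.session_path:
            session_path = Path(cfg.session_path)
            if not session_path.exists():
                raise FileNotFoundError(
                    "stage 'simulate': session file %s missing" % session_path)
        elif not _exists(session_path, force):
            log.info("simulate: generating session")
            write_session_hdf5(generate_session(cfg.session), session_path)
        artifacts["session"] = str(session_path)
    problems = validate_session(session_path)
    if problems:
        raise ValueError("invalid session container: " + "; ".join(problems))
    session = (read_session_npz(session_path) if session_path.suffix == ".npz"
               else read_session_hdf5(session_path))

    model_path = out / "laminar_model.json"
    if "layers" in stages:
        if not _exists(model_path, force):
            log.info("layers: CSD boundary estimation")
            if session.lfp is None:
                raise ValueError("stage 'layers': session has no LFP block")
            onsets = session.trials["onset"].values[: session.config.n_lfp_trials]
            model = estimate_laminar_model(session.lfp, onsets,
                                           cfg.thickness_offsets)
            model_path.write_text(json.dumps(model.to_dict(), indent=1))
        artifacts["laminar_model"] = str(model_path)
    downstream = {"tuning", "decode", "ndc", "sensitivity", "report"}
    model = None
    if downstream & set(stages):
        if not model_path.exists():
            raise FileNotFoundError("stage 'tuning': laminar model missing; "
                                    "run the 'layers' stage first")
        md = json.loads(model_path.read_text())
        model = LaminarModel(md["top_23"], md["b_23_4ab"], md["b_4ab_4c"],
                             md["b_4c_56"], md["b_56_wm"],
                             tuple(md["thickness_offsets"]))

    metrics_path = out / "metrics.csv"
    if "tuning" in stages:
        if not _exists(metrics_path, force):
            log.info("tuning: per-neuron metrics")
            metrics = compute_metrics(session, model, latency=cfg.latency)
            metrics.to_csv(metrics_path, index=False, float_format=CSV_FMT)
        artifacts["metrics"] = str(metrics_path)
    metrics = pd.read_csv(metrics_path) if metrics_path.exists() else None

    dconf = cfg.decode_config()
    decode_path = out / "decode.csv"
    responsive = (np.flatnonzero(metrics["responsive"].values)
                  if metrics is not None else np.arange(session.n_neurons))
    if "decode" in stages:
        if not _exists(decode_path, force):
            log.info("decode: %d families", len(cfg.families))
            pop = build_response_matrix(session, cfg.window, neurons=responsive)
            subs = build_subpopulations(pop.depths, model, k=cfg.k,
                                        stride=cfg.stride)
            res = decode_subpopulations(pop, subs, dconf)
            res.to_csv(decode_path, index=False, float_format=CSV_FMT)
        artifacts["decode"] = str(decode_path)

    ndc_path = out / "ndc.csv"
    if "ndc" in stages:
        if not _exists(ndc_path, force):
            log.info("ndc: neuron-dropping curves (LDA)")
            pop = build_response_matrix(session, cfg.window, neurons=responsive)
            comps = np.array([str(c) for c in
                              np.atleast_1d(model_assign(pop.depths, model))])
            frames = []
            for comp in ("2/3", "4A/B", "4C", "5/6"):
                cols = np.flatnonzero(comps == comp)
                if len(cols) == 0:
                    continue
                df = neuron_dropping_curve(pop.subset(cols), cfg.ndc_grid,
                                           dconf, reps=cfg.ndc_reps,
                                           rng=np.random.default_rng(cfg.seed))
                df.insert(0, "compartment", comp)
                frames.append(df)
            pd.concat(frames, ignore_index=True).to_csv(
                ndc_path, index=False, float_format=CSV_FMT)
        artifacts["ndc"] = str(ndc_path)

    sens_path = out / "sensitivity.csv"
    if "sensitivity" in stages:
        if not _exists(sens_path, force):
            if not decode_path.exists():
                raise FileNotFoundError("stage 'sensitivity': decode table "
                                        "missing; run the 'decode' stage first")
            res = pd.read_csv(decode_path)
            lda = res[res["algorithm"] == "LDA"]
            frames = []
            for s_id, grp in lda.groupby("subpopulation"):
                sens = sensitivity(grp, threshold=cfg.sensitivity_threshold)
                sens.insert(0, "subpopulation", s_id)
                sens.insert(1, "compartment", grp["compartment"].iloc[0])
                frames.append(sens)
            pd.concat(frames, ignore_index=True).to_csv(
                sens_path, index=False, float_format=CSV_FMT)
        artifacts["sensitivity"] = str(sens_path)

    report_path = out / "stats.json"
    if "report" in stages:
        if not _exists(report_path, force):
            report = {"kurtosis_convention": "Pearson (non-excess)"}
            if metrics is not None:
                resp = metrics[metrics["responsive"]]
                for metric in ("max_rate", "modulation_ratio", "di", "oi",
                               "bandwidth", "fano"):
                    samples = {c: resp.loc[resp["compartment"] == c,
                                           metric].dropna().values
                               for c in ("2/3", "4A/B", "4C", "5/6")}
                    samples = {k: v for k, v in samples.items() if len(v) >= 2}
                    if len(samples) >= 2:
                        cc = omnibus_compare(samples, metric)
                        report[metric] = {
                            "H": cc.h_statistic, "df": cc.df, "p": cc.p_value,
                            "medians": cc.medians,
                            "pairwise": cc.pairwise.to_dict("records")}
            if decode_path.exists() and metrics is not None:
                res = pd.read_csv(decode_path)
                sub_acc = (res.groupby("subpopulation")
                           .agg(accuracy=("accuracy", "mean"),
                                center_depth=("center_depth", "first")))
                pop = build_response_matrix(session, cfg.window,
                                            neurons=responsive)
                subs = build_subpopulations(pop.depths, model, k=cfg.k,
                                            stride=cfg.stride)
                ff_by_neuron = metrics.set_index("neuron")["fano"]
                sub_ff = [float(np.nanmean(
                    ff_by_neuron.reindex(pop.neuron_indices[s.indices]).values))
                    for s in subs]
                if len(sub_ff) >= 3 and np.std(sub_ff) > 0:
                    r, p = ff_performance_correlation(
                        sub_ff, sub_acc["accuracy"].values[: len(sub_ff)])
                    report["ff_accuracy_correlation"] = {"r": r, "p": p}
            report_path.write_text(json.dumps(report, indent=1))
        artifacts["report"] = str(report_path)

    manifest = {"version": __version__, "config": cfg.to_dict(),
                "config_hash": config_hash(cfg), "seed": cfg.seed,
                "stages": list(stages), "artifacts": artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def model_assign(depths, model: LaminarModel):
    from .csd import assign_neuron_layer
    return assign_neuron_layer(np.asarray(depths, dtype=float), model)
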