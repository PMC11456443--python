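"""Session container I/O.

HDF5 layout: /neurons (depth, flat ragged spike_times + offsets),
/trials (direction, sf, eye, onset), /lfp (data, channel_depths, fs);
the SessionConfig travels as a JSON attribute and, for HDF5 files, an
optional JSON sidecar.  A compact NPZ writer covers test fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import LfpBlock, NeuronSpec, Session, SessionConfig


def _flatten_spikes(session: Session):
    n_neurons, n_trials = session.n_neurons, len(session.trials)
    lengths = np.array([[len(session.spikes[j][t]) for t in range(n_trials)]
                        for j in range(n_neurons)], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths.ravel())])
    flat = (np.concatenate([st for tr in session.spikes for st in tr])
            if offsets[-1] else np.empty(0))
    return flat, offsets, (n_neurons, n_trials)


def _unflatten_spikes(flat, offsets, shape):
    n_neurons, n_trials = shape
    out = []
    k = 0
    for _ in range(n_neurons):
        row = []
        for _ in range(n_trials):
            row.append(np.asarray(flat[offsets[k]:offsets[k + 1]]))
            k += 1
        out.append(row)
    return out


def _specs_to_table(neurons: list[NeuronSpec]) -> dict[str, np.ndarray]:
    fields = [f.name for f in dataclasses.fields(NeuronSpec)]
    table = {}
    for name in fields:
        vals = [getattr(n, name) for n in neurons]
        table[name] = (np.array(vals, dtype="S16")
                       if isinstance(vals[0], str) else np.array(vals))
    return table


def _specs_from_table(table) -> list[NeuronSpec]:
    fields = [f.name for f in dataclasses.fields(NeuronSpec)]
    n = len(np.asarray(table[fields[0]]))
    specs = []
    for i in range(n):
        kw = {}
        for name in fields:
            v = np.asarray(table[name])[i]
            kw[name] = v.decode() if isinstance(v, bytes) else float(v) \
                if np.issubdtype(np.asarray(v).dtype, np.number) else str(v)
        specs.append(NeuronSpec(**kw))
    return specs


def write_session_hdf5(session: Session, path, sidecar: bool = True) -> None:
    path = Path(path)
    flat, offsets, shape = _flatten_spikes(session)
    with h5py.File(path, "w") as f:
        f.attrs["config"] = session.config.to_json()
        f.attrs["n_neurons"], f.attrs["n_trials"] = shape
        g = f.create_group("neurons")
        g.create_dataset("spike_times", data=flat)
        g.create_dataset("spike_offsets", data=offsets)
        for name, vals in _specs_to_table(session.neurons).items():
            g.create_dataset(name, data=vals)
        g.create_dataset("true_compartment",
                         data=np.array(session.true_compartments, dtype="S8"))
        t = f.create_group("trials")
        t.create_dataset("direction", data=session.trials["direction"].values)
        t.create_dataset("sf", data=session.trials["sf"].values)
        t.create_dataset("eye", data=session.trials["eye"].values.astype("S16"))
        t.create_dataset("onset", data=session.trials["onset"].values)
        if session.lfp is not None:
            lg = f.create_group("lfp")
            lg.create_dataset("data", data=session.lfp.data)
            lg.create_dataset("channel_depths", data=session.lfp.channel_depths)
            lg.attrs["fs"] = session.lfp.fs
    if sidecar:
        path.with_suffix(".json").write_text(session.config.to_json())


def read_session_hdf5(path) -> Session:
    with h5py.File(path, "r") as f:
        cfg = _config_from_json(f.attrs["config"])
        shape = (int(f.attrs["n_neurons"]), int(f.attrs["n_trials"]))
        g = f["neurons"]
        spikes = _unflatten_spikes(g["spike_times"][:], g["spike_offsets"][:], shape)
        specs = _specs_from_table({k: g[k][:] for k in g
                                   if k not in ("spike_times", "spike_offsets",
                                                "true_compartment")})
        comps = [c.decode() for c in g["true_compartment"][:]]
        trials = pd.DataFrame({
            "direction": f["trials/direction"][:],
            "sf": f["trials/sf"][:],
            "eye": [e.decode() for e in f["trials/eye"][:]],
            "onset": f["trials/onset"][:],
        })
        lfp = None
        if "lfp" in f:
            lfp = LfpBlock(data=f["lfp/data"][:],
                           channel_depths=f["lfp/channel_depths"][:],
                           fs=float(f["lfp"].attrs["fs"]))
    return Session(config=cfg, neurons=specs, spikes=spikes, trials=trials,
                   lfp=lfp, true_compartments=comps)


def write_session_npz(session: Session, path) -> None:
    """Compact single-file fixture writer (no LFP compression tricks)."""
    flat, offsets, shape = _flatten_spikes(session)
    arrays = {
        "config_json": np.array(session.config.to_json()),
        "spike_times": flat, "spike_offsets": offsets,
        "shape": np.array(shape),
        "trial_direction": session.trials["direction"].values,
        "trial_sf": session.trials["sf"].values,
        "trial_eye": session.trials["eye"].values.astype("S16"),
        "trial_onset": session.trials["onset"].values,
        "true_compartment": np.array(session.true_compartments, dtype="S8"),
    }
    for name, vals in _specs_to_table(session.neurons).items():
        arrays[f"neuron_{name}"] = vals
    if session.lfp is not None:
        arrays["lfp_data"] = session.lfp.data
        arrays["lfp_depths"] = session.lfp.channel_depths
        arrays["lfp_fs"] = np.array(session.lfp.fs)
    np.savez_compressed(path, **arrays)


def read_session_npz(path) -> Session:
    z = np.load(path, allow_pickle=False)
    cfg = _config_from_json(str(z["config_json"]))
    shape = tuple(z["shape"])
    spikes = _unflatten_spikes(z["spike_times"], z["spike_offsets"], shape)
    specs = _specs_from_table({k[len("neuron_"):]: z[k] for k in z.files
                               if k.startswith("neuron_")})
    trials = pd.DataFrame({
        "direction": z["trial_direction"], "sf": z["trial_sf"],
        "eye": [e.decode() for e in z["trial_eye"]],
        "onset": z["trial_onset"],
    })
    lfp = None
    if "lfp_data" in z.files:
        lfp = LfpBlock(data=z["lfp_data"], channel_depths=z["lfp_depths"],
                       fs=float(z["lfp_fs"]))
    return Session(config=cfg, neurons=specs, spikes=spikes, trials=trials,
                   lfp=lfp,
                   true_compartments=[c.decode() for c in z["true_compartment"]])


def _config_from_json(text: str) -> SessionConfig:
    d = json.loads(text)
    for key in ("depth_range", "compartment_thicknesses", "sf_set",
                "eye_conditions", "fano_by_compartment"):
        if key in d:
            d[key] = tuple(d[key])
    return SessionConfig(**d)
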