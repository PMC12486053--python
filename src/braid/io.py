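"""Serialization: HDF5 datasets, JSON true-model sidecars, model checkpoints."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .model import BRAIDModel, ModelSection, SignalScaler, TransformSpec
from .simulation import TimeSeriesDataset, TrueSimModel

__all__ = ["save_dataset", "load_dataset", "save_true_model", "load_true_model",
           "save_checkpoint", "load_checkpoint", "CHECKPOINT_SCHEMA"]

CHECKPOINT_SCHEMA = 1


# -- datasets ----------------------------------------------------------------

def save_dataset(path, dataset: TimeSeriesDataset):
    with h5py.File(path, "w") as f:
        for name in ("y", "z", "u"):
            f.create_dataset(name, data=np.asarray(getattr(dataset, name), float))
        f.attrs["dt"] = dataset.dt
        f.attrs["seed"] = dataset.seed
        if dataset.fold_ids is not None:
            f.create_dataset("fold_ids", data=dataset.fold_ids)
        if dataset.latents is not None:
            f.create_dataset("latents", data=dataset.latents)
        if dataset.extras:
            g = f.create_group("extras")
            for k, v in dataset.extras.items():
                g.create_dataset(k, data=np.asarray(v))


def load_dataset(path) -> TimeSeriesDataset:
    with h5py.File(path, "r") as f:
        ds = TimeSeriesDataset(
            y=f["y"][:], z=f["z"][:], u=f["u"][:],
            dt=float(f.attrs.get("dt", 1.0)), seed=int(f.attrs.get("seed", 0)),
            fold_ids=f["fold_ids"][:] if "fold_ids" in f else None,
            latents=f["latents"][:] if "latents" in f else None,
            extras={k: f["extras"][k][:] for k in f["extras"]} if "extras" in f else {},
        )
    return ds


# -- true simulation models --------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return {"__array__": obj.tolist()}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _unjsonify(obj):
    if isinstance(obj, dict):
        if "__array__" in obj:
            return np.asarray(obj["__array__"])
        return {k: _unjsonify(v) for k, v in obj.items()}
    return obj


def save_true_model(path, model: TrueSimModel):
    payload = {k: _jsonify(getattr(model, k)) for k in
               ("A_fw", "K_fw", "Cy", "Q", "R", "eps_std", "input_pole",
                "input_std", "nonlinearity", "cz_params", "input_encoder",
                "behavior_specific", "seed")}
    with open(path, "w") as f:
        json.dump(payload, f)


def load_true_model(path) -> TrueSimModel:
    with open(path) as f:
        payload = json.load(f)
    return TrueSimModel(**{k: _unjsonify(v) for k, v in payload.items()})


# -- model checkpoints -------------------------------------------------------

def _write_maps(group, maps):
    for name, mp in maps.items():
        if mp is None:
            continue
        g = group.create_group(name)
        for k, v in mp.params.items():
            g.create_dataset(k, data=v)


def _read_maps(group, maps):
    for name, mp in maps.items():
        if mp is None:
            continue
        for k, v in mp.params.items():
            v[:] = group[name][k][:]


def save_checkpoint(path, model: BRAIDModel):
    """Single-file archive: all weights plus a JSON header of the specs."""
    header = {
        "schema": CHECKPOINT_SCHEMA,
        "variant": model.variant,
        "meta": {k: v for k, v in model.meta.items() if k != "log"},
        "scalers": {k: {"mean": s.mean.tolist(), "std": s.std.tolist()}
                    for k, s in model.scalers.items()},
        "sections": {
            str(sid): {
                "section_id": sec.section_id,
                "state_dim": sec.state_dim,
                "n_y": sec.n_y, "n_z": sec.n_z, "n_u": sec.n_u,
                "x1_dim": sec.x1_dim,
                "input_signals": list(sec.input_signals),
                "specs": {n: sp.to_dict() for n, sp in sec.specs.items()},
            } for sid, sec in model.sections.items()},
        "has_preprocessor": model.preprocessor is not None,
    }
    if model.preprocessor is not None:
        D = model.preprocessor.D
        header["preprocessor"] = {
            "state_dim": model.preprocessor.state_dim,
            "hidden_layers": D.hidden_layers,
            "hidden_units": D.layers[0].d_out if D.hidden_layers else 32,
            "activation": D.act_name,
        }
    with h5py.File(path, "w") as f:
        f.attrs["header"] = json.dumps(header)
        for sid, sec in model.sections.items():
            _write_maps(f.create_group(f"sections/{sid}"), sec.maps)
        if model.preprocessor is not None:
            pre = model.preprocessor
            g = f.create_group("preprocessor")
            g.attrs["state_dim"] = pre.state_dim
            _write_maps(g, {"A": pre.A, "K": pre.K, "D": pre.D})


def load_checkpoint(path) -> BRAIDModel:
    from .training import FilterRegressor, TrainingConfig

    with h5py.File(path, "r") as f:
        header = json.loads(f.attrs["header"])
        if header["schema"] != CHECKPOINT_SCHEMA:
            raise ValueError(f"checkpoint schema {header['schema']} not supported "
                             f"(expected {CHECKPOINT_SCHEMA})")
        scalers = {k: SignalScaler(mean=np.asarray(s["mean"]),
                                   std=np.asarray(s["std"]))
                   for k, s in header["scalers"].items()}
        rng = np.random.default_rng(0)
        sections = {}
        for sid_s, info in header["sections"].items():
            specs = {n: TransformSpec.from_dict(d) for n, d in info["specs"].items()}
            sec = ModelSection(info["section_id"], info["state_dim"],
                               info["n_y"], info["n_z"], info["n_u"],
                               tuple(info["input_signals"]), specs, rng,
                               x1_dim=info["x1_dim"])
            _read_maps(f[f"sections/{sid_s}"], sec.maps)
            sections[int(sid_s)] = sec
        preprocessor = None
        if header["has_preprocessor"]:
            g = f["preprocessor"]
            n_y = len(scalers["y"].mean)
            n_z = len(scalers["z"].mean)
            pinfo = header["preprocessor"]
            cfg = TrainingConfig(hidden_layers=pinfo["hidden_layers"],
                                 hidden_units=pinfo["hidden_units"],
                                 activation=pinfo["activation"])
            preprocessor = FilterRegressor(n_y, n_z, pinfo["state_dim"],
                                           cfg, rng)
            _read_maps(g, {"A": preprocessor.A, "K": preprocessor.K,
                           "D": preprocessor.D})
    return BRAIDModel(sections=sections, scalers=scalers,
                      preprocessor=preprocessor, variant=header["variant"],
                      meta=header["meta"])
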