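"""HDF5 / CSV serialization for datasets, models, reconstructions and traces."""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .neural_inverter import LossWeights, ModelConfig, TrainedModel, build_model
from .simulator import (
    ComplexImage2D,
    Dataset,
    DiffractionPattern,
    GridSpec,
    SimulatorConfig,
    TrainingSample,
)

__all__ = [
    "write_dataset",
    "read_dataset",
    "save_model",
    "load_model",
    "write_image",
    "read_pattern",
    "write_trace_csv",
    "write_error_table_csv",
]

_PROV_KEYS = ["seed", "a", "b", "c", "e", "n", "L_x", "L_y", "L_z",
              "phase_span", "field_seed"]


def write_dataset(path: str, dataset: Dataset) -> None:
    """Dataset layout: /patterns, /amplitude, /phase_scaled, /provenance, /meta."""
    n = len(dataset)
    with h5py.File(path, "w") as f:
        f.create_dataset("patterns", data=dataset.patterns(), compression="gzip")
        f.create_dataset("amplitude", data=dataset.amplitudes(), compression="gzip")
        f.create_dataset("phase_scaled", data=dataset.phases_scaled(), compression="gzip")
        prov = f.create_group("provenance")
        for key in _PROV_KEYS:
            prov.create_dataset(
                key, data=np.array([s.provenance.get(key, np.nan) for s in dataset.samples])
            )
        prov.create_dataset(
            "quaternion",
            data=np.array([s.provenance.get("quaternion", [np.nan] * 4)
                           for s in dataset.samples]),
        )
        meta = f.create_group("meta")
        meta.create_dataset("train_idx", data=dataset.train_idx)
        meta.create_dataset("val_idx", data=dataset.val_idx)
        meta.attrs["meta_json"] = json.dumps(dataset.meta)
        meta.attrs["n_samples"] = n


def read_dataset(path: str) -> Dataset:
    with h5py.File(path, "r") as f:
        patterns = f["patterns"][...]
        amps = f["amplitude"][...]
        phases = f["phase_scaled"][...]
        prov_arrays = {k: f["provenance"][k][...] for k in f["provenance"]}
        train_idx = f["meta/train_idx"][...]
        val_idx = f["meta/val_idx"][...]
        meta = json.loads(f["meta"].attrs["meta_json"])
    samples = []
    for i in range(len(patterns)):
        prov = {k: (v[i].tolist() if v.ndim > 1 else v[i].item())
                for k, v in prov_arrays.items()}
        samples.append(
            TrainingSample(
                pattern=DiffractionPattern(intensity=patterns[i]),
                target_amplitude=amps[i],
                target_phase_scaled=phases[i],
                provenance=prov,
            )
        )
    return Dataset(samples=samples, train_idx=train_idx, val_idx=val_idx, meta=meta)


def dataset_config(dataset: Dataset) -> SimulatorConfig:
    cfg = dataset.meta["config"]
    return SimulatorConfig(
        grid=GridSpec(**cfg["grid"]),
        semi_axis_range=tuple(cfg["semi_axis_range"]),
        exponent_range=tuple(cfg["exponent_range"]),
        corr_length_range=tuple(cfg["corr_length_range"]),
        phase_span=cfg["phase_span"],
        smoothing_sigma=cfg["smoothing_sigma"],
        train_fraction=cfg["train_fraction"],
    )


def save_model(path: str, trained: TrainedModel) -> None:
    """Checkpoint with the architecture, weights, BN statistics, history and
    input-normalization spec embedded."""
    state = trained.model.get_state()
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(dataclasses.asdict(trained.config))
        f.attrs["loss_weights_json"] = json.dumps(dataclasses.asdict(trained.loss_weights))
        f.attrs["normalization"] = trained.normalization
        f.attrs["history_json"] = json.dumps(trained.history)
        wg = f.create_group("weights")
        for i, w in enumerate(state["weights"]):
            wg.create_dataset(f"p{i:04d}", data=w)
        bg = f.create_group("bn")
        for i, (m, v) in enumerate(state["bn"]):
            bg.create_dataset(f"mean{i:04d}", data=m)
            bg.create_dataset(f"var{i:04d}", data=v)


def load_model(path: str) -> TrainedModel:
    with h5py.File(path, "r") as f:
        config = ModelConfig(**json.loads(f.attrs["config_json"]))
        weights_cfg = LossWeights(**json.loads(f.attrs["loss_weights_json"]))
        normalization = str(f.attrs["normalization"])
        history = json.loads(f.attrs["history_json"])
        weights = [f["weights"][k][...] for k in sorted(f["weights"])]
        n_bn = len(f["bn"]) // 2
        bn = [(f["bn"][f"mean{i:04d}"][...], f["bn"][f"var{i:04d}"][...])
              for i in range(n_bn)]
    model = build_model(config)
    model.set_state({"weights": weights, "bn": bn})
    return TrainedModel(
        config=config, model=model, normalization=normalization,
        history=history, loss_weights=weights_cfg,
    )


def write_image(path: str, image: ComplexImage2D, extra: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("amplitude", data=image.amplitude)
        f.create_dataset("phase", data=image.phase)
        for k, v in (extra or {}).items():
            f.create_dataset(k, data=np.asarray(v))


def read_pattern(path: str, index: int = 0) -> DiffractionPattern:
    """Read one diffraction pattern from a dataset file or a bare /intensity file."""
    with h5py.File(path, "r") as f:
        if "patterns" in f:
            return DiffractionPattern(intensity=f["patterns"][index][...])
        if "intensity" in f:
            return DiffractionPattern(intensity=f["intensity"][...])
    raise ValueError(f"{path} holds neither /patterns nor /intensity")


def write_trace_csv(path: str, trace) -> None:
    with open(path, "w") as f:
        f.write("iteration,algorithm,chi2\n")
        for i, (alg, chi2) in enumerate(zip(trace.algorithm, trace.chi2), start=1):
            f.write(f"{i},{alg},{chi2:.10e}\n")


def write_error_table_csv(path: str, table: dict) -> None:
    keys = ["sample_id", "chi2_modulus", "chi2_amplitude", "chi2_phase"]
    with open(path, "w") as f:
        f.write(",".join(keys) + "\n")
        for row in zip(*[table[k] for k in keys]):
            f.write(f"{int(row[0])}," + ",".join(f"{x:.10e}" for x in row[1:]) + "\n")
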