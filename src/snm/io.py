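"""Serialization: HDF5 model containers, npz datasets, JSON reports.

The model container stores weights, masks, thresholds, neuron parameters,
the simulation/encoder configuration and the build seed, plus a SHA-256
checksum over all array payloads so that tampering or corruption surfaces as
an explicit format error rather than silently wrong numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .data import LabeledDataset
from .errors import FormatError
from .network import NetworkModel, SimulationConfig
from .neuron import IzhikevichParams, LIFParams
from .plasticity import SynapseMatrix

FORMAT_VERSION = 1


def _model_checksum(model: NetworkModel) -> str:
    h = hashlib.sha256()
    for conn in model.connections:
        h.update(np.ascontiguousarray(conn.weights).tobytes())
        h.update(np.ascontiguousarray(conn.mask.astype(np.uint8)).tobytes())
    for th in model.thresholds:
        h.update(np.ascontiguousarray(th).tobytes())
    return h.hexdigest()


def save_model(model: NetworkModel, path) -> None:
    """Write a model to an HDF5 container (checksummed, versioned)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["neuron_kind"] = model.neuron_kind
        f.attrs["trained"] = bool(model.trained)
        f.attrs["seed"] = -1 if model.seed is None else int(model.seed)
        f.attrs["lif"] = json.dumps(asdict(model.lif))
        f.attrs["izh"] = json.dumps(asdict(model.izh))
        f.attrs["sim"] = json.dumps(asdict(model.sim))
        f.create_dataset("layer_sizes", data=np.asarray(model.layer_sizes, dtype=int))
        for k, conn in enumerate(model.connections):
            g = f.create_group(f"connection_{k}")
            g.create_dataset("weights", data=conn.weights)
            g.create_dataset("mask", data=conn.mask.astype(np.uint8))
            g.attrs["pre_layer"] = conn.pre_layer
            g.attrs["post_layer"] = conn.post_layer
        for k, th in enumerate(model.thresholds):
            f.create_dataset(f"thresholds_{k}", data=th)
        f.attrs["checksum"] = _model_checksum(model)


def load_model(path) -> NetworkModel:
    """Load a model container; raises FormatError on version mismatch or a
    checksum failure (tampered/corrupt file)."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise FormatError(f"unsupported model container version {version}")
        sizes = tuple(int(s) for s in f["layer_sizes"][()])
        connections = []
        for k in range(len(sizes) - 1):
            g = f[f"connection_{k}"]
            connections.append(
                SynapseMatrix(
                    g["weights"][()],
                    g["mask"][()],
                    str(g.attrs["pre_layer"]),
                    str(g.attrs["post_layer"]),
                )
            )
        thresholds = [f[f"thresholds_{k}"][()] for k in range(len(sizes) - 1)]
        seed = int(f.attrs["seed"])
        model = NetworkModel(
            layer_sizes=sizes,
            neuron_kind=str(f.attrs["neuron_kind"]),
            connections=connections,
            thresholds=thresholds,
            lif=LIFParams(**json.loads(f.attrs["lif"])),
            izh=IzhikevichParams(**json.loads(f.attrs["izh"])),
            sim=SimulationConfig(**json.loads(f.attrs["sim"])),
            seed=None if seed == -1 else seed,
            trained=bool(f.attrs["trained"]),
        )
        stored = str(f.attrs["checksum"])
    if _model_checksum(model) != stored:
        raise FormatError("model container checksum mismatch (corrupt or tampered)")
    return model


def save_dataset(dataset: LabeledDataset, path) -> None:
    """Write a dataset as npz with a JSON provenance sidecar."""
    path = Path(path)
    np.savez(path, samples=dataset.samples, labels=dataset.labels)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(dataset.provenance, sort_keys=True, indent=2))


def load_dataset(path) -> LabeledDataset:
    path = Path(path)
    with np.load(path) as z:
        samples, labels = z["samples"], z["labels"]
    sidecar = path.with_suffix(".json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return LabeledDataset(samples, labels, prov)


def save_report(report: dict, path) -> None:
    """Deterministic JSON serialization (sorted keys, fixed float repr)."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
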