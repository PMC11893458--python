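"""HDF5 / NPZ serialization of models, fits and batches."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .circuit import FitMetrics, FitResult, LatentCircuit
from .rnn import RNNParams
from .task import TrialBatch, TrialCondition

FORMAT_VERSION = 1

__all__ = [
    "save_rnn",
    "load_rnn",
    "save_circuit",
    "load_circuit",
    "save_fit",
    "load_fit",
    "save_batch",
    "load_batch",
]


def _check_version(f: h5py.File, path):
    v = f.attrs.get("format_version")
    if v != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported format version {v!r}")


def save_rnn(path, p: RNNParams, extra_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "rnn"
        for name in ("W_rec", "W_in", "W_out", "dale_mask"):
            f.create_dataset(name, data=getattr(p, name))
        for name in ("tau", "dt", "sigma_rec"):
            f.attrs[name] = getattr(p, name)
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def load_rnn(path) -> RNNParams:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        return RNNParams(
            W_rec=f["W_rec"][...],
            W_in=f["W_in"][...],
            W_out=f["W_out"][...],
            dale_mask=f["dale_mask"][...],
            tau=float(f.attrs["tau"]),
            dt=float(f.attrs["dt"]),
            sigma_rec=float(f.attrs["sigma_rec"]),
        )


def _write_circuit(g, lc: LatentCircuit):
    for name in ("w_rec", "w_in", "w_out", "B_cayley"):
        g.create_dataset(name, data=getattr(lc, name))
    g.create_dataset("Q", data=lc.Q)  # materialized for external consumers
    if lc.b is not None:
        g.create_dataset("b", data=lc.b)
    g.attrs["alpha"] = lc.alpha
    g.attrs["sigma_rec"] = lc.sigma_rec


def _read_circuit(g) -> LatentCircuit:
    return LatentCircuit(
        w_rec=g["w_rec"][...],
        w_in=g["w_in"][...],
        w_out=g["w_out"][...],
        B_cayley=g["B_cayley"][...],
        b=g["b"][...] if "b" in g else None,
        alpha=float(g.attrs["alpha"]),
        sigma_rec=float(g.attrs["sigma_rec"]),
    )


def save_circuit(path, lc: LatentCircuit) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "circuit"
        _write_circuit(f, lc)


def load_circuit(path) -> LatentCircuit:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        return _read_circuit(f)


def save_fit(path, res: FitResult) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "fit"
        _write_circuit(f.create_group("circuit"), res.circuit)
        f.create_dataset("loss_trace", data=np.asarray(res.loss_trace))
        f.create_dataset("train_idx", data=res.train_idx)
        f.create_dataset("test_idx", data=res.test_idx)
        f.attrs["metrics"] = json.dumps(res.metrics.as_dict())
        f.attrs["seed"] = res.seed
        f.attrs["converged"] = res.converged


def load_fit(path) -> FitResult:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        metrics = FitMetrics(**json.loads(f.attrs["metrics"]))
        return FitResult(
            circuit=_read_circuit(f["circuit"]),
            loss_trace=list(f["loss_trace"][...]),
            metrics=metrics,
            train_idx=f["train_idx"][...],
            test_idx=f["test_idx"][...],
            seed=int(f.attrs["seed"]),
            converged=bool(f.attrs["converged"]),
        )


def save_batch(path, batch: TrialBatch) -> None:
    """NPZ container with named arrays plus a JSON condition sidecar field."""
    meta = {
        "dt_ms": batch.dt_ms,
        "seed": batch.seed,
        "conditions": [
            [c.context, c.motion_coherence, c.color_coherence] for c in batch.conditions
        ],
    }
    np.savez(
        path,
        u=batch.u,
        z_target=batch.z_target,
        mask=batch.mask,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_batch(path) -> TrialBatch:
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        conds = [TrialCondition(c, mc, cc) for c, mc, cc in meta["conditions"]]
        return TrialBatch(
            u=f["u"],
            z_target=f["z_target"],
            mask=f["mask"],
            conditions=conds,
            dt_ms=meta["dt_ms"],
            seed=meta["seed"],
        )
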