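"""Serialization: model containers (HDF5), label maps and matrices (TSV),
manifests (JSON).

Label maps are 1-based in files (parcels 1..K) and 0-based in memory.
Model files carry a format version and are rejected on mismatch.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .arrangement import ArrangementParams
from .emission import DataBundle, EmissionParams, Session
from .fusion import FusionModel

__all__ = [
    "MODEL_FORMAT_VERSION",
    "save_model",
    "load_model",
    "save_bundle",
    "load_bundle",
    "save_labels",
    "load_labels",
    "save_matrix",
    "load_matrix",
    "write_json",
    "read_json",
]

MODEL_FORMAT_VERSION = 1


def save_model(model: FusionModel, path, meta: dict | None = None) -> None:
    """Write a fusion model (eta + per-session emission params) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = MODEL_FORMAT_VERSION
        f.attrs["K"] = model.K
        f.attrs["P"] = model.P
        f.attrs["subjects"] = json.dumps(list(model.subjects))
        if meta is not None:
            f.attrs["meta"] = json.dumps(meta)
        f.create_dataset("eta", data=model.arrangement.eta)
        for i, (em, sid) in enumerate(zip(model.emissions, model.session_ids)):
            g = f.create_group(f"emission/{i:03d}")
            g.attrs["session_id"] = sid
            g.attrs["model_type"] = em.model_type
            g.attrs["subject_ids"] = json.dumps(list(em.subject_ids))
            g.create_dataset("V", data=em.V)
            g.create_dataset("kappa", data=np.asarray(em.kappa))


def load_model(path) -> tuple[FusionModel, dict | None]:
    """Read a fusion model written by :func:`save_model`.

    Returns ``(model, meta)``; ``meta`` is the metadata dict or None.
    """
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model file format version {version} not supported "
                f"(expected {MODEL_FORMAT_VERSION})"
            )
        eta = f["eta"][()]
        subjects = tuple(json.loads(f.attrs["subjects"]))
        emissions, session_ids = [], []
        for key in sorted(f["emission"]):
            g = f[f"emission/{key}"]
            kappa = g["kappa"][()]
            emissions.append(
                EmissionParams(
                    V=g["V"][()],
                    kappa=kappa if kappa.ndim else float(kappa),
                    model_type=str(g.attrs["model_type"]),
                    subject_ids=tuple(json.loads(g.attrs["subject_ids"])),
                )
            )
            session_ids.append(str(g.attrs["session_id"]))
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else None
    return FusionModel(ArrangementParams(eta), emissions, session_ids, subjects), meta


def save_bundle(bundle: DataBundle, path) -> None:
    """Write a data bundle (all sessions) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = MODEL_FORMAT_VERSION
        f.attrs["unit_normalized"] = bool(bundle.unit_normalized)
        for i, s in enumerate(bundle.sessions):
            g = f.create_group(f"session/{i:03d}")
            g.attrs["session_id"] = s.session_id
            g.attrs["subject_ids"] = json.dumps(list(s.subject_ids))
            g.create_dataset("Y", data=s.Y)


def load_bundle(path) -> DataBundle:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"bundle file format version {version} not supported")
        sessions = []
        for key in sorted(f["session"]):
            g = f[f"session/{key}"]
            sessions.append(
                Session(
                    session_id=str(g.attrs["session_id"]),
                    subject_ids=tuple(json.loads(g.attrs["subject_ids"])),
                    Y=g["Y"][()],
                )
            )
        return DataBundle(sessions, unit_normalized=bool(f.attrs["unit_normalized"]))


def save_labels(labels: np.ndarray, path) -> None:
    """Write label map(s) as TSV, 1-based; rows = maps, columns = locations."""
    arr = np.atleast_2d(np.asarray(labels, dtype=int)) + 1
    np.savetxt(path, arr, fmt="%d", delimiter="\t")


def load_labels(path, K: int | None = None) -> np.ndarray:
    """Read 1-based TSV label map(s) into 0-based arrays; validates range."""
    arr = np.atleast_2d(np.loadtxt(path, delimiter="\t", dtype=int))
    if np.any(arr < 1):
        raise ValueError("label files are 1-based; found a label < 1")
    if K is not None and np.any(arr > K):
        raise ValueError(f"label file contains a label > K={K}")
    arr = arr - 1
    return arr[0] if arr.shape[0] == 1 else arr


def save_matrix(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.10g", delimiter="\t")


def load_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t", dtype=float))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
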