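"""Delimited-text persistence for recordings, features, models and reports.

Every format carries a version header; readers reject unknown versions.
Recordings are TSV (one row per channel) with a JSON sidecar holding fs,
channel names, subject id and state.  Models serialize to a single JSON
container including architecture, all weights, scaling parameters, config
and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Union

import numpy as np

from . import _mlp
from .ann import ANNConfig, ANNModel
from .containers import (
    EEGRecording,
    FeatureMatrix,
    MinMaxScaling,
    TrainTrace,
)
from .dbn import DBNModel
from .rbm import RBMParams, TrainConfig

FEATURES_MAGIC = "#eegfatigue/features v1"
RECORDING_MAGIC = "eegfatigue/recording v1"
MODEL_MAGIC = "eegfatigue/model v1"

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# recordings

def write_recording(rec: EEGRecording, data_path: PathLike) -> None:
    """TSV (channels x samples) plus a ``<stem>.meta.json`` sidecar."""
    data_path = Path(data_path)
    np.savetxt(data_path, rec.data, delimiter="\t", fmt="%.10g")
    meta = {
        "format": RECORDING_MAGIC,
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "subject_id": rec.subject_id,
        "state": rec.state,
    }
    data_path.with_suffix(data_path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1)
    )


def read_recording(data_path: PathLike) -> EEGRecording:
    data_path = Path(data_path)
    meta_path = data_path.with_suffix(data_path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text())
    if meta.get("format") != RECORDING_MAGIC:
        raise ValueError(f"unsupported recording format {meta.get('format')!r}")
    data = np.loadtxt(data_path, delimiter="\t", ndmin=2)
    return EEGRecording(
        data=data,
        fs=meta["fs"],
        channel_names=meta["channel_names"],
        subject_id=meta["subject_id"],
        state=meta["state"],
    )


# ---------------------------------------------------------------------------
# feature matrices

def write_features(fm: FeatureMatrix, path: PathLike) -> None:
    """Header row of feature names plus a trailing integer label column."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(FEATURES_MAGIC + "\n")
        fh.write("\t".join(fm.feature_names + ["label"]) + "\n")
        for row, label in zip(fm.X, fm.y):
            fh.write("\t".join(f"{v:.10g}" for v in row) + f"\t{int(label)}\n")


def read_features(path: PathLike) -> FeatureMatrix:
    path = Path(path)
    with path.open() as fh:
        magic = fh.readline().rstrip("\n")
        if magic != FEATURES_MAGIC:
            raise ValueError(f"unsupported features format {magic!r}")
        names = fh.readline().rstrip("\n").split("\t")
        if not names or names[-1] != "label":
            raise ValueError("malformed feature header: missing label column")
        body = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if body.size == 0:
        raise ValueError("empty feature file")
    return FeatureMatrix(body[:, :-1], body[:, -1].astype(int), names[:-1])


# ---------------------------------------------------------------------------
# models

def _scaling_to_dict(s: MinMaxScaling | None) -> dict | None:
    if s is None:
        return None
    return {"mins": s.mins.tolist(), "maxs": s.maxs.tolist()}


def _scaling_from_dict(d: dict | None) -> MinMaxScaling | None:
    if d is None:
        return None
    return MinMaxScaling(np.asarray(d["mins"]), np.asarray(d["maxs"]))


def save_model(model: Union[DBNModel, ANNModel], path: PathLike) -> None:
    """Versioned JSON container for either model kind."""
    kind = "sparse-dbn" if isinstance(model, DBNModel) else "ann"
    doc = {
        "format": MODEL_MAGIC,
        "kind": kind,
        "architecture": model.architecture,
        "net": [{"W": W.tolist(), "b": b.tolist()} for W, b in model.net],
        "scaling": _scaling_to_dict(model.scaling),
        "config": asdict(model.config) if model.config is not None else None,
        "train_trace": asdict(model.train_trace),
    }
    if isinstance(model, DBNModel):
        doc["layers"] = [
            {"W": p.W.tolist(), "a": p.a.tolist(), "b": p.b.tolist()} for p in model.layers
        ]
    Path(path).write_text(json.dumps(doc))


def load_model(path: PathLike) -> Union[DBNModel, ANNModel]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != MODEL_MAGIC:
        raise ValueError(f"unsupported model format {doc.get('format')!r}")
    net: _mlp.Net = [(np.asarray(l["W"]), np.asarray(l["b"])) for l in doc["net"]]
    trace = TrainTrace(**doc["train_trace"])
    scaling = _scaling_from_dict(doc.get("scaling"))
    if doc["kind"] == "sparse-dbn":
        layers = [
            RBMParams(np.asarray(l["W"]), np.asarray(l["a"]), np.asarray(l["b"]))
            for l in doc.get("layers", [])
        ]
        cfg = TrainConfig(**doc["config"]) if doc.get("config") else None
        return DBNModel(layers=layers, net=net, architecture=doc["architecture"],
                        train_trace=trace, scaling=scaling, config=cfg)
    cfg = ANNConfig(**doc["config"]) if doc.get("config") else None
    return ANNModel(net=net, architecture=doc["architecture"], train_trace=trace,
                    scaling=scaling, config=cfg)


# ---------------------------------------------------------------------------
# reports

def write_report(report_dict: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
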