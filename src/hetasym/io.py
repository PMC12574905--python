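"""YAML serialization of model parameters and HDF5 storage of ground truth."""

from __future__ import annotations

import h5py
import numpy as np
import yaml

from .connectome import Connectome
from .dynamics import (
    FixedPoint,
    GroundTruth,
    ModelAParams,
    ModelBParams,
    ModelCParams,
)
from .exceptions import ValidationError

__all__ = ["save_params", "load_params", "save_ground_truth", "load_ground_truth"]

_MODEL_TAGS = {ModelAParams: "A", ModelBParams: "B", ModelCParams: "C"}
_TAG_MODELS = {v: k for k, v in _MODEL_TAGS.items()}


def _to_plain(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def save_params(params, path) -> None:
    tag = _MODEL_TAGS.get(type(params))
    if tag is None:
        raise ValidationError(f"cannot serialize {type(params)!r}")
    doc = {"model": tag, "connectome": {"C": params.conn.C.tolist(),
                                        "labels": list(params.conn.labels),
                                        "row_normalized": params.conn.row_normalized}}
    for name, value in vars(params).items():
        if name == "conn":
            continue
        doc[name] = _to_plain(value)
    with open(str(path), "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def load_params(path):
    with open(str(path)) as f:
        doc = yaml.safe_load(f)
    tag = doc.pop("model")
    cls = _TAG_MODELS.get(tag)
    if cls is None:
        raise ValidationError(f"unknown model tag {tag!r}")
    cd = doc.pop("connectome")
    conn = Connectome(np.asarray(cd["C"], float), labels=list(cd["labels"]),
                      row_normalized=bool(cd.get("row_normalized", False)))
    kwargs = {k: (np.asarray(v, float) if isinstance(v, list) else v) for k, v in doc.items()}
    return cls(conn=conn, **kwargs)


def save_ground_truth(gt: GroundTruth, path) -> None:
    with h5py.File(str(path), "w") as f:
        g = f.create_group("ground_truth")
        g.create_dataset("J", data=gt.J)
        g.create_dataset("h", data=gt.h)
        g.create_dataset("S_star", data=gt.fixed_point.S_star)
        g.create_dataset("x_star", data=gt.fixed_point.x_star)
        g.create_dataset("H_star", data=gt.fixed_point.H_star)
        g.create_dataset("gain", data=gt.fixed_point.gain)
        g.attrs["residual"] = gt.fixed_point.residual


def load_ground_truth(path) -> GroundTruth:
    with h5py.File(str(path), "r") as f:
        g = f["ground_truth"]
        fp = FixedPoint(
            S_star=g["S_star"][()],
            x_star=g["x_star"][()],
            H_star=g["H_star"][()],
            gain=g["gain"][()],
            residual=float(g.attrs["residual"]),
        )
        return GroundTruth(J=g["J"][()], h=g["h"][()], fixed_point=fp)
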