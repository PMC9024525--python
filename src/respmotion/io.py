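"""File formats: trace CSV, profile/manifest YAML, windowed CSV, checkpoints.

The trace dialect is a plain CSV with header
``time_s,marker_x_mm,marker_y_mm,marker_z_mm,tumor_disp_mm,phase`` where the
last two columns may be empty.  Model checkpoints are JSON holding the head
kind, every weight/bias array, the fitted scaler parameters and the training
config — enough for a bit-exact reload (floats round-trip via repr).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import network
from .estimators import TimeLaggedDisplacementRegressor, TimeLaggedPhaseClassifier
from .preprocess import MinMaxScaler, Standardizer
from .simulate import BpmClass, BreathingPattern, MotionTrace, SubjectProfile

__all__ = [
    "read_trace",
    "write_trace",
    "read_profile",
    "write_profile",
    "write_manifest",
    "read_manifest",
    "save_model",
    "load_model",
]

PathLike = Union[str, Path]
_TRACE_COLUMNS = ["time_s", "marker_x_mm", "marker_y_mm", "marker_z_mm"]


def write_trace(trace: MotionTrace, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "marker_x_mm": trace.marker[:, 0],
            "marker_y_mm": trace.marker[:, 1],
            "marker_z_mm": trace.marker[:, 2],
            "tumor_disp_mm": trace.tumor_disp
            if trace.tumor_disp is not None
            else np.full(len(trace.time), np.nan),
            "phase": trace.phase_truth
            if trace.phase_truth is not None
            else np.full(len(trace.time), np.nan),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_trace(path: PathLike, subject_id: str | None = None) -> MotionTrace:
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} lacks required column(s): {missing}")
    time = df["time_s"].to_numpy(dtype=float)
    if len(time) < 2 or np.any(np.diff(time) <= 0):
        raise ValueError(f"trace file {path} has non-monotone or too-short time")
    sample_rate = 1.0 / float(np.median(np.diff(time)))
    marker = df[_TRACE_COLUMNS[1:]].to_numpy(dtype=float)

    tumor = None
    if "tumor_disp_mm" in df.columns and df["tumor_disp_mm"].notna().all():
        tumor = df["tumor_disp_mm"].to_numpy(dtype=float)
    phase = None
    if "phase" in df.columns and df["phase"].notna().all():
        phase = df["phase"].to_numpy(dtype=float).astype(int)
    return MotionTrace(
        subject_id=subject_id or Path(path).stem,
        sample_rate=sample_rate,
        time=time,
        marker=marker,
        tumor_disp=tumor,
        phase_truth=phase,
    )


def write_profile(profile: SubjectProfile, path: PathLike) -> None:
    payload = dataclasses.asdict(profile)
    payload["pattern"] = profile.pattern.value
    payload["bpm_class"] = profile.bpm_class.value
    payload["tumor_midpoint"] = list(profile.tumor_midpoint)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_profile(path: PathLike) -> SubjectProfile:
    payload = yaml.safe_load(Path(path).read_text())
    return SubjectProfile(
        subject_id=payload["subject_id"],
        age=int(payload["age"]),
        weight=float(payload["weight"]),
        height=float(payload["height"]),
        bpm=float(payload["bpm"]),
        heart_rate=float(payload["heart_rate"]),
        tumor_midpoint=tuple(float(v) for v in payload["tumor_midpoint"]),
        pattern=BreathingPattern(payload["pattern"]),
        bpm_class=BpmClass(payload["bpm_class"]),
    )


def write_manifest(manifest: dict, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(path: PathLike) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _array_payload(a: np.ndarray) -> dict:
    return {"shape": list(a.shape), "data": a.ravel().tolist()}


def _array_from(payload: dict) -> np.ndarray:
    return np.array(payload["data"], dtype=float).reshape(payload["shape"])


def _params_payload(params: network.NetworkParams) -> dict:
    return {
        "head": params.head,
        "w_in": _array_payload(params.w_in),
        "b_in": _array_payload(params.b_in),
        "hidden_w": [_array_payload(w) for w in params.hidden_w],
        "hidden_b": [_array_payload(b) for b in params.hidden_b],
        "w_out": _array_payload(params.w_out),
        "b_out": _array_payload(params.b_out),
    }


def _params_from(payload: dict) -> network.NetworkParams:
    return network.NetworkParams(
        head=payload["head"],
        w_in=_array_from(payload["w_in"]),
        b_in=_array_from(payload["b_in"]),
        hidden_w=[_array_from(w) for w in payload["hidden_w"]],
        hidden_b=[_array_from(b) for b in payload["hidden_b"]],
        w_out=_array_from(payload["w_out"]),
        b_out=_array_from(payload["b_out"]),
    )


def save_model(
    model: TimeLaggedPhaseClassifier | TimeLaggedDisplacementRegressor,
    path: PathLike,
) -> None:
    """Checkpoint a fitted estimator (head, params, scalers, config)."""
    model._check_is_fitted()
    payload: dict = {
        "kind": type(model).__name__,
        "config": model.get_params(),
        "params": _params_payload(model.params_),
        "layer_widths": list(network.HIDDEN_WIDTHS),
    }
    if isinstance(model, TimeLaggedPhaseClassifier):
        payload["scaler"] = {
            "mean": model.scaler_.mean_.tolist(),
            "scale": model.scaler_.scale_.tolist(),
        }
    else:
        payload["x_scaler"] = {
            "min": model.x_scaler_.data_min_.tolist(),
            "max": model.x_scaler_.data_max_.tolist(),
        }
        payload["y_scaler"] = {
            "min": model.y_scaler_.data_min_.tolist(),
            "max": model.y_scaler_.data_max_.tolist(),
        }
    Path(path).write_text(json.dumps(payload))


def load_model(path: PathLike):
    """Reload a checkpoint into a fitted estimator."""
    payload = json.loads(Path(path).read_text())
    kind = payload["kind"]
    if kind == "TimeLaggedPhaseClassifier":
        model = TimeLaggedPhaseClassifier(**payload["config"])
        model.scaler_ = Standardizer.from_params(
            payload["scaler"]["mean"], payload["scaler"]["scale"]
        )
        model.classes_ = np.arange(10)
    elif kind == "TimeLaggedDisplacementRegressor":
        model = TimeLaggedDisplacementRegressor(**payload["config"])
        model.x_scaler_ = MinMaxScaler.from_params(
            payload["x_scaler"]["min"], payload["x_scaler"]["max"]
        )
        model.y_scaler_ = MinMaxScaler.from_params(
            payload["y_scaler"]["min"], payload["y_scaler"]["max"]
        )
    else:
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    model.params_ = _params_from(payload["params"])
    model.n_features_in_ = 33
    model.history_ = {}
    return model
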