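"""On-disk formats: detections/annotations CSV, EGM and phase HDF5, params JSON."""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd

from .detect import DetectorParams
from .phase import EgmSet, PhaseSequence

DETECTION_COLUMNS = ["frame", "node", "row", "col", "chirality", "loop_gradient"]


def save_detections(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in DETECTION_COLUMNS if c in df.columns])


def load_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"frame", "node"} - set(df.columns)
    if missing:
        raise ValueError(f"detections file lacks columns {sorted(missing)}")
    return df


def save_egm(egm: EgmSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=egm.samples)
        f.create_dataset("fs", data=float(egm.fs))
        f.create_dataset("node_map", data=egm.node_map)


def load_egm(path) -> EgmSet:
    path = str(path)
    if path.endswith(".csv") or path.endswith(".txt"):
        df = pd.read_csv(path)
        node_map = np.array([int(c) for c in df.columns], dtype=np.int64)
        # delimited text carries no rate; caller must know it (512 Hz default)
        return EgmSet(samples=df.to_numpy().T, fs=512.0, node_map=node_map)
    with h5py.File(path, "r") as f:
        return EgmSet(
            samples=f["samples"][...],
            fs=float(f["fs"][()]),
            node_map=f["node_map"][...] if "node_map" in f else None,
        )


def save_egm_csv(egm: EgmSet, path) -> None:
    pd.DataFrame(egm.samples.T, columns=[str(n) for n in egm.node_map]).to_csv(
        path, index=False
    )


def save_phase(seq: PhaseSequence, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("phase", data=seq.phase)
        f.create_dataset("frame_rate", data=float(seq.frame_rate))


def load_phase(path) -> PhaseSequence:
    with h5py.File(path, "r") as f:
        return PhaseSequence(phase=f["phase"][...], frame_rate=float(f["frame_rate"][()]))


def save_params(params: DetectorParams, path) -> None:
    with open(path, "w") as f:
        json.dump(dataclasses.asdict(params), f, indent=2)


def load_params(path) -> DetectorParams:
    with open(path) as f:
        return DetectorParams(**json.load(f))
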