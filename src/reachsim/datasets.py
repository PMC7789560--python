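"""Supervised datasets from recordings: in-zone filtering and C+/C− schemas.

The context-unaware network (C−) receives the three shoulder angles; the
context-aware network (C+) additionally receives the contextual quadruplet:
the shoulder-center→target-center vector expressed in an egocentric frame
attached to the shoulder (axes parallel to the world frame, origin at the
instantaneous shoulder center) plus the target's frontal-plane tilt.
Outputs are always the four distal angles of the same sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import ArmGeometry, fk_batch
from .recording import ANGLE_COLS, MotionRecording
from .tasks import Tolerance, in_zone_batch

SHOULDER_COLS = ANGLE_COLS[:3]
DISTAL_COLS = ANGLE_COLS[3:]
CONTEXT_COLS = ["dx", "dy", "dz", "tilt"]


@dataclass(frozen=True)
class ContextFeatures:
    dx: float
    dy: float
    dz: float
    tilt: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz, self.tilt])


@dataclass
class TrainingDataset:
    """Aligned input/output rows for one network mode.

    ``provenance`` holds the source-recording row indices, 1:1 with rows.
    """

    mode: str  # "C+" | "C-"
    inputs: np.ndarray
    outputs: np.ndarray
    feature_names: list[str]
    provenance: np.ndarray

    def __post_init__(self):
        width = 7 if self.mode == "C+" else 3
        if self.mode not in ("C+", "C-"):
            raise ValueError("mode must be 'C+' or 'C-'")
        if self.inputs.shape[1] != width:
            raise ValueError(
                f"{self.mode} dataset requires input width {width}, "
                f"got {self.inputs.shape[1]}"
            )
        if len(self.inputs) != len(self.outputs):
            raise ValueError("inputs and outputs must align 1:1")
        if self.outputs.shape[1] != 4:
            raise ValueError("outputs must be the 4 distal angles")

    @property
    def n_samples(self) -> int:
        return len(self.inputs)


def make_context(shoulder_position: np.ndarray, target) -> ContextFeatures:
    """Contextual quadruplet: egocentric target vector + tilt."""
    d = np.asarray(target.position, float) - np.asarray(shoulder_position, float)
    return ContextFeatures(float(d[0]), float(d[1]), float(d[2]), float(target.tilt))


def recompute_in_zone(
    recording: MotionRecording, geometry: ArmGeometry, tol: Tolerance
) -> np.ndarray:
    """In-zone flags from poses + targets (consistency / recovery path)."""
    flags = np.zeros(len(recording.df), dtype=bool)
    q = recording.angles
    sh = recording.shoulder_positions
    trial_ids = recording.df["trial_id"].to_numpy()
    for tr in recording.trials:
        m = trial_ids == tr.trial_id
        if not m.any():
            continue
        f = fk_batch(q[m], geometry, sh[m])
        flags[m] = in_zone_batch(f["hand_center"], f["axis"], tr.target, tol)
    return flags


def filter_in_zone(recording: MotionRecording) -> np.ndarray:
    """Indices of rows recorded inside the target zone.

    Raises ``ValueError`` if the recording carries no trial/target
    metadata; warns (and returns an empty index) if nothing is in zone.
    """
    if not recording.trials:
        raise ValueError("recording has no targets attached")
    idx = np.flatnonzero(recording.df["in_zone"].to_numpy())
    if len(idx) == 0:
        warnings.warn("no in-zone samples in recording", stacklevel=2)
    return idx


def build_dataset(recording: MotionRecording, mode: str) -> TrainingDataset:
    """In-zone-filtered supervised dataset in the C+ or C− schema."""
    idx = filter_in_zone(recording)
    df = recording.df.iloc[idx]
    x_sh = df[SHOULDER_COLS].to_numpy()
    y = df[DISTAL_COLS].to_numpy()
    if mode == "C+":
        sh_pos = df[["shx", "shy", "shz"]].to_numpy()
        trial_ids = df["trial_id"].to_numpy()
        ctx = np.zeros((len(df), 4))
        for tr in recording.trials:
            m = trial_ids == tr.trial_id
            if not m.any():
                continue
            ctx[m, :3] = tr.target.position - sh_pos[m]
            ctx[m, 3] = tr.target.tilt
        x = np.hstack([x_sh, ctx])
        names = SHOULDER_COLS + CONTEXT_COLS
    else:
        x = x_sh
        names = list(SHOULDER_COLS)
    return TrainingDataset(
        mode=mode,
        inputs=x,
        outputs=y,
        feature_names=names,
        provenance=idx,
    )


def dataset_to_csv(ds: TrainingDataset, path) -> None:
    """CSV plus a JSON schema sidecar (mode, feature names, output names)."""
    import json
    from pathlib import Path

    df = pd.DataFrame(ds.inputs, columns=ds.feature_names)
    for j, c in enumerate(DISTAL_COLS):
        df[f"out_{c}"] = ds.outputs[:, j]
    df["source_row"] = ds.provenance
    df.to_csv(path, index=False, float_format="%.10g")
    Path(path).with_suffix(".schema.json").write_text(
        json.dumps(
            {
                "mode": ds.mode,
                "features": ds.feature_names,
                "outputs": [f"out_{c}" for c in DISTAL_COLS],
                "standardization": "inside predictor (training-set mean/SD)",
            },
            indent=1,
        )
    )


def dataset_from_csv(path, mode: str) -> TrainingDataset:
    df = pd.read_csv(path)
    names = SHOULDER_COLS + (CONTEXT_COLS if mode == "C+" else [])
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise ValueError(f"dataset/mode mismatch: missing columns {missing}")
    return TrainingDataset(
        mode=mode,
        inputs=df[names].to_numpy(),
        outputs=df[[f"out_{c}" for c in DISTAL_COLS]].to_numpy(),
        feature_names=names,
        provenance=df["source_row"].to_numpy(),
    )
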