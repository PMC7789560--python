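"""Motion recordings: the 90 Hz stream of postures + shoulder positions.

A recording is a flat table (one row per sample) plus per-trial metadata
(the target and outcome of every trial). Hybrid-control phases carry a
second, synchronized "mimicked" angle block: the postures natural
whole-arm control would have displayed for the same commanded shoulder
angles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import DOF_NAMES, HandPose
from .tasks import Target, TrialOutcome

ANGLE_COLS = list(DOF_NAMES)
MIM_COLS = [f"mim_{n}" for n in DOF_NAMES]
BASE_COLS = ["t", "phase", "trial_id"] + ANGLE_COLS + ["shx", "shy", "shz", "in_zone"]


@dataclass
class MotionRecording:
    """90 Hz stream of postures, shoulder positions and trial annotations."""

    df: pd.DataFrame
    trials: list[TrialOutcome]
    phase: str
    meta: dict = field(default_factory=dict)

    @property
    def angles(self) -> np.ndarray:
        return self.df[ANGLE_COLS].to_numpy()

    @property
    def shoulder_positions(self) -> np.ndarray:
        return self.df[["shx", "shy", "shz"]].to_numpy()

    @property
    def mimicked_angles(self) -> np.ndarray | None:
        if MIM_COLS[0] not in self.df.columns:
            return None
        return self.df[MIM_COLS].to_numpy()

    def target_for_trial(self, trial_id: int) -> Target:
        for tr in self.trials:
            if tr.trial_id == trial_id:
                return tr.target
        raise KeyError(f"no trial {trial_id} in recording")


def _target_payload(t: Target) -> dict:
    return {
        "grid_index": list(t.grid_index),
        "position": [float(x) for x in t.position],
        "tilt": t.tilt,
        "role": t.role,
    }


def _target_from_payload(d: dict) -> Target:
    return Target(
        tuple(d["grid_index"]), np.array(d["position"]), d["tilt"], d["role"]
    )


def write_recording(recording: MotionRecording, path: str | Path) -> None:
    """CSV + JSON sidecar (same stem, ``.meta.json``); round-trips to 1e-9."""
    path = Path(path)
    df = recording.df.copy()
    df["in_zone"] = df["in_zone"].astype(int)
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "schema_version": 1,
        "phase": recording.phase,
        "meta": recording.meta,
        "trials": [
            {
                "trial_id": tr.trial_id,
                "target": _target_payload(tr.target),
                "success": bool(tr.success),
                "approach_time": tr.approach_time,
                "end_time": tr.end_time,
                "zone_entered": bool(tr.zone_entered),
                "start_center": [float(x) for x in tr.start_hand_pose.center],
                "start_axis": [float(x) for x in tr.start_hand_pose.axis],
                "hold_span": list(tr.hold_span) if tr.hold_span else None,
            }
            for tr in recording.trials
        ],
    }
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> MotionRecording:
    """Header-driven CSV read; unknown columns are a format error."""
    path = Path(path)
    df = pd.read_csv(path)
    known = set(BASE_COLS) | set(MIM_COLS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown recording columns: {unknown}")
    missing = [c for c in BASE_COLS if c not in df.columns and c != "in_zone"]
    if missing:
        raise ValueError(f"recording missing required columns: {missing}")
    sidecar_path = path.with_suffix(".meta.json")
    if not sidecar_path.exists():
        raise ValueError(f"missing recording sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("schema_version") != 1:
        raise ValueError("unsupported recording schema version")
    trials = [
        TrialOutcome(
            trial_id=d["trial_id"],
            target=_target_from_payload(d["target"]),
            success=d["success"],
            approach_time=d["approach_time"],
            end_time=d["end_time"],
            zone_entered=d["zone_entered"],
            start_hand_pose=HandPose(
                np.array(d["start_center"]), np.array(d["start_axis"])
            ),
            hold_span=tuple(d["hold_span"]) if d["hold_span"] else None,
        )
        for d in sidecar["trials"]
    ]
    df = df[[c for c in BASE_COLS + MIM_COLS if c in df.columns]]
    df["in_zone"] = df["in_zone"].astype(bool) if "in_zone" in df else False
    return MotionRecording(
        df=df, trials=trials, phase=sidecar["phase"], meta=sidecar.get("meta", {})
    )
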