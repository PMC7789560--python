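"""Online performance metrics: approach speed, shoulder spread volume,
and the variability of average reaching postures.

Approach speed (AS) normalizes the approach time (trial start → first
zone entry) by the start-to-target distance; it is defined only for trials
whose zone was entered. The shoulder spread volume (SV) is the volume of
the ellipsoid centered on the mean shoulder position whose semi-axes are
three standard deviations along each principal direction of the shoulder
position covariance; a trivariate normal cloud keeps ≈ 97% of its mass
inside this ellipsoid. Average reaching postures are the per-trial means
of the seven angles over the last in-zone run (the holding period).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import ANGLE_COLS, MIM_COLS, MotionRecording
from .tasks import DT, TrialOutcome


@dataclass
class SpreadResult:
    volume_cm3: float
    coverage: float
    degenerate: bool

    @property
    def volume_dm3(self) -> float:
        return self.volume_cm3 / 1000.0


@dataclass
class ReachingPosture:
    trial_id: int
    group: str  # N | C+ | C- | MC+ | MC-
    angles: np.ndarray  # (7,) mean over the holding period, deg


def approach_speed(trial: TrialOutcome) -> float:
    """cm/s: start-hand-center→target distance over approach time.

    The approach time is floored at one sample period to guard the
    degenerate already-in-zone case. Raises if the zone was never entered:
    the metric assigns no value to such trials.
    """
    if not trial.zone_entered or trial.approach_time is None:
        raise ValueError("approach speed undefined: target zone never entered")
    at = max(trial.approach_time, DT)
    dist_m = float(
        np.linalg.norm(trial.start_hand_pose.center - trial.target.position)
    )
    return 100.0 * dist_m / at


def shoulder_spread_volume(shoulder_positions: np.ndarray) -> SpreadResult:
    """SV (cm³) = 36π σ₁σ₂σ₃ over the principal axes of the position
    covariance (sample covariance, n−1), plus the fraction of samples
    inside the 3-SD ellipsoid. Rotation/translation invariant."""
    p = np.asarray(shoulder_positions, float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 2:
        raise ValueError("need at least two 3-D shoulder samples")
    mean = p.mean(0)
    cov = np.cov(p.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    degenerate = bool((evals <= 1e-18).any())
    sigmas = np.sqrt(evals)
    vol_m3 = 0.0 if degenerate else 36.0 * np.pi * float(np.prod(sigmas))
    # coverage: Mahalanobis distance <= 3 in the principal frame
    if degenerate:
        coverage = float("nan")
    else:
        z = (p - mean) @ evecs / sigmas
        coverage = float(((z**2).sum(1) <= 9.0).mean())
    return SpreadResult(volume_cm3=vol_m3 * 1e6, coverage=coverage,
                        degenerate=degenerate)


def average_reaching_postures(
    recording: MotionRecording,
    outcomes: list[TrialOutcome],
    group: str,
    mimicked: bool = False,
) -> list[ReachingPosture]:
    """One mean posture per zone-entered trial, over the last in-zone run.

    With ``mimicked=True`` the parallel mimicked-angle block is averaged
    instead (groups MC±); its shoulder angles equal the displayed ones.
    """
    cols = MIM_COLS if mimicked else ANGLE_COLS
    if mimicked and MIM_COLS[0] not in recording.df.columns:
        raise ValueError("recording has no mimicked angle block")
    out = []
    trial_ids = recording.df["trial_id"].to_numpy()
    ang = recording.df[cols].to_numpy()
    for tr in outcomes:
        if not tr.zone_entered or tr.hold_span is None:
            continue
        rows = np.flatnonzero(trial_ids == tr.trial_id)
        lo, hi = tr.hold_span
        seg = ang[rows[lo] : rows[lo] + (hi - lo + 1)]
        out.append(
            ReachingPosture(
                trial_id=tr.trial_id, group=group, angles=seg.mean(0)
            )
        )
    return out


def posture_sd(postures: list[ReachingPosture]) -> dict[str, float]:
    """Per-DoF sample SD (deg, n−1) across trials' average postures."""
    if len(postures) < 2:
        raise ValueError("need at least two average reaching postures")
    arr = np.array([p.angles for p in postures])
    sds = arr.std(0, ddof=1)
    return dict(zip(ANGLE_COLS, map(float, sds)))


def tidy_metrics(per_phase: dict[str, dict], subject: int | str) -> "object":
    """Long-format table (subject, phase, metric, trial_id, value) from
    per-phase summaries produced by :func:`phase_metrics`."""
    import pandas as pd

    rows = []
    for phase, pm in per_phase.items():
        for metric, key in (("AT", "per_trial_at_s"), ("AS", "per_trial_as_cm_s")):
            for tid, v in enumerate(pm.get(key, [])):
                rows.append((subject, phase, metric, tid, v))
        for metric in ("sv_cm3", "success_rate", "mean_at_s", "mean_as_cm_s"):
            rows.append((subject, phase, metric, -1, pm[metric]))
    return pd.DataFrame(
        rows, columns=["subject", "phase", "metric", "trial_id", "value"]
    )


def phase_metrics(
    outcomes: list[TrialOutcome], shoulder_positions: np.ndarray, phase: str
) -> dict:
    """Tidy per-phase summary: AT/AS means, SV, success rate."""
    entered = [t for t in outcomes if t.zone_entered]
    ats = [t.approach_time for t in entered]
    ass = [approach_speed(t) for t in entered]
    sv = shoulder_spread_volume(shoulder_positions)
    return {
        "phase": phase,
        "n_trials": len(outcomes),
        "success_rate": float(np.mean([t.success for t in outcomes])),
        "mean_at_s": float(np.mean(ats)) if ats else float("nan"),
        "mean_as_cm_s": float(np.mean(ass)) if ass else float("nan"),
        "sv_cm3": sv.volume_cm3,
        "sv_coverage": sv.coverage,
        "per_trial_at_s": [float(a) for a in ats],
        "per_trial_as_cm_s": [float(a) for a in ass],
    }
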