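"""Targets, target sets, constrained random orders, and the trial lifecycle.

Pick-and-place targets live on a 5 (high) x 5 (wide) x 2 (deep) lattice with
8 cm pitch, roughly centered on the shoulder, each combined with one of five
frontal-plane tilts {-45, -22.5, 0, 22.5, 45} degrees. A task is completed
by holding the hand inside the 6-D target zone (spatial + angular tolerance)
for one second; each trial times out after 15 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .kinematics import ArmGeometry, HandPose, axis_from_tilt

TILTS = (-45.0, -22.5, 0.0, 22.5, 45.0)

SAMPLE_RATE_HZ = 90.0
DT = 1.0 / SAMPLE_RATE_HZ

#: spatial (m) / angular (deg) tolerance pairs
ACQUISITION_TOLERANCE = (0.02, 5.0)
TEST_TOLERANCE = (0.04, 10.0)

#: grid placement relative to the shoulder center: near face anterior offset,
#: and full lateral/vertical half-span (2 * 8 cm)
GRID_SPACING = 0.08
GRID_NEAR_FACE = 0.24


@dataclass(frozen=True)
class Tolerance:
    spatial: float
    angular: float

    def __post_init__(self):
        if self.spatial <= 0 or self.angular <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class Target:
    """Grid position plus frontal-plane tilt, with a pick or place role."""

    grid_index: tuple[int, int, int]  # (col 0-4, row 0-4, depth 0-1)
    position: np.ndarray
    tilt: float
    role: str = "pick"

    def __post_init__(self):
        if self.tilt not in TILTS:
            raise ValueError(f"tilt {self.tilt} not in {TILTS}")
        if self.role not in ("pick", "place"):
            raise ValueError("role must be pick or place")
        object.__setattr__(self, "position", np.asarray(self.position, float))

    @property
    def axis(self) -> np.ndarray:
        return axis_from_tilt(self.tilt)

    def with_role(self, role: str) -> "Target":
        return Target(self.grid_index, self.position, self.tilt, role)


@dataclass(frozen=True)
class TargetSet:
    name: str  # "whole" | "subset"
    targets: tuple[Target, ...]


@dataclass(frozen=True)
class TargetOrder:
    sequence: tuple[Target, ...]
    seed: int


@dataclass
class TrialOutcome:
    trial_id: int
    target: Target
    success: bool
    approach_time: float | None
    end_time: float
    zone_entered: bool
    start_hand_pose: HandPose
    hold_span: tuple[int, int] | None = None  # sample slice of last in-zone run


def build_target_grid(
    geometry: ArmGeometry,
    spacing: float = GRID_SPACING,
    near_face: float = GRID_NEAR_FACE,
) -> dict[tuple[int, int, int], np.ndarray]:
    """The 50 lattice positions, keyed by (col, row, depth) index.

    Column 0 is leftmost (subject's left, +y), row 0 is the top, depth 0 the
    near face. The grid center sits at shoulder height, laterally aligned
    with the shoulder. Raises ``ValueError`` listing any index beyond the
    arm's reach radius.
    """
    sh = geometry.shoulder_home
    positions = {}
    bad = []
    for col in range(5):
        for row in range(5):
            for depth in range(2):
                p = sh + np.array(
                    [
                        near_face + spacing * depth,
                        2 * spacing - spacing * col,
                        2 * spacing - spacing * row,
                    ]
                )
                if np.linalg.norm(p - sh) >= geometry.total_reach:
                    bad.append((col, row, depth))
                positions[(col, row, depth)] = p
    if bad:
        raise ValueError(f"grid positions beyond reach radius: {bad}")
    return positions


def build_target_set(
    grid: dict[tuple[int, int, int], np.ndarray], which: str
) -> TargetSet:
    """All position x tilt combinations ("whole", 250) or the 120-target
    "subset" over the 24 positions retained after dropping the leftmost
    column, rightmost column and lowest row."""
    if which not in ("whole", "subset"):
        raise ValueError("which must be 'whole' or 'subset'")
    targets = []
    for (col, row, depth), pos in sorted(grid.items()):
        if which == "subset" and (col == 0 or col == 4 or row == 4):
            continue
        for tilt in TILTS:
            targets.append(Target((col, row, depth), pos, tilt))
    return TargetSet(which, tuple(targets))


def _neighboring(a: tuple[int, int, int], b: tuple[int, int, int]) -> bool:
    """26-neighborhood on the lattice: all index offsets within 1 (identity
    included — consecutive targets may not repeat a position either)."""
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]), abs(a[2] - b[2])) <= 1


def generate_target_order(
    target_set: TargetSet, min_length: int, seed: int
) -> TargetOrder:
    """Draw targets without replacement, forbidding consecutive targets at
    neighboring grid positions, with strictly alternating pick/place roles.

    A draw that dead-ends before ``min_length`` is regenerated wholesale
    with the next seed; the returned order records the seed that succeeded.
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    if len(target_set.targets) < min_length:
        raise ValueError("target set smaller than the requested minimum order")
    s = int(seed)
    while True:
        rng = np.random.default_rng(s)
        remaining = list(target_set.targets)
        order: list[Target] = []
        while remaining:
            if order:
                last = order[-1].grid_index
                candidates = [
                    i
                    for i, t in enumerate(remaining)
                    if not _neighboring(t.grid_index, last)
                ]
            else:
                candidates = list(range(len(remaining)))
            if not candidates:
                break
            pick = candidates[rng.integers(len(candidates))]
            role = "pick" if len(order) % 2 == 0 else "place"
            order.append(remaining.pop(pick).with_role(role))
        if len(order) >= min_length:
            return TargetOrder(tuple(order), s)
        s += 1


def in_target_zone(hand: HandPose, target: Target, tol: Tolerance) -> bool:
    """True iff the hand center is within the spatial tolerance of the
    target center AND the unsigned angle between hand and target axes is
    within the angular tolerance (closed boundaries)."""
    if np.linalg.norm(hand.center - target.position) > tol.spatial:
        return False
    cosang = abs(float(np.clip(hand.axis @ target.axis, -1.0, 1.0)))
    return np.rad2deg(np.arccos(cosang)) <= tol.angular + 1e-12


def in_zone_batch(
    centers: np.ndarray, axes: np.ndarray, target: Target, tol: Tolerance
) -> np.ndarray:
    """Vectorized zone test over (n, 3) hand centers and axes."""
    d = np.linalg.norm(centers - target.position, axis=1)
    cosang = np.abs(np.clip(axes @ target.axis, -1.0, 1.0))
    ang = np.rad2deg(np.arccos(cosang))
    return (d <= tol.spatial) & (ang <= tol.angular + 1e-12)


class TrialMonitor:
    """Incremental trial-lifecycle logic on the 90 Hz sample grid.

    Feed one in-zone flag per sample; the trial succeeds at the first
    sample for which the zone has been continuously occupied for at least
    ``hold_s`` (span between first and current sample of the run), and
    otherwise ends at ``timeout_s``.
    """

    def __init__(self, hold_s: float = 1.0, timeout_s: float = 15.0, dt: float = DT):
        self.hold_s = hold_s
        self.timeout_s = timeout_s
        self.dt = dt
        self.i = 0
        self.first_entry: int | None = None
        self.run_start: int | None = None
        self.last_run: tuple[int, int] | None = None
        self.done = False
        self.success = False
        self.end_index: int | None = None

    def update(self, in_zone: bool) -> bool:
        """Advance one sample; returns True when the trial has ended."""
        if self.done:
            return True
        if self.i * self.dt >= self.timeout_s - 1e-12:
            self.done = True
            self.end_index = self.i
            self.i += 1
            return True
        if in_zone:
            if self.first_entry is None:
                self.first_entry = self.i
            if self.run_start is None:
                self.run_start = self.i
            self.last_run = (self.run_start, self.i)
            if (self.i - self.run_start) * self.dt >= self.hold_s - 1e-12:
                self.done = True
                self.success = True
                self.end_index = self.i
        else:
            self.run_start = None
        self.i += 1
        return self.done

    def outcome(
        self, trial_id: int, target: Target, start_hand_pose: HandPose
    ) -> TrialOutcome:
        if not self.done:
            # stream exhausted before success or timeout
            self.end_index = self.i - 1
        zone_entered = self.first_entry is not None
        return TrialOutcome(
            trial_id=trial_id,
            target=target,
            success=self.success,
            approach_time=(
                self.first_entry * self.dt if zone_entered else None
            ),
            end_time=(self.end_index if self.end_index is not None else 0) * self.dt,
            zone_entered=zone_entered,
            start_hand_pose=start_hand_pose,
            hold_span=self.last_run,
        )


def run_trial_lifecycle(
    poses: list[HandPose] | tuple[np.ndarray, np.ndarray],
    target: Target,
    tol: Tolerance,
    hold_s: float = 1.0,
    timeout_s: float = 15.0,
    trial_id: int = 0,
) -> TrialOutcome:
    """Evaluate a recorded 90 Hz hand-pose stream against one target.

    ``poses`` is either a list of :class:`HandPose` or a pair of arrays
    (centers (n,3), axes (n,3)). The stream is read from trial start;
    samples after success or timeout are ignored.
    """
    if isinstance(poses, tuple):
        centers, axes = poses
    else:
        if len(poses) == 0:
            raise ValueError("empty hand-pose stream")
        centers = np.array([p.center for p in poses])
        axes = np.array([p.axis for p in poses])
    if len(centers) == 0:
        raise ValueError("empty hand-pose stream")
    flags = in_zone_batch(centers, axes, target, tol)
    mon = TrialMonitor(hold_s, timeout_s)
    for fz in flags:
        if mon.update(bool(fz)):
            break
    return mon.outcome(trial_id, target, HandPose(centers[0], axes[0]))


def order_to_json(order: TargetOrder, spacing: float = GRID_SPACING) -> str:
    payload = {
        "spacing_m": spacing,
        "seed": order.seed,
        "targets": [
            {
                "i": t.grid_index[0],
                "j": t.grid_index[1],
                "k": t.grid_index[2],
                "tilt": t.tilt,
                "role": t.role,
            }
            for t in order.sequence
        ],
    }
    return json.dumps(payload, indent=1)
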