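"""Experiment configuration: arm, grid, tolerances, subjects, phases."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .kinematics import DOF_NAMES, ArmGeometry, DEFAULT_JOINT_LIMITS, JointPosture
from .subject import DEFAULT_COMFORT, SubjectParams
from .tasks import ACQUISITION_TOLERANCE, GRID_NEAR_FACE, GRID_SPACING, TEST_TOLERANCE


@dataclass
class ExperimentConfig:
    """Full description of one simulated experiment.

    ``phase_order`` is derived per subject: subjects with an even index
    run their first test phase with the context-aware network (C+ first),
    odd-index subjects with the context-unaware one, which counterbalances
    the two orders over any even number of subjects.
    """

    n_subjects: int = 2
    subject_seeds: list[int] = field(default_factory=lambda: [101, 202])
    context_coupling: float = 1.0
    motor_noise_sd: float = 1.0
    arm_lengths: tuple[float, float, float] = (0.30, 0.25, 0.08)
    grid_near_face: float = GRID_NEAR_FACE
    grid_spacing: float = GRID_SPACING
    acquisition_tolerance: tuple[float, float] = ACQUISITION_TOLERANCE
    test_tolerance: tuple[float, float] = TEST_TOLERANCE
    min_order_whole: int = 200
    min_order_subset: int = 100
    # optional truncation of the generated orders (a constrained draw runs
    # until it dead-ends, ~250/~118 trials; caps give reduced-scale runs)
    order_cap_whole: int | None = None
    order_cap_subset: int | None = None
    comfort_posture: tuple = tuple(DEFAULT_COMFORT.as_array())
    joint_limits: dict = field(default_factory=lambda: dict(DEFAULT_JOINT_LIMITS))
    # predictor hyperparameters
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 150
    patience: int = 15
    max_train_rows: int | None = 6000
    master_seed: int = 0
    output_dir: str = "runs"

    def __post_init__(self):
        if len(self.subject_seeds) != self.n_subjects:
            raise ValueError("need one seed per subject")

    def geometry(self) -> ArmGeometry:
        u, f, h = self.arm_lengths
        return ArmGeometry(u, f, h)

    def subject(self, index: int) -> SubjectParams:
        return SubjectParams(
            comfort_posture=JointPosture.from_array(np.array(self.comfort_posture)),
            context_coupling=self.context_coupling,
            motor_noise_sd=self.motor_noise_sd,
            seed=self.subject_seeds[index],
        )

    def cplus_first(self, index: int) -> bool:
        return index % 2 == 0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["comfort_posture"] = dict(zip(DOF_NAMES, map(float, self.comfort_posture)))
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        if isinstance(d.get("comfort_posture"), dict):
            d["comfort_posture"] = tuple(
                d["comfort_posture"][n] for n in DOF_NAMES
            )
        for key in ("arm_lengths", "acquisition_tolerance", "test_tolerance"):
            if key in d:
                d[key] = tuple(d[key])
        d["joint_limits"] = {
            k: tuple(v) for k, v in d.get("joint_limits", DEFAULT_JOINT_LIMITS).items()
        }
        return cls(**d)


def toy_config(master_seed: int = 0) -> ExperimentConfig:
    """Two-subject reduced-scale configuration for fast end-to-end runs."""
    return ExperimentConfig(
        n_subjects=2,
        subject_seeds=[101, 202],
        min_order_whole=15,
        min_order_subset=6,
        order_cap_whole=15,
        order_cap_subset=6,
        max_epochs=30,
        patience=8,
        max_train_rows=1500,
        master_seed=master_seed,
    )
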