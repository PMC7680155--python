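"""Experiment design: reference line, stimulus grid, prior support.

The task this package models is an orientation-identification experiment in
which a target line is shown together with a known reference line tilted at
``R`` degrees (45° by default).  All inference happens on the *cognitive
angle* ``alpha = theta - R``, the signed angle between target and reference.
Angles are linear quantities in degrees throughout: the stimulus range never
approaches the circular wrap-around, so no modular arithmetic is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExperimentDesign",
    "DEFAULT_STIMULUS_GRID",
    "DEFAULT_LEARNING_REPS",
    "cognitive_angle",
    "theta_from_angle",
]

#: The 25 target orientations of the reference condition: every 2° from 22°
#: to 68°, plus the reference orientation 45° itself.
DEFAULT_STIMULUS_GRID: tuple[float, ...] = tuple(
    float(t) for t in (*range(22, 45, 2), 45, *range(46, 69, 2))
)

#: Repetitions per stimulus in the feedback (learning) phase.
DEFAULT_LEARNING_REPS = 16


@dataclass(frozen=True)
class ExperimentDesign:
    """Geometry and sampling plan of the identification experiment.

    Parameters
    ----------
    reference_deg : float
        Orientation ``R`` of the known reference line, degrees.
    stimulus_grid : tuple of float
        Ordered target orientations shown to the observer, degrees.
    alpha_min, alpha_max : float
        Support bounds of the uniform prior over the cognitive angle,
        degrees relative to the reference.
    reps_per_stimulus : int
        Repetitions of each stimulus in the (no-feedback) estimating phase.
        The default, 32, gives 25 x 32 = 800 trials per subject.
    """

    reference_deg: float = 45.0
    stimulus_grid: tuple[float, ...] = field(default=DEFAULT_STIMULUS_GRID)
    alpha_min: float = -23.0
    alpha_max: float = 23.0
    reps_per_stimulus: int = 32

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimulus_grid", tuple(float(t) for t in self.stimulus_grid))
        if not self.alpha_min < self.alpha_max:
            raise ValueError(
                f"alpha_min ({self.alpha_min}) must be < alpha_max ({self.alpha_max})"
            )
        if self.reps_per_stimulus < 1:
            raise ValueError("reps_per_stimulus must be >= 1")
        for theta in self.stimulus_grid:
            a = theta - self.reference_deg
            if not (self.alpha_min <= a <= self.alpha_max):
                raise ValueError(
                    f"stimulus {theta}° lies outside the prior support "
                    f"[{self.reference_deg + self.alpha_min}, "
                    f"{self.reference_deg + self.alpha_max}]°"
                )

    @property
    def theta_min(self) -> float:
        """Smallest orientation any estimate can take, ``R + alpha_min``."""
        return self.reference_deg + self.alpha_min

    @property
    def theta_max(self) -> float:
        """Largest orientation any estimate can take, ``R + alpha_max``."""
        return self.reference_deg + self.alpha_max

    def angles(self) -> np.ndarray:
        """Cognitive angles of the stimulus grid, ``theta - R``."""
        return np.asarray(self.stimulus_grid) - self.reference_deg

    # -- plain key/value serialization ------------------------------------
    def to_dict(self) -> dict:
        return {
            "reference_deg": self.reference_deg,
            "stimulus_grid": list(self.stimulus_grid),
            "alpha_min": self.alpha_min,
            "alpha_max": self.alpha_max,
            "reps_per_stimulus": self.reps_per_stimulus,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls(
            reference_deg=float(d["reference_deg"]),
            stimulus_grid=tuple(float(t) for t in d["stimulus_grid"]),
            alpha_min=float(d["alpha_min"]),
            alpha_max=float(d["alpha_max"]),
            reps_per_stimulus=int(d.get("reps_per_stimulus", 32)),
        )


def cognitive_angle(theta, design: ExperimentDesign):
    """Signed angle between target and reference, ``alpha = theta - R``."""
    return np.asarray(theta, dtype=float) - design.reference_deg


def theta_from_angle(alpha, design: ExperimentDesign):
    """Inverse of :func:`cognitive_angle`: ``theta = R + alpha``."""
    return design.reference_deg + np.asarray(alpha, dtype=float)
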