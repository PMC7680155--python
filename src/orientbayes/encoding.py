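"""Sensory encoding stage: the measurement distribution p(alpha_m | alpha).

The observer never sees the cognitive angle ``alpha`` directly; sensory
noise turns it into an internal measurement ``alpha_m``, modeled as Gaussian
with mean ``alpha``.  Two precision patterns are supported:

* **EP** (equal precision): constant SD ``lam`` for every stimulus.
* **VP** (variable precision, scalar variability): SD grows linearly with
  the angle magnitude, ``lam * |alpha|``, with ``lam`` the Weber fraction.
  At ``alpha = 0`` (target on the reference line) the measurement is exact.

Measurements are real-valued; rounding to integer degrees only happens when
responses are reported or binned for the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._seeding import KEY_MEASUREMENT, rng_for, stimulus_key

__all__ = [
    "EncodingModel",
    "DegenerateEncodingError",
    "measurement_sd",
    "measurement_density",
    "draw_measurements",
]

PATTERNS = ("EP", "VP")


class DegenerateEncodingError(ValueError):
    """Raised when a density is requested where the measurement SD is 0.

    Happens only for VP encoding at ``alpha = 0``: the measurement
    distribution is a point mass at 0 and has no density.  Callers must
    special-case this (draws return exact zeros; decoders return the
    reference).
    """


@dataclass(frozen=True)
class EncodingModel:
    """Precision pattern plus its single noise parameter.

    ``lam`` is the measurement SD in degrees under EP, and the dimensionless
    Weber fraction under VP.
    """

    pattern: str
    lam: float

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")


def measurement_sd(alpha, enc: EncodingModel):
    """SD of the measurement distribution at cognitive angle ``alpha``.

    Vectorized; returns a scalar for scalar input.
    """
    alpha = np.asarray(alpha, dtype=float)
    if enc.pattern == "EP":
        out = np.broadcast_to(np.float64(enc.lam), alpha.shape).copy()
    else:
        out = enc.lam * np.abs(alpha)
    return out if out.ndim else float(out)


def measurement_density(alpha_m, alpha, enc: EncodingModel):
    """Gaussian density of measurement ``alpha_m`` given true angle ``alpha``."""
    sd = measurement_sd(alpha, enc)
    if np.any(np.asarray(sd) == 0.0):
        raise DegenerateEncodingError(
            "measurement SD is 0 (VP encoding at alpha=0); the measurement "
            "distribution is a point mass and has no density"
        )
    out = stats.norm.pdf(np.asarray(alpha_m, dtype=float), loc=alpha, scale=sd)
    return out if np.ndim(out) else float(out)


def draw_measurements(alpha, enc: EncodingModel, n: int, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` measurements of a single cognitive angle.

    VP at ``alpha = 0`` returns exact zeros (the degenerate point mass).
    With a ``seed``, the stream is derived from (seed, alpha) so the same
    stimulus always gets the same draws regardless of evaluation order.
    The draws are ``alpha + sd * z`` with ``z`` standard normal, so under a
    fixed seed they are common random numbers across noise levels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    alpha = float(alpha)
    sd = float(measurement_sd(alpha, enc))
    if rng is None:
        rng = rng_for(0 if seed is None else seed, KEY_MEASUREMENT, stimulus_key(alpha))
    z = rng.standard_normal(int(n))
    return alpha + sd * z
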