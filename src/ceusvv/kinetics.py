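"""Destruction–replenishment kinetics of microbubble contrast.

After a high-energy destruction pulse clears microbubbles from the imaging
plane, tissue video-intensity recovers as fresh bubbles wash in.  The
standard model for this replenishment is a mono-exponential rise

    I(t) = I0 + A * (1 - exp(-beta * (t - t0)))    for t >= t0,

where ``I0`` is the pre-contrast baseline intensity, ``A`` the plateau
enhancement (proportional to fractional vascular volume), ``beta`` the
replenishment rate (proportional to flow velocity) and ``t0`` the time of
the destruction pulse.  Before ``t0`` the intensity sits at baseline.

Intensities are on the linear 8-bit video scale (0–255).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = ["KineticsParams", "replenishment_intensity"]


@dataclass(frozen=True)
class KineticsParams:
    """Parameters of the mono-exponential replenishment curve.

    Attributes
    ----------
    baseline:
        Pre-contrast video-intensity ``I0`` (0–255 scale), >= 0.
    amplitude:
        Plateau enhancement ``A`` in video-intensity units, >= 0.
    rate:
        Replenishment rate ``beta`` in 1/s, strictly positive.
    onset_time:
        Time ``t0`` of the destruction pulse (start of replenishment), s.
    """

    baseline: float
    amplitude: float
    rate: float
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise InvalidParameterError("baseline must be >= 0")
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be >= 0")
        if not self.rate > 0:
            raise InvalidParameterError("rate must be > 0")
        if self.onset_time < 0:
            raise InvalidParameterError("onset_time must be >= 0")

    @property
    def plateau(self) -> float:
        """Supremum of the curve, ``baseline + amplitude``."""
        return self.baseline + self.amplitude


def replenishment_intensity(params: KineticsParams, t):
    """Evaluate the replenishment curve at time(s) ``t`` (seconds).

    Returns ``baseline`` for ``t < onset_time`` and
    ``baseline + amplitude * (1 - exp(-rate * (t - onset_time)))`` after the
    destruction pulse.  The curve is monotone non-decreasing and bounded by
    ``baseline + amplitude``.

    ``t`` may be a scalar or array; negative times are rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("time must be >= 0")
    dt = np.maximum(t_arr - params.onset_time, 0.0)
    # -expm1(-x) = 1 - exp(-x), accurate for small x
    out = params.baseline + params.amplitude * (-np.expm1(-params.rate * dt))
    if np.ndim(t) == 0:
        return float(out)
    return out
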