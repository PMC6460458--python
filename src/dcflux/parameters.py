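"""Core parameter types for the skin -> draining-lymph-node trafficking model.

The model tracks a cohort of photoconverted (red-Kaede) dendritic cells:
cells present in the footpad at the photoconversion time leave the skin with
a per-cell migration hazard ``mu(t)``, spend a fixed transit time ``tau`` in
the lymphatics, and are then removed from the draining lymph node (dLN) by a
first-order loss rate ``delta`` that conflates death and egress.

Under saline (steady state) the migration hazard is constant, ``mu0``.
Under alum/LPS it carries an inflammatory pulse::

    mu_alum(t) = mu0 + alpha * t * exp(-m * t)

with ``t`` in hours post-injection. The pulse peaks at ``t = 1/m`` with
fold-change ``1 + alpha * exp(-1) / (m * mu0)`` over baseline.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass


class Condition(str, enum.Enum):
    """Treatment arm of a photoconversion experiment."""

    ALUM = "alum"
    SALINE = "saline"

    @classmethod
    def coerce(cls, value: "Condition | str") -> "Condition":
        if isinstance(value, Condition):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"condition must be one of {[c.value for c in cls]}, got {value!r}"
            ) from None


@dataclass(frozen=True)
class RateParameters:
    """Rates and times governing the two-site trafficking model.

    Parameters
    ----------
    mu0 : float
        Basal skin egress (migration) hazard, per hour. Strictly positive;
        its reciprocal is the mean skin residence time at steady state.
    alpha : float
        Amplitude of the inflammatory migration pulse, per hour^2.
        ``alpha = 0`` collapses the alum hazard onto the saline hazard.
    m : float
        Decay constant of the inflammatory pulse, per hour. The alum hazard
        peaks at ``1/m`` hours post-injection.
    tau : float
        Fixed lymphatic transit delay between skin egress and dLN arrival,
        hours.
    delta_alum : float
        First-order dLN loss rate (death + egress) under alum/LPS, per hour.
    delta_saline : float
        First-order dLN loss rate under saline, per hour.
    """

    mu0: float
    alpha: float
    m: float
    tau: float
    delta_alum: float
    delta_saline: float

    def __post_init__(self) -> None:
        if not self.mu0 > 0:
            raise ValueError(f"mu0 must be > 0, got {self.mu0}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.m < 0:
            raise ValueError(f"m must be >= 0, got {self.m}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        for name in ("delta_alum", "delta_saline"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        for name in ("mu0", "alpha", "m", "tau", "delta_alum", "delta_saline"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def delta(self, condition: Condition | str) -> float:
        """dLN loss rate for the given condition, per hour."""
        condition = Condition.coerce(condition)
        return self.delta_alum if condition is Condition.ALUM else self.delta_saline

    def replace(self, **changes: float) -> "RateParameters":
        from dataclasses import replace

        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {
            "mu0": self.mu0,
            "alpha": self.alpha,
            "m": self.m,
            "tau": self.tau,
            "delta_alum": self.delta_alum,
            "delta_saline": self.delta_saline,
        }


@dataclass(frozen=True)
class SkinPoolState:
    """Photoconverted skin pool at the moment of photoconversion.

    ``x0`` cells carry the red label at ``t_pc`` hours post-injection; only
    these cells are tracked downstream (later arrivals in skin are green and
    invisible to the model).
    """

    x0: float
    t_pc: float

    def __post_init__(self) -> None:
        if self.x0 < 0:
            raise ValueError(f"x0 must be >= 0, got {self.x0}")
        if self.t_pc < 0:
            raise ValueError(f"t_pc must be >= 0, got {self.t_pc}")
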