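"""Photoconversion experiment designs.

A design is one photoswitching strategy: which footpad treatment, when the
violet-light photoconversion happened, and when skin and draining-lymph-node
(dLN) harvests were taken. ``study_designs`` reproduces the three schedule
families used in the Kaede footpad experiments this model was developed for;
``dense_designs`` is a finer schedule used for transit-time identifiability
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import Condition

SITES = ("skin", "dln")


@dataclass(frozen=True)
class PhotoconversionDesign:
    """One photoswitching strategy.

    Times are hours post-injection (a single clock: injection at t = 0).
    """

    condition: Condition
    t_pc: float
    harvest_times: tuple[float, ...]
    n_replicates: int = 4
    sites: tuple[str, ...] = SITES
    design_id: str = field(default="")

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition.coerce(self.condition))
        object.__setattr__(self, "harvest_times", tuple(float(t) for t in self.harvest_times))
        object.__setattr__(self, "sites", tuple(self.sites))
        if self.t_pc < 0:
            raise ValueError("t_pc must be >= 0")
        if not self.harvest_times:
            raise ValueError("harvest_times must be non-empty")
        if min(self.harvest_times) < self.t_pc:
            raise ValueError("every harvest time must be >= t_pc")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.sites or not set(self.sites) <= set(SITES):
            raise ValueError(f"sites must be a non-empty subset of {SITES}")
        if not self.design_id:
            object.__setattr__(
                self,
                "design_id",
                f"{self.condition.value}-tpc{self.t_pc:g}-"
                + "h" + "-".join(f"{t:g}" for t in self.harvest_times),
            )


def study_designs(n_replicates: int = 4) -> list[PhotoconversionDesign]:
    """The three photoswitch/harvest schedule families, for both conditions.

    * delayed-switch: photoconvert at 0, 4, 8 or 12 h; harvest 24 and 48 h.
    * fixed-switch: photoconvert at 12 h; harvest 24, 36, 48 and 72 h.
    * sliding-switch: photoconvert at 12, 24, 36 or 60 h; harvest 12 h later.

    All designs measure both skin and dLN with ``n_replicates`` mice.
    """
    designs: list[PhotoconversionDesign] = []
    for cond in (Condition.ALUM, Condition.SALINE):
        c = cond.value
        for t_pc in (0.0, 4.0, 8.0, 12.0):
            designs.append(
                PhotoconversionDesign(
                    cond, t_pc, (24.0, 48.0), n_replicates,
                    design_id=f"{c}-delayed-tpc{t_pc:02.0f}",
                )
            )
        designs.append(
            PhotoconversionDesign(
                cond, 12.0, (24.0, 36.0, 48.0, 72.0), n_replicates,
                design_id=f"{c}-fixed-tpc12",
            )
        )
        for t_pc in (12.0, 24.0, 36.0, 60.0):
            designs.append(
                PhotoconversionDesign(
                    cond, t_pc, (t_pc + 12.0,), n_replicates,
                    design_id=f"{c}-sliding-tpc{t_pc:02.0f}",
                )
            )
    return designs


def dense_designs(
    t_pc: float = 12.0,
    spacing: float = 2.0,
    span: float = 24.0,
    n_replicates: int = 4,
) -> list[PhotoconversionDesign]:
    """Dense-harvest designs: both sites every ``spacing`` h from ``t_pc`` to
    ``t_pc + span``, both conditions.

    The short inter-harvest interval makes the lymphatic transit delay tau
    identifiable, unlike the sparse schedules of ``study_designs``.
    """
    n = int(round(span / spacing))
    harvests = tuple(t_pc + spacing * i for i in range(n + 1))
    return [
        PhotoconversionDesign(
            cond, t_pc, harvests, n_replicates,
            design_id=f"{cond.value}-dense-tpc{t_pc:g}",
        )
        for cond in (Condition.ALUM, Condition.SALINE)
    ]
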