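"""Hemithioacetal (HA) equilibrium model for GLYI assay design.

Methylglyoxal (MG) and reduced glutathione (GSH) condense spontaneously
and reversibly into the hemithioacetal, the true GLYI substrate.  At
equilibrium the dissociation constant

    Kdiss = [GSH_free] * [MG_free] / [HA]       (default 3.0 mM)

together with the mass balances [HA] + [MG_free] = MG_total and
[HA] + [GSH_free] = GSH_total determines all species.  The forward solve
reduces to a quadratic in [HA]; the inverse problem (choose totals that
give a target [HA] at a fixed free-GSH level, as done when building
substrate series for kinetics) is closed-form.

All concentrations are in mM end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DEFAULT_KDISS", "EquilibriumState", "solve_hemithioacetal",
           "design_assay"]

DEFAULT_KDISS = 3.0   # mM


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium composition of an MG/GSH mixture (all fields in mM)."""

    mg_total: float
    gsh_total: float
    kdiss: float
    ha: float
    mg_free: float
    gsh_free: float

    def __post_init__(self) -> None:
        for name in ("mg_total", "gsh_total", "kdiss", "ha", "mg_free", "gsh_free"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.ha > min(self.mg_total, self.gsh_total) * (1 + 1e-12) + 1e-15:
            raise ValueError("HA exceeds a total concentration")
        scale = max(self.mg_total, self.gsh_total, self.kdiss, 1.0)
        if abs(self.ha + self.mg_free - self.mg_total) > 1e-9 * scale:
            raise ValueError("MG mass balance violated")
        if abs(self.ha + self.gsh_free - self.gsh_total) > 1e-9 * scale:
            raise ValueError("GSH mass balance violated")
        if self.ha > 0 and abs(
            self.gsh_free * self.mg_free - self.kdiss * self.ha
        ) > 1e-9 * scale * scale:
            raise ValueError("equilibrium condition violated")


def solve_hemithioacetal(mg_total: float, gsh_total: float,
                         kdiss: float = DEFAULT_KDISS) -> EquilibriumState:
    """Equilibrium species from total MG and GSH concentrations.

    [HA] is the smaller root of
    x**2 - (MG_t + GSH_t + Kdiss) x + MG_t * GSH_t = 0, computed in the
    cancellation-free form 2*MG_t*GSH_t / (b + sqrt(b**2 - 4*MG_t*GSH_t))
    so that Kdiss >> totals stays accurate.  Free species follow from mass
    balance (not from the quadratic a second time).
    """
    if mg_total < 0 or gsh_total < 0:
        raise ValueError("total concentrations must be nonnegative")
    if kdiss <= 0:
        raise ValueError("kdiss must be positive")
    prod = mg_total * gsh_total
    if prod == 0.0:
        ha = 0.0
    else:
        b = mg_total + gsh_total + kdiss
        disc = b * b - 4.0 * prod
        ha = 2.0 * prod / (b + math.sqrt(disc))
    # the larger root would exceed min(totals); assert rather than assume
    assert ha <= min(mg_total, gsh_total) + 1e-12 * max(mg_total, gsh_total, 1.0)
    return EquilibriumState(
        mg_total=mg_total,
        gsh_total=gsh_total,
        kdiss=kdiss,
        ha=ha,
        mg_free=mg_total - ha,
        gsh_free=gsh_total - ha,
    )


def design_assay(ha_target: float, gsh_free_target: float,
                 kdiss: float = DEFAULT_KDISS) -> tuple[float, float]:
    """Total MG and GSH that equilibrate to a target [HA] at fixed free GSH.

    Inverse of the equilibrium: MG_free = Kdiss * HA / GSH_free, then
    totals by mass balance.  Used to build substrate series in which the
    inhibitory free GSH is held constant (e.g. 0.2 mM) while [HA] varies.
    """
    if ha_target < 0:
        raise ValueError("ha_target must be nonnegative")
    if gsh_free_target <= 0:
        if ha_target > 0:
            raise ValueError("infeasible: HA > 0 requires free GSH > 0")
        return 0.0, max(gsh_free_target, 0.0)
    if kdiss <= 0:
        raise ValueError("kdiss must be positive")
    mg_free = kdiss * ha_target / gsh_free_target
    return mg_free + ha_target, gsh_free_target + ha_target
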