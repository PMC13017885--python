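"""Respiratory carbon costs: maintenance (with the explicit defense
term), growth, and an itemized process-sum accounting mode.

Maintenance respiration per organ and day is

    R_maintenance = R_basal + D x C_defense
    R_basal       = m_base(kind) x structural_mass x f_T

where D is the organ's defense coefficient, C_defense the respiratory
cost of full defense activation per unit mass, and f_T a Q10 temperature
factor.  Writing the defense burden as its own term keeps defense
energetics out of the generic maintenance catch-all.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RespirationParams
from .state import OrganState


def temperature_factor(t: float, t_ref: float = 25.0, q10: float = 2.0) -> float:
    """Q10 scaling: q10 ** ((t - t_ref) / 10)."""
    return q10 ** ((t - t_ref) / 10.0)


@dataclass
class MaintenanceDemand:
    basal: float  # g C d-1
    defense: float  # g C d-1

    @property
    def total(self) -> float:
        return self.basal + self.defense


def maintenance_respiration(
    organ: OrganState, t: float, params: RespirationParams
) -> MaintenanceDemand:
    """Daily maintenance carbon demand of one organ, split into the basal
    term and the defense-activation term (affine in the defense
    coefficient with slope c_defense x mass)."""
    f_t = temperature_factor(t, params.t_ref, params.q10)
    basal = params.m_base[organ.kind] * organ.structural_mass * f_t
    defense = organ.d_coef * params.c_defense * organ.structural_mass
    return MaintenanceDemand(basal=basal, defense=defense)


def growth_respiration(
    delta_mass: float, c_per_g_dm: float, growth_yield: float
) -> float:
    """Carbon respired while building ``delta_mass`` g of structure:
    c_per_g_dm x delta_mass x (1 - Yg) / Yg.  Yg = 1 is lossless."""
    if delta_mass < 0:
        raise ValueError("delta_mass must be >= 0")
    return c_per_g_dm * delta_mass * (1.0 - growth_yield) / growth_yield


def process_sum_respiration(
    activities: dict[str, float], params: RespirationParams
) -> float:
    """Itemized accounting mode: sum of activity x metabolic cost over
    processes.  Every listed process must have a configured cost."""
    total = 0.0
    for process, activity in activities.items():
        if process not in params.process_costs:
            raise KeyError(f"no metabolic cost configured for process '{process}'")
        total += activity * params.process_costs[process]
    return total
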