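"""Root nitrate uptake: high-affinity (Michaelis-Menten) and low-affinity
(linear) transport systems, regulated by root carbon status.

Soil nitrate is an exogenous, non-limiting driver: uptake removes nothing
from a soil budget.  The carbon-status regulation is a bounded saturating
factor f_C = f_min + (1 - f_min) c / (K + c) of the root labile-C
concentration; with f_min = 1 regulation is disabled.
"""

from __future__ import annotations

from .config import NitrogenUptakeParams
from .state import OrganKind, OrganState


def hats_rate(no3: float, vmax_hats: float, km_hats: float) -> float:
    """High-affinity transport: vmax * no3 / (km + no3), g N g-1 root d-1."""
    if no3 < 0:
        raise ValueError("no3 must be >= 0")
    return vmax_hats * no3 / (km_hats + no3)


def lats_rate(no3: float, k_lats: float, threshold: float = 0.0) -> float:
    """Low-affinity transport: linear in nitrate above an optional
    activation threshold (default 0: the linear form already vanishes at
    low concentration)."""
    if no3 < 0:
        raise ValueError("no3 must be >= 0")
    return k_lats * max(no3 - threshold, 0.0)


def carbon_regulation_factor(
    c_concentration: float, c_reg_k: float, f_min: float
) -> float:
    """Saturating regulation of uptake by root labile carbon, in [f_min, 1)."""
    if c_concentration < 0:
        raise ValueError("carbon concentration must be >= 0")
    return f_min + (1.0 - f_min) * c_concentration / (c_reg_k + c_concentration)


def organ_nitrogen_uptake(
    root: OrganState,
    soil_no3: float,
    params: NitrogenUptakeParams,
    downregulation: float = 0.0,
) -> float:
    """Daily plant-level nitrate uptake, g N d-1.

    (HATS + LATS) x f_C x root structural mass x (1 - downregulation).
    A massless root takes up nothing.
    """
    if root.kind is not OrganKind.ROOTS:
        raise ValueError("nitrogen uptake is computed for the root compartment only")
    if root.structural_mass <= 0.0:
        return 0.0
    rate = hats_rate(soil_no3, params.vmax_hats, params.km_hats) + lats_rate(
        soil_no3, params.k_lats, params.lats_threshold
    )
    if params.regulation:
        c_conc = root.c_store / root.structural_mass
        f_c = carbon_regulation_factor(c_conc, params.c_reg_k, params.f_min)
    else:
        f_c = 1.0
    f_down = 1.0 - min(max(downregulation, 0.0), 1.0)
    return rate * f_c * root.structural_mass * f_down
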