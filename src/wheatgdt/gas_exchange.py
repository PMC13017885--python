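"""Leaf gas exchange: FvCB biochemistry coupled to Ball-Woodrow-Berry
stomatal conductance.

Net assimilation is the minimum of the Rubisco-limited, electron-
transport-limited and triose-phosphate-limited rates minus day
respiration, with every kinetic parameter scaled from its 25 degC value
by an Arrhenius function.  The intercellular CO2 concentration Ci is
found by bisection on the coupled assimilation/diffusion system

    A = A_net(Ci)          (biochemistry)
    Ci = Ca - 1.6 A / gs   (diffusion through stomata)
    gs = g0 + g1 max(A,0) hs / Cs   (BWB, Cs = Ca, hs = air RH)

Boundary-layer conductance is omitted and the temperature response is a
simple (non-peaked) Arrhenius form; both are documented limitations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import GasExchangeParams

R_GAS = 8.314  # J mol-1 K-1
T_REF_K = 298.15  # 25 degC reference in kelvin

RUBISCO = "rubisco"
ELECTRON_TRANSPORT = "electron_transport"
TPU = "tpu"
DARK = "dark"


class GasExchangeError(RuntimeError):
    pass


def arrhenius_scale(p25: float, ea: float, t_leaf: float) -> float:
    """Scale a 25 degC parameter to leaf temperature ``t_leaf`` (degC)."""
    if t_leaf <= -273.15:
        raise ValueError("t_leaf below absolute zero")
    t_k = t_leaf + 273.15
    return p25 * math.exp(ea * (t_k - T_REF_K) / (T_REF_K * R_GAS * t_k))


def electron_transport(par: float, jmax: float, alpha: float, theta: float) -> float:
    """Potential electron transport rate J from the non-rectangular hyperbola.

    Smaller root of theta J^2 - (alpha I + Jmax) J + alpha I Jmax = 0;
    the theta = 0 limit is the rectangular hyperbola.
    """
    if par < 0:
        raise ValueError("par must be >= 0")
    i = alpha * par
    if i <= 0.0 or jmax <= 0.0:
        return 0.0
    if theta == 0.0:
        return i * jmax / (i + jmax)
    b = i + jmax
    disc = b * b - 4.0 * theta * i * jmax
    return (b - math.sqrt(max(disc, 0.0))) / (2.0 * theta)


@dataclass
class ScaledParams:
    vcmax: float
    jmax: float
    tpu: float
    rd: float
    kc: float
    ko: float
    gamma_star: float


def scale_params(
    params: GasExchangeParams, t_leaf: float, downregulation: float = 0.0
) -> ScaledParams:
    """Arrhenius-scale all kinetic parameters; source downregulation scales
    the three capacity parameters (Vcmax, Jmax, TPU) by (1 - downregulation)."""
    f = 1.0 - min(max(downregulation, 0.0), 1.0)
    ea = params.ea
    return ScaledParams(
        vcmax=f * arrhenius_scale(params.vcmax25, ea.vcmax, t_leaf),
        jmax=f * arrhenius_scale(params.jmax25, ea.jmax, t_leaf),
        tpu=f * arrhenius_scale(params.tpu25, ea.tpu, t_leaf),
        rd=arrhenius_scale(params.rd25, ea.rd, t_leaf),
        kc=arrhenius_scale(params.kc25, ea.kc, t_leaf),
        ko=arrhenius_scale(params.ko25, ea.ko, t_leaf),
        gamma_star=arrhenius_scale(params.gamma_star25, ea.gamma_star, t_leaf),
    )


def net_assimilation_at_ci(
    ci: float,
    par: float,
    t_leaf: float,
    params: GasExchangeParams,
    downregulation: float = 0.0,
) -> tuple[float, str]:
    """Net assimilation (umol CO2 m-2 s-1) at a given intercellular CO2.

    Returns ``(a_net, limitation)`` where the limitation labels the
    minimum of the three gross rates (``dark`` when PAR is zero).
    """
    if ci <= 0:
        raise ValueError("ci must be > 0")
    sp = scale_params(params, t_leaf, downregulation)
    ac = sp.vcmax * (ci - sp.gamma_star) / (ci + sp.kc * (1.0 + params.o2 / sp.ko))
    j = electron_transport(par, sp.jmax, params.alpha, params.theta)
    aj = j * (ci - sp.gamma_star) / (4.0 * ci + 8.0 * sp.gamma_star)
    ap = 3.0 * sp.tpu
    rates = {RUBISCO: ac, ELECTRON_TRANSPORT: aj, TPU: ap}
    limitation = min(rates, key=rates.get)
    a_net = rates[limitation] - sp.rd
    if par <= 0.0:
        limitation = DARK
    return a_net, limitation


def stomatal_conductance(
    a_net: float, rel_humidity: float, cs: float, g0: float, g1: float
) -> float:
    """BWB conductance, clamped to g0 for non-positive assimilation
    (the raw linear form would drop below g0 at night)."""
    if cs <= 0:
        raise ValueError("cs must be > 0")
    if not (0.0 <= rel_humidity <= 1.0):
        raise ValueError("rel_humidity must lie in [0, 1]")
    return g0 + g1 * max(a_net, 0.0) * rel_humidity / cs


@dataclass
class GasExchangeResult:
    a_net: float  # umol CO2 m-2 s-1
    gs: float  # mol m-2 s-1 (CO2 basis)
    ci: float  # umol mol-1
    e_transp: float  # mmol H2O m-2 s-1
    limitation: str


def _saturation_vapor_pressure(t: float) -> float:
    """kPa, Tetens form."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def _transpiration(gs: float, t_leaf: float, rel_humidity: float) -> float:
    """Water flux through stomata: E = 1.6 gs VPD / P, in mmol m-2 s-1."""
    vpd = _saturation_vapor_pressure(t_leaf) * (1.0 - rel_humidity)
    return 1.6 * gs * vpd / 101.3 * 1000.0


def solve_gas_exchange(
    par: float,
    t_leaf: float,
    rel_humidity: float,
    ca: float,
    params: GasExchangeParams,
    downregulation: float = 0.0,
    ci_tol: float = 1e-6,
) -> GasExchangeResult:
    """Solve the coupled FvCB/BWB system for one leaf and one day.

    Bisection on Ci between just above the (scaled) CO2 compensation point
    and ``ca + 1.6 Rd / g0`` (the dark solution exceeds Ca, so the bracket
    extends past ambient).  Falls back to the closed-form dark solution
    when PAR is zero.
    """
    sp = scale_params(params, t_leaf, downregulation)
    g0, g1 = params.g0, params.g1
    if g0 <= 0:
        raise GasExchangeError("g0 must be > 0 to define the dark/negative-A solution")

    def dark_result() -> GasExchangeResult:
        a = -sp.rd
        gs = g0
        ci = ca - 1.6 * a / gs
        return GasExchangeResult(a, gs, ci, _transpiration(gs, t_leaf, rel_humidity), DARK)

    if par <= 0.0:
        return dark_result()

    def residual(ci: float) -> tuple[float, float, float, str]:
        a, lim = net_assimilation_at_ci(ci, par, t_leaf, params, downregulation)
        gs = stomatal_conductance(a, rel_humidity, ca, g0, g1)
        return ca - 1.6 * a / gs - ci, a, gs, lim

    lo = sp.gamma_star * (1.0 + 1e-9) + 1e-12
    hi = ca + 1.6 * sp.rd / g0 + 1.0
    f_lo = residual(lo)[0]
    f_hi = residual(hi)[0]
    if f_lo < 0.0 or f_hi > 0.0:
        raise GasExchangeError(
            f"no sign change on the Ci bracket [{lo:.3f}, {hi:.3f}] "
            f"(f_lo={f_lo:.3e}, f_hi={f_hi:.3e})"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = residual(mid)[0]
        if f_mid > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < ci_tol:
            break
    ci = 0.5 * (lo + hi)
    _, a, gs, lim = residual(ci)
    if not (math.isfinite(a) and math.isfinite(gs) and math.isfinite(ci)):
        raise GasExchangeError("non-finite gas-exchange solution")
    return GasExchangeResult(a, gs, ci, _transpiration(gs, t_leaf, rel_humidity), lim)


def daily_carbon_flux(
    a_net: float, area: float, daylight_hours: float
) -> float:
    """Convert leaf-level net assimilation (umol CO2 m-2 s-1) to a daily
    plant-level carbon flux in g C d-1 (12e-6 g C per umol CO2)."""
    return a_net * daylight_hours * 3600.0 * area * 12.0e-6
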