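"""Coupled ODE system for the EJ2 + SR8 co-culture.

Each strain consumes only its own sugar (no substrate competition), so the
two monoculture models are coupled solely through the shared ethanol pool
and six dimensionless weighing factors r1..r6:

* ``r1``/``r2`` amend the ethanol-inhibition effect felt by each strain:
  the growth Luong factors are evaluated at ``r1*P`` (EJ2) and ``r2*P``
  (SR8).  ``r1 > r2``: in mixed culture EJ2's growth is shut down by less
  ethanol than SR8's.
* ``r3``/``r4`` weight the biomass accumulation rates (``r3 < r4``: SR8
  dominates biomass accumulation).
* ``r5``/``r6`` weight each strain's contribution to the observable ethanol
  pool, together with initial-condition share factors built from the ratios
  of initial sugar concentrations and inoculum sizes (``r5 < r6``: SR8
  dominates ethanol production).

Substrate is consumed at the intrinsic (monoculture) production rate plus
the realised growth and maintenance, while the observable ethanol pool
accrues only the share-weighted production flux: the co-culture model is
deliberately non-conservative in ethanol, which is how it reproduces the
observation that mixed-culture ethanol falls short of the sum of the two
single-strain fermentations.  A single share exponent (default 0.983),
calibrated once against that published shortfall ratio at the 40+40 g/L
reference condition, sharpens the share factors; the exponent leaves the
single-strain limit (share = 1) untouched, so with unit weighing factors
and one strain absent the system reduces exactly to the monoculture model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

from .kinetics import (
    DEPLETION_EPS,
    StrainKinetics,
    ej2_kinetics,
    ethanol_rate,
    growth_rate,
    sr8_kinetics,
)

__all__ = [
    "CocultureParams",
    "CocultureState",
    "default_coculture",
    "coupling_weights",
    "initial_condition_shares",
    "coculture_rhs",
]

#: Share exponent calibrated against the published mixed-culture ethanol
#: shortfall (single-strain ethanol sum = 1.38 x co-culture ethanol at
#: 40+40 g/L, equal inocula).
DEFAULT_SHARE_EXPONENT = 0.983


@dataclass(frozen=True)
class CocultureParams:
    """Strain kinetics, weighing factors and initial conditions of one run."""

    ej2: StrainKinetics
    sr8: StrainKinetics
    r1: float = 3.75
    r2: float = 1.76
    r3: float = 1.44
    r4: float = 2.48
    r5: float = 1.82
    r6: float = 4.29
    S0_c: float = 40.0
    S0_x: float = 40.0
    X0_E: float = 0.45
    X0_S: float = 0.45
    share_exponent: float = DEFAULT_SHARE_EXPONENT

    def __post_init__(self) -> None:
        for fname in ("r1", "r2", "r3", "r4", "r5", "r6"):
            if not (getattr(self, fname) > 0):
                raise ValueError(f"{fname} must be > 0")
        for fname in ("S0_c", "S0_x", "X0_E", "X0_S"):
            if getattr(self, fname) < 0:
                raise ValueError(f"{fname} must be >= 0")
        if self.X0_E + self.X0_S <= 0:
            raise ValueError("at least one inoculum must be > 0")

    def with_updates(self, **updates) -> "CocultureParams":
        return replace(self, **updates)


def default_coculture(**updates) -> CocultureParams:
    """Co-culture parameter set with the fitted weighing factors."""
    params = CocultureParams(ej2=ej2_kinetics(), sr8=sr8_kinetics())
    return params.with_updates(**updates) if updates else params


@dataclass(frozen=True)
class CocultureState:
    """Co-culture state with per-strain biomass (observable X = X_E + X_S)."""

    t: float
    X_E: float
    X_S: float
    S_c: float
    S_x: float
    P: float

    def __post_init__(self) -> None:
        for fname in ("t", "X_E", "X_S", "S_c", "S_x", "P"):
            if getattr(self, fname) < 0:
                raise ValueError(f"{fname} must be >= 0")

    @property
    def X(self) -> float:
        return self.X_E + self.X_S


def coupling_weights(p: CocultureParams) -> tuple:
    """Normalized initial-condition weights (rho_E, rho_S), rho_E + rho_S = 1.

    rho_E is the EJ2 share of the initial (sugar x inoculum) product.  These
    are the normalized counterparts of `initial_condition_shares`; they are
    exposed for alternative couplings and for summarising how skewed a
    scenario's initial conditions are.
    """
    num_E = p.S0_c * p.X0_E
    num_S = p.S0_x * p.X0_S
    total = num_E + num_S
    if total <= 0:
        raise ValueError("degenerate scenario: both S0*X0 products are zero")
    return num_E / total, num_S / total


def initial_condition_shares(p: CocultureParams) -> tuple:
    """Unnormalized share factors (phi_E, phi_S) entering ethanol accrual.

    phi_i multiplies the sugar fraction by the inoculum fraction of strain i;
    each factor is 1 in the single-strain limit and 1/4 in the fully
    symmetric case.  The calibrated share exponent is applied on top.
    """
    S_tot = p.S0_c + p.S0_x
    X_tot = p.X0_E + p.X0_S
    if S_tot <= 0 or X_tot <= 0:
        raise ValueError("degenerate scenario: no sugar or no inoculum")
    q = p.share_exponent
    phi_E = ((p.S0_c / S_tot) * (p.X0_E / X_tot)) ** q
    phi_S = ((p.S0_x / S_tot) * (p.X0_S / X_tot)) ** q
    return phi_E, phi_S


def coculture_rhs(p: CocultureParams, X_E: float, X_S: float, S_c: float,
                  S_x: float, P: float,
                  shares: Optional[tuple] = None) -> tuple:
    """Time derivatives (dX_E, dX_S, dS_c, dS_x, dP) of the co-culture system.

    Each sugar's terms freeze at the depletion epsilon exactly as in the
    monoculture model; the other strain's dynamics continue unaffected
    (coupling is only through shared P).  ``shares`` may be passed to avoid
    recomputing the constant share factors inside an ODE solver loop.
    """
    phi_E, phi_S = initial_condition_shares(p) if shares is None else shares
    kE, kS = p.ej2, p.sr8

    dX_E = dX_S = dS_c = dS_x = dP = 0.0
    if S_c > DEPLETION_EPS and X_E > 0.0:
        mu_E = growth_rate(kE, S_c, p.r1 * P)
        v_E = ethanol_rate(kE, S_c, P, p.S0_c)
        dX_E = p.r3 * mu_E * X_E
        dP += phi_E * p.r5 * v_E * X_E
        dS_c = -(v_E * X_E / (kE.b1 * kE.Yps) + dX_E / (kE.b2 * kE.Yxs)
                 + kE.m * X_E)
    if S_x > DEPLETION_EPS and X_S > 0.0:
        mu_S = growth_rate(kS, S_x, p.r2 * P)
        v_S = ethanol_rate(kS, S_x, P, p.S0_x)
        dX_S = p.r4 * mu_S * X_S
        dP += phi_S * p.r6 * v_S * X_S
        dS_x = -(v_S * X_S / (kS.b1 * kS.Yps) + dX_S / (kS.b2 * kS.Yxs)
                 + kS.m * X_S)
    return (dX_E, dX_S, dS_c, dS_x, dP)
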