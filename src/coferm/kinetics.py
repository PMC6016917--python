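"""Pointwise rate laws for batch ethanol fermentation by specialist yeast strains.

The model describes oxygen-limited batch fermentation of a single sugar
(cellobiose or xylose) by an engineered *S. cerevisiae* strain.  Specific
growth follows Monod kinetics with an optional Haldane substrate-inhibition
term (``S**2/Ki`` in the denominator) and a Luong ethanol-inhibition factor
``1 - (P/Pm)**beta`` that drives the rate to zero exactly at the critical
ethanol concentration ``Pm``.  Specific ethanol production has the same
shape with its own constants, plus an empirical exponential boost in the
initial sugar load, ``exp(a_s0 * S0)``.  Substrate consumption books
ethanol, biomass and maintenance against the yield coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrainKinetics",
    "FermentationState",
    "Trajectory",
    "ej2_kinetics",
    "sr8_kinetics",
    "growth_rate",
    "ethanol_rate",
    "substrate_rate",
    "monoculture_rhs",
    "DEPLETION_EPS",
    "YPS_THEORETICAL_MAX",
]

#: Sugar concentration (g/L) below which a sugar is treated as exhausted and
#: all rates feeding on it are frozen.  Prevents the maintenance term from
#: driving S negative after depletion.
DEPLETION_EPS = 1e-6

#: Stoichiometric ceiling for the ethanol yield on sugar (g ethanol / g sugar),
#: on a per-gram-of-disaccharide basis.
YPS_THEORETICAL_MAX = 0.538


@dataclass(frozen=True)
class StrainKinetics:
    """Complete rate-law parameter set for one strain growing on one sugar.

    ``Ki``/``Kip`` set to ``None`` structurally omit the substrate-inhibition
    term (rather than approximating it with a large constant).  ``b1``/``b2``
    amend the ethanol and biomass yields in the substrate balance; they
    default to 1, which recovers the plain yield bookkeeping.

    Parameters
    ----------
    name : strain label.
    mu_m : maximum specific growth rate (/h).
    Ks : Monod constant for growth (g/L).
    Ki : substrate-inhibition constant for growth (g/L), or None.
    Pm : ethanol concentration halting growth (g/L).
    beta : growth ethanol-inhibition exponent.
    m : maintenance coefficient (/h).
    Yps : ethanol yield on substrate (g/g).
    Yxs : biomass yield on substrate (g/g).
    b1, b2 : yield amendment constants (dimensionless).
    vm : maximum specific ethanol production rate (/h).
    Ksp : Monod constant for production (g/L).
    Kip : substrate-inhibition constant for production (g/L), or None.
    Pmp : ethanol concentration halting production (g/L).
    gamma : production ethanol-inhibition exponent.
    a_s0 : initial-substrate coefficient of the production boost (/(g/L)).
    """

    name: str
    mu_m: float
    Ks: float
    Pm: float
    beta: float
    m: float
    Yps: float
    Yxs: float
    vm: float
    Ksp: float
    Pmp: float
    gamma: float
    Ki: Optional[float] = None
    Kip: Optional[float] = None
    b1: float = 1.0
    b2: float = 1.0
    a_s0: float = 0.0

    def __post_init__(self) -> None:
        positive = ("mu_m", "Ks", "Pm", "beta", "m", "Yps", "Yxs",
                    "vm", "Ksp", "Pmp", "gamma", "b1", "b2")
        for fname in positive:
            value = getattr(self, fname)
            if not (value > 0):
                raise ValueError(f"{self.name}: {fname} must be > 0, got {value!r}")
        for fname in ("Ki", "Kip"):
            value = getattr(self, fname)
            if value is not None and not (value > 0):
                raise ValueError(f"{self.name}: {fname} must be > 0 or None, got {value!r}")
        if self.a_s0 < 0:
            raise ValueError(f"{self.name}: a_s0 must be >= 0, got {self.a_s0!r}")
        if self.Yps > YPS_THEORETICAL_MAX:
            raise ValueError(
                f"{self.name}: Yps={self.Yps} exceeds the theoretical "
                f"maximum {YPS_THEORETICAL_MAX} g/g"
            )

    def with_updates(self, **updates) -> "StrainKinetics":
        """Return a copy with the given parameters replaced."""
        return replace(self, **updates)

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls) if f.name != "name")


def ej2_kinetics() -> StrainKinetics:
    """Fitted parameter set for the cellobiose-consuming strain EJ2."""
    return StrainKinetics(
        name="EJ2", mu_m=0.154, Ks=0.568, Ki=204.0, Pm=69.0, beta=1.1,
        m=0.01, Yps=0.5, Yxs=0.48, b1=1.0, b2=1.0,
        vm=0.416, Ksp=5.0, Kip=52.0, Pmp=100.0, gamma=1.1, a_s0=0.011,
    )


def sr8_kinetics() -> StrainKinetics:
    """Fitted parameter set for the xylose-consuming strain SR8.

    Substrate-inhibition constants are absent (a sensitivity comparison of
    model variants showed dropping them lowers the fit error), and the
    yield-amendment constants b1/b2 absorb ethanol re-assimilation effects.
    """
    return StrainKinetics(
        name="SR8", mu_m=0.154, Ks=1.31, Ki=None, Pm=25.33, beta=0.742,
        m=0.01, Yps=0.4, Yxs=0.35, b1=1.12, b2=1.32,
        vm=0.401, Ksp=13.32, Kip=None, Pmp=27.0, gamma=1.04, a_s0=0.0,
    )


@dataclass(frozen=True)
class FermentationState:
    """Instantaneous state of a batch fermentation.

    t in h; X total biomass (g DCW/L); S_c cellobiose and S_x xylose (g/L);
    P ethanol (g/L).
    """

    t: float
    X: float
    S_c: float
    S_x: float
    P: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"t must be >= 0, got {self.t}")
        for fname in ("X", "S_c", "S_x", "P"):
            if getattr(self, fname) < 0:
                raise ValueError(f"{fname} must be >= 0, got {getattr(self, fname)}")


_TRAJ_COLUMNS = ["time_h", "biomass_gdcw_L", "cellobiose_g_L", "xylose_g_L",
                 "ethanol_g_L"]
_TRAJ_OPTIONAL = ["biomass_ej2_gdcw_L", "biomass_sr8_gdcw_L"]


@dataclass
class Trajectory:
    """Time course of a batch fermentation on a fixed output grid.

    Thin wrapper around a DataFrame with the documented column dialect;
    per-strain biomass columns are present only for co-culture runs.
    """

    data: pd.DataFrame
    provenance: str = "simulated"  # simulated | synthetic | fitted
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        missing = [c for c in _TRAJ_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory missing columns: {missing}")
        t = self.data["time_h"].to_numpy()
        if len(t) == 0:
            raise ValueError("trajectory is empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.provenance not in ("simulated", "synthetic", "fitted"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def t(self) -> np.ndarray:
        return self.data["time_h"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_strain_split(self) -> bool:
        return all(c in self.data.columns for c in _TRAJ_OPTIONAL)

    @classmethod
    def from_arrays(cls, t, X, S_c, S_x, P, *, X_E=None, X_S=None,
                    provenance: str = "simulated",
                    replicate: Optional[int] = None) -> "Trajectory":
        cols = {
            "time_h": np.asarray(t, dtype=float),
            "biomass_gdcw_L": np.asarray(X, dtype=float),
            "cellobiose_g_L": np.asarray(S_c, dtype=float),
            "xylose_g_L": np.asarray(S_x, dtype=float),
            "ethanol_g_L": np.asarray(P, dtype=float),
        }
        if X_E is not None and X_S is not None:
            cols["biomass_ej2_gdcw_L"] = np.asarray(X_E, dtype=float)
            cols["biomass_sr8_gdcw_L"] = np.asarray(X_S, dtype=float)
        return cls(pd.DataFrame(cols), provenance=provenance, replicate=replicate)


def _check_nonnegative(**values) -> None:
    for name, value in values.items():
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")


def growth_rate(k: StrainKinetics, S: float, P: float) -> float:
    """Specific growth rate (/h) at sugar S and ethanol P (both g/L).

    Monod/Haldane term times the Luong ethanol factor, clamped at zero for
    P above Pm (the raw form would go negative and, for non-integer beta,
    produce complex powers).
    """
    _check_nonnegative(S=S, P=P)
    denom = k.Ks + S + (S * S / k.Ki if k.Ki is not None else 0.0)
    luong = max(0.0, 1.0 - (P / k.Pm) ** k.beta)
    return k.mu_m * S / denom * luong


def ethanol_rate(k: StrainKinetics, S: float, P: float, S0: float) -> float:
    """Specific ethanol production rate (/h).

    S0 is the *initial* load of this strain's sugar; the empirical factor
    exp(a_s0*S0) captures the observed increase of specific productivity
    with the initial sugar concentration.
    """
    _check_nonnegative(S=S, P=P, S0=S0)
    denom = k.Ksp + S + (S * S / k.Kip if k.Kip is not None else 0.0)
    luong = max(0.0, 1.0 - (P / k.Pmp) ** k.gamma)
    return math.exp(k.a_s0 * S0) * k.vm * S / denom * luong


def substrate_rate(k: StrainKinetics, dPdt: float, dXdt: float, X: float) -> float:
    """Substrate consumption rate (g/L/h, nonnegative).

    Sugar feeds ethanol (yield b1*Yps), biomass (yield b2*Yxs) and
    maintenance m*X.
    """
    _check_nonnegative(X=X)
    return dPdt / (k.b1 * k.Yps) + dXdt / (k.b2 * k.Yxs) + k.m * X


def monoculture_rhs(k: StrainKinetics, X: float, S: float, P: float,
                    S0: float) -> tuple:
    """Time derivatives (dX/dt, dS/dt, dP/dt) for a single-strain batch.

    All derivatives freeze once the sugar is depleted (S below the depletion
    epsilon) or no biomass is present; the rate laws are not defined past
    depletion.
    """
    if S <= DEPLETION_EPS or X <= 0.0:
        return (0.0, 0.0, 0.0)
    dXdt = growth_rate(k, S, P) * X
    dPdt = ethanol_rate(k, S, P, S0) * X
    dSdt = -substrate_rate(k, dPdt, dXdt, X)
    return (dXdt, dSdt, dPdt)


def monoculture_rhs_state(k: StrainKinetics, state: FermentationState,
                          S0: float, sugar: str = "auto") -> tuple:
    """`monoculture_rhs` on a FermentationState; picks the nonzero sugar."""
    if sugar == "auto":
        sugar = "cellobiose" if state.S_c > 0 or state.S_x == 0 else "xylose"
    S = state.S_c if sugar == "cellobiose" else state.S_x
    return monoculture_rhs(k, state.X, S, state.P, S0)
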