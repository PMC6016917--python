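"""Synthetic fermentation datasets with the study's statistical structure.

Emulates the experimental design behind the kinetic models: duplicate batch
fermentations sampled every few hours over one to two days, with initial
sugar loads in the 10-120 g/L range and inoculum densities around
0.45 g DCW/L.  Observations carry multiplicative Gaussian noise (relative
error dominates at high concentration, as for HPLC peak quantification)
plus a small additive detection floor, truncated at zero.  The published
study reports no error model of its own — the 5% default coefficient of
variation is a conservative stand-in chosen here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .coculture import CocultureParams
from .estimate import GrowthPoint
from .kinetics import StrainKinetics, Trajectory, growth_rate
from .simulate import SimOptions, simulate_coculture, simulate_monoculture

__all__ = ["SyntheticSpec", "generate_trajectory", "generate_coculture_dataset",
           "generate_growth_points"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of a synthetic fermentation campaign.

    ``sample_times`` defaults to every 3 h out to 48 h, matching the marker
    density of the published time courses; ``replicates`` defaults to 2
    (fermentations performed in duplicate).
    """

    kinetics: Union[StrainKinetics, CocultureParams]
    sample_times: Sequence[float] = field(
        default_factory=lambda: tuple(np.arange(0.0, 48.1, 3.0)))
    replicates: int = 2
    cv: float = 0.05
    floor_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.floor_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        times = np.asarray(self.sample_times, dtype=float)
        if len(times) == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
            raise ValueError("sample times must be nonempty, nonnegative, "
                             "strictly increasing")


def _noisy(values: np.ndarray, spec: SyntheticSpec,
           rng: np.random.Generator) -> np.ndarray:
    out = values * (1.0 + spec.cv * rng.standard_normal(values.shape))
    out = out + spec.floor_sd * rng.standard_normal(values.shape)
    return np.maximum(out, 0.0)


def _resample(traj: Trajectory, times: np.ndarray) -> dict:
    grid = traj.t
    if times[-1] > grid[-1] + 1e-9:
        raise ValueError(
            f"sample times extend to {times[-1]} h but the simulation "
            f"ends at {grid[-1]} h")
    cols = {}
    for col in traj.data.columns:
        if col == "time_h":
            continue
        cols[col] = np.interp(times, grid, traj.column(col))
    return cols


def generate_trajectory(spec: SyntheticSpec, S0: float, X0: float,
                        opts: Optional[SimOptions] = None) -> List[Trajectory]:
    """Simulate one monoculture condition and emit noisy replicates.

    The noiseless model trajectory is evaluated at the sampling times; each
    replicate then receives independent noise.  With zero noise the output
    equals the simulated trajectory at the sampling times exactly, and the
    same spec and seed always reproduce the identical dataset.
    """
    if not isinstance(spec.kinetics, StrainKinetics):
        raise TypeError("generate_trajectory expects monoculture kinetics; "
                        "use generate_coculture_dataset for CocultureParams")
    times = np.asarray(spec.sample_times, dtype=float)
    opts = opts or SimOptions(t_end=max(48.0, float(times[-1])))
    clean = simulate_monoculture(spec.kinetics, S0, X0, opts=opts)
    sampled = _resample(clean, times)
    rng = np.random.default_rng(spec.seed)
    out = []
    for rep in range(1, spec.replicates + 1):
        noisy = {col: _noisy(vals, spec, rng) for col, vals in sampled.items()}
        out.append(Trajectory.from_arrays(
            times, noisy["biomass_gdcw_L"], noisy["cellobiose_g_L"],
            noisy["xylose_g_L"], noisy["ethanol_g_L"],
            provenance="synthetic", replicate=rep))
    return out


def generate_coculture_dataset(spec: SyntheticSpec,
                               opts: Optional[SimOptions] = None
                               ) -> List[Trajectory]:
    """Noisy replicate observations of one co-culture scenario.

    Only the observable columns (total biomass, sugars, ethanol) receive
    noise; the per-strain biomass split is not experimentally observable
    and is omitted from the synthetic output.
    """
    if not isinstance(spec.kinetics, CocultureParams):
        raise TypeError("generate_coculture_dataset expects CocultureParams")
    times = np.asarray(spec.sample_times, dtype=float)
    opts = opts or SimOptions(t_end=max(48.0, float(times[-1])))
    clean = simulate_coculture(spec.kinetics, opts=opts)
    sampled = _resample(clean, times)
    rng = np.random.default_rng(spec.seed)
    out = []
    for rep in range(1, spec.replicates + 1):
        noisy = {col: _noisy(sampled[col], spec, rng)
                 for col in ("biomass_gdcw_L", "cellobiose_g_L",
                             "xylose_g_L", "ethanol_g_L")}
        out.append(Trajectory.from_arrays(
            times, noisy["biomass_gdcw_L"], noisy["cellobiose_g_L"],
            noisy["xylose_g_L"], noisy["ethanol_g_L"],
            provenance="synthetic", replicate=rep))
    return out


def generate_growth_points(k: StrainKinetics, S_grid: Sequence[float],
                           cv: float = 0.0, seed: int = 0) -> List[GrowthPoint]:
    """Specific growth-rate observations mu(S) at P=0 with relative noise.

    Emulates log-phase growth-rate measurements across initial sugar loads,
    the input to the double-reciprocal (Lineweaver-Burk) estimate.
    """
    S_grid = list(S_grid)
    if not S_grid:
        raise ValueError("S_grid must be nonempty")
    rng = np.random.default_rng(seed)
    points = []
    for S in S_grid:
        mu = growth_rate(k, float(S), 0.0)
        if cv > 0:
            mu *= 1.0 + cv * float(rng.standard_normal())
        points.append(GrowthPoint(S=float(S), mu=max(mu, 1e-12)))
    return points
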