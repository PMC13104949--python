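"""1-D Langevin dynamics with well-tempered metadynamics on analytic potentials.

A desk-scale stand-in for biased ligand-unbinding simulations: a single
particle evolves on a known 1-D potential (default: symmetric double well
V(s) = h·((s/a)² − 1)², h = 6 kcal/mol, a = 1) under a BAOAB Langevin
integrator while Gaussian hills are deposited along the coordinate with
well-tempered height scaling h_k = h₀·exp(−V(s_k)/((γ−1)kT)).

The run returns a :class:`~bindkin.colvar.ColvarSeries` carrying, per recorded
frame: time (ns), CV value, instantaneous bias V(s_i, t_i), the final bias
V_final(s_i), and the well-tempered time offset c(t_i) — everything the
reweighting and time-rescaling stages need. Because the underlying potential
is analytic, reweighted free-energy profiles and Boltzmann histograms have
exact oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import logsumexp

from ..colvar import ColvarSeries
from ..units import KB_KCAL, NS_PER_PS


@dataclass
class DoubleWell:
    """V(s) = h·((s/a)² − 1)²: minima at ±a, barrier h at s = 0 (kcal/mol)."""

    height: float = 6.0
    half_width: float = 1.0

    def value(self, s):
        u = (np.asarray(s) / self.half_width) ** 2 - 1.0
        return self.height * u * u

    def force(self, s):
        s = np.asarray(s)
        a2 = self.half_width ** 2
        return -4.0 * self.height * s * (s * s / a2 - 1.0) / a2


@dataclass
class HarmonicWell:
    """V(s) = ½·k·(s − s0)² (kcal/mol per CV unit²)."""

    k: float = 2.0
    s0: float = 0.0

    def value(self, s):
        d = np.asarray(s) - self.s0
        return 0.5 * self.k * d * d

    def force(self, s):
        return -self.k * (np.asarray(s) - self.s0)


@dataclass
class LangevinMetadSpec:
    """Parameters of a toy well-tempered metadynamics run.

    Units: energies kcal/mol, time ps (output times in ns), CV dimensionless
    "Å-like" units, temperature K, friction ps⁻¹, mass in internal units
    chosen so that kT/m has (CV unit/ps)² dimensions.
    """

    potential: object = field(default_factory=DoubleWell)
    temperature: float = 300.0
    friction: float = 1.0            # ps⁻¹
    timestep: float = 0.01           # ps
    n_steps: int = 500_000
    hill_height: float = 0.5         # kcal/mol (0 → plain Langevin)
    hill_width: float = 0.2          # CV units (Gaussian sigma)
    deposition_stride: int = 500     # steps between hills
    bias_factor: float = 8.0         # well-tempered γ > 1
    unbound_threshold: float = 2.0   # CV units
    seed: int = 0
    mass: float = 1.0
    start: Optional[float] = None    # default: left minimum / 0
    record_stride: int = 50
    grid_min: float = -4.0
    grid_max: float = 4.0
    grid_points: int = 1024

    def __post_init__(self):
        if self.bias_factor <= 1:
            raise ValueError("bias_factor must be > 1")
        if self.hill_height < 0:
            raise ValueError("hill_height must be >= 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.n_steps < 1 or self.deposition_stride < 1 or self.record_stride < 1:
            raise ValueError("step counts must be positive")
        if self.grid_max <= self.grid_min or self.grid_points < 8:
            raise ValueError("invalid bias grid")


def run_langevin_metad(spec: LangevinMetadSpec) -> ColvarSeries:
    """Integrate the biased Langevin dynamics and return the CV/bias series.

    Raises ``RuntimeError`` if the trajectory becomes non-finite (numerically
    unstable timestep for the given potential stiffness).
    """
    pot = spec.potential
    kT = KB_KCAL * spec.temperature
    dt = spec.timestep
    m = spec.mass
    gamma = spec.bias_factor
    rng = np.random.default_rng(spec.seed)

    c1 = math.exp(-spec.friction * dt)
    c2 = math.sqrt(kT / m * (1.0 - c1 * c1))

    G = spec.grid_points
    grid = np.linspace(spec.grid_min, spec.grid_max, G)
    dx = grid[1] - grid[0]
    inv_dx = 1.0 / dx
    gmin = spec.grid_min
    bias_grid = np.zeros(G)
    bias_force_grid = np.zeros(G)

    if spec.start is not None:
        s = float(spec.start)
    elif isinstance(pot, DoubleWell):
        s = -pot.half_width
    else:
        s = 0.0
    v = rng.normal(0.0, math.sqrt(kT / m))
    noise = rng.standard_normal(spec.n_steps)

    pot_force = pot.force

    def bias_at(x):
        idx = (x - gmin) * inv_dx
        if idx <= 0.0 or idx >= G - 1:
            return 0.0
        i = int(idx)
        w = idx - i
        return bias_grid[i] * (1.0 - w) + bias_grid[i + 1] * w

    def bias_force_at(x):
        idx = (x - gmin) * inv_dx
        if idx <= 0.0 or idx >= G - 1:
            return 0.0
        i = int(idx)
        w = idx - i
        return bias_force_grid[i] * (1.0 - w) + bias_force_grid[i + 1] * w

    times, cvs, biases, cts = [], [], [], []
    c_t = 0.0
    first_cross = None
    depositing = spec.hill_height > 0
    sigma = spec.hill_width
    inv_2s2 = 1.0 / (2.0 * sigma * sigma)
    beta = 1.0 / kT
    wt_denom = (gamma - 1.0) * kT

    f = float(pot_force(s)) + bias_force_at(s)
    half_dt = 0.5 * dt
    for step in range(1, spec.n_steps + 1):
        # BAOAB splitting: B A O A B with one force evaluation per step
        v += half_dt * f / m
        s += half_dt * v
        v = c1 * v + c2 * noise[step - 1]
        s += half_dt * v
        if not (-1e6 < s < 1e6):
            raise RuntimeError(
                "trajectory diverged: timestep too large for the "
                "potential stiffness (reduce timestep or friction)")
        f = float(pot_force(s)) + bias_force_at(s)
        v += half_dt * f / m

        if first_cross is None and s > spec.unbound_threshold:
            first_cross = step

        if depositing and step % spec.deposition_stride == 0:
            h_k = spec.hill_height * math.exp(-bias_at(s) / wt_denom)
            d = grid - s
            g = h_k * np.exp(-d * d * inv_2s2)
            bias_grid += g
            bias_force_grid += g * d * (2.0 * inv_2s2)   # -dV/ds of the hill
            # well-tempered time offset c(t) from the current bias landscape
            c_t = (logsumexp(beta * gamma / (gamma - 1.0) * bias_grid)
                   - logsumexp(beta / (gamma - 1.0) * bias_grid)) * kT

        if step % spec.record_stride == 0:
            if not (math.isfinite(s) and math.isfinite(v)):
                raise RuntimeError(
                    "trajectory diverged: timestep too large for the "
                    "potential stiffness (reduce timestep or friction)")
            times.append(step * dt * NS_PER_PS)
            cvs.append(s)
            biases.append(bias_at(s))
            cts.append(c_t)

    cvs = np.asarray(cvs)
    final_bias = np.interp(cvs, grid, bias_grid, left=0.0, right=0.0)
    meta = {
        "first_crossing_step": first_cross,
        "first_crossing_time_ns": (None if first_cross is None
                                   else first_cross * dt * NS_PER_PS),
        "n_hills": int(spec.n_steps // spec.deposition_stride) if depositing else 0,
        "bias_grid": bias_grid,
        "bias_grid_axis": grid,
    }
    return ColvarSeries(time=np.asarray(times), cv=cvs,
                        bias=np.asarray(biases),
                        temperature=spec.temperature,
                        bias_factor=(gamma if depositing else None),
                        final_bias=final_bias, c_t=np.asarray(cts),
                        cv_names=("cv",), meta=meta)
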