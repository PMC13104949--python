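"""Synthetic radioligand assay tables and exponential unbinding-time samples.

Noise-free outputs satisfy the closed-form assay models exactly; counting
noise is multiplicative Gaussian with a fixed coefficient of variation,
floored at zero cpm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..assays import (AssayTable, association_model, competition_model,
                      dissociation_model, saturation_model)
from ..units import LN2


@dataclass
class AssayParams:
    """Ground-truth parameters for one synthetic radioligand experiment.

    Defaults emulate a slowly dissociating, sub-nanomolar-affinity opioid
    (Kd ≈ 0.16 nM, t_1/2 ≈ 34.5 min) measured with ~5000 cpm of bound signal.
    """

    mode: str
    Kd: float = 0.164                 # nM
    Bmax: float = 5000.0              # cpm
    kon: float = 0.93                 # nM⁻¹ min⁻¹
    koff: float = LN2 / 34.5          # min⁻¹
    radioligand_conc: float = 1.0     # nM
    Ki: float = 16.0                  # nM (competitor)
    nonspecific_slope: float = 0.0    # cpm/nM
    noise_cv: float = 0.0
    n_points: int = 16
    seed: int = 0

    def __post_init__(self):
        for name in ("Kd", "Bmax", "kon", "koff", "radioligand_conc", "Ki"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_points < 4:
            raise ValueError("need n_points >= 4")


def _apply_noise(cpm: np.ndarray, cv: float, rng: np.random.Generator
                 ) -> np.ndarray:
    if cv == 0:
        return cpm
    noisy = cpm * (1.0 + cv * rng.standard_normal(cpm.shape))
    return np.maximum(noisy, 0.0)


def gen_assay(params: AssayParams) -> AssayTable:
    """Generate one assay table following the mode's closed-form model.

    x grids: dissociation/association over 0–3 characteristic times (min);
    saturation log-spaced over Kd/10–10·Kd (nM); competition log-spaced over
    IC50/300–300·IC50 (nM). Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    p = params
    L = p.radioligand_conc
    if p.mode == "dissociation":
        t_half = LN2 / p.koff
        t = np.linspace(0.0, 3.0 * t_half, p.n_points)
        floor = p.nonspecific_slope * L
        cpm = dissociation_model(t, floor, p.Bmax, p.koff)
        x, x_unit = t, "min"
    elif p.mode == "association":
        kobs = p.kon * L + p.koff
        t = np.linspace(0.0, 3.0 / kobs, p.n_points)
        plateau = p.Bmax * L / (p.Kd + L)
        cpm = association_model(t, plateau, kobs)
        x, x_unit = t, "min"
    elif p.mode == "saturation":
        conc = np.geomspace(p.Kd / 10.0, 10.0 * p.Kd, p.n_points)
        cpm = saturation_model(conc, p.Bmax, p.Kd, p.nonspecific_slope)
        x, x_unit = conc, "nM"
    elif p.mode == "competition":
        IC50 = p.Ki * (1.0 + L / p.Kd)
        conc = np.geomspace(IC50 / 300.0, IC50 * 300.0, p.n_points)
        top = p.Bmax * L / (p.Kd + L)
        bottom = p.nonspecific_slope * L
        cpm = competition_model(np.log10(conc), top, bottom,
                                np.log10(IC50), 1.0)
        x, x_unit = conc, "nM"
    else:
        raise ValueError(f"unknown assay mode {p.mode!r}")
    if np.any(x < 0):
        raise ValueError("negative concentrations/times generated")
    cpm = _apply_noise(cpm, p.noise_cv, rng)
    meta = {"radioligand_conc": L, "truth": {
        "Kd": p.Kd, "Bmax": p.Bmax, "kon": p.kon, "koff": p.koff,
        "Ki": p.Ki, "nonspecific_slope": p.nonspecific_slope,
        "t_half": LN2 / p.koff}}
    return AssayTable(mode=p.mode, x=x, cpm=cpm, x_unit=x_unit, meta=meta)


def gen_unbinding_times(tau: float, n: int, seed: int = 0) -> np.ndarray:
    """i.i.d. exponential dissociation times (s) with mean ``tau``.

    Emulates the rescaled physical unbinding times obtained from a set of
    independent biased dissociation trajectories (typically n = 15).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    return rng.exponential(tau, size=n)
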