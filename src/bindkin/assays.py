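"""Radioligand binding-assay models and nonlinear least-squares fits.

Implements the four standard radioligand experiments at a receptor:

- saturation binding          cpm = Bmax·L/(Kd + L) + ns·L
- one-phase association       cpm = plateau·(1 − e^(−k_obs·t)),  k_obs = k_on·L + k_off
- one-phase dissociation      cpm = plateau + span·e^(−k_off·t),  t_1/2 = ln2/k_off
- competitive displacement    cpm = top + (bottom − top)/(1 + 10^(h·(logIC50 − logI)))
                              K_i = IC50/(1 + L/Kd)   (Cheng–Prusoff)

with cpm the counts-per-minute signal, L the radioligand concentration (nM),
t time (min) and I the competitor concentration (nM). Fits use relative
(constant-coefficient-of-variation) weighting by default — counting noise
scales with the signal, and unweighted least squares gives anti-conservative
confidence intervals on decay rates; pass ``weighted=None`` for plain
unweighted least squares. Standard errors come from the asymptotic
covariance; 95% confidence intervals use Student-t quantiles with n − p
degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .units import LN2

MODES = ("saturation", "association", "dissociation", "competition")


@dataclass
class AssayTable:
    """One radioligand experiment: x (nM or min) vs cpm readings."""

    mode: str
    x: np.ndarray
    cpm: np.ndarray
    replicate: Optional[np.ndarray] = None
    x_unit: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        self.x = np.asarray(self.x, dtype=float)
        self.cpm = np.asarray(self.cpm, dtype=float)
        if self.x.shape != self.cpm.shape:
            raise ValueError("x and cpm must have equal length")
        if np.any(self.x < 0):
            raise ValueError("x values must be non-negative")
        if self.replicate is None:
            self.replicate = np.zeros(len(self.x), dtype=int)
        else:
            self.replicate = np.asarray(self.replicate, dtype=int)
        if not self.x_unit:
            self.x_unit = "min" if self.mode in ("association", "dissociation") else "nM"
        if len(np.unique(self.x)) < 4:
            raise ValueError("need at least 4 distinct x values per fit")

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"mode": self.mode, "replicate": self.replicate,
                           "x_value": self.x, "x_unit": self.x_unit,
                           "cpm": self.cpm})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: Optional[dict] = None) -> "AssayTable":
        df = pd.read_csv(path)
        modes = df["mode"].unique()
        if len(modes) != 1:
            raise ValueError("CSV must contain exactly one assay mode")
        return cls(mode=str(modes[0]), x=df["x_value"].to_numpy(),
                   cpm=df["cpm"].to_numpy(),
                   replicate=df["replicate"].to_numpy(),
                   x_unit=str(df["x_unit"].iloc[0]), meta=dict(meta or {}))


# ----------------------------------------------------------------- models

def saturation_model(L, Bmax, Kd, ns):
    return Bmax * L / (Kd + L) + ns * L


def association_model(t, plateau, kobs):
    return plateau * (1.0 - np.exp(-kobs * t))


def dissociation_model(t, plateau, span, koff):
    return plateau + span * np.exp(-koff * t)


def competition_model(logI, top, bottom, logIC50, hill):
    return top + (bottom - top) / (1.0 + 10.0 ** (hill * (logIC50 - logI)))


def _fit(model, x, y, p0, bounds, weighted="relative"):
    popt, pcov = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds,
                                    maxfev=20000)
    if weighted == "relative":
        # two-pass: weight by the first-pass model values (constant-CV noise)
        sigma = np.maximum(np.abs(model(x, *popt)), 1e-12)
        popt, pcov = optimize.curve_fit(model, x, y, p0=popt, bounds=bounds,
                                        sigma=sigma, maxfev=20000)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    resid = y - model(x, *popt)
    dof = max(len(x) - len(popt), 1)
    return popt, se, resid, dof


def _tcrit(dof, level=0.95):
    return stats.t.ppf(0.5 + level / 2.0, dof)


# ----------------------------------------------------------------- results

@dataclass
class DissociationFit:
    koff: float                   # min⁻¹
    koff_se: float
    t_half: float                 # min, = ln2/koff
    t_half_se: float
    plateau: float
    plateau_se: float
    span: float
    ok: bool = True
    message: str = ""
    koff_ci: tuple = (np.nan, np.nan)

    def __post_init__(self):
        if self.ok:
            assert abs(self.t_half * self.koff - LN2) < 1e-12 * LN2


@dataclass
class AssociationFit:
    kobs: float                   # min⁻¹
    kobs_se: float
    kon: float                    # nM⁻¹min⁻¹
    kon_se: float
    koff_assumed: float
    plateau: float
    ok: bool = True
    message: str = ""


@dataclass
class SaturationFit:
    Kd: float                     # nM
    Kd_se: float
    Bmax: float                   # cpm
    Bmax_se: float
    ns_slope: float               # cpm/nM
    ns_slope_se: float
    ok: bool = True
    warning: str = ""
    Kd_ci: tuple = (np.nan, np.nan)


@dataclass
class CompetitionFit:
    IC50: float                   # nM
    IC50_se: float
    Ki: float                     # nM
    Ki_se: float
    hill_slope: float
    top: float
    bottom: float
    ok: bool = True
    message: str = ""


# ------------------------------------------------------------------- fits

def fit_dissociation(data: AssayTable, weighted="relative") -> DissociationFit:
    """Fit a one-phase exponential decay; t_1/2 = ln2/k_off.

    Non-decaying data (k_off confidence interval including 0, or negative
    fitted span) is returned flagged ``ok=False`` rather than raised.
    """
    if data.mode != "dissociation":
        raise ValueError("expected a dissociation assay")
    t, y = data.x, data.cpm
    span0 = max(y.max() - y.min(), 1e-9)
    tspan = max(t.max() - t.min(), 1e-9)
    p0 = (y.min(), span0, LN2 / (0.3 * tspan))
    try:
        popt, se, _, dof = _fit(dissociation_model, t, y, p0,
                                ([-np.inf, -np.inf, 0], np.inf), weighted)
    except RuntimeError as exc:
        return DissociationFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                               np.nan, np.nan, ok=False,
                               message=f"fit failed: {exc}")
    plateau, span, koff = popt
    tc = _tcrit(dof)
    ci = (koff - tc * se[2], koff + tc * se[2])
    span_negligible = span <= 1e-6 * max(np.abs(y).max(), 1e-12)
    if koff <= 0 or span <= 0 or ci[0] <= 0 or span_negligible:
        return DissociationFit(koff, se[2], np.nan, np.nan, plateau, se[0],
                               span, ok=False, koff_ci=ci,
                               message="no significant decay "
                                       "(koff CI includes 0)")
    t_half = LN2 / koff
    return DissociationFit(koff, se[2], t_half, LN2 / koff ** 2 * se[2],
                           plateau, se[0], span, koff_ci=ci)


def fit_association(data: AssayTable, koff: float, weighted="relative"
                    ) -> AssociationFit:
    """Fit one-phase association for k_obs, then k_on = (k_obs − k_off)/L.

    ``L`` (radioligand concentration, nM) must be present in
    ``data.meta["radioligand_conc"]``. If k_obs < k_off the association rate
    is unphysical; k_on is reported as 0 with ``ok=False``.
    """
    if data.mode != "association":
        raise ValueError("expected an association assay")
    if "radioligand_conc" not in data.meta:
        raise ValueError("data.meta must provide 'radioligand_conc' (nM)")
    L = float(data.meta["radioligand_conc"])
    if L <= 0:
        raise ValueError("radioligand concentration must be positive")
    if koff < 0:
        raise ValueError("koff must be non-negative")
    t, y = data.x, data.cpm
    p0 = (y.max(), LN2 / (0.3 * max(t.max() - t.min(), 1e-9)))
    popt, se, _, dof = _fit(association_model, t, y, p0,
                            ([0, 0], np.inf), weighted)
    plateau, kobs = popt
    kon = (kobs - koff) / L
    kon_se = se[1] / L
    if kon < 0:
        return AssociationFit(kobs, se[1], 0.0, kon_se, koff, plateau,
                              ok=False,
                              message=f"k_obs ({kobs:.4g}) < koff ({koff:.4g})"
                                      "; kon clamped to 0")
    return AssociationFit(kobs, se[1], kon, kon_se, koff, plateau)


def fit_saturation(data: AssayTable, weighted="relative") -> SaturationFit:
    """Fit hyperbolic saturation binding with a linear nonspecific term."""
    if data.mode != "saturation":
        raise ValueError("expected a saturation assay")
    L, y = data.x, data.cpm
    if len(np.unique(L)) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    Kd0 = np.median(L[L > 0])
    p0 = (y.max(), Kd0, 0.0)
    popt, se, _, dof = _fit(saturation_model, L, y, p0,
                            ([0, 1e-12, -np.inf], np.inf), weighted)
    Bmax, Kd, ns = popt
    tc = _tcrit(dof)
    ci = (Kd - tc * se[1], Kd + tc * se[1])
    warning = ""
    Lpos = L[L > 0]
    if se[1] > Kd or Kd > Lpos.max() or Kd < Lpos.min():
        warning = ("Kd poorly determined: outside tested concentration "
                   "range or CI wider than estimate")
    return SaturationFit(Kd, se[1], Bmax, se[0], ns, se[2],
                         warning=warning, Kd_ci=ci)


def cheng_prusoff(IC50: float, L: float, Kd: float) -> float:
    """K_i = IC50/(1 + L/Kd) for competitive displacement."""
    if L < 0 or Kd <= 0:
        raise ValueError("need L ≥ 0 and Kd > 0")
    return IC50 / (1.0 + L / Kd)


def fit_competition_ki(data: AssayTable, Kd_radioligand: float, L: float,
                       weighted="relative") -> CompetitionFit:
    """Fit a sigmoidal displacement curve and convert IC50 to K_i.

    The Cheng–Prusoff correction K_i = IC50/(1 + L/Kd) uses the radioligand
    concentration L and its independently measured Kd.
    """
    if data.mode != "competition":
        raise ValueError("expected a competition assay")
    if Kd_radioligand <= 0 or L <= 0:
        raise ValueError("Kd_radioligand and L must be positive")
    I, y = data.x, data.cpm
    if np.any(I <= 0):
        raise ValueError("competitor concentrations must be positive (log axis)")
    logI = np.log10(I)
    p0 = (y.max(), y.min(), np.median(logI), 1.0)
    popt, se, _, dof = _fit(competition_model, logI, y, p0,
                            ([0, 0, logI.min() - 3, 0.1],
                             [np.inf, np.inf, logI.max() + 3, 10.0]), weighted)
    top, bottom, logIC50, hill = popt
    span = top - bottom
    noise = np.std(y - competition_model(logI, *popt))
    if span <= max(3.0 * noise, 1e-9):
        return CompetitionFit(np.nan, np.nan, np.nan, np.nan, hill, top,
                              bottom, ok=False,
                              message="no displacement across tested range")
    IC50 = 10.0 ** logIC50
    IC50_se = IC50 * math.log(10.0) * se[2]
    factor = 1.0 + L / Kd_radioligand
    return CompetitionFit(IC50, IC50_se, IC50 / factor, IC50_se / factor,
                          hill, top, bottom)


def fold_ratio(numerator: float, denominator: float, decimals: int = 1
               ) -> float:
    """Rounded quotient with half-away-from-zero rounding.

    Used for potency/half-life comparisons between compounds (e.g. K_i of a
    reversal agent for one opioid vs another).
    """
    if denominator == 0:
        raise ZeroDivisionError("fold_ratio denominator is zero")
    q = numerator / denominator
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(q) * scale + 0.5), q) / scale
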