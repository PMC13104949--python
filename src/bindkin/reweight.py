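"""Unbiasing metadynamics frames into free-energy profiles (PMFs).

Frames visited under a history-dependent bias are not Boltzmann-distributed;
statistical weights w_i ∝ exp(+V_i/kT) restore unbiased averages. Two weight
schemes are provided:

- ``final_bias`` (default): w_i ∝ exp(V_final(s_i)/kT), the static last-bias
  estimator — robust once the well-tempered bias has nearly converged;
- ``time_dependent``: w_i ∝ exp((V(s_i, t_i) − c(t_i))/kT) with c(t) the
  standard well-tempered time offset, valid throughout the run when c(t) is
  available.

A PMF along any per-frame observable (here: receptor-ligand contact numbers)
is F(b) = −kT·ln Σ_{i∈b} w_i, shifted so its minimum is zero; empty bins are
undefined (NaN), never zero. Per-bin standard errors come from independent
blocks or trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .colvar import ColvarSeries
from .units import kT as thermal_kT

SCHEMES = ("final_bias", "time_dependent")


def compute_frame_weights(colvar: ColvarSeries,
                          scheme: str = "final_bias") -> np.ndarray:
    """Normalized per-frame statistical weights from a biased run.

    Overflow is guarded by subtracting the maximum exponent before
    exponentiation (weights are shift-invariant in the bias).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    kT = thermal_kT(colvar.temperature)
    if scheme == "final_bias":
        if colvar.final_bias is None:
            raise ValueError(
                "final_bias scheme needs the final-bias column "
                "(V_final evaluated at each frame's CV); re-run the "
                "simulation with final-bias output or use 'time_dependent'")
        expo = colvar.final_bias / kT
    else:
        expo = colvar.bias.copy()
        if colvar.c_t is not None:
            expo = expo - colvar.c_t
        else:
            warnings.warn("no c(t) column; treating bias as already "
                          "offset-corrected (rbias)", stacklevel=2)
        expo = expo / kT
    if not np.all(np.isfinite(expo)):
        raise ValueError("non-finite bias values")
    w = np.exp(expo - expo.max())
    return w / w.sum()


@dataclass
class PMFProfile:
    """Free energy (kcal/mol) vs binned observable, min-shifted to zero."""

    bin_centers: np.ndarray
    free_energy: np.ndarray      # NaN for empty bins
    se: Optional[np.ndarray] = None
    kT: float = 0.0

    def defined(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame({"bin_center": self.bin_centers,
                           "F_kcal_mol": self.free_energy})
        df["se"] = self.se if self.se is not None else np.nan
        df.to_csv(path, index=False)


def _as_values(values) -> np.ndarray:
    if hasattr(values, "counts"):
        return np.asarray(values.counts, dtype=float)
    return np.asarray(values, dtype=float)


def reweighted_pmf(values, weights: np.ndarray, bins: Union[int, np.ndarray],
                   kT: float) -> PMFProfile:
    """F(b) = −kT·ln(Σ weights in bin b), shifted so min F = 0.

    ``values`` may be a ContactSeries or any per-frame array aligned with
    ``weights``; ``bins`` follows numpy histogram conventions.
    """
    v = _as_values(values)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must be aligned")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if kT <= 0:
        raise ValueError("kT must be positive")
    hist, edges = np.histogram(v, bins=bins, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    F = np.full(len(centers), np.nan)
    nz = hist > 0
    if not nz.any():
        raise ValueError("no probability mass in any bin")
    if nz.sum() == 1:
        warnings.warn("all weight in a single bin: degenerate profile",
                      stacklevel=2)
    F[nz] = -kT * np.log(hist[nz])
    F -= np.nanmin(F)
    return PMFProfile(bin_centers=centers, free_energy=F, kT=kT)


def pmf_error(values, weights: np.ndarray, block_labels: Sequence,
              bins: np.ndarray, kT: float) -> np.ndarray:
    """Per-bin standard error across independent blocks or trajectories.

    Each block's PMF is computed (and min-shifted) separately; the SE of the
    mean across blocks is returned per bin, NaN where fewer than two blocks
    define the bin.
    """
    v = _as_values(values)
    w = np.asarray(weights, dtype=float)
    labels = np.asarray(block_labels)
    if not (len(v) == len(w) == len(labels)):
        raise ValueError("values, weights and block labels must be aligned")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 blocks for an error estimate")
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValueError("bins must be explicit edges for block errors")
    profiles = []
    for lab in uniq:
        m = labels == lab
        wm = w[m]
        hist, _ = np.histogram(v[m], bins=edges, weights=wm / wm.sum())
        F = np.full(len(edges) - 1, np.nan)
        nz = hist > 0
        F[nz] = -kT * np.log(hist[nz])
        F -= np.nanmin(F)
        profiles.append(F)
    P = np.vstack(profiles)
    n_def = np.sum(np.isfinite(P), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(P, axis=0, ddof=1)
    se = sd / np.sqrt(n_def)
    se[n_def < 2] = np.nan
    return se


def locate_minimum(pmf: PMFProfile):
    """(bin center, free energy) of the global minimum.

    Ties are broken toward the larger bin center — for contact-number axes
    that is the more-bound state.
    """
    F = pmf.free_energy
    ok = np.isfinite(F)
    if not ok.any():
        raise ValueError("all-undefined profile")
    fmin = np.nanmin(F)
    idx = np.flatnonzero(ok & (F == fmin))
    best = idx[np.argmax(pmf.bin_centers[idx])]
    return float(pmf.bin_centers[best]), float(F[best])
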