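"""Per-frame collective-variable/bias time series (COLVAR-style tables).

A :class:`ColvarSeries` holds what an enhanced-sampling engine writes alongside
a biased trajectory: time, collective-variable (CV) values, and the
instantaneous bias energy at the visited CV position. Two optional columns
support reweighting: the *final* bias evaluated at each frame's CV position
(static last-bias reweighting) and the well-tempered time offset c(t)
(time-dependent reweighting).

On disk the series is a whitespace table with a ``#! FIELDS ...`` header line,
the convention used by PLUMED COLVAR files, plus optional ``#! SET`` lines for
temperature and bias factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


@dataclass
class ColvarSeries:
    """Time series of CV values and bias energies from a biased run.

    Parameters
    ----------
    time : array, shape (n,)
        Frame times in ns, strictly increasing.
    cv : array, shape (n,) or (n, k)
        CV values per frame (e.g. ligand z displacement in Å, or a
        receptor-ligand coordination number).
    bias : array, shape (n,)
        Instantaneous bias V(s_i, t_i) in kcal/mol.
    temperature : float
        Simulation temperature in K.
    bias_factor : float, optional
        Well-tempered bias factor γ > 1, if applicable.
    final_bias : array, optional
        V_final(s_i): the bias at the *end* of the run evaluated at each
        frame's CV position (kcal/mol). Needed for last-bias reweighting.
    c_t : array, optional
        Well-tempered time offset c(t_i) in kcal/mol for time-dependent
        reweighting.
    meta : dict
        Free-form provenance (e.g. first barrier-crossing index).
    """

    time: np.ndarray
    cv: np.ndarray
    bias: np.ndarray
    temperature: float = 310.0
    bias_factor: Optional[float] = None
    final_bias: Optional[np.ndarray] = None
    c_t: Optional[np.ndarray] = None
    cv_names: Sequence[str] = ("cv",)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        n = len(self.time)
        if self.cv.shape[0] != n or len(self.bias) != n:
            raise ValueError("time, cv and bias must have equal length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name in ("final_bias", "c_t"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col, dtype=float)
                if len(col) != n:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, col)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def cv1(self) -> np.ndarray:
        """First CV column as a 1-D array."""
        return self.cv if self.cv.ndim == 1 else self.cv[:, 0]

    # ---------------------------------------------------------------- I/O

    def write(self, path) -> None:
        """Write as a COLVAR-style whitespace table."""
        cv2d = self.cv.reshape(len(self), -1)
        names = list(self.cv_names)
        if len(names) != cv2d.shape[1]:
            names = [f"cv{i + 1}" for i in range(cv2d.shape[1])]
        cols = [self.time] + [cv2d[:, j] for j in range(cv2d.shape[1])] + [self.bias]
        fields = ["time"] + names + ["bias"]
        if self.final_bias is not None:
            cols.append(self.final_bias)
            fields.append("final_bias")
        if self.c_t is not None:
            cols.append(self.c_t)
            fields.append("c_t")
        header = ["#! FIELDS " + " ".join(fields),
                  f"#! SET temperature {self.temperature:g}"]
        if self.bias_factor is not None:
            header.append(f"#! SET biasfactor {self.bias_factor:g}")
        body = np.column_stack(cols)
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            np.savetxt(fh, body, fmt="%.10g")

    @classmethod
    def read(cls, path) -> "ColvarSeries":
        """Read a COLVAR-style table written by :meth:`write` (or PLUMED)."""
        path = Path(path)
        fields = None
        temperature = None
        bias_factor = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#! FIELDS"):
                    fields = line.split()[2:]
                elif line.startswith("#! SET"):
                    parts = line.split()
                    if len(parts) >= 4 and parts[2] == "temperature":
                        temperature = float(parts[3])
                    elif len(parts) >= 4 and parts[2] == "biasfactor":
                        bias_factor = float(parts[3])
                elif not line.startswith("#"):
                    break
        if fields is None:
            raise ValueError(f"{path}: missing '#! FIELDS' header")
        data = np.loadtxt(path, comments="#", ndmin=2)
        if data.shape[1] != len(fields):
            raise ValueError(f"{path}: column count does not match FIELDS")
        col = {name: data[:, j] for j, name in enumerate(fields)}
        if "time" not in col or "bias" not in col:
            raise ValueError(f"{path}: need 'time' and 'bias' columns")
        cv_names = [f for f in fields
                    if f not in ("time", "bias", "final_bias", "c_t")]
        if not cv_names:
            raise ValueError(f"{path}: no CV columns found")
        cv = np.column_stack([col[f] for f in cv_names])
        if cv.shape[1] == 1:
            cv = cv[:, 0]
        if temperature is None:
            import warnings
            temperature = 310.0
            warnings.warn(
                f"{path}: no '#! SET temperature' header; assuming 310 K",
                stacklevel=2)
        return cls(time=col["time"], cv=cv, bias=col["bias"],
                   temperature=temperature, bias_factor=bias_factor,
                   final_bias=col.get("final_bias"), c_t=col.get("c_t"),
                   cv_names=cv_names)
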