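"""Divergence of the displacement field and the contractility trace D(t).

The divergence ∂u/∂x + ∂v/∂y of the displacement field relative to the
diastolic reference is nondimensional (px of displacement per px of grid
spacing) and measures the relative change of monolayer area — negative
where cells contract.  Its spatial average per frame gives the temporal
contractility tracing D(t); under the default *absolute* convention D(t)
is the mean of |div| over valid cells, so both contraction and the
accompanying expansion elsewhere contribute positively.  The element-wise
square root of D(t) can be read as a cell-shortening measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .piv import DisplacementField

__all__ = [
    "DivergenceField",
    "ContractilityTrace",
    "divergence_field",
    "contractility_value",
    "contractility_trace",
    "shortening_trace",
]

_CONVENTIONS = ("absolute", "signed")


@dataclass
class DivergenceField:
    """Scalar divergence on the displacement grid minus its one-cell border."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    div: np.ndarray
    valid: np.ndarray
    t: float = 0.0


@dataclass
class ContractilityTrace:
    """Spatially averaged divergence per frame.

    ``convention`` is ``absolute`` (mean |div|, nonnegative) or ``signed``
    (mean of −div, contraction positive). ``n_valid`` counts the divergence
    cells contributing at each frame.
    """

    t: np.ndarray
    D: np.ndarray
    convention: str
    n_valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.n_valid = np.asarray(self.n_valid)
        if self.t.shape != self.D.shape:
            raise ValueError("t and D must have equal length")
        if self.convention not in _CONVENTIONS:
            raise ValueError("convention must be 'absolute' or 'signed'")

    @property
    def frame_rate(self) -> float:
        if self.t.size < 2:
            raise ValueError("frame rate undefined for a single-sample trace")
        return 1.0 / float(np.median(np.diff(self.t)))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "D": self.D, "n_valid": self.n_valid}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, convention: str = "absolute") -> "ContractilityTrace":
        df = pd.read_csv(path)
        return cls(
            t=df["t"].to_numpy(),
            D=df["D"].to_numpy(),
            convention=convention,
            n_valid=df["n_valid"].to_numpy(),
        )


def divergence_field(field: DisplacementField) -> DivergenceField:
    """Central-difference divergence on the window grid.

    div[i, j] = (u[i, j+1] − u[i, j−1] + v[i+1, j] − v[i−1, j]) / (2h) with
    h the grid spacing — exact for fields affine in position.  A cell is
    valid only if the full five-point stencil lies on valid windows; the
    result lives on the grid minus a one-cell border.
    """
    ny, nx = field.u.shape
    if ny < 3 or nx < 3:
        raise ValueError(f"grid {field.u.shape} too small for a central-difference stencil")
    h = field.spacing
    u, v, valid = field.u, field.v, field.valid
    du_dx = (u[1:-1, 2:] - u[1:-1, :-2]) / (2.0 * h)
    dv_dy = (v[2:, 1:-1] - v[:-2, 1:-1]) / (2.0 * h)
    div = du_dx + dv_dy
    stencil_ok = (
        valid[1:-1, 1:-1]
        & valid[1:-1, 2:]
        & valid[1:-1, :-2]
        & valid[2:, 1:-1]
        & valid[:-2, 1:-1]
    )
    div = np.where(stencil_ok, div, np.nan)
    return DivergenceField(
        grid_x=field.grid_x[1:-1],
        grid_y=field.grid_y[1:-1],
        div=div,
        valid=stencil_ok,
        t=field.t,
    )


def contractility_value(divfield: DivergenceField, convention: str = "absolute") -> float:
    """Spatial average of the divergence under the chosen sign convention."""
    if convention not in _CONVENTIONS:
        raise ValueError("convention must be 'absolute' or 'signed'")
    if not divfield.valid.any():
        raise ValueError("no valid divergence cells")
    vals = divfield.div[divfield.valid]
    if convention == "absolute":
        return float(np.mean(np.abs(vals)))
    return float(np.mean(-vals))


def contractility_trace(
    fields: list[DisplacementField], convention: str = "absolute"
) -> ContractilityTrace:
    """D(t): one spatially averaged divergence value per displacement field."""
    if not fields:
        raise ValueError("fields must be nonempty")
    t, D, n_valid = [], [], []
    for fld in fields:
        dv = divergence_field(fld)
        t.append(fld.t)
        D.append(contractility_value(dv, convention))
        n_valid.append(int(dv.valid.sum()))
    return ContractilityTrace(
        t=np.asarray(t), D=np.asarray(D), convention=convention, n_valid=np.asarray(n_valid)
    )


def shortening_trace(trace: ContractilityTrace) -> np.ndarray:
    """Element-wise √D(t), a cell-shortening measure (absolute convention only)."""
    if trace.convention != "absolute":
        raise ValueError("shortening is defined for the absolute convention only")
    return np.sqrt(trace.D)
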