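"""The hypothetical-drug grid and the retrograde intrinsic-clearance calculation.

The study's synthetic data is a Cartesian grid of drug properties:

* binding protein — exclusive binding to HSA or AGP;
* ``fu_adult`` — 11 adult unbound fractions from 0.05 to 1;
* ``kp`` — 5 erythrocyte-to-plasma partition coefficients, 0 to 4;
* ``clint_t`` — 39 transporter-mediated intrinsic clearances, log-spaced
  over [2, 500] uL/min per 10^6 proximal tubule cells with the anchor
  values 5, 50 and 500 forced onto the grid.

The retrograde calculation inverts the forward clearance model to recover
``clint_t`` from an observed adult renal plasma clearance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

FU_ADULT_GRID = (0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95, 1.0)
KP_GRID = (0.0, 1.0, 2.0, 3.0, 4.0)
BINDING_PROTEINS = ("HSA", "AGP")
CLINT_T_RANGE = (2.0, 500.0)
CLINT_T_ANCHORS = (5.0, 50.0, 500.0)
N_CLINT_T = 39


@dataclass(frozen=True)
class HypotheticalDrug:
    """One point of the drug-property grid."""

    binding_protein: str
    fu_adult: float
    kp: float
    clint_t: float  # uL/min per 10^6 proximal tubule cells

    def __post_init__(self) -> None:
        if self.binding_protein not in BINDING_PROTEINS:
            raise ValueError(f"unknown binding protein: {self.binding_protein!r}")
        if not 0 < self.fu_adult <= 1:
            raise ValueError("fu_adult must lie in (0, 1]")
        if self.kp < 0:
            raise ValueError("kp cannot be negative")
        if self.clint_t < 0:
            raise ValueError("clint_t cannot be negative")


def clint_t_grid(
    n: int = N_CLINT_T,
    lo: float = CLINT_T_RANGE[0],
    hi: float = CLINT_T_RANGE[1],
    anchors: Sequence[float] = CLINT_T_ANCHORS,
) -> np.ndarray:
    """Log-spaced intrinsic-clearance grid with the anchors snapped on.

    Each anchor replaces the nearest log-spaced point, keeping the grid
    size at ``n`` and the ordering strictly increasing.
    """
    grid = np.geomspace(lo, hi, n)
    for a in anchors:
        grid[np.argmin(np.abs(grid - a))] = a
    grid = np.sort(grid)
    if len(np.unique(grid)) != n:
        raise ValueError("anchor snapping collapsed grid points")
    return grid


def generate_drug_grid(
    proteins: Sequence[str] = BINDING_PROTEINS,
    fu_values: Sequence[float] = FU_ADULT_GRID,
    kp_values: Sequence[float] = KP_GRID,
    clint_values: Sequence[float] | None = None,
) -> list[HypotheticalDrug]:
    """Full Cartesian product of the drug-property lists, in a stable order
    (protein, fu_adult, kp, clint_t)."""
    if clint_values is None:
        clint_values = clint_t_grid()
    return [
        HypotheticalDrug(p, fu, kp, cl)
        for p, fu, kp, cl in product(proteins, fu_values, kp_values, clint_values)
    ]


def drug_grid_frame(**kwargs) -> pd.DataFrame:
    """The drug grid as a DataFrame (one row per drug), exportable as CSV."""
    drugs = generate_drug_grid(**kwargs)
    return pd.DataFrame(
        {
            "binding_protein": [d.binding_protein for d in drugs],
            "fu_adult": [d.fu_adult for d in drugs],
            "kp": [d.kp for d in drugs],
            "clint_t": [d.clint_t for d in drugs],
        }
    )


class NoSecretionError(ValueError):
    """The observed clearance leaves no active-secretion component."""


class FlowLimitedError(ValueError):
    """The observed clearance sits at or above the perfusion ceiling, where
    the forward model is insensitive to CL_int,T and cannot be inverted."""


def retrograde_clint_t(
    clr_adult: float,
    fu_adult: float,
    bp: float,
    gfr: float,
    qr: float,
    ptcpgk: float,
    kw: float,
) -> float:
    """Invert the forward model: adult CL_R -> CL_int,T.

    Subtracts the filtration component, solves the well-stirred secretion
    term for CL_int,sec and unscales by cell density and kidney weight.
    Returns CL_int,T in uL/min per 10^6 cells.

    Raises
    ------
    NoSecretionError
        If ``clr_adult <= fu_adult * gfr`` (nothing left for secretion).
    FlowLimitedError
        If the implied CL_ATS reaches the perfusion ceiling
        ``(qr - gfr) * bp``.
    """
    if min(clr_adult, fu_adult, bp, gfr, qr, ptcpgk, kw) <= 0:
        raise ValueError("all inputs must be strictly positive")
    if qr <= gfr:
        raise ValueError("renal blood flow must exceed GFR")
    cl_ats = clr_adult - fu_adult * gfr
    if cl_ats <= 0:
        raise NoSecretionError(
            "adult CL_R does not exceed f_u*GFR: no secretion component"
        )
    headroom = (qr - gfr) - cl_ats / bp
    if headroom <= 0 or cl_ats >= (qr - gfr) * bp:
        raise FlowLimitedError(
            "implied CL_ATS at or above the perfusion ceiling: flow-limited, "
            "not invertible"
        )
    clint_sec = cl_ats * qr / (fu_adult * headroom)  # mL/min
    return clint_sec * 1000.0 / (ptcpgk * kw)  # -> uL/min per 10^6 cells


def retrograde_table(
    table: pd.DataFrame,
    gfr: float,
    qr: float,
    hematocrit: float,
    ptcpgk: float,
    kw: float,
) -> pd.DataFrame:
    """Apply the retrograde calculation to a table of adult observations.

    ``table`` needs columns ``drug_id``, ``clr_adult``, ``fu_adult`` and
    either ``bp`` or ``kp`` (Kp is converted to BP with the supplied adult
    hematocrit).  Returns a copy with ``clint_t`` added; rows that cannot
    be inverted carry NaN and a reason in ``retrograde_error``.
    """
    required = {"drug_id", "clr_adult", "fu_adult"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if "bp" not in table.columns and "kp" not in table.columns:
        raise ValueError("table must have a 'bp' or 'kp' column")
    out = table.copy()
    values, errors = [], []
    for row in out.itertuples(index=False):
        bp = (
            float(row.bp)
            if "bp" in out.columns
            else 1.0 + hematocrit * (float(row.fu_adult) * float(row.kp) - 1.0)
        )
        try:
            values.append(
                retrograde_clint_t(
                    float(row.clr_adult), float(row.fu_adult), bp,
                    gfr, qr, ptcpgk, kw,
                )
            )
            errors.append("")
        except ValueError as exc:
            values.append(float("nan"))
            errors.append(str(exc))
    out["clint_t"] = values
    out["retrograde_error"] = errors
    return out
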