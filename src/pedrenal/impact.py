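"""Impact of ignoring transporter ontogeny: %PD and acceptability.

The percentage prediction difference (%PD) compares the renal clearance
predicted while ignoring transporter ontogeny (ont_T = 1, the naive adult
extrapolation) with the prediction that includes it:

    %PD = 100 * (CL_R[ont=1] - CL_R[ont]) / CL_R[ont]

Because every ontogeny fraction lies in (0, 1], ignoring it can only
over-predict, so %PD is non-negative.  Predictions are *acceptable* below
30%, *reasonably acceptable* between 30 and 50% (inclusive) and
*unacceptable* above 50%.  An age/scenario is *systematically* acceptable
only when the maximum %PD over the entire drug grid stays below 30% — a
single badly predicted drug breaks systematic acceptability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ACCEPTABLE_LIMIT = 30.0
REASONABLE_LIMIT = 50.0


@dataclass(frozen=True)
class PDResult:
    """%PD for one (drug, individual, scenario)."""

    drug_id: int
    individual: str
    scenario: str
    pd_percent: float
    acceptability: str


@dataclass(frozen=True)
class HeatmapSummary:
    """Min/median/max %PD over the drug grid for one scenario and age."""

    transporter: str
    age_label: str
    pd_min: float
    pd_median: float
    pd_max: float
    systematic_class: str

    def __post_init__(self) -> None:
        if not self.pd_min <= self.pd_median <= self.pd_max:
            raise ValueError("%PD summary must satisfy min <= median <= max")


def percent_prediction_difference(
    clr_adult_ont: float, clr_pediatric_ont: float
) -> float:
    """%PD between the ontogeny-free and ontogeny-aware predictions."""
    if clr_adult_ont <= 0 or clr_pediatric_ont <= 0:
        raise ValueError("clearances must be strictly positive")
    return 100.0 * (clr_adult_ont - clr_pediatric_ont) / clr_pediatric_ont


def classify_pd(pd_percent: float) -> str:
    """Acceptability class of a %PD value (30 and 50 fall in the middle class)."""
    if pd_percent < 0:
        raise ValueError("%PD cannot be negative for ontogeny fractions <= 1")
    if pd_percent < ACCEPTABLE_LIMIT:
        return "acceptable"
    if pd_percent <= REASONABLE_LIMIT:
        return "reasonably_acceptable"
    return "unacceptable"


def classify_systematic(pd_max: float) -> str:
    """Systematic acceptability of an age/scenario from the grid-wide max %PD."""
    if pd_max < ACCEPTABLE_LIMIT:
        return "acceptable"
    if pd_max <= REASONABLE_LIMIT:
        return "reasonably_acceptable"
    return "not_acceptable"


def systematic_acceptability(
    pds: Iterable[PDResult] | Sequence[float],
    age_label: str,
    transporter: str = "",
) -> HeatmapSummary:
    """Summarize %PD over the full drug grid at one age.

    Accepts either :class:`PDResult` records or bare %PD values.  The
    median is midpoint-interpolated for even counts.
    """
    values = np.asarray(
        [p.pd_percent if isinstance(p, PDResult) else float(p) for p in pds],
        dtype=float,
    )
    if values.size == 0:
        raise ValueError("cannot summarize an empty %PD collection")
    pd_max = float(values.max())
    return HeatmapSummary(
        transporter=transporter,
        age_label=age_label,
        pd_min=float(values.min()),
        pd_median=float(np.median(values)),
        pd_max=pd_max,
        systematic_class=classify_systematic(pd_max),
    )


def heatmap_table(pd_table: pd.DataFrame) -> pd.DataFrame:
    """Scenario x age heat-map summary from a long-format %PD table.

    ``pd_table`` needs columns ``scenario``, ``individual`` and
    ``pd_percent``; row order follows first appearance in the input.
    """
    for col in ("scenario", "individual", "pd_percent"):
        if col not in pd_table.columns:
            raise ValueError(f"%PD table lacks column {col!r}")
    rows = []
    for (scenario, age), grp in pd_table.groupby(
        ["scenario", "individual"], sort=False
    ):
        s = systematic_acceptability(
            grp["pd_percent"].to_numpy(), age_label=age, transporter=scenario
        )
        rows.append(
            {
                "scenario": scenario,
                "individual": age,
                "pd_min": s.pd_min,
                "pd_median": s.pd_median,
                "pd_max": s.pd_max,
                "systematic_class": s.systematic_class,
            }
        )
    return pd.DataFrame(rows)
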