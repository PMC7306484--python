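"""Headline aggregates of the simulation study.

Computes the summary quantities the original analysis reports in prose —
mean pathway contributions by CL_int,T stratum, mean CL_R by
(CL_int,T, f_u,adult) stratum with their fold-changes, the Kp sensitivity
ratios and the %PD extrema for the constant-ontogeny scenarios — and pairs
each with its published reference value for side-by-side inspection.

Averaging scopes
----------------
The pathway-contribution means are taken over all HSA-binding grid drugs
(11 f_u x 5 Kp) and all nine individuals.  The mean-CL_R strata follow the
age profiles of the representative drugs (Kp = 1) averaged over the eight
pediatric ages; both scopes are explicit keyword arguments.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .physiology import ALL_LABELS, PEDIATRIC_LABELS

#: Published reference values of the original analysis, used only for
#: side-by-side display in the report; never fed back into a computation.
REFERENCE_VALUES = {
    "ats_contribution_clint5": 41.0,
    "ats_contribution_clint50": 80.0,
    "ats_contribution_clint500": 90.0,
    "ats_contribution_clint5_neonate": 52.0,
    "mean_clr_clint5_fu005": 3.0,
    "mean_clr_clint5_fu095": 46.0,
    "mean_clr_clint50_fu005": 11.0,
    "mean_clr_clint50_fu095": 130.0,
    "mean_clr_clint500_fu095": 238.0,
    "fold_clr_fu_clint5": 15.0,
    "fold_clr_fu_clint50": 12.0,
    "fold_clr_clint_5_to_50": 2.8,
    "fold_clr_clint_50_to_500": 1.8,
    "kp_ratio_clint50_fu055": 1.15,
    "kp_ratio_clint500_fu095": 1.25,
    "pd_max_gf_drugs_under6mo": 113.0,
    "pd_max_ats_low_fu": 918.0,
    "pd_max_clint50": 316.0,
}


def _require_nonempty(df: pd.DataFrame, what: str) -> pd.DataFrame:
    if df.empty:
        raise ValueError(f"empty stratum: {what}")
    return df


def mean_ats_contribution(
    clearance: pd.DataFrame,
    clint_t: float,
    protein: str = "HSA",
    individuals: Sequence[str] = ALL_LABELS,
    scenario: str = "fixed_adult",
) -> float:
    """Mean ATS contribution (%) over all f_u and Kp for one CL_int,T."""
    sub = clearance[
        (clearance["scenario"] == scenario)
        & (clearance["binding_protein"] == protein)
        & (clearance["clint_t"] == clint_t)
        & clearance["individual"].isin(individuals)
    ]
    return float(
        _require_nonempty(sub, f"clint_t={clint_t}")["ats_contribution"].mean()
    )


def mean_clr(
    clearance: pd.DataFrame,
    clint_t: float,
    fu_adult: float,
    kp_values: Sequence[float] = (1.0,),
    protein: str = "HSA",
    individuals: Sequence[str] = PEDIATRIC_LABELS,
    scenario: str = "fixed_adult",
) -> float:
    """Mean CL_R (mL/min) for one (CL_int,T, f_u,adult) drug stratum."""
    sub = clearance[
        (clearance["scenario"] == scenario)
        & (clearance["binding_protein"] == protein)
        & (clearance["clint_t"] == clint_t)
        & (clearance["fu_adult"] == fu_adult)
        & clearance["kp"].isin(kp_values)
        & clearance["individual"].isin(individuals)
    ]
    return float(
        _require_nonempty(sub, f"clint_t={clint_t}, fu={fu_adult}")["cl_r"].mean()
    )


def kp_fold_change(
    clearance: pd.DataFrame,
    clint_t: float,
    fu_adult: float,
    kp_lo: float = 1.0,
    kp_hi: float = 4.0,
    individuals: Sequence[str] = ALL_LABELS,
) -> float:
    """Fold-change of mean CL_R when Kp rises from ``kp_lo`` to ``kp_hi``."""
    hi = mean_clr(clearance, clint_t, fu_adult, (kp_hi,), individuals=individuals)
    lo = mean_clr(clearance, clint_t, fu_adult, (kp_lo,), individuals=individuals)
    return hi / lo


def pd_extrema(pd_table: pd.DataFrame) -> dict[str, float]:
    """Maximum %PD for the representative-drug strata of the
    constant-ontogeny analysis.

    The nine representative drugs bind HSA, have Kp = 1 and span
    f_u,adult in {0.05, 0.55, 0.95} x CL_int,T in {5, 50, 500}.
    """
    const = pd_table[
        pd_table["scenario"].str.startswith("constant:")
        & (pd_table["binding_protein"] == "HSA")
        & (pd_table["kp"] == 1.0)
        & pd_table["fu_adult"].isin((0.05, 0.55, 0.95))
    ].copy()
    _require_nonempty(const, "constant-ontogeny scenarios, representative drugs")
    ont = const["ont_t"].astype(float)
    out = {}
    # GF-dominated drugs, under 6 months, underdeveloped transporters.
    sub = const[
        (const["clint_t"] == 5.0)
        & (ont < 0.2)
        & const["individual"].isin(("1 day", "1 month", "3 months"))
    ]
    out["pd_max_gf_drugs_under6mo"] = float(
        _require_nonempty(sub, "GF drugs under 6 months")["pd_percent"].max()
    )
    # Secretion-dominated, highly bound drugs at low ontogeny.
    sub = const[
        (const["clint_t"] >= 50.0) & (const["fu_adult"] == 0.05) & (ont <= 0.5)
    ]
    out["pd_max_ats_low_fu"] = float(
        _require_nonempty(sub, "ATS drugs, fu=0.05")["pd_percent"].max()
    )
    # CL_int,T = 50 drugs with medium-to-high unbound fraction, low ontogeny.
    sub = const[
        (const["clint_t"] == 50.0) & (const["fu_adult"] >= 0.55) & (ont <= 0.2)
    ]
    out["pd_max_clint50"] = float(
        _require_nonempty(sub, "clint_t=50, low ontogeny")["pd_percent"].max()
    )
    return out


def summarize_results_numbers(
    tables: dict[str, pd.DataFrame],
    contribution_individuals: Sequence[str] = ALL_LABELS,
    clr_individuals: Sequence[str] = PEDIATRIC_LABELS,
    clr_kp_values: Sequence[float] = (1.0,),
) -> pd.DataFrame:
    """Compute the headline aggregates from the study tables.

    Returns a table with one row per quantity: the computed value and the
    published reference value.  Raises on any missing stratum.
    """
    clearance = tables["clearance"]
    values: dict[str, float] = {}
    for clint in (5.0, 50.0, 500.0):
        values[f"ats_contribution_clint{clint:g}"] = mean_ats_contribution(
            clearance, clint, individuals=contribution_individuals
        )
    values["ats_contribution_clint5_neonate"] = mean_ats_contribution(
        clearance, 5.0, individuals=("1 day",)
    )
    for clint, fu in ((5.0, 0.05), (5.0, 0.95), (50.0, 0.05), (50.0, 0.95),
                      (500.0, 0.95)):
        values[f"mean_clr_clint{clint:g}_fu{fu:.2f}".replace(".", "", 1)] = mean_clr(
            clearance, clint, fu, clr_kp_values, individuals=clr_individuals
        )
    # fold-changes between strata
    values["fold_clr_fu_clint5"] = (
        values["mean_clr_clint5_fu095"] / values["mean_clr_clint5_fu005"]
    )
    values["fold_clr_fu_clint50"] = (
        values["mean_clr_clint50_fu095"] / values["mean_clr_clint50_fu005"]
    )
    values["fold_clr_clint_5_to_50"] = (
        values["mean_clr_clint50_fu095"] / values["mean_clr_clint5_fu095"]
    )
    values["fold_clr_clint_50_to_500"] = (
        values["mean_clr_clint500_fu095"] / values["mean_clr_clint50_fu095"]
    )
    values["kp_ratio_clint50_fu055"] = kp_fold_change(clearance, 50.0, 0.55)
    values["kp_ratio_clint500_fu095"] = kp_fold_change(clearance, 500.0, 0.95)
    if "pd" in tables:
        values.update(pd_extrema(tables["pd"]))
    return pd.DataFrame(
        {
            "quantity": list(values),
            "value": [values[k] for k in values],
            "reference": [REFERENCE_VALUES.get(k) for k in values],
        }
    )
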