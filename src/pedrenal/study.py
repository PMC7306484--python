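"""End-to-end study orchestration.

Runs the clearance model over the full drug grid, the nine typical
individuals and a list of ontogeny scenarios, producing long-format tables:
per-row clearance results, %PD against the ontogeny-free reference, the
scenario x age heat-map summary and pathway-contribution summaries.  The
grid evaluation is vectorized over drugs, so a full default run (4290 drugs
x 9 individuals x 11 scenarios) completes in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import drug_space, impact
from .clearance import PERFUSION_LIMIT, PERMEABILITY_LIMIT
from .ontogeny import OntogenyScenario, ont_evaluate
from .physiology import (
    ALL_LABELS,
    PEDIATRIC_LABELS,
    SystemParameters,
    TypicalIndividual,
    adult_protein_concentration,
    load_individuals,
    system_parameters,
)

logger = logging.getLogger(__name__)

DEFAULT_SCENARIOS = (
    "fixed_adult",
    "constant:0.05",
    "constant:0.2",
    "constant:0.5",
    "constant:0.7",
    "published:PGP",
    "published:OAT1",
    "published:OAT3",
    "published:OCT2",
    "published:ATS_HAYTON",
    "published:ATS_DEWOSKIN",
)

CLEARANCE_COLUMNS = (
    "scenario", "individual", "binding_protein", "fu_adult", "kp", "clint_t",
    "ont_t", "fu_age", "bp", "clint_sec", "cl_gf", "cl_ats", "cl_r",
    "gfr_contribution", "ats_contribution", "flow_ratio", "limitation",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one study run; the defaults reproduce the study grid."""

    scenarios: tuple[str, ...] = DEFAULT_SCENARIOS
    individuals: tuple[str, ...] = ALL_LABELS
    proteins: tuple[str, ...] = drug_space.BINDING_PROTEINS
    fu_values: tuple[float, ...] = drug_space.FU_ADULT_GRID
    kp_values: tuple[float, ...] = drug_space.KP_GRID
    clint_values: tuple[float, ...] | None = None  # None -> 39-point grid
    oct2_corrected: bool = False
    pediatric_pd_only: bool = True  # heat map over the eight pediatric ages
    output_dir: Path | None = None

    def drug_frame(self) -> pd.DataFrame:
        return drug_space.drug_grid_frame(
            proteins=self.proteins,
            fu_values=self.fu_values,
            kp_values=self.kp_values,
            clint_values=(
                None if self.clint_values is None else list(self.clint_values)
            ),
        )


def evaluate_drug_frame(
    drugs: pd.DataFrame,
    ind: TypicalIndividual,
    sys: SystemParameters,
    ont_t: float,
    scenario_name: str,
) -> pd.DataFrame:
    """Vectorized clearance evaluation of a drug table for one individual.

    Mirrors :func:`pedrenal.clearance.renal_clearance` column-wise; the two
    implementations are cross-checked in the test suite.
    """
    fu_adult = drugs["fu_adult"].to_numpy(float)
    kp = drugs["kp"].to_numpy(float)
    clint_t = drugs["clint_t"].to_numpy(float)
    is_hsa = (drugs["binding_protein"] == "HSA").to_numpy()

    ratio = np.where(
        is_hsa,
        sys.hsa_conc / adult_protein_concentration("HSA"),
        sys.agp_conc / adult_protein_concentration("AGP"),
    )
    fu = 1.0 / (1.0 + (1.0 - fu_adult) * ratio / fu_adult)
    bp = 1.0 + sys.hematocrit_fraction * (fu * kp - 1.0)
    if np.any(bp <= 0):
        raise ValueError("blood-to-plasma ratio must be positive on the grid")
    sec = clint_t * ont_t * sys.ptcpgk * sys.kidney_weight / 1000.0
    cl_gf = fu * sys.gfr
    cl_ats = (sys.qr - sys.gfr) * fu * sec / (sys.qr + fu * sec / bp)
    cl_r = cl_gf + cl_ats
    flow_ratio = cl_r / sys.qr
    limitation = np.where(
        flow_ratio < PERMEABILITY_LIMIT,
        "permeability",
        np.where(flow_ratio > PERFUSION_LIMIT, "perfusion", "mixed"),
    )
    return pd.DataFrame(
        {
            "scenario": scenario_name,
            "individual": ind.label,
            "binding_protein": drugs["binding_protein"].to_numpy(),
            "fu_adult": fu_adult,
            "kp": kp,
            "clint_t": clint_t,
            "ont_t": ont_t,
            "fu_age": fu,
            "bp": bp,
            "clint_sec": sec,
            "cl_gf": cl_gf,
            "cl_ats": cl_ats,
            "cl_r": cl_r,
            "gfr_contribution": 100.0 * cl_gf / cl_r,
            "ats_contribution": 100.0 * cl_ats / cl_r,
            "flow_ratio": flow_ratio,
            "limitation": limitation,
        }
    )


def run_study(config: RunConfig = RunConfig()) -> dict[str, pd.DataFrame]:
    """Run the full simulation study.

    Returns a dict of tables: ``clearance`` (one row per drug x individual x
    scenario), ``pd`` (%PD against the ontogeny-free reference), ``heatmap``
    (scenario x age min/median/max %PD with systematic acceptability) and
    ``contributions`` (mean pathway shares by scenario, protein and
    CL_int,T).  If ``config.output_dir`` is set, each table is also written
    as CSV with a stable row order.
    """
    drugs = config.drug_frame()
    individuals = [i for i in load_individuals() if i.label in config.individuals]
    if not individuals:
        raise ValueError("no valid individuals selected")
    scenarios = [OntogenyScenario.parse(s) for s in config.scenarios]
    logger.info(
        "run: %d drugs x %d individuals x %d scenarios "
        "(CO in L/h, fr as CO-fraction, CL_int,T in uL/min/10^6 cells)",
        len(drugs), len(individuals), len(scenarios),
    )

    reference = OntogenyScenario.fixed_adult()
    frames: list[pd.DataFrame] = []
    ref_frames: dict[str, pd.DataFrame] = {}
    for ind in individuals:
        sys = system_parameters(ind)
        ref_frames[ind.label] = evaluate_drug_frame(
            drugs, ind, sys, ont_evaluate(reference, ind), reference.name
        )
        for scen in scenarios:
            if scen.name == reference.name:
                frames.append(ref_frames[ind.label])
                continue
            ont = ont_evaluate(scen, ind, oct2_corrected=config.oct2_corrected)
            frames.append(evaluate_drug_frame(drugs, ind, sys, ont, scen.name))
    clearance = pd.concat(frames, ignore_index=True)

    pd_rows = []
    for scen in scenarios:
        for ind in individuals:
            if config.pediatric_pd_only and ind.label not in PEDIATRIC_LABELS:
                continue
            ref = ref_frames[ind.label]
            sub = clearance[
                (clearance["scenario"] == scen.name)
                & (clearance["individual"] == ind.label)
            ].reset_index(drop=True)
            pdp = 100.0 * (ref["cl_r"].to_numpy() - sub["cl_r"].to_numpy()) / sub[
                "cl_r"
            ].to_numpy()
            frame = sub[
                ["scenario", "individual", "binding_protein", "fu_adult", "kp",
                 "clint_t", "ont_t"]
            ].copy()
            frame["pd_percent"] = pdp
            frame["acceptability"] = np.where(
                pdp < impact.ACCEPTABLE_LIMIT,
                "acceptable",
                np.where(
                    pdp <= impact.REASONABLE_LIMIT,
                    "reasonably_acceptable",
                    "unacceptable",
                ),
            )
            pd_rows.append(frame)
    pd_table = pd.concat(pd_rows, ignore_index=True)

    heatmap = impact.heatmap_table(pd_table)
    contributions = (
        clearance.groupby(["scenario", "binding_protein", "clint_t"], sort=False)[
            ["gfr_contribution", "ats_contribution", "cl_r"]
        ]
        .mean()
        .reset_index()
    )

    tables = {
        "clearance": clearance,
        "pd": pd_table,
        "heatmap": heatmap,
        "contributions": contributions,
    }
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        logger.info("tables written to %s", out)
    return tables
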