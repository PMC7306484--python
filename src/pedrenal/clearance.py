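"""The forward renal-clearance model.

Total renal plasma clearance is the serial sum of glomerular filtration and
active tubular secretion, with the secretion pathway described by a
well-stirred kidney term:

    CL_R = f_u * GFR + (Q_R - GFR) * f_u * CL_int,sec
                       ---------------------------------
                        Q_R + f_u * CL_int,sec / BP

Only unbound drug in plasma is filtered or secreted; drug bound to plasma
proteins or partitioned into erythrocytes is unavailable.  Reabsorption,
renal metabolism and passive permeability are deliberately absent from the
model.  CL_int,sec is the whole-kidney intrinsic secretion clearance,
obtained by scaling the per-cell transporter-mediated intrinsic clearance
CL_int,T by the ontogeny fraction, the proximal-tubule cell density and the
kidney weight.
"""

from __future__ import annotations

from dataclasses import dataclass

from .drug_space import HypotheticalDrug
from .physiology import SystemParameters, adult_protein_concentration, fu_pediatric

#: CL_R/Q_R thresholds separating permeability- from perfusion-limited
#: secretion regimes.
PERMEABILITY_LIMIT = 0.3
PERFUSION_LIMIT = 0.7


@dataclass(frozen=True)
class ClearanceResult:
    """All pathway-level outputs for one (drug, individual, scenario)."""

    cl_gf: float  # mL/min
    cl_ats: float  # mL/min
    cl_r: float  # mL/min
    fu_age: float
    bp: float
    clint_sec: float  # mL/min
    gfr_contribution: float  # percent
    ats_contribution: float  # percent
    flow_ratio: float  # CL_R / Q_R
    limitation: str  # permeability | mixed | perfusion


def blood_plasma_ratio(hematocrit: float, fu_age: float, kp: float) -> float:
    """Blood-to-plasma concentration ratio: 1 + hematocrit*(f_u*Kp - 1).

    Hematocrit enters as a fraction.  Kp = 0 (no erythrocyte partitioning)
    gives BP = 1 - hematocrit.
    """
    if not 0 < hematocrit < 1:
        raise ValueError("hematocrit must be a fraction in (0, 1)")
    if not 0 < fu_age <= 1:
        raise ValueError("fraction unbound must lie in (0, 1]")
    if kp < 0:
        raise ValueError("Kp cannot be negative")
    bp = 1.0 + hematocrit * (fu_age * kp - 1.0)
    if bp <= 0:
        raise ValueError("blood-to-plasma ratio must be positive")
    return bp


def clint_sec(clint_t: float, ont_t: float, ptcpgk: float, kw: float) -> float:
    """Whole-kidney intrinsic secretion clearance in mL/min.

    clint_t is in uL/min per 10^6 proximal tubule cells, ptcpgk in 10^6
    cells per gram kidney, kw in grams; the product is converted uL -> mL.
    """
    if min(clint_t, ont_t, ptcpgk, kw) < 0:
        raise ValueError("all scaling inputs must be non-negative")
    return clint_t * ont_t * ptcpgk * kw / 1000.0


def fraction_unbound_at_age(drug: HypotheticalDrug, sys: SystemParameters) -> float:
    """Age-specific f_u for the drug's binding protein."""
    conc_ped = sys.hsa_conc if drug.binding_protein == "HSA" else sys.agp_conc
    conc_adult = adult_protein_concentration(drug.binding_protein)
    return fu_pediatric(drug.fu_adult, conc_ped, conc_adult)


def classify_flow_limitation(flow_ratio: float) -> str:
    """Classify the secretion regime from CL_R/Q_R."""
    if flow_ratio < PERMEABILITY_LIMIT:
        return "permeability"
    if flow_ratio > PERFUSION_LIMIT:
        return "perfusion"
    return "mixed"


def renal_clearance(
    drug: HypotheticalDrug, sys: SystemParameters, ont_t: float
) -> ClearanceResult:
    """Evaluate the serial filtration + secretion model for one grid point."""
    if not 0 <= ont_t <= 1:
        raise ValueError("ont_t must lie in [0, 1]")
    fu = fraction_unbound_at_age(drug, sys)
    bp = blood_plasma_ratio(sys.hematocrit_fraction, fu, drug.kp)
    sec = clint_sec(drug.clint_t, ont_t, sys.ptcpgk, sys.kidney_weight)
    cl_gf = fu * sys.gfr
    cl_ats = (
        (sys.qr - sys.gfr) * fu * sec / (sys.qr + fu * sec / bp) if sec > 0 else 0.0
    )
    cl_r = cl_gf + cl_ats
    flow_ratio = cl_r / sys.qr
    return ClearanceResult(
        cl_gf=cl_gf,
        cl_ats=cl_ats,
        cl_r=cl_r,
        fu_age=fu,
        bp=bp,
        clint_sec=sec,
        gfr_contribution=100.0 * cl_gf / cl_r,
        ats_contribution=100.0 * cl_ats / cl_r,
        flow_ratio=flow_ratio,
        limitation=classify_flow_limitation(flow_ratio),
    )
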