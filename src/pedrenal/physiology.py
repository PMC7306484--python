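"""Age-resolved renal physiology for typical pediatric and adult individuals.

Implements the system-parameter maturation functions of the mechanistic
kidney model: glomerular filtration rate (GFR), renal blood flow (cardiac
output times the renal fraction), hematocrit, kidney weight, and the plasma
concentrations of the two drug-binding proteins, human serum albumin (HSA)
and alpha-1-acid glycoprotein (AGP).  The nine demographic anchors (one day
to thirty-five years) ship as a package fixture and are the individuals on
which all downstream simulations run.

Unit conventions
----------------
* GFR and Q_R in mL/min; cardiac output internally in L/h with the renal
  fraction as a fraction of CO (percent/100); kidney weight in g.
* Each maturation function takes age in the unit its source used: days for
  the protein concentrations, years for cardiac output, renal fraction and
  hematocrit, postmenstrual weeks for GFR.
* Postmenstrual age assumes term birth: PMA_weeks = PNA_weeks + 40.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import pandas as pd

DAYS_PER_YEAR = 365.25
WEEKS_PER_YEAR = 52.18
TERM_GESTATION_WEEKS = 40.0
ADULT_AGE_YEARS = 35.0
ADULT_AGE_DAYS = ADULT_AGE_YEARS * DAYS_PER_YEAR

#: Proximal tubule cells per gram kidney, in units of 10^6 cells/g.
#: Assumed age-invariant (adult value) for lack of ontogeny data.
PTCPGK = 60.0

Protein = Literal["HSA", "AGP"]


@dataclass(frozen=True)
class TypicalIndividual:
    """One demographic anchor with age expressed in every unit the model needs.

    The nine shipped instances (see :func:`load_individuals`) carry the
    hematocrit of record; synthetic individuals built with :meth:`from_age`
    fall back on the hematocrit maturation function.
    """

    label: str
    age_years: float
    age_days: float
    pna_weeks: float
    pma_weeks: float
    weight: float  # kg
    height: float  # cm
    bsa: float  # m^2
    hematocrit_fraction: float

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.bsa <= 0:
            raise ValueError("weight and BSA must be positive")
        if not 0 < self.hematocrit_fraction < 1:
            raise ValueError("hematocrit must be a fraction in (0, 1)")
        if self.age_days < 0:
            raise ValueError("age cannot be negative")

    @classmethod
    def from_age(
        cls,
        label: str,
        age_years: float,
        weight: float,
        bsa: float,
        height: float = float("nan"),
        hematocrit_fraction: float | None = None,
    ) -> "TypicalIndividual":
        """Build a synthetic individual at an arbitrary age.

        Hematocrit defaults to the maturation formula; the anchors instead
        use their tabulated values.
        """
        if hematocrit_fraction is None:
            hematocrit_fraction = hematocrit_maturation(age_years)
        pna = age_years * WEEKS_PER_YEAR
        return cls(
            label=label,
            age_years=age_years,
            age_days=age_years * DAYS_PER_YEAR,
            pna_weeks=pna,
            pma_weeks=pna + TERM_GESTATION_WEEKS,
            weight=weight,
            height=height,
            bsa=bsa,
            hematocrit_fraction=hematocrit_fraction,
        )


@dataclass(frozen=True)
class SystemParameters:
    """Age-resolved physiology feeding the clearance model.

    gfr, qr in mL/min; co in L/h; kidney_weight in g; ptcpgk in 10^6
    cells/g; protein concentrations in g/L.
    """

    gfr: float
    qr: float
    co: float
    renal_fraction: float
    hematocrit_fraction: float
    kidney_weight: float
    ptcpgk: float
    hsa_conc: float
    agp_conc: float

    def __post_init__(self) -> None:
        for name in ("gfr", "qr", "co", "renal_fraction", "hematocrit_fraction",
                     "kidney_weight", "ptcpgk", "hsa_conc", "agp_conc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def load_individuals() -> tuple[TypicalIndividual, ...]:
    """The nine typical individuals (1 day ... adult) of the study."""
    path = resources.files("pedrenal.data").joinpath("individuals.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    out = []
    for row in df.itertuples(index=False):
        age_days = float(row.age_days)
        age_years = age_days / DAYS_PER_YEAR
        pna = age_years * WEEKS_PER_YEAR
        out.append(
            TypicalIndividual(
                label=str(row.label),
                age_years=age_years,
                age_days=age_days,
                pna_weeks=pna,
                pma_weeks=pna + TERM_GESTATION_WEEKS,
                weight=float(row.weight_kg),
                height=float(row.height_cm),
                bsa=float(row.bsa_m2),
                hematocrit_fraction=float(row.hematocrit_pct) / 100.0,
            )
        )
    return tuple(out)


def individual(label: str) -> TypicalIndividual:
    """Look up one of the nine anchors by its label (e.g. ``"6 months"``)."""
    for ind in load_individuals():
        if ind.label == label:
            return ind
    raise KeyError(f"unknown individual label: {label!r}")


PEDIATRIC_LABELS = (
    "1 day", "1 month", "3 months", "6 months",
    "1 year", "2 years", "5 years", "15 years",
)
ALL_LABELS = PEDIATRIC_LABELS + ("Adult",)


def gfr_maturation(weight: float, pma_weeks: float) -> float:
    """Glomerular filtration rate (mL/min) from weight and postmenstrual age.

    Allometric weight scaling to the 70-kg adult reference combined with a
    sigmoid maturation in PMA (half-maximal at 55.4 weeks, Hill 3.3).
    """
    if weight <= 0 or pma_weeks <= 0:
        raise ValueError("weight and postmenstrual age must be positive")
    sig = pma_weeks**3.3 / (pma_weeks**3.3 + 55.4**3.3)
    return 112.0 * (weight / 70.0) ** 0.63 * sig


def protein_concentration(age_days: float, protein: Protein) -> float:
    """Plasma concentration (g/L) of HSA or AGP at a given postnatal age.

    Both published expressions are treated as absolute concentrations; the
    pediatric/adult ratio needed by :func:`fu_pediatric` is formed by the
    caller against the value at the adult reference age.
    """
    if age_days < 1:
        raise ValueError("age_days must be >= 1 (log divergence below one day)")
    if protein == "HSA":
        return 1.1287 * math.log(age_days) + 33.746
    if protein == "AGP":
        return 0.887 * age_days**0.38 / (8.89**0.38 + age_days**0.38)
    raise ValueError(f"unknown binding protein: {protein!r}")


def adult_protein_concentration(protein: Protein) -> float:
    """Reference concentration at the 35-year adult age."""
    return protein_concentration(ADULT_AGE_DAYS, protein)


def fu_pediatric(fu_adult: float, conc_ped: float, conc_adult: float) -> float:
    """Age-adjusted fraction unbound from the binding-protein concentration ratio.

    Assumes one binding protein and a constant affinity, so the bound:free
    ratio scales with protein concentration.
    """
    if not 0 < fu_adult <= 1:
        raise ValueError("fu_adult must lie in (0, 1]")
    if conc_ped <= 0 or conc_adult <= 0:
        raise ValueError("protein concentrations must be positive")
    return 1.0 / (1.0 + (1.0 - fu_adult) * conc_ped / (conc_adult * fu_adult))


def cardiac_output(bsa: float, age_years: float) -> float:
    """Cardiac output in L/h from body surface area and age in years.

    The bracket is the cardiac index (L/h/m^2): 110 at birth, peaking near
    210 in childhood and settling at ~159 in the adult; BSA converts it to
    whole-body output.
    """
    if bsa <= 0 or age_years < 0:
        raise ValueError("BSA must be positive and age non-negative")
    return bsa * (
        110.0 + 184.0 * (math.exp(-0.0378 * age_years) - math.exp(-0.24477 * age_years))
    )


def renal_fraction(age_years: float) -> float:
    """Fraction of cardiac output perfusing the kidneys (sex-averaged).

    Both sexes start at 4.53% at birth and saturate near 19.2% (males) and
    17.5% (females); the model always averages the two.
    """
    if age_years < 0:
        raise ValueError("age cannot be negative")
    males = 4.53 + 14.63 * age_years / (0.1888 + age_years)
    females = 4.53 + 13.0 * age_years**1.15 / (0.188**1.15 + age_years**1.15)
    return (males + females) / 2.0 / 100.0


def renal_blood_flow(ind: TypicalIndividual) -> float:
    """Renal blood flow Q_R in mL/min for one individual."""
    co = cardiac_output(ind.bsa, ind.age_years)  # L/h
    fr = renal_fraction(ind.age_years)
    return co * fr * 1000.0 / 60.0


def hematocrit_maturation(age_years: float) -> float:
    """Sex-averaged hematocrit as a fraction, from age in years.

    Both sexes start at 53% in the neonate; the male and female curves are
    averaged.  The nine anchors use their tabulated hematocrit instead (the
    formula disagrees slightly with the table at 1 day).
    """
    if age_years < 0:
        raise ValueError("age cannot be negative")
    if age_years == 0:
        return 0.53
    a112 = age_years**1.12
    a025 = age_years**0.25
    male = 53.0 - (43.0 * a112 / (0.05**1.12 + a112)) * (
        1.0 - 0.93 * a025 / (0.10**0.25 + a025)
    )
    female = 53.0 - (37.4 * a112 / (0.05**1.12 + a112)) * (
        1.0 - 0.80 * a025 / (0.10**0.25 + a025)
    )
    return (male + female) / 2.0 / 100.0


def kidney_weight(weight: float) -> float:
    """Combined weight of both kidneys in grams, from body weight in kg.

    Kidney volume (L) from two sub-allometric terms, times a tissue density
    of 1050 g/L.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    return 1050.0 * (4.214 * weight**0.823 + 4.456 * weight**0.795) / 1000.0


def system_parameters(ind: TypicalIndividual) -> SystemParameters:
    """Assemble all age-resolved system parameters for one individual."""
    co = cardiac_output(ind.bsa, ind.age_years)
    fr = renal_fraction(ind.age_years)
    return SystemParameters(
        gfr=gfr_maturation(ind.weight, ind.pma_weeks),
        qr=co * fr * 1000.0 / 60.0,
        co=co,
        renal_fraction=fr,
        hematocrit_fraction=ind.hematocrit_fraction,
        kidney_weight=kidney_weight(ind.weight),
        ptcpgk=PTCPGK,
        hsa_conc=protein_concentration(max(ind.age_days, 1.0), "HSA"),
        agp_conc=protein_concentration(max(ind.age_days, 1.0), "AGP"),
    )
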