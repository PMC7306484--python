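"""Renal secretion-transporter ontogeny scenarios.

The transporter-mediated intrinsic clearance of a pediatric individual is
expressed as a fraction ``ont_T`` in (0, 1] of the adult value.  Three kinds
of scenario are supported:

* ``fixed_adult`` — ontogeny ignored, ont_T = 1 at every age;
* ``constant_fraction`` — ont_T held at a fixed fraction (the study grid
  uses 0.05, 0.2, 0.5 and 0.7) across the whole pediatric range;
* ``published`` — one of six literature age-varying functions: four
  transporter-specific sigmoids in postnatal age (P-gp, OAT1, OAT3, OCT2)
  and two aggregated active-tubular-secretion profiles (a continuous
  weight/age function and a step function over age groups).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .physiology import TypicalIndividual

TRANSPORTERS = ("NONE", "PGP", "OAT1", "OAT3", "OCT2", "ATS_HAYTON", "ATS_DEWOSKIN")
CONSTANT_FRACTIONS = (0.05, 0.2, 0.5, 0.7)

#: Step values of the aggregated tubular-secretion ontogeny of the
#: literature age-group compilation: (age in years at which the step starts,
#: secretion rate relative to the adult 79.8).  Values for children between
#: 1 and 18 years are the published child/adult averages.
_DEWOSKIN_STEPS = (
    (0.0, 20.3),        # neonate
    (1.0 / 12.0, 14.9),  # 1 month
    (0.25, 31.3),        # 3 months
    (0.5, 46.5),         # 6 months
    (1.0, 44.2),         # 1 year
    (2.0, 66.5),         # 2 years
    (5.0, 73.15),        # 5 years (child/adult average)
    (15.0, 73.15),       # 15 years
    (18.0, 79.8),        # adult
)
_DEWOSKIN_ADULT = 79.8

#: Body weight (kg) used to normalize the continuous aggregated function at
#: its 12-year maturity point; linear interpolation of the anchor table
#: between 5 y (18.25 kg) and 15 y (54.25 kg).
HAYTON_REFERENCE_WEIGHT_KG = 43.45
HAYTON_MATURE_AGE_YEARS = 12.0


@dataclass(frozen=True)
class OntogenyScenario:
    """One rule producing ont_T per individual."""

    kind: str  # fixed_adult | constant_fraction | published
    transporter: str = "NONE"
    constant_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_adult", "constant_fraction", "published"):
            raise ValueError(f"unknown scenario kind: {self.kind!r}")
        if self.transporter not in TRANSPORTERS:
            raise ValueError(f"unknown transporter: {self.transporter!r}")
        if self.kind == "constant_fraction":
            if self.constant_value is None or not 0 < self.constant_value <= 1:
                raise ValueError("constant_fraction needs constant_value in (0, 1]")
        if self.kind == "published" and self.transporter == "NONE":
            raise ValueError("published scenario needs a transporter")

    @property
    def name(self) -> str:
        if self.kind == "fixed_adult":
            return "fixed_adult"
        if self.kind == "constant_fraction":
            return f"constant:{self.constant_value:g}"
        return f"published:{self.transporter}"

    @classmethod
    def fixed_adult(cls) -> "OntogenyScenario":
        return cls(kind="fixed_adult")

    @classmethod
    def constant(cls, value: float) -> "OntogenyScenario":
        return cls(kind="constant_fraction", constant_value=value)

    @classmethod
    def published(cls, transporter: str) -> "OntogenyScenario":
        return cls(kind="published", transporter=transporter)

    @classmethod
    def parse(cls, text: str) -> "OntogenyScenario":
        """Parse a scenario name: ``fixed_adult``, ``constant:0.2`` or
        ``published:OAT1``."""
        text = text.strip()
        if text == "fixed_adult":
            return cls.fixed_adult()
        if text.startswith("constant:"):
            return cls.constant(float(text.split(":", 1)[1]))
        if text.startswith("published:"):
            return cls.published(text.split(":", 1)[1])
        raise ValueError(f"cannot parse ontogeny scenario {text!r}")


def _cheung_sigmoid(pna_weeks: float, exponent: float, half_max: float,
                    half_max_exponent: float | None = None) -> float:
    # half_max_exponent allows the OCT2 function to be used exactly as
    # printed (numerator PNA^1 against 4.38^0.51 in the denominator).
    if half_max_exponent is None:
        half_max_exponent = exponent
    num = pna_weeks**exponent
    return num / (num + half_max**half_max_exponent)


def ont_pgp(pna_weeks: float) -> float:
    return _cheung_sigmoid(pna_weeks, 0.73, 4.02)


def ont_oat1(pna_weeks: float) -> float:
    return _cheung_sigmoid(pna_weeks, 0.43, 19.71)


def ont_oat3(pna_weeks: float) -> float:
    return _cheung_sigmoid(pna_weeks, 0.51, 30.70)


def ont_oct2(pna_weeks: float, corrected: bool = False) -> float:
    """OCT2 ontogeny.

    As printed, the half-maximum constant carries exponent 0.51 while the
    postnatal age carries exponent 1; ``corrected=True`` switches to the
    internally consistent 4.38^1 variant.
    """
    if corrected:
        return _cheung_sigmoid(pna_weeks, 1.0, 4.38)
    return _cheung_sigmoid(pna_weeks, 1.0, 4.38, half_max_exponent=0.51)


def hayton_raw(weight_kg: float, age_years: float) -> float:
    """Unnormalized aggregated secretion capacity (arbitrary units)."""
    e = math.exp(-0.185 * age_years)
    w = weight_kg**1.04
    return 1.08 * w * e + 1.83 * w * (1.0 - e)


def ont_hayton(
    weight_kg: float,
    age_years: float,
    reference_weight_kg: float = HAYTON_REFERENCE_WEIGHT_KG,
) -> float:
    """Continuous aggregated ontogeny, normalized to its 12-year value.

    The source function covers ages up to 12 years; its 12-year value is
    taken as mature and assigned to older individuals (15-year-old, adult),
    so the fraction is capped at 1.
    """
    if age_years >= HAYTON_MATURE_AGE_YEARS:
        return 1.0
    ref = hayton_raw(reference_weight_kg, HAYTON_MATURE_AGE_YEARS)
    return min(hayton_raw(weight_kg, age_years) / ref, 1.0)


def dewoskin_interpolation(age_years: float) -> float:
    """Step-function aggregated ontogeny over literature age groups.

    Returns the secretion rate of the age group containing ``age_years``
    relative to the adult rate.  Not monotone: the 1-month group sits below
    the neonatal one, and 1 year below 6 months.
    """
    if age_years < 0:
        raise ValueError("age cannot be negative")
    value = _DEWOSKIN_STEPS[0][1]
    for start, v in _DEWOSKIN_STEPS:
        if age_years >= start:
            value = v
    return value / _DEWOSKIN_ADULT


def ont_evaluate(
    scenario: OntogenyScenario,
    ind: TypicalIndividual,
    oct2_corrected: bool = False,
    hayton_reference_weight_kg: float = HAYTON_REFERENCE_WEIGHT_KG,
) -> float:
    """Evaluate ont_T in (0, 1] for one scenario and one individual."""
    if scenario.kind == "fixed_adult":
        return 1.0
    if scenario.kind == "constant_fraction":
        # The reference adult keeps the adult transporter complement.
        return 1.0 if ind.label == "Adult" else float(scenario.constant_value)
    t = scenario.transporter
    if t == "PGP":
        return ont_pgp(ind.pna_weeks)
    if t == "OAT1":
        return ont_oat1(ind.pna_weeks)
    if t == "OAT3":
        return ont_oat3(ind.pna_weeks)
    if t == "OCT2":
        return ont_oct2(ind.pna_weeks, corrected=oct2_corrected)
    if t == "ATS_HAYTON":
        return ont_hayton(ind.weight, ind.age_years, hayton_reference_weight_kg)
    if t == "ATS_DEWOSKIN":
        return dewoskin_interpolation(ind.age_years)
    raise ValueError(f"unknown transporter: {t!r}")
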