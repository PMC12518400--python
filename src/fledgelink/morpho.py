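"""Morphometric and observational utilities.

Chick age from eighth-primary (P8) feather length via inversion of the
Gompertz growth curve, the visual sex-assignment decision rule used with
colour-ring resighting records, and 10-day age binning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

# Gompertz growth-curve constants for the eighth primary:
# P8(t) = P8_ASYMPTOTE * exp(-exp(-GROWTH_RATE * (t - INFLECTION_DAY)))
P8_ASYMPTOTE = 247.0  # mm
GROWTH_RATE = 0.095  # per day
INFLECTION_DAY = 19.3  # days

#: Situation codes whose visual sex identification counts as certain:
#: 1 seen copulating, 2 partner with clear difference, 5 partner molecularly
#: sexed, 7 incubated at night (female).  Codes 3, 4 and 6 are uncertain.
CERTAIN_CODES = frozenset({1, 2, 5, 7})
UNCERTAIN_CODES = frozenset({3, 4, 6})
VALID_CODES = CERTAIN_CODES | UNCERTAIN_CODES

AGE_WINDOW_MIN = 35  # days; fledging age, start of the post-fledging window
AGE_WINDOW_MAX = 136  # days; oldest chick with parental contact in the data


def p8_from_age(age_days: float) -> float:
    """Forward Gompertz curve: expected P8 length (mm) at a given age (days)."""
    return P8_ASYMPTOTE * math.exp(-math.exp(-GROWTH_RATE * (age_days - INFLECTION_DAY)))


def age_from_p8(p8_mm: float) -> float:
    """Chick age in days from P8 length in mm.

    Inverts the Gompertz growth curve, giving
    ``age = 19.3 - ln(-ln(p8/247)) / 0.095``.

    Parameters
    ----------
    p8_mm : float
        Length of the eighth primary in millimetres; must lie strictly
        between 0 and the asymptote (247 mm).

    Returns
    -------
    float
        Estimated age in days (real-valued; strictly increasing in p8).
    """
    if not (0.0 < p8_mm < P8_ASYMPTOTE):
        raise ValueError(
            f"P8 length must lie strictly between 0 and the Gompertz asymptote "
            f"{P8_ASYMPTOTE} mm; got {p8_mm!r}"
        )
    return INFLECTION_DAY - math.log(-math.log(p8_mm / P8_ASYMPTOTE)) / GROWTH_RATE


def bin_age(age_days: float) -> int:
    """Map an age in days to its 10-day age-class midpoint label.

    Class 40 covers 35-44 days, class 50 covers 45-54 days, and so on.
    Ages below 35 d are outside the post-fledging window and rejected.
    """
    if age_days < AGE_WINDOW_MIN:
        raise ValueError(
            f"age {age_days!r} is below the post-fledging window minimum "
            f"({AGE_WINDOW_MIN} d)"
        )
    return 40 + 10 * int((math.floor(age_days) - AGE_WINDOW_MIN) // 10)


Sex = Literal["female", "male", "unknown"]


@dataclass(frozen=True)
class SexEvidence:
    """One visual sex identification of a bird.

    ``situation_code`` is 1-7; ``claimed_sex`` is 'female' or 'male'.
    """

    bird_id: str
    situation_code: int
    claimed_sex: str
    date: str | None = None

    def __post_init__(self) -> None:
        if self.situation_code not in VALID_CODES:
            raise ValueError(
                f"unknown situation code {self.situation_code!r}; valid codes are 1-7"
            )
        if self.claimed_sex not in ("female", "male"):
            raise ValueError(f"claimed_sex must be 'female' or 'male', got {self.claimed_sex!r}")


@dataclass(frozen=True)
class SexAssignment:
    bird_id: str
    sex: Sex
    n_certain_f: int
    n_certain_m: int
    n_uncertain_f: int
    n_uncertain_m: int
    rule_fired: str  # only-certain-single-sex | majority-gt-2 | unresolved


def assign_sex(evidence: Iterable[SexEvidence], bird_id: str | None = None) -> SexAssignment:
    """Apply the visual sex-assignment decision rule to a bird's evidence.

    Certain identifications (codes 1, 2, 5, 7) of only a single sex settle
    the sex directly.  Otherwise the bird is assigned the majority sex when
    total female and male identifications (certain and uncertain combined)
    differ by more than two; in all remaining cases the sex is unknown.
    """
    evidence = list(evidence)
    if bird_id is None:
        bird_id = evidence[0].bird_id if evidence else ""
    ncf = sum(1 for e in evidence if e.situation_code in CERTAIN_CODES and e.claimed_sex == "female")
    ncm = sum(1 for e in evidence if e.situation_code in CERTAIN_CODES and e.claimed_sex == "male")
    nuf = sum(1 for e in evidence if e.situation_code in UNCERTAIN_CODES and e.claimed_sex == "female")
    num = sum(1 for e in evidence if e.situation_code in UNCERTAIN_CODES and e.claimed_sex == "male")

    if (ncf > 0) != (ncm > 0):  # certain identifications of exactly one sex
        sex: Sex = "female" if ncf > 0 else "male"
        rule = "only-certain-single-sex"
    else:
        total_f, total_m = ncf + nuf, ncm + num
        if abs(total_f - total_m) > 2:
            sex = "female" if total_f > total_m else "male"
            rule = "majority-gt-2"
        else:
            sex = "unknown"
            rule = "unresolved"
    return SexAssignment(bird_id, sex, ncf, ncm, nuf, num, rule)


def assign_sex_table(evidence_df) -> "pd.DataFrame":  # noqa: F821
    """Vector version: evidence DataFrame (bird_id, situation_code, claimed_sex)
    -> one assignment row per bird."""
    import pandas as pd

    rows = []
    for bird_id, grp in evidence_df.groupby("bird_id", sort=True):
        ev = [
            SexEvidence(str(bird_id), int(r.situation_code), str(r.claimed_sex))
            for r in grp.itertuples()
        ]
        a = assign_sex(ev, bird_id=str(bird_id))
        rows.append(vars(a) if not hasattr(a, "__dataclass_fields__") else {
            "bird_id": a.bird_id, "sex": a.sex,
            "n_certain_f": a.n_certain_f, "n_certain_m": a.n_certain_m,
            "n_uncertain_f": a.n_uncertain_f, "n_uncertain_m": a.n_uncertain_m,
            "rule_fired": a.rule_fired,
        })
    return pd.DataFrame(rows, columns=[
        "bird_id", "sex", "n_certain_f", "n_certain_m",
        "n_uncertain_f", "n_uncertain_m", "rule_fired",
    ])
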