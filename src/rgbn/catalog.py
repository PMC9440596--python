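"""Variable catalog and study-group definitions.

The model operates on 15 variables per participant: six anthropometric
covariates (age, weight, height, BMI, waist circumference, hip
circumference) and nine dual-energy X-ray absorptiometry (DXA) body
composition responses — fat, lean and bone mineral content (BMC) masses for
trunk, legs and arms.  Short codes follow the field's convention: TF = trunk
fat, TL = trunk lean, TB = trunk BMC, LF/LL/LB = leg, AF/AL/AB = arm.

Participants are split into four sex-by-pubertal-age groups around the
average age of puberty: girls at 13 years, boys at 14 years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Role = Literal["covariate", "response"]
Segment = Literal["trunk", "leg", "arm", "none"]
Tissue = Literal["fat", "lean", "bone", "none"]


@dataclass(frozen=True)
class Variable:
    name: str
    role: Role
    unit: str
    segment: Segment = "none"
    tissue: Tissue = "none"


#: The six easy-to-measure anthropometric predictors.
COVARIATES = (
    Variable("Age", "covariate", "year"),
    Variable("W", "covariate", "kg"),
    Variable("H", "covariate", "cm"),
    Variable("BMI", "covariate", "kg/m2"),
    Variable("WC", "covariate", "cm"),
    Variable("HC", "covariate", "cm"),
)

#: The nine segmental DXA compartments, in canonical report order.
RESPONSES = (
    Variable("TF", "response", "kg", "trunk", "fat"),
    Variable("TL", "response", "kg", "trunk", "lean"),
    Variable("TB", "response", "kg", "trunk", "bone"),
    Variable("LF", "response", "kg", "leg", "fat"),
    Variable("LL", "response", "kg", "leg", "lean"),
    Variable("LB", "response", "kg", "leg", "bone"),
    Variable("AF", "response", "kg", "arm", "fat"),
    Variable("AL", "response", "kg", "arm", "lean"),
    Variable("AB", "response", "kg", "arm", "bone"),
)

COVARIATE_NAMES = tuple(v.name for v in COVARIATES)
RESPONSE_NAMES = tuple(v.name for v in RESPONSES)
ALL_NAMES = COVARIATE_NAMES + RESPONSE_NAMES

#: Mapping from variable code to the cohort CSV column holding it.
CSV_COLUMNS = {
    "Age": "age",
    "W": "weight_kg",
    "H": "height_cm",
    "BMI": "bmi",
    "WC": "wc_cm",
    "HC": "hc_cm",
    "TF": "tf_kg",
    "TL": "tl_kg",
    "TB": "tb_kg",
    "LF": "lf_kg",
    "LL": "ll_kg",
    "LB": "lb_kg",
    "AF": "af_kg",
    "AL": "al_kg",
    "AB": "ab_kg",
}


@dataclass(frozen=True)
class VariableCatalog:
    """The full 15-variable catalog; validates the 6 + 9 structure."""

    variables: tuple[Variable, ...] = COVARIATES + RESPONSES

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in catalog")
        n_cov = sum(1 for v in self.variables if v.role == "covariate")
        n_resp = sum(1 for v in self.variables if v.role == "response")
        if (n_cov, n_resp) != (6, 9):
            raise ValueError(
                f"catalog must have 6 covariates and 9 responses, got {n_cov}/{n_resp}"
            )

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role == "covariate")

    @property
    def responses(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role == "response")


@dataclass(frozen=True)
class GroupSpec:
    """One sex-by-pubertal-age study group.

    ``side='older'`` means age >= cutoff (the boundary belongs to the older
    group, which reproduces the published group sizes), ``'younger'`` means
    age < cutoff.  The cutoff is 13 years for girls and 14 for boys.
    """

    sex: Literal["M", "F"]
    side: Literal["younger", "older"]

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.side not in ("younger", "older"):
            raise ValueError(f"side must be younger or older, got {self.side!r}")

    @property
    def age_cutoff(self) -> float:
        return 14.0 if self.sex == "M" else 13.0

    @property
    def label(self) -> str:
        word = "over" if self.side == "older" else "under"
        sex = "boys" if self.sex == "M" else "girls"
        return f"{sex}_{word}_{int(self.age_cutoff)}"

    @property
    def age_window(self) -> tuple[float, float]:
        """[low, high) age range used when simulating this group."""
        lo, hi = AGE_RANGE
        if self.side == "older":
            return (self.age_cutoff, hi)
        return (lo, self.age_cutoff)

    def contains(self, sex: str, age: float) -> bool:
        if sex != self.sex:
            return False
        return age >= self.age_cutoff if self.side == "older" else age < self.age_cutoff


#: Study recruitment age range, years.
AGE_RANGE = (9.0, 18.5)

GIRLS_OLDER = GroupSpec("F", "older")
GIRLS_YOUNGER = GroupSpec("F", "younger")
BOYS_OLDER = GroupSpec("M", "older")
BOYS_YOUNGER = GroupSpec("M", "younger")

#: The four groups in the order their sizes are reported.
GROUPS = (GIRLS_OLDER, GIRLS_YOUNGER, BOYS_OLDER, BOYS_YOUNGER)

#: Published per-group sample sizes (total 476: 235 girls, 241 boys).
GROUP_SIZES = {
    GIRLS_OLDER.label: 147,
    GIRLS_YOUNGER.label: 88,
    BOYS_OLDER.label: 136,
    BOYS_YOUNGER.label: 105,
}

GROUP_BY_LABEL = {g.label: g for g in GROUPS}
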