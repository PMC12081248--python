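"""Virtual individuals and populations.

Builds organ-scale physiologies (volumes, regional blood flows, enzyme and
transporter expression) from a versioned reference table, applies allometric
scaling for body size and age, assigns genotype-derived enzyme phenotypes,
and samples virtual populations with independent log-normal inter-individual
variability.

Units: volumes L, flows L/h, enzyme expression µmol/L, age years, weight kg,
height cm.
"""

from __future__ import annotations

import functools
import importlib.resources
from typing import Dict, List, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

ORGAN_NAMES = (
    "lung",
    "liver",
    "gut",
    "kidney",
    "muscle",
    "adipose",
    "skin",
    "brain",
    "heart",
    "bone",
    "spleen",
    "rest",
    "arterial_blood",
    "venous_blood",
)

#: organs whose perfusion sums to cardiac output (venous return)
SYSTEMIC_ORGANS = (
    "liver",
    "gut",
    "spleen",
    "kidney",
    "muscle",
    "adipose",
    "skin",
    "brain",
    "heart",
    "bone",
    "rest",
)


@functools.lru_cache(maxsize=1)
def reference_tables() -> dict:
    """Load the shipped reference-physiology table (cached)."""
    ref = importlib.resources.files("hsctpbpk.data") / "reference_physiology.yaml"
    return yaml.safe_load(ref.read_text())


class OrganCompartment(BaseModel):
    name: Literal[ORGAN_NAMES]  # type: ignore[valid-type]
    volume: float = Field(gt=0, description="L")
    blood_flow: float = Field(ge=0, description="L/h")


class EnzymeState(BaseModel):
    """One enzyme/transporter pool: baseline E0, current level E, turnover."""

    enzyme: str
    E0: float = Field(ge=0, description="µmol/L in expressing tissue")
    E: float = Field(ge=0, description="current pool, µmol/L")
    kdeg: float = Field(gt=0, description="1/h")
    expressing_organs: Dict[str, float]
    ontogeny_factor: float = Field(default=1.0, gt=0)

    @model_validator(mode="after")
    def _weights_sum_to_one(self):
        total = sum(self.expressing_organs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"expression weights for {self.enzyme} sum to {total}, expected 1"
            )
        return self


class IndividualPhysiology(BaseModel):
    age: float = Field(gt=0, description="years")
    weight: float = Field(gt=0, description="kg")
    height: float = Field(gt=0, description="cm")
    sex: Literal["male", "female"]
    ethnicity: str = "European"
    cardiac_output: float = Field(gt=0, description="L/h")
    organs: List[OrganCompartment]
    enzyme_states: Dict[str, EnzymeState]

    @model_validator(mode="after")
    def _conservation(self):
        by_name = {o.name: o for o in self.organs}
        missing = set(ORGAN_NAMES) - set(by_name)
        if missing:
            raise ValueError(f"missing compartments: {sorted(missing)}")
        q = sum(by_name[o].blood_flow for o in SYSTEMIC_ORGANS)
        if abs(q - self.cardiac_output) > 1e-9 * self.cardiac_output:
            raise ValueError(
                f"systemic flows sum to {q} L/h but cardiac output is "
                f"{self.cardiac_output} L/h"
            )
        vtot = sum(o.volume for o in self.organs)
        if vtot > 1.05 * self.weight:  # density 1 kg/L
            raise ValueError(
                f"organ volumes sum to {vtot:.1f} L exceeding body volume "
                f"{self.weight:.1f} L by more than 5%"
            )
        return self

    @property
    def organ(self) -> Dict[str, OrganCompartment]:
        return {o.name: o for o in self.organs}

    def copy_deep(self) -> "IndividualPhysiology":
        return self.model_copy(deep=True)


class PopulationSpec(BaseModel):
    """Specification of a virtual population.

    ``variability`` maps parameter names to geometric coefficients of
    variation of an independent log-normal (median-preserving) multiplier.
    Supported names: ``weight``, ``height``, ``cardiac_output`` and
    ``<ENZYME>.E0`` (e.g. ``CYP3A4.E0``).
    """

    n: int = Field(ge=1)
    ethnicity: str = "European"
    sex: Literal["male", "female"] = "male"
    age: float = 30.0
    variability: Dict[str, float] = Field(default_factory=dict)
    phenotype_frequencies: Dict[str, Dict[str, float]] = Field(default_factory=dict)
    seed: int = 0

    @field_validator("variability")
    @classmethod
    def _cv_nonneg(cls, v):
        for k, cv in v.items():
            if cv < 0:
                raise ValueError(f"negative CV for {k}")
        return v

    @field_validator("phenotype_frequencies")
    @classmethod
    def _freqs_sum(cls, v):
        for enz, freqs in v.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"phenotype frequencies for {enz} sum to {total}")
        return v


def ontogeny_factor(enzyme: str, age: float) -> float:
    """Piecewise-linear activity multiplier vs age; 1.0 where unspecified."""
    table = reference_tables().get("ontogeny", {})
    if enzyme not in table:
        return 1.0
    pts = table[enzyme]
    ages = [p[0] for p in pts]
    vals = [p[1] for p in pts]
    return float(np.interp(age, ages, vals))


def _default_anthropometrics(age: float, sex: str, ethnicity: str):
    demo = reference_tables()["demographics"]
    if age < 18:
        # simple pediatric growth approximation when weight/height omitted
        return 2.0 * age + 8.0, min(50.0 + 6.0 * age, 165.0)
    row = demo.get(ethnicity, demo["European"])[sex]
    return row["weight"], row["height"]


def build_individual(
    age: float = 30.0,
    weight: Optional[float] = None,
    height: Optional[float] = None,
    sex: str = "male",
    ethnicity: str = "European",
) -> IndividualPhysiology:
    """Build a complete physiology with all 14 compartments.

    Defaults follow the reference virtual subject: a 30-year-old male
    European at the mean weight/height of the demographic table. Organ
    volumes scale ~linearly with body weight (brain with a shallow
    exponent); regional flows are fixed fractions of cardiac output, which
    scales as weight^0.75, so venous return equals cardiac output exactly
    for every individual.
    """
    if age <= 0:
        raise ValueError("age must be positive")
    ref = reference_tables()
    w_def, h_def = _default_anthropometrics(age, sex, ethnicity)
    weight = w_def if weight is None else weight
    height = h_def if height is None else height
    for fname, val in (("weight", weight), ("height", height)):
        if val <= 0:
            raise ValueError(f"{fname} must be positive, got {val}")

    w_ref = ref["reference"]["weight_kg"]
    co_ref = ref["reference"]["cardiac_output_L_h"]
    allo = ref["allometry"]
    sex_adj = ref["sex_adjustments"].get(sex, {})

    co = co_ref * (weight / w_ref) ** allo["cardiac_output_exponent"]
    co *= sex_adj.get("cardiac_output", 1.0)

    organs = []
    for name in ORGAN_NAMES:
        v_ref = ref["volumes_L"][name]
        expo = (
            allo["volume_exponent_brain"]
            if name == "brain"
            else allo["volume_exponent_default"]
        )
        vol = v_ref * (weight / w_ref) ** expo
        vol *= sex_adj.get(name, 1.0)
        if name in SYSTEMIC_ORGANS:
            flow = ref["flow_fractions"][name] * co
        else:
            flow = co  # lung and blood pools route the full cardiac output
        organs.append(OrganCompartment(name=name, volume=vol, blood_flow=flow))

    enzyme_states = {}
    for enz, row in ref["enzymes"].items():
        ont = ontogeny_factor(enz, age)
        enzyme_states[enz] = EnzymeState(
            enzyme=enz,
            E0=row["E0"],
            E=row["E0"],
            kdeg=row["kdeg"],
            expressing_organs=dict(row["organs"]),
            ontogeny_factor=ont,
        )

    return IndividualPhysiology(
        age=age,
        weight=weight,
        height=height,
        sex=sex,
        ethnicity=ethnicity,
        cardiac_output=co,
        organs=organs,
        enzyme_states=enzyme_states,
    )


def phenotype_table(enzyme: str) -> Dict[str, float]:
    tables = reference_tables()["phenotypes"]
    if enzyme not in tables:
        raise KeyError(
            f"no phenotype table registered for {enzyme}; "
            f"available: {sorted(tables)}"
        )
    return dict(tables[enzyme])


def set_enzyme_phenotype(
    individual: IndividualPhysiology, enzyme: str, phenotype: str
) -> IndividualPhysiology:
    """Return a copy with the enzyme's baseline expression set to the
    phenotype reference concentration (e.g. CYP2C19 NM/IM/PM)."""
    table = phenotype_table(enzyme)
    if phenotype not in table:
        raise ValueError(
            f"unknown phenotype {phenotype!r} for {enzyme}; "
            f"valid labels: {sorted(table)}"
        )
    out = individual.copy_deep()
    state = out.enzyme_states[enzyme]
    e0 = table[phenotype]
    if e0 > 0:
        state.E0 = e0
        state.E = e0
    else:  # phenotype-null pool
        state.E0 = 1e-12
        state.E = 0.0
    return out


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(sigma * rng.standard_normal()))


def sample_population(spec: PopulationSpec) -> List[IndividualPhysiology]:
    """Sample ``spec.n`` individuals; a pure function of ``spec.seed``.

    Each individual draws from an independent stream keyed by
    ``(seed, index)``, so populations are reproducible regardless of
    evaluation order.
    """
    out = []
    for i in range(spec.n):
        rng = np.random.default_rng([spec.seed, i])
        w_mult = _lognormal_multiplier(rng, spec.variability.get("weight", 0.0))
        h_mult = _lognormal_multiplier(rng, spec.variability.get("height", 0.0))
        w_def, h_def = _default_anthropometrics(spec.age, spec.sex, spec.ethnicity)
        ind = build_individual(
            age=spec.age,
            weight=w_def * w_mult,
            height=h_def * h_mult,
            sex=spec.sex,
            ethnicity=spec.ethnicity,
        )
        co_cv = spec.variability.get("cardiac_output", 0.0)
        if co_cv > 0:
            mult = _lognormal_multiplier(rng, co_cv)
            ind = _scale_cardiac_output(ind, mult)
        # genotype phenotypes, then residual expression variability on top
        for enz in sorted(spec.phenotype_frequencies):
            freqs = spec.phenotype_frequencies[enz]
            labels = sorted(freqs)
            probs = np.array([freqs[k] for k in labels])
            label = labels[int(rng.choice(len(labels), p=probs))]
            ind = set_enzyme_phenotype(ind, enz, label)
        for key in sorted(spec.variability):
            if not key.endswith(".E0"):
                continue
            enz = key[:-3]
            if enz not in ind.enzyme_states:
                raise KeyError(f"variability on unknown enzyme {enz}")
            mult = _lognormal_multiplier(rng, spec.variability[key])
            st = ind.enzyme_states[enz]
            st.E0 *= mult
            st.E *= mult
        out.append(ind)
    return out


def _scale_cardiac_output(
    ind: IndividualPhysiology, mult: float
) -> IndividualPhysiology:
    out = ind.copy_deep()
    out.cardiac_output *= mult
    for o in out.organs:
        o.blood_flow *= mult
    return IndividualPhysiology.model_validate(out.model_dump())


def population_to_frame(pop: List[IndividualPhysiology]) -> pd.DataFrame:
    """One row per individual: demographics plus sampled parameters."""
    rows = []
    for i, ind in enumerate(pop):
        row = {
            "individual": i,
            "age": ind.age,
            "weight": ind.weight,
            "height": ind.height,
            "sex": ind.sex,
            "ethnicity": ind.ethnicity,
            "cardiac_output": ind.cardiac_output,
        }
        for enz, st in ind.enzyme_states.items():
            row[f"{enz}.E0"] = st.E0
        rows.append(row)
    return pd.DataFrame(rows)
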