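"""Whole-body PBPK ODE engine.

Assembles and integrates a 14-compartment, perfusion-limited whole-body
model for one or more simultaneously dosed compounds, with oral absorption
(first-order or Weibull dissolution), hepatic/gut enzymatic elimination
scaled by local enzyme pools, renal excretion, prodrug conversion, and
enzyme-pool dynamics driven by mechanism-based inactivation and induction.

Conventions
-----------
* amounts mg, volumes L, flows L/h, time h, concentrations mg/L (= µg/mL)
* enzyme pools µmol/L; Ki/KI/EC50/Km µmol/L (unbound)
* pathway intrinsic clearances are specific: µL/min per µmol enzyme for
  linear pathways, µmol/min per µmol enzyme (with Km) for saturable ones
* renal clearance is referenced to arterial plasma (filtration-like), so
  total systemic clearance is the well-stirred hepatic clearance plus the
  renal clearance, additively
* tissue:plasma partition coefficients come from logP, fu and a tissue
  composition table by a Poulin–Theil-style calculation applied uniformly
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Literal, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.integrate import solve_ivp

from .interactions import (
    InductionSpec,
    InhibitionSpec,
    InteractionSpec,
    induction_effect,
    inactivation_rate,
)
from .physiology import ORGAN_NAMES, IndividualPhysiology, reference_tables

IDX = {name: i for i, name in enumerate(ORGAN_NAMES)}
N_COMP = len(ORGAN_NAMES)
LUNG, LIVER, GUT, KIDNEY = IDX["lung"], IDX["liver"], IDX["gut"], IDX["kidney"]
SPLEEN, ART, VEN = IDX["spleen"], IDX["arterial_blood"], IDX["venous_blood"]

# per-compound auxiliary states appended after the 14 compartments
AUX_LUMEN, AUX_MET, AUX_RENAL, AUX_CONV = 0, 1, 2, 3
N_AUX = 4
BLOCK = N_COMP + N_AUX


class AssemblyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# compound parameterization


class ClearancePathway(BaseModel):
    """One enzymatic/transporter clearance route.

    Exactly one kinetics form: linear ``clint_specific`` (µL/min/µmol
    enzyme) or saturable ``vmax_specific`` (µmol/min/µmol enzyme) with
    ``km`` (µmol/L, unbound).
    """

    enzyme: str
    clint_specific: Optional[float] = Field(default=None, gt=0)
    vmax_specific: Optional[float] = Field(default=None, gt=0)
    km: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _one_form(self):
        linear = self.clint_specific is not None
        sat = self.vmax_specific is not None or self.km is not None
        if linear == sat:
            raise ValueError(
                f"pathway via {self.enzyme}: exactly one kinetics form required"
            )
        if sat and (self.vmax_specific is None or self.km is None):
            raise ValueError(
                f"pathway via {self.enzyme}: saturable kinetics needs vmax and km"
            )
        return self

    @property
    def saturable(self) -> bool:
        return self.vmax_specific is not None


class AbsorptionModel(BaseModel):
    """Oral absorption: optional Weibull dissolution feeding a first-order
    absorption step; ``f_abs`` is the bioavailable (absorbable) fraction of
    dose."""

    model: Literal["first_order", "weibull"] = "first_order"
    ka: float = Field(gt=0, description="1/h")
    f_abs: float = Field(default=1.0, gt=0, le=1)
    shape: Optional[float] = Field(default=None, gt=0)
    scale: Optional[float] = Field(default=None, gt=0, description="h")

    @model_validator(mode="after")
    def _weibull_params(self):
        if self.model == "weibull" and (self.shape is None or self.scale is None):
            raise ValueError("weibull absorption requires shape and scale")
        return self


class FedModifiers(BaseModel):
    """Multiplicative fed-state factors on dissolution scale and the
    bioavailable fraction."""

    dissolution_scale: float = Field(default=1.0, gt=0)
    f_abs_factor: float = Field(default=1.0, gt=0)


class ProdrugLink(BaseModel):
    target: str
    rate: float = Field(gt=0, description="first-order conversion, 1/h")


class TherapeuticWindow(BaseModel):
    metric: Literal["Cmin", "AUC"]
    lower: float = Field(gt=0)
    upper: Optional[float] = None
    unit: str
    evaluation: str = ""

    @model_validator(mode="after")
    def _ordered(self):
        if self.upper is not None and not self.lower < self.upper:
            raise ValueError("therapeutic window requires lower < upper")
        return self


class CompoundParameters(BaseModel):
    """Physicochemistry, ADME, formulation, interaction and target window
    parameters for one drug."""

    schema_version: int = 1
    name: str
    mw: float = Field(gt=0, description="g/mol")
    logp: float
    fu: float = Field(gt=0, le=1)
    pka: List[dict] = Field(default_factory=list)
    blood_plasma_ratio: float = Field(default=1.0, gt=0)
    pathways: List[ClearancePathway] = Field(default_factory=list)
    renal_clearance: float = Field(default=0.0, ge=0, description="L/h")
    absorption: Optional[AbsorptionModel] = None
    formulations: Dict[str, AbsorptionModel] = Field(default_factory=dict)
    fed_state: Optional[FedModifiers] = None
    interactions: List[InteractionSpec] = Field(default_factory=list)
    prodrug_to: Optional[ProdrugLink] = None
    therapeutic_window: Optional[TherapeuticWindow] = None

    @model_validator(mode="after")
    def _stamp_perpetrator(self):
        for spec in self.interactions:
            if not spec.perpetrator:
                spec.perpetrator = self.name
        return self

    def absorption_for(self, formulation: Optional[str]) -> Optional[AbsorptionModel]:
        if formulation:
            if formulation not in self.formulations:
                raise KeyError(
                    f"{self.name}: unknown formulation {formulation!r}; "
                    f"available: {sorted(self.formulations)}"
                )
            return self.formulations[formulation]
        return self.absorption


#: alias used by the drug library
CompoundRecord = CompoundParameters


# ---------------------------------------------------------------------------
# dosing


class DoseEvent(BaseModel):
    time: float = Field(ge=0, description="h")
    dose: Optional[float] = Field(default=None, gt=0, description="mg")
    dose_per_kg: Optional[float] = Field(default=None, gt=0, description="mg/kg")
    route: Literal["iv_bolus", "iv_infusion", "oral"] = "oral"
    duration: Optional[float] = Field(default=None, gt=0, description="h")
    formulation: Optional[str] = None
    fed: bool = False

    @model_validator(mode="after")
    def _dose_given(self):
        if (self.dose is None) == (self.dose_per_kg is None):
            raise ValueError("specify exactly one of dose (mg) or dose_per_kg")
        if self.route == "iv_infusion" and self.duration is None:
            raise ValueError("iv_infusion requires a duration")
        return self

    def resolve_dose(self, weight_kg: float) -> float:
        return self.dose if self.dose is not None else self.dose_per_kg * weight_kg


class Regimen(BaseModel):
    events: List[DoseEvent] = Field(default_factory=list)

    @model_validator(mode="after")
    def _sorted(self):
        self.events.sort(key=lambda e: e.time)
        return self

    @classmethod
    def repeating(
        cls,
        dose: float,
        interval: float,
        n_doses: int,
        route: str = "oral",
        start: float = 0.0,
        duration: Optional[float] = None,
        per_kg: bool = False,
        formulation: Optional[str] = None,
        fed: bool = False,
    ) -> "Regimen":
        events = [
            DoseEvent(
                time=start + i * interval,
                dose=None if per_kg else dose,
                dose_per_kg=dose if per_kg else None,
                route=route,
                duration=duration,
                formulation=formulation,
                fed=fed,
            )
            for i in range(n_doses)
        ]
        return cls(events=events)

    @classmethod
    def single(cls, dose: float, route: str = "oral", **kw) -> "Regimen":
        return cls.repeating(dose, 1.0, 1, route=route, **kw)


def weibull_release(t: float, shape: float, scale: float) -> float:
    """Cumulative fraction released at time t: 1 - exp(-(t/scale)^shape)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    return -math.expm1(-((t / scale) ** shape))


def _weibull_rate(t: float, shape: float, scale: float) -> float:
    if t <= 0:
        return 0.0
    x = t / scale
    return (shape / scale) * x ** (shape - 1.0) * math.exp(-(x**shape))


# ---------------------------------------------------------------------------
# partition coefficients


def partition_coefficients(compound: CompoundParameters) -> np.ndarray:
    """Tissue:plasma partition coefficients for all 14 compartments.

    Poulin–Theil-style: drug distributes into tissue water and (neutral +
    30% of phospho-) lipid according to 10^logP, normalized to plasma
    composition, with a plasma/tissue unbound-fraction correction that
    assumes tissue binding at half the plasma binding strength. Adipose
    uses the vegetable-oil:water partition (log Pvow = 1.115 logP - 1.35)
    and no tissue-binding correction, which keeps lipophilic drugs from
    implausibly large fat volumes of distribution. Blood pools get Kp = 1
    (they are plasma-referenced)."""
    comp = reference_tables()["tissue_composition"]
    fu = compound.fu

    def term(f, P):
        return P * (f["nlipid"] + 0.3 * f["plipid"]) + (f["water"] + 0.7 * f["plipid"])

    P = 10.0 ** compound.logp
    P_vow = 10.0 ** (1.115 * compound.logp - 1.35)
    fu_t = 1.0 / (1.0 + 0.5 * (1.0 - fu) / fu)
    kp = np.ones(N_COMP)
    for name, i in IDX.items():
        if name in ("arterial_blood", "venous_blood"):
            continue
        if name == "adipose":
            kp[i] = term(comp[name], P_vow) / term(comp["plasma"], P_vow) * fu
        else:
            kp[i] = term(comp[name], P) / term(comp["plasma"], P) * fu / fu_t
    return kp


# ---------------------------------------------------------------------------
# assembly


@dataclass
class _ElimTerm:
    organ: int
    enzyme: str
    linear_base: float  # L/h per (µmol/L enzyme), linear pathways
    vmax_base: float  # µmol/h per (µmol/L enzyme), saturable pathways
    km: float  # µmol/L
    saturable: bool
    rev_specs: List[Tuple[int, InhibitionSpec]] = field(default_factory=list)


@dataclass
class ODESystem:
    """Assembled right-hand side for one individual and a set of compounds.

    State layout: per compound 14 compartment amounts + [lumen, cumulative
    metabolized, cumulative renal, cumulative converted], then one state per
    dynamically modeled enzyme pool."""

    individual: IndividualPhysiology
    compounds: List[CompoundParameters]
    F: np.ndarray
    kp: List[np.ndarray]
    inv_vkp: List[np.ndarray]
    elim_terms: List[List[_ElimTerm]]
    dynamic_enzymes: List[str]
    pool_mbi: Dict[str, List[Tuple[int, InhibitionSpec]]]
    pool_ind: Dict[str, List[Tuple[int, InductionSpec]]]
    prodrug_edges: List[Tuple[int, int, float, float]]  # parent, child, k, mw ratio

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_enzyme_states(self) -> int:
        return len(self.dynamic_enzymes)

    @property
    def n_states(self) -> int:
        return BLOCK * self.n_compounds + self.n_enzyme_states

    def compound_index(self, name: str) -> int:
        for i, c in enumerate(self.compounds):
            if c.name == name:
                return i
        raise KeyError(f"compound {name!r} not in system")

    def compound(self, name: str) -> CompoundParameters:
        return self.compounds[self.compound_index(name)]

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        off = BLOCK * self.n_compounds
        for j, enz in enumerate(self.dynamic_enzymes):
            y0[off + j] = self.individual.enzyme_states[enz].E0
        return y0

    def enzyme_level(self, enz: str, y: np.ndarray) -> float:
        st = self.individual.enzyme_states[enz]
        if enz in self.dynamic_enzymes:
            j = self.dynamic_enzymes.index(enz)
            return y[BLOCK * self.n_compounds + j]
        return st.E0


def assemble_model(
    individual: IndividualPhysiology,
    compounds: Sequence[CompoundParameters],
    interaction_bindings: Optional[Sequence[InteractionSpec]] = None,
) -> ODESystem:
    """Build the coupled whole-body system.

    ``interaction_bindings`` defaults to the union of every compound's
    declared interactions; pass an explicit list (with ``perpetrator`` set)
    to override. Enzyme pools become dynamic states only where a
    mechanism-based inactivator or inducer targets them."""
    compounds = list(compounds)
    names = [c.name for c in compounds]
    if len(set(names)) != len(names):
        raise AssemblyError(f"duplicate compound names: {names}")

    est = individual.enzyme_states
    for c in compounds:
        for p in c.pathways:
            if p.enzyme not in est:
                raise AssemblyError(
                    f"compound {c.name}: pathway enzyme {p.enzyme!r} not in "
                    "the individual's enzyme registry"
                )

    if interaction_bindings is None:
        bindings = [s for c in compounds for s in c.interactions]
    else:
        bindings = list(interaction_bindings)
    for s in bindings:
        if s.target not in est:
            raise AssemblyError(
                f"interaction by {s.perpetrator}: target enzyme {s.target!r} "
                "not in the individual's enzyme registry"
            )
        if s.perpetrator not in names:
            raise AssemblyError(
                f"interaction perpetrator {s.perpetrator!r} not in system"
            )

    # flow matrix: dA = F @ yp, yp = plasma-referenced concentrations
    org = individual.organ
    co = individual.cardiac_output
    q = {name: org[name].blood_flow for name in ORGAN_NAMES}
    F = np.zeros((N_COMP, N_COMP))
    F[LUNG, VEN] += co
    F[LUNG, LUNG] -= co
    F[ART, LUNG] += co
    F[ART, ART] -= co
    F[VEN, VEN] -= co
    q_liv_out = q["liver"] + q["gut"] + q["spleen"]
    for name in ("gut", "spleen"):
        i = IDX[name]
        F[i, ART] += q[name]
        F[i, i] -= q[name]
        F[LIVER, i] += q[name]
    F[LIVER, ART] += q["liver"]
    F[LIVER, LIVER] -= q_liv_out
    F[VEN, LIVER] += q_liv_out
    for name in ("kidney", "muscle", "adipose", "skin", "brain", "heart", "bone", "rest"):
        i = IDX[name]
        F[i, ART] += q[name]
        F[i, i] -= q[name]
        F[VEN, i] += q[name]

    vols = np.array([org[name].volume for name in ORGAN_NAMES])
    kps, inv_vkps, elim_terms = [], [], []
    rev_bindings = [
        s for s in bindings if isinstance(s, InhibitionSpec) and s.type != "irreversible"
    ]
    for c in compounds:
        kp = partition_coefficients(c)
        kps.append(kp)
        inv_vkps.append(1.0 / (vols * kp))
        terms = []
        for p in c.pathways:
            state = est[p.enzyme]
            for organ_name, w in state.expressing_organs.items():
                if w <= 0:
                    continue
                oi = IDX[organ_name]
                ont = state.ontogeny_factor
                vol = vols[oi]
                if p.saturable:
                    term = _ElimTerm(
                        organ=oi,
                        enzyme=p.enzyme,
                        linear_base=0.0,
                        vmax_base=p.vmax_specific * 60.0 * w * vol * ont,
                        km=p.km,
                        saturable=True,
                    )
                else:
                    term = _ElimTerm(
                        organ=oi,
                        enzyme=p.enzyme,
                        linear_base=p.clint_specific * 60e-6 * w * vol * ont,
                        vmax_base=0.0,
                        km=1.0,
                        saturable=False,
                    )
                term.rev_specs = [
                    (names.index(s.perpetrator), s)
                    for s in rev_bindings
                    if s.target == p.enzyme
                ]
                terms.append(term)
        elim_terms.append(terms)

    pool_mbi: Dict[str, list] = {}
    pool_ind: Dict[str, list] = {}
    for s in bindings:
        if isinstance(s, InhibitionSpec) and s.type == "irreversible":
            pool_mbi.setdefault(s.target, []).append((names.index(s.perpetrator), s))
        elif isinstance(s, InductionSpec):
            pool_ind.setdefault(s.target, []).append((names.index(s.perpetrator), s))
    dynamic = sorted(set(pool_mbi) | set(pool_ind))

    prodrug_edges = []
    for i, c in enumerate(compounds):
        if c.prodrug_to is not None:
            if c.prodrug_to.target not in names:
                raise AssemblyError(
                    f"{c.name} converts to {c.prodrug_to.target!r}, which is "
                    "not in the system; include it"
                )
            j = names.index(c.prodrug_to.target)
            prodrug_edges.append(
                (i, j, c.prodrug_to.rate, compounds[j].mw / c.mw)
            )

    return ODESystem(
        individual=individual,
        compounds=compounds,
        F=F,
        kp=kps,
        inv_vkp=inv_vkps,
        elim_terms=elim_terms,
        dynamic_enzymes=dynamic,
        pool_mbi=pool_mbi,
        pool_ind=pool_ind,
        prodrug_edges=prodrug_edges,
    )


# ---------------------------------------------------------------------------
# simulation


@dataclass
class _Forcings:
    """Continuous inputs per compound: iv infusions and Weibull
    dissolution of oral doses."""

    infusions: List[Tuple[float, float, float]] = field(default_factory=list)
    weibull_doses: List[Tuple[float, float, float, float]] = field(default_factory=list)

    def infusion_rate(self, t: float) -> float:
        return sum(r for (t0, t1, r) in self.infusions if t0 <= t < t1)

    def dissolution_rate(self, t: float) -> float:
        return sum(
            amt * _weibull_rate(t - t0, sh, sc)
            for (t0, amt, sh, sc) in self.weibull_doses
            if t > t0
        )

    def cumulative_input(self, t: np.ndarray, boluses) -> np.ndarray:
        """Cumulative systemically-available input (mg) at each time."""
        out = np.zeros_like(t, dtype=float)
        for t0, amt in boluses:
            # strict inequality: the state recorded exactly at an event time
            # is the pre-dose value
            out += np.where(t > t0 + 5e-10, amt, 0.0)
        for t0, t1, r in self.infusions:
            out += r * np.clip(t - t0, 0.0, t1 - t0)
        for t0, amt, sh, sc in self.weibull_doses:
            dt = np.clip(t - t0, 0.0, None)
            out += amt * (1.0 - np.exp(-((dt / sc) ** sh)))
        return out


@dataclass
class SimulationResult:
    """Trajectories of one simulation: compartment amounts, enzyme pools,
    cumulative elimination, plus the input bookkeeping needed for mass
    balance. Concentrations are plasma-referenced, in mg/L (= µg/mL)."""

    system: ODESystem
    t: np.ndarray
    y: np.ndarray  # (n_states, T)
    forcings: Dict[str, _Forcings]
    boluses: Dict[str, List[Tuple[float, float]]]

    def _off(self, name: str) -> int:
        return BLOCK * self.system.compound_index(name)

    def amounts(self, name: str) -> np.ndarray:
        off = self._off(name)
        return self.y[off : off + N_COMP]

    def plasma(self, name: str) -> np.ndarray:
        """Venous plasma concentration, mg/L (= µg/mL)."""
        i = self.system.compound_index(name)
        return self.y[BLOCK * i + VEN] * self.system.inv_vkp[i][VEN]

    def outflow_plasma_conc(self, name: str, organ: str) -> np.ndarray:
        if organ not in IDX:
            raise KeyError(f"unknown site {organ!r}")
        i = self.system.compound_index(name)
        oi = IDX[organ]
        return self.y[BLOCK * i + oi] * self.system.inv_vkp[i][oi]

    def enzyme_pool(self, enzyme: str) -> np.ndarray:
        sysm = self.system
        if enzyme in sysm.dynamic_enzymes:
            j = sysm.dynamic_enzymes.index(enzyme)
            return self.y[BLOCK * sysm.n_compounds + j]
        return np.full_like(self.t, sysm.individual.enzyme_states[enzyme].E0)

    def eliminated(self, name: str) -> Dict[str, np.ndarray]:
        off = self._off(name)
        return {
            "metabolic": self.y[off + N_COMP + AUX_MET],
            "renal": self.y[off + N_COMP + AUX_RENAL],
            "converted": self.y[off + N_COMP + AUX_CONV],
        }

    def lumen(self, name: str) -> np.ndarray:
        return self.y[self._off(name) + N_COMP + AUX_LUMEN]

    def dosed_input(self, name: str) -> np.ndarray:
        """Cumulative systemically-available input, mg (doses × bioavailable
        fraction, infusion integrals, plus prodrug conversion inflow)."""
        inp = self.forcings[name].cumulative_input(self.t, self.boluses[name])
        for pi, ci, _, mwr in self.system.prodrug_edges:
            if self.system.compounds[ci].name == name:
                parent = self.system.compounds[pi].name
                inp = inp + self.eliminated(parent)["converted"] * mwr
        return inp

    def mass_balance_error(self, name: str) -> float:
        """Max relative deviation of (in-system + eliminated) from the
        cumulative input, over times with non-zero input."""
        inp = self.dosed_input(name)
        elim = self.eliminated(name)
        total = (
            self.amounts(name).sum(axis=0)
            + self.lumen(name)
            + elim["metabolic"]
            + elim["renal"]
            + elim["converted"]
        )
        mask = inp > 0
        if not mask.any():
            return 0.0
        return float(np.max(np.abs(total[mask] - inp[mask]) / inp[mask]))

    def min_concentration(self) -> float:
        out = math.inf
        for c in self.system.compounds:
            out = min(out, float(self.plasma(c.name).min(initial=math.inf)))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time, compound, compartment, value, unit."""
        rows = []
        for i, c in enumerate(self.system.compounds):
            conc = self.y[BLOCK * i : BLOCK * i + N_COMP] * self.system.inv_vkp[i][
                :, None
            ]
            for oi, org in enumerate(ORGAN_NAMES):
                rows.append(
                    pd.DataFrame(
                        {
                            "time_h": self.t,
                            "compound": c.name,
                            "compartment": org,
                            "value": conc[oi],
                            "unit": "ug/mL",
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


class SolverError(RuntimeError):
    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last accepted time {last_time:.4g} h)")
        self.last_time = last_time


def _make_rhs(system: ODESystem, forcings: List[_Forcings]):
    n_c = system.n_compounds
    pool_off = BLOCK * n_c
    est = system.individual.enzyme_states
    abs_cache = [c.absorption for c in system.compounds]
    # unbound mg/L -> µmol/L, the unit of Ki/KI/EC50/Km
    to_um = [1000.0 / c.mw for c in system.compounds]

    def enzyme_value(enz: str, y: np.ndarray) -> float:
        if enz in system.dynamic_enzymes:
            return max(y[pool_off + system.dynamic_enzymes.index(enz)], 0.0)
        return est[enz].E0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        yps = [
            y[BLOCK * i : BLOCK * i + N_COMP] * system.inv_vkp[i] for i in range(n_c)
        ]
        for i, c in enumerate(system.compounds):
            off = BLOCK * i
            yp = yps[i]
            dA = system.F @ yp
            # absorption from the gut lumen
            lum = y[off + N_COMP + AUX_LUMEN]
            absm = abs_cache[i]
            if absm is not None:
                flux = absm.ka * lum
                dy[off + N_COMP + AUX_LUMEN] = (
                    forcings[i].dissolution_rate(t) - flux
                )
                dA[GUT] += flux
            # enzymatic / transporter elimination
            for term in system.elim_terms[i]:
                e_val = enzyme_value(term.enzyme, y)
                cu_mgl = c.fu * yp[term.organ]
                if cu_mgl <= 0 or e_val <= 0:
                    continue
                d_km, d_s = 1.0, 1.0
                for pj, spec in term.rev_specs:
                    I = system.compounds[pj].fu * yps[pj][term.organ] * to_um[pj]
                    if I <= 0:
                        continue
                    r = I / spec.ki
                    if spec.type == "competitive":
                        d_km += r
                    elif spec.type == "uncompetitive":
                        d_s += r
                    elif spec.type == "non-competitive":
                        d_km += r
                        d_s += r
                    else:  # mixed
                        d_km += r
                        d_s += I / (spec.alpha * spec.ki)
                if term.saturable:
                    cu_um = cu_mgl * 1000.0 / c.mw
                    v_um_h = (
                        term.vmax_base
                        * e_val
                        * cu_um
                        / (term.km * d_km + cu_um * d_s)
                    )
                    rate = v_um_h * c.mw / 1000.0  # mg/h
                else:
                    rate = term.linear_base * e_val * cu_mgl / d_km
                dA[term.organ] -= rate
                dy[off + N_COMP + AUX_MET] += rate
            # renal excretion, arterial-plasma referenced
            if c.renal_clearance > 0:
                rr = c.renal_clearance * yp[ART]
                dA[KIDNEY] -= rr
                dy[off + N_COMP + AUX_RENAL] += rr
            dA[VEN] += forcings[i].infusion_rate(t)
            dy[off : off + N_COMP] += dA
        # prodrug conversion in the blood pools
        for pi, ci, k, mwr in system.prodrug_edges:
            po, co_ = BLOCK * pi, BLOCK * ci
            for bi in (ART, VEN):
                r = k * y[po + bi]
                dy[po + bi] -= r
                dy[co_ + bi] += r * mwr
                dy[po + N_COMP + AUX_CONV] += r
        # enzyme pool turnover (driver: unbound liver concentration)
        for j, enz in enumerate(system.dynamic_enzymes):
            st = est[enz]
            E = y[pool_off + j]
            lam = 0.0
            for pj, spec in system.pool_mbi.get(enz, []):
                I = system.compounds[pj].fu * yps[pj][LIVER] * to_um[pj]
                lam += spec.kinact * I / (spec.KI + I)
            ind = 0.0
            for pj, spec in system.pool_ind.get(enz, []):
                I = system.compounds[pj].fu * yps[pj][LIVER] * to_um[pj]
                ind += spec.emax * I / (spec.ec50 + I)
            dy[pool_off + j] = st.kdeg * st.E0 * (1.0 + ind) - E * (st.kdeg + lam)
        return dy

    return rhs


def simulate(
    system: ODESystem,
    regimens: Dict[str, Regimen],
    t_end: float,
    grid_dt: float = 0.1,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    t0: float = 0.0,
    y0: Optional[np.ndarray] = None,
) -> SimulationResult:
    """Integrate the system under the given regimens up to ``t_end`` hours.

    Bolus doses are state discontinuities (the integrator restarts at every
    event); infusions and Weibull dissolution are forcing terms. Output is
    on a uniform grid of step ``grid_dt`` (dense enough for trapezoidal AUC
    at the default)."""
    weight = system.individual.weight
    names = [c.name for c in system.compounds]
    for n in regimens:
        if n not in names:
            raise KeyError(f"regimen for unknown compound {n!r}")

    forcings = []
    boluses: Dict[str, List[Tuple[float, float]]] = {n: [] for n in names}
    jumps: Dict[float, List[Tuple[int, int, float]]] = {}
    breakpoints = {t0, t_end}
    for i, c in enumerate(system.compounds):
        fc = _Forcings()
        reg = regimens.get(c.name)
        for ev in (reg.events if reg else []):
            if ev.time > t_end:
                raise ValueError(
                    f"{c.name}: dose at {ev.time} h beyond t_end={t_end} h"
                )
            amt = ev.resolve_dose(weight)
            if ev.route == "iv_bolus":
                jumps.setdefault(ev.time, []).append((BLOCK * i + VEN, 0, amt))
                boluses[c.name].append((ev.time, amt))
                breakpoints.add(ev.time)
            elif ev.route == "iv_infusion":
                fc.infusions.append((ev.time, ev.time + ev.duration, amt / ev.duration))
                breakpoints.update((ev.time, ev.time + ev.duration))
            else:  # oral
                absm = c.absorption_for(ev.formulation)
                if absm is None:
                    raise AssemblyError(
                        f"{c.name}: oral dose but no absorption model"
                    )
                f_abs = absm.f_abs
                scale_mult = 1.0
                if ev.fed and c.fed_state is not None:
                    f_abs = min(f_abs * c.fed_state.f_abs_factor, 1.0)
                    scale_mult = c.fed_state.dissolution_scale
                avail = amt * f_abs
                if absm.model == "weibull":
                    fc.weibull_doses.append(
                        (ev.time, avail, absm.shape, absm.scale * scale_mult)
                    )
                else:
                    jumps.setdefault(ev.time, []).append(
                        (BLOCK * i + N_COMP + AUX_LUMEN, 0, avail)
                    )
                    boluses[c.name].append((ev.time, avail))
                breakpoints.add(ev.time)
        forcings.append(fc)
        # oral events entering via forcing are counted in cumulative_input
        # through the Weibull CDF, not the bolus list

    # formulation override may swap the absorption model used by the RHS:
    # simulate supports one absorption model per compound per run, chosen
    # from the first oral event's formulation
    eff_abs = []
    for i, c in enumerate(system.compounds):
        reg = regimens.get(c.name)
        form = None
        for ev in (reg.events if reg else []):
            if ev.route == "oral":
                form = ev.formulation
                break
        eff_abs.append(c.absorption_for(form))
    system_eff = system
    if any(a is not b for a, b in zip(eff_abs, [c.absorption for c in system.compounds])):
        comps = [
            c.model_copy(update={"absorption": a}) if a is not None else c
            for c, a in zip(system.compounds, eff_abs)
        ]
        system_eff = ODESystem(
            individual=system.individual,
            compounds=comps,
            F=system.F,
            kp=system.kp,
            inv_vkp=system.inv_vkp,
            elim_terms=system.elim_terms,
            dynamic_enzymes=system.dynamic_enzymes,
            pool_mbi=system.pool_mbi,
            pool_ind=system.pool_ind,
            prodrug_edges=system.prodrug_edges,
        )

    rhs = _make_rhs(system_eff, forcings)
    bpts = sorted(b for b in breakpoints if t0 <= b <= t_end)
    grid = np.arange(t0, t_end + grid_dt / 2, grid_dt)
    # refine just after each event so fast mixing/distribution transients
    # are resolved by the trapezoidal AUC
    refine = grid_dt * np.array([0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5])
    extra = (np.array(bpts[:-1])[:, None] + refine[None, :]).ravel()
    grid = np.unique(np.concatenate([grid, np.array(bpts), extra]))
    grid = grid[(grid >= t0) & (grid <= t_end)]

    y = y0.copy() if y0 is not None else system.initial_state()
    ts_out = [np.array([t0])]
    ys_out = [y.reshape(-1, 1).copy()]
    for k in range(len(bpts) - 1):
        a, b = bpts[k], bpts[k + 1]
        if jumps.get(a):
            for idx, _, amt in jumps[a]:
                y[idx] += amt
            # record the post-dose state at an epsilon offset so jumps are
            # visible to the trapezoid without disturbing trough reads
            ts_out.append(np.array([a + 1e-9]))
            ys_out.append(y.reshape(-1, 1).copy())
        seg = grid[(grid > a + 1e-6) & (grid <= b)]
        t_eval = np.concatenate([[a], seg]) if len(seg) else np.array([a, b])
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverError(sol.message, sol.t[-1] if len(sol.t) else a)
        y = sol.y[:, -1].copy()
        ts_out.append(sol.t[1:])
        ys_out.append(sol.y[:, 1:])
    t_all = np.concatenate(ts_out)
    y_all = np.concatenate(ys_out, axis=1)
    return SimulationResult(
        system=system_eff,
        t=t_all,
        y=y_all,
        forcings={n: f for n, f in zip(names, forcings)},
        boluses=boluses,
    )


# ---------------------------------------------------------------------------
# PK metrics


@dataclass
class PKMetrics:
    """AUC (µg·h/mL), Cmax and trough Cmin (µg/mL) over a stated interval."""

    auc: float
    cmax: float
    cmin: float
    t_start: float
    t_end: float
    mw: float
    unit: str = "ug/mL"

    def __post_init__(self):
        if self.auc < 0:
            raise ValueError("negative AUC")
        if self.cmin > self.cmax * (1 + 1e-9):
            raise ValueError("Cmin exceeds Cmax")

    @property
    def auc_um_min(self) -> float:
        """AUC in µM·min: µg·h/mL × 60 min/h × 1000/MW."""
        return self.auc * 60.0 * 1000.0 / self.mw

    def conc_ng_ml(self, value: float) -> float:
        return value * 1000.0

    @property
    def cmin_ng_ml(self) -> float:
        return self.cmin * 1000.0

    @property
    def cmax_ng_ml(self) -> float:
        return self.cmax * 1000.0


def compute_pk_metrics(
    result: SimulationResult,
    compound: str,
    t_start: Optional[float] = None,
    t_end: Optional[float] = None,
) -> PKMetrics:
    """Trapezoidal AUC, Cmax and end-of-interval trough on the output grid."""
    t = result.t
    t_start = t[0] if t_start is None else t_start
    t_end = t[-1] if t_end is None else t_end
    if not (t[0] - 1e-9 <= t_start < t_end <= t[-1] + 1e-9):
        raise ValueError(
            f"interval [{t_start}, {t_end}] outside simulated range "
            f"[{t[0]}, {t[-1]}]"
        )
    conc = result.plasma(compound)
    mask = (t >= t_start - 1e-9) & (t <= t_end + 1e-9)
    ti, ci = t[mask], conc[mask]
    if len(ti) < 2:
        raise ValueError("empty evaluation interval")
    auc = float(np.trapezoid(ci, ti))
    return PKMetrics(
        auc=auc,
        cmax=float(ci.max()),
        cmin=float(ci[-1]),
        t_start=float(ti[0]),
        t_end=float(ti[-1]),
        mw=result.system.compound(compound).mw,
    )


def auc_infinity(result: SimulationResult, compound: str) -> float:
    """AUC extrapolated to infinity: trapezoidal AUC to the last output
    time plus C_last/λz, with the terminal rate λz from a log-linear fit to
    the final stretch of the profile."""
    t = result.t
    conc = result.plasma(compound)
    auc_t = float(np.trapezoid(conc, t))
    n = len(t)
    tail = slice(max(n - max(20, n // 5), n // 2), n)
    ct, tt = conc[tail], t[tail]
    ok = ct > 0
    if ok.sum() < 3:
        return auc_t
    slope = np.polyfit(tt[ok], np.log(ct[ok]), 1)[0]
    if slope >= 0:
        return auc_t
    return auc_t + float(conc[-1] / -slope)


def interval_aucs(
    result: SimulationResult, compound: str, interval: float, start: float = 0.0
) -> List[float]:
    """AUC of each complete dosing interval from ``start``."""
    out = []
    a = start
    while a + interval <= result.t[-1] + 1e-9:
        out.append(compute_pk_metrics(result, compound, a, a + interval).auc)
        a += interval
    return out


def is_steady_state(
    result: SimulationResult,
    compound: str,
    interval: float,
    start: float = 0.0,
    tol: float = 0.01,
) -> bool:
    """Steady state when the last two complete dosing-interval AUCs agree
    within ``tol`` (relative)."""
    aucs = interval_aucs(result, compound, interval, start)
    if len(aucs) < 2:
        return False
    a, b = aucs[-2], aucs[-1]
    return abs(b - a) <= tol * max(a, b)
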