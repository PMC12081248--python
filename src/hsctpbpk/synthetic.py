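"""Synthetic inputs with known ground truth.

Everything the pipeline can consume without external downloads: toy
compounds with controllable kinetics, noisy observed-like concentration
datasets generated from a known truth model (multiplicative log-normal
noise, the PK convention), and fixtures carrying the printed summary
values of the reference HSCT DDI simulation study for arithmetic
verification. Each fixture number has a retrievable source anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .engine import (
    AbsorptionModel,
    CompoundParameters,
    ODESystem,
    Regimen,
    assemble_model,
    simulate,
)
from .fitting import ObservedDataset
from .interactions import InductionSpec, InhibitionSpec
from .physiology import IndividualPhysiology, build_individual


# ---------------------------------------------------------------------------
# toy compounds


def toy_compound(
    name: str = "toy",
    clint_specific: float = 50000.0,
    enzyme: str = "CYP3A4",
    fu: float = 0.5,
    mw: float = 300.0,
    logp: float = 1.0,
    renal_clearance: float = 0.0,
    ka: Optional[float] = None,
    f_abs: float = 1.0,
    km: Optional[float] = None,
    **kw,
) -> CompoundParameters:
    """A minimal linear-kinetics compound; pass ``ka`` to make it oral,
    ``km`` (µmol/L) to make the pathway saturable."""
    if km is None:
        pathway = dict(enzyme=enzyme, clint_specific=clint_specific)
    else:
        pathway = dict(enzyme=enzyme, vmax_specific=clint_specific * km / 1e6, km=km)
    absorption = (
        AbsorptionModel(model="first_order", ka=ka, f_abs=f_abs) if ka else None
    )
    return CompoundParameters(
        name=name,
        mw=mw,
        logp=logp,
        fu=fu,
        pathways=[pathway],
        renal_clearance=renal_clearance,
        absorption=absorption,
        **kw,
    )


def toy_inhibitor(
    name: str = "inhibitor",
    target: str = "CYP3A4",
    ki: float = 1.0,
    inh_type: str = "competitive",
    **kw,
) -> CompoundParameters:
    """A slowly-cleared reversible inhibitor of ``target``."""
    kw.setdefault("fu", 1.0)
    kw.setdefault("clint_specific", 500.0)
    kw.setdefault("enzyme", "CYP1A2")  # cleared off-target
    c = toy_compound(name=name, **kw)
    c.interactions = [
        InhibitionSpec(perpetrator=name, target=target, type=inh_type, ki=ki)
    ]
    return c


def toy_mbi(
    name: str = "inactivator",
    target: str = "CYP3A4",
    kinact: float = 0.5,
    KI: float = 5.0,
    **kw,
) -> CompoundParameters:
    kw.setdefault("fu", 1.0)
    kw.setdefault("clint_specific", 500.0)
    kw.setdefault("enzyme", "CYP1A2")
    c = toy_compound(name=name, **kw)
    c.interactions = [
        InhibitionSpec(
            perpetrator=name, target=target, type="irreversible", kinact=kinact, KI=KI
        )
    ]
    return c


def toy_inducer(
    name: str = "inducer",
    target: str = "CYP3A4",
    emax: float = 4.0,
    ec50: float = 2.0,
    **kw,
) -> CompoundParameters:
    kw.setdefault("fu", 1.0)
    kw.setdefault("clint_specific", 500.0)
    kw.setdefault("enzyme", "CYP1A2")
    c = toy_compound(name=name, **kw)
    c.interactions = [
        InductionSpec(perpetrator=name, target=target, emax=emax, ec50=ec50)
    ]
    return c


# ---------------------------------------------------------------------------
# observed-like datasets


class SyntheticStudySpec(BaseModel):
    """Generating spec for an observed-like dataset: truth compound,
    regimen, sampling schedule and a multiplicative log-normal noise CV."""

    compound: CompoundParameters
    regimen: Regimen
    t_end: float = Field(gt=0)
    sampling_times: List[float]
    noise_cv: float = Field(default=0.0, ge=0)
    n_subjects: int = Field(default=1, ge=1)
    seed: int = 0

    model_config = {"arbitrary_types_allowed": True}

    @property
    def truth(self) -> CompoundParameters:
        return self.compound


def generate_observed_profile(
    spec: SyntheticStudySpec,
    individual: Optional[IndividualPhysiology] = None,
) -> Tuple[List[ObservedDataset], CompoundParameters]:
    """Simulate the truth model and emit noisy observed datasets plus the
    sidecar truth record for recovery tests. Seeded and deterministic."""
    if max(spec.sampling_times) > spec.t_end:
        raise ValueError("sampling times extend beyond the simulated horizon")
    individual = individual or build_individual()
    system = assemble_model(individual, [spec.compound])
    res = simulate(system, {spec.compound.name: spec.regimen}, spec.t_end)
    times = np.asarray(spec.sampling_times, dtype=float)
    clean = np.interp(times, res.t, res.plasma(spec.compound.name))
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    datasets = []
    for subj in range(spec.n_subjects):
        rng = np.random.default_rng([spec.seed, subj])
        noisy = (
            clean * np.exp(sigma * rng.standard_normal(len(times)))
            if sigma > 0
            else clean.copy()
        )
        datasets.append(
            ObservedDataset(
                time_h=times.tolist(),
                conc=noisy.tolist(),
                unit="ug/mL",
                arm=f"subject-{subj}",
                source="synthetic",
            )
        )
    return datasets, spec.compound


# ---------------------------------------------------------------------------
# printed-value fixtures from the reference HSCT simulation study


def table2_fixture() -> pd.DataFrame:
    """Reported day-6 cyclosporine trough summaries (mean ± SD, ng/mL) and
    1-decimal trough ratios under different perpetrator sets, as printed in
    the source study's scenario table ("Table 2"). Used for arithmetic
    verification of the ratio pipeline, not as simulation targets."""
    rows = [
        ("100 mg po bid", "", 104.9, 32.2, None),
        ("100 mg po bid", "phenytoin 100 mg po tid", 82.7, 26.1, 0.8),
        ("100 mg po bid", "letermovir 240 mg po qd", 126.3, 49.7, 1.2),
        ("100 mg po bid", "fluconazole 200 mg po qd", 169.2, 67.6, 1.6),
        ("100 mg po bid", "posaconazole 200 mg po tid", 208.6, 113.1, 2.0),
        ("100 mg po bid", "itraconazole 200 mg po qd", 215.2, 119.1, 2.1),
        ("100 mg po bid", "voriconazole 200 mg po bid (CYP2C19 NM)", 233.8, 147.7, 2.2),
        ("100 mg po bid", "voriconazole 200 mg po bid (CYP2C19 IM)", 327.7, 193.3, 3.1),
        ("100 mg po bid", "voriconazole 200 mg po bid (CYP2C19 PM)", 422.7, 227.2, 4.0),
        (
            "100 mg po bid",
            "voriconazole (NM) + letermovir 240 mg po qd",
            240.6,
            124.6,
            2.3,
        ),
        (
            "100 mg po bid",
            "voriconazole (NM) + letermovir + phenytoin day -5 to -1",
            173.1,
            76.3,
            1.7,
        ),
        (
            "150 mg po bid",
            "voriconazole (NM) + letermovir + phenytoin day -5 to -1",
            261.3,
            109.7,
            2.5,
        ),
    ]
    df = pd.DataFrame(
        rows,
        columns=["victim_regimen", "perpetrators", "cmin_mean", "cmin_sd", "ratio_reported"],
    )
    df["anchor"] = "Table 2"
    return df


def discussion_fixture() -> Dict[str, object]:
    """Reported summary numbers from the source study's discussion of dose
    optimization: pediatric/adult busulfan exposures (µM·min) and the
    fold-change / percent-decrease lists for cyclosporine and co-medicated
    victims. All entries carry their source anchor."""
    return {
        "busulfan_auc_um_min": {
            "child_0.8_mg_kg": 979.4,
            "child_0.8_mg_kg_sd": 76.2,
            "adult_0.8_mg_kg": 1078.8,
            "adult_0.8_mg_kg_sd": 103.9,
            "child_0.8_mg_kg_with_phenytoin": 847.9,
            "child_0.8_mg_kg_with_phenytoin_sd": 68.4,
            "child_1.0_mg_kg": 1060.7,
            "child_1.0_mg_kg_sd": 95.5,
            "anchor": "Discussion (pediatric busulfan)",
        },
        "cyclosporine_cmin_fold_changes": {
            "values": [2.2, 2.1, 2.0, 1.6, 1.2],
            "perpetrators": [
                "voriconazole",
                "itraconazole",
                "posaconazole",
                "fluconazole",
                "letermovir",
            ],
            "anchor": "Results (dose-optimization scenarios)",
        },
        "phenytoin_percent_decreases": {
            "values": [21.1, 36.9, 8.5, 13.4, 51.0],
            "victims": [
                "cyclosporine Cmin",
                "aprepitant AUC",
                "fosaprepitant AUC",
                "busulfan AUC",
                "voriconazole Cmin",
            ],
            "anchor": "Results (dose-optimization scenarios)",
        },
        "cyclosporine_cmin_means": {
            "alone": 104.9,
            "with_phenytoin": 82.7,
            "anchor": "Table 2",
        },
    }
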