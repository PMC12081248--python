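"""Curated compound library: 13 drugs used around HSCT.

One YAML file per drug (physicochemistry, clearance pathways, absorption,
interaction specs, therapeutic window), schema-validated into
:class:`~hsctpbpk.engine.CompoundRecord`, plus interaction-network
introspection.

The numeric interaction and clearance constants are curated
literature-typical values (reported in vitro constants are scattered across
primary sources and vendor databases); they are internally consistent
fixtures, not ground truth, and every field is annotated with a provenance
comment in its YAML file.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .engine import CompoundRecord, Regimen, TherapeuticWindow
from .interactions import InductionSpec, InhibitionSpec

DRUGS = (
    "busulfan",
    "phenytoin",
    "voriconazole",
    "posaconazole",
    "itraconazole",
    "fluconazole",
    "letermovir",
    "fosaprepitant",
    "aprepitant",
    "omeprazole",
    "cyclosporine",
    "tacrolimus",
    "sirolimus",
)

#: conventional single/repeat administrations used for smoke simulation and
#: scenario defaults: (dose, route, interval h, infusion duration h, per_kg)
STANDARD_REGIMENS: Dict[str, dict] = {
    "busulfan": dict(dose=0.8, route="iv_infusion", interval=6, duration=2.0, per_kg=True),
    "phenytoin": dict(dose=100, route="oral", interval=8),
    "voriconazole": dict(dose=200, route="oral", interval=12),
    "posaconazole": dict(dose=200, route="oral", interval=8),
    "itraconazole": dict(dose=200, route="oral", interval=24),
    "fluconazole": dict(dose=200, route="oral", interval=24),
    "letermovir": dict(dose=240, route="oral", interval=24),
    "fosaprepitant": dict(dose=150, route="iv_infusion", interval=24, duration=0.5),
    "aprepitant": dict(dose=125, route="oral", interval=24),
    "omeprazole": dict(dose=20, route="oral", interval=24),
    "cyclosporine": dict(dose=100, route="oral", interval=12),
    "tacrolimus": dict(dose=2, route="oral", interval=12),
    "sirolimus": dict(dose=2, route="oral", interval=24),
}


class SchemaError(ValueError):
    pass


def _library_dir():
    return importlib.resources.files("hsctpbpk") / "compounds"


def _parse_interaction(raw: dict, idx: int, name: str):
    kind = raw.get("kind")
    try:
        if kind == "inhibition":
            return InhibitionSpec(**raw)
        if kind == "induction":
            return InductionSpec(**raw)
    except ValidationError as e:
        raise SchemaError(
            f"{name}: interaction #{idx} ({raw.get('type', kind)} of "
            f"{raw.get('target', '?')}) is invalid: {e.errors()[0]['msg']}"
        ) from e
    raise SchemaError(f"{name}: interaction #{idx} has unknown kind {kind!r}")


def load_compound(path: Union[str, Path, "importlib.resources.abc.Traversable"]) -> CompoundRecord:
    """Load and validate one compound file."""
    if isinstance(path, (str, Path)):
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"compound file not found: {p}")
        raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: not a mapping")
    name = raw.get("name", str(path))
    interactions = [
        _parse_interaction(r, i, name)
        for i, r in enumerate(raw.pop("interactions", []) or [])
    ]
    try:
        rec = CompoundRecord(**raw, interactions=interactions)
    except ValidationError as e:
        first = e.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise SchemaError(f"{name}: field {loc}: {first['msg']}") from e
    return rec


def save_compound(record: CompoundRecord, path: Union[str, Path]) -> None:
    data = record.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_library(directory: Optional[Union[str, Path]] = None) -> Dict[str, CompoundRecord]:
    """Load the shipped 13-drug library (or any directory of compound
    YAMLs); prodrug links are cross-checked against the loaded set."""
    if directory is None:
        files = [f for f in _library_dir().iterdir() if f.name.endswith(".yaml")]
    else:
        files = sorted(Path(directory).glob("*.yaml"))
    lib = {}
    for f in sorted(files, key=lambda x: x.name):
        rec = load_compound(f)
        lib[rec.name] = rec
    for rec in lib.values():
        if rec.prodrug_to and rec.prodrug_to.target not in lib:
            raise SchemaError(
                f"{rec.name}: prodrug target {rec.prodrug_to.target!r} "
                "not in library"
            )
    return lib


def therapeutic_window(
    drug: str, library: Optional[Dict[str, CompoundRecord]] = None
) -> Optional[TherapeuticWindow]:
    """The drug's therapeutic window, or None for drugs monitored without
    a numeric target (fluconazole, letermovir, fosaprepitant, aprepitant,
    omeprazole)."""
    library = library if library is not None else load_library()
    if drug not in library:
        raise KeyError(f"unknown drug {drug!r}; library has {sorted(library)}")
    return library[drug].therapeutic_window


def interaction_network(
    library: Optional[Dict[str, CompoundRecord]] = None,
    include_auto: bool = False,
) -> pd.DataFrame:
    """Edge list (perpetrator, mechanism, target, victim) over the library.

    Victims are compounds with a clearance pathway through the target
    enzyme/transporter. Self-edges (a compound modulating its own pathway)
    are flagged ``auto`` and excluded from the report unless
    ``include_auto``."""
    library = library if library is not None else load_library()
    rows = []
    for rec in library.values():
        for spec in rec.interactions:
            mech = (
                spec.type if isinstance(spec, InhibitionSpec) else "induction"
            )
            for victim in library.values():
                if any(p.enzyme == spec.target for p in victim.pathways):
                    rows.append(
                        {
                            "perpetrator": rec.name,
                            "mechanism": mech,
                            "target": spec.target,
                            "victim": victim.name,
                            "auto": victim.name == rec.name,
                        }
                    )
    df = pd.DataFrame(
        rows, columns=["perpetrator", "mechanism", "target", "victim", "auto"]
    )
    if not include_auto:
        df = df[~df["auto"]].reset_index(drop=True)
    return df


def standard_regimen(drug: str, n_doses: int = 1, start: float = 0.0) -> Regimen:
    """Conventional regimen for one drug (single dose by default)."""
    if drug not in STANDARD_REGIMENS:
        raise KeyError(f"no standard regimen for {drug!r}")
    r = STANDARD_REGIMENS[drug]
    return Regimen.repeating(
        r["dose"],
        r["interval"],
        n_doses,
        route=r["route"],
        start=start,
        duration=r.get("duration"),
        per_kg=r.get("per_kg", False),
    )
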