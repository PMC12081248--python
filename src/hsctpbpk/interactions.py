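"""Enzyme inhibition and induction mechanisms.

Five reversible inhibition types (competitive, uncompetitive,
non-competitive, mixed, plus the irreversible/mechanism-based class handled
through enzyme turnover), Emax/EC50 induction of enzyme synthesis, and
composition rules for multiple simultaneous perpetrators acting on one
target.

All inhibitor/inducer concentrations are unbound concentrations at the
enzyme's site (µmol/L); the driver is the unbound liver-tissue concentration
for hepatic enzymes and the unbound gut concentration for gut enzymes.
"""

from __future__ import annotations

from typing import Dict, List, Literal, NamedTuple, Optional, Sequence, Union

from pydantic import BaseModel, Field, model_validator

ReversibleType = Literal["competitive", "uncompetitive", "non-competitive", "mixed"]


class InhibitionSpec(BaseModel):
    """One perpetrator→enzyme inhibition edge.

    For reversible types ``ki`` is the inhibition constant (for mixed, the
    competitive-site constant; the uncompetitive site gets ``alpha * ki``).
    Irreversible (mechanism-based) inactivation is parameterized by
    ``kinact`` (1/h, maximum inactivation rate) and ``KI`` (µmol/L,
    half-maximal inactivator concentration).
    """

    kind: Literal["inhibition"] = "inhibition"
    perpetrator: str = ""
    target: str
    type: Literal[
        "competitive", "uncompetitive", "non-competitive", "mixed", "irreversible"
    ]
    ki: Optional[float] = Field(default=None, description="µmol/L")
    alpha: Optional[float] = Field(default=None, description="mixed-type factor")
    kinact: Optional[float] = Field(default=None, description="1/h")
    KI: Optional[float] = Field(default=None, description="µmol/L")

    @model_validator(mode="after")
    def _required_constants(self):
        if self.type == "irreversible":
            if not (self.kinact and self.kinact > 0 and self.KI and self.KI > 0):
                raise ValueError(
                    f"irreversible inhibition of {self.target} requires "
                    "kinact > 0 and KI > 0"
                )
        else:
            if not (self.ki and self.ki > 0):
                raise ValueError(
                    f"{self.type} inhibition of {self.target} requires Ki > 0"
                )
            if self.type == "mixed":
                if not (self.alpha and self.alpha > 0):
                    raise ValueError(
                        f"mixed inhibition of {self.target} requires alpha > 0"
                    )
        return self


class InductionSpec(BaseModel):
    """Emax/EC50 induction of an enzyme's synthesis rate.

    ``emax`` is the maximum fold-increase minus one of the synthesis rate;
    ``ec50`` the unbound inducer concentration at half-maximal effect.
    """

    kind: Literal["induction"] = "induction"
    perpetrator: str = ""
    target: str
    emax: float = Field(ge=0)
    ec50: float = Field(gt=0, description="µmol/L")


InteractionSpec = Union[InhibitionSpec, InductionSpec]


def reversible_rate_factor(
    S: float, I: float, spec: InhibitionSpec, Km: float = 1.0
) -> float:
    """Multiplicative factor on v = Vmax*S/(Km+S) for one reversible
    inhibitor at unbound concentration ``I`` (µmol/L).

    Standard forms: competitive scales Km by (1+I/Ki); uncompetitive divides
    Vmax and Km by (1+I/Ki); non-competitive divides Vmax by (1+I/Ki); mixed
    uses v = Vmax*S / (Km*(1+I/Ki) + S*(1+I/(alpha*Ki))).

    ``S`` in the same (µmol/L) units as ``Km``; for linear (S << Km)
    pathways pass S=0.
    """
    if S < 0 or I < 0:
        raise ValueError("concentrations must be non-negative")
    if spec.type == "irreversible":
        raise TypeError(
            "irreversible inhibition modifies the enzyme pool via turnover, "
            "not the instantaneous rate; use enzyme_turnover_rhs"
        )
    return combine_reversible(S, [(spec, I)], Km)


def combine_reversible(
    S: float, specs_conc: Sequence[tuple], Km: float = 1.0
) -> float:
    """Net rate factor for several reversible inhibitors at one target.

    Competitive-site contributions add inside a single (1 + Σ I/Ki)
    denominator on Km; uncompetitive-site contributions add on the S term.
    """
    d_km = 1.0
    d_s = 1.0
    target = None
    for spec, I in specs_conc:
        if target is None:
            target = spec.target
        elif spec.target != target:
            raise ValueError("all reversible specs must share one target")
        if spec.type == "irreversible":
            continue
        r = I / spec.ki
        if spec.type == "competitive":
            d_km += r
        elif spec.type == "uncompetitive":
            d_s += r
        elif spec.type == "non-competitive":
            d_km += r
            d_s += r
        elif spec.type == "mixed":
            d_km += r
            d_s += I / (spec.alpha * spec.ki)
    return (Km + S) / (Km * d_km + S * d_s)


def inactivation_rate(specs_conc: Sequence[tuple]) -> float:
    """Net first-order inactivation hazard Σ kinact*I/(KI+I) (1/h)."""
    lam = 0.0
    for spec, I in specs_conc:
        if getattr(spec, "type", None) == "irreversible":
            lam += spec.kinact * I / (spec.KI + I)
    return lam


def induction_effect(specs_conc: Sequence[tuple]) -> float:
    """Net additive induction term Σ Emax*I/(EC50+I) (dimensionless)."""
    eff = 0.0
    for spec, I in specs_conc:
        if isinstance(spec, InductionSpec):
            eff += spec.emax * I / (spec.ec50 + I)
    return eff


def enzyme_turnover_rhs(
    E: float,
    E0: float,
    kdeg: float,
    mbi: Sequence[tuple] = (),
    induction: Sequence[tuple] = (),
) -> float:
    """dE/dt for one enzyme pool under turnover with mechanism-based
    inactivation and induction of synthesis:

        dE/dt = kdeg*E0*(1 + Σ Emax_j*I_j/(EC50_j+I_j))
                - E*(kdeg + Σ kinact_m*I_m/(KI_m+I_m))

    At baseline (no perpetrators, E=E0) synthesis balances degradation.
    """
    synth = kdeg * E0 * (1.0 + induction_effect(induction))
    loss = E * (kdeg + inactivation_rate(mbi))
    return synth - loss


class NetModifiers(NamedTuple):
    reversible_factor: float
    inactivation_rate: float  # 1/h
    induction_term: float  # dimensionless additive effect


def combine_perpetrators(
    specs: Sequence[InteractionSpec],
    concentrations: Sequence[float],
    S: float = 0.0,
    Km: float = 1.0,
) -> NetModifiers:
    """Compose simultaneous perpetrators at one target into net modifiers.

    Returns the net reversible rate factor (at substrate concentration S),
    the net inactivation hazard, and the net additive induction term.
    Permutation-invariant by construction.
    """
    if len(specs) != len(concentrations):
        raise ValueError("specs and concentrations must align")
    targets = {s.target for s in specs}
    if len(targets) > 1:
        raise ValueError(f"specs target multiple enzymes: {sorted(targets)}")
    pairs = list(zip(specs, concentrations))
    rev = [(s, c) for s, c in pairs if isinstance(s, InhibitionSpec)]
    ind = [(s, c) for s, c in pairs if isinstance(s, InductionSpec)]
    return NetModifiers(
        reversible_factor=combine_reversible(S, rev, Km) if rev else 1.0,
        inactivation_rate=inactivation_rate(rev),
        induction_term=induction_effect(ind),
    )


def mbi_steady_state_ratio(kdeg: float, kinact: float, KI: float, I: float) -> float:
    """Closed-form E_ss/E0 under constant mechanism-based inactivator
    exposure: kdeg / (kdeg + kinact*I/(KI+I))."""
    return kdeg / (kdeg + kinact * I / (KI + I))


def induction_steady_state_ratio(emax: float, ec50: float, I: float) -> float:
    """Closed-form E_ss/E0 under constant inducer exposure:
    1 + Emax*I/(EC50+I)."""
    return 1.0 + emax * I / (ec50 + I)


def interaction_driver_concentration(result, perpetrator: str, site: str):
    """Unbound perpetrator concentration time-course at an interaction site.

    ``site`` is an organ name or ``venous_plasma``; returns fu × the
    plasma-referenced concentration leaving that site, in mass units
    (mg/L); divide by MW/1000 for the µmol/L scale of Ki/KI/EC50.
    """
    fu = result.system.compound(perpetrator).fu
    if site == "venous_plasma":
        return fu * result.plasma(perpetrator)
    return fu * result.outflow_plasma_conc(perpetrator, site)
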