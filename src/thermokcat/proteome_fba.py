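"""Proteome-constrained flux balance analysis with temperature-dependent kcat.

Classic FBA maximizes a growth flux v_growth subject to steady state
(S v = 0) and flux bounds.  The proteome extension reserves a fixed mass
fraction phi_Q of the total proteome P_TOT (g protein / gDW) for
housekeeping and bounds the flexible sectors -- catabolism (C), anabolism
(A, ribosome) and transport (T) -- by a single pooled linear constraint:

    v_growth / a_ribosome
      + sum_catabolic v_i * MW_i / k_i   (or v_i / a_i)
      + sum_transport v_j / a_j
    <= (1 - phi_Q) * P_TOT

Each term is the protein mass (g/gDW) a flux demands.  Temperature enters
through the catabolic k_i: predicted kcat(T) values re-parameterize the
constraint at every temperature, turning growth rate into a function of T.

Units: fluxes mmol/gDW/h; kcat given in 1/s (converted x3600 to 1/h);
enzyme molar mass MW in g/mol (converted /1000 to g/mmol); specific
activities a in mmol/h/gE for sector-level activities, or umol/min/mg
(x60 -> mmol/h/g) for per-reaction assignments.  LP solving is delegated
to COBRApy/GLPK; the sector constraint is added through the optlang solver
interface so reversible reactions consume capacity in both directions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

SECONDS_PER_HOUR = 3600.0
MG_PER_G_TIMES_MIN = 60.0   # umol/min/mg -> mmol/h/g
G_PER_MOL_TO_G_PER_MMOL = 1e-3


class FBAError(RuntimeError):
    pass


class InfeasibleError(FBAError):
    pass


class UnboundedError(FBAError):
    pass


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]   # metabolite -> coefficient (+ product)
    lb: float = 0.0
    ub: float = 1000.0

    def __post_init__(self):
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lb > ub")


@dataclass
class MetabolicModel:
    """Stoichiometric model: metabolites, bounded reactions, growth objective."""

    metabolites: list[str]
    reactions: list[Reaction]
    objective_reaction: str

    def __post_init__(self):
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")
        if self.objective_reaction not in ids:
            raise ValueError(f"objective reaction {self.objective_reaction!r} missing")
        mets = set(self.metabolites)
        for r in self.reactions:
            unknown = set(r.stoichiometry) - mets
            if unknown:
                raise ValueError(f"reaction {r.id} uses unknown metabolites {unknown}")

    # -- interchange -------------------------------------------------------
    def to_dict(self) -> dict:
        return {"metabolites": list(self.metabolites),
                "reactions": [{"id": r.id, "stoichiometry": r.stoichiometry,
                               "lb": r.lb, "ub": r.ub} for r in self.reactions],
                "objective": self.objective_reaction}

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicModel":
        return cls(metabolites=list(d["metabolites"]),
                   reactions=[Reaction(r["id"], dict(r["stoichiometry"]),
                                       float(r.get("lb", 0.0)),
                                       float(r.get("ub", 1000.0)))
                              for r in d["reactions"]],
                   objective_reaction=d["objective"])

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "MetabolicModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_sbml(cls, path, objective_reaction: str | None = None) -> "MetabolicModel":
        """Read an SBML Level 3 model (for users with genome-scale models)."""
        cm = cobra.io.read_sbml_model(str(path))
        obj = objective_reaction
        if obj is None:
            objs = [r.id for r in cm.reactions if r.objective_coefficient]
            if len(objs) != 1:
                raise ValueError("SBML model has no unique objective; pass one")
            obj = objs[0]
        return cls(metabolites=[m.id for m in cm.metabolites],
                   reactions=[Reaction(r.id,
                                       {m.id: c for m, c in r.metabolites.items()},
                                       r.lower_bound, r.upper_bound)
                              for r in cm.reactions],
                   objective_reaction=obj)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions)."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        mi = {m: i for i, m in enumerate(self.metabolites)}
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[mi[m], j] = c
        return S

    def to_cobra(self) -> cobra.Model:
        cm = cobra.Model("model")
        mets = {m: cobra.Metabolite(m) for m in self.metabolites}
        for r in self.reactions:
            cr = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
            cm.add_reactions([cr])
            cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        cm.objective = self.objective_reaction
        return cm


@dataclass
class EnzymeAssignment:
    """Enzyme capacity data for one catabolic reaction.

    Either turnover mode (kcat in 1/s plus molar mass MW in g/mol) or
    specific-activity mode (a in umol/min/mg enzyme).
    """

    reaction_id: str
    mode: str                      # "turnover" | "specific_activity"
    k_cat: float | None = None     # 1/s
    MW: float | None = None        # g/mol
    a: float | None = None         # umol/min/mg

    def __post_init__(self):
        if self.mode == "turnover":
            if not (self.k_cat and self.k_cat > 0 and self.MW and self.MW > 0):
                raise ValueError(f"{self.reaction_id}: turnover mode needs k_cat>0, MW>0")
            if self.a is not None:
                raise ValueError(f"{self.reaction_id}: 'a' not allowed in turnover mode")
        elif self.mode == "specific_activity":
            if not (self.a and self.a > 0):
                raise ValueError(f"{self.reaction_id}: specific_activity mode needs a>0")
            if self.k_cat is not None or self.MW is not None:
                raise ValueError(f"{self.reaction_id}: k_cat/MW not allowed in this mode")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    def mass_per_flux(self, k_cat_override: float | None = None) -> float:
        """Enzyme mass (g/gDW) demanded per unit flux (mmol/gDW/h)."""
        if self.mode == "turnover":
            k = k_cat_override if k_cat_override is not None else self.k_cat
            if not k > 0:
                raise ValueError(f"{self.reaction_id}: kcat must be positive")
            return (self.MW * G_PER_MOL_TO_G_PER_MMOL) / (k * SECONDS_PER_HOUR)
        return 1.0 / (self.a * MG_PER_G_TIMES_MIN)


@dataclass
class ProteomeSectorSpec:
    """Sector budget and activities for the pooled proteome constraint.

    phi_Q: housekeeping mass fraction (dimensionless); P_TOT: total proteome
    mass per gDW; a_ribosome/a_AT/a_CT: sector-level specific activities in
    mmol/h/gE (ribosome 107.4, acid export 6360, carbon uptake e.g. 361.14
    for a glucose PTS or 540 for a lactose antiporter).
    """

    phi_Q: float = 0.5
    P_TOT: float = 0.5
    a_ribosome: float = 107.4
    a_AT: float = 6360.0
    a_CT: float = 361.14
    transport_reactions: dict[str, str] = field(default_factory=dict)  # id -> "AT"|"CT"
    catabolic: dict[str, EnzymeAssignment] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.phi_Q < 1.0:
            raise ValueError("phi_Q must lie in (0, 1)")
        for v in (self.P_TOT, self.a_ribosome, self.a_AT, self.a_CT):
            if not v > 0:
                raise ValueError("all activities and P_TOT must be positive")
        for rid, sector in self.transport_reactions.items():
            if sector not in ("AT", "CT"):
                raise ValueError(f"transport reaction {rid}: sector must be AT or CT")

    @property
    def budget(self) -> float:
        """(1 - phi_Q) * P_TOT, the flexible-sector protein mass."""
        return (1.0 - self.phi_Q) * self.P_TOT


@dataclass
class FBAResult:
    growth: float
    fluxes: dict[str, float]
    status: str
    sector_usage: float | None = None   # LHS of the proteome constraint


def _solve(cm: cobra.Model, objective_id: str) -> FBAResult:
    cm.slim_optimize(error_value=float("nan"))
    status = cm.solver.status
    if status == "infeasible":
        raise InfeasibleError("LP infeasible under the given bounds/constraints")
    if status == "unbounded":
        raise UnboundedError(f"objective {objective_id!r} is unbounded")
    if status != "optimal":
        raise FBAError(f"solver returned status {status!r}")
    from cobra.core.solution import get_solution
    sol = get_solution(cm)
    return FBAResult(growth=float(sol.objective_value),
                     fluxes={r: float(v) for r, v in sol.fluxes.items()},
                     status=status)


def fba(model: MetabolicModel) -> FBAResult:
    """Plain flux balance analysis: maximize the objective flux."""
    cm = model.to_cobra()
    return _solve(cm, model.objective_reaction)


def add_proteome_constraints(cm: cobra.Model, model: MetabolicModel,
                             sectors: ProteomeSectorSpec,
                             kcat_overrides: dict[str, float] | None = None) -> None:
    """Attach the pooled sector constraint to a cobra model in place.

    Reversible reactions contribute |v| through their forward and reverse
    LP variables, so enzyme capacity is consumed in either direction.
    kcat_overrides replaces the kcat of turnover-mode assignments (e.g.
    with temperature-specific predictions).
    """
    kcat_overrides = kcat_overrides or {}
    declared = set(sectors.catabolic)
    for rid in declared:
        if rid not in {r.id for r in model.reactions}:
            raise ValueError(f"catabolic reaction {rid!r} not in model")
    coeffs: dict[str, float] = {}
    coeffs[model.objective_reaction] = 1.0 / sectors.a_ribosome
    for rid, asg in sectors.catabolic.items():
        ov = kcat_overrides.get(rid)
        coeffs[rid] = coeffs.get(rid, 0.0) + asg.mass_per_flux(ov)
    for rid, sector in sectors.transport_reactions.items():
        act = sectors.a_AT if sector == "AT" else sectors.a_CT
        coeffs[rid] = coeffs.get(rid, 0.0) + 1.0 / act
    terms = []
    for rid, c in coeffs.items():
        rxn = cm.reactions.get_by_id(rid)
        terms.append(c * (rxn.forward_variable + rxn.reverse_variable))
    constraint = cm.problem.Constraint(sum(terms), ub=sectors.budget,
                                       name="proteome_sectors")
    cm.add_cons_vars(constraint)


def constrained_fba(model: MetabolicModel, sectors: ProteomeSectorSpec | None,
                    kcat_overrides: dict[str, float] | None = None) -> FBAResult:
    """FBA with the proteome-sector constraint (or plain FBA if sectors is None)."""
    cm = model.to_cobra()
    if sectors is not None:
        add_proteome_constraints(cm, model, sectors, kcat_overrides)
    res = _solve(cm, model.objective_reaction)
    if sectors is not None:
        usage = res.growth / sectors.a_ribosome
        kcat_overrides = kcat_overrides or {}
        for rid, asg in sectors.catabolic.items():
            usage += abs(res.fluxes[rid]) * asg.mass_per_flux(kcat_overrides.get(rid))
        for rid, sector in sectors.transport_reactions.items():
            act = sectors.a_AT if sector == "AT" else sectors.a_CT
            usage += abs(res.fluxes[rid]) / act
        res.sector_usage = usage
    return res


def growth_vs_temperature(model: MetabolicModel, sectors: ProteomeSectorSpec,
                          kcat_table: pd.DataFrame) -> pd.DataFrame:
    """One constrained-FBA solve per temperature column of `kcat_table`.

    kcat_table columns: reaction_id, temperature_C, kcat_s.  Every declared
    turnover-mode catabolic reaction must have a kcat at every temperature.
    Infeasible temperatures yield growth 0 with feasible=False rather than
    an exception, so curves stay plottable.
    """
    required = {rid for rid, a in sectors.catabolic.items() if a.mode == "turnover"}
    rows = []
    for temp, sub in kcat_table.groupby("temperature_C"):
        overrides = dict(zip(sub["reaction_id"], sub["kcat_s"]))
        missing = required - set(overrides)
        if missing:
            raise ValueError(f"kcat table incomplete at T={temp}: missing {sorted(missing)}")
        try:
            res = constrained_fba(model, sectors, overrides)
            rows.append({"temperature_C": float(temp), "growth": res.growth,
                         "feasible": True})
        except InfeasibleError:
            rows.append({"temperature_C": float(temp), "growth": 0.0,
                         "feasible": False})
    return pd.DataFrame(rows).sort_values("temperature_C").reset_index(drop=True)


def kcat_log2_fold_changes(kcat_table: pd.DataFrame, t_ref: float,
                           t_cmp: float) -> pd.DataFrame:
    """Per-reaction log2(kcat(t_cmp)/kcat(t_ref)) from a kcat table."""
    ref = kcat_table[kcat_table.temperature_C == t_ref].set_index("reaction_id").kcat_s
    cmp_ = kcat_table[kcat_table.temperature_C == t_cmp].set_index("reaction_id").kcat_s
    common = ref.index.intersection(cmp_.index)
    return pd.DataFrame({"reaction_id": common,
                         "log2_fold_change": np.log2(cmp_[common] / ref[common]).values})


def sectors_to_dict(sectors: ProteomeSectorSpec) -> dict:
    return {"phi_Q": sectors.phi_Q, "P_TOT": sectors.P_TOT,
            "a_ribosome": sectors.a_ribosome, "a_AT": sectors.a_AT,
            "a_CT": sectors.a_CT,
            "transport_reactions": dict(sectors.transport_reactions),
            "catabolic": [{"reaction_id": a.reaction_id, "mode": a.mode,
                           "k_cat": a.k_cat, "MW": a.MW, "a": a.a}
                          for a in sectors.catabolic.values()]}


def sectors_from_dict(d: dict) -> ProteomeSectorSpec:
    catabolic = {a["reaction_id"]: EnzymeAssignment(
        a["reaction_id"], a["mode"], k_cat=a.get("k_cat"),
        MW=a.get("MW"), a=a.get("a")) for a in d.get("catabolic", [])}
    return ProteomeSectorSpec(
        phi_Q=float(d.get("phi_Q", 0.5)), P_TOT=float(d.get("P_TOT", 0.5)),
        a_ribosome=float(d.get("a_ribosome", 107.4)),
        a_AT=float(d.get("a_AT", 6360.0)), a_CT=float(d.get("a_CT", 361.14)),
        transport_reactions=dict(d.get("transport_reactions", {})),
        catabolic=catabolic)


def load_sectors_json(path) -> ProteomeSectorSpec:
    with open(path, encoding="utf-8") as fh:
        return sectors_from_dict(json.load(fh))


def save_sectors_json(sectors: ProteomeSectorSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(sectors_to_dict(sectors), fh, indent=1)


def select_reaction_kcat(isozyme_predictions, primary_substrate: str | None = None) -> float:
    """Aggregate predicted kcats to one value per reaction.

    `isozyme_predictions`: one item per isozyme, each either a bare kcat or
    a list of (substrate, kcat) predictions.  For multi-substrate isozymes
    the primary substrate's value is used (the named one, else the first
    listed); across isozymes the largest kcat wins.
    """
    if not isozyme_predictions:
        raise ValueError("no kcat candidates given")
    chosen = []
    for item in isozyme_predictions:
        if isinstance(item, (int, float)):
            chosen.append(float(item))
            continue
        if not item:
            raise ValueError("empty substrate prediction list for an isozyme")
        if primary_substrate is not None:
            hits = [k for s, k in item if s == primary_substrate]
            if not hits:
                raise ValueError(f"primary substrate {primary_substrate!r} absent")
            chosen.append(float(hits[0]))
        else:
            chosen.append(float(item[0][1]))
    return max(chosen)
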