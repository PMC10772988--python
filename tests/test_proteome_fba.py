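"""FBA correctness on hand-solvable toy models and behaviour of the pooled
proteome-sector constraint."""

import numpy as np
import pandas as pd
import pytest

import thermokcat as tk
from thermokcat.proteome_fba import (EnzymeAssignment, InfeasibleError,
                                     MetabolicModel, ProteomeSectorSpec,
                                     Reaction, UnboundedError, constrained_fba,
                                     fba, growth_vs_temperature,
                                     kcat_log2_fold_changes,
                                     load_sectors_json, save_sectors_json,
                                     sectors_from_dict, sectors_to_dict,
                                     select_reaction_kcat)


def chain_model(uptake_ub=10.0):
    """uptake (ub) -> A -> biomass; the single bottleneck sets growth."""
    return MetabolicModel(
        metabolites=["A", "bm"],
        reactions=[Reaction("EX_A", {"A": 1.0}, 0.0, uptake_ub),
                   Reaction("GROWTH", {"A": -1.0, "bm": 1.0}, 0.0, 1000.0),
                   Reaction("EX_bm", {"bm": -1.0}, 0.0, 1000.0)],
        objective_reaction="GROWTH")


def branched_model():
    """Two parallel routes (ub 10 and 4) feed biomass: optimum 14."""
    return MetabolicModel(
        metabolites=["A", "B", "bm"],
        reactions=[Reaction("EX_A", {"A": 1.0}, 0.0, 10.0),
                   Reaction("EX_B", {"B": 1.0}, 0.0, 4.0),
                   Reaction("R_A", {"A": -1.0, "bm": 1.0}, 0.0, 1000.0),
                   Reaction("R_B", {"B": -1.0, "bm": 1.0}, 0.0, 1000.0),
                   Reaction("GROWTH", {"bm": -1.0}, 0.0, 1000.0)],
        objective_reaction="GROWTH")


def mass_balance_residual(model, fluxes):
    S = model.stoichiometric_matrix()
    v = np.array([fluxes[r.id] for r in model.reactions])
    return np.abs(S @ v).max()


def test_fba_single_bottleneck():
    res = fba(chain_model())
    assert res.growth == pytest.approx(10.0, abs=1e-6)
    assert mass_balance_residual(chain_model(), res.fluxes) <= 1e-6


def test_fba_closed_exchanges_give_zero_growth():
    res = fba(chain_model(uptake_ub=0.0))
    assert res.growth == pytest.approx(0.0, abs=1e-9)


def test_fba_branched_two_bottlenecks():
    res = fba(branched_model())
    assert res.growth == pytest.approx(14.0, abs=1e-6)
    assert mass_balance_residual(branched_model(), res.fluxes) <= 1e-6


def test_fba_unbounded_is_reported():
    m = MetabolicModel(
        metabolites=["A"],
        reactions=[Reaction("IN", {"A": 1.0}, 0.0, 1e6),
                   Reaction("GROWTH", {"A": -1.0}, 0.0, float("inf"))],
        objective_reaction="GROWTH")
    m.reactions[0].ub = float("inf")
    with pytest.raises(UnboundedError, match="GROWTH"):
        fba(m)


def test_model_validation():
    with pytest.raises(ValueError, match="objective"):
        MetabolicModel(["A"], [Reaction("R", {"A": 1.0})], "missing")
    with pytest.raises(ValueError, match="unknown metabolites"):
        MetabolicModel(["A"], [Reaction("R", {"B": 1.0})], "R")
    with pytest.raises(ValueError):
        Reaction("R", {}, lb=1.0, ub=0.0)


def test_ribosome_only_bound():
    """With only the ribosome term in the constraint, max growth equals
    (1 - phi_Q) * P_TOT * a_ribosome = 0.5 * 0.5 * 107.4 = 26.85."""
    model = chain_model(uptake_ub=1e5)
    sectors = ProteomeSectorSpec(phi_Q=0.5, P_TOT=0.5, a_ribosome=107.4)
    res = constrained_fba(model, sectors)
    assert res.growth == pytest.approx(26.85, abs=1e-6)
    assert res.sector_usage == pytest.approx(sectors.budget, abs=1e-6)


def test_huge_proteome_budget_recovers_plain_fba():
    model, sectors, _ = tk.generate_toy_gsmm(0)
    relaxed = ProteomeSectorSpec(
        phi_Q=sectors.phi_Q, P_TOT=1e9, a_ribosome=sectors.a_ribosome,
        a_AT=sectors.a_AT, a_CT=sectors.a_CT,
        transport_reactions=sectors.transport_reactions,
        catabolic=sectors.catabolic)
    plain = fba(model)
    res = constrained_fba(model, relaxed)
    assert res.growth == pytest.approx(plain.growth, abs=1e-9)


def test_no_sectors_identical_to_plain_fba():
    model = branched_model()
    assert constrained_fba(model, None).growth == fba(model).growth


def test_growth_monotone_in_kcat_and_ptot():
    model, sectors, _ = tk.generate_toy_gsmm(0)
    base = constrained_fba(model, sectors).growth
    rng = np.random.default_rng(4)
    for _ in range(5):
        scale = float(rng.uniform(1.0, 3.0))
        overrides = {rid: a.k_cat * scale for rid, a in sectors.catabolic.items()
                     if a.mode == "turnover"}
        up = constrained_fba(model, sectors, overrides).growth
        assert up >= base - 1e-9
    bigger = ProteomeSectorSpec(
        phi_Q=sectors.phi_Q, P_TOT=sectors.P_TOT * 2,
        a_ribosome=sectors.a_ribosome, a_AT=sectors.a_AT, a_CT=sectors.a_CT,
        transport_reactions=sectors.transport_reactions,
        catabolic=sectors.catabolic)
    assert constrained_fba(model, bigger).growth >= base - 1e-9


def test_sector_constraint_tight_at_optimum():
    model, sectors, expected = tk.generate_toy_gsmm(0)
    res = constrained_fba(model, sectors)
    # sector-limited regime: the constraint's LHS equals the budget
    assert res.sector_usage == pytest.approx(sectors.budget, abs=1e-6)
    assert mass_balance_residual(model, res.fluxes) <= 1e-6


def test_missing_catabolic_assignment_is_configuration_error():
    model = chain_model()
    sectors = ProteomeSectorSpec(
        catabolic={"NOPE": EnzymeAssignment("NOPE", "turnover",
                                            k_cat=10.0, MW=5e4)})
    with pytest.raises(ValueError, match="NOPE"):
        constrained_fba(model, sectors)


def test_enzyme_assignment_modes_and_units():
    with pytest.raises(ValueError):
        EnzymeAssignment("R", "turnover", k_cat=10.0)          # missing MW
    with pytest.raises(ValueError):
        EnzymeAssignment("R", "specific_activity")             # missing a
    with pytest.raises(ValueError):
        EnzymeAssignment("R", "weird", k_cat=1.0, MW=1.0)
    turn = EnzymeAssignment("R", "turnover", k_cat=10.0, MW=50000.0)
    # (50000 g/mol -> 50 g/mmol) / (10/s -> 36000/h)
    assert turn.mass_per_flux() == pytest.approx(50.0 / 36000.0)
    act = EnzymeAssignment("R", "specific_activity", a=30.0)
    # 30 umol/min/mg -> 1800 mmol/h/g
    assert act.mass_per_flux() == pytest.approx(1.0 / 1800.0)


def test_reversible_reaction_consumes_capacity_both_directions():
    """A reversible catabolic step running backward still uses enzyme mass."""
    model = MetabolicModel(
        metabolites=["A", "B"],
        reactions=[Reaction("EX_B", {"B": 1.0}, 0.0, 1000.0),
                   Reaction("CONV", {"A": -1.0, "B": 1.0}, -1000.0, 1000.0),
                   Reaction("GROWTH", {"A": -1.0}, 0.0, 1000.0)],
        objective_reaction="GROWTH")
    k, mw = 10.0, 3.6e4   # mass per flux = 36/36000 = 1e-3
    sectors = ProteomeSectorSpec(
        catabolic={"CONV": EnzymeAssignment("CONV", "turnover", k_cat=k, MW=mw)})
    res = constrained_fba(model, sectors)
    # CONV must run backward (B -> A, negative flux) to feed growth:
    # budget 0.25 = g/107.4 + |v_conv| * 1e-3 with |v_conv| = g
    expected = 0.25 / (1.0 / 107.4 + 1e-3)
    assert res.fluxes["CONV"] == pytest.approx(-res.growth, abs=1e-6)
    assert res.growth == pytest.approx(expected, abs=1e-6)


def test_growth_vs_temperature_flat_and_monotone():
    model, sectors, _ = tk.generate_toy_gsmm(0)
    turnover = [rid for rid, a in sectors.catabolic.items()
                if a.mode == "turnover"]
    rows = [{"reaction_id": rid, "temperature_C": t, "kcat_s": k}
            for t in (30.0, 34.0, 38.0)
            for rid, k in zip(turnover, [50.0, 40.0])]
    flat = growth_vs_temperature(model, sectors, pd.DataFrame(rows))
    assert flat.feasible.all()
    assert np.ptp(flat.growth.values) <= 1e-9      # constant kcat -> flat curve

    doubled = [dict(r, kcat_s=r["kcat_s"] * (2.0 if r["temperature_C"] > 30 else 1.0))
               for r in rows]
    curve = growth_vs_temperature(model, sectors, pd.DataFrame(doubled))
    assert curve.growth.iloc[1] >= curve.growth.iloc[0] - 1e-9


def test_growth_vs_temperature_requires_complete_columns():
    model, sectors, _ = tk.generate_toy_gsmm(0)
    rows = pd.DataFrame([{"reaction_id": "HEX", "temperature_C": 30.0,
                          "kcat_s": 10.0}])
    with pytest.raises(ValueError, match="missing"):
        growth_vs_temperature(model, sectors, rows)


def test_kcat_log2_fold_changes():
    table = pd.DataFrame([
        {"reaction_id": "R1", "temperature_C": 30.0, "kcat_s": 2.0},
        {"reaction_id": "R1", "temperature_C": 38.0, "kcat_s": 8.0},
    ])
    fc = kcat_log2_fold_changes(table, 30.0, 38.0)
    assert fc.log2_fold_change.iloc[0] == pytest.approx(2.0)


def test_select_reaction_kcat_rules():
    assert select_reaction_kcat([2.0, 5.0, 3.0]) == 5.0     # isozymes -> max
    assert select_reaction_kcat([7.5]) == 7.5
    preds = [[("glc", 1.0), ("fru", 9.0), ("gal", 3.0)]]
    assert select_reaction_kcat(preds, primary_substrate="fru") == 9.0
    assert select_reaction_kcat(preds) == 1.0               # default: first listed
    with pytest.raises(ValueError):
        select_reaction_kcat([])
    with pytest.raises(ValueError):
        select_reaction_kcat(preds, primary_substrate="xyl")


def test_json_roundtrips(tmp_path):
    model, sectors, _ = tk.generate_toy_gsmm(1)
    mpath = tmp_path / "model.json"
    model.save_json(mpath)
    loaded = MetabolicModel.load_json(mpath)
    assert loaded.to_dict() == model.to_dict()
    assert fba(loaded).growth == pytest.approx(fba(model).growth, abs=1e-9)
    spath = tmp_path / "sectors.json"
    save_sectors_json(sectors, spath)
    s2 = load_sectors_json(spath)
    assert sectors_to_dict(s2) == sectors_to_dict(sectors)
    assert constrained_fba(model, s2).growth == pytest.approx(
        constrained_fba(model, sectors).growth, abs=1e-9)
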