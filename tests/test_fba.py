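import itertools

import numpy as np
import pandas as pd
import pytest

from microwbm.fba import (
    FBASolution,
    add_demand_reaction,
    extract_biomass_shadow_prices,
    is_microbiome_influenced,
    predict_blood_fluxes,
    remove_demand_reaction,
    solve_fba,
)
from microwbm.model import ModelError, Reaction, Reconstruction, model_to_dict
from microwbm.pipeline import build_demo_model


# -- independent LP oracle: exhaustive vertex enumeration ---------------------


def vertex_enumeration_max(model: Reconstruction, objective_rxn: str) -> float:
    """Maximize by enumerating basic solutions of {S v = 0, lb <= v <= ub}.

    For every choice of n - rank(S) variables fixed at one of their bounds,
    solve the remaining square system and keep feasible points. Only valid
    for small models without couplings and with a bounded optimum.
    """
    assert not model.couplings
    n = len(model.reactions)
    mets = list(model.metabolites)
    S = np.zeros((len(mets), n))
    midx = {m: i for i, m in enumerate(mets)}
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoich.items():
            S[midx[met], j] = coef
    lb = np.array([r.lb for r in model.reactions])
    ub = np.array([r.ub for r in model.reactions])
    rank = np.linalg.matrix_rank(S)
    n_fix = n - rank
    obj = [r.id for r in model.reactions].index(objective_rxn)
    best = -np.inf
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(bounds_choice)
            A = S[:, free]
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if not np.allclose(A @ sol, rhs, atol=1e-9):
                continue
            v = np.empty(n)
            v[list(fixed)] = bounds_choice
            v[free] = sol
            if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
                best = max(best, v[obj])
    return best


def branched_model(upt=4.0, split=2.5):
    """Diet -> lumen, two routes to blood with one capped branch."""
    m = Reconstruction(id="branch")
    m.add_reaction(Reaction("EX_A", {"A[luM]": -1.0}, -upt, 0.0))
    m.add_reaction(Reaction("r1", {"A[luM]": -1.0, "B[bc]": 1.0}, 0.0, split))
    m.add_reaction(Reaction("r2", {"A[luM]": -1.0, "C[c]": 1.0}, 0.0, 1e3))
    m.add_reaction(Reaction("r3", {"C[c]": -1.0, "B[bc]": 1.0}, 0.0, 1.0))
    m.add_reaction(Reaction("DM_B[bc]", {"B[bc]": -1.0}, 0.0, 1e3))
    return m


class TestDemandReactions:
    def test_demand_consumes_with_coefficient_minus_one(self, chain_model):
        rid = add_demand_reaction(chain_model, "A")
        assert rid == "DM_A[bc]"
        assert chain_model.reaction(rid).stoich == {"A[bc]": -1.0}
        assert chain_model.reaction(rid).lb == 0.0

    def test_duplicate_demand_rejected_without_mutation(self, chain_model):
        add_demand_reaction(chain_model, "A")
        before = model_to_dict(chain_model)
        with pytest.raises(ModelError):
            add_demand_reaction(chain_model, "A")
        assert model_to_dict(chain_model) == before

    def test_add_remove_round_trip(self, chain_model):
        before = model_to_dict(chain_model)
        rid = add_demand_reaction(chain_model, "A")
        remove_demand_reaction(chain_model, rid)
        assert model_to_dict(chain_model) == before

    def test_missing_metabolite_rejected(self, chain_model):
        with pytest.raises(ModelError):
            add_demand_reaction(chain_model, "missing")


class TestSolveFBA:
    def test_chain_bottleneck(self, chain_model):
        rid = add_demand_reaction(chain_model, "A")
        sol = solve_fba(chain_model, rid)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(5.0)
        # steady state holds on the returned fluxes
        for met in chain_model.metabolites:
            balance = sum(coef * sol.fluxes[r.id]
                          for r in chain_model.reactions
                          for m, coef in r.stoich.items() if m == met)
            assert balance == pytest.approx(0.0, abs=1e-6)

    def test_unproducible_metabolite_gives_zero(self, chain_model):
        chain_model.add_reaction(Reaction("T_u_B", {"B[bc]": -1.0, "B[u]": 1.0},
                                          0.0, 1e6))
        rid = add_demand_reaction(chain_model, "B")
        sol = solve_fba(chain_model, rid)
        assert sol.objective_value == pytest.approx(0.0)

    @pytest.mark.parametrize("upt,split", [(4.0, 2.5), (0.5, 2.0), (10.0, 0.0)])
    def test_matches_vertex_enumeration_oracle(self, upt, split):
        m = branched_model(upt, split)
        expected = vertex_enumeration_max(m, "DM_B[bc]")
        sol = solve_fba(m, "DM_B[bc]")
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)

    def test_infeasible_status(self):
        m = Reconstruction(id="bad")
        m.add_reaction(Reaction("r1", {"a[c]": 1.0}, 1.0, 2.0))  # forces a>0
        sol = solve_fba(m, "r1")
        assert sol.status == "infeasible" and sol.fluxes is None

    def test_unbounded_status(self):
        m = Reconstruction(id="unb")
        m.add_reaction(Reaction("r1", {"a[c]": 1.0}, -1e30, 1e30))
        m.add_reaction(Reaction("r2", {"a[c]": -1.0}, -1e30, 1e30))
        sol = solve_fba(m, "r1")
        assert sol.status == "unbounded"

    def test_cross_check_against_cobra(self, chain_model):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("chain")
        mets = {mid: cobra.Metabolite(mid) for mid in chain_model.metabolites}
        rid = add_demand_reaction(chain_model, "A")
        for rxn in chain_model.reactions:
            cr = cobra.Reaction(rxn.id)
            cr.add_metabolites({mets[m]: c for m, c in rxn.stoich.items()})
            cr.bounds = (rxn.lb, min(rxn.ub, 1e3))
            cm.add_reactions([cr])
        cm.objective = rid
        assert cm.optimize().objective_value == pytest.approx(
            solve_fba(chain_model, rid).objective_value)


class TestShadowPrices:
    def test_finite_difference_matches_dual_convention(self, chain_model):
        """pi_i = -dZ/db_i for the steady-state rhs S v = b."""
        rid = add_demand_reaction(chain_model, "A")
        base = solve_fba(chain_model, rid)
        eps = 1e-4
        for met in ("A[luLI]", "A[bc]"):
            up = solve_fba(chain_model, rid, b_eq_shift={met: eps})
            dz_db = (up.raw_fluxes[rid] - base.raw_fluxes[rid]) / eps
            assert -dz_db == pytest.approx(base.shadow_prices[met], abs=1e-5)

    def test_sole_producer_has_negative_biomass_shadow_price(
            self, two_species_model):
        rid = add_demand_reaction(two_species_model, "P")
        sol = solve_fba(two_species_model, rid)
        prices = extract_biomass_shadow_prices(sol, two_species_model)
        assert prices["A"] < 0  # more A biomass raises Z
        assert prices["B"] == 0.0
        # finite-difference check on the biomass row itself: supplying the
        # biomass metabolite (negative rhs) lowers v_bio and the objective
        eps = 1e-5
        shifted = solve_fba(two_species_model, rid,
                            b_eq_shift={"panA_biomass[c]": -eps})
        dz = shifted.raw_fluxes[rid] - sol.raw_fluxes[rid]
        assert dz / (-eps) == pytest.approx(-prices["A"], rel=1e-4)

    def test_tolerance_zeroes_tiny_prices(self, two_species_model):
        rid = add_demand_reaction(two_species_model, "P")
        sol = solve_fba(two_species_model, rid)
        sol.shadow_prices.loc["panB_biomass[c]"] = 5e-7
        prices = extract_biomass_shadow_prices(sol, two_species_model)
        assert prices["B"] == 0.0

    def test_microbiome_influence_flag(self, two_species_model):
        rid = add_demand_reaction(two_species_model, "P")
        sol = solve_fba(two_species_model, rid)
        assert is_microbiome_influenced(sol, two_species_model)

    def test_host_only_metabolite_not_influenced(self):
        model, _ = build_demo_model(n_species=3, seed=2)
        # xeno fillers pass diet -> lumen -> blood without microbial reactions
        xeno = next(m[: m.rindex("[")] for m in model.metabolites
                    if m.startswith("xeno_") and m.endswith("[bc]"))
        rid = add_demand_reaction(model, xeno)
        sol = solve_fba(model, rid)
        assert sol.optimal
        assert not is_microbiome_influenced(sol, model)


class TestPredictBloodFluxes:
    def test_bookkeeping_and_determinism(self):
        model_a, _ = build_demo_model(n_species=3, seed=4)
        model_b, _ = build_demo_model(n_species=3, seed=4)
        mets = ["met_00", "met_01", "met_02"]
        fm = predict_blood_fluxes({"s1": model_a, "s2": model_b}, mets)
        assert fm.fluxes.shape == (2, 3)
        assert len(fm.solutions) == fm.fluxes.notna().sum().sum()
        pd.testing.assert_series_equal(fm.fluxes.loc["s1"], fm.fluxes.loc["s2"],
                                       check_names=False)

    def test_missing_producer_lowers_flux(self):
        from microwbm.synthetic import producers_by_metabolite
        full, catalog = build_demo_model(n_species=4, seed=0)
        multi = {m: p for m, p in producers_by_metabolite(catalog).items()
                 if len(p) >= 2}
        met, producers = sorted(multi.items())[0]
        dropped = sorted(producers)[0]
        reduced_abund = {s: v for s, v in full.abundances.items() if s != dropped}
        total = sum(reduced_abund.values())
        reduced_abund = {s: v / total for s, v in reduced_abund.items()}
        reduced, _ = build_demo_model(n_species=4, seed=0,
                                      abundances=reduced_abund)
        fm = predict_blood_fluxes({"with": full, "without": reduced}, [met])
        assert fm.fluxes.loc["without", met] < fm.fluxes.loc["with", met]

    def test_relaxing_diet_uptake_never_decreases_flux(self):
        model, _ = build_demo_model(n_species=3, seed=6)
        rid = add_demand_reaction(model, "met_00")
        base = solve_fba(model, rid).objective_value
        for rxn in model.reactions:
            if rxn.id.startswith("Diet_EX_") and rxn.lb < 0:
                relaxed = solve_fba(model, rid,
                                    bound_overrides={rxn.id: (rxn.lb * 2, rxn.ub)})
                assert relaxed.objective_value >= base - 1e-6


def syn_abund(model):
    return dict(model.abundances)
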