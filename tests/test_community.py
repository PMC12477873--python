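import numpy as np
import pytest

from microwbm.community import (
    DEFAULT_COUPLING_FACTOR,
    EXCRETION_RXN,
    WHOLE_BODY_OBJECTIVE_RXN,
    add_coupling_constraints,
    apply_diet,
    assemble_community,
    build_pan_species,
    join_host,
    pan_biomass_metabolite_id,
)
from microwbm.fba import add_demand_reaction, n_coupling_rows, solve_fba
from microwbm.model import ModelError, Reaction, Reconstruction, compartment_of
from microwbm.synthetic import (
    DietSpec,
    default_diet_metabolites,
    generate_host_template,
    generate_strain_catalog,
)


def strain(rid, reactions, species="SpX"):
    m = Reconstruction(id=rid)
    for r in reactions:
        m.add_reaction(Reaction(r[0], r[1], r[2], r[3], species=species,
                                is_biomass=len(r) > 4 and r[4]))
    return m


def simple_strain(rid, extra=(), species="SpX"):
    rxns = [
        ("upt_a", {"a[luM]": -1.0, "a[c]": 1.0}, 0.0, 1e6),
        ("bio", {"a[c]": -1.0, "biomass[c]": 1.0}, 0.0, 1e6, True),
        ("EX_a[luM]", {"a[luM]": -1.0}, -1e6, 1e6),
    ]
    return strain(rid, rxns + list(extra), species=species)


class TestPanSpecies:
    def test_single_strain_is_identity_union(self):
        s = simple_strain("st1")
        pan = build_pan_species([s], "SpX")
        assert len(pan.reactions) == len(s.reactions)
        assert len(pan.biomass_reactions()) == 1
        assert pan.biomass_reactions()[0].id == "panSpX_biomass"
        assert pan_biomass_metabolite_id("SpX") in pan.metabolites

    def test_disjoint_reaction_sets_union_count(self):
        extra_a = [(f"ra{i}", {"a[c]": -1.0, f"x{i}[c]": 1.0}, 0.0, 1e6)
                   for i in range(6)]  # 8 non-EX reactions total
        extra_b = [(f"rb{i}", {"a[c]": -1.0, f"y{i}[c]": 1.0}, 0.0, 1e6)
                   for i in range(3)]  # 5 non-EX reactions total
        a = simple_strain("st1", extra_a)
        b = simple_strain("st2", extra_b)
        pan = build_pan_species([a, b], "SpX")
        non_ex = [r for r in pan.reactions if not r.id.startswith("EX_")]
        assert len(non_ex) == 8 + 5 - 2  # shared upt_a and merged biomass

    def test_widest_bounds_rule(self):
        a = simple_strain("st1", [("rx", {"a[c]": -1.0, "b[c]": 1.0}, 0.0, 10.0)])
        b = simple_strain("st2", [("rx", {"a[c]": -1.0, "b[c]": 1.0}, -5.0, 10.0)])
        pan = build_pan_species([a, b], "SpX")
        assert (pan.reaction("rx").lb, pan.reaction("rx").ub) == (-5.0, 10.0)

    def test_conflicting_stoichiometry_rejected(self):
        a = simple_strain("st1", [("rx", {"a[c]": -1.0, "b[c]": 1.0}, 0.0, 1.0)])
        b = simple_strain("st2", [("rx", {"a[c]": -2.0, "b[c]": 1.0}, 0.0, 1.0)])
        with pytest.raises(ModelError, match="conflicting"):
            build_pan_species([a, b], "SpX")

    def test_empty_strain_list_rejected(self):
        with pytest.raises(ModelError):
            build_pan_species([], "SpX")


def two_pans():
    pa = build_pan_species([simple_strain("a1", species="SpA")], "SpA")
    pb = build_pan_species([simple_strain("b1", species="SpB")], "SpB")
    return {"SpA": pa, "SpB": pb}


class TestAssembleCommunity:
    def test_community_biomass_coefficients_are_abundances(self):
        comm = assemble_community(two_pans(), {"SpA": 0.6, "SpB": 0.4})
        cb = comm.reaction("communityBiomass")
        assert cb.stoich[pan_biomass_metabolite_id("SpA")] == -0.6
        assert cb.stoich[pan_biomass_metabolite_id("SpB")] == -0.4
        assert cb.stoich["microbiota_LI_biomass[luM]"] == 1.0

    def test_single_species_coefficient_minus_one(self):
        pans = {"SpA": build_pan_species([simple_strain("a1", species="SpA")],
                                         "SpA")}
        comm = assemble_community(pans, {"SpA": 1.0})
        assert comm.reaction("communityBiomass").stoich[
            pan_biomass_metabolite_id("SpA")] == -1.0

    def test_every_lumen_metabolite_has_species_transport(self):
        comm = assemble_community(two_pans(), {"SpA": 0.5, "SpB": 0.5})
        for met in comm.metabolites_in("luM"):
            if met.startswith("microbiota_LI_biomass"):
                continue
            assert any(met in r.stoich and r.species is not None
                       for r in comm.reactions)

    def test_bad_abundances_rejected(self):
        pans = two_pans()
        with pytest.raises(ModelError, match="sum"):
            assemble_community(pans, {"SpA": 0.5, "SpB": 0.4})
        with pytest.raises(ModelError, match="non-positive"):
            assemble_community(pans, {"SpA": 1.0, "SpB": 0.0})
        with pytest.raises(ModelError, match="cover exactly"):
            assemble_community(pans, {"SpA": 1.0})


class TestCoupling:
    def test_row_counting_rule(self):
        m = strain("toy", [
            ("irrev", {"a[c]": -1.0, "b[c]": 1.0}, 0.0, 1e6),
            ("rev", {"b[c]": -1.0, "a[c]": 1.0}, -1e6, 1e6),
            ("bio", {"a[c]": -1.0, "biomass[c]": 1.0}, 0.0, 1e6, True),
        ])
        comm = assemble_community(
            {"SpX": build_pan_species([m], "SpX")}, {"SpX": 1.0})
        add_coupling_constraints(comm)
        # 1 irreversible (1 row) + 1 reversible (2 rows) non-biomass reaction
        assert n_coupling_rows(comm) == 3
        assert all(c["factor"] == DEFAULT_COUPLING_FACTOR
                   for c in comm.couplings)

    def test_zero_biomass_forces_zero_fluxes(self, two_species_model):
        m = two_species_model.copy()
        # starve species B by pinning its biomass to zero and supplying the
        # community-biomass requirement externally is not possible here, so
        # instead rebuild with B absent from the objective path: force via ub
        m.reaction("panB_biomass").ub = 0.0
        # relax the community pin so the model stays feasible
        m.reaction("communityBiomass").stoich["panB_biomass[c]"] = 0.0
        dm = add_demand_reaction(m, "Q")
        sol = solve_fba(m, dm)
        assert sol.optimal
        for rid in ("B__upt_N", "B__conv", "B__sec"):
            assert sol.fluxes[rid] == pytest.approx(0.0, abs=1e-9)

    def test_coupled_flux_bounded_by_factor_times_biomass(self):
        from conftest import two_species_community
        m = two_species_community(r_a=0.25, r_b=0.75)
        add_demand_reaction(m, "P")
        sol = solve_fba(m, "A__upt_N")  # maximize a coupled species reaction
        assert sol.optimal
        # with v_bio pinned at 0.25 the coupling caps |v| at 400 * 0.25 = 100
        assert sol.objective_value <= 100.0 + 1e-6
        assert sol.objective_value == pytest.approx(100.0, abs=1e-6)


class TestJoinHost:
    def setup_method(self):
        self.host = generate_host_template(
            "male", diet_metabolites=default_diet_metabolites(8, 2))
        catalog = generate_strain_catalog(2, 1, seed=5)
        pans = {m.species_tags()[0]: build_pan_species([m], m.species_tags()[0])
                for m in catalog}
        self.comm = add_coupling_constraints(
            assemble_community(pans, {"Species_00": 0.7, "Species_01": 0.3}))

    def test_pinned_bounds(self):
        joined = join_host(self.host, self.comm)
        exc = joined.reaction(EXCRETION_RXN)
        assert (exc.lb, exc.ub) == (1.0, 1.0)
        wbo = joined.reaction(WHOLE_BODY_OBJECTIVE_RXN)
        assert (wbo.lb, wbo.ub) == (1.0, 1.0)

    def test_host_only_bounds_conserved(self):
        before = {r.id: (r.lb, r.ub) for r in self.host.reactions}
        joined = join_host(self.host, self.comm)
        for rid, bounds in before.items():
            if rid == WHOLE_BODY_OBJECTIVE_RXN:
                continue
            r = joined.reaction(rid)
            assert (r.lb, r.ub) == bounds

    def test_biomass_fluxes_pinned_to_abundances(self):
        from microwbm.synthetic import generate_diet
        joined = apply_diet(join_host(self.host, self.comm),
                            generate_diet(8, 0.0, seed=1,
                                          metabolite_ids=default_diet_metabolites(8, 2)))
        dm = add_demand_reaction(joined, "met_00")
        sol = solve_fba(joined, dm)
        assert sol.optimal
        assert sol.raw_fluxes["panSpecies_00_biomass"] == pytest.approx(0.7, abs=1e-6)
        assert sol.raw_fluxes["panSpecies_01_biomass"] == pytest.approx(0.3, abs=1e-6)

    def test_missing_lumen_rejected(self):
        bad_host = Reconstruction(id="nohost")
        bad_host.add_reaction(Reaction("r", {"a[bc]": -1.0}, 0.0, 1.0))
        with pytest.raises(ModelError, match="luLI"):
            join_host(bad_host, self.comm)


class TestApplyDiet:
    def make_joined(self):
        host = generate_host_template(
            "male", diet_metabolites=default_diet_metabolites(6, 2))
        catalog = generate_strain_catalog(2, 1, seed=5)
        pans = {m.species_tags()[0]: build_pan_species([m], m.species_tags()[0])
                for m in catalog}
        comm = add_coupling_constraints(
            assemble_community(pans, {"Species_00": 0.5, "Species_01": 0.5}))
        return join_host(host, comm)

    def test_uptake_bounds_follow_intakes(self):
        joined = self.make_joined()
        diet = DietSpec(entries={"nut_univ": 10.0, "nut_00": 0.05})
        apply_diet(joined, diet, flexibility=1.0)
        assert joined.reaction("Diet_EX_nut_univ[d]").lb == -10.0
        assert joined.reaction("Diet_EX_nut_00[d]").lb == -0.05
        assert diet.is_trace("nut_00")
        # metabolites absent from the diet cannot be taken up
        assert joined.reaction("Diet_EX_nut_01[d]").lb == 0.0

    def test_flexibility_scales_uptake(self):
        joined = self.make_joined()
        apply_diet(joined, DietSpec(entries={"nut_univ": 10.0}), flexibility=0.5)
        assert joined.reaction("Diet_EX_nut_univ[d]").lb == -5.0

    def test_unmatched_diet_entries_skipped(self, caplog):
        joined = self.make_joined()
        apply_diet(joined, DietSpec(entries={"nut_univ": 10.0,
                                             "no_such_met": 1.0}))
        assert joined.reaction("Diet_EX_nut_univ[d]").lb == -10.0


def test_scale_consistency_split_species():
    """Duplicating a species at half abundance leaves the blood flux unchanged."""
    catalog = generate_strain_catalog(1, 1, seed=5, species_ids=["SpA"])
    pan = build_pan_species(catalog, "SpA")
    pan2 = build_pan_species(
        [Reconstruction(id="copy",
                        metabolites=list(catalog[0].metabolites),
                        reactions=[Reaction(r.id, dict(r.stoich), r.lb, r.ub,
                                            species="SpA2", is_biomass=r.is_biomass)
                                   for r in catalog[0].reactions])], "SpA2")
    host = generate_host_template(
        "male", diet_metabolites=default_diet_metabolites(8, 1))
    from microwbm.synthetic import generate_diet
    diet = generate_diet(8, 0.0, seed=2,
                         metabolite_ids=default_diet_metabolites(8, 1))

    def blood_flux(pans, abund):
        comm = add_coupling_constraints(assemble_community(pans, abund))
        joined = apply_diet(join_host(host, comm), diet)
        dm = add_demand_reaction(joined, "met_00")
        sol = solve_fba(joined, dm)
        assert sol.optimal
        return sol.objective_value

    single = blood_flux({"SpA": pan}, {"SpA": 1.0})
    split = blood_flux({"SpA": pan, "SpA2": pan2}, {"SpA": 0.5, "SpA2": 0.5})
    assert split == pytest.approx(single, abs=1e-5)
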