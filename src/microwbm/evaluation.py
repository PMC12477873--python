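"""Validation experiments: calibration and method-correctness checks.

These routines bundle the package's standing QA experiments so they can be
run from the test suite or a report script:

* cohort odds ratios recomputed from published case/control counts,
* shadow-price contributions (``deltaZ = -pi * v_bio``) checked against
  the brute-force species-removal oracle over an ensemble of random toy
  communities,
* the abundance-pinning property of the joined models,
* type-I error calibration of the flux logistic regression under the null,
* bootstrap CI width against normal theory,
* cluster-search recovery of a planted two-species signal,
* end-to-end planted-effect recovery across seeded cohort replicates.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from . import contribution as ct
from . import stats as st
from . import synthetic as syn
from .fba import add_demand_reaction, remove_demand_reaction, solve_fba
from .pipeline import PipelineConfig, build_demo_model, run_pipeline

logger = logging.getLogger(__name__)

#: published case/control counts (yes_pd, no_pd, yes_ctrl, no_ctrl) for the
#: medication/lifestyle covariates of the study cohort (435 PD / 219 controls)
COHORT_2X2_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "laxatives": (131, 304, 23, 196),
    "mood_meds": (165, 270, 50, 169),
    "antihistamines": (70, 365, 70, 149),
    "sleep_aid": (175, 260, 58, 161),
    "pain_meds": (97, 338, 36, 183),
}


def table1_odds_ratios() -> dict[str, float]:
    """Fisher sample odds ratios recomputed from the published counts."""
    return {name: st.fisher_2x2(*cells).odds_ratio
            for name, cells in COHORT_2X2_COUNTS.items()}


# -- contribution oracle ensemble ---------------------------------------------


def oracle_ensemble(
    n_communities: int = 100,
    seed: int = 0,
    mets_per_community: int = 2,
    tol: float = 1e-5,
) -> pd.DataFrame:
    """Shadow-price contributions vs brute-force removal over random 3-6 species communities.

    Returns one row per (community, species, metabolite) pair with both
    contribution estimates, the agreement flag at ``tol``, the basis-change
    flag, and a sign comparison (magnitudes below ``tol`` count as zero).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_communities):
        n_species = int(rng.integers(3, 7))
        community_seed = int(rng.integers(0, 2**31 - 1))
        model, catalog = build_demo_model(n_species=n_species,
                                          strains_per_species=2,
                                          seed=community_seed)
        producers = sorted(syn.producers_by_metabolite(catalog))
        for met in producers[:mets_per_community]:
            df = ct.contribution_vs_oracle(model, met, tol=tol)
            df.insert(0, "community", i)
            df.insert(1, "metabolite", met)
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)

    def _sign(x):
        return np.where(np.abs(x) <= tol, 0, np.sign(x))

    out["sign_agree"] = np.where(
        out["feasible"],
        _sign(out["delta_z_formula"]) == _sign(out["delta_z_oracle"]), True)
    return out


def summarize_oracle(df: pd.DataFrame) -> dict[str, float]:
    feasible = df[df["feasible"]]
    exceptions = feasible[~feasible["agree"]]
    return {
        "n_pairs": int(len(feasible)),
        "agreement_pct": 100.0 * feasible["agree"].mean(),
        "sign_agreement_pct": 100.0 * feasible["sign_agree"].mean(),
        "exceptions_flagged_pct":
            100.0 * (exceptions["basis_change"].mean() if len(exceptions)
                     else 1.0),
        "infeasible_removals": int((~df["feasible"]).sum()),
    }


# -- abundance pinning ---------------------------------------------------------


def pinning_max_deviation(n_models: int = 10, seed: int = 0) -> float:
    """Max |v_biomass - abundance| over joined models (solver-precision fluxes)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_models):
        n_species = int(rng.integers(3, 7))
        model, catalog = build_demo_model(
            n_species=n_species, seed=int(rng.integers(0, 2**31 - 1)))
        met = sorted(syn.producers_by_metabolite(catalog))[0]
        rid = add_demand_reaction(model, met)
        sol = solve_fba(model, rid)
        remove_demand_reaction(model, rid)
        if not sol.optimal:
            continue
        for species, r in model.abundances.items():
            v = float(sol.raw_fluxes[f"pan{species}_biomass"])
            worst = max(worst, abs(v - r))
    return worst


# -- statistical calibration ----------------------------------------------------


def regression_type_i_error(n_reps: int = 500, n_per_group: int = 200,
                            seed: int = 0, alpha: float = 0.05) -> float:
    """Fraction of null replicates with flux-term p < alpha."""
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(n_reps):
        cfg = syn.SyntheticConfig(n_pd=n_per_group, n_ctrl=n_per_group,
                                  n_species=3,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        _, meta = syn.generate_abundance_cohort(cfg,
                                                syn.default_species_ids(3))
        flux = pd.Series(rng.normal(0, 1, len(meta)), index=meta.index)
        (res,) = st.flux_logistic_regression(flux, meta)
        if res.converged and res.p < alpha:
            hits += 1
    return hits / n_reps


def bootstrap_width_ratio(n: int = 200, seed: int = 0,
                          n_boot: int = 50_000) -> float:
    """Bootstrap CI width relative to the normal-theory width 2*1.96*sd/sqrt(n)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n)
    _, lo, hi = ct.bootstrap_mean_ci(x, n_boot=n_boot, rng=rng)
    return (hi - lo) / (2 * 1.96 * x.std(ddof=0) / np.sqrt(n))


# -- cluster search -------------------------------------------------------------


def cluster_pair_gain(seed: int = 0, n_samples: int = 150) -> dict[str, object]:
    """Recover a planted two-species signal; report the |rho| gain over singles."""
    rng = np.random.default_rng(seed)
    species = [f"sp{c}" for c in "ABCDE"]
    table = pd.DataFrame(rng.lognormal(0.0, 0.6, (5, n_samples)), index=species,
                         columns=[f"s{i}" for i in range(n_samples)])
    flux = table.loc["spA"] + table.loc["spB"]
    res = ct.search_microbe_clusters(species, table, flux)
    gain = abs(res.best_by_size[2][1]) - abs(res.best_by_size[1][1])
    return {"selected": res.selected_species, "rho": res.rho, "gain": gain}


# -- planted-effect recovery -----------------------------------------------------


def planted_effect_recovery(
    n_replicates: int = 20,
    n_per_group: int = 100,
    effect: float = 0.2,
    n_species: int = 8,
    n_boot: int = 50_000,
    base_seed: int = 0,
) -> dict[str, object]:
    """End-to-end recovery of an abundance effect planted on a sole producer.

    For each replicate seed, a fresh catalog/cohort is generated, the first
    sole-producer (species, metabolite) pair is the planted target, and
    recovery requires the metabolite at FDR < 0.1 *and* the planted species
    in its pruned contributor set.
    """
    recovered, details = 0, []
    for rep in range(n_replicates):
        rep_seed = base_seed + rep
        catalog = syn.generate_strain_catalog(n_species, 2, seed=rep_seed)
        pairs = syn.sole_producer_pairs(catalog)
        species, met = pairs[0]
        cfg = PipelineConfig(
            synthetic=syn.SyntheticConfig(
                n_pd=n_per_group, n_ctrl=n_per_group, n_species=n_species,
                strains_per_species=2, effect_map={species: effect},
                seed=rep_seed),
            n_boot=n_boot, seed=rep_seed)
        bundle = run_pipeline(cfg)
        hit = met in bundle.significant and species in bundle.pruned.get(met, [])
        recovered += hit
        details.append({"seed": rep_seed, "species": species, "metabolite": met,
                        "significant": met in bundle.significant,
                        "in_pruned": species in bundle.pruned.get(met, []),
                        "recovered": hit})
        logger.info("replicate %d: %s", rep, "recovered" if hit else "MISSED")
    return {"recovery_rate": recovered / n_replicates,
            "n_replicates": n_replicates,
            "details": pd.DataFrame(details)}
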