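"""Per-species contribution potentials, bootstrap ranking, cluster search.

The contribution potential of species *i* to a predicted blood flux Z is the
maximal change in Z when the species is removed from the community while all
other abundances stay fixed. Because the community-biomass excretion is
pinned, each species' biomass flux equals its relative abundance, and the
removal effect can be read off the FBA solution already at hand:

    deltaZ_i = -pi_biomass,i * v_biomass,i

where ``pi_biomass,i`` is the shadow price of the species' pan biomass
metabolite. This equals the brute-force removal result exactly whenever the
LP basis is stable over the whole removal range; :func:`contribution_vs_oracle`
compares both routes and flags basis changes.

Downstream, species are ranked by the magnitude of their bootstrapped mean
contribution, pruned to the smallest set covering 95% of the total, and
correlated (Spearman) with the predicted fluxes; an exhaustive subset search
over pairs..quintets finds the smallest combination whose summed abundances
best explain the flux.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .community import COMMUNITY_BIOMASS_RXN, HostMicrobiomeModel
from .fba import (
    FBASolution,
    SHADOW_PRICE_TOL,
    add_demand_reaction,
    extract_biomass_shadow_prices,
    remove_demand_reaction,
    solve_fba,
    species_biomass_metabolites,
    species_biomass_reactions,
)
from .model import ModelError, Reconstruction

__all__ = [
    "ContributionRecord",
    "ClusterResult",
    "contribution_potentials",
    "brute_force_contribution",
    "contribution_vs_oracle",
    "bootstrap_mean_ci",
    "prune_to_cumulative",
    "correlate_species_flux",
    "search_microbe_clusters",
]

logger = logging.getLogger(__name__)

_ORACLE_TOL = 1e-5
_VBIO_ABUNDANCE_TOL = 1e-5


@dataclass
class ContributionRecord:
    species: str
    shadow_price: float
    biomass_flux: float
    delta_z: float
    sample: str | None = None
    metabolite: str | None = None


def contribution_potentials(
    solution: FBASolution,
    model: Reconstruction,
    abundances: Mapping[str, float] | None = None,
    sample: str | None = None,
    metabolite: str | None = None,
) -> list[ContributionRecord]:
    """One record per species: deltaZ = -pi * v_biomass.

    ``v_biomass`` is read from the solution's biomass reaction flux; when
    abundances are supplied, agreement with the pinned value is asserted.
    """
    if not solution.optimal:
        raise ValueError("contributions require an optimal solution")
    prices = extract_biomass_shadow_prices(solution, model)
    bio_rxns = species_biomass_reactions(model)
    flux_src = solution.raw_fluxes if solution.raw_fluxes is not None \
        else solution.fluxes
    records = []
    for species, pi in prices.items():
        rxn_id = bio_rxns[species]
        if rxn_id not in flux_src.index:
            raise ModelError(f"solution lacks biomass flux for {species}")
        v_bio = float(flux_src.loc[rxn_id])
        if abundances is not None:
            r = abundances[species]
            if abs(v_bio - r) > _VBIO_ABUNDANCE_TOL:
                raise AssertionError(
                    f"{species}: biomass flux {v_bio} != abundance {r}")
        records.append(ContributionRecord(
            species=species, shadow_price=pi, biomass_flux=v_bio,
            delta_z=-pi * v_bio, sample=sample, metabolite=metabolite))
    return records


def brute_force_contribution(
    model: HostMicrobiomeModel,
    species: str,
    metabolite: str,
    compartment: str = "[bc]",
    full_solution: FBASolution | None = None,
) -> tuple[float | None, FBASolution | None]:
    """Removal oracle: deltaZ = Z(full) - Z(species removed).

    Removal pins the species' biomass flux to zero and supplies its biomass
    metabolite externally (steady-state rhs shift of -v_biomass), so the
    community-biomass reaction stays satisfiable while flux coupling closes
    every reaction of the species. Returns (None, None) when the reduced
    model is infeasible (the species is an obligate cross-feeding source).
    """
    bio_met = species_biomass_metabolites(model)[species]
    bio_rxn = species_biomass_reactions(model)[species]
    # the exact pinned biomass flux is the communityBiomass coefficient;
    # the solution's flux is rounded and would make the equality infeasible
    if model.has_reaction(COMMUNITY_BIOMASS_RXN):
        v_pin = -float(model.reaction(COMMUNITY_BIOMASS_RXN).stoich[bio_met])
    else:
        v_pin = None
    dm = add_demand_reaction(model, metabolite, compartment)
    try:
        if full_solution is None:
            full_solution = solve_fba(model, dm)
        if not full_solution.optimal:
            raise ModelError(f"full model not optimal for {metabolite}")
        if v_pin is None:
            v_pin = float(full_solution.fluxes.loc[bio_rxn])
        reduced = solve_fba(
            model, dm,
            b_eq_shift={bio_met: -v_pin},
            bound_overrides={bio_rxn: (0.0, 0.0)},
        )
    finally:
        remove_demand_reaction(model, dm)
    if not reduced.optimal:
        logger.warning("removal of %s infeasible for %s", species, metabolite)
        return None, None
    z_full = float(full_solution.raw_fluxes.loc[dm])
    z_red = float(reduced.raw_fluxes.loc[dm])
    return z_full - z_red, reduced


def contribution_vs_oracle(
    model: HostMicrobiomeModel,
    metabolite: str,
    compartment: str = "[bc]",
    tol: float = _ORACLE_TOL,
) -> pd.DataFrame:
    """Compare shadow-price contributions against the removal oracle.

    Returns one row per species with both estimates, the mismatch, and a
    ``basis_change`` flag. The flag is raised independently of the mismatch
    by two witnesses of a basis change over the removal range: the optimal
    value at half removal deviating from the chord midpoint (the LP value is
    concave and piecewise linear in the rhs, so linearity over the range is
    equivalent to the midpoint lying on the chord), or the biomass dual
    changing between the full and the reduced solve.
    """
    dm = add_demand_reaction(model, metabolite, compartment)
    try:
        full = solve_fba(model, dm)
        if not full.optimal:
            raise ModelError(f"model infeasible for demand on {metabolite}")
        records = contribution_potentials(full, model, abundances=model.abundances)
    finally:
        remove_demand_reaction(model, dm)

    bio_mets = species_biomass_metabolites(model)
    rows = []
    for rec in records:
        bio_met = bio_mets[rec.species]
        oracle, reduced = brute_force_contribution(
            model, rec.species, metabolite, compartment, full_solution=full)
        row = {
            "species": rec.species,
            "delta_z_formula": rec.delta_z,
            "delta_z_oracle": oracle,
            "feasible": oracle is not None,
        }
        if oracle is None:
            row.update(mismatch=np.nan, agree=False, basis_change=True)
            rows.append(row)
            continue
        dm2 = add_demand_reaction(model, metabolite, compartment)
        try:
            mid = solve_fba(model, dm2,
                            b_eq_shift={bio_met: -rec.biomass_flux / 2})
        finally:
            remove_demand_reaction(model, dm2)
        z_full = float(full.raw_fluxes.loc[dm2])
        z_red = z_full - oracle
        z_mid = (float(mid.raw_fluxes.loc[dm2]) if mid.optimal else np.nan)
        nonlinear = (not mid.optimal or
                     abs(z_mid - (z_full + z_red) / 2) > tol)
        dual_changed = (not reduced.optimal or
                        abs(float(reduced.shadow_prices.loc[bio_met]) -
                            rec.shadow_price) > SHADOW_PRICE_TOL)
        row.update(
            mismatch=abs(rec.delta_z - oracle),
            agree=abs(rec.delta_z - oracle) <= tol,
            basis_change=bool(nonlinear or dual_changed),
        )
        rows.append(row)
    return pd.DataFrame(rows)


# -- bootstrap ranking -------------------------------------------------------


def _bootstrap_weights(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Resampling-with-replacement counts, one row per bootstrap replicate."""
    return rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)


def bootstrap_mean_ci(
    values: Sequence[float] | np.ndarray,
    n_boot: int = 50_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    weights: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Bootstrapped mean and percentile 2.5/97.5 CI (with replacement).

    Pass precomputed ``weights`` (from :func:`_bootstrap_weights`) to share
    one resampling across many vectors of the same length.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if weights is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        weights = _bootstrap_weights(v.size, n_boot, rng)
    boot_means = weights @ v / v.size
    return (float(boot_means.mean()),
            float(np.percentile(boot_means, 2.5)),
            float(np.percentile(boot_means, 97.5)))


def prune_to_cumulative(
    species_mean_contributions: Mapping[str, float], frac: float = 0.95
) -> list[str]:
    """Smallest prefix of |mean deltaZ|-ranked species covering ``frac``.

    Ranking uses magnitudes (consumers are influential through negative
    contributions); ties break lexicographically by species ID. All-zero
    contributions yield an empty list.
    """
    mags = {sp: abs(v) for sp, v in species_mean_contributions.items()}
    total = sum(mags.values())
    if total == 0:
        return []
    ordered = sorted(mags, key=lambda sp: (-mags[sp], sp))
    out, cum = [], 0.0
    for sp in ordered:
        out.append(sp)
        cum += mags[sp]
        if cum >= frac * total - 1e-12:
            break
    return out


# -- correlation and cluster search ------------------------------------------


def correlate_species_flux(
    abundance: Sequence[float] | pd.Series, flux: Sequence[float] | pd.Series
) -> tuple[float, float]:
    """Spearman rho and two-sided p; missing flux cells dropped pairwise.

    Returns (nan, nan) when either vector is constant after pairwise deletion.
    """
    a = np.asarray(abundance, dtype=float)
    f = np.asarray(flux, dtype=float)
    if a.shape != f.shape:
        raise ValueError("abundance and flux must have equal length")
    mask = ~(np.isnan(a) | np.isnan(f))
    a, f = a[mask], f[mask]
    if a.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(f) == 0:
        logger.warning("zero variance: Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(a, f)
    return float(rho), float(p)


@dataclass
class ClusterResult:
    """Best species combination explaining one metabolite's flux."""

    selected_species: tuple[str, ...]
    rho: float
    best_by_size: dict[int, tuple[tuple[str, ...], float]] = field(
        default_factory=dict)
    metabolite: str | None = None

    @property
    def size(self) -> int:
        return len(self.selected_species)


def search_microbe_clusters(
    pruned_species: Sequence[str],
    abundance_table: pd.DataFrame,
    flux_vector: pd.Series,
    max_k: int = 5,
    delta: float = 0.05,
    max_subsets: int = 500_000,
    metabolite: str | None = None,
) -> ClusterResult:
    """Exhaustive search over size-1..max_k species subsets.

    For each size k, the Spearman |rho| of the subset's summed abundances
    against the flux is evaluated over all C(n, k) subsets; the reported
    combination is the best subset of the largest k whose best |rho| exceeds
    the best |rho| of *every* smaller size by more than ``delta``. Ties at
    equal |rho| resolve to the lexicographically first subset.
    """
    species = sorted(set(pruned_species))
    if not species:
        raise ValueError("pruned_species must be non-empty")
    missing = [s for s in species if s not in abundance_table.index]
    if missing:
        raise ValueError(f"species missing from abundance table: {missing}")
    samples = flux_vector.dropna().index
    A = abundance_table.loc[species, samples].to_numpy(dtype=float)
    f = flux_vector.loc[samples].to_numpy(dtype=float)
    if f.size < 3:
        raise ValueError("need at least 3 samples with predicted fluxes")

    max_k = min(max_k, len(species))
    from math import comb
    budget = sum(comb(len(species), k) for k in range(1, max_k + 1))
    if budget > max_subsets:
        raise ValueError(
            f"{budget} candidate subsets exceed the cap of {max_subsets}; "
            "prune the species set more tightly")

    f_rank = sps.rankdata(f)
    best_by_size: dict[int, tuple[tuple[str, ...], float]] = {}
    for k in range(1, max_k + 1):
        best_subset: tuple[int, ...] | None = None
        best_abs = -1.0
        best_rho = np.nan
        for subset in itertools.combinations(range(len(species)), k):
            summed = A[list(subset)].sum(axis=0)
            if np.ptp(summed) == 0:
                continue
            rho = float(np.corrcoef(sps.rankdata(summed), f_rank)[0, 1])
            if abs(rho) > best_abs + 1e-15:
                best_abs, best_rho, best_subset = abs(rho), rho, subset
        if best_subset is not None:
            best_by_size[k] = (tuple(species[i] for i in best_subset), best_rho)

    selected_k = 1
    for k in sorted(best_by_size):
        if k == 1:
            continue
        if all(abs(best_by_size[k][1]) > abs(best_by_size[j][1]) + delta
               for j in best_by_size if j < k):
            selected_k = k
    subset, rho = best_by_size[selected_k]
    return ClusterResult(selected_species=subset, rho=rho,
                         best_by_size=best_by_size, metabolite=metabolite)
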