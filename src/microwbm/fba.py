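"""Flux balance analysis: LP formulation, demand reactions, shadow prices.

FBA maximizes the flux through an objective reaction subject to steady-state
mass balance ``S v = 0`` and flux bounds ``lb <= v <= ub``; flux-coupling
declarations on the model are expanded into inequality rows
``|v_j| <= factor * v_biomass`` so that no reaction of a species can carry
flux unless the species grows.

Shadow prices follow the convention ``pi_i = -dZ/db_i`` where ``b_i`` is the
right-hand side of metabolite *i*'s steady-state row (``S v = b``, surplus-
production sense). Under this convention the biomass metabolite of a species
that limits the objective has a *negative* shadow price, and the species'
contribution potential is ``-pi * v_biomass`` (see :mod:`microwbm.contribution`).
scipy's HiGHS interface solves the minimization form, whose equality marginals
are exactly this ``pi``; the mapping is pinned by a finite-difference unit test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .model import ModelError, Reaction, Reconstruction, compartment_of

__all__ = [
    "FBASolution",
    "FluxMatrix",
    "SolverError",
    "add_demand_reaction",
    "remove_demand_reaction",
    "solve_fba",
    "extract_biomass_shadow_prices",
    "is_microbiome_influenced",
    "predict_blood_fluxes",
    "species_biomass_metabolites",
    "SHADOW_PRICE_TOL",
    "DEMAND_UB",
]

logger = logging.getLogger(__name__)

#: shadow prices with magnitude below this are reported as exactly zero
SHADOW_PRICE_TOL = 1e-6

#: demand reactions are effectively unconstrained sinks
DEMAND_UB = 1e6

_ROUND_DECIMALS = 6


class SolverError(RuntimeError):
    """LP solver failed for a numerical (non-infeasibility) reason."""


@dataclass
class FBASolution:
    """Optimal value, fluxes (6-decimal rounded) and steady-state duals."""

    status: str  # optimal | infeasible | unbounded
    objective_rxn: str
    objective_value: float | None = None
    fluxes: pd.Series | None = None
    shadow_prices: pd.Series | None = None
    #: solver-precision fluxes, used by sensitivity computations where the
    #: 6-decimal reporting round-off would contaminate products with duals
    raw_fluxes: pd.Series | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# -- demand reactions ------------------------------------------------------


def demand_reaction_id(metabolite: str, compartment: str = "[bc]") -> str:
    return f"DM_{metabolite}{compartment}"


def add_demand_reaction(
    model: Reconstruction, metabolite: str, compartment: str = "[bc]"
) -> str:
    """Add an unbalanced sink ``DM_<met><comp>: 1 met -> (nothing)``.

    Returns the new reaction ID. The metabolite must already exist in the
    compartment; adding the same demand twice is an error and leaves the
    model unchanged.
    """
    met_id = f"{metabolite}{compartment}"
    rxn_id = demand_reaction_id(metabolite, compartment)
    if not model.has_metabolite(met_id):
        raise ModelError(f"model {model.id}: no metabolite {met_id!r} for demand")
    if model.has_reaction(rxn_id):
        raise ModelError(f"model {model.id}: demand {rxn_id!r} already present")
    model.add_reaction(Reaction(id=rxn_id, stoich={met_id: -1.0}, lb=0.0, ub=DEMAND_UB))
    return rxn_id


def remove_demand_reaction(model: Reconstruction, rxn_id: str) -> None:
    if not rxn_id.startswith("DM_"):
        raise ModelError(f"{rxn_id!r} is not a demand reaction")
    model.remove_reaction(rxn_id, prune_metabolites=False)


# -- LP solve --------------------------------------------------------------


def _coupling_rows(model: Reconstruction):
    """Expand coupling declarations into sparse A_ub rows (rhs = 0).

    Each coupling {rxn j, biomass_rxn m, factor f} yields v_j - f*v_m <= 0,
    plus -v_j - f*v_m <= 0 when j is reversible (lb < 0).
    """
    rows, cols, vals = [], [], []
    nrow = 0
    for cpl in model.couplings:
        j = model._rxn_index[cpl["rxn"]]
        m = model._rxn_index[cpl["biomass_rxn"]]
        f = float(cpl["factor"])
        rows += [nrow, nrow]
        cols += [j, m]
        vals += [1.0, -f]
        nrow += 1
        if model.reactions[j].reversible:
            rows += [nrow, nrow]
            cols += [j, m]
            vals += [-1.0, -f]
            nrow += 1
    return rows, cols, vals, nrow


def n_coupling_rows(model: Reconstruction) -> int:
    """Number of inequality rows the coupling declarations expand into."""
    return _coupling_rows(model)[3]


def solve_fba(
    model: Reconstruction,
    objective_rxn: str,
    sense: str = "max",
    b_eq_shift: Mapping[str, float] | None = None,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FBASolution:
    """Solve the FBA linear program for one objective reaction.

    ``b_eq_shift`` relaxes selected steady-state rows to ``S_i v = b_i``
    (surplus-production sense; negative values model external supply) and is
    used for sensitivity analyses and the species-removal oracle.
    ``bound_overrides`` maps reaction IDs to temporary (lb, ub) pairs without
    mutating the model.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    obj = model.reaction(objective_rxn)  # raises if absent

    n = len(model.reactions)
    m = len(model.metabolites)
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoich.items():
            rows.append(model._met_index[met])
            cols.append(j)
            vals.append(coef)
    A_eq = sparse.csr_matrix((vals, (rows, cols)), shape=(m, n))
    b_eq = np.zeros(m)
    if b_eq_shift:
        for met, b in b_eq_shift.items():
            b_eq[model.metabolite_index(met)] = b

    bounds = [(r.lb, r.ub) for r in model.reactions]
    if bound_overrides:
        for rxn_id, pair in bound_overrides.items():
            bounds[model._rxn_index[rxn_id]] = pair

    crows, ccols, cvals, nrow = _coupling_rows(model)
    A_ub = b_ub = None
    if nrow:
        A_ub = sparse.csr_matrix((cvals, (crows, ccols)), shape=(nrow, n))
        b_ub = np.zeros(nrow)

    c = np.zeros(n)
    c[model._rxn_index[objective_rxn]] = -1.0 if sense == "max" else 1.0

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                  method="highs")
    if res.status == 2:
        return FBASolution(status="infeasible", objective_rxn=objective_rxn)
    if res.status == 3:
        return FBASolution(status="unbounded", objective_rxn=objective_rxn)
    if res.status != 0:
        raise SolverError(f"LP for {objective_rxn} failed: {res.message}")

    rxn_ids = [r.id for r in model.reactions]
    raw = pd.Series(res.x, index=rxn_ids)
    fluxes = pd.Series(np.round(res.x, _ROUND_DECIMALS), index=rxn_ids)
    # HiGHS equality marginals d(min objective)/db; for the max problem
    # (min -Z) this is -dZ/db, i.e. the pi convention; for sense="min" flip.
    marg = np.asarray(res.eqlin.marginals, dtype=float)
    pi = marg if sense == "max" else -marg
    shadow = pd.Series(pi, index=list(model.metabolites))
    z = float(fluxes.loc[objective_rxn])
    return FBASolution(
        status="optimal",
        objective_rxn=objective_rxn,
        objective_value=z,
        fluxes=fluxes,
        shadow_prices=shadow,
        raw_fluxes=raw,
    )


# -- shadow-price extraction ----------------------------------------------


def species_biomass_metabolites(model: Reconstruction) -> dict[str, str]:
    """Map each species tag to the metabolite its biomass reaction produces."""
    out: dict[str, str] = {}
    for rxn in model.reactions:
        if rxn.is_biomass and rxn.species is not None:
            produced = [met for met, coef in rxn.stoich.items() if coef > 0]
            if len(produced) != 1:
                raise ModelError(
                    f"biomass reaction {rxn.id} must produce exactly one metabolite"
                )
            out[rxn.species] = produced[0]
    return out


def species_biomass_reactions(model: Reconstruction) -> dict[str, str]:
    return {
        r.species: r.id
        for r in model.reactions
        if r.is_biomass and r.species is not None
    }


def extract_biomass_shadow_prices(
    solution: FBASolution, model: Reconstruction, tol: float = SHADOW_PRICE_TOL
) -> dict[str, float]:
    """Per-species shadow price of the pan biomass metabolite.

    Values with magnitude below ``tol`` are reported as exactly zero.
    """
    if not solution.optimal:
        raise ValueError("shadow prices require an optimal solution")
    out: dict[str, float] = {}
    for species, met in species_biomass_metabolites(model).items():
        pi = float(solution.shadow_prices.loc[met])
        out[species] = 0.0 if abs(pi) < tol else pi
    return out


def is_microbiome_influenced(
    solution: FBASolution, model: Reconstruction, tol: float = SHADOW_PRICE_TOL
) -> bool:
    """True iff any species' biomass shadow price is nonzero after tolerance."""
    prices = extract_biomass_shadow_prices(solution, model, tol=tol)
    return any(pi != 0.0 for pi in prices.values())


# -- batch prediction ------------------------------------------------------


@dataclass
class FluxMatrix:
    """Samples x metabolites maximal blood fluxes with influence flags.

    ``fluxes`` holds NaN where the per-cell LP failed (missing, not zero);
    ``influenced`` is the per-cell microbiome-influence flag; ``solutions``
    retains the full FBA solution per (sample, metabolite) so downstream
    contribution analysis does not re-solve.
    """

    fluxes: pd.DataFrame
    influenced: pd.DataFrame
    solutions: dict[tuple[str, str], FBASolution] = field(default_factory=dict)


def predict_blood_fluxes(
    models_by_sample: Mapping[str, Reconstruction],
    metabolites: Sequence[str],
    compartment: str = "[bc]",
    keep_solutions: bool = True,
) -> FluxMatrix:
    """One FBA per (sample, metabolite): add demand, maximize, remove demand."""
    samples = list(models_by_sample)
    fluxes = pd.DataFrame(np.nan, index=samples, columns=list(metabolites))
    influenced = pd.DataFrame(False, index=samples, columns=list(metabolites))
    solutions: dict[tuple[str, str], FBASolution] = {}
    for sample, model in models_by_sample.items():
        for met in metabolites:
            try:
                rxn_id = add_demand_reaction(model, met, compartment)
            except ModelError:
                logger.warning("sample %s: no %s%s in blood; cell left missing",
                               sample, met, compartment)
                continue
            try:
                sol = solve_fba(model, rxn_id, sense="max")
            except SolverError as exc:
                logger.warning("sample %s metabolite %s: %s", sample, met, exc)
                continue
            finally:
                remove_demand_reaction(model, rxn_id)
            if not sol.optimal:
                logger.warning("sample %s metabolite %s: %s", sample, met, sol.status)
                continue
            fluxes.loc[sample, met] = sol.objective_value
            influenced.loc[sample, met] = is_microbiome_influenced(sol, model)
            if keep_solutions:
                solutions[(sample, met)] = sol
    return FluxMatrix(fluxes=fluxes, influenced=influenced, solutions=solutions)
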