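"""Pan-species models, community assembly, host join, coupling and diet.

The construction mirrors the standard community-modeling recipe for
host-microbiome co-metabolism:

1. strain reconstructions of one species are merged into a *pan-species*
   model (union of reactions/metabolites, widest bounds);
2. pan models are connected through a shared microbiota lumen ``[luM]`` and
   a ``communityBiomass`` reaction that consumes each species' biomass
   metabolite with its relative abundance as the (negative) stoichiometric
   coefficient;
3. every non-biomass reaction of a species is flux-coupled to that species'
   biomass reaction (``|v| <= factor * v_biomass``, factor 400 by default);
4. the community is joined to the host's large-intestine lumen ``[luLI]``,
   the excretion of the community biomass compound is pinned to
   [1, 1] mmol/day/person -- which forces every species' biomass flux to
   equal its relative abundance -- and the whole-body objective reaction is
   pinned to [1, 1];
5. the diet sets uptake bounds on the host's diet exchange reactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import ModelError, Reaction, Reconstruction, compartment_of
from .synthetic import DietSpec

__all__ = [
    "CommunityModel",
    "HostMicrobiomeModel",
    "build_pan_species",
    "assemble_community",
    "add_coupling_constraints",
    "join_host",
    "apply_diet",
    "pan_biomass_reaction_id",
    "pan_biomass_metabolite_id",
    "COMMUNITY_BIOMASS_RXN",
    "MICROBIOTA_BIOMASS_MET",
    "EXCRETION_RXN",
    "WHOLE_BODY_OBJECTIVE_RXN",
    "DEFAULT_COUPLING_FACTOR",
]

logger = logging.getLogger(__name__)

COMMUNITY_BIOMASS_RXN = "communityBiomass"
MICROBIOTA_BIOMASS_MET = "microbiota_LI_biomass"
EXCRETION_RXN = "Excretion_EX_microbiota_LI_biomass[fe]"
WHOLE_BODY_OBJECTIVE_RXN = "Whole_body_objective_rxn"
DEFAULT_COUPLING_FACTOR = 400.0

_ABUNDANCE_SUM_TOL = 1e-9


@dataclass
class CommunityModel(Reconstruction):
    """Multi-species model with a shared lumen and relative abundances."""

    abundances: dict[str, float] = field(default_factory=dict)


@dataclass
class HostMicrobiomeModel(Reconstruction):
    """Host + community model with pinned excretion and whole-body objective."""

    abundances: dict[str, float] = field(default_factory=dict)


def pan_biomass_reaction_id(species: str) -> str:
    return f"pan{species}_biomass"


def pan_biomass_metabolite_id(species: str) -> str:
    return f"pan{species}_biomass[c]"


# -- pan-species construction ------------------------------------------------


def build_pan_species(
    strain_models: Sequence[Reconstruction], species_id: str
) -> Reconstruction:
    """Union of the strains' reactions and metabolites for one species.

    Reactions present in several strains must agree in stoichiometry; their
    bounds are merged to the widest interval. The strains' biomass reactions
    are merged into a single ``pan<Species>_biomass`` reaction producing the
    ``pan<Species>_biomass[c]`` metabolite.
    """
    if not strain_models:
        raise ModelError("cannot build a pan model from zero strains")
    for m in strain_models:
        tags = set(m.species_tags())
        if tags and tags != {species_id}:
            raise ModelError(f"strain {m.id} is not tagged with species {species_id}")

    pan = Reconstruction(id=f"pan{species_id}")
    bio_rxn_id = pan_biomass_reaction_id(species_id)
    bio_met_id = pan_biomass_metabolite_id(species_id)
    biomass_stoich: dict[str, float] | None = None
    biomass_bounds: tuple[float, float] | None = None

    for strain in strain_models:
        n_bio = len(strain.biomass_reactions())
        if n_bio != 1:
            raise ModelError(f"strain {strain.id} has {n_bio} biomass reactions")
        for rxn in strain.reactions:
            if rxn.is_biomass:
                # normalize the produced biomass metabolite to the pan ID
                stoich = {
                    (bio_met_id if coef > 0 else met): coef
                    for met, coef in rxn.stoich.items()
                }
                if biomass_stoich is None:
                    biomass_stoich = stoich
                    biomass_bounds = (rxn.lb, rxn.ub)
                elif stoich != biomass_stoich:
                    raise ModelError(
                        f"species {species_id}: strains disagree on biomass "
                        "stoichiometry")
                else:
                    biomass_bounds = (min(biomass_bounds[0], rxn.lb),
                                      max(biomass_bounds[1], rxn.ub))
                continue
            if pan.has_reaction(rxn.id):
                existing = pan.reaction(rxn.id)
                if existing.stoich != rxn.stoich:
                    raise ModelError(
                        f"species {species_id}: conflicting stoichiometry for "
                        f"reaction {rxn.id}")
                existing.lb = min(existing.lb, rxn.lb)  # widest interval
                existing.ub = max(existing.ub, rxn.ub)
            else:
                pan.add_reaction(Reaction(rxn.id, dict(rxn.stoich), rxn.lb, rxn.ub,
                                          species=species_id))
    pan.add_reaction(Reaction(bio_rxn_id, biomass_stoich, *biomass_bounds,
                              species=species_id, is_biomass=True))
    pan.validate()
    return pan


# -- community assembly ------------------------------------------------------


def _species_prefixed(met: str, species: str) -> str:
    """Internal [c] metabolites are namespaced per species; lumen is shared."""
    comp = compartment_of(met)
    if comp == "luM" or met.startswith("pan"):
        return met
    return f"{species}__{met}"


def assemble_community(
    pan_models: Mapping[str, Reconstruction] | Sequence[Reconstruction],
    abundances: Mapping[str, float],
) -> CommunityModel:
    """Connect pan models through a shared lumen and add ``communityBiomass``.

    ``abundances`` must cover exactly the pan models' species and sum to one;
    zero or negative abundances are rejected (exclude absent species before
    assembly). Species-internal metabolites and reactions are namespaced per
    species; boundary exchanges on the shared lumen are deduplicated into
    community-level exchanges.
    """
    if not isinstance(pan_models, Mapping):
        pan_models = {m.species_tags()[0]: m for m in pan_models}
    if set(pan_models) != set(abundances):
        raise ModelError(
            f"abundances must cover exactly the pan species: "
            f"{sorted(set(pan_models) ^ set(abundances))} mismatched")
    for sp, r in abundances.items():
        if r <= 0:
            raise ModelError(
                f"species {sp} has non-positive abundance {r}; exclude absent "
                "species upstream")
    total = sum(abundances.values())
    if abs(total - 1.0) > _ABUNDANCE_SUM_TOL:
        raise ModelError(f"abundances sum to {total}, expected 1")

    community = CommunityModel(id="community", abundances=dict(abundances))
    lumen_exchanges: dict[str, None] = {}
    for species, pan in pan_models.items():
        for rxn in pan.reactions:
            if rxn.id.startswith("EX_") and all(
                    compartment_of(m) == "luM" for m in rxn.stoich):
                for met in rxn.stoich:
                    lumen_exchanges.setdefault(met, None)
                continue
            stoich = {_species_prefixed(met, species): coef
                      for met, coef in rxn.stoich.items()}
            rxn_id = rxn.id if rxn.id.startswith("pan") else f"{species}__{rxn.id}"
            community.add_reaction(Reaction(rxn_id, stoich, rxn.lb, rxn.ub,
                                            species=species,
                                            is_biomass=rxn.is_biomass))
    for met in lumen_exchanges:
        community.add_reaction(Reaction(f"EX_{met}", {met: -1.0}, -1e6, 1e6))

    stoich = {pan_biomass_metabolite_id(sp): -float(r)
              for sp, r in abundances.items()}
    stoich[f"{MICROBIOTA_BIOMASS_MET}[luM]"] = 1.0
    community.add_reaction(Reaction(COMMUNITY_BIOMASS_RXN, stoich, 0.0, 1e6))
    community.add_reaction(Reaction(f"EX_{MICROBIOTA_BIOMASS_MET}[luM]",
                                    {f"{MICROBIOTA_BIOMASS_MET}[luM]": -1.0},
                                    0.0, 1e6))
    community.validate()
    return community


# -- coupling ---------------------------------------------------------------


def add_coupling_constraints(
    model: CommunityModel, coupling_factor: float = DEFAULT_COUPLING_FACTOR
) -> CommunityModel:
    """Couple every non-biomass reaction of each species to its biomass flux.

    Records one coupling declaration per reaction; the LP layer expands each
    into ``v_j - f*v_bio <= 0`` plus, for reversible reactions,
    ``-v_j - f*v_bio <= 0``.
    """
    biomass_by_species = {
        r.species: r.id for r in model.reactions if r.is_biomass and r.species}
    model.couplings = []
    for rxn in model.reactions:
        if rxn.species is None or rxn.is_biomass:
            continue
        if rxn.species not in biomass_by_species:
            raise ModelError(f"species {rxn.species} has no biomass reaction")
        model.couplings.append({
            "rxn": rxn.id,
            "biomass_rxn": biomass_by_species[rxn.species],
            "factor": float(coupling_factor),
        })
    logger.debug("added %d coupling declarations", len(model.couplings))
    return model


# -- host join ----------------------------------------------------------------


def join_host(host: Reconstruction, community: CommunityModel) -> HostMicrobiomeModel:
    """Join a coupled community to the host's large-intestine lumen.

    The community lumen is merged with the host LI lumen via reversible
    transport reactions; lumen metabolites the host does not know get an
    absorption route to blood and a fecal route so they behave like any other
    lumenal compound. The community-biomass excretion is pinned to [1, 1],
    which pins every species' biomass flux to its relative abundance, and the
    whole-body objective reaction is pinned to [1, 1]. Host-only reaction
    bounds are otherwise untouched.
    """
    if not any(compartment_of(m) == "luLI" for m in host.metabolites):
        raise ModelError(f"host {host.id} lacks a large-intestine lumen [luLI]")
    if not host.has_reaction(WHOLE_BODY_OBJECTIVE_RXN):
        raise ModelError(f"host {host.id} lacks {WHOLE_BODY_OBJECTIVE_RXN}")

    joined = HostMicrobiomeModel(id=f"{host.id}__microbiome",
                                 abundances=dict(community.abundances))
    for rxn in host.reactions:
        joined.add_reaction(Reaction(rxn.id, dict(rxn.stoich), rxn.lb, rxn.ub,
                                     species=rxn.species, is_biomass=rxn.is_biomass))
    for rxn in community.reactions:
        if rxn.id.startswith("EX_"):  # community boundary opens at the host now
            continue
        joined.add_reaction(Reaction(rxn.id, dict(rxn.stoich), rxn.lb, rxn.ub,
                                     species=rxn.species, is_biomass=rxn.is_biomass))
    joined.couplings = [dict(c) for c in community.couplings]

    # merge lumens: transports [luM] <-> [luLI] for every community lumen met
    for met in community.metabolites_in("luM"):
        base = met[: met.rindex("[")]
        if base == MICROBIOTA_BIOMASS_MET:
            continue
        host_met = f"{base}[luLI]"
        joined.add_reaction(Reaction(f"T_LI_{base}", {met: -1.0, host_met: 1.0},
                                     -1e6, 1e6))
        if not host.has_metabolite(host_met):
            # microbial compound unknown to the host template: give it the
            # standard lumenal fate (absorption to blood, fecal excretion)
            joined.add_reaction(Reaction(f"T_abs_{base}",
                                         {host_met: -1.0, f"{base}[bc]": 1.0},
                                         0.0, 1e6))
            joined.add_reaction(Reaction(f"T_fe_{base}",
                                         {host_met: -1.0, f"{base}[fe]": 1.0},
                                         0.0, 1e6))
            joined.add_reaction(Reaction(f"EX_{base}[fe]", {f"{base}[fe]": -1.0},
                                         0.0, 1e6))

    # community biomass is excreted in feces at exactly 1 mmol/day/person
    joined.add_reaction(Reaction(
        f"T_fe_{MICROBIOTA_BIOMASS_MET}",
        {f"{MICROBIOTA_BIOMASS_MET}[luM]": -1.0, f"{MICROBIOTA_BIOMASS_MET}[fe]": 1.0},
        0.0, 1e6))
    joined.add_reaction(Reaction(
        EXCRETION_RXN, {f"{MICROBIOTA_BIOMASS_MET}[fe]": -1.0}, 1.0, 1.0))

    wbo = joined.reaction(WHOLE_BODY_OBJECTIVE_RXN)
    wbo.lb, wbo.ub = 1.0, 1.0
    joined.validate()
    return joined


# -- diet ---------------------------------------------------------------------


def apply_diet(
    model: HostMicrobiomeModel, diet: DietSpec, flexibility: float = 1.0
) -> HostMicrobiomeModel:
    """Constrain diet exchanges to the dietary intakes (uptake-negative).

    Diet-matched exchanges get ``lb = -flexibility * intake``; every other
    exchange uptake is closed (lb = 0); secretion stays unrestricted. Diet
    entries without a matching exchange reaction are logged and skipped.
    """
    matched: set[str] = set()
    for rxn in model.reactions:
        if rxn.id.startswith("Diet_EX_"):
            base = rxn.id[len("Diet_EX_"):]
            base = base[: base.rindex("[")]
            if base in diet.entries:
                rxn.lb = -flexibility * diet.entries[base]
                matched.add(base)
            else:
                rxn.lb = 0.0
        elif rxn.id.startswith("EX_") and rxn.lb < 0:
            rxn.lb = 0.0  # no uptake outside the diet
    for met in diet.entries:
        if met not in matched:
            logger.warning("diet entry %s has no diet exchange reaction; skipped",
                           met)
    return model
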