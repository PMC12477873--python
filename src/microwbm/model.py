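"""Stoichiometric model container and JSON serialization.

A :class:`Reconstruction` holds the constraint-based representation used
throughout the package: metabolites with compartment tags (``glc[luM]``,
``leu_L[bc]`` ...), reactions with sparse stoichiometry and flux bounds in
mmol/day/person, optional per-reaction species tags (community models), and
optional flux-coupling declarations tying a reaction's flux magnitude to a
multiple of its species' biomass flux.

The on-disk format is a small JSON dialect::

    {
      "id": ...,
      "compartments": [...],
      "metabolites": [{"id": "glc[luM]", "compartment": "luM"}, ...],
      "reactions": [{"id": ..., "stoich": {met: coef, ...}, "lb": ..,
                     "ub": .., "species": .. (optional), "is_biomass": bool}, ...],
      "couplings": [{"rxn": .., "biomass_rxn": .., "factor": ..}, ...]
    }
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Reaction",
    "Reconstruction",
    "ModelError",
    "read_model_json",
    "write_model_json",
    "compartment_of",
]

_COMPARTMENT_RE = re.compile(r"\[([^\[\]]+)\]$")


class ModelError(ValueError):
    """Raised for structurally invalid models or invalid model edits."""


def compartment_of(metabolite_id: str) -> str:
    """Return the compartment tag of a metabolite ID like ``glc[luM]``."""
    m = _COMPARTMENT_RE.search(metabolite_id)
    if not m:
        raise ModelError(f"metabolite ID {metabolite_id!r} lacks a [compartment] tag")
    return m.group(1)


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float
    ub: float
    species: str | None = None
    is_biomass: bool = False

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ModelError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")
        if not self.stoich:
            raise ModelError(f"reaction {self.id}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lb < 0


@dataclass
class Reconstruction:
    """A stoichiometric model (strain, pan-species, community, or host)."""

    id: str
    metabolites: list[str] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    couplings: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._rxn_index: dict[str, int] = {}
        self._met_index: dict[str, int] = {}
        self._reindex()

    def _reindex(self) -> None:
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._met_index = {m: i for i, m in enumerate(self.metabolites)}
        if len(self._rxn_index) != len(self.reactions):
            raise ModelError(f"model {self.id}: duplicate reaction IDs")
        if len(self._met_index) != len(self.metabolites):
            raise ModelError(f"model {self.id}: duplicate metabolite IDs")

    # -- queries ---------------------------------------------------------

    @property
    def compartments(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.metabolites:
            seen.setdefault(compartment_of(m), None)
        return list(seen)

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise ModelError(f"model {self.id}: no reaction {rxn_id!r}") from None

    def metabolite_index(self, met_id: str) -> int:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise ModelError(f"model {self.id}: no metabolite {met_id!r}") from None

    def biomass_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_biomass]

    def species_tags(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            if r.species is not None:
                seen.setdefault(r.species, None)
        return list(seen)

    def metabolites_in(self, compartment: str) -> list[str]:
        return [m for m in self.metabolites if compartment_of(m) == compartment]

    # -- edits -----------------------------------------------------------

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise ModelError(f"model {self.id}: reaction {rxn.id!r} already present")
        for met in rxn.stoich:
            compartment_of(met)  # validates the tag
            if met not in self._met_index:
                self._met_index[met] = len(self.metabolites)
                self.metabolites.append(met)
        self._rxn_index[rxn.id] = len(self.reactions)
        self.reactions.append(rxn)

    def remove_reaction(self, rxn_id: str, prune_metabolites: bool = True) -> None:
        if rxn_id not in self._rxn_index:
            raise ModelError(f"model {self.id}: no reaction {rxn_id!r}")
        self.reactions = [r for r in self.reactions if r.id != rxn_id]
        if prune_metabolites:
            used = {m for r in self.reactions for m in r.stoich}
            self.metabolites = [m for m in self.metabolites if m in used]
        self.couplings = [c for c in self.couplings if c["rxn"] != rxn_id]
        self._reindex()

    def copy(self) -> "Reconstruction":
        return copy.deepcopy(self)

    def validate(self) -> None:
        """Check structural invariants (unique IDs, lb<=ub, nonzero columns)."""
        self._reindex()
        for r in self.reactions:
            if r.lb > r.ub:
                raise ModelError(f"reaction {r.id}: lb > ub")
            if not any(v != 0 for v in r.stoich.values()):
                raise ModelError(f"reaction {r.id}: all-zero stoichiometry")
            for m in r.stoich:
                if m not in self._met_index:
                    raise ModelError(f"reaction {r.id}: unknown metabolite {m!r}")


# -- JSON I/O ------------------------------------------------------------


def _to_dict(model: Reconstruction) -> dict:
    return {
        "id": model.id,
        "compartments": model.compartments,
        "metabolites": [
            {"id": m, "compartment": compartment_of(m)} for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": r.stoich,
                "lb": r.lb,
                "ub": r.ub,
                **({"species": r.species} if r.species is not None else {}),
                "is_biomass": r.is_biomass,
            }
            for r in model.reactions
        ],
        "couplings": model.couplings,
    }


def _from_dict(data: Mapping) -> Reconstruction:
    model = Reconstruction(
        id=data["id"],
        metabolites=[m["id"] for m in data.get("metabolites", [])],
        reactions=[
            Reaction(
                id=r["id"],
                stoich={k: float(v) for k, v in r["stoich"].items()},
                lb=float(r["lb"]),
                ub=float(r["ub"]),
                species=r.get("species"),
                is_biomass=bool(r.get("is_biomass", False)),
            )
            for r in data.get("reactions", [])
        ],
        couplings=[dict(c) for c in data.get("couplings", [])],
    )
    model.validate()
    return model


def write_model_json(model: Reconstruction, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_to_dict(model), indent=1, sort_keys=False) + "\n")


def read_model_json(path: str | Path) -> Reconstruction:
    return _from_dict(json.loads(Path(path).read_text()))


def model_to_dict(model: Reconstruction) -> dict:
    """Plain-dict form of the JSON schema (useful for in-memory round trips)."""
    return _to_dict(model)


def model_from_dict(data: Mapping) -> Reconstruction:
    return _from_dict(data)
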