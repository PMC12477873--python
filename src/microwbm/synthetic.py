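"""Synthetic inputs: strain catalogs, host template, abundance cohorts, diets.

The generators emulate the structure of the real study inputs at desk scale:

* **Strain catalogs** stand in for large strain-resolved reconstruction
  resources. Each species has a small core network -- uptake of shared
  dietary precursors from the community lumen, conversion to one dedicated
  plus up to two shared product metabolites, secretion back to the lumen,
  and a biomass reaction fed by an always-present dietary nutrient
  (``nut_univ``). Strains of a species share the core and differ in a few
  accessory reactions. A minority of species additionally *consume* a small
  amount of another species' dedicated product in their biomass reaction
  (cross-feeding), which produces genuinely negative contribution potentials
  downstream.
* **Host template** is a miniature compartmentalized whole-body model:
  diet boundary ``[d]`` -> large-intestine lumen ``[luLI]`` -> blood ``[bc]``
  -> urine ``[u]``, with a fecal route ``[fe]``, per-organ biomass reactions
  and a ``Whole_body_objective_rxn`` combining organ biomass terms with
  weight coefficients. Male and female templates differ in their organ sets.
* **Abundance cohorts** follow a log-normal-then-closure compositional
  model with group-structured multiplicative effects on selected taxa, plus
  metadata (diagnosis, sex, age, BMI, six binary lifestyle/medication
  covariates, read counts) with group rates loosely matching a PD
  case-control cohort.
* **Diets** list per-metabolite intakes in mmol/day/person including trace
  entries strictly below 0.1 mmol/day. Non-trace nutrient supplies are
  generous so that microbial capacity (growth coupling), not the diet, is
  the limiting resource for the focal pathways.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Reaction, Reconstruction

__all__ = [
    "SyntheticConfig",
    "DietSpec",
    "generate_strain_catalog",
    "generate_host_template",
    "generate_abundance_cohort",
    "generate_diet",
    "default_species_ids",
    "precursor_pool",
    "product_pool",
    "default_diet_metabolites",
    "producers_by_metabolite",
    "sole_producer_pairs",
    "TRACE_THRESHOLD",
    "UNIVERSAL_NUTRIENT",
]

TRACE_THRESHOLD = 0.1  # mmol/day/person
UNIVERSAL_NUTRIENT = "nut_univ"

#: within-group geometric SD of abundances (log-normal scale)
_ABUNDANCE_SIGMA = 0.75

#: cross-feeding: probability a species consumes another's product in biomass
_CROSSFEED_PROB = 0.25
_CROSSFEED_COEF = 0.05

# group rates for the six binary covariates, loosely matching a PD cohort
_BINARY_RATES = {
    "alcohol": (0.37, 0.51),
    "laxatives": (0.30, 0.105),
    "pain_meds": (0.22, 0.16),
    "mood_meds": (0.38, 0.23),
    "antihistamines": (0.16, 0.32),
    "sleep_aid": (0.40, 0.26),
}
_MALE_RATE = (0.63, 0.30)
_AGE = ((68.5, 8.6), (65.8, 8.8))
_BMI = ((28.0, 5.5), (28.5, 6.5))


@dataclass
class SyntheticConfig:
    """Cohort-level generator settings."""

    n_pd: int = 100
    n_ctrl: int = 100
    n_species: int = 8
    strains_per_species: int = 2
    effect_map: dict[str, float] = field(default_factory=dict)
    n_diet_mets: int = 24
    trace_fraction: float = 92 / 192
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pd", "n_ctrl", "n_species", "strains_per_species",
                     "n_diet_mets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(e <= 0 for e in self.effect_map.values()):
            raise ValueError("abundance effects must be positive")
        if not 0.0 <= self.trace_fraction <= 1.0:
            raise ValueError("trace_fraction must be in [0, 1]")


@dataclass
class DietSpec:
    """Metabolite ID -> intake in mmol/day/person."""

    entries: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("dietary intakes must be non-negative")

    def is_trace(self, metabolite: str) -> bool:
        return self.entries[metabolite] < TRACE_THRESHOLD

    @property
    def trace_metabolites(self) -> list[str]:
        return [m for m in self.entries if self.is_trace(m)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite": list(self.entries),
                "intake_mmol_per_day": list(self.entries.values()),
                "trace": [self.is_trace(m) for m in self.entries],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_diet_tsv(path: str | Path) -> DietSpec:
    df = pd.read_csv(path, sep="\t")
    return DietSpec(entries=dict(zip(df["metabolite"], df["intake_mmol_per_day"])))


# -- metabolite pools ------------------------------------------------------


def default_species_ids(n_species: int) -> list[str]:
    return [f"Species_{i:02d}" for i in range(n_species)]


def precursor_pool(n_species: int) -> list[str]:
    n_prec = max(4, n_species // 2 + 2)
    return [f"nut_{i:02d}" for i in range(n_prec)]


def product_pool(n_species: int) -> list[str]:
    return [f"met_{i:02d}" for i in range(n_species + 3)]


def default_diet_metabolites(n_mets: int, n_species: int = 8) -> list[str]:
    """Diet metabolite order: universal nutrient, precursors, then fillers."""
    base = [UNIVERSAL_NUTRIENT] + precursor_pool(n_species)
    fillers = [f"xeno_{i:03d}" for i in range(max(0, n_mets - len(base)))]
    return (base + fillers)[:n_mets]


# -- strain catalog --------------------------------------------------------


def _species_blueprint(species_ids: Sequence[str], rng: np.random.Generator):
    """Draw the per-species core design (products, precursors, cross-feeds)."""
    n = len(species_ids)
    precs = precursor_pool(n)
    prods = product_pool(n)
    shared_tail = prods[n:]
    blueprints = []
    for i, sp in enumerate(species_ids):
        dedicated = prods[i]
        n_extra = int(rng.integers(0, min(3, len(shared_tail)) + 1))
        extras = list(rng.choice(shared_tail, size=n_extra, replace=False)) if n_extra else []
        # dedicated product runs off the universal nutrient; extras off the pool
        routes = {dedicated: UNIVERSAL_NUTRIENT}
        for p in extras:
            routes[p] = str(rng.choice(precs))
        crossfeed = None
        if i >= 2 and rng.random() < _CROSSFEED_PROB:
            crossfeed = prods[int(rng.integers(0, i))]
        blueprints.append(
            {"species": sp, "products": [dedicated] + extras, "routes": routes,
             "crossfeed": crossfeed}
        )
    return blueprints


def _core_reactions(bp: Mapping) -> list[Reaction]:
    sp = bp["species"]
    lumen_mets: dict[str, None] = {}
    rxns: list[Reaction] = []

    def uptake(met: str) -> None:
        rid = f"upt_{met}"
        if any(r.id == rid for r in rxns):
            return
        lumen_mets.setdefault(met, None)
        rxns.append(Reaction(rid, {f"{met}[luM]": -1.0, f"{met}[c]": 1.0},
                             0.0, 1e6, species=sp))

    uptake(UNIVERSAL_NUTRIENT)
    for prod, prec in bp["routes"].items():
        uptake(prec)
        rxns.append(Reaction(f"conv_{prec}_to_{prod}",
                             {f"{prec}[c]": -1.0, f"{prod}[c]": 1.0},
                             0.0, 1e6, species=sp))
        rxns.append(Reaction(f"sec_{prod}",
                             {f"{prod}[c]": -1.0, f"{prod}[luM]": 1.0},
                             0.0, 1e6, species=sp))
        lumen_mets.setdefault(prod, None)

    bio_stoich = {f"{UNIVERSAL_NUTRIENT}[c]": -1.0, "biomass[c]": 1.0}
    if bp["crossfeed"] is not None:
        cf = bp["crossfeed"]
        uptake(cf)
        bio_stoich[f"{cf}[c]"] = -_CROSSFEED_COEF
    rxns.append(Reaction(f"bio_{sp}", bio_stoich, 0.0, 1e6, species=sp,
                         is_biomass=True))

    for met in lumen_mets:
        rxns.append(Reaction(f"EX_{met}[luM]", {f"{met}[luM]": -1.0},
                             -1e6, 1e6, species=sp))
    return rxns


def _accessory_reactions(bp: Mapping, n_species: int,
                         rng: np.random.Generator) -> list[list[Reaction]]:
    """Pool of optional accessory routes (alternative production paths)."""
    sp = bp["species"]
    precs = precursor_pool(n_species)
    pool: list[list[Reaction]] = []
    for j in range(4):
        prec = str(rng.choice(precs))
        prod = str(rng.choice(bp["products"]))
        pool.append([
            Reaction(f"acc_upt_{sp}_{j}",
                     {f"{prec}[luM]": -1.0, f"{prec}_acc{j}[c]": 1.0},
                     0.0, 1e6, species=sp),
            Reaction(f"acc_conv_{sp}_{j}",
                     {f"{prec}_acc{j}[c]": -1.0, f"{prod}[c]": 1.0},
                     0.0, 1e6, species=sp),
        ])
    return pool


def generate_strain_catalog(
    n_species: int,
    strains_per_species: int,
    seed: int,
    species_ids: Sequence[str] | None = None,
) -> list[Reconstruction]:
    """Generate ``n_species * strains_per_species`` strain reconstructions.

    Strains of one species share the species core (>=50% of reactions) and
    differ in accessory uptake/conversion routes. Deterministic given seed.
    """
    if n_species < 1 or strains_per_species < 1:
        raise ValueError("n_species and strains_per_species must be >= 1")
    ids = list(species_ids) if species_ids is not None else default_species_ids(n_species)
    if len(ids) != n_species:
        raise ValueError("species_ids length must equal n_species")
    rng = np.random.default_rng(seed)
    catalog: list[Reconstruction] = []
    for bp in _species_blueprint(ids, rng):
        core = _core_reactions(bp)
        acc_pool = _accessory_reactions(bp, n_species, rng)
        for s in range(strains_per_species):
            rxns = [Reaction(r.id, dict(r.stoich), r.lb, r.ub, r.species,
                             r.is_biomass) for r in core]
            if s > 0:
                n_acc = int(rng.integers(0, len(acc_pool) + 1))
                picked = rng.choice(len(acc_pool), size=n_acc, replace=False)
                for j in sorted(int(k) for k in picked):
                    for r in acc_pool[j]:
                        rxns.append(Reaction(r.id, dict(r.stoich), r.lb, r.ub,
                                             r.species, r.is_biomass))
            model = Reconstruction(id=f"{bp['species']}_strain_{s + 1:02d}",
                                   reactions=[])
            for r in rxns:
                model.add_reaction(r)
            model.validate()
            catalog.append(model)
    return catalog


def producers_by_metabolite(catalog: Sequence[Reconstruction]) -> dict[str, set[str]]:
    """Which species can synthesize each product metabolite (``met_*``)."""
    out: dict[str, set[str]] = {}
    for model in catalog:
        for rxn in model.reactions:
            for met, coef in rxn.stoich.items():
                if coef > 0 and met.startswith("met_") and met.endswith("[c]"):
                    # transports only move the compound; true synthesis has no
                    # lumen counterpart of the same metabolite in the reaction
                    if f"{met[:-3]}[luM]" in rxn.stoich:
                        continue
                    out.setdefault(met[:-3], set()).add(rxn.species)
    return out


def sole_producer_pairs(catalog: Sequence[Reconstruction]) -> list[tuple[str, str]]:
    """(species, metabolite) pairs where the species is the only producer."""
    return sorted(
        (next(iter(species)), met)
        for met, species in producers_by_metabolite(catalog).items()
        if len(species) == 1
    )


# -- host template ---------------------------------------------------------

_ORGAN_WEIGHTS = {
    "male": {"muscle": 0.6, "liver": 0.3, "brain": 0.1},
    "female": {"muscle": 0.48, "liver": 0.3, "brain": 0.12, "uterus": 0.1},
}


def generate_host_template(
    sex: str, diet_metabolites: Sequence[str] | None = None
) -> Reconstruction:
    """Miniature compartmentalized host model.

    Every diet metabolite gets a diet exchange, digestion (diet -> LI lumen),
    absorption (lumen -> blood), fecal and urinary routes; organ biomass
    reactions draw the universal nutrient from blood and feed the
    ``Whole_body_objective_rxn``.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    mets = list(diet_metabolites) if diet_metabolites is not None else \
        default_diet_metabolites(24)
    if UNIVERSAL_NUTRIENT not in mets:
        mets = [UNIVERSAL_NUTRIENT] + mets
    host = Reconstruction(id=f"host_{sex}")
    for m in mets:
        host.add_reaction(Reaction(f"Diet_EX_{m}[d]", {f"{m}[d]": -1.0}, -1e6, 1e6))
        host.add_reaction(Reaction(f"T_diet_{m}", {f"{m}[d]": -1.0, f"{m}[luLI]": 1.0},
                                   0.0, 1e6))
        host.add_reaction(Reaction(f"T_abs_{m}", {f"{m}[luLI]": -1.0, f"{m}[bc]": 1.0},
                                   0.0, 1e6))
        host.add_reaction(Reaction(f"T_fe_{m}", {f"{m}[luLI]": -1.0, f"{m}[fe]": 1.0},
                                   0.0, 1e6))
        host.add_reaction(Reaction(f"EX_{m}[fe]", {f"{m}[fe]": -1.0}, 0.0, 1e6))
        host.add_reaction(Reaction(f"T_u_{m}", {f"{m}[bc]": -1.0, f"{m}[u]": 1.0},
                                   0.0, 1e6))
        host.add_reaction(Reaction(f"EX_{m}[u]", {f"{m}[u]": -1.0}, 0.0, 1e6))
    objective_stoich: dict[str, float] = {}
    for organ, weight in _ORGAN_WEIGHTS[sex].items():
        host.add_reaction(Reaction(
            f"{organ}_biomass_rxn",
            {f"{UNIVERSAL_NUTRIENT}[bc]": -1.0, f"biomass_{organ}[bc]": 1.0},
            0.0, 1e6, is_biomass=True))
        objective_stoich[f"biomass_{organ}[bc]"] = -weight
    host.add_reaction(Reaction("Whole_body_objective_rxn", objective_stoich, 0.0, 1e6))
    host.validate()
    return host


# -- abundance cohort ------------------------------------------------------


def generate_abundance_cohort(
    config: SyntheticConfig, species_ids: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compositional abundance table (species x samples) plus metadata.

    Abundances are log-normal draws around species-specific baselines; PD
    samples have the baselines of species named in ``effect_map`` multiplied
    by the stated effect before closure. Columns sum to one.
    """
    if not species_ids:
        raise ValueError("species_ids must be non-empty")
    unknown = set(config.effect_map) - set(species_ids)
    if unknown:
        raise ValueError(f"effect_map names unknown species: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    n_sp = len(species_ids)
    baselines = rng.lognormal(mean=0.0, sigma=1.0, size=n_sp)
    effects = np.array([config.effect_map.get(sp, 1.0) for sp in species_ids])

    samples = [f"PD_{i:03d}" for i in range(config.n_pd)] + \
              [f"CT_{i:03d}" for i in range(config.n_ctrl)]
    is_pd = np.array([s.startswith("PD_") for s in samples])

    noise = rng.normal(0.0, _ABUNDANCE_SIGMA, size=(n_sp, len(samples)))
    log_mean = np.log(baselines)[:, None] + np.where(is_pd[None, :],
                                                     np.log(effects)[:, None], 0.0)
    raw = np.exp(log_mean + noise)
    abund = pd.DataFrame(raw / raw.sum(axis=0), index=list(species_ids),
                         columns=samples)

    meta = {"diagnosis": np.where(is_pd, "PD", "control")}
    grp = (~is_pd).astype(int)  # 0 = PD, 1 = control
    meta["sex"] = np.where(
        rng.random(len(samples)) < np.choose(grp, _MALE_RATE), "male", "female")
    for j, (mu_sd_pd, mu_sd_ct) in enumerate([_AGE, _BMI]):
        mus = np.choose(grp, (mu_sd_pd[0], mu_sd_ct[0]))
        sds = np.choose(grp, (mu_sd_pd[1], mu_sd_ct[1]))
        vals = np.clip(rng.normal(mus, sds), 18.0, 100.0)
        meta["age" if j == 0 else "bmi"] = np.round(vals, 1)
    for name, rates in _BINARY_RATES.items():
        meta[name] = (rng.random(len(samples)) < np.choose(grp, rates)).astype(int)
    meta["read_count"] = np.maximum(
        rng.lognormal(np.log(1.8e7), 0.5, size=len(samples)).astype(np.int64), 1)
    metadata = pd.DataFrame(meta, index=samples)
    metadata.index.name = "sample"
    return abund, metadata


# -- diet ------------------------------------------------------------------


def generate_diet(
    n_mets: int,
    trace_fraction: float,
    seed: int,
    metabolite_ids: Sequence[str] | None = None,
) -> DietSpec:
    """Diet with exactly ``floor(trace_fraction * n_mets)`` trace entries.

    Trace status is assigned from the tail of the metabolite list, so the
    universal nutrient and the shared precursors stay generously supplied
    unless the trace fraction forces otherwise.
    """
    if n_mets < 1:
        raise ValueError("n_mets must be >= 1")
    if not 0.0 <= trace_fraction <= 1.0:
        raise ValueError("trace_fraction must be in [0, 1]")
    mets = list(metabolite_ids) if metabolite_ids is not None else \
        default_diet_metabolites(n_mets)
    if len(mets) != n_mets:
        raise ValueError("metabolite_ids length must equal n_mets")
    rng = np.random.default_rng(seed)
    n_trace = int(np.floor(trace_fraction * n_mets))
    entries: dict[str, float] = {}
    for i, met in enumerate(mets):
        if i >= n_mets - n_trace:
            entries[met] = float(np.exp(rng.uniform(np.log(1e-3), np.log(0.0999))))
        elif met == UNIVERSAL_NUTRIENT:
            entries[met] = 1000.0
        elif met.startswith("nut_"):
            entries[met] = float(np.round(np.exp(rng.uniform(np.log(100.0),
                                                             np.log(1000.0))), 4))
        else:
            entries[met] = float(np.round(np.exp(rng.uniform(np.log(0.1),
                                                             np.log(100.0))), 4))
    return DietSpec(entries=entries)


# -- tabular I/O -----------------------------------------------------------


def write_abundance_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="species", float_format="%.12g")


def read_abundance_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="species")


def write_metadata_csv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index_label="sample")


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample")
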