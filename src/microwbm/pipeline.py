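"""End-to-end orchestration: map -> build -> FBA -> statistics -> contributions.

The pipeline reproduces the study design on any input set (real files or the
synthetic generators): map species onto the catalog and renormalize, build
abundance-personalized community models joined to a sex-matched host, predict
maximal blood fluxes per metabolite by FBA, filter metabolites without
microbiome influence, remove outlier samples, regress fluxes on case/control
status with confounders and BH-FDR, derive per-species contribution
potentials from the FBA shadow prices, bootstrap-rank and prune contributors,
correlate them with fluxes, and search for the best small species
combinations. Every stage is deterministic given the configured seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import community as cm
from . import contribution as ct
from . import fba
from . import mapping as mp
from . import stats as st
from . import synthetic as syn
from .model import Reconstruction, read_model_json

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "write_reports",
           "build_sample_models", "build_demo_model"]

logger = logging.getLogger(__name__)

_CSV_FLOATS = "%.10g"


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run."""

    synthetic: syn.SyntheticConfig | None = None
    # file inputs (used when synthetic is None)
    abundance_path: str | None = None
    metadata_path: str | None = None
    catalog_dir: str | None = None
    host_male_path: str | None = None
    host_female_path: str | None = None
    diet_path: str | None = None
    # parameters
    threshold: float = mp.DEFAULT_ABUNDANCE_THRESHOLD
    coupling_factor: float = cm.DEFAULT_COUPLING_FACTOR
    metabolites: list[str] | None = None
    diet_flexibility: float = 1.0
    n_boot: int = 50_000
    prune_frac: float = 0.95
    max_k: int = 5
    delta_rho: float = 0.05
    fdr: float = 0.1
    outlier_k: float = 3.0
    interaction: str | None = None
    seed: int = 0
    out_dir: str | None = None


@dataclass
class ReportBundle:
    coverage: mp.CoverageReport
    flux_matrix: pd.DataFrame
    influenced: pd.DataFrame
    kept_metabolites: list[str]
    outlier_scores: pd.Series
    outlier_flagged: list[str]
    regressions: pd.DataFrame
    significant: list[str]
    contributions: pd.DataFrame
    pruned: dict[str, list[str]]
    correlations: pd.DataFrame
    clusters: pd.DataFrame
    cohort: pd.DataFrame
    run_metadata: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        s = config.synthetic
        species = syn.default_species_ids(s.n_species)
        diet_mets = syn.default_diet_metabolites(s.n_diet_mets, s.n_species)
        catalog = syn.generate_strain_catalog(s.n_species, s.strains_per_species,
                                              seed=s.seed, species_ids=species)
        hosts = {sex: syn.generate_host_template(sex, diet_metabolites=diet_mets)
                 for sex in ("male", "female")}
        abund, meta = syn.generate_abundance_cohort(s, species)
        diet = syn.generate_diet(s.n_diet_mets, s.trace_fraction, seed=s.seed,
                                 metabolite_ids=diet_mets)
        return catalog, hosts, abund, meta, diet
    catalog = [read_model_json(p)
               for p in sorted(Path(config.catalog_dir).glob("*.json"))]
    hosts = {"male": read_model_json(config.host_male_path),
             "female": read_model_json(config.host_female_path)}
    abund = syn.read_abundance_tsv(config.abundance_path)
    meta = syn.read_metadata_csv(config.metadata_path)
    diet = syn.read_diet_tsv(config.diet_path)
    return catalog, hosts, abund, meta, diet


def build_sample_models(
    pans: Mapping[str, Reconstruction],
    abundances: pd.DataFrame,
    hosts: Mapping[str, Reconstruction],
    metadata: pd.DataFrame,
    diet: syn.DietSpec,
    coupling_factor: float = cm.DEFAULT_COUPLING_FACTOR,
    diet_flexibility: float = 1.0,
) -> dict[str, cm.HostMicrobiomeModel]:
    """One personalized host-microbiome model per sample column."""
    models: dict[str, cm.HostMicrobiomeModel] = {}
    for sample in abundances.columns:
        r = abundances[sample]
        present = r[r > 0]
        sub = {sp: pans[sp] for sp in present.index}
        comm = cm.assemble_community(sub, (present / present.sum()).to_dict())
        cm.add_coupling_constraints(comm, coupling_factor)
        host = hosts[str(metadata.loc[sample, "sex"])]
        joined = cm.join_host(host, comm)
        models[sample] = cm.apply_diet(joined, diet, flexibility=diet_flexibility)
    return models


def build_demo_model(
    n_species: int = 4,
    strains_per_species: int = 2,
    seed: int = 0,
    sex: str = "male",
    n_diet_mets: int = 20,
    trace_fraction: float = 0.4,
    coupling_factor: float = cm.DEFAULT_COUPLING_FACTOR,
    abundances: Mapping[str, float] | None = None,
) -> tuple[cm.HostMicrobiomeModel, list[Reconstruction]]:
    """One fully built host-microbiome model from the synthetic generators.

    Convenience for demonstrations and sensitivity checks; returns the joined,
    coupled, diet-constrained model together with the strain catalog it was
    built from.
    """
    species = syn.default_species_ids(n_species)
    diet_mets = syn.default_diet_metabolites(n_diet_mets, n_species)
    catalog = syn.generate_strain_catalog(n_species, strains_per_species,
                                          seed=seed, species_ids=species)
    host = syn.generate_host_template(sex, diet_metabolites=diet_mets)
    diet = syn.generate_diet(n_diet_mets, trace_fraction, seed=seed,
                             metabolite_ids=diet_mets)
    if abundances is None:
        cfg = syn.SyntheticConfig(n_pd=1, n_ctrl=1, n_species=n_species,
                                  strains_per_species=strains_per_species,
                                  seed=seed)
        col = syn.generate_abundance_cohort(cfg, species)[0].iloc[:, 0]
        abundances = (col / col.sum()).to_dict()
    by_species: dict[str, list[Reconstruction]] = {}
    for strain in catalog:
        by_species.setdefault(strain.species_tags()[0], []).append(strain)
    pans = {sp: cm.build_pan_species(strains, sp)
            for sp, strains in by_species.items()}
    comm = cm.assemble_community({sp: pans[sp] for sp in abundances}, abundances)
    cm.add_coupling_constraints(comm, coupling_factor)
    joined = cm.apply_diet(cm.join_host(host, comm), diet)
    return joined, catalog


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    t0 = time.time()
    stage = "inputs"
    try:
        catalog, hosts, abund_raw, meta, diet = _load_inputs(config)

        stage = "mapping"
        species_in_catalog = {m.species_tags()[0] for m in catalog}
        mapped, unmapped = mp.map_taxa(abund_raw, species_in_catalog)
        mapped = mp.renormalize(mapped)
        final_abund = mp.apply_abundance_threshold(mapped, config.threshold)
        coverage = mp.coverage_stats(abund_raw, final_abund)
        logger.info("mapping: %d/%d species retained, mean coverage %.3f",
                    coverage.post_species, coverage.pre_species,
                    coverage.mean_mapped_fraction)

        stage = "community_build"
        by_species: dict[str, list[Reconstruction]] = {}
        for strain in catalog:
            by_species.setdefault(strain.species_tags()[0], []).append(strain)
        pans = {sp: cm.build_pan_species(strains, sp)
                for sp, strains in by_species.items()}
        models = build_sample_models(pans, final_abund, hosts, meta, diet,
                                     config.coupling_factor,
                                     config.diet_flexibility)

        stage = "fba"
        mets = config.metabolites or sorted(syn.producers_by_metabolite(catalog))
        fluxmat = fba.predict_blood_fluxes(models, mets)
        logger.info("fba: %d/%d cells solved",
                    int(fluxmat.fluxes.notna().sum().sum()),
                    fluxmat.fluxes.size)

        stage = "influence_filter"
        kept = st.filter_metabolites_by_influence(
            fluxmat.influenced, valid=fluxmat.fluxes.notna())

        stage = "outliers"
        if len(kept) >= 2 and fluxmat.fluxes.shape[0] >= 3:
            scores, flagged = st.detect_outliers(fluxmat.fluxes[kept],
                                                 k_iqr=config.outlier_k)
        else:
            scores = pd.Series(0.0, index=fluxmat.fluxes.index)
            flagged = []
        samples = [s for s in fluxmat.fluxes.index if s not in set(flagged)]

        stage = "regression"
        reg_rows: list[st.RegressionResult] = []
        for met in kept:
            try:
                z, _ = st.transform_fluxes(fluxmat.fluxes.loc[samples, met])
            except ValueError as exc:
                logger.warning("metabolite %s skipped: %s", met, exc)
                continue
            reg_rows.extend(st.flux_logistic_regression(
                z, meta.loc[samples], interaction=config.interaction,
                metabolite=met))
        regressions = pd.DataFrame([asdict(r) for r in reg_rows])
        significant: list[str] = []
        if not regressions.empty:
            fluxterm = regressions["term"] == "flux"
            qs = st.bh_fdr(regressions.loc[fluxterm, "p"])
            regressions.loc[fluxterm, "q"] = qs
            sig_mask = fluxterm & (regressions["q"] < config.fdr)
            significant = sorted(regressions.loc[sig_mask, "metabolite"])

        stage = "contributions"
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
        contrib_rows: list[ct.ContributionRecord] = []
        pruned: dict[str, list[str]] = {}
        corr_rows, cluster_rows = [], []
        weights = None
        for met in significant:
            for sample in samples:
                sol = fluxmat.solutions.get((sample, met))
                if sol is None:
                    continue
                contrib_rows.extend(ct.contribution_potentials(
                    sol, models[sample], abundances=models[sample].abundances,
                    sample=sample, metabolite=met))
            met_rows = [r for r in contrib_rows if r.metabolite == met]
            if not met_rows:
                continue
            wide = pd.DataFrame(
                [(r.sample, r.species, r.delta_z) for r in met_rows],
                columns=["sample", "species", "delta_z"],
            ).pivot(index="sample", columns="species", values="delta_z").fillna(0.0)
            if weights is None or weights.shape[1] != wide.shape[0]:
                weights = ct._bootstrap_weights(wide.shape[0], config.n_boot, rng)
            means: dict[str, float] = {}
            for sp in wide.columns:
                mean, lo, hi = ct.bootstrap_mean_ci(wide[sp].to_numpy(),
                                                    weights=weights)
                means[sp] = mean
                corr_rows.append({"metabolite": met, "species": sp,
                                  "boot_mean": mean, "ci_lo": lo, "ci_hi": hi})
            pruned[met] = ct.prune_to_cumulative(means, config.prune_frac)
            flux_vec = fluxmat.fluxes.loc[samples, met]
            for row in corr_rows:
                if row["metabolite"] == met and row["species"] in pruned[met] \
                        and "rho" not in row:
                    rho, p = ct.correlate_species_flux(
                        final_abund.loc[row["species"], samples], flux_vec)
                    row["rho"], row["rho_p"] = rho, p
            if pruned[met]:
                res = ct.search_microbe_clusters(
                    pruned[met], final_abund[samples], flux_vec,
                    max_k=config.max_k, delta=config.delta_rho, metabolite=met)
                cluster_rows.append({
                    "metabolite": met, "size": res.size,
                    "species": "+".join(res.selected_species), "rho": res.rho,
                    **{f"best_rho_k{k}": v[1]
                       for k, v in sorted(res.best_by_size.items())},
                })

        stage = "reports"
        contributions = pd.DataFrame(
            [(r.sample, r.metabolite, r.species, r.shadow_price, r.biomass_flux,
              r.delta_z) for r in contrib_rows],
            columns=["sample", "metabolite", "species", "pi", "v_bio", "delta_z"])
        bundle = ReportBundle(
            coverage=coverage,
            flux_matrix=fluxmat.fluxes,
            influenced=fluxmat.influenced,
            kept_metabolites=kept,
            outlier_scores=scores,
            outlier_flagged=flagged,
            regressions=regressions,
            significant=significant,
            contributions=contributions,
            pruned=pruned,
            correlations=pd.DataFrame(corr_rows),
            clusters=pd.DataFrame(cluster_rows),
            cohort=st.cohort_summary(meta),
            run_metadata={
                "seed": config.seed,
                "threshold": config.threshold,
                "coupling_factor": config.coupling_factor,
                "n_boot": config.n_boot,
                "prune_frac": config.prune_frac,
                "max_k": config.max_k,
                "delta_rho": config.delta_rho,
                "fdr": config.fdr,
                "n_samples": len(samples),
                "n_metabolites": len(mets),
            },
        )
        logger.info("pipeline finished in %.1f s", time.time() - t0)
    except Exception as exc:  # noqa: BLE001 - re-tagged with the stage name
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    if config.out_dir:
        write_reports(bundle, config.out_dir)
    return bundle


def write_reports(bundle: ReportBundle, out_dir: str | Path) -> list[str]:
    """Write all report CSVs plus a run-metadata record; returns the manifest."""
    if bundle.flux_matrix.empty:
        raise ValueError("cannot write reports for an empty bundle")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def _csv(name: str, frame: pd.DataFrame, **kw) -> None:
        path = out / name
        frame.to_csv(path, float_format=_CSV_FLOATS, **kw)
        manifest.append(str(path))

    _csv("flux_matrix.csv", bundle.flux_matrix, index_label="sample")
    _csv("influence.csv", bundle.influenced, index_label="sample")
    _csv("coverage.csv", bundle.coverage.per_sample, index_label="sample")
    _csv("coverage_summary.csv", bundle.coverage.summary(), index=False)
    _csv("regressions.csv", bundle.regressions, index=False)
    _csv("contributions.csv", bundle.contributions, index=False)
    _csv("pruned_contributors.csv", pd.DataFrame(
        [(met, i + 1, sp) for met, sps_ in bundle.pruned.items()
         for i, sp in enumerate(sps_)],
        columns=["metabolite", "rank", "species"]), index=False)
    _csv("correlations.csv", bundle.correlations, index=False)
    _csv("clusters.csv", bundle.clusters, index=False)
    _csv("outliers.csv", pd.DataFrame({
        "score": bundle.outlier_scores,
        "flagged": [s in set(bundle.outlier_flagged)
                    for s in bundle.outlier_scores.index]}),
         index_label="sample")
    _csv("cohort_summary.csv", bundle.cohort, index=False)
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(bundle.run_metadata, indent=1, sort_keys=True)
                         + "\n")
    manifest.append(str(meta_path))
    return manifest
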