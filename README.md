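# microwbm

Constraint-based modeling of host–gut-microbiome co-metabolism for
case/control cohorts. `microwbm` builds abundance-personalized community
metabolic models joined to a miniature whole-body host model, predicts the
maximal production flux of blood metabolites by flux balance analysis (FBA),
decomposes each prediction into per-species *contribution potentials* via
linear-programming shadow prices, and runs the downstream statistics that
link those fluxes to disease status.

## Who this is for

Researchers who want to test, on a controlled synthetic cohort, the full
inference chain used in microbiome–metabolome modeling studies: from a
species × sample relative-abundance table to "which microbial species could
drive the altered blood level of metabolite X in cases vs. controls."

## The model

Each sample's model is assembled in four steps:

1. **Pan-species models.** Strain reconstructions of one species are merged
   into a pan model (union of reactions and metabolites; widest bounds for
   shared reactions; one `pan<Species>_biomass` reaction).
2. **Community.** Pan models share a microbiota lumen; a `communityBiomass`
   reaction consumes each species' biomass metabolite with its relative
   abundance *rᵢ* as the stoichiometric coefficient.
3. **Coupling.** Every non-biomass reaction *j* of species *i* is coupled to
   its biomass flux: |vⱼ| ≤ 400 · v_bio,i — no flux without growth.
4. **Host join and diet.** The community lumen merges with the host's
   large-intestine lumen; the excretion of the community biomass compound
   and the `Whole_body_objective_rxn` are both pinned to [1, 1]
   mmol/day/person, which forces v_bio,i = rᵢ in every feasible solution;
   diet exchange bounds are set from a per-metabolite intake table.

Fluxes come from the standard FBA linear program

```
max  cᵀv   s.t.  S·v = 0,  lb ≤ v ≤ ub,
```

with an unbalanced demand reaction `DM_<met>[bc]: met[bc] → ∅` as the
objective for each blood metabolite. The shadow price of metabolite *i* is
πᵢ = −∂Z/∂bᵢ (with bᵢ the right-hand side of its steady-state row), and the
contribution potential of species *i* to a predicted flux Z is

```
δZᵢ = −π_biomass,i · v_biomass,i
```

— the maximal flux change when the species is removed while all other
abundances stay fixed. A brute-force removal oracle (re-solving the LP with
the species' biomass pinned to zero) validates this identity; the two routes
agree exactly whenever the LP basis is stable over the removal range, and
disagreements are flagged.

Downstream, fluxes are log2- and z-transformed and regressed on case/control
status (logistic, adjusting for age, sex, six binary lifestyle/medication
covariates and log read counts) with Benjamini–Hochberg FDR; contributors are
bootstrap-ranked (50,000 resamples), pruned to 95% cumulative contribution,
Spearman-correlated with fluxes, and searched exhaustively over species
pairs…quintets for the smallest combination whose summed abundances best
explain the flux (selection rule: largest size whose best |ρ| beats every
smaller size by > 0.05).

## Worked example

Plant a 0.2× abundance effect on the sole producer of one metabolite in a
synthetic 80 + 80 cohort and recover it end to end:

```python
from microwbm import synthetic as syn
from microwbm.pipeline import PipelineConfig, run_pipeline

catalog = syn.generate_strain_catalog(6, 2, seed=0)
species, met = syn.sole_producer_pairs(catalog)[0]   # ('Species_00', 'met_00')

cfg = PipelineConfig(
    synthetic=syn.SyntheticConfig(n_pd=80, n_ctrl=80, n_species=6,
                                  strains_per_species=2,
                                  effect_map={species: 0.2}, seed=0),
    seed=0)
bundle = run_pipeline(cfg)

row = bundle.regressions.query("metabolite == @met and term == 'flux'").iloc[0]
print(f"beta = {row.beta:.2f}  95% CI [{row.ci_lo:.2f}, {row.ci_hi:.2f}]  q = {row.q:.2e}")
print(bundle.pruned[met])
```

prints

```
beta = -3.00  95% CI [-4.12, -1.87]  q = 1.52e-06
['Species_00']
```

The planted metabolite's flux associates negatively with case status (−3.00
log-odds per SD of transformed flux, q ≈ 1.5 × 10⁻⁶), and the pruned
contributor set for `met_00` contains exactly the planted species. Its
abundance alone correlates with the predicted flux at ρ ≈ 1.00, so the
cluster search keeps the singleton; metabolites with several producers
select multi-species combinations instead (e.g. a four-species cluster at
ρ ≈ 0.98 in the same run).

The same analysis runs from the shell:

```bash
microwbm simulate --config sim.yaml --out-dir inputs/
microwbm pipeline run --config pipeline.yaml
```

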