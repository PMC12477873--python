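# Methods

This note documents the models, algorithms, parameter choices and numerical
conventions implemented in `microwbm`, and what the synthetic test bed does
and does not establish.

## Model construction

**Pan-species models.** Strains of a species are merged by reaction ID:
union of reactions and metabolites, widest bound interval for reactions
present in several strains, error on conflicting stoichiometry. The strains'
biomass reactions must agree in stoichiometry and are merged into a single
`pan<Species>_biomass` reaction producing the `pan<Species>_biomass[c]`
metabolite. This mirrors the standard pan-model recipe for strain-resolved
reconstruction resources.

**Community assembly.** Species-internal metabolites and reactions are
namespaced per species; lumen metabolites (`[luM]`) are shared. The
`communityBiomass` reaction consumes each species' biomass metabolite with
coefficient −rᵢ (relative abundance) and produces one unit of
`microbiota_LI_biomass[luM]`. Abundances must be strictly positive and sum
to 1 within 1e-9; absent species are excluded before assembly rather than
carried at zero abundance.

**Flux coupling.** Each non-biomass reaction of species *i* receives the
standard coupling envelope vⱼ − f·v_bio,i ≤ 0 (plus −vⱼ − f·v_bio,i ≤ 0 for
reversible reactions) with f = 400 by default. The coupling is an *upper*
envelope |vⱼ| ≤ f·v_bio — it prevents flux through non-growing organisms; it
does not force a minimum flux.

**Host join.** The community lumen merges with the host's large-intestine
lumen (`[luLI]`) through reversible transports. Lumen metabolites unknown to
the host template receive the standard lumenal fate (absorption to blood and
a fecal route); a full-scale host reconstruction would already contain these
compounds, the miniature template cannot. Two bounds are pinned at the join:
the fecal excretion of the community biomass compound
(`Excretion_EX_microbiota_LI_biomass[fe]`) at [1, 1] mmol/day/person, and the
`Whole_body_objective_rxn` at [1, 1]. Pinning the excretion fixes the
community biomass flux at 1 and therefore every species' biomass flux at its
relative abundance — the structural fact the contribution formula relies on.
All other host bounds are untouched by the join.

**Diet.** Diet exchanges follow the uptake-negative convention:
lb = −flexibility × intake (flexibility defaults to 1.0; whether a dietary
flexibility factor should scale intakes is genuinely open, so it is exposed
as a parameter). All non-diet exchange uptakes are closed; secretion is never
restricted. Diet entries without a matching exchange are logged and skipped.

## FBA and shadow prices

LPs are solved with HiGHS via `scipy.optimize.linprog`. Reported fluxes and
objective values are rounded to six decimals to suppress numerical
artifacts; solver-precision fluxes are retained on the solution object
because sensitivity products (π · v) would otherwise inherit round-off of up
to |π| · 5e-7.

The shadow-price convention is πᵢ = −∂Z/∂bᵢ for the steady-state rows
S v = b (surplus-production sense: bᵢ < 0 models external supply). HiGHS
returns the equality marginals of the minimization form min(−cᵀv), which are
exactly this π; the mapping is pinned by a finite-difference unit test.
Duals can be non-unique at degenerate optima; the solver's dual is used
as-is and downstream consumers flag disagreements (below). Shadow prices
with |π| < 1e-6 are reported as exactly zero, and a metabolite counts as
microbiome-influenced when any species' biomass-metabolite shadow price
survives that tolerance. Demand reactions are added per FBA with bounds
[0, 1e6] (the unconstrained-default magnitude of the modeling convention)
and removed afterwards.

## Contribution potentials

The contribution potential of species *i* to a predicted flux Z is
δZᵢ = −π_biomass,i · v_biomass,i. Because the community biomass flux is
pinned, supplying the species' biomass metabolite externally (rhs shift
−v_bio) while pinning its biomass reaction to zero is exactly "removal with
all other abundances fixed"; the LP optimal value is concave and piecewise
linear in the rhs, so the formula equals the brute-force removal result
whenever the basis is stable over the removal range. v_bio is read from the
solution (solver precision) with an assertion that it matches the abundance.

`eq3_vs_oracle` compares both routes per species and raises a
`basis_change` flag from two witnesses that do not use the mismatch itself:
(i) the optimal value at half removal deviating from the chord midpoint
(equivalent to nonlinearity over the range, by concavity), and (ii) the
biomass dual changing between the full and reduced solves. Removal of an
obligate cross-feeding source makes the reduced model infeasible; the oracle
is then undefined and the pair is flagged and excluded from agreement
statistics.

Rankings use the *magnitude* of the bootstrapped mean contribution:
consumers (negative δZ) are influential too. The bootstrap (50,000 resamples
with replacement, percentile 2.5/97.5 CI) is implemented with multinomial
resampling weights so one resampling can be shared across species via a
matrix product. Pruning keeps the smallest |mean δZ|-ranked prefix covering
95% of the total, ties broken lexicographically.

## Cluster search

For each size k = 1..5 the Spearman |ρ| of summed abundances against the
flux is evaluated over all C(n, k) subsets of the pruned species (a
configurable cap guards the combinatorial budget). The reported combination
is the best subset of the largest k whose best |ρ| exceeds the best |ρ| of
*every* smaller size by more than 0.05. The alternative reading — comparing
only against the best nested subset — would never select a smaller set when
a larger one ties, and is not implemented. Ties at equal |ρ| resolve to the
lexicographically first subset, so results are invariant to species input
order.

## Statistical layer

* **Influence filter:** metabolites keep their place in the analysis only if
  microbiome-influenced in strictly more than 5% of (successfully solved)
  samples; a metabolite not influenced in ≥95% of samples is removed.
* **Outliers:** alternating-least-squares PCA (3 components by default,
  matching visual inspection depth of the first components; ALS because
  missing flux cells must be tolerated) on z-scored fluxes; a sample's score
  is the Euclidean norm of its PC scores weighted by explained-variance
  fractions. Flagging is automated at Q3 + 3·IQR — the original workflow
  selected outliers manually, so the threshold is a parameter and flagged
  samples are reported for review rather than silently discarded elsewhere.
* **Transform:** log2 then z-score. Exact zeros (possible after rounding)
  get a half-minimum-positive pseudocount, recorded per metabolite.
* **Regression:** maximum-likelihood logistic regression of case/control
  status on the transformed flux, adjusting for age (z), sex, alcohol,
  laxatives, antihistamines, mood medications, pain medications, sleep aid,
  and log10+z total read counts; Wald 95% CIs; optional flux × sex or
  flux × age interaction. Perfect separation yields a flagged result with no
  finite estimates. Flux-term p-values are BH-adjusted across metabolites;
  the significance threshold defaults to FDR < 0.1 and near-misses are
  reported, not auto-included.
* **Cohort description:** Fisher's exact test with the sample OR
  (pd_yes·ctrl_no)/(pd_no·ctrl_yes) and Wald CI on the log OR for binary
  covariates; Wilcoxon rank-sum (exact enumeration when both groups have
  n ≤ 10 and no ties, normal approximation otherwise) for numeric ones.

## Mapping stage

Species names are matched to the catalog after case-folding and mapping
space/period runs to underscores. After restriction to the catalog the table
is renormalized; entries strictly below the relative-abundance threshold are
zeroed and the table renormalized again. The threshold defaults to 1e-7 as a
fraction (0.00001%); coverage is reported as the summed pre-mapping
abundance of retained species, so mapped fraction and dropped mass add to
one per sample.

## Synthetic test bed

The generators define the study conditions for all tests:

* **Strain catalogs.** Each species has a core network: uptake of shared
  dietary precursors from the lumen, 1:1 conversions to one dedicated plus
  up to two shared product metabolites, secretion, and a biomass reaction
  consuming one unit of an always-present nutrient (`nut_univ`). Strains
  share the core and differ in up to four accessory uptake/conversion
  routes, keeping within-species reaction-set Jaccard above cross-species
  values. From the third species on, each species cross-feeds with
  probability 0.25 by consuming 0.05 units of an earlier species' dedicated
  product in its biomass reaction — this produces genuinely negative
  contribution potentials (consumers) and obligate dependencies.
* **Host template.** Diet boundary → LI lumen → blood → urine with a fecal
  route, per-organ biomass reactions drawing the universal nutrient from
  blood, and a whole-body objective combining organ biomass terms with
  weight coefficients; male and female templates differ in their organ sets.
* **Abundances.** Log-normal draws (within-group geometric SD 0.75 on the
  natural-log scale) around species baselines drawn once per cohort from
  lognormal(0, 1), multiplied by group effects for case samples, then closed
  to sum 1 per sample. The real cohort's generative distribution is unknown;
  this is a standard compositional null with controllable effects, not a
  calibration.
* **Metadata.** Independent Bernoulli binary covariates with group rates
  loosely matching a PD case/control cohort (e.g. laxatives 0.30/0.105,
  antihistamines 0.16/0.32), age ≈ 68.5 ± 8.6 vs 65.8 ± 8.8 years, and
  log-normal read counts around 1.8 × 10⁷.
* **Diet.** Intakes in mmol/day/person; exactly ⌊trace_fraction·n⌋ entries
  are trace (below 0.1), assigned from the tail of the metabolite list so
  that the universal nutrient (1000) and shared precursors (log-uniform
  100–1000) stay generous. The default trace fraction is 92/192, the
  proportion in the average Western diet formulation. With generous
  precursor supplies, microbial capacity (the 400 × biomass coupling), not
  the diet, limits the focal pathways — so a species' product flux scales
  with its abundance, planted effects propagate to fluxes, and the
  contribution formula operates in its intended regime. Trace-bound
  metabolites exercise the opposite regime (no microbiome influence, hence
  filtered).

What passing tests show: the construction rules, the dual conventions, the
contribution identity and its failure modes, and the statistical layer are
implemented correctly, and the full chain recovers planted effects at
realistic noise. What they do not show: anything about real genome-scale
reconstructions (loops, redundant pathways, mass-imbalance artifacts),
realistic diets, strain-level variation, or cohort-scale confounding beyond
the simulated covariates.

## Problem sizes and defaults

Defaults are chosen so the full validation suite runs on one CPU in minutes:
cohorts of 100+100 samples with 8 species × 2 strains for end-to-end
recovery (20 replicates), ensembles of 100 random 3–6 species communities
for the contribution oracle, 500 null replicates at n = 400 for regression
calibration, and 50,000 bootstrap resamples throughout (the analysis-scale
value; it is cheap via the weight-matrix formulation).

## Known limitations

* Dual degeneracy can make individual shadow prices non-unique; contribution
  estimates are validated in aggregate and flagged cases are reported, but a
  single flagged δZ should not be over-interpreted.
* The removal oracle is undefined for obligate cross-feeding sources
  (reduced model infeasible) — as in the full-scale workflow, where the
  reduced community may not support the pinned community biomass.
* The miniature host has one absorption route per metabolite and no organ
  resolution; host-side saturation phenomena are represented only through
  the pinned whole-body objective.
* The ALS robust PCA recovers classical PCA when no cells are missing; it is
  robust to missingness, not to heavy-tailed noise.
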