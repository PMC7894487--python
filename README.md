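# natdiv — diversification rates and the naturalization success of plant families

Some angiosperm families contribute far more naturalized alien species to
the global flora than others. `natdiv` asks whether a family's
macroevolutionary history helps explain that imbalance: it builds
family-level predictors from species checklists and fits Bayesian
phylogenetic generalized linear mixed models (PGLMMs) of naturalization
success on net diversification rate, native range size and horticultural
use. It is written for invasion macroecologists who work with
family-level checklist data and a dated family phylogeny.

## The model

For each family *f* the **naturalization-success index** is

&nbsp;&nbsp;&nbsp;&nbsp;*I<sub>f</sub>* = (*n*<sub>nat</sub> / *n*<sub>tot</sub>) × *R<sub>f</sub>*,

the proportion of the family's species that are naturalized anywhere,
times the total count of naturalized (species, region) records
*R<sub>f</sub>*. The **net diversification rate** comes from the stem-age
method-of-moments estimator

&nbsp;&nbsp;&nbsp;&nbsp;*r* = ln(*n*(1 − ε) + ε) / *t*,

with *n* extant richness, *t* stem age (Myr) and ε = μ/λ the relative
extinction (computed at ε = 0.9, with ε = 0 reported alongside). Range
predictors are mean species range sizes (km², total and split into
tropical/temperate parts); horticultural use is the proportion of the
family's species in cultivation.

The regression is the Gaussian "animal model"

&nbsp;&nbsp;&nbsp;&nbsp;**y** = **Xβ** + **u** + **e**, **u** ~ N(0, σ²<sub>p</sub>**A**), **e** ~ N(0, σ²<sub>e</sub>**I**),

where **y** is the sqrt-transformed index, **X** holds transformed and
standardized predictors (plus interaction products), and **A** is the
phylogenetic correlation matrix (shared root-to-MRCA path lengths,
rescaled to unit diagonal). Three predictor sets are fitted: main
effects only (model 1), rate × range interactions (model 2), and a
rate × horticulture interaction (model 3). Fitting is by a Gibbs
sampler with inverse-Wishart(V = 1, ν = 0.002) variance priors and an
effectively flat Gaussian prior on **β**; convergence is checked with
Gelman–Rubin diagnostics (multivariate PSRF < 1.1) and models are
compared by DIC. An order-level GLMM (orders as random intercepts)
serves as a structural validation.

A bundled synthetic-data generator produces every input — dated
birth–death family tree, region table, species/occurrence checklists —
with known regression coefficients and phylogenetic signal, so the whole
chain is testable end to end without any database download.

## Worked example

The numbered scripts under `analysis/` run the full chain on a synthetic
bundle (200 simulated families, of which ~170 survive the ≥ 50-species
filter; true coefficients β = 0.5, 0.4, 0.38 and σ²<sub>p</sub> = σ²<sub>e</sub> = 1):

```sh
python analysis/01_simulate_inputs.py     # writes results/bundle/
python analysis/02_build_family_table.py  # family metrics + exclusion log
python analysis/03_fit_models.py          # PGLMMs 1-3 + report
python analysis/04_model_selection.py     # DIC stepwise selection
python analysis/05_order_level_validation.py
```

`03_fit_models.py` prints, for model 1 (three chains, 52 000 iterations
each, burn-in 2 000, thinning 10):

```
model1  (mPSRF 1.0005, DIC 526.2)
            post_mean  hpd_lower  hpd_upper    eff_samp   pmcmc
div_rate       0.6100     0.4255     0.7909  14761.4810  0.0001
mean_range     0.3473     0.1749     0.5191  14540.3405  0.0003
hort           0.5947     0.4257     0.7725  15000.0000  0.0001
sigma2_p       1.1605     0.4758     1.9227   7445.8092  0.0001
sigma2_e       1.0039     0.7238     1.3051  11997.9874  0.0001
```

Each row is a posterior mean with its 95% highest-posterior-density
interval, effective sample size and pMCMC (two-sided tail probability of
crossing zero, floored at 2/draws). The multivariate PSRF is far below
the 1.1 threshold, all three effects are recovered as strongly positive,
and the variance components sit on their generating values. In this
particular realization the horticulture interval (0.43–0.77) lands above
its generating value of 0.38 — single draws of a 168-family data set do
that about 5% of the time per coefficient, which is exactly what the
calibration test in `tests/test_acceptance.py` verifies over 200
replicates. The DIC selection in `04` ranks the full predictor set
first:

```
                   model   DIC
div_rate+mean_range+hort 526.4
           div_rate+hort 542.7
     div_rate+mean_range 573.9
                div_rate 579.3
```

The same pipeline runs behind a CLI
(`natdiv simulate|metrics|fit|select|report`) for use on real-format
inputs: a Newick tree plus `regions.csv`, `species.csv` and
`occurrences.csv` as described in `docs/methods.md`.

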