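# treesam

Stochastic antecedent modelling (SAM) of annual tree radial growth:
a hierarchical Bayesian regression that estimates *which past months* of
temperature and precipitation drive ring width, while accounting for tree
age, prior-year growth and the legacy of historical forest harvesting.

It is written for dendroecologists who have raw ring-width series
(Tucson/RWL), monthly site climate and archival harvesting records, and who
want climate-memory and management-legacy inference without fixing the lag
structure a priori — plus a synthetic-data generator with known ground
truth so the whole pipeline can be validated end to end.

## The model

Log-scale ring width `G = log(r + 1)` of core *c* in year *t* is normal
with a nine-term mean,

```
mu = a1 + a2*Age + a3*Pant + a4*Tant + a5*Pant*Tant
   + a6*G(t-1) + a7*HI + a8*HI*Pant + a9*HI*Tant
```

where the antecedent covariates are Dirichlet-weighted averages of the
previous 60 months of climate,

```
Xant_t = sum_{y=0..4} sum_{m=1..12} X_{t-y,m} * w_{y,m}
```

The monthly importance weights `w` are estimated from the data on a
simplex with current-year October–December fixed at zero and temporal
resolution declining with lag (single months, then 2-, 3-, 4-month
blocks; 34 free blocks). Core-level coefficients are pooled through
global normals (the age effect truncated to be non-positive), and weak
hyperpriors complete the model. From the weights the package derives
annual and cumulative weight profiles and the memory lengths **M50/M90**
(months into the past at which cumulative weight reaches 50%/90%), the
uncentered antecedent climate series, net climate sensitivities such as
`dG/dPant = a3 + a5*Tant + a8*HI`, a posterior-predictive `R²`, and the
share of fit owed to the autoregressive term. Details and all numerical
choices are in `docs/methods.md`.

## Worked example

```python
import treesam as ts

# a synthetic stressed-site dataset with known truth (30 cores x 60 years)
cfg = ts.make_paper_like_fixture("stressed")
cfg.seed = 3
series, climate, harvest, truth = ts.generate(cfg)

design = ts.build_design(series, climate, harvest, (1957, 2016))
chains = ts.run_mcmc(
    design,
    ts.MCMCSettings(n_chains=2, n_iter=10_000, burn_in=4_000, thin=12),
    seed=1003,
)
print(ts.summarize_coefficients(chains)[["name", "mean", "ci_low", "ci_high"]])
print(ts.memory_table(chains)[["variable", "measure", "mean"]])
print("R2:", round(ts.fit_r2(chains, design), 3),
      " truth:", round(truth["r2_true"], 3))
```

prints (seeds as above):

```
        name      mean    ci_low   ci_high
0  intercept  0.843241  0.785997  0.899744
1        age -0.001625 -0.002416 -0.000217
2      p_ant  0.010055  0.008056  0.012239
3      t_ant  0.356569  0.298081  0.416929
4      p_x_t  0.012507  0.009291  0.015969
5         ar  0.233363  0.186424  0.282512
6         hi -0.747262 -1.233582 -0.296683
7     hi_x_p  0.095036  0.044747  0.159375
8     hi_x_t  1.048313  0.022459  2.376148
        variable measure    mean
0  precipitation     M50  13.935
1  precipitation     M90  43.371
2    temperature     M50  17.088
3    temperature     M90  45.914
R2: 0.905  truth: 0.895
```

Each row is a global (species-site) effect with its 95% credible
interval: growth increases with antecedent precipitation and temperature,
carries a positive autoregressive signal from the prior year's ring, and
is reduced by harvesting at average climate — while the positive
`hi_x_t` interaction means harvesting hurts less (or helps) in warm
periods. Memory lengths say half the climate influence lies within ~14-17
months of ring formation and 90% within ~44-46 months. The generating
values for this dataset (`truth["mu_alpha"]` = 0.875, −0.002, 0.012,
0.35, 0.012, 0.2, −0.8, 0.06, 1.5) sit inside all nine credible
intervals.

The same pipeline runs from the shell:

```
treesam simulate --preset stressed --seed 3 --out data/
treesam fit --rwl data/rings.rwl --ages data/ages.csv \
            --climate data/climate.csv --harvest data/harvest.csv \
            --range 1957 2016 --iters 10000 --burnin 4000 --thin 12 \
            --seed 1003 --out fit/
treesam summarize --fit-dir fit/
treesam recover --preset smoke --seed 1 --out recovery/
```

`fit` writes the retained draws, convergence diagnostics (Gelman–Rubin
PSRF, effective sample sizes) and a CSV bundle of all posterior products;
`recover` simulates, refits and checks the truth is recovered.

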