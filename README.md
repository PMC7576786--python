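# reefcatch

How much of a jurisdiction's fish catch depends on coral reefs — and
what happens to reef stocks if coral loss suddenly cuts their
productivity?

`reefcatch` is a tested, reusable pipeline for answering those two
questions from ordinary fishery data (logbook catch tables and CPUE
series), built around the situation of Queensland, Australia and the
Great Barrier Reef but configurable for any jurisdiction. It is aimed
at fisheries scientists and quantitative ecologists who want a
transparent, fully scriptable alternative to ad-hoc spreadsheet
analyses of habitat dependence and stock risk.

## What it computes

**1. Coral-dependence classification.** Every fished taxon is rated on
an ordinal scale reflecting sensitivity to coral mortality:

| Category | Meaning |
|---|---|
| 1 | not known to be associated with coral reefs (live or dead) |
| 2 | associated with coral reefs, not known to depend on live coral |
| 3 | documented dependence on live coral cover |
| 4 | obligate dependence on live coral cover |

Evidence is structured data (one row per species × life-stage ×
observation method × habitat, with boolean coral-association /
live-coral-dependence / obligate flags); a species' category is the
highest level its evidence supports, and a catch group reported above
species level (genus, family, "unspecified") conservatively takes the
highest category of any member. Unresolvable labels go to a rejects
report, never to a silent default.

**2. Catch composition.** Catch records (taxon × region × sector ×
year × quantity) are aggregated into per-category percentage shares by
gear, region or sector over an analysis window, on a weight basis
(commercial, charter) or count basis (recreational, aquarium) — never
mixed.

**3. Reef-area regression.** Per region, the percent of catch in each
category is regressed on the region's percent coral-reef area under a
Gaussian likelihood with broad priors (flat intercept, N(0, 1000)
slope, log-gamma prior on the precision), sampled by
Metropolis-within-Gibbs. The headline summary is the posterior median
slope β and P(β > 0).

**4. Stock dynamics.** For each reef-dependent stock, a Bayesian
Schaefer surplus-production model is fitted to catch + CPUE:

    B_{t+1} = B_t + r B_t (1 − B_t/K) − C_t,
    CPUE_t ~ Lognormal(log(q(t) B_t), σ²),

with catchability q(t) allowed to change at a regime year (default
2004, the year of the Great Barrier Reef rezoning and line-fishery
restructure) and an optional 1 %/yr fishing-efficiency trend. Sampling
is adaptive random-walk Metropolis (4 chains, gated on split R-hat
< 1.05 and ESS ≥ 400), with the catchabilities integrated out
analytically and re-drawn from their exact conditionals. Derived per
draw: MSY = rK/4 and final-year depletion B_T/K.

**5. Overfishing risk under productivity decline.** Coral loss is
represented as a sudden reduction of r by p percent. The risk curve is
the posterior probability that recent catch (mean over a reference
window, default 2016–2018) exceeds MSY(p) = r(1 − p/100)K/4, swept
over p = 0…100 in 1 % steps.

A synthetic-data module generates all four input tables with known
ground truth, so the entire pipeline is testable end to end without any
data download.

## Worked example

```python
import numpy as np
import reefcatch as rc

# simulate a 40-year stock (r=0.3, K=5000 t) and fit it
sim = rc.simulate_spm_series(rc.SPMSimConfig(seed=1))
post = rc.fit_spm(sim.series, mcmc=rc.MCMCConfig(seed=1))

print(post.draws[["r", "K", "msy"]].median().round(3))
lo, med, hi = rc.depletion_summary(post)
print(f"depletion: {med:.0f}% of unfished (95% CI {lo:.0f}-{hi:.0f}%)")

# risk of overfishing if productivity drops, at catch = 70% of true MSY
curve = rc.risk_curve(post, 0.7 * sim.truth["msy"])
print("50% risk crossed at", curve.crossing(), "% reduction in r")
```

prints

```
r         0.297
K      5029.659
msy     373.106
depletion: 47% of unfished (95% CI 44-49%)
50% risk crossed at 30 % reduction in r
```

i.e. the sampler recovers the simulated stock (true r = 0.3, K = 5000,
MSY = 375 t, final depletion 49%), and the risk curve crosses 50 %
close to the analytic value 1 − catch/MSY = 30 %.

The same analysis runs from the shell:

```
reefcatch simulate --seed 7 --outdir out      # four input CSVs + truth
reefcatch classify --evidence out/habitat_evidence.csv --outdir out
reefcatch profile  --catch out/catch.csv --catalog out/catalog.csv --outdir out
reefcatch regress  --profiles out/profiles.csv --regions out/regions.csv --outdir out
reefcatch fit      --cpue out/cpue.csv --outdir out
reefcatch risk     --draws out/spm_draws_synthetic_stock.csv --cpue out/cpue.csv --outdir out
```

or in one step from a YAML config: `reefcatch all --config pipeline.yaml`.

## Layout

- `src/reefcatch/habitat.py` — categories, classifier, group rule, 95%-of-catch coverage ranking
- `src/reefcatch/composition.py` — catch profiles by gear/region/sector
- `src/reefcatch/regression.py` — Bayesian share-vs-reef-area regression
- `src/reefcatch/spm.py` — Schaefer surplus-production model + MCMC
- `src/reefcatch/risk.py` — risk-of-overfishing curves
- `src/reefcatch/synthetic.py` — ground-truth input generators
- `src/reefcatch/tables.py`, `config.py`, `cli.py` — strict CSV I/O, config, CLI
- `docs/methods.md` — modelling choices, assumptions and limitations
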