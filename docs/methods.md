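# Methods

This note records the models, the defaults and why they were chosen,
what the synthetic data do and do not emulate, and the numerical
decisions a user extending the package should know about.

## Coral-dependence classification

The classifier operates on structured evidence rows, not on literature
text: each row carries three boolean flags forming a strict hierarchy
(obligate live-coral dependence ⇒ live-coral dependence ⇒ coral
association; a coral-reef substrate observation also implies coral
association). A species' category is 1 plus the number of hierarchy
levels attested by *any* of its rows. Three deliberate choices:

- **Conflicting rows resolve upward.** A species with one row recording
  live-coral dependence and ten rows without is category 3. This
  mirrors the conservative group rule and makes the classifier monotone
  (more evidence can never lower a category), a property verified by
  test.
- **Life stage does not alter the label.** Evidence of dependence at
  any stage (e.g. juvenile recruitment to live coral) counts for the
  species as a whole, because recruitment bottlenecks propagate to the
  fished stock.
- **No evidence is an error, not category 1.** Category 1 is a positive
  statement ("reviewed, no reef association found"); an unreviewed
  taxon must surface in the rejects report.

Group labels (genus/family/"unspecified" catch buckets) take the
maximum member category. Over-broad arbitrary buckets (e.g. a bare
"fish" category) are flagged unclassifiable and rejected. Overrides
exist for labels rated from external assessments rather than from
evidence rows — aquarium taxa rated by global coral-reef-fish
vulnerability studies, and live coral itself, which is fixed at
category 4.

The review-scoping helper `coverage_rank` returns the shortest
highest-catch prefix reaching a coverage threshold (default 95 % by
weight, ties broken lexicographically); a prefix reaching the threshold
exactly qualifies.

## Catch composition

Mean annual quantities are computed over an inclusive year window
(default 2008–2017) with absent taxon-years counted as zero — logbook
semantics, under which non-reporting means no landings; treating
absence as missing data would silently inflate means. Shares are
percentages of the *classified* quantity; unclassified catch is
tracked separately so that classified + excluded equals the input mass
exactly (a property test enforces this). Weight-based and count-based
records never mix in one aggregation, and the category-4 column is
always carried even when empty so "no catch in category 4" is an
explicit zero rather than a missing column. Where multiple recreational
surveys must be combined into one representative catch, the
combination rule (mean vs sum) is a config choice defaulting to mean.

## Regression of catch share on reef area

Each category is fitted separately (shares are near-complementary
across categories, so a joint compositional model would add machinery
without changing the question asked of each slope). The model is
percent-on-percent: y = percent of regional catch in the category,
x = percent reef area, Gaussian likelihood, priors: intercept flat
(implemented as N(0, 10⁸) for sampler stability), slope N(0, 1000),
and a log-gamma prior on the precision τ = 1/σ² — τ ~ Gamma(shape 1,
rate 5·10⁻⁵), a standard broad default; both hyperparameters are
exposed in `RegressionPriors`. Sampling is Metropolis-within-Gibbs:
τ by its conjugate gamma draw, α and β by adaptive scalar random
walks (target acceptance 0.44), 4 chains, convergence gated on split
R-hat < 1.05 with up to two run-length doublings. The summaries are
the posterior median slope, P(β>0)/P(β<0) (fractions of draws strictly
on each side of zero) and the central 95 % credible interval.

## Surplus-production model

**Form.** Discrete-time Schaefer (logistic) dynamics were chosen as
the standard surplus-production form with the familiar reference point
MSY = rK/4; no shape parameter (Fox/Pella-Tomlinson) and no
recruitment lags. Estimation is observation-error-only: biomass is a
deterministic function of (r, K, ψ) and the catch history, and all
stochasticity is lognormal observation error on CPUE. A process-error
flag exists in the simulator (off by default) for robustness probing,
but the fitted model is deliberately the simplest CPUE-driven form.

**Regime change and efficiency trend.** Catchability may switch at a
configured regime year (default 2004): years strictly before the
regime year use q_pre, the regime year itself and later use q_post.
An optional efficiency trend multiplies both regimes by
(1 + e/100)^(t − t₁) from the first data year, representing
fishery-wide technological drift.

**Priors** (defaults, all exposed in `SPMPriors`):
r ~ Lognormal(log 0.3, 0.5²) /yr — moderate productivity typical of
reef meso-predators; K ~ Lognormal(log(5·max catch), 1²) tonnes — a
catch-scaled anchor; log q_pre, log q_post improper uniform; σ_obs ~
Half-Normal(0.3); initial depletion ψ = B₁/K ~ Uniform(0.2, 1). These
are weakly informative and support parameter recovery on 40-year
series.

**Sampler.** Because q enters the likelihood purely as a location
shift of the log-CPUE residuals and carries a flat log-scale prior, it
is integrated out analytically per regime block; the adaptive
random-walk Metropolis chains (4 by default) then explore only
(log r, log K, log σ, ψ), and each retained draw's catchabilities are
re-sampled from their exact Gaussian conditionals,
log q_j ~ N(mean residual_j, σ/√n_j). This removes the q–K ridge
which otherwise makes a plain random walk mix orders of magnitude too
slowly (effective sample sizes of tens instead of thousands for the
same budget). ψ is sampled on its natural bounded scale (proposals
outside [0.2, 1] rejected) rather than logit-transformed, because
posteriors concentrating at ψ → 1 (unfished start) would otherwise
push the chain onto an unbounded flat plateau. Warmup re-estimates the
proposal covariance from the recent half of the warmup history every
200 iterations and tunes a global scale toward 0.2–0.4 acceptance; a
short Nelder–Mead mode search positions the chains initially, with the
K starting value walked upward until the catch history is supportable.
Fits are gated on split R-hat < 1.05 and bulk ESS ≥ 400 for every
parameter (arviz diagnostics); a failed gate doubles warmup and draws
up to twice before raising an error that carries the diagnostics.
Default run length is 4 chains × (2000 warmup + 4000 draws), which on
the simulated 40-year stocks yields effective sample sizes in the
thousands in about a second per fit.

**Numerical details.** Biomass is floored at 10⁻⁶ K during projection;
a floor hit zeroes the likelihood (−∞) rather than truncating
silently. The biomass update is computed as B + (growth − catch) so
that exact equilibria (catch equal to surplus production) hold
bit-exactly. CPUE gaps are skipped in the likelihood; catch must be
complete. The fit statistic R² is the squared correlation of observed
vs posterior-median-predicted **log** CPUE (the scale on which the
error model lives), requiring ≥ 3 observed years. MSY and final
depletion are derived per posterior draw and stored alongside the raw
draws, recomputable from them.

## Risk of overfishing

Habitat loss is represented as a sudden reduction of r by p %,
applied to r only (K unchanged): the reference point becomes
MSY(p) = r(1 − p/100)K/4 **per posterior draw**, and the risk at p is
the posterior fraction of draws with recent catch strictly above
MSY(p). "Strictly" means ties count as not overfishing; under any
continuous posterior ties have measure zero. Evaluating per draw (not
at posterior medians) is the proper Bayesian reading of "probability
that catch exceeds MSY". Recent catch is the arithmetic mean over a
reference window (default 2016–2018; synthetic stocks use their last
three years). The curve over p = 0…100 in 1 % steps is exactly
non-decreasing, equals the direct MSY-exceedance probability at p = 0,
and equals 1 at p = 100 whenever recent catch is positive. No forward
re-projection of biomass under reduced r is attempted — the metric is
a static reference-point comparison.

## Synthetic data: what it emulates, and what it does not

The generators produce the four pipeline inputs with known ground
truth. Defaults are the study conditions: 57 commercially fished taxa,
the nine Queensland reporting ("Mapstone") regions, a 2008–2017
analysis decade, and 40-year stock series ending in 2018.

- **Habitat evidence**: each species draws a true category (default
  prevalences 0.50/0.30/0.15/0.05 for categories 1–4, a realistic mix
  in which most catch is non-reef) and emits one defining evidence row
  plus 0–2 corroborating lower-level rows. Classifying the table
  recovers the truth exactly *by construction* — this validates the
  plumbing, not the ecological judgement embedded in real evidence.
- **Catch tables**: the expected category-3 share in region i is
  baseline + slope × reef_pct_i (default slope 2.0 percentage points
  per point of reef area, clipped to [0, 100]), the remainder split
  among the other categories by prevalence; each taxon-region cell
  gets one multiplicative lognormal noise factor (default CV 0.1,
  mean 1, constant across years). Real catch data have year-to-year
  variation, spatial autocorrelation and reporting-resolution quirks
  that this deliberately omits.
- **Stock series**: forward Schaefer dynamics (default r = 0.3/yr,
  K = 5000 t, σ_obs = 0.05, q = 10⁻³) under a configurable harvest
  pattern. The default "up_down" pattern (harvest rate rising to
  0.8 r at 60 % of the series, then easing to 0.3 r) is used because
  one-way harvest histories leave r and K weakly identified and
  parameter-recovery experiments need informative contrast; "one_way"
  and "constant_fraction" (rate r/2, which holds a half-depleted stock
  exactly at MSY equilibrium) are available, as is an explicit catch
  vector. Configurations driving biomass below 10⁻³ K are rejected
  with the offending year named, keeping simulated data inside the
  fitted model's support. The simulator emits an already-standardised
  CPUE index; no CPUE standardisation step is modelled.

All generator randomness derives from deterministic sub-streams of one
master seed, so outputs are bit-reproducible.

Because the synthetic data are generated by the same model family that
is fitted, passing recovery tests demonstrates the correctness of the
inference machinery — not that real CPUE obeys Schaefer dynamics, nor
that real evidence tables are as clean as simulated ones.

## Test problem sizes

The recovery experiments run at sizes chosen to balance statistical
power against desk-scale runtimes: 20 simulated stocks for parameter
recovery (posterior medians of r and K within ±30 % of truth in
≥ 16/20; 95 % depletion intervals covering truth in ≥ 90 %), one
regime-change stock (posterior median q_post/q_pre in [1.5, 2.5] for a
simulated doubling), 50 replicates for the regression-slope coverage
study, and 1000 random instances for the projection oracle. The full
suite runs in under a minute on one CPU.

## Known limitations

- The classification is deterministic and ordinal; no probabilistic or
  fuzzy categories, and no per-life-stage labels.
- The regression ignores spatial correlation between neighbouring
  regions and treats percentages as unconstrained Gaussians; with
  shares near 0 or 100 the model can place mass outside [0, 100].
- The production model has no age structure, no recruitment lags and
  no process error in estimation; stocks with strong lag dynamics will
  be summarised optimistically.
- The risk metric compares a fixed recent catch to a shifted reference
  point; it does not simulate management response or future biomass.
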