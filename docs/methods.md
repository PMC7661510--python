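# Methods

`reefadapt` implements a seascape-genomics workflow for coral reef systems:
it converts daily sea-surface-temperature (SST) and surface-current rasters
plus coral SNP tables into per-reef indicators — bleaching-alert frequency,
probability of heat-stress adaptation, and dispersal connectivity — and
tests whether those indicators explain coral-cover change. Every stage can
be exercised on synthetic archipelagos with recorded ground truth, so the
whole pipeline is testable without satellite or genomic downloads.

## Thermal stress (`reefadapt.thermal`)

Heat stress follows the Coral Reef Watch accumulation logic. Per reef cell:

- **Monthly climatology** — mean SST per calendar month (missing days
  excluded); the **maximal monthly mean (MMM)** is the warmest month's
  climatological mean, the bleaching reference temperature.
- **Hotspot value** — `SST(t) − MMM` retained only when the excess is at
  least 1 °C (inclusive), else 0.
- **Bleaching alert** — a day is under alert when the cumulated hotspot
  over the trailing 84-day window is positive. Because hotspots are
  non-negative this is equivalent to "any hotspot day within the window".
- **BAF_year** — flagged days / observed days per calendar year;
  **BAF_overall** — unweighted mean of BAF_year over the valid range.

Conventions the definition leaves open, and the choices made here:

- The 84-day window *includes the current day* (`alert_flags` is
  configurable via `window_days`; the inclusion convention is fixed, as the
  accumulation style implies it).
- The climatology baseline defaults to the full series. The first four
  calendar years are excluded from BAF (a short record biases the MMM);
  `first_valid_year` is configurable and defaults to the fifth year.
- Days with fewer than 84 days of history use the available prefix. These
  warm-up days all precede the first valid BAF year under the defaults.
- Missing SST days are excluded from climatology means; a day is flagged if
  any non-missing hotspot in its window is positive.
- Monotonicity: *given the MMM*, hotspots, flags and BAF are monotone
  non-decreasing in SST. Raising an SST value can also raise the MMM
  through the climatology, which is why the property tests hold the MMM
  fixed.
- The synthetic calendar has 365-day years (no leap days) so planted alert
  days have closed forms. Real-data ingestion attaches true calendars to
  the same containers.
- For survey records, `BAF_previous_year` is BAF_year(survey year − 1) and
  the record-level `BAF_overall` averages BAF_year from the first valid
  year to two years before the survey.

## Connectivity graph (`reefadapt.graph`)

Sea pixels form a directed graph; each ordered adjacent pair (i→j) gets
cost `L / c(i→j)` with `c(i→j) = max(0, w̄·d̂) + ε`, where `L` is the
pixel-center distance (km), `d̂` the unit step direction, `w̄` the mean of
the two pixels' current vectors (m/s), and `ε > 0` a base conductance
(default 0.01 m/s) representing transport that does not follow the mean
current. Downstream steps are cheap; a step dead against the current costs
at most `L/ε`. This functional form is this package's codification of
"transition costs inversely proportional to transition frequency"; `ε` is
the main modelling knob and only cost *ratios* matter (units are
dimensionless "cost units").

Other choices: 8-neighborhood by default (diagonals at `L·√2`;
4-neighborhood available); the static field is the temporal mean of the
daily current record; each reef cell is represented by the sea pixel
nearest its centroid, keeping the cost matrix at cells × cells; unreachable
pairs carry `+inf` rather than being dropped. Bilinear refinement of the
current field preserves source-pixel centers (odd factors) and is exact for
affine fields; near coasts it interpolates from nearest-sea values before
re-masking. Shortest paths are Dijkstra passes (`scipy.sparse.csgraph`);
border distances use multi-source passes on the forward and transposed
graphs. Row index increases northward, column index eastward.

## Connectivity indices (`reefadapt.indices`)

For a threshold CDt, **OCI** (outbound) of a cell is the total area (km²)
of the *other* reef cells with `d(i→j) ≤ CDt`; **ICI** (inbound) uses
`d(j→i) ≤ CDt`. The focal cell's own area is excluded (configurable).
`select_cdt` codifies "maximize the neighborhood without border effects":
the largest multiple of the granularity (default 100) strictly below the
smaller of the two border minima. Applied to border minima of 836 and 801
units this yields 800.

With equal cell areas `ΣOCI = ΣICI` (each ordered qualifying pair
contributes once to each side); with unequal areas the *pair counts* match
while OCI sums destination areas and ICI source areas. The synthetic grids
use uniform areas, so tests assert the sum identity there and the count
identity in general.

## Adaptation models (`reefadapt.adaptation`)

Per putatively adaptive genotype, presence (carrying ≥ 1 copy of the
associated allele; dominant coding) is modelled as
`logit P(presence) = a + b·BAF_overall`, fitted by Newton iteration on
per-site binomial counts with an optional ridge `λ‖(a,b)‖²`
(default λ = 1e-4, enough to survive quasi-separation at extreme sites;
λ = 0 reports complete separation as non-convergence). Skill is evaluated
by **leave-one-population-out CV**: refit without one site, predict that
site's genotype frequency, and correlate predicted with observed
frequencies (Pearson) across sites; genotypes with zero observed frequency
variance have undefined r and are excluded from the per-species mean ± sd
(aggregated over genotypes). The **random-genotype baseline** runs the
same CV on genotypes sampled from the neutral pool (with replacement when
the pool is smaller than the requested draws).

The **pooled model** is a Bernoulli-logit mixed model with fixed intercept
and BAF slope and crossed random intercepts for genotype, individual and
species, estimated by maximizing a Laplace approximation to the marginal
likelihood. The inner mode over random effects is found by Newton steps on
a variance-scaled system (`M = I + D^{1/2} Z'WZ D^{1/2}`), which stays
well conditioned as any variance collapses; at zero variance the objective
reduces exactly to the plain logistic likelihood. The outer optimization
(L-BFGS-B over fixed effects and log-sd's, bounded in [−8, 3]) starts from
the plain logistic fit at two variance levels (0.5 and ≈0) and restarts
from jittered points on non-convergence. A random factor with fewer than
two levels, or with no replicated level, is pinned at variance 0 with a
note in the fitting log. **PA_HEAT** is the population-level prediction
`expit(â + b̂·BAF)` (random effects at zero); a strictly monotone transform
of BAF.

## Genetic structure validation (`reefadapt.structure`)

Response: per-site minor-allele frequencies (minor allele defined globally
across sites; sites need ≥ 5 samples), Hellinger-transformed
(`sqrt(y/rowsum)`), then the leading principal components cumulatively
explaining 80 % of the variance. Predictors: distance-based Moran's
eigenvector maps of the between-site least-cost distances, computed with
the classical PCNM construction — truncate at the longest
minimum-spanning-tree edge `t`, replace larger entries by `4t`,
double-center `−½D²`, keep positive-eigenvalue eigenvectors scaled by
`√eigenvalue`. Directed site-to-site distances are symmetrized by the
arithmetic mean of the two directions (min/max available) before dbMEM.

Forward selection over the dbMEMs uses (1) a *global pre-test*: the full
model must be significant under the permutation test before any step —
without it, picking the best of k candidates with an unadjusted marginal
test inflates the null selection rate far above α; (2) per-step admission
when the marginal permutation p ≤ α **and** the running adjusted R² does
not exceed the full model's (double stopping rule). The permutation ANOVA
permutes raw rows of Y (unrestricted), with
`pseudo-F = (explained SS/m)/(residual SS/(n−m−1))` and
`p = (1 + #{F* ≥ F})/(n_perm + 1)`; 999 permutations plus the observed
statistic give a 1000-permutation test.

## Coral-cover models (`reefadapt.cover`)

Cover rates in (0,1) are modelled by beta regression with logit mean link
and a single precision φ, plus a Gaussian random intercept per station
(surveys at one station across years are not independent). The marginal
likelihood integrates the station effect with adaptive Gauss–Hermite
quadrature (15 nodes; stations factorize because the random effect is
nested). Station modes are found by damped Newton with numerically
differentiated curvature, clipped at `0.5/σ²`; below σ = 1e-7 the model is
evaluated as a fixed-effects beta regression, and the likelihood at σ → 0
matches `statsmodels` `BetaModel` to 1e-4 (tested). Standard errors come
from the numerical observed information of the marginal likelihood; Wald
`p = 2(1 − Φ(|z|))`; `AIC = 2k − 2 logLik` with k counting fixed effects,
φ and the station variance. Covariates are standardized to mean 0, sd 1;
interaction terms are products of standardized covariates. Cover values of
exactly 0 or 1 are squeezed by `(y(n−1)+0.5)/n` when `squeeze=True`, else
rejected. Model sets: four univariate fits (BAF_prev, PA_HEAT, OCI, ICI)
and three interaction fits with fixed effects {BAF_prev, BAF_prev × M} —
deliberately *without* the moderator main effect, matching the modelling
design this package reproduces — ranked by AIC. The significance threshold
is 0.05 with no multiplicity correction.

## Synthetic seascapes (`reefadapt.synthetic`)

What the generators emulate, and their defaults:

- **Reef grid** — random connected region growth (8-adjacency) on a
  rectangular raster; uniform cell areas (default 25 km², 5 km pixels).
- **SST** — sinusoid (baseline 26 °C, amplitude 3 °C, maximum in
  mid-February so the MMM falls in month 2) plus rectangular heat
  anomalies per cell plus iid Gaussian noise (default sd 0.1 °C). The
  planted alert days are derived from the noise-free signal by an
  independent implementation of the thermal definitions (sliding-window
  maximum instead of running sums), so agreement with the thermal module
  is a genuine cross-check.
- **Currents** — constant drift (default 0.05 m/s westward, the prevailing
  transport of the emulated region) plus iid noise.
- **Genotypes** — adaptive presence is Bernoulli with
  `expit(intercept + slope·BAF_site)`; neutral genotypes are Bernoulli
  with BAF-independent frequencies drawn once per genotype from U(0.1, 0.9).
- **Surveys** — station-level covariates from a correlated latent Gaussian:
  PA-like values through a logistic transform, connectivity indices as
  *bounded* logistic-normal draws (indices are physically bounded by the
  reef area inside the dispersal neighborhood; unbounded draws produce
  high-leverage designs no coastal survey network would yield), and yearly
  BAF_prev around a station-specific thermal propensity. Cover is
  `Beta(μφ, (1−μ)φ)` with `logit μ` = standardized fixed effects + station
  intercept. Defaults: intercept −0.85 (≈30 % cover), BAF_prev effect
  −0.06 (the reported standardized coefficient), station sd 0.5, and
  precision φ = 18 — calibrated so that fitted coefficient standard errors
  reproduce the reported uncertainty scale (SE ≈ 0.027 at ≈600 records
  over 60 stations).

What the generators do **not** emulate: real geography and bathymetry,
cloud-gap structure in SST, seasonally varying currents, linkage between
SNPs, spatial autocorrelation of genotypes beyond the BAF cline, and
temporal autocorrelation of cover beyond the station intercept. Passing
tests therefore demonstrate the correctness and calibration of the
*methods*, not the realism of any particular coral system.

## Problem sizes in the test suite

Simulation-based tests use sizes chosen to make the checks sharp but
cheap: logistic recovery at n = 2000 over 200 replicates; CV contrast over
40 replicates of 8 sites × 25 individuals; RDA calibration over 400 null
replicates of 20 sites with 199 permutations; cover-model recovery over
100 replicates of ≈600 records across 60 stations. The mixed-model AIC
selection check uses the generator defaults above; its planted interaction
effect (+0.07) gives a detection z ≈ 2.5, so the AIC preference for the
true interaction model is expected in roughly 80–85 % of replicates — a
deliberately marginal regime that mirrors the modest effect sizes typical
of reef survey data.

## Known limitations

- The conductance formula is one defensible codification of
  current-driven transition costs; Lagrangian particle tracking or
  seasonal spawning-window graphs are out of scope.
- The Laplace approximation for the crossed-random-effects Bernoulli model
  can bias variance components at few levels per factor (a generic
  limitation of Laplace for binary data); fixed effects are accurate in
  the regimes tested.
- `BinomialBayesMixedGLM` (variational) would be an alternative route for
  the pooled model; it is used only as a cross-check because its priors
  shrink variances differently.
- dbMEM/RDA assume finite, symmetric distances; unreachable site pairs
  abort rather than being imputed.
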