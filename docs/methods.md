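# Methods

## Generative model

Time is an integer day grid with day 0 = birth; week *w* spans days
[7(w−1), 7w). One tissue is one `TissueSchedule`:

* **Influx** g(t) ≥ 0: expected number of new Tregs entering the pool on day
  t, abstracting thymic output, peripheral conversion and colonization.
  Units are arbitrary; the model works in relative masses.
* **Division** π(t) ∈ [0, 1): per-cell per-day division probability, shared
  by all cohorts alive on day t.
* **Loss** δ ∈ [0, 1): per-day loss probability, depending only on a cell's
  birth day — δ_res for cohorts born before the residency cutoff day D,
  δ_flux for cohorts born on/after D. δ_res > δ_flux (faster loss of the
  early cohort, "anti-residency") is allowed and logged.

The expected mass of the cohort born on day b evolves as
N_b(t+1) = N_b(t)·(1 + π(t) − δ_b), with N_b seeded by g(b). Influx arriving
on the analysis day itself is not yet part of the measured pool; this
convention makes the calibration below exact.

**Labeling.** A pulse is a first-dose day plus an 8-day activity kernel
k(1..8) (default trapezoid: full weight days 1–5, linear decay to 0 over
days 6–8; the two tamoxifen doses are folded into this one envelope) and a
per-tissue efficiency E. A cell present before the window starts is tagged
with probability E; a cell born on kernel day j only sees the remaining
activity, giving E·Σ_{d≥j}k(d)/Σ_d k(d); cells born after day 8 of the
window are never tagged. The tag is heritable and neutral: division and loss
act identically on tagged and untagged cells, so a cohort's tagged share is
fixed once the window closes.

**Observation.** A mouse's true tagged fraction is Beta-distributed around
the expectation-engine fraction with concentration κ (default 50 — chosen to
reproduce the mouse-to-mouse scatter of published flow data, roughly ±7
points at mid-range fractions); the observed count is Binomial over the
tissue's sampled-cell number (default 2000). The recent-division marker
(Ki67-like) is modeled as "divided within the trailing `window_days` days"
(default 4 days, a literature-typical persistence for the marker): a cohort
born on day b is positive with probability 1 − Π(1−π(s)) over the window
truncated at b, and cohorts are weighted by mass.

## Scenario calibration

The bundled scenario declares *observables*, not influx vectors:

* `cumulative_targets`: the expected tagged fraction (unit efficiency) of
  the 8-week pool for pulses in weeks 1..6 — the published cumulative
  generation values per tissue (e.g. skin 60%/85% by weeks 1/2; lymph nodes
  25% by week 2, 50% by week 4; colonic GATA3⁺ 62% vs RORγt⁺ 12% by week 2).
  Week 1–2 values and several week-4 values are stated in the source text;
  remaining weeks are interpolated from the published curves.
* `division`: π(t) piecewise constant, transcribed from Ki67⁺ time courses
  via K = 1 − (1−π)⁴ (4-day window): e.g. skin π = 0.40/day before day 14
  (Ki67 ≈ 85–87%), decaying to 0.026/day in adults (Ki67 ≈ 10%).
* loss rates and the residency cutoff, set from the aging observations:
  skin residents lose mass at a net 0.004/day (60% → 35% between weeks 8 and
  28, the two-point rate ≈ 0.027/week), lymphoid "flux" cells at a net
  1.2%/day while the early resident cohort is stable (week-1 label ≈
  constant at 10–15%).

Because cohorts do not interact, every expected mass is *linear* in the
influx. The per-week neonatal influx levels (weeks 1–8; weeks 7–8 share the
post-week-6 tail equally) therefore solve an 8×8 linear system that makes the
model's expected tagged fractions equal the declared targets exactly, with
the 8-week pool normalized to 1; nonnegativity of the solution is checked
and infeasible target profiles are rejected. The adult influx level (day 56
onward) is then chosen so the total pool mass is stationary between the
8- and 28-week analyses. Calibration runs at scenario load in milliseconds.

One deliberate inconsistency: for VAT, the published week-1 label decline
(≈37% → 10% between 8 and 28 weeks) cannot coexist with strong adult label
retention under resident-favoured retention in a stationary pool, so VAT is
modeled with δ_res > δ_flux (neonatal cohort replaced by early-adult cells,
slow later renewal). The adult-pulse VAT retention is consequently only
qualitatively reproduced. The whole-colon schedule and the sum of the three
colonic subset schedules are likewise independent models, not constrained to
agree.

## Estimators

**Composition** (`PoolCompositionModel`): per-mouse fractions
n_tagged/n_cells; group summary = median across mice (the convention of the
source figures; mean behind `stat="mean"`); efficiency correction
min(F/E, 1) per group; weighted isotonic projection (pool-adjacent-
violators, weights = mice per group) enforcing the structural monotonicity of
cumulative labeling; differencing into per-week increments plus the
"generated later" tail. Uncertainty: percentile bootstrap (default B=1000,
α=0.05) resampling mice with replacement within groups and rerunning the
whole pipeline. The order correct→isotonic→difference treats efficiency as a
group-level measurement artifact and monotonicity as a structural truth.
Waffle rendering uses largest-remainder (Hamilton) apportionment of 100
cells, remainder ties going to the earlier week.

Known small-sample property: percentile intervals around a median of 8 mice
are coarse (few distinct resample values), so per-week coverage of the
95% CI can dip to ~85% for the first-week increment while pooled coverage
across weeks stays above 90% (measured over 100 simulated replicates).

**Turnover** (`LabelDecayModel`): weighted least squares for
F(t) = π_res + (F₀ − π_res)e^{−r(t−t₁)} with box constraints
0 ≤ π_res ≤ F₀ ≤ 1 (enforced by the parametrization π_res = s·F₀, s ∈ [0,1])
and r ≥ 0, five deterministic starts (r ∈ {0, 0.05, 0.2, 1, two-point
estimate}), best SSE kept. Fitted rates below 1e−6/week are reported as
r = 0 with plateau = F₀ (indistinguishable from flat over a 20-week span);
half-life = ln2/r, ∞ at r = 0. `persistence_ratio` assumes a constant pool
between the two observations and logs that assumption on every call.

**Phenotype** (`paired_marker_test`): Wilcoxon signed-rank on within-mouse
differences of marker-positive fractions (both arms come from the same
sample). Zero differences are discarded by default (Pratt handling behind a
flag). The null tail is exact for ≤25 retained pairs, computed by convolution
over doubled midranks — exactness is preserved under tied magnitudes, where
standard exact implementations fall back to approximations. Differences are
rounded to 12 decimals before ranking so floating-point subtraction cannot
split a genuine tie. Above n=25 a continuity-corrected normal approximation
with tie-corrected variance is used. Multi-marker reports adjust p-values by
Benjamini–Hochberg.

## What the synthetic data do and do not emulate

Emulated: per-week generation influx with neonatal bias; finite labeling
window with per-tissue efficiency; cohort-dependent retention (residency)
versus continuous renewal; proliferation-marker kinetics; mouse-level
overdispersion and finite flow sampling; the colonic transcription-factor
strata; tagged-vs-untagged marker contrasts (fixed per-tissue positive
fractions with Beta jitter).

Not emulated: inter-tissue migration and recirculation, spatial structure,
absolute pool sizes (only relative masses), age-dependent efficiency,
litter/batch effects, marker correlations within mice, and any
transcriptome-level structure. Passing tests therefore demonstrate that the
inference pipeline recovers the generative kinetics under realistic sampling
noise — not that the biological model is mechanistically complete.

## Problem sizes and determinism

Default study conditions: 6 pulse weeks × 8 mice × (7 tissues + 3 colonic
subsets), 2000 sampled cells per mouse (1000 within subsets), analysis at
8 weeks; aging and adult-pulse designs with 8 mice per timepoint. Because a
single 8-mouse cohort at κ=50 carries 2–3.5-point standard deviations on the
recovered percentages, headline quantities in the acceptance script and
tests are averaged over 5 independently simulated experiments — the same
pooling of independent experiments that underlies the published group
values. All randomness flows through a single seeded generator per
simulation; bootstrap and simulation seeds are derived from one root seed,
and pipeline outputs are byte-identical given the same configuration and
seed.
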