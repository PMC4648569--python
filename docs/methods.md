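# Methods

This note documents the model as implemented, the parameter conventions,
the design decisions taken where the published description leaves the
design open, and what the synthetic landscape generator does and does not
emulate.

## Model structure

One simulated generation is one year.  Its phases:

1. **Emergence.**  The generation's females are assigned emergence days by
   a multinomial draw over the 54-day season, with day probabilities
   proportional to a Beta(1.75, 8.28) density evaluated at day midpoints.
   Each female draws an integer lifespan `ceil(−1/ln x)` (x ~ normal on
   (0, 1), resampled outside the interval, minimum one day).  Lifespan
   absorbs both death and emigration.  An emerging female mates immediately
   with a male drawn uniformly *with replacement* from the generation's
   surviving male pool; males have no movement or phenotype of their own.
2. **Daily flight.**  An active female repeats: read the step length from
   her current cell (6 cells if it holds an available host — the short
   oviposition-search step — else 8/10/15 cells by wet/intermediate/dry
   aridity); move that distance in a uniform-random direction with specular
   reflection at the habitat edges; if the landing cell holds an available
   host she accepts (natives always; the non-native only with the
   acceptance allele) and lays one egg with probability 0.75.  She stops
   after the step on which her cumulative distance first reaches the day's
   truncated-normal flight budget, or as soon as her daily egg load is
   exhausted.  Cells hold unlimited eggs; unlaid eggs do not carry over.
3. **Phenology.**  The season splits into trimesters of 18 days.  All five
   host species are available in trimester 1; *Boechera* and *Descurainia*
   senesce in trimester 2; only *Cardamine* remains in trimester 3.
   Senescent hosts count as non-hosts for both movement and oviposition.
4. **Turnover.**  Each egg survives to adulthood independently (0.00651 on
   native hosts, 0 on the non-native).  Surviving daughters start the next
   season in their natal cells; surviving sons form the mating pool.
   Female immigrants arrive at rate 0.07 of the surviving female count
   (floor plus a Bernoulli on the fraction), start on random native-host
   cells, and carry alleles at the focal population's current frequency
   (configurable); having mated outside the habitat, their mates are drawn
   at Hardy–Weinberg proportions at the same frequency.
5. **Census.**  N_t and the allele frequencies are recorded on the emerging
   adult pool (post-survival, post-immigration).  R and G are geometric
   means of successive ratios, truncated at the first zero.

The daily-movement loop is JIT-compiled (numba); the spec-level operations
(`fly_one_day`, `run_flight_season`) are thin wrappers over the same
kernel, so there is a single behavioural code path.

## Parameter conventions

All defaults live in `LifeHistoryParams` and are overridable via JSON.
Two published parameters are written as "(mu, v)" without stating whether
`v` is a variance or a standard deviation.  The package fixes them by
feasibility of the published calibration (a stationary population, R = 1,
without the non-native host):

* **Daily flight distance** N(4134.54, 6.43e7), bounds 16.38–28800 m:
  6.43e7 is only plausible as a variance (sd ≈ 8019 m).  Sampling is by
  rejection, not clipping; the resulting truncated mean is ≈ 8.1 km/day.
* **Lifespan** x ~ N(0.86, 0.04): read as **sd = 0.04**.  Under the
  variance reading (sd = 0.2) the expected lifetime potential fecundity is
  at most ≈ 262 eggs, below the ≈ 287 required for stationarity at the
  fixed juvenile survival — unreachable on any landscape.
* **Daily egg load** 483.7 × lognormal-density(age; 1.69, 0.66): the scale
  spreads the lifetime potential (≈ 484 eggs) over ages; 0.66 is read as a
  **log-variance** (log-sd ≈ 0.812).  Under the log-sd reading the
  potential (≈ 340) combined with the saturation floor described below
  would force R ≥ ~1.02 on any landscape with the observed host abundance —
  also inconsistent with stationarity.  Both flags can be switched
  (`lifespan_second_moment_as`, `egg_second_moment_as`).

A numerical corner: the uncapped expectation of `ceil(−1/ln x)` diverges
logarithmically as x → 1, so distributional tests compare *capped*
expectations (E[min(L, cap)]) against an exact piecewise normal-cdf sum;
in simulation the season caps activity at 54 days regardless.

## The synthetic landscape and its calibration

`generate_fixture_landscape` stands in for the observed field map (which is
an external deposit).  It emulates: a rectangular 16.1 ha habitat on a
0.25 m grid; ~8% host cover (1.3 ha); four native crucifers with
species-characteristic patch sizes; small scattered non-native patches at
2.7% of host cells (~60 patches); block-structured wet/intermediate/dry
zones; and species segregated by moisture (*Cardamine* forms streamside
stands in the wet zone, *Boechera*/*Descurainia* occupy intermediate
meadows, *Draba* the dry zone).

The published parameterisation is *defined* by demographic stationarity:
juvenile survival was set so that the population neither grows nor declines
when the non-native host is absent.  With survival pinned at 0.00651, that
property depends on landscape structure the original description does not
quantify.  Two structural facts dominate:

* females are born inside host patches and daily flight budgets are large,
  so egg laying **saturates** whenever the natal neighbourhood retains
  available hosts — early-season reproduction is insensitive to patchiness;
* the binding loss is **phenology**: females emerging (or surviving) past
  trimester 1 whose natal species has senesced must reach the *Cardamine*
  refuge by random-walk search (~140 m net displacement per day), losing
  whole days of laying.

The generator's free structural parameters were therefore calibrated once
to the stationarity property and frozen: a 100 m × 1610 m corridor with
the moisture gradient along its length, species mix
Boechera 0.37 / Cardamine 0.21 / Draba 0.05 / Descurainia 0.37, stratified
patch placement along the corridor, and mean-reverting zone boundaries.
Across six independent map seeds the zero-cover replicate-mean R is
0.997–1.005.  The calibration touched only these structural parameters —
never the life-history values, tolerances, or simulation seeds.

What the fixture does **not** emulate: the exact observed patch mosaic and
its metric values (distances on the deposit reach ~150 m between the trap
and native hosts; the fixture's observed-cover layout has shorter
distances), terrain, and any spatial correlation between aridity and the
trap.  Passing tests on the fixture therefore demonstrate the model's
mechanisms and calibrated demography, not cell-level reproduction of the
deposited maps or of statistics that depend on them (e.g. the exact
regression coefficients of the 40-scenario experiment).

## Scenario generation

Placement modes rebuild the non-native layer from scratch (natives
untouched): `scatter` allocates single-cell patches with a spacing
constraint; `squares`/`elongated` place axis-aligned blocks of the target
total cover (squares have compactness exactly 1 when unobstructed);
`enlarge` dilates the existing patches shell by shell about their original
locations, overwriting natives in conflict and merging neighbours, exactly
as the high-cover scenarios were constructed.  `close`/`far` placement
relative to native hosts (and mutually) restricts candidate cells by a
distance-transform band; realized attributes are always re-measured with
`compute_spatial_metrics` rather than trusted from the recipe.

Patch geometry conventions: adjacency is 4-connected (the perimeter
formula counts edges); periphery distances are continuous-geometry
distances between cell squares (touching patches are 0 m apart; an
independent polygon-based oracle confirms to 1e−9); `dist`/`thdist` are
unweighted means over trap patches; `thdist` is undefined (NaN) with fewer
than two patches.

## Statistics

`ols_t_test` (classical OLS t-tests, statsmodels), `spearman_rho`
(average-rank Spearman, scipy) and `sensitivity_analysis` (one-at-a-time
±3% perturbations of lifespan mean, immigration, oviposition probability,
initial allele frequency, juvenile survival and initial size; 50 females,
30 generations, 50 replicates by default) mirror the published analysis
workflow.  The initial-size perturbation of ±3% of 50 rounds to 48/52.

## Problem sizes and determinism

End-to-end stochastic checks and the acceptance script run 50 replicates ×
30 generations per cover level on the full-size fixture — the movement
kernel's cost scales with butterfly-days, not cells, so the 16.1 ha grid
costs the same as a toy map.  Replicate seeds derive from a master seed by
a counter-based scheme (`SeedSequence([master, i])`), so scenarios are
comparable under matched seeds and identical configurations reproduce
bit-identical trajectories.

## Known limitations

* Males neither move nor die within a season; mate choice is uniform.
* No within-season density dependence; a growing population (R > 1) grows
  without bound, so long horizons on easy landscapes are expensive.
* Immigrant genotype frequency tied to the focal population is an
  assumption (supported by the high observed gene flow); a fixed source
  frequency is available via `immigrant_p`.
* Evolution of larval ability to use the trap plant, mutation, and
  multi-locus architectures are out of scope.
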