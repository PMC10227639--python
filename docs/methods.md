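# Methods

## The estimation problem

Scat contents are a biased record of what an animal ate: easily digested
foods leave little residue, so their share of fecal volume under-represents
their share of the ingested diet. The standard remedy in bear diet studies
is a per-ingredient *correction factor* (CF), the grams of dry matter
ingested per millilitre of fecal residue, estimated from feeding trials.
Given the visually assessed fecal volume percentages `Vf_i` of each
identified ingredient in a scat, the estimated dietary content is

    EDC_i = 100 · Vf_i · CF_i / Σ_j Vf_j · CF_j        (% of ingested DM)

a closed composition over ingredients. Because closure absorbs any common
scale, EDC is invariant to multiplying all CFs by a positive constant; only
CF *ratios* matter.

Unidentifiable matter ("miscellaneous") has no defensible CF. We give it
the mean CF of the identified ingredients present in the same scat
(configurable to a fixed constant), use the resulting share only to apply
the omission rule — scats with strictly more than 5% miscellaneous EDC are
dropped, since no nutrient composition can be attached to that fraction —
and in kept scats remove the residual miscellaneous share and re-close the
EDC over identified ingredients before any nutrient computation. The same
convention is used in the generator's forward model, which makes the
EDC→Vf→EDC round trip exact rather than approximate.

## Nutrient profiles and the two bases

Ingredient compositions are proximate-analysis values on a dry-matter
basis: crude protein (CP), crude fat (EE), ash, crude fiber, and total
dietary fiber (TDF). Digestible carbohydrate (NfE) is computed by
difference, with a kingdom-dependent rule:

* plants: `NfE = 100 − CP − EE − Ash − TDF` (TDF, the more complete fiber
  measure, takes priority over crude fiber, which is carried for reference
  only);
* vertebrates, invertebrates, and eggs: `NfE = 100 − CP − EE − Ash`.
  Animal "fiber" (hair, tendon, chitin) is proteinaceous and already
  counted inside CP, so subtracting TDF again would double-count it.

Diet-level nutrients are EDC-weighted sums, hence linear in EDC. A useful
audit identity follows: a plant-only diet satisfies
`CP+EE+NfE+TDF+Ash = 100` exactly, and a mixed diet exceeds 100 by exactly
the EDC-weighted animal TDF (the CP/TDF overlap). Both are asserted in
tests.

The metabolizable-energy basis uses unmodified Atwater factors
(16.72 kJ/g protein, 37.62 kJ/g fat, 16.72 kJ/g NfE; configurable). Fiber
and ash carry zero energy. ME fractions close to 100 by construction and
`me_density` (kJ/g DM) is reported alongside.

Two ratios summarize macronutrient geometry: the protein ratio
`CP:(EE+NfE)` (≈0.2 on an ME basis is the published ursid optimum for
pre-hibernation fattening) and the non-fat:fat ratio `(CP+NfE):EE`, an
index of glucogenic-substrate sufficiency: beta-oxidation of fat requires
oxaloacetate, which only protein or carbohydrate can supply. The DM-basis
floor of 3.55 is taken as a configured constant (its stoichiometric
derivation is upstream of this package); the ME-basis floor is *derived*,
never stored: with equal protein and NfE factors the basis change scales
the ratio by `16.72/37.62`, giving 1.58 from 3.55. Storing one constant
makes the two flags provably consistent — a diet is below the floor on one
basis iff on the other — and that equivalence is tested. Undefined ratios
(zero denominator) are explicit `None` sentinels, never infinities, so
they propagate as missing values in summaries.

Reporting convention: ratios to 2 decimals, percents to 1 decimal in
rendered tables; full precision is kept in all stored CSVs.

## Dataset compilation

Seasons follow the phenological pivots of the study system: spring from
den exit (per-year configurable; default April 15) to the end of moose
calving (May 20), summer May 21 – July 31 (first berry ripening), fall
August 1 – late October (default October 31). Assignment uses the
collection date. Reproductive classes are the six standard demographic
groups (lone adult female, adult male, female with cubs of the year,
female with yearlings, subadult female, subadult male); offspring flags
take precedence over the lone-female class. Subadults still accompanying
their mother are excluded outright (logged); spring scats are retained but
flagged `stats_eligible = False`, because spring is not represented in
every year or class — descriptive tables may include them, models never
do.

Vf closure: visual estimation implies rounding slack, so vectors whose sum
deviates from 100 by at most 0.5 may be renormalized (opt-in); larger
deviations always reject with a record-naming error.

## Statistical models

Each response (category EDC shares, nutrients on either basis, ratios) is
fit with a linear mixed model with a random intercept per bear, since
scats from one individual are not independent. Fixed effects are chosen by
backward stepwise elimination from {year, season, reproductive class} and
all two-way interactions: at each step the least significant droppable
term is removed if its likelihood-ratio p-value (nested ML fits, χ²
reference) exceeds α = 0.05, with marginality respected (interactions
removed before their main effects). The minimal adequate model is refit by
REML for reporting. Year is categorical throughout.

Post-hoc pairwise comparisons use estimated marginal means — predictions
averaged over a balanced grid of the other retained factors — with Tukey
adjustment through the studentized range distribution,
`p = P(Q_{k,df} ≥ |t|·√2)`, which reduces to the unadjusted t-test at
k = 2. Denominator df use the residual approximation `n − rank(X)` by
default, with a containment-style option (`n − rank(X) − (groups − 1)`);
fractional-df approximations tied to the REML covariance (e.g.
Satterthwaite) are not provided, and the df method is recorded in the
output metadata. With the cluster sizes these designs produce (hundreds of
scats, tens of bears), contrast p-values are insensitive to this choice
except in very small strata, where the containment option is the
conservative one.

Diagnostics: Shapiro–Wilk W on marginal residuals (seeded subsampling
above n = 4500, where the statistic's approximation degrades) plus a
fitted-vs-standardized-residual table for homogeneity plots. Group means
use the sample SD (n−1), matching ecological reporting convention.

## The synthetic generator

The generator emulates the *structure* of a multi-year scat collection
from a Scandinavian brown bear population, not any particular deposited
dataset. Hierarchy per scat: category shares from a per-(season, class)
Dirichlet over the six primary categories; ingredient shares within each
category from a nested Dirichlet; a per-bear Gaussian intercept
(SD 0.4) applied on the logit of the fruit share, creating the
within-bear correlation the random effect targets. Category means follow
the published seasonal pattern (fall ≈ 70% fruit with an oat tail, summer
split between insects, vertebrates, and vegetation) and the published
between-scat spread (total Dirichlet concentration ≈ 1.5–2, so many scats
sit near a single category, as real scats do). Class effects are injected
as multiplicative concentration tweaks: adult males trade berries for oats
in fall, females with cubs of the year avoid vertebrate-rich sites,
subadults eat more ants. A berry-failure year (2015 in the `study_shape`
preset) collapses the summer fruit concentration and boosts ants. Eggs
exist in the reference table but get zero weight in the presets; an
egg-dominated diet is the one composition in the table below the
non-fat:fat floor, and such scats are rare outliers best studied by
supplying an explicit configuration.

Observed fecal volumes come from the exact algebraic inverse of the EDC
transform (`Vf_i ∝ EDC_i / CF_i`, closed to 100), so the no-noise round
trip recovers truth to machine precision — the pipeline's core arithmetic
is testable without tolerance hand-waving. Optional multinomial resampling
of Vf (emulating visual subsample counting) adds consistency-checkable
noise: recovery error shrinks as the draw count grows. All randomness
derives from a single seed; output files embed it in a header comment.

The `study_shape` preset runs 55 bears over 2015–2018, each active in a
given year with probability 0.53 (≈116 bear-years) and contributing
1/3/4 scats in spring/summer/fall of active years — ≈900 scats, matching
the published scale. What passing tests on this preset do *not* show:
recovery of any real population's values (the illustrative reference table
is not the study's), robustness to non-multinomial observation error
(mis-identification, differential fragment counting), or behavior under
unbalanced designs more extreme than the preset's.

## Numerical choices and limitations

* EDC/Vf vectors keep explicit zeros so vectors stay alignable.
* Degenerate inputs fail loudly: all-zero Vf, pure-miscellaneous scats,
  zero-energy diets, constant residuals.
* Mixed-model optimization tries lbfgs, then derivative-free fallbacks
  (powell, nm), rejecting non-finite log-likelihoods; a boundary
  (near-zero) random-effect variance is kept with a warning rather than
  refit without the random effect.
* Selection calibration is a property of the per-term α = 0.05 test; with
  the full interaction candidate set, "factor retained anywhere" compounds
  several tests and exceeds α by design, which is why the calibration
  check in the test suite uses the main-effects-only candidate set.
* The misc-CF convention (scat-mean) is one of several defensible choices;
  it is configurable, flagged in output metadata, and only ever affects
  the omission decision, never nutrient values.
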