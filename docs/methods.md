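# Methods

## Problem and scope

The package models what adding zinc and folic acid to iodized salt would do
to nutrient adequacy in two Ethiopian regions chosen as the extremes of
micronutrient deficiency prevalence (Addis Ababa lowest, Somali highest).
The causal chain it implements is: single 24-h recall → one-day nutrient
intake → usual-intake distribution → discretionary-salt exposure →
fortificant delivery → prevalence of inadequate (< EAR) and excessive
(> UL) intake → constrained choice of addition rates. Survey weighting,
uncertainty intervals around prevalences, bioavailability modelling beyond
the low-bioavailability zinc EAR set, iodine accounting, and cost or
sensory feasibility are out of scope.

## Usual intake from one recall day

A single recall per person makes the within-person variance inestimable
from the data, so it is imputed externally. The imputed quantities (0.47
and 0.61 for zinc in children and adults; 0.72 and 0.89 for folate) are
interpreted here as the **ratio of within- to between-person variance on
the log scale**. Their source does not define their scale; the ratio
interpretation is the only one that transfers across nutrients with
different units, and it is exactly what the shrinkage construction needs.
The interpretation is isolated in one place (`fit_usual_model`) so a
different convention can be swapped in.

Given the ratio `r` and the observed log-scale variance `v_obs` of a
stratum, the decomposition is `v_between = v_obs/(1+r)`,
`v_within = v_obs·r/(1+r)`, and each person's usual intake is

    t_usual = μ + sqrt(1/(1+r)) · (t_obs − μ)

on the log scale. The shrunk distribution has variance exactly
`v_between`; rank order is preserved; with `r = 0` the observed day *is*
the usual intake.

Choices within this stage:

* **Transform** — natural log. Intakes are strictly positive and noise is
  multiplicative; the variance-ratio interpretation is cleanest there. A
  Box–Cox option was considered and deliberately not implemented: none of
  the downstream outputs (medians, cut-point prevalences) are sensitive to
  the choice for data of this shape, and a second transform would double
  the surface needing validation.
* **Back-transform** — plain `exp()` for per-person estimates. Medians and
  cut-point prevalences are invariant to any monotone mean correction, so
  a lognormal mean ("smearing") correction would change nothing that is
  reported; it is therefore omitted rather than carried as dead weight.
* **Covariates** — recall-day nuisance effects (weekend, sickness, unusual
  consumption) are removed by OLS on the log scale before shrinkage, and
  each observation is re-expressed as prediction-at-reference + residual.
  The reference day is "weekday, well, usual consumption"; predicting at
  the covariate means is available via `mode="mean"` because conventions
  differ between tools and neither is canonical. Stratifiers (region, SES,
  residence, sex) are never removed — they are what the reports stratify
  on. Constant columns are dropped with a warning.
* **Zeros** — a recorded zero intake is replaced by half the smallest
  positive value in the stratum (logged). Folate zeros on a single day are
  plausible; dropping them would bias the left tail that the EAR cut-point
  lives in.
* **Stratum floor** — 30 participants. Below it, estimation falls back to
  a region-collapsed model for that life stage (logged); in the default
  population this is triggered by the 24 Somali men, who are pooled with
  the 86 Addis men.

## Discretionary salt

Total adult salt intake (urinary-sodium-derived; sodium converted at
2.5 g salt per 1000 mg Na, the source surveys' own 2000 mg ↔ 5 g
equivalence, not the molar 2.542) is multiplied by the discretionary
fraction 0.9. Children have no urinary data; their salt is the group-mean
adult discretionary salt scaled by their individual energy intake relative
to the group-mean adult energy, the grouping being region by default
(configurable). Under the recommended scenario every adult is set to
5 g/d and children scale off that. Full precision propagates internally;
one-decimal rounding happens only in rendered reports, because the
reference design table's printed one-decimal values are themselves
internally inconsistent about when rounding was applied.

## Fortification

Delivered nutrient is linear in salt and rate. Folic acid is counted 1 μg
= 1 μg DFE (`dfe_factor = 1.0`) because the reference design arithmetic
does exactly that (6.7 g/d × 22 μg/g = 147 μg DFE); the conventional 1.7
factor for fortificant folic acid on food is one config switch away.
Fortificant is added to the *post-shrinkage* usual intake. Adding it to
observed days before adjustment would shrink the fortificant's tail
contribution too; since salt fortification is a daily, habitual exposure,
treating it as a constant shift of usual intake is the defensible default
(a pre-adjustment variant can be composed from the stage functions if
wanted). The delivered amount is kept as its own column so the two UL
conventions below can use different bases.

## Adequacy

EAR cut-point on the empirical distribution of per-person usual-intake
estimates; a closed-form lognormal variant exists for analytic
cross-checks. Excess uses total usual intake against the zinc UL but
fortificant-delivered folic acid against the folic-acid UL, following the
IOM convention that the folate UL applies to the synthetic form only.
Ties at exactly the EAR or UL count as adequate / not excess. The EAR for
women of reproductive age depends on physiological status: nonpregnant,
nonlactating women take the low end of the published range (zinc 9.9 mg/d,
folate 320 μg DFE/d), pregnant women the high end (13.7, 520), and
lactating women intermediate values pinned in the packaged CSV (zinc
11.8 mg/d — the range midpoint; folate 450 μg DFE/d — the IOM lactation
EAR). UL values are IOM defaults (zinc 7/40 mg/d child/adult, folic acid
300/1000 μg/d), shipped in the same CSV with a `source` column and fully
overridable; the constraint logic, not these constants, is the modelling
contribution.

## Rate optimisation

Exhaustive grid search (zinc 0–1.5 mg/g step 0.1; folic acid 0–50 μg/g
step 1 by default). Through empirical quantiles both the objective and the
constraint are step functions of the rate, so a grid is exact up to its
resolution and continuous optimisation would add nothing but fragility.
The objective is the population-weighted mean pp reduction across strata
(equal per-capita weighting; per-stratum weights are configurable for
equity analyses). The excess constraint is evaluated **per stratum** by
default — the strictest reading of "< 5% of the population" — with a
pooled option. Ties break toward the lowest (cheapest) rate. The two
nutrients are searched independently: deliveries and constraints do not
interact across nutrients in this model. An infeasible grid returns a
result object with the full trace rather than raising.

## The synthetic survey generator

The restricted consumption-survey microdata is emulated, not reproduced.
Per (region × group) stratum the generator draws:

* true usual intake: lognormal, median set to the published baseline
  median for that stratum (zinc 2.5/6.9/9.2 mg/d in Addis Ababa and
  1.8/4.2/5.4 in Somali for children/women/men; folate 126/457/552 and
  62/159/207 μg DFE/d), between-person log-SD 0.5 — a geometric SD of
  ≈1.65, typical of micronutrient intakes in low-income settings;
* observed day = truth × lognormal noise with log-variance
  `ratio × 0.25`, plus optional log-scale covariate effects
  (default zero) for recovery tests;
* adult total salt: truncated normal, base mean 8.3 g/d (the national
  adult estimate) with region × sex offsets chosen so that group-mean
  discretionary salt reproduces the design values (8.5/6.7 g/d men/women
  in Addis Ababa, 6.8/5.3 in Somali), SD 2.0 g/d;
* energy: truncated normal, adults 2200 ± 450 kcal/d, children at ratio
  0.45 of the adult mean (± 220), which puts recommended child salt near
  2.3 g/d;
* structure: stratum sizes 422/722/86 (Addis) and 414/603/24 (Somali) for
  children/women/men; Addis all-urban, Somali 17% urban; SES quintile and
  pregnancy/lactation distributions matching the published participant
  characteristics; covariate flags at weekend 2/7, sickness 5%, unusual
  consumption 5%.

Randomness uses one root seed with per-stratum substreams keyed by a
SHA-256 hash of the stratum label, so resizing or removing one stratum
never perturbs another — a property the tests assert.

What the generator does **not** emulate: item-level recalls (nutrient
totals are drawn directly; the recall→FCT stage is tested on its own toy
fixtures), survey design effects and weights, seasonality, correlation
between salt and nutrient intake within person, and non-lognormal shapes
(episodic consumption, point masses at zero). Passing tests therefore
demonstrate the *machinery* is correct under lognormal conditions with
known variance structure, not that the published population estimates are
recovered — those depend on the restricted microdata.

## Numerical and reporting choices

* Prevalences are exact count ratios; no smoothing. Empty strata raise
  rather than reporting 0%.
* Reports round percentages to integers and medians/salt to one decimal;
  machine-readable CSVs keep full precision and carry unit-suffixed column
  names (`zinc_mg_d`, `folate_ug_dfe_d`) to prevent mg/μg confusion.
* Pipeline outputs are deterministic given the seed, byte-identical across
  reruns, with a provenance JSON (config hash, seed, versions).
* Analysis problem sizes: the default population (n = 2271) runs the full
  pipeline with optimisation in a few seconds; test fixtures use scaled
  strata (~200–300 participants) and the statistical validation tests use
  single 10,000–50,000-person strata, sizes at which Monte-Carlo error is
  comfortably inside the asserted tolerances.

## Known limitations

* The variance-ratio scale interpretation (above) is an assumption; if the
  imputed values were absolute log-scale within-person variances the
  shrinkage would differ.
* The EAR status mapping for lactating women is a package default, not a
  published value; users stratifying on lactation should pin their own.
* Per-person usual-intake *estimates* understate true between-person
  spread in small strata (shrinkage uses the plug-in variance estimate);
  prevalence estimates near 0% or 100% are correspondingly coarse.
* The child-salt scaling base (region-mean adult discretionary salt) is
  one of several defensible conventions; it is configurable because the
  choice moves child delivered doses by ~±20%.
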