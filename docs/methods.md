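# Methods

## The liability-threshold model and its estimators

A binary phenotype is modelled as the dichotomization of an unobserved
liability L ~ N(0, 1): affected iff L > t = Φ⁻¹(1 − K), where K is the
trait prevalence. For a relative pair, (L₁, L₂) is bivariate normal with
correlation r. Under purely additive genetics and no shared environment,
r = ρ·h² for a pair with additive genetic correlation ρ, so a
parent–offspring pair (ρ = 0.5) gives h² = 2r. The adoption design
justifies omitting a shared-environment deduction for biological pairs:
adoptees never lived with their biological parents, and the
adoptive-parent association — which would capture household transmission
— is checked separately and expected to be null. `relatedness` is a
free parameter so other relative classes can be analysed.

### Tetrachoric correlation from an odds ratio

Registry case-control analyses report an OR between the statuses of the
pair, not the raw 2×2 table. Given the OR and the two margin
prevalences, the implied table is

    p11 = P(L1 > t1, L2 > t2; r),  p10 = p1 − p11,
    p01 = p2 − p11,                p00 = 1 − p1 − p2 + p11,

and r is the unique root of `OR(r) = OR_obs` (the OR is strictly
increasing in r at fixed margins). We solve by Brent's method on
log OR with tolerance 1e-10 on r; near |r| = 1 a cell degenerates and
the objective is treated as ±∞, which keeps the bracket valid.

**Margins.** The proband (adoptee) margin is the *assumed population
prevalence*, scanned over a grid because the prevalence of a clinically
ascertained trait is genuinely uncertain — this is the sensitivity
analysis, default grid {0.01%, 0.05%, 0.1%, 0.5%, 1%, 2%, 5%}. The
relative margin is the *exposure* prevalence: the rate of "≥ 1 affected
biological parent", a pair-level collapse of the two parents. In the
tinnitus analysis this is the observed cohort rate 383/11 060 ≈ 3.46%.
Passing no exposure prevalence gives the symmetric-margin solve, which
is the right choice when both margins are dichotomized at the same
population prevalence (e.g. single-relative pairs on simulated data).
The pair-level asymmetric reading is what reproduces the published
sensitivity table; the symmetric solve at 2% gives r ≈ 0.143 instead of
0.153-0.154, a visible discrepancy we document rather than hide.

A count-based entry point (`tetrachoric_from_counts`) implements the
classical two-step estimator for synthetic or fully tabulated data:
thresholds from the margins, r solved from the both-affected cell.

### Orthant probabilities

P(X > t₁, Y > t₂; r) is computed in closed form via Owen's T function
(`scipy.special.owens_t`), with the Drezner–Wesolowsky correlation
integral (adaptive quadrature, `epsabs` 1e-13) as fallback at zero
thresholds where the Owen decomposition degenerates. The two routes
agree to ~1e-15 on random inputs and the closed form is ~1000× faster,
which matters because the bootstrap oracle re-solves r 10 000 times.

### Standard errors

The OR's 95% CI is back-transformed to the SE of log OR,
(ln hi − ln lo)/3.92. The delta method then gives
se(r) = se(log OR) / |d log OR/d r|, the derivative by central
difference with step 1e-5, and se(h²) = se(r)/ρ. A parametric bootstrap
(log OR resampled normally, r re-solved) agrees within 10% and guards
the implementation in the tests. The exact SE recipe behind the
published table is uncited detail of its source; our delta-method SEs
land within ±0.012 of the printed values.

### Falconer regression

x_g = Φ⁻¹(1 − q_g), x_r = Φ⁻¹(1 − q_r), a_g = φ(x_g)/q_g,
b = (x_g − x_r)/a_g, h² = b/ρ. The SE propagates the binomial variance
of each prevalence through the threshold transform,
Var(x) = q(1 − q)/(n φ(x)²), Var(b) = (Var(x_g) + Var(x_r))/a_g².
Estimates are clipped to [0, 1] with an `out_of_range` flag preserving
the raw value.

## Cohort machinery

* **Phenotype extraction** is exact (version, code) matching after
  whitespace trimming; main and secondary diagnoses are treated alike;
  unknown ICD versions are dropped with a warning. The tinnitus map
  {(7, 781.32), (8, 781.31), (9, 388D), (10, H931)} ships as default;
  comorbidity maps are user-supplied configuration because no canonical
  public list exists for the source study.
* **Exclusions** run in a fixed order (died before 16, emigrated before
  16, died before 1964, missing a biological or adoptive link, cohabited
  with a biological parent), each adoptee tallied under the first rule
  that hits, so retained + Σ tallies = input count. Cohabitation means
  any shared (area, year) between adoptee and a linked biological parent
  before the adoptee turns 16; residency is stored as year ranges and
  compared by range overlap, which is equivalent to year-by-year records
  and far smaller.
* **Follow-up** runs from birth to the earliest of first diagnosis,
  death, emigration, or 2015-12-31; year arithmetic is exact day counts
  / 365.25. Starting at birth (rather than age 16 or 1964) matches the
  published person-time total (~513 000 years over 11 060 adoptees ≈ 46
  years each, consistent only with birth start for a cohort born
  1960–1990).
* **Exposure** is time-invariant: a parent ever diagnosed during
  1964–2015 makes the adoptee exposed, including diagnoses predating the
  adoptee's birth. There is no immortal-time handling — a documented
  limitation shared with the design this mirrors.
* **Incidence CIs** are log-scale Wald, exp(ln rate ± 1.96/√events);
  zero events fall back to the rule-of-three Poisson bound. At large
  event counts plain-scale Wald rounds slightly differently (0.46 vs
  0.47 upper bound on a 201-event rate); log-scale is kept for
  correctness at the small counts where the choice matters.
* **Logistic fits** use Newton/IRLS with Wald SEs (statsmodels `Logit`
  behind the module surface). Model 1 is the crude single-exposure
  model; model 2 adds birth year (continuous), sex, county (unordered
  categorical), education, and the comorbidity flags when present.
  Constant outcomes and complete separation raise a dedicated error;
  plain non-convergence is flagged, never silently interpreted.

## Matched case-control

Greedy 1:4 matching, exact on sex, education (with "unknown" matchable
as its own level) and county of birth, ±1 year on birth year. Cases are
processed in seeded random order; controls are sampled without
replacement *across* sets so the conditional likelihood factors
independently over sets. Cases with fewer than 4 eligible controls are
reported as unmatched and excluded — the source analysis shows analogous
attrition (146 of 214 cases analysed) without stating its mechanism, so
the count is surfaced rather than hidden. The conditional logistic
likelihood Π exp(x_case β)/Σ_set exp(x_j β) is maximized by Newton's
method (statsmodels `ConditionalLogit`); exposure-concordant sets are
provably uninformative and are dropped before fitting, with an explicit
error if none remain.

## Synthetic registry generator

The generator exists so every downstream stage has a truth to recover.
Liability structure per family (two biological parents, two adoptive
parents, one adoptee):

* biological parent: A ~ N(0, h²), E ~ N(0, 1 − h²)
* adoptee: A = midparent + N(0, h²/2) (Mendelian segregation variance,
  the standard infinitesimal-model choice making offspring additive
  variance h² again), plus household C ~ N(0, c²) and
  E ~ N(0, 1 − h² − c²)
* adoptive parent: own independent A ~ N(0, h²) plus the same C and E

giving unit variances, Cov(adoptee, biological parent) = h²/2 and
Cov(adoptee, adoptive parent) = c². Parents are drawn independently (no
assortative mating — the design's own untestable assumption, simulated
as stated).

Demography is calibrated loosely to the source cohort: adoptees born
uniformly 1960–1990, ~47% female; biological parents ~24 ± 5 years older
than the adoptee at its birth and adoptive parents ~33 ± 6 (matching the
published median birth-year gaps); diagnosis ages truncated-normal on
[16, 90] with medians 43/65/71 for adoptee/biological/adoptive roles.
Censoring (death age ~ N(80, 10), 0.3% child mortality, 2% emigration)
and the cohabitation (1%), missing-link (0.5%) and comorbidity
parameters are synthetic-only free parameters: the source data cannot
constrain them, and they exist to exercise the exclusion and adjustment
code, not to be estimated. ICD revision follows the diagnosis year
(ICD-7 to 1968, ICD-8 to 1986, ICD-9 to 1996, ICD-10 after), and record
source respects each register's coverage window. Comorbidities are drawn
with a simple log-odds bump for tinnitus-affected persons — association
without causal structure.

**What passing tests show, and what they do not.** Because diagnosis
requires surviving, staying in the country and reaching the diagnosis
age inside the register windows, observed prevalence (~0.9% per role at
the default settings) is lower than the liability-model 2%, and this
thinning attenuates observed associations. Estimator-recovery tests
therefore run on the uncensored affection statuses (clean truth:
estimates land within ±0.03 of h² at n = 200 000), while the end-to-end
pipeline test asserts the wider interval [0.10, 0.55] for true h² = 0.32
at 50 000 adoptees, derived from repeated runs. Passing shows the
estimators and plumbing are correct under the model's own assumptions;
it does not validate the liability-threshold model, random mating, or
diagnosis-independent censoring against real registry behaviour.

## Pipeline and reporting

Stages run registry → cohort → case-control → heritability,
deterministic under a fixed config and seed; reports are plain CSV plus
a text summary (no plotting dependency). The heritability stage feeds
the conditional-logistic biological-parent OR into the sensitivity
table with the exposure margin at its observed cohort rate, and runs
Falconer regression on parental prevalence among case vs control
adoptees from the matched sample. Problem sizes in the shipped tests
(50 000-adoptee pipeline runs, 200 000-family draws, 10⁷-draw Monte
Carlo oracles) were chosen as the smallest at which Monte-Carlo error is
comfortably inside the asserted tolerances.

## Known limitations

* Exposure misclassification from censored parents (a parent dying
  before the registers open can never be observed affected) attenuates
  ORs in both the generator and any real registry; no correction is
  attempted.
* The matched design conditions on fixed covariates only — no risk-set
  sampling by calendar time.
* The sensitivity table treats the input OR as estimating the pair-level
  status OR exactly; finite-sample bias of conditional-logistic ORs at
  few informative sets is not propagated.
* Education, county and the censoring processes are independent of
  liability in the generator; real confounding structures are not
  emulated.
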