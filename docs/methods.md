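# Methods

`healthbia` implements a benefit-incidence analysis (BIA) of the public
subsidy for noncommunicable-disease (NCD) care among the elderly, from
NSS-style survey microdata to concentration curves and indices, together
with a synthetic-data generator that plants a known equity structure so
every stage can be tested against ground truth.

## The analysis pipeline

**Population and units.** The analysis population is individuals aged 60
and above.  Inpatient (IP) care is observed per hospitalization episode
(365-day recall); outpatient (OP) care per *spell* — the survey pools the
out-of-pocket expenditure (OOPE) of all visits in a 15-day recall window,
so the spell is the finest unit at which OP spending exists.  An OP spell
enters the NCD analysis only if *every* visit's ailment is an NCD; a
spell with any non-NCD visit cannot be attributed to NCD care and is
excluded entirely.  Ailments are partitioned into communicable (CD),
noncommunicable (NCD) and residual other (OD) groups in the spirit of the
World Development Report 1993 three-way grouping; because no normative
code list ships with survey extracts, the mapping is an editable config
(`AilmentMap`) and unmapped codes fall to OD with a warning.  Each
inpatient episode carries one ailment code; multi-ailment
hospitalizations must be pre-assigned a principal code upstream (a
simplification the data model makes explicit).

**Living-standard classes.** Household living standard is equivalized
monthly per-capita expenditure, MPCE = T/√N (OECD square-root scale,
T = total monthly expenditure, N = household size).  Within every
(state, sector) cell, households are split at the weighted quartiles of
MPCE into Poorest / Lower-Middle / Upper-Middle / Richest classes, which
members inherit.  Quantiles use the left-continuous inverse of the
weighted empirical CDF (the lowest value whose cumulative weight share
reaches p) — no interpolation, so results are reproducible on discrete
survey data and invariant to weight rescaling; ties at a cutpoint go to
the lower class.  Cells with fewer than 4 households are unusable and
dropped with a warning.

**OOPE decomposition.** Per episode/spell: medicine; medical = medicine +
other medical care (fees, diagnostics); total = medical + transport +
other non-medical spending.  By construction medicine ≤ medical ≤ total.
All means and shares are weighted by the survey multipliers; the
"combine" sector pools rural and urban records rather than averaging
columns.

**Modal-cost subsidy imputation.** The public provision cost of an
episode is proxied by the *modal* private-facility total OOPE in the same
stratum: state × sector × MPCE class × duration band (length of stay for
IP; total ailment duration for OP).  Duration proxies severity.  Band
edges are a configurable design choice (IP 1–3 / 4–7 / 8–14 / 15+ days;
OP 0–14 / 15–30 / 31–90 / 91+ days); the survey instrument fixes no
canonical edges, so these were chosen once to give every band real
support.  The mode of a continuous cost is defined by fixed-width binning
(default 500 INR for IP, 50 INR for OP): values fall into half-open bins
[m·w, (m+1)·w); the modal cost is the weighted mean of the values in the
weighted-count-maximizing bin, ties broken toward the lower bin.  Strata
with fewer than `min_cell_size = 5` private episodes fall back along the
pooling ladder drop_duration → drop_class → drop_state → global, and the
level used is recorded per stratum, so sparse-data imputations are
auditable.

**Net subsidy and benefit incidence.** For a public-facility episode k,
γ_k = modal private cost(stratum of k) − total OOPE of k, floored at 0 by
default (a subsidy cannot be negative under the proxy's own logic; the
clamp count is reported and a switch restores the literal subtraction —
whether the original analysis clamped is not stated, so both are
available).  With δ_j the weighted share of class j among all public
episodes for the service, the class benefit is

    π_j = δ_j · Σ_{k ∈ class j} w_k γ_k ,

and the benefit-incidence share is 100·π_j / Σ_j π_j.  The sum over k
runs over the members of class j (the prose reading "added all the
individual subsidy of a particular MPCE class").  The δ-weighting counts
utilization twice relative to plain subsidy sums; it is nevertheless the
formula as printed and is the default, with the unweighted variant
available as a sensitivity option (`weighted_rates=False`).

**Concentration curves and indices.** Records (public-facility NCD
episodes of the elderly — the population whose n is reported alongside
each index) are ranked poorest to richest by the individual's
*continuous* equivalized MPCE, with stable tie-breaking by record order;
ranking by the 4-level class is available but makes a micro index
ill-defined and is not the default.  With midpoint fractional ranks
r_i = Σ_{j<i} w̃_j + w̃_i/2 the index is the weighted covariance form
C = (2/μ)·cov_w(h, r), which equals twice the signed trapezoid area
between the concentration curve and the 45° line exactly (a test
enforces agreement to 1e-6, and equality with the grouped-data formula
C = Σ p_t L_{t+1} − p_{t+1} L_t when h is constant within contiguous
groups).  Negative C = pro-poor, positive = pro-rich.

The *health variable* h is the per-episode net subsidy γ_k.  The
δ-weighted individual benefit δ_j·γ_k is also supported: it is the
variable whose grouped index matches the benefit-incidence table, and
the recovery tests use it (see below).  Standard errors come from the
convenient regression — WLS of 2·var_w(r)·h_i/μ on r_i, whose slope is
algebraically identical to C — with HC1 covariance and t-based p-values
(df = n−2).  Household-cluster SEs are available; whether survey-design
clustering should enter the SE is genuinely open, and HC1 is the default
as the plainer choice.  Curve confidence bands are pointwise 2.5/97.5
percentile envelopes from a household bootstrap (default B = 500,
households resampled with replacement, episodes following their
household), evaluated on a fixed 100-point population-share grid and
deterministic given a seed.

## The synthetic-data generator

The generator emulates the *structure* of a national health round, not
any survey's actual marginals: a state × sector household frame with
lognormal expenditure; survey multiplier weights drawn uniform on
[0.5, 2]× a base, independent of expenditure (so weighted and unweighted
estimands differ detectably); household sizes 1 + Poisson; ~8.2% elderly;
age-graded NCD morbidity (logit intercept −0.35, slope 0.02 per year over
60, giving ~42–50% NCD shares among elderly care); facility choice by a
logit in the MPCE quartile with log-odds gradient g (`private_gradient`,
default 0.4: richer patients choose private care more, so public
utilization is pro-poor; g = 0 plants no gradient; g < 0 plants a
pro-rich public mix).  Default scale is ~66k households (~320k
individuals); `SimConfig.with_target_ip_episodes(n)` rescales the frame
to an expected elderly-NCD hospitalization count.

Total household expenditure scales with √(household size) around the
sector log-mean, so equivalized MPCE is independent of size.  Without
this, larger households (mechanically poorer under T/√N) would
contribute more members and hence more episodes, superposing a
class-composition tilt on utilization that would contaminate the planted
gradient — with it, g is the *only* planted driver of class differences
under default settings.

**Cost model.** Every stratum has a true cost location: base location
(IP 18,250 / 26,250 INR rural/urban; OP 525/725 INR) × duration-band
multiplier (IP up to 3.5× for 15+ day stays) × optional class and state
factors (flat by default, so planted equity is utilization-driven; the
demo scenario in `analysis/` switches on a class price gradient
0.8–1.3×).  Private totals are drawn from a shifted lognormal
re-parameterized by its *mode*: X = (loc − s) + LogNormal(ln s + σ², σ)
with peak scale s (300 INR IP, 30 INR OP) and σ = 1, so the distribution
peaks exactly at the planted location with a long right tail.  Public
totals are `public_fraction` (0.3) of the location times lognormal noise
(mean-preserving, log-sd 0.25), so public OOPE sits systematically below
private in every stratum.  Totals are split into the four OOPE heads by
service-specific Dirichlet draws (medicine-heavy for OP).  The true net
subsidy of a public episode is max(location − public OOPE, 0).

The peak scale is deliberately *tight* relative to real private-price
dispersion: the binned-mode estimator can only identify a stratum's
location when the modal bin dominates its neighbours at the stratum's
sample size (a few dozen private episodes under survey-scale
conditions).  This is the identifiability condition of the modal-cost
proxy made explicit; passing tests therefore show that the pipeline
recovers a *recoverable* planted cost, not that real private charges are
this concentrated.  Similarly, base locations are deliberately not
multiples of the bin width — bin-edge-aligned locations are a degenerate
configuration that maximizes the discretization offset of the
bin-mean mode estimator.  Other things real data have that the generator
omits: multistage (FSU) cluster sampling (records are independent given
strata; the bootstrap resamples households instead), item nonresponse,
recall bias, multi-ailment episodes, and calibration of any marginal to
published totals.

**Ground truth.** `TruthRecord` carries per-stratum true locations,
per-episode true subsidies for the analysis set, the planted class
utilization shares δ and benefit shares (δ-weighted, mirroring the
pipeline), and the planted gradient.  `true_concentration_index`
evaluates the grouped formula over the planted benefit shares with
either equal class population shares of 0.25 (the four classes are
population quartiles) or the classes' shares of the *episode*
population.  These are different estimands whenever utilization is
class-graded: the micro index is computed over public-facility episodes,
a population in which class j has share δ_j ≠ 0.25 once g ≠ 0.
Recovery tests therefore compare the benefit-weighted micro index with
the episode-population ("utilization") grouped truth — the matched
estimand — while the equal-population version is the natural descriptive
summary and coincides with the other at g = 0.

## Problem sizes and numerical choices

Statistical tests run at the following scales, chosen to keep every
check well-powered: recovery and null checks at ~20,000 elderly-NCD
hospitalization episodes per seed (≈540k households) over 20 fixed seeds
(1–20); power checks at ~5,000 episodes over 20 seeds; modal-cost
recovery at 10,000 draws per stratum.  Recovery and null checks are
evaluated within the rural sector: the combined-sector ranking mixes the
(planted) sector difference in cost locations with the sector difference
in expenditure levels, a real between-sector component that the
within-sector grouped truth deliberately excludes; the power check uses
the combined sample, where that component is part of the planted
pro-rich signal.  Observed behaviour at these sizes: benefit shares
recovered within 0.2pp (tolerance 3pp), recovery z-scores within ±0.5,
null-configuration indices within ±0.01 of zero with uniform-looking
p-values, modal costs within one bin width in every full-support
stratum.

Degenerate inputs are handled explicitly rather than by accident: empty
quantile cells are dropped with warnings; an all-equal MPCE cell yields
three equal cutpoints and every household in class P; a zero total
benefit makes shares/indices missing with a warning rather than raising;
an exactly-fitting convenient regression (constant h) reports p = 1; the
bootstrap refuses fewer than 10 households.  Floating-point equalities in
tests use explicit tolerances (1e-12 for algebraic identities through
different summation orders, 1e-6 for the area identity).

## Known limitations

* The modal-cost proxy inherits all the caveats of using private charges
  as a shadow price of public provision; the pipeline reports pooling
  provenance and clamp counts so the imputation's reach is visible, but
  cannot validate the proxy itself.
* The δ-weighted benefit formula double-counts utilization; results for
  the unweighted variant can differ materially when utilization is
  strongly class-graded.
* HC1 standard errors ignore survey-design clustering; the
  household-cluster option captures within-household correlation only.
* The generator's tight private-price dispersion (see above) is a
  deliberate identifiability condition, not a claim about real markets;
  on real data, sparse strata will pool more often and modal costs will
  be noisier than the recovery tests suggest.
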