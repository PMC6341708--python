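# Methods

## The scoring model

The instrument is a weighted checklist of ~160 indicators grouped into
nine sections: six quality dimensions (QD1 physical environment and
equipment, QD2 job expectations, QD3 professional knowledge/skills/
ethics, QD4 management and administration, QD5 staff motivation, QD6
client satisfaction), with QD3 split into four clinical sub-sections
(IMCI, maternal health, fever, HIV/TB). Each indicator carries an
importance weight `w ∈ {1..5}` and is answered yes/no/not-applicable;
medicine-availability items in QD4 use a graded scale in `[0, 1]`.

For indicator `i` at facility `f` in year `t`, the credit is the
*fraction met*

    f_i = #yes / (#yes + #no)            (binary; NA answers excluded)
    f_i = mean(graded values)            (graded)

so repeated answers earn fractional credit: a facility that answers an
indicator three times must meet it three times for full credit, which
is why heavily assessed facilities tend to score lower than a
qualitative impression would suggest. An indicator whose answers are
all NA is excluded.

A section/QD score is the percentage of possible points,
`100 · Σ w_i f_i / Σ w_i` (with `w_i = 1` in unweighted mode), and the
overall facility score is the **unweighted mean of the six QD scores**,
so each dimension contributes equally regardless of its indicator
count. Two choices here were genuinely open:

* **QD3 aggregation** — the four sub-sections pool into one weighted
  QD3 aggregate by default (`qd3="pooled"`); averaging the four
  sub-scores is available as `qd3="submean"`. Pooling was chosen
  because the sub-sections are size-heterogeneous clinical modules of
  one dimension, and the concordance analysis treats them separately
  anyway.
* **Undefined QDs** — if nothing in a dimension is applicable/assessed
  (level-of-care mandates make some indicators NA at dispensaries), the
  overall score averages only the defined QDs rather than penalising
  the facility for its mandate.

Ranks are assigned in descending score order, rank 1 best, ties broken
by facility id so output is deterministic. Rank agreement between two
rankings is reported as Spearman's rho, Kendall's tau, and per-facility
rank displacement.

## The synthetic-data generator

No real assessment data ship with this package; every analysis runs on
a generator whose ground truth is fully recorded. It emulates eight
district councils with 20 facilities each (70% dispensaries, 22% health
centers, 8% hospitals; owners 60% public, 20% private-not-for-profit,
15% private-for-profit, 5% parastatal), assessed each year 2011–2014
with a 159-indicator catalog laid out as QD1 41, QD2 17, QD3A 17,
QD3B 19, QD3C 10, QD3D 12, QD4 16, QD5 21, QD6 6 (`total_indicators`
rescales proportionally).

Responses follow a latent logistic model. The per-answer success
probability is

    p = invlogit( μ + year_t + level_f + owner_f + u_c(f)
                  + δ_{f,s} + slope · (w_i − w̄) − d_i )

with council intercepts `u_c ~ N(0, council_sd)` (default 0.5 logit —
scores are strongly correlated within councils), facility-by-section
deviations `δ ~ N(0, qd_sd)` (default 0.5, matching a realistic 8–10 pp
within-council spread of QD scores; these deviations are also what a
factor analysis can recover), and indicator difficulties
`d ~ N(0, 1)`. Clinical-observation and exit-interview sections
(QD3A–D, QD6) draw 1–3 answers per indicator uniformly, other sections
one — reproducing repeated-answer averages in the 1.3–2.0 range. A
configurable share (20%) of indicators is inapplicable at dispensaries;
half of QD4 uses the graded `{0, 0.5, 1}` scale (drawn with mean `p`).

**Calibration.** Effect sizes are configured in percentage points of
overall score — the defaults are the reference programme's estimates
(+3.1/+6.5/+8.4 for 2012–2014; hospital +1.8, dispensary −7.7;
private-for-profit −5.5, public +1.8, parastatal −0.9; reference mean
67.3) — and converted to logit offsets numerically. Because the model
is logistic, a fixed logit shift does not move the expected score
equally at every covariate combination; each offset is therefore solved
(fixed-point iteration with Gauss–Hermite marginalisation over the
noise distributions) so that its *population-average* expected-score
contrast equals the configured gap exactly. That population-average
contrast is the estimand a main-effects linear regression targets,
which makes "planted effect" well defined for recovery tests.

Two further design choices matter for interpretation:

* **Weight–difficulty decorrelation.** Sampled difficulties are
  residualised against weights within each section on the
  (marginalised) success-probability scale. A 159-indicator catalog
  otherwise carries a random weight–success covariance of the same
  order as a realistic compliance tilt (a few tenths of a percentage
  point), which would make `weight_compliance_slope` uninterpretable in
  any single catalog. Default slope 0.05 logit per weight unit yields a
  weighted-minus-unweighted mean-score gap of roughly 0.4–0.8 pp.
* **Realized vs planted effects.** With 8 councils and 159
  difficulties per dataset, the effect realized *in a given dataset*
  fluctuates around the planted value (sd ≈ 0.3 pp for year effects, up
  to ≈ 1 pp for the dispensary effect, whose counterfactual also
  switches indicator applicability). `SyntheticTruth.realized_effects_pp`
  computes the dataset's exact expected-score contrasts; recovery tests
  compare fitted confidence intervals against these, and a separate
  deterministic check verifies the calibration plants the configured
  magnitudes.

What the generator does **not** emulate: real answer-count
distributions per section (unpublished), informative missingness
(dropout is independent of quality), assessor effects or courtesy bias,
and any fitting to the real Tanzanian score distributions. Passing
tests therefore demonstrate that the machinery recovers known structure
under a plausible model, not that the original field estimates are
reproduced.

## Robustness analyses

The *subset curve* recomputes unweighted overall scores from nested,
section-stratified random indicator subsets (each smaller set contained
in the next, every section retaining at least one indicator) and
reports the mean absolute score and rank change against the full
catalog; "positive difference" is implemented as absolute difference,
since signed changes cancel across facilities. Trends are fit by least
squares — quadratic for the score curve, linear for the rank curve.
The real historical indicator sets are unavailable, so nesting is
seeded-random; explicit sets can be supplied instead.

*Weight ablation* scores identical responses weighted and unweighted
and reports both means plus mean |Δscore| and |Δrank|. The report is
symmetric in which scoring is called reference.

## Factor concordance

The facility-by-indicator matrix of 2014 unweighted fractions is
factored with k = 9: principal-axis extraction (iterated communalities,
SMC start) with varimax rotation, both implemented here and
cross-checked in tests against scikit-learn's maximum-likelihood factor
analysis with varimax. Missing cells are mean-imputed (simplest
deterministic choice); constant columns are dropped with a log entry.
Each indicator is allocated to the factor with the largest |loading|
(ties to the lower factor index, logged); allocations are flagged
*weak* below |0.4| and *cross-loaded* when another factor's |loading|
is within 0.2 — absolute values throughout, since the thresholds are
symmetric in sign. Factors are matched one-to-one to designed sections
by maximising the contingency-table agreement (Hungarian algorithm),
and the concordance table reports per-section matched counts with the
weak/cross-loading breakdowns (percentages use the section total for
the match rate and the matched/unmatched counts for their respective
breakdowns).

On default generator output the matched share is modest (~30–40%):
with one yes/no answer per indicator, per-cell sampling noise
(sd ≈ 0.4–0.5) dominates the latent section signal (≈ 0.1 on the
fraction scale). The planted-loading design (within-block 0.8, noise
0.05, 300 facilities) recovers ≥ 90% and is the benchmark for the
machinery itself.

## Effect estimation

Facility-year scores (percentage scale, untransformed) are modelled by
linear mixed models with categorical year, level and owner and a
council random intercept; references are 2011, health center and
private-not-for-profit. Model selection starts from the full three-way
factorial, reduced first to the largest estimable model when covariate
cells are empty, then prunes interactions backwards by per-term Wald
tests — highest order first, largest p first — at α = 0.05
(configurable). Selection fits use ML so the recorded AICs are
comparable; the final model is refit by REML. The sensitivity check
refits the fixed effects by OLS with council-clustered sandwich
standard errors and reports per-coefficient deltas. With few councils
and strong council intercepts, chance covariate imbalance across
councils can legitimately separate the OLS and mixed estimands on
synthetic data; the "no major difference" behaviour appears when
council heterogeneity is mild.

A facility random intercept (for data where facility-level deviations
persist across years, i.e. `qd_sd > 0`) is available behind the
`facility_re` flag; the default follows the reference specification
with the council effect only, and recovery simulations use `qd_sd = 0`
so that model is correctly specified.

## Problem sizes and numerics

Analysis and acceptance runs use the full default size (160 facilities
× 4 years × 159 indicators; ~136k answers, simulated and scored in
under a second). Recovery simulations use 100 replicates at that size;
the pruning power/type-I checks use 12-replicate batches. Percentages
are reported to one decimal; internal arithmetic is double precision;
rank ties and factor ties break deterministically as described; the
pipeline derives every stage seed from one master seed and writes a
SHA-256 manifest, so a rerun with the same config is byte-identical.

## Known limitations

* The graded medicine-availability scale of the original instrument is
  unpublished; `{0, 0.5, 1}` is a configurable stand-in.
* Whether the original overall score pools QD3 or averages nine section
  scores is not fully documented; both modes exist, pooling is the
  default.
* The published per-section indicator counts sum to 159 while the
  instrument is described as 183 indicators; the catalog default
  follows the per-section counts.
* Rank-difference statistics assume the deterministic id tie-break; a
  different tie convention would change mean |Δrank| slightly.
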