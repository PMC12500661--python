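# Methods

`brmcda` implements a quantitative benefit-risk assessment pipeline of the
kind used to compare two treatment regimens from published trial evidence:
meta-analytic pooling of arm-level outcomes, a swing-weighted additive
multi-criteria decision analysis (MCDA) value model with linear partial
value functions, deterministic weight-sensitivity analysis, and Monte Carlo
propagation of effect-estimate uncertainty. The packaged reference model is
a published evaluation of an adjunctive herbal decoction added to
platinum-based chemotherapy versus chemotherapy alone in non-small cell
lung cancer (NSCLC), with five criteria: change in Karnofsky Performance
Status (KPS), the tumor markers CA211 (CYFRA 21-1) and CEA, change on the
Cancer Fatigue Scale (benefits), and the incidence of gastrointestinal
adverse reactions (risk).

## Value model

The decision model is a two-level value tree. The top level splits weight
between a *benefit* and a *risk* category (reference model: 0.75 / 0.25);
each category holds leaf criteria carrying swing weights on the 0-100
convention — the most important criterion in a category is set to 100 and
the others scaled against it. Hierarchical normalization gives each
criterion a relative weight

    w_j = W_c * s_j / Σ_{k in c} s_k ,

which sums to one over the tree and is invariant to rescaling a category's
swings by a common factor. The reference tree normalizes to
20/15/15/25/25 percent for KPS/CA211/CEA/Fatigue/GI.

The schema supports exactly two levels; deeper nesting is rejected so the
aggregation semantics stay unambiguous. Unknown configuration keys warn
rather than being silently ignored.

### Partial value functions

Each criterion's single-attribute value function is linear between two
anchors: the *worst* outcome value maps to preference 0 and the *optimal*
to 100,

    U_benefit = (U − U_min) / (U_max − U_min) × 100
    U_risk    = (U_max − U) / (U_max − U_min) × 100 ,

the risk form being the reversed scale (low incidence = high preference).
Dispatch is on anchor order: optimal above worst gives the increasing
form, optimal below worst the decreasing form. Values outside the anchored
range are clamped to the boundary with a warning — the function is not
defined beyond its anchors, and extrapolating a linear preference would
produce scores outside [0, 100].

Some pooled changes are printed with a sign that is a bookkeeping
convention of the contrast rather than a direction of effect (the
reference KPS change, −9.38, against positive anchors 2–11 denotes a
9.38-point shift). The default `auto` orientation policy therefore takes
the magnitude whenever the value's sign is opposite to the whole anchor
range; `signed` and `magnitude` policies force either behaviour. `auto` on
the reference inputs reproduces the published KPS preferences (82 / 18)
exactly.

### Aggregation

Category scores are swing-weighted averages Σ w_j p_j / Σ w_j; the total
benefit-risk value is the category-weighted **sum**

    total = W_benefit × benefit_value + W_risk × risk_value .

Because the risk scale is already reversed, summing is the correct
combination — with the reference weights this reproduces
0.75 × 72.27 + 0.25 × 56 = 68.2. All comparisons and differences use
unrounded values; integer display uses round-half-up, matching the
convention of the published score tables.

### Known non-reproductions

Two published preference cells per benefit marker (CA211 67/33, CEA 75/25,
Fatigue 66/36) are *not* recovered by applying the stated formulas to the
stated anchors and pooled estimates (the formulas give 66.0/29.7, 66.0/26.3
and 81.0/20.6), and the published control benefit of 29 recomputes to 28.4
from its own printed preferences. The package computes from the formulas,
additionally ships the published table verbatim as an `asserted`
preference matrix, and the pipeline's reproduction report flags each
divergent cell rather than reconciling it silently. The cells that the
formulas do determine — KPS 82/18, GI 56/24, benefit 72, totals 68/27,
difference 41, relative weights 20%/25% — reproduce exactly at display
precision.

## Evidence pooling

Evidence enters as per-study, per-arm summaries (continuous: n, mean
change, SD; binary: events/n). Each (criterion, arm) cell is pooled
separately — the value model scores the two arms as alternatives, so the
evidence layer mirrors that per-arm structure rather than pooling a
between-arm contrast.

Continuous outcomes use inverse-variance weights 1/(sd²/n + τ²);
τ² is the DerSimonian–Laird moment estimator, with Cochran's Q and
I² = max(0, (Q − df)/Q) reported alongside. The default model policy is
fixed effect when I² ≤ 50% and random effects above, overridable per call
— a common systematic-review convention. Binary outcomes pool raw
proportions by inverse variance; the variance uses a 0.5-continuity-
corrected proportion so zero-event studies keep a finite weight while the
estimate itself stays uncorrected, and a single study receives a Wilson
score interval. All intervals are normal-approximation 95% intervals
(z = 1.959964). The random-effects interval is never narrower than the
fixed-effect interval on the same data, but it is not a superset: a
single precise outlying study can shift the fixed-effect center outside
the random-effects interval, which is why the tests assert width
ordering, not containment.

## Sensitivity analysis

Weight robustness is probed by scaling one criterion's swing weight or
one category's weight by (1 + δ) (relative mode; an absolute point-shift
mode is also exposed) and renormalizing siblings proportionally. The
conventional robustness band is δ = ±20%. When a scaled swing exceeds
100, the whole category is rescaled so its largest swing is 100 — swings
are ratio-scale within a category, so this changes no score.

For two alternatives the total-score difference is affine in any single
weight once siblings are renormalized proportionally, so the crossover
weight (where the ranking would flip) has a closed form; it is reported
only inside [0, 1]. In the reference model the combination arm scores
higher on *every* criterion, so no weight perturbation of any size can
reverse the ranking — the ±20% sweep (5 criteria + 2 categories, both
signs) finds zero reversals, and every crossover is absent, which a
0.001-step grid scan confirms independently in the tests.

## Monte Carlo uncertainty propagation

Each pooled effect is modelled as a triangular distribution with minimum
and maximum at the 95% CI bounds and mode at the point estimate — the
natural parameterization when only an estimate and interval are
available. Sampling is by inverse-CDF transform of uniforms from a single
seeded `numpy` generator; the draw order is fixed by (arm × criterion)
position, so a run is bit-reproducible from (model, n_iter, seed).

Each of the n_iter = 10,000 default iterations samples all
(arm × criterion) effects independently (no correlation structure is
assumed), scores both arms — sampled values falling outside an anchor
range are clamped at scoring time rather than truncating the
distribution — aggregates, and records the experimental-minus-control
benefit, risk and total differences. Summaries are equal-tailed 2.5/97.5
percentile intervals, and the probability of superiority is the fraction
of iterations with a positive total difference.

Because scoring + aggregation is affine within the anchor ranges, the MC
mean of the total difference converges to the model evaluated at the
triangular means (a + b + c)/3; the tests check agreement within three MC
standard errors at n_iter = 10⁴. The clamping of the small tail mass that
falls below an anchor (e.g. control KPS draws under 2) introduces a bias
orders of magnitude below that tolerance.

The source evaluation's own simulation outputs are internally
inconsistent — its printed 95% CI for the total difference does not
contain its printed mean, and its 81.83% exceedance probability is not
derivable from any interval resembling the printed one — so the package
does not target those numbers. The MC stage is instead validated by
properties: seed determinism, the affine-mean agreement above, a
superiority probability of 0.5 ± 0.02 when both arms share identical
distributions, and a Kolmogorov–Smirnov distance below 0.01 between the
sampler and the closed-form triangular CDF at n = 10⁵.

## Synthetic evidence generator

The generator emulates the reference evidence base: six two-arm RCTs with
arm sizes 45/45, 29/28, 30/30, 20/20, 30/30, 24/24 and the observed
partial-reporting pattern (four trials report KPS; two report the tumor
markers and adverse reactions; two report the fatigue scale). For each
study, the study-level true mean change is drawn Normal(effect, τ²);
reported per-arm means and SDs are sample moments of n Normal draws;
binary arms report Binomial(n, rate) events with the study rate jittered
by τ_binary on the probability scale. Masked outcomes still consume their
draws, so masking never shifts the random stream.

Defaults: true effects equal the reference pooled point estimates
(KPS −9.38/−3.63, CA211 4.98/3.89, CEA 9.96/7.58, Fatigue 14.58/3.70, GI
rates 0.44/0.76); within-arm SDs (8, 2.9, 5, 15) are back-calculated from
the reported CI widths and total sample sizes; τ = 0.5 outcome units of
mild between-study heterogeneity and τ_binary = 0.02. The generator
simulates arm-level *summaries* of change scores, not individual
patients, and makes no attempt at survival outcomes, correlated criteria
within a patient, or publication bias — so passing tests demonstrate that
the pipeline recovers the structure it assumes, not that real evidence
satisfies those assumptions.

Under these defaults the full pipeline (pool → score → aggregate → rank)
places the combination arm first in ≥ 99% of 500 replicates, and at
τ = 0 the nominal 95% pooled CIs attain 93–97% empirical coverage over
1,000 replicates (k = 6 studies of n = 40 per arm; coverage sits slightly
below nominal because study SDs are estimated but intervals use z).

## Numerical choices and degenerate inputs

- Rounding: round-half-up to integers for display; never for arithmetic.
- Weight-sum validation tolerance 1e-9 on input, 1e-12 on normalized
  output; ranking ties detected at 1e-12 and broken by benefit value,
  then lexicographic id, with a flag.
- Degenerate anchors (optimal = worst) are rejected at configuration
  time; a degenerate triangular spec (low = mode = high) is a point mass
  and samples exactly.
- A single study pools to itself (Q = I² = τ² = 0); all-zero-event binary
  pools return estimate 0 with CI floor 0.
- Problem sizes in the test-suite simulations (200-replicate parameter
  recovery, 1,000-replicate coverage, 500-replicate end-to-end) were
  chosen to keep each check well under a couple of minutes while leaving
  the binomial sampling error of each asserted proportion far smaller
  than the asserted margin.

## Limitations

- Per-arm pooling follows the reference evaluation's structure; pooling a
  between-arm contrast per study is the more standard meta-analytic
  design and is out of scope here.
- Only pooled incidence is supported for binary outcomes (no odds or risk
  ratios), and only linear partial value functions (no exponential or
  piecewise shapes).
- Weight sensitivity is deterministic perturbation; probabilistic weight
  sensitivity (SMAA-style rank acceptability) would be a natural
  extension point.
- The elicitation that produced the swing weights (expert consultation
  plus heterogeneity-based adjustment) is upstream of this package;
  weights arrive already elicited.
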