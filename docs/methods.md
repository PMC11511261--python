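# Methods

This note records the statistical model, the conventions chosen where
the underlying study left the design open, and what the synthetic data
can and cannot establish.

## Study structure

Ten groups of two-year-old grafted 'Luoyanghong' tree peony seedlings:
a control T0 and nine groups T1–T9 arranged as an L9(3⁴) orthogonal
array over root pruning A ∈ {25, 33, 50 %}, rooting agent
B ∈ {250, 500, 750 mg/L} and *Metarhizium anisopliae*
C ∈ {10, 15, 20 million U/mL}; the fourth L9 column is unused. Three
measurement campaigns: leaf gas exchange and antioxidant assays during
vigorous growth (n = 5 plants per group for gas exchange, n = 4
otherwise), destructive morphology and NSC harvest at defoliation
(n = 4), and ornamental traits at forced peak bloom (n = 4). The
control sits outside the array: it is excluded from range analysis but
included in summaries, correlations and networks.

## Derived indices

WUE = Pn/Tr, SI = SD/SL × WPB, CWI = CW/PH, NSCA = content × biomass,
NSCAT = Σ organs, CI = 100 × CWI. All are computed **per plant and then
averaged within group**. The published group values are consistent with
this convention and not with applying the formulas to group means
(e.g. SI of T1 prints 20.8 while the formula on means gives 20.56);
formula-on-means remains available simply by passing group means to the
same functions, and the two agree to first order. Internal computation
is full precision; report formatting uses one decimal for most traits
and two for ratios, matching the source tables. Percent changes are
signed (negative = reduction) and reported as positive magnitudes
labelled as reductions where prose requires.

## Flowering-index rubric

Bins are left-closed/right-open: a printed boundary belongs to the
upper bin, so "21–25" means [21, 25). This is forced by the printed
grid's touching boundaries and is applied uniformly. Two repairs to the
printed CI row were needed ("123" → 120, "40" → 140) to obtain a
gap-free monotone grid; the count rows are completed monotonically
(BN = 5 scores 5; a non-flowering plant, FNP = 0, scores 1 — the
lowest defined level). FI is the unweighted sum of six levels, per
plant, then averaged per group; fractional group means such as 19.8
arise from averaging integers. The rubric is a data object
(YAML-serializable), so alternative national-standard grids can be
swapped in without code changes.

## Range analysis

K[f][ℓ] is the mean response of the three groups at level ℓ of factor
f; R = max − min; factors rank by descending R (ties keep input order
with a warning); the optimum takes each factor's best level
independently, which is valid under the no-interaction assumption of
the orthogonal design. A within-factor tie at the optimum raises an
error rather than choosing silently. K is computed from whatever
per-group response is supplied; the published table's K1/K2 entries for
factor A are internally inconsistent with its own FI column (likely
unrounded inputs or a row transposition upstream), so only the
internally consistent cells are used as test anchors. In the pipeline's
synthetic mode the range-analysis response is the published group mean
FI carried by the generating summaries — the study's own values — so
that output is exact and deterministic; when analysing a measured
per-plant table the response is the mean of per-plant FI.

## ANOVA and Duncan letters

Standard fixed-effect one-way decomposition; F = MSB/MSW. Duncan's
multiple range test computes the least significant range for a span of
p ordered means as q(αp, p, df_w) · √(MSW/n_h) with
αp = 1 − (1 − α)^(p−1), q from scipy's studentized-range distribution
(machine-precision; agrees with printed Duncan tables to their
precision), and n_h the harmonic mean group size (the study is
balanced; harmonic n is the standard unequal-n fallback). Spans are
tested widest-first; a span within its critical range is homogeneous
together with everything it contains. Letters come from the maximal
homogeneous intervals of the descending-sorted means, "a" starting at
the largest mean. The protected variant (default) assigns one shared
letter when the omnibus ANOVA p ≥ α. Degenerate inputs: zero
within-variance with zero between-variance yields an undefined (NaN)
F; zero within-variance with separated means yields infinite F and
zero-width critical ranges.

## Correlations, network, dose–response

The unit of observation is the **group** (10 matched observations per
trait pair): the defoliation harvest is destructive, so plants cannot
be matched across stages, and group means are the only coherent
cross-stage unit. A per-plant mode exists for within-stage analyses.
Pearson r with the two-sided t-test p; stars at raw p < 0.05 / < 0.01
without multiplicity correction (a Benjamini–Hochberg step would be a
one-line addition but is deliberately off to match the conventional
presentation); network edges kept iff |r| ≥ 0.4 and p < 0.05, node
size = weighted degree Σ|r|, isolated nodes retained. Dose–response
uses simple linear OLS of SI and FI on root NSC accumulation (and FI
on SI) at the group level; an optional natural-log predictor transform
covers the saturating "fast then slow" shape but is off by default
since the published fitted form is unstated.

## Synthetic replicate generator

"±" in the source summaries is SE (stated in the table notes), so
replicate SD is reconstructed as SE·√n. Continuous traits are drawn
from Normal(mean, SD), truncated at zero **by redraw** for strictly
positive traits — clipping would put a point mass at zero; all means
here sit many SD above zero, so truncation bias is negligible. Count
traits (BN, FNP) use a distribution on {0..8} obtained by rounding a
normal whose location is calibrated by root finding so the discretized
mean matches the printed mean (within 0.05 by construction, exactly up
to root-finding tolerance). Traits are drawn independently — the
summaries carry no covariance information — so the generator does not
reproduce the study's per-plant correlation structure or its printed
R² values (0.4530/0.5129/0.4825) and r = 0.668; those depend on
unpublished raw replicates. Controlled dependence for regression tests
comes from the planted-effect mechanism, which regenerates a response
trait as intercept + slope × predictor + Normal(0, σ), matching
replicates across stages by (group, replicate index). Each (group,
stage, trait) stream derives from the seed through a SeedSequence
keyed on the spec's identity, so output is byte-reproducible and
independent of generation order.

What passing tests show: the pipeline's algebra, inference machinery
and determinism are correct, and parameter recovery works under the
generator's normal-independent model. What they do not show: behaviour
under real between-trait covariance, non-normal replicate
distributions, or measurement error structure — conclusions about real
trials still require real replicates.

## Numerical choices and problem sizes

Key tolerances: generator mean/SD recovery is checked at n = 10⁴
(mean within 0.3, SD within 5 %); planted-slope recovery within 3
standard errors at n = 200; the null-slope rejection rate over 500
replicates of n = 20 against the 99 % binomial band; Duncan letters
against an exhaustive brute-force closure on 50 randomized instances
of 3–5 groups; rubric coverage/monotonicity on 10⁴-point grids. These
sizes give stable checks in seconds while keeping the suite fast.
Floating-point CSV round-trips use `repr` on write and round-trip
float parsing on read, which is exact for IEEE doubles.

## Known limitations

- The rubric repair and bin convention are reasoned reconstructions of
  a misprinted grid; a different national-standard edition could bin
  boundary values differently (affecting FI by at most one level per
  trait).
- Petal biochemistry replicates were pooled in the source protocol;
  the generator treats them as n = 4 independent draws.
- Whether the published WUE means average per-leaf or per-plant ratios
  is unstated; neither convention exactly reproduces every printed
  WUE value, and the per-plant convention is used.
- No ANOVA-based variance decomposition of the orthogonal design and
  no interaction terms: the design analysis is range analysis only.
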