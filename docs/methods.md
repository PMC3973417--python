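# Methods

## Scope and data model

`soilfert` assesses soil fertility from a tidy sample table (one row per
composite sample: `sample_id`, `group`, optional `age_years`, and one
column per nutrient index) against a *grade standard matrix* of ordered
boundary values per index. Grades are numbered `1..K` with 1 the most
fertile; all internal arrays use this single convention, and
`lower_is_better` indexes are handled by mirroring, which keeps
orientation logic in exactly one place.

The packaged standard (`src/soilfert/data/nutrient_grades.csv`) carries
the six-level thresholds commonly cited from the Chinese national
soil-survey nutrient classification. It is deliberately an editable
fixture loaded at run time — the thresholds are configuration, not code
— and any CSV/JSON file with the same schema can replace it. `K` is
data-driven everywhere; nothing assumes six grades.

## Single-index attribute measures

For a `higher_is_better` index with boundaries `b_1 > … > b_{K-1}`, the
default (`anchor="midpoint"`) membership of grade *k* is piecewise
linear with value 1 at the grade's *anchor* and value 0.5 at its
boundaries:

- interior anchors are the grade-interval midpoints
  `t_k = (b_{k-1} + b_k)/2`;
- the bottom anchor is the midpoint of `[0, b_{K-1}]`;
- the top anchor extends symmetrically above the best boundary,
  `t_1 = b_1 + (b_1 − b_2)/2` (`1.5·b_1` when `K = 2`);
- beyond the outermost anchors the edge grade has full membership
  (saturation).

Placing an explicit 0.5 knot at each boundary (rather than interpolating
straight between anchors) is what guarantees the exact 0.5/0.5 split at
a grade boundary even when adjacent grade intervals have unequal widths;
with equal widths the two constructions coincide. The alternative
`anchor="boundary"` mode ramps linearly between consecutive boundaries
(full membership attained *at* a boundary, with the worst grade ramping
to zero concentration). Both modes satisfy the same invariants — each
measure vector is a distribution supported on at most two adjacent
grades, and a larger value is stochastically better — so the choice is
exposed as configuration rather than buried; midpoint is the default
because it treats a grade's centre, not its edge, as the prototypical
member.

Ties need no epsilon rules: every value maps through one closed-form
interpolation. Missing values are a hard error by default (silent
imputation would distort the entropy weights); an explicit `drop` policy
removes affected samples.

## Entropy weights

Weights are computed *within each group over its replicates*, one weight
vector per land use or restoration age, since the study design reports
them that way. From the group matrix `x_ij` (n samples × m indexes):

1. normalisation to shares, either `proportional`
   (`p_ij = x_ij / Σ_i x_ij`, the default — it is exactly invariant to
   positive rescaling of a column, i.e. to units) or `minmax`
   (range-scaled then proportional);
2. `H_j = −(1/ln n) Σ_i p_ij ln p_ij` with `0·ln 0 ≡ 0`,
   `d_j = 1 − H_j`, `w_j = d_j / Σ_j d_j`.

A constant column is flagged during normalisation and assigned `d_j = 0`
(it discriminates nothing); if *every* column is constant the method is
uninformative and the weights fall back to `1/m` each with a logged
warning. Tiny negative `d_j` from floating-point cancellation at the
uniform limit is clipped to zero. A `measure` weighting mode is also
provided, in which entropy is taken over per-sample grade scores
`q_ij = Σ_k c_k μ_ijk` instead of raw values, for users who prefer to
weight inside the attribute-measure framework; `raw` is the default.
Groups need `n ≥ 2`; singleton groups are an error, not a silent
equal-weight.

## Synthesis, classification, scoring

The comprehensive measure `μ_ik = Σ_j w_j μ_ijk` is a convex combination
of distributions and therefore a distribution. The confidence criterion
assigns `k* = min{k : Σ_{l≤k} μ_il ≥ λ}`, scanning best→worst; ties at
exactly λ assign that grade (`≥`, a closed deterministic rule). λ must
lie in (0.5, 1] — below 0.5 two grades could both qualify — and defaults
to 0.7, the upper end of the conventional 0.6–0.7 range, favouring
conservative (worse-grade) assignments. If floating-point summation
leaves the final cumulative a few ulp short of 1 with λ = 1, the worst
grade is returned. Scores use `c_k = K + 1 − k` by default so that
larger score = better fertility; the vector is configurable and recorded
in each result.

## Group statistics

Summaries report the sample SD (n−1 denominator) and CV = SD/mean.
One-way ANOVA is computed from sums of squares with the F survival
function for p, so the degenerate zero-within-variance case has a
defined outcome (p = 0 if any means differ, p = 1 if all observations
are identical) instead of a NaN. Pairwise comparisons use Fisher's LSD
(pooled MSE, t on the within-group df) with a deterministic
insert-and-absorb compact letter display ordered by descending mean;
exact replication of SPSS's Duncan grouping is a non-goal. The weight
spread is `D = (max w − min w)/min w × 100` by default, with
`(max w − min w)/mean w × 100` as an alternative (the statistic's exact
form in the motivating study is not recoverable, so both candidates are
implemented and the method used is recorded in every output row).

## Synthetic data generator

The generator emulates the study design: five land uses (farmland,
artificial grassland, natural grassland, woodland, shrubland) and a
0/5/10/15/20/25-year restoration chronosequence, five replicates per
group, with per-group per-index means and dispersions taken from the
published summary tables (land uses report CVs; restoration ages report
SDs, converted to CVs). Replicates are lognormal by default — nutrient
concentrations are positive and right-skewed — with parameters solved so
the distribution's *true* moments equal the specification
(`σ² = ln(1 + CV²)`, `μ = ln(mean) − σ²/2`); a zero-truncated normal is
available for sensitivity analyses, with the caveat that truncation
shifts the realised mean slightly upward at large CV. `CV = 0` returns
the mean exactly. Each group draws from its own RNG substream keyed by
`(seed, crc32(label))`, so adding or reordering groups never perturbs
another group's values; seeds are mandatory arguments.

The 52-sample study fixture combines 5 land uses × 5 replicates with 5
restoration ages × 5 replicates, the farmland group doubling as the
0-year control, plus 2 extra farmland replicates to reach the reported
52 — the true overlap of the two designs is not stated anywhere, so this
composition is the fixture's own documented convention.

What the generator does **not** model: spatial autocorrelation between
plots, depth profiles, measurement error, and (by default) within-group
correlation among indexes, which the study does not report — an
equicorrelated Gaussian-copula knob exists but defaults to zero.
Passing tests therefore demonstrate the *method's* correctness and the
design's qualitative behaviour, not agreement with the unpublished field
measurements; the study's printed weight tables cannot be recomputed
without the raw matrix and no attempt is made to match them numerically.

## Numerical and testing choices

- Measure vectors sum to 1 by construction (linear interpolation of
  knot values that sum to 1); tests enforce 1e-9.
- Entropy weights are checked against a literal loop transcription of
  the three formulas to 1e-12 on 1000 random matrices; classification is
  checked against a linear-scan oracle on 10⁴ random simplex vectors
  across a λ grid.
- ANOVA is cross-checked against an independent summary-statistics
  route (F from group means/SDs/n) to 1e-10, and against `t²` in the
  two-group case.
- Simulation-based checks (moment recovery at n = 10⁴ within 2 %/5 %,
  dispersion→weight dominance over 200 replicates of n = 50,
  chronosequence weight-spread convergence at n = 300 per age) use fixed
  seeds; the problem sizes were chosen so the asymptotic property being
  tested is comfortably resolved while the whole suite runs in a few
  seconds.
- End-to-end determinism is enforced byte-for-byte on the CLI pipeline.

## Known limitations

- The attribute-measure functional form, entropy normalisation and λ
  are methodological conventions; where the motivating study is silent,
  the package exposes the choice as configuration and documents the
  default instead of canonicalising silently.
- LSD-based letters do not control the family-wise error rate; they
  mirror the reporting style of the field, not a multiplicity-corrected
  inference.
- Weight spread under `range_over_min` is volatile at n = 5 replicates
  (the minimum weight can be near zero); `range_over_mean` is the stabler
  alternative for small groups.
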