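# Methods

This note documents the models and numerical choices behind
`roughdelphi`: what each stage computes, the parameters that matter, what
the synthetic-data generator does and does not emulate, and the design
decisions taken where more than one reasonable construction existed.

## Fuzzy Delphi screening

Experts rate each candidate criterion with a conservative score C and an
optimistic score O on the 1–10 integer scale (C ≤ O; violations are
rejected at load with a listing of the offending rows). Per criterion the
two score series are processed independently:

1. **Outlier trimming.** A single pass removes scores farther than two
   *sample* standard deviations (n−1 denominator) from the series mean.
   One pass, not iterated: repeated trimming on panels of 15–20 experts
   can cascade and hollow out the series. A zero-variance series is kept
   whole. Single-pass two-sigma trimming has a known masking limit —
   once contamination drifts past roughly 20% of a series, the inflated
   standard deviation hides the outliers — which is inherent to the rule,
   not to this implementation.
2. **Triangular fuzzy numbers.** Each trimmed series becomes
   (min, geometric mean, max). The geometric mean is the default central
   statistic; an arithmetic-mean switch is provided because aggregated
   score tables in this literature are often consistent with either. By
   AM–GM the mode never exceeds the arithmetic mean.
3. **Gray-zone convergence and consensus.** With Z = C_U − O_L and
   M = O_M − C_M:
   - C_U < O_L (strict): full overlap, G = (C_M + O_M)/2;
   - Z ≤ M: acceptable partial overlap,
     G = (C_U·O_M − O_L·C_M) / ((C_U − C_M) + (O_M − O_L));
   - otherwise: no consensus; the criterion is flagged for re-survey and
     never silently dropped.

   The boundary C_U = O_L = k is deliberately routed through the quotient,
   which reduces algebraically to k there; the midpoint branch would not
   honour that identity. A zero denominator forces Z = −Z = 0 and with it
   a zero numerator, so the only degenerate case is the 0/0 of two
   identical point-mass fuzzy numbers, defined as the mode midpoint (a
   constant panel screens by its constant value). A zero denominator with
   nonzero numerator cannot arise from valid fuzzy numbers but is guarded
   by a dedicated error anyway.
4. **Retention.** G ≥ threshold retains (default 7 of 10); the comparison
   carries a 1e-9 round-off allowance so a criterion that equals the
   threshold in exact arithmetic is retained despite the floating-point
   quotient landing a few ulps below it.

## Rough-set analysis

The survey is a complete categorical decision table; Likert codes are
compared by equality only (classical indiscernibility — the dominance
order of the codes is deliberately not used, and no missing-value
semantics exist: incomplete rows are rejected at load).

- **Partitions** are computed by grouping value tuples; blocks appear in
  order of their first object, and all object sets are reported in table
  order, so every run of every operation is byte-reproducible.
- **Approximations.** Lower = union of blocks inside the target, upper =
  union of blocks meeting it; accuracy = |lower|/|upper|, defined as 1.0
  for an empty target (vacuously exact; both approximations are empty).
- **Dependency.** γ_B(d) is the fraction of objects whose block is pure in
  the decision; γ = 1 means the table is consistent.
- **Reducts and core** come from an exhaustive subset-lattice search,
  smallest subsets first, pruning supersets of reducts already found —
  exact up to 20 condition attributes (the study schema needs 9). Beyond
  20 the search refuses unless an explicitly non-exhaustive greedy
  backward elimination is requested. The core is the intersection of all
  reducts and may be empty.
- **Rule induction** is a LEM2-style minimal covering per decision class:
  greedy literal selection by most uncovered objects gained, ties broken
  by fewer matches outside the class's lower approximation, then by
  attribute order, then by value; each conjunction is then minimised
  literal by literal and redundant rules are dropped. Every induced rule
  is certain (certainty 1), has at least one literal, and the union of a
  class's rule matches equals the class's lower approximation exactly, so
  inconsistent tables are handled by construction.
- **Rule statistics.** Support counts objects matching conditions and
  decision; coverage divides by the decision-class size in the full
  table (so coverage·|class| = support in integer arithmetic); certainty
  divides by the condition matches. Filtering keeps rules with coverage ≥
  the threshold (boundary kept) in the designated classes, order-stable.
- **Classification** (needed for cross-validation): exact-matching rules
  vote with their support; with no exact match, the rule with the largest
  fraction of satisfied literals wins (ties: higher support, then rule
  order). The function is total and deterministic for a fixed rule order.
- **Cross-validation** is stratified: each class's shuffled members are
  dealt round-robin with a single counter across classes, so no fold is
  empty. If a training split would lose a class entirely (singleton
  classes), the offending fold is merged into its neighbour with a
  warning. Cross-validation defaults to the full induced rule set; a flag
  restricts it to the coverage-filtered set.

## The synthetic survey generator

The generator emulates an ordinal satisfaction survey: 163 respondents,
nine Likert(1–5) condition attributes, satisfaction classes sized
14/41/108. Its central feature is **planted conjunction rules**: a planted
rule pins its literal pattern onto a designed number of class members, and
exclusivity (default) guarantees no object outside the class matches the
pattern, so the planted conjunction is a certain rule with coverage
exactly count/class-size. Exactness is maintained by a repair loop that
redraws free cells of accidental matches; planting, repair and the
consistency option below interleave until jointly stable, and the final
state is asserted, never assumed.

Choices that shape the data:

- **Response profiles.** Dissatisfied respondents draw all answers from a
  low-skewed categorical profile, satisfied respondents from a high-skewed
  one. A *neutral* respondent adopts one of those two styles wholesale
  (a respondent-level 50/50 mixture) rather than owning a distinctive
  centred profile: overall neutrality is then an emergent judgment, not a
  recoverable per-item signature. A centred neutral profile makes the
  neutral class trivially separable and pushes cross-validated accuracy
  far above what ordinal satisfaction surveys of this kind achieve; the
  mixture reproduces the low-0.7 accuracy regime reported for such data.
- **Carrier packing** (`pack_fraction`, default 0.75). Planted patterns
  are packed onto shared compatible respondents for that fraction of
  their carriers; the remainder are fresh. Packing reflects that condition
  configurations co-occur on the same respondents and leaves part of each
  class pattern-free — if every class member carried a perfectly
  predictive configuration, held-out accuracy would be implausibly high.
  The published counts force some overlap regardless (class-1 counts sum
  to 16 over 14 members, class-3 to 117 over 108); that forced share is
  allocated to the largest rules, which retain exclusive carriers anyway,
  because a small rule whose whole region is absorbed by other patterns is
  invisible to minimal-covering induction.
- **Carrier-signature diversification.** After planting, no attribute
  outside a rule's literals may be constant across the rule's carriers
  (one free cell is redrawn if it is); otherwise a coincidental literal
  would explain the carrier region as well as the planted conjunction
  does, and greedy covering might prefer it.
- **Noise** re-randomises non-pinned cells uniformly with the given
  probability (default 0.10 for the study-shaped fixture). Noise never
  touches the decision column, and the repair pass restores planted
  exactness afterwards, so class sizes and planted counts are invariant
  to the noise level.
- **Consistency option.** For approximation-quality analyses, a variant
  fixture perturbs duplicated condition profiles that straddle classes so
  the profile determines the decision and γ_C(d) = 1 exactly.
- **Recovery benchmark.** `recovery_survey_spec` is a separate
  configuration for parameter-recovery testing: generous, fully exclusive
  planted regions (no packing, no noise) over a uniform response
  background. There, every planted conjunction is the dominant certain
  description of its region and minimal covering provably prefers its
  literals, so induction plus the 10% coverage filter recovers each
  planted rule (possibly condition-minimised) with at least the designed
  support. The study-shaped fixture cannot offer that guarantee — its
  forced carrier overlap and skewed profiles create coincidental literal
  unions that greedy covering may legitimately prefer — which is why
  recovery is benchmarked on its own spec.

**What the generator does not emulate:** respondent demographics and their
correlation with answers, item nonresponse, acquiescence or central-tendency
response styles, multi-round Delphi dynamics, and any particular real
survey's joint distribution. Passing tests therefore demonstrate that the
algebra, induction and statistics are correct and that the pipeline
recovers structure it is told to plant — not that any specific empirical
rule set is true of real respondents.

The expert-panel generator draws a latent midpoint per expert × criterion
around the criterion's true importance (normal, sd 0.8 by default), places
the conservative/optimistic scores half the interval width (default 2.5)
either side, rounds and clips to the 1–10 integers, and with probability
`outlier_rate` replaces the whole interval with an aberrant far-side value
— both series are then contaminated at exactly the outlier rate, which is
what a trimming-calibration check needs.

## Defaults and problem sizes

| Parameter | Default | Why |
| --- | --- | --- |
| FDM threshold | 7 (of 10) | the conventional retention benchmark for 10-point importance scales |
| central statistic | geometric mean | standard for fuzzy aggregation of ratio-scaled scores; arithmetic switch provided |
| trim rule | 2 sample sd, one pass | conservative on 15–20-expert panels |
| survey size | 163 = 14/41/108 | the study-shaped class structure the fixture emulates |
| min coverage | 0.10 | rules covering less than a tenth of their class are too narrow to guide design |
| kept classes | {1, 3} | configurational questions concern satisfaction and dissatisfaction, not neutrality |
| folds | 10, stratified | standard for n ≈ 160 with a 14-member minority class |
| noise | 0.10 | measurement noise on Likert items without degrading planted structure |
| pack_fraction | 0.75 | calibrated so the fixture's cross-validated accuracy sits in the low-0.7 regime reported for comparable ordinal survey data |
| reduct search bound | 20 attributes | 2^20 subsets with pruning is the practical exhaustive limit; study schema needs 2^9 |

Oracle-equivalence tests run 200 randomized tables of up to 50 objects and
6 attributes against independent O(n²) pairwise and full-enumeration
implementations; recovery runs 20 seeds of the benchmark spec. These sizes
keep the default suite fast while exercising every code path the study
sizes exercise.

## Known limitations

- The exhaustive reduct search is exponential in the attribute count;
  beyond 20 attributes only the flagged greedy heuristic is available.
- LEM2-style covering is greedy: it returns *a* minimal covering, not all
  minimal coverings, and which certain rules appear can depend on
  attribute order through the documented tie-breaks.
- The classifier's partial-match fallback is a pragmatic device for
  cross-validation, not a calibrated probabilistic model.
- Dominance-based rough sets (which exploit the ordinal structure of
  Likert codes), variable-precision approximations and fuzzy-rough
  hybrids are out of scope.
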