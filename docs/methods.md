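# Methods

## Data model

An annotated odorant dataset couples a real-valued descriptor matrix
(molecules × physicochemical descriptors, missing entries allowed) with a
multi-label mapping from each molecule to a set of olfactory qualities.
The label structure this package targets is the one found in curated odor
atlases: around three labels per molecule on average, with per-quality
supports spanning two orders of magnitude (a couple of molecules for the
rarest qualities, hundreds for the most common).

A *description* `D` is a conjunction of closed intervals, at most one per
descriptor.  A molecule is covered iff every restricted descriptor value
lies inside its interval; a missing value on a restricted descriptor makes
the molecule **not** covered (the conservative reading: the coverage
condition cannot be verified).  A molecule is a *positive* for a target
quality set `Q` iff it carries every quality of `Q` (`Q ⊆ class(m)`).  The
mirrored containment (`class(m) ⊆ Q`) would exclude multi-labeled molecules
from their own qualities and contradicts the package's worked example, where
molecules carrying *fruity, vanillin* count as vanillin positives.

## Quality measures

With `support(D) = |cov(D)|` and `support(Q)` the dataset-wide positive
count:

    P = positives-in-coverage / support(D)
    R = positives-in-coverage / support(Q)
    F_β = (1 + β)·P·R / (β·P + R)
    β(x) = (0.5 · (1 + tanh((x − xBeta) / lBeta)))²,  x = support(Q)

All measures are defined as 0 when their denominator vanishes, with a flag
in the returned metrics; nothing raises during a mining run.  Note the
`(1 + β)` combination (not the `(1 + β²)` of the classical F-beta family):
β here plays the role of the squared weight directly, which is why the
sigmoid is squared.  `F_β` equals `P` at β = 0 and the harmonic mean F1 at
β = 1, and is monotone in β between `P` and `R`.  The sigmoid is oriented so
that β **increases** with support: rare qualities are scored by precision
(a rare quality's few molecules cannot anchor a high-recall box that means
anything), frequent ones increasingly by recall.  `beta_weight(...,
direction="decreasing")` provides the mirrored convention for comparison.

Parameter meanings and defaults (the reference corpus-scale settings):

| parameter       | default | role                                                |
|-----------------|--------:|-----------------------------------------------------|
| `minSupp`       |       5 | minimum coverage of an emitted rule (all covered molecules, not only positives); typically swept over {5, 10, 20, 30} |
| `maxSupp`       |     700 | maximum coverage of an *emitted* rule               |
| `MaxQual`       |       1 | maximum size of the target quality set              |
| `MaxProperties` |       8 | maximum restricted descriptors per rule             |
| `beamwidth`     |      30 | beam width                                          |
| `maxoutput`     |     100 | rules returned per target                           |
| `XBeta`         |     110 | support at which β = 0.25 (sigmoid midpoint)        |
| `lBeta`         |      20 | sigmoid length scale (smaller = sharper transition) |

`XBeta`/`lBeta` are experimenter-set and must match the corpus scale: 110/20
positions the precision→recall transition around support ≈ 110–150 on a
~1700-molecule corpus.  On smaller datasets the midpoint should be rescaled
accordingly (the planted-box benchmark below uses 40/20 on 500 molecules for
exactly this reason).

## Beam search

The search space is the lattice of interval patterns whose bounds lie on a
per-descriptor grid: either every observed value (`refinement_grid=
"observed"`) or the empirical quantiles (`"quantiles:K"`).  Search starts
from the unrestricted description and refines by *minimal shrinks*: raise a
lower bound to the next grid value above the covered minimum, or lower an
upper bound symmetrically; restricting a new descriptor counts toward
`MaxProperties`.  Every refinement strictly removes at least the molecules
attaining the covered extremum, so coverage shrinks monotonically along any
path.  Candidates below `minSupp` are pruned (safe: coverage only shrinks),
candidates whose coverage set was already seen are deduplicated (F_β depends
only on the coverage), and the `beamwidth` best by F_β seed the next level.

Tie-breaking is fully specified — larger coverage first, then fewer
conditions, then lexicographic on (descriptor, lo, hi) — making the miner
deterministic and invariant to row order; no randomness is used anywhere.

Termination: by default the search runs until the beam produces no coverage
set not seen before, which is guaranteed finite.  An optional `max_stall`
stops earlier after that many consecutive levels without improving the best
score; this is a speed knob for corpus-scale data.  The default was chosen
over a pure no-improvement stop because greedy stopping can halt on a score
plateau before the optimum, breaking the guarantee (tested) that a
sufficiently wide beam equals exhaustive search on enumerable instances.

`maxSupp` is enforced only on emitted rules, not on beam intermediates:
reaching a specific small box requires passing through broad ancestors.

Open design points resolved here (the original search internals are not
normative): the beam is seeded with the unrestricted description rather than
positive-example-closed patterns, and `minSupp` counts all covered
molecules, following the plain reading of "support(D) greater than a
threshold".

## Rule combinations and selection

A quality is usually described by several complementary boxes, so selection
works on *disjunctions*: a combination of up to 12 rules covers the union of
member coverages, the only semantics under which adding a rule can raise
recall.  Per mining run, candidates are ranked by precision (ties: support,
then parsimony) and nested prefixes of sizes 1..12 are evaluated; each
combination is the point `(error, recall) = (1 − P, R)` and the winner
minimizes the Euclidean distance to the ideal `(0, 1)`.  All ties at the
minimal distance (within 1e−12) are kept — equal-distance selections are
meaningful, not noise.  Combinations never mix rules mined under different
`minSupp` runs; each run is a separate candidate pool.  For pools of ≤ 15
rules an exhaustive all-subsets strategy doubles as an oracle: the prefix
heuristic can never beat it, and matches it on the packaged fixtures.

Group boundaries follow the printed conventions verbatim: groups 1/2 require
error strictly < 0.5, groups 1/3 require recall ≥ 0.5.  Distance quartiles
use linear-interpolation percentiles at 25/50/75 with ties sharing the
lowest applicable bin; the percentile method is fixed for reproducibility.

## Bootstrap significance

For a selected ruleset covering X molecules, the null asks how well a random
X-molecule set (drawn uniformly **with replacement** from the whole dataset,
no stratification) would score.  Per resample, precision counts positive
draws over the multiset; recall counts *distinct* positive IDs over
`support(Q)`, capped at 1 — with replacement a duplicate positive is not new
evidence (duplicate counting is available behind `duplicate_recall=True`).
The CI is the plain empirical percentile interval; significance is
one-sided: `observed F > upper bound`.  The F-measure defaults to the same
adaptive F_β used in mining (internal consistency), with F1 selectable.  No
multiple-testing correction is applied across qualities; that is a
deliberate mirror of standard practice for this procedure and is noted
rather than silently changed.

Calibration: under a shuffled-label null with rulesets fixed *independently*
of the labels, the empirical flag rate of the 99% one-sided procedure is
~0.5–1.5%.  Two honest caveats, both measured by the calibration benchmark
(400 molecules, box coverages of ~60, supports 40–80, F1): the observed
coverage is a distinct set while resamples draw with replacement, and the
null F distribution is discrete, so the strict exceedance rate is not
exactly the nominal 0.5%.  The benchmark uses F1 because at these supports
the small-β adaptive measure degenerates to pure precision, whose coarse
discreteness makes the strict test conservative.  Mining rules *on* the
shuffled data and then testing them would inflate the rate far above
nominal — the bootstrap guards a fixed ruleset, not a search.

## External validation

Rulesets are applied to novel rated panels (continuous per-quality scores on
whatever scale the panel uses; ANOVA and η² are affine-invariant, so the
scale is irrelevant).  Molecules are split into Rule(1) (inside the union
coverage) and Rule(0); a classical one-way fixed-effects ANOVA reports
`F = MS_between / MS_within` with df `(1, n − 2)`, p from the F distribution
and `η² = SS_between / SS_total`.  For two groups F equals the squared
pooled-variance t statistic (a tested invariant).  Qualities with fewer than
5 Rule(1) molecules are skipped (logged), matching the usual minimum-group
practice; zero within-group variance with unequal means reports F = ∞, p = 0.
Quality-name alignment across vocabularies (e.g. a ruleset's "sulfuraceous"
vs a panel's "decayed") is a user-supplied alias table, never automatic.
Ratings are analyzed raw; no transformation or assumption checking is
applied.

## Synthetic data

The generator emulates exactly the features the miner assumes: uniform(0,1)
or normal(0,1) descriptors; planted axis-aligned boxes whose members carry a
quality with probability `p_inside` (vs `p_outside` outside); background
labels with a geometric frequency profile (`rate · decay^j`) reproducing the
unbalanced support spectrum; optional top-up sprinkling to hit a target mean
labels-per-molecule; and a one-label fill-in for label-free molecules so the
output loads in annotated mode.  Everything is a deterministic function of
the seed, down to byte-identical CSV files.

What it does **not** emulate: the descriptor correlations of real molecules,
heavy-tailed descriptor marginals, label noise correlated with chemistry, or
annotator idiosyncrasies.  Passing the recovery benchmark therefore shows
the *search* works when the generating process matches the hypothesis class;
it does not certify performance on real atlases.  A `rotate=True` planted
rule places the box in a rotated frame (outside the hypothesis class) for
misspecification studies.

### The recovery benchmark

`benchmark_spec(seed)`: 500 molecules × 5 uniform descriptors; one quality
planted in a 2-descriptor box covering ~16% of molecules (≈ 80), with
`p_inside = 0.9`, `p_outside = 0.02`, background labels averaging ~3 per
molecule.  Mining uses `minSupp 10`, beam 30, `quantiles:16` grid, and
`XBeta 40 / lBeta 20`.  The midpoint rescaling is forced by the measure's
algebra, not tuned: at the corpus-scale 110/20 the planted support of ~80
gives β ≈ 0.002, i.e. a pure-precision objective whose optimum is the
largest all-positive sub-box — recovering the full planted coverage is then
*undesirable* under the measure itself.  With the midpoint at half the
planted support, β ≈ 0.96 and the F_β optimum coincides with the planted
box up to grid resolution and label noise.  Median coverage Jaccard across
20 seeds is ~0.87.

## Numerical choices

- Interval bounds are closed on both ends; coverage comparisons use plain
  IEEE `>=`/`<=` (NaN compares false, giving the not-covered semantics).
- `variance_retained` is the ratio of summed per-column sample variances
  (ddof = 1), computed on raw unstandardized values.  This is one concrete
  stand-in for an otherwise underdetermined "fraction of variance" notion
  (a PCA-based definition would differ); it is monotone under subset growth
  and equals 1 on the full set, which is what the filtering report needs.
- Correlation pruning visits columns in file order and keeps the earlier of
  any pair exceeding the threshold (absolute Pearson r over complete pairs)
  — deterministic and reproducible, since the choice within a pair is
  otherwise arbitrary.
- Selection ties use an absolute tolerance of 1e−12 on distances.
- Degenerate inputs: empty candidate pools, zero-support qualities, empty
  union coverages and all-Rule(1) panels are flagged/skipped with warnings,
  not raised, wherever a batch must survive.

## Problem sizes

The bundled tests and the acceptance script run entirely on synthetic or
packaged inputs: enumerable instances of ≤ 8 molecules × ≤ 3 descriptors for
exhaustive-oracle comparisons, 500-molecule benchmarks for recovery (20
seeds), and 1,000 shuffled-label qualities at 10,000 bootstrap resamples for
calibration.  These sizes make the full pipeline reproducible on a laptop in
well under a minute while keeping every Monte-Carlo tolerance meaningful;
corpus-scale runs (thousands of molecules, ~100,000 resamples) use the same
code paths with the parameters in the table above.

## Known limitations

- The prefix combination search is a heuristic; it is exact on the packaged
  fixtures but can in principle miss the optimal subset on adversarial
  pools (the exhaustive strategy covers pools ≤ 15).
- The bootstrap guards a *fixed* ruleset; it does not correct for the
  selection performed by mining, nor across qualities.
- β's support argument uses the full-dataset support of Q; under heavy
  missingness the effective evaluable support may be smaller.
- Quality vocabularies are treated as flat strings; no semantic similarity
  between labels is modeled.
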