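# Methods

## Removal metrics

Peak areas are treated as relative abundances; no calibration to
concentrations is attempted, so all metrics are ratios that cancel
instrument response. For a treatment stage *x* with input peak area
`P_in`, output `P_out`, and train-influent reference `P_initial`
(all for the same compound and sampling event):

- unit removal efficiency `URE_x = (P_in − P_out) / P_initial`, a
  dimensionless fraction of the influent abundance removed by that
  stage. For a fully measured event the per-stage UREs telescope:
  their sum equals the overall removed fraction
  `(P_initial − P_final) / P_initial`.
- removal efficiency `RE_x = 100 (P_in − P_out) / P_in`, in percent of
  the stage's own input. `RE ≤ 100` always; both metrics can be
  negative when a stage output exceeds its input (desorption,
  deconjugation of metabolites, or measurement noise).

The input of stage *x* is the measured value at the sampling point
immediately upstream, so consecutive stages chain. Stage metrics are
averaged over sampling events with the unweighted arithmetic mean.

### Below-detection rules

A value under the detection limit is a categorical flag ("B.D."), never
the number zero. Per event and stage:

| input | output | RE | URE |
|---|---|---|---|
| measured | measured | computed | computed |
| measured | B.D. | computed with output := 0 (complete removal) | same |
| B.D. | measured | skipped (undefined without an input) | computed with input := 0 |
| B.D. | B.D. | skipped | skipped |

An event whose influent itself is below detection contributes no URE
(the normalising reference is undefined); RE is unaffected except
through the input rule above. A record absent from the table is treated
as below detection. When every event is skipped the stage average is
absent, with a zero usable-event count; a stage whose input is B.D. in
every event is marked `bd_input`, which feeds the pattern encoding.
Usable-event counts are tracked separately for URE and RE because the
one-sided rules differ.

### Preprocessing

Two filters run before any clustering: compounds with no detected value
at any stage of any event are removed, and the table is then restricted
to compounds shared among all sampling events (present means having any
record in the event, measured or B.D.). The filters are idempotent and
never invent records. Replicate injections, when present in the input
file, are averaged at read time, ignoring B.D. replicates unless all
replicates are B.D.

## C1: best-stage clustering

Per compound, the stage with the highest average URE among stages with
at least one usable event; compounds sharing a winning stage form a
cluster. Exact ties break toward the upstream stage, making the
assignment deterministic. A compound whose best URE is negative is
still assigned (every retained compound receives a label) but its
best-URE value is exported so such cases are visible. Compounds with no
eligible stage at all are reported as unassignable rather than dropped.

## C2: removal-pattern clustering

Average RE per stage is compared with the previous stage's and coded as
increase (difference > ε), decrease (< −ε), or same, with ε = 1
percentage point by default; exact float equality would make "same"
unreachable, and ε is exposed as a flag. The first treatment process is
compared against a 0% baseline so all sequences have equal length. A
stage whose input is below detection in every event codes as the fourth
symbol, B.D.; when a compound becomes measurable again after a B.D.
stretch, the comparison resumes against the most recent defined
average.

The sequences are clustered by K-modes (k = 3 by default): Hamming
(simple matching) dissimilarity, cluster centres updated per position to
the most frequent member symbol. The implementation is written for full
determinism given a seed:

- initial modes are k distinct observed patterns sampled without
  replacement (duplicates, with a warning, when fewer distinct patterns
  exist);
- assignment ties go to the lowest cluster index;
- a mode-update tie keeps the previous mode's symbol when it is among
  the tied symbols, otherwise takes the first tied symbol in the
  canonical order (increase, decrease, same, B.D.);
- an empty cluster is reseeded with the pattern farthest from its
  assigned mode (skipped when all distances are already zero, e.g. all
  patterns identical — the final result then simply has fewer non-empty
  clusters);
- 50 random restarts by default; lowest total cost wins, earliest
  restart on ties. Total cost is asserted non-increasing at every
  iteration.

B.D. participates in the Hamming distance as an ordinary fourth symbol.
On small instances (≤ 8 patterns, length ≤ 4, k ≤ 3) the restarted
heuristic attains the exhaustively enumerated optimal partition cost;
this is exercised in the test suite against a brute-force oracle.

## Descriptor classification

Features are the six Abraham solvation descriptors — E (excess molar
refraction), S (dipolarity/polarizability), A (hydrogen-bond acidity),
B (hydrogen-bond basicity), V (McGowan volume), L (log gas–hexadecane
partition) — plus log K_ow, in that fixed column order. Labels come
from C1 or C2. Three classifiers are compared with pinned
configurations so "defaults" is an explicit, frozen statement: SVM
(RBF kernel, C = 1, γ scaled from feature variance), random forest
(100 trees, Gini splitting, bootstrap), logistic regression (ridge
penalty, C = 1, LBFGS). No feature standardisation is applied by
default; a `--standardize` option exists because the RBF kernel is
scale-sensitive.

Cross-validation uses seeded shuffled folds of near-equal size (plain
splits by default, stratified on request). Accuracy on the held-out
fold is the metric; per-class recall is emitted for diagnostics only. A
fold whose training half degenerates to one class is excluded from the
mean with a warning; a class with fewer than two members triggers a
warning but is kept. Feature importance is the impurity-decrease
importance of a forest trained on all data, normalised to sum to one.

## Concordance and statistics

Descriptors are z-scored per column (population SD; constant columns
zeroed with a warning — without scaling, Euclidean distances would be
dominated by L) and clustered with K-means (k-means++ seeding, 10
restarts), with k taken from the paired removal clustering. The overlap
between removal and property clusters is counted on the contingency
matrix under the injective row-to-column correspondence maximising the
matched sum, found by optimal assignment; this upper-bounds any fixed
pairing and is deterministic. The dominant-cell heuristic is not used
for the headline number.

Kruskal–Wallis H is computed from mid-ranks with the standard tie
correction and a chi-square p-value on (groups − 1) degrees of freedom;
the implementation is independent of `scipy.stats.kruskal`, which
serves as a cross-check oracle in the tests. One test per descriptor is
run across clusters at α = 0.05 without multiple-testing correction
(a Bonferroni column is emitted for transparency but does not drive
the significance flag). The degenerate all-identical case returns
(H = 0, p = 1).

## Synthetic studies

Each compound belongs to one archetype with true per-stage removal
fractions `r_s ∈ [0, 1)`. Peak areas propagate multiplicatively,
`A_s = A_{s−1} (1 − r_s) e^ε` with `ε ~ N(0, σ²)` independent per stage
and event, from a lognormal influent draw per compound and event;
multiplicative lognormal noise reflects positive, heteroscedastic
instrument intensities. Expected areas follow
`A_0 ∏(1 − r_i) · e^{σ² s / 2}`. Any area under the detection limit is
recorded as B.D. Descriptor vectors are Gaussian per archetype; the
separation between archetype means is scaled by an effect size Δ, so
Δ = 0 is a built-in null where descriptors carry no cluster
information. The ground truth stores each compound's archetype and its
dominant stage, defined on the influent-normalised removed fraction
`r_s ∏_{i<s}(1 − r_i)` — the same objective C1 maximises.

Two presets emulate typical field configurations: `potable`, an 8-stage
advanced-reuse train (influent, primary, activated sludge,
flocculation/sedimentation, ozone, BAC, GAC, UV) and `nonpotable`, a
5-stage train ending in denitrification-filtration and chlorination.
Both use 120 compounds, 4 sampling events, three archetypes
(biodegradable / oxidisable / adsorbable, equal weights) with distinct
dominant stages, influent log-mean 13 (≈ 4.4 × 10⁵ area units) with
log-SD 1, noise σ = 0.15 (≈ 15% multiplicative measurement error, a
typical non-target LC-MS variability), detection limit 5 × 10³ (low
enough that only strongly removed compounds go below detection at late
stages), and Δ = 1.

What the generator does **not** emulate: correlation structure among
the Abraham descriptors of real molecules (draws are independent
Gaussians), transformation products re-forming parents (negative
removals arise only stochastically from noise), matrix effects, and
event-to-event drift. Recovery results on synthetic studies therefore
demonstrate the correctness and determinism of the algorithms under the
stated data model, not field-data performance.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script use 40–150 compounds
per study, 4 events, 5–8 stages, and 5–20 seeds per recovery
experiment — sizes at which every planted-truth check is sharp while a
full run stays fast. K-modes optimality is verified by exhaustive
enumeration only on small instances, where enumeration is exact.
Pattern-recovery studies use three archetypes whose noise-free symbol
sequences are pairwise Hamming distance 3 apart with noise σ = 0.01, so
"low noise" is concrete and the ≥ 0.9 adjusted-agreement bar tests the
clustering, not the generator. Pipeline outputs are written with sorted
JSON keys and fixed float rounding so equal seeds give byte-identical
summaries.

## Known limitations

- The first pattern symbol is defined against a 0% baseline and is
  therefore almost always "increase"; it carries little information but
  keeps sequence lengths uniform.
- Accuracy is the sole cross-validation metric, which can flatter
  majority classes under imbalance; per-class recall is exported for
  inspection.
- The overlap percentage under optimal matching is an upper bound over
  fixed cluster pairings and should not be compared against numbers
  derived from a dominant-cell heuristic.
- Kruskal–Wallis p-values rely on the chi-square approximation, which
  is inaccurate for very small groups; a warning is raised for
  singleton clusters.
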