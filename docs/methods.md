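# Methods

## Problem and model

Multi-fatality road crashes (three or more deaths) arise from interacting
driver, vehicle, roadway, environment and crash-dynamic factors. The package
treats a corpus of crash records as a boolean transaction table — one row per
crash, one column per coded sub-item of an 18-category scheme — and extracts
interpretable structure in two stages:

1. **Association-rule mining.** Apriori level-wise search enumerates frequent
   itemsets, and rules `X → Y` (itemset antecedent, single-item consequent)
   are scored by support `Supp(X→Y) = #(X∪Y)/N`, confidence
   `Conf(X→Y) = Supp(X∪Y)/Supp(X)`, and lift `Lift(X→Y) = Conf(X→Y)/Supp(Y)`.
   Lift 1 is item independence; lift > 1 marks positive association.
2. **Rules-graph structures (RGS).** The kept rule set becomes a directed
   graph with one node per factor and per rule (antecedent factors → rule
   node → consequent factor). Degrees, closeness, PageRank, and a Louvain
   community partition with Newman modularity Q summarise which factors are
   central and which rule families cluster together.

## Mining thresholds

The default working point is S ≥ 6 %, C ≥ 75 %, L > 1.3 with at most three
antecedent items. Support and confidence are inclusive bounds, lift strictly
greater — mirroring how the working point is conventionally quoted. The
antecedent-size cap of 3 is configurable; all published high-value rules in
this setting have ≤ 3 antecedents. `threshold_sweep` reproduces the
trial-and-error calibration view (rule count and lift range per grid point,
without a lift cut) that motivates such a working point: very permissive
thresholds produce tens of thousands of rules with lifts straddling 1, and
very strict ones produce a handful of near-independent rules.

All items are eligible as antecedents and consequents at mining time; domain
exclusions are deferred to the declarative meaningfulness filter so the
mining stage stays mechanical and the exclusions auditable.

## Rule screening

Stages run strictly in order — LIC, significance, meaningfulness — and each
stage only removes rules.

* **Lift-increase (LIC).** For a rule with n+1 antecedent items,
  `LIC = Lift(X_{n+1}→Y) / Lift(X_n→Y)` against an n-item base rule with the
  same consequent. Below the default threshold 1.03 the added item does not
  buy interest and the longer rule is redundant. The strictest reading is the
  default: the improvement must hold against *every* immediate sub-rule
  (`lic_mode="all"`); a relaxed `"any"` mode is available. Base rules that
  fail the mining thresholds are recomputed directly from the data rather
  than skipped, so the comparison is always defined. The recorded LIC is the
  binding (minimum) ratio under `"all"`.
* **Significance.** One-sided Fisher's exact test (alternative: positive
  association, matching the lift > 1 screen) on the 2×2 antecedent ×
  consequent contingency, computed as the upper hypergeometric tail.
  Degenerate margins give p = 1 by convention. Bonferroni correction uses
  m = the number of rules entering the stage (post-LIC); keep p < α/m with
  α = 0.01. The denominator choice is configurable (`correction="none"`
  disables it); FDR-style alternatives are deliberately out of scope beyond
  this hook.
* **Meaningfulness.** Rules whose antecedent merely restates the consequent
  (an afternoon time band implying daylight; a > 80 km/h posted limit
  implying a freeway) carry no safety information. The shipped blacklist
  holds both directions of the two canonical tautology pairs
  (Time ↔ Light condition, Limit speed ↔ Road category) at category level;
  entries may also name individual items for finer overrides. The filter is
  declarative on purpose — this exclusion is a judgement call and must be
  visible in configuration, not buried in code.

## Graph analysis

* **Projection.** Closeness and modularity operate on the undirected
  projection of the factor/rule digraph: on the raw directed graph most
  node pairs are mutually unreachable (consequent-only factors have no
  outgoing edges), which would leave closeness mostly undefined, and the
  Newman modularity formula is an undirected form.
* **Closeness** is `C(x) = N / Σ_y d(y,x)` with N the graph node count. On
  disconnected graphs distances are summed within x's component and the
  score scaled by `(reachable−1)/(N−1)` (Wasserman–Faust), so small
  fragments do not dominate; isolated nodes score 0.
* **PageRank** is the classic unnormalized recursion
  `PR(v) = (1−d) + d·Σ_u PR(u)/outdeg(u)` over in-neighbours u, damping
  d = 0.85, iterated from all-ones until the max-norm change is below `tol`
  (default 1e-10; non-convergence raises with the residual). Scores need not
  sum to 1: a node with no in-edges scores exactly 0.15 and a directed cycle
  fixes at 1. Dangling-node rank is not redistributed. The stochastic
  (normalized) variant is available behind `normalized=True` purely as a
  cross-check.
* **Modularity and communities.** Q is the Newman form with m = undirected
  edge count (a common prose slip defines m as the module count; that reading
  does not produce Q ∈ [−½, 1] and is not used). Community detection is the
  Blondel et al. greedy agglomeration (Louvain, via networkx) with a fixed
  seed; modules are relabelled by lexicographically smallest member so output
  is stable. Q > 0.3 is read as the conventional significance bar, and only
  that inequality — not a specific Q value — is treated as reproducible,
  since Louvain outcomes are run-dependent in the third decimal.
* **Factor contributions.** Within each system construct (driver, vehicle,
  roadway, environment, crash), a factor's contribution is its closeness as a
  percentage of the construct total, ranked descending — the hierarchical
  "which factor matters most within its subsystem" view.

## Synthetic generator

The generator exists so every stage is testable without the study's deposited
data. It emulates two things about real crash tables: the *marginal*
frequencies of the 85 coded items (defaults are the published per-item counts
over the 1068-record corpus) and *planted* antecedent→consequent dependencies
with exact analytic metrics.

Planting is blockwise: a latent indicator is true with probability `p_lhs`,
forcing the whole LHS on and drawing Y with `conf_true`; otherwise LHS items
follow their background marginals *conditioned on not all being true*
(rejection resampling) and Y uses `conf_false`. The conditioning removes
leakage, so

    support = p_lhs·conf_true,  confidence = conf_true,
    lift = conf_true / (p_lhs·conf_true + (1−p_lhs)·conf_false)

hold exactly in expectation — recovery tests compare mined metrics to these
closed forms within 3 binomial standard errors at n = 20 000. Multiple
planted rules must have disjoint consequents (shared consequents would
compound the conditionals and destroy the closed form), and a planted
consequent may not carry an independent background marginal.

What the generator does **not** emulate: the exclusivity structure (items are
drawn independently, so e.g. two terrain levels can co-occur in a synthetic
record), the full joint dependence of the 84-odd real items, and the realistic
construct-combination (Venn) profile — with independent draws at these
marginals nearly every record touches all four system constructs, whereas
real corpora show a much lower all-four share. Passing tests on synthetic
data therefore demonstrate the correctness of the mining/filtering/graph
machinery, not distributional claims about real crash data.

The default demonstration configuration (1068 records) plants four
dependencies emulating documented strong patterns — sharp-radius/down-grade
geometry, roadside single-vehicle run-off-road, multi-lane rear-end, and
undivided-highway head-on — with confidences 0.80–0.85 and block
probabilities chosen so the implied consequent marginals match the published
ones (e.g. P(Lanes num > 2) ≈ 0.50). These are fixed package defaults, not
tuning knobs.

## Numerical choices

* All rule metrics are computed from integer record counts, so
  `support = confidence × Supp(LHS)` holds to float rounding.
* Fisher p-values use the hypergeometric survival function; tests verify it
  against exhaustive fixed-margins enumeration up to n = 60.
* Itemset and rule orderings are canonical (size, then lexicographic label),
  k-means and Louvain take explicit seeds, and rule nodes get stable ids in
  canonical rule order — reruns under the same seed are byte-identical.
* The raw-categorical CSV loader encodes blank cells as all-false across the
  category's items: N is preserved and no value is imputed. Exclusivity
  violations are reported (and warn in the pipeline) rather than fatal by
  default, since published coded data may contain coding noise; a strict CLI
  flag turns them into errors.
* The catalog stores the published per-item counts verbatim, including two
  internally inconsistent cells of the source table (a count/percentage
  mismatch for passenger overload and for angle collisions); observed
  marginals from data are always reported in preference to forcing agreement
  with the printed table. The printed sub-item rows total 85 although the
  accompanying text says 84; the catalog carries all 85 printed rows.

## Problem sizes

The default test and acceptance workloads use 1068-record tables over the
full 85-item catalog for pipeline runs, n = 20 000 tables over a handful of
items for recovery experiments, and ≤ 300-record, ≤ 12-item tables for
exhaustive-oracle equivalence — sizes at which every oracle (full itemset
enumeration, fixed-margins Fisher enumeration, brute-force shortest paths)
is itself exact and fast.

## Known limitations

* The meaningfulness stage is only as good as its blacklist; no semantic
  detection of tautological rules is attempted.
* K-means on binary antecedent-membership vectors is the conventional
  grouping tool here, but Euclidean k-means on binary data is a heuristic;
  group labels (dominant items) are descriptive, not model-based.
* The unnormalized PageRank variant is kept for fidelity to the RGS
  formulation; for cross-study comparison the normalized variant should be
  preferred.
* Reproduction checks against the deposited 1068-crash corpus and 1452-rule
  file require those supplementary CSVs to be placed under `data/`; they are
  not redistributed with the package.
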