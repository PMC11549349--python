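# Methods

This note documents the models, numerical choices, and limitations behind
each stage of the pipeline, in the order the stages run.

## Vertebral morphometrics

A vertebra is a bag of named positive lengths (mm), angles in (0, 180]
degrees, and boolean anatomical flags. Missing measurements are absent
keys — never zeros — and propagate as "missing" through every downstream
computation; a ratio is reported only when both operands are recorded.
Reported ratios are rounded half-up to a caller-chosen number of
decimals (matching how such ratios are conventionally printed); stored
measurements are never rounded.

Trunk-position classification is deliberately simple and deterministic:

1. a hypapophysis marks an anterior trunk vertebra (ATV);
2. a chisel-shaped posterior hemal process marks a mid-trunk vertebra
   (MTV);
3. otherwise the neural-arch-width criterion applies: zygapophyseal
   width / centrum length > 1 classifies as MTV, ≤ 1 as posterior trunk.

The width operand defaults to the trans-prezygapophyseal width (prW) and
can be switched to poW; the positional criterion in the comparative
literature does not fix the operand, so it is a parameter. Cloacal/caudal
vertebrae are out of scope (the classifier never returns that class); the
boundary case width/cL = 1 goes to posterior trunk, so MTV strictly
requires relative widening. Size-estimation specimens are the
MTV-classified subset sorted by descending width with a lexicographic
specimen-id tie-break, making selection reproducible under permutation.

## Allometric body-length estimation

Vertebral width tracks total body length (TBL) tightly enough across
extant snakes that a single width supports a point estimate. Three
published predictive equations ship as frozen coefficient sets
(provenance BUILTIN); their comparative datasets are not bundled, so
built-in models support prediction and algebraic inversion but not
prediction intervals (those need the design matrix). All equations work
in mm on both axes; metres are a rendering (half-up to 0.1 m), never the
computation scale. We verified the unit convention by evaluating the
log-log model C at the largest observed prezygapophyseal width
(111.4 mm), which yields 15,218 mm ≈ 15.2 m, the expected magnitude for
the largest madtsoiids.

Fitting uses ordinary least squares (statsmodels). The LOG10LOG10 form
log-transforms both variables before the fit — the standard
normalisation for allometric data — and back-transforms predictions;
the LINEAR form fits raw mm. The slope p-value is the two-sided t-test
with n−2 df. `se_pred` reports the residual standard error on the
response scale; for log10 fits it is converted by the delta method at
the mean predictor (a first-order approximation adequate for the small
residual scatter these datasets show). Prediction intervals are the
standard OLS new-observation intervals, symmetric on the fitted scale
and back-transformed for log-log models; degenerate designs (zero
predictor variance) raise a dedicated error rather than producing
numerically meaningless coefficients.

## Metabolic-scaling paleothermometry

Poikilotherm maximum body size is temperature-limited: resting metabolic
rate scales with mass to an exponent α and increases by a factor Q10 per
10 °C. Comparing a fossil's maximum TBL with the maximum TBL of its
closest modern analogue living at a known mean annual temperature (MAT)
gives a mean annual paleotemperature:

    MAPT = MAT + 3·α·10 · log10(TBL_v / TBL_M) / log10(Q10)

Parameters (with defaults): MAT = 26.5 °C, TBL_M = 10.05 m (reticulated
python, the longest extant snake), Q10 = 2.6 (pythonid mass-specific
metabolic rate), α = 0.17. All logarithms are base 10.

Two algebraically near-identical forms are implemented. The EXACT form
uses log10(Q10) = log10(2.6) = 0.41497…; the SIMPLIFIED form uses the
widely printed truncated constants 5.1 (= 3·α·10) and 0.41. Over 5–20 m
the forms differ by at most 0.05 °C; the EXACT form is the default and
reports always show both plus their difference. Evaluated at
TBL_v = 15.2 m the simplified form gives 28.74 °C (28.7 at one decimal),
about 0.1 °C above the commonly quoted 28.6 °C upper bound for this
chain — a rounding-path difference we document rather than tune away,
since the identity MAPT(TBL_M) = MAT holds exactly and the computation
is a direct evaluation of the printed equation. The assumptions are
strong (the analogue is at its thermal maximum body size; α and Q10
transfer across clades); the module therefore deliberately exposes every
parameter and does no uncertainty propagation beyond evaluating the
equation at user-supplied TBL endpoints.

## Maximum parsimony

### Matrix model

Cells are state sets (singleton = observed state, larger = polymorphism)
or the sentinels MISSING (`?`) and INAPPLICABLE (`-`). Both sentinels are
optimized as full ambiguity — the pragmatic convention of mainstream
parsimony software — but the distinction survives every I/O round trip.
Characters carry per-column ordering (default unordered), activity, and
positive integer weights; TNT `ccode` fragments (`+ - [ ] /N`, indices
and `a.b` ranges) set them. TNT xread parsing is implemented natively
(no installed library reads TNT); NEXUS goes through dendropy.

### Tree length

Unordered characters use the Fitch bitmask pass, vectorized across
columns (state sets as uint64 masks; an intersection-empty node
contributes its column weight). Ordered characters use the Farris
bounded-interval pass with polymorphic cells reduced to their [min, max]
interval. Lengths are exact minima for binary trees; the test suite
cross-checks every tested instance against an independent uniform-cost
Sankoff dynamic program and, on six/seven-taxon problems, against
exhaustive enumeration of all topologies.

### Search

Each replicate draws a random taxon addition sequence, builds a greedy
Wagner starting tree, and hill-climbs by tree-bisection-reconnection:
every edge is bisected and the two subtrees rejoined across all pairs of
attachment edges. Strictly shorter neighbors are accepted immediately
(so the within-replicate best length is monotone non-increasing); on a
plateau up to `trees_per_rep` distinct equal-length trees are collected
and each is swapped once. The global pool is deduplicated by bipartition
set, capped at `maxtrees`, and filtered to the overall minimum. All
randomness flows from one seeded generator (`SeedSequence([seed, rep])`),
so runs are bit-reproducible; tie-breaks are first-found under sorted
edge enumeration. Defaults (50 replicates, 10 trees/replicate,
maxtrees 10,000) mirror the conventional "traditional search" protocol.
The implementation targets matrices up to roughly a hundred taxa;
no ratchet or sectorial search is provided.

### Ensemble indices

CI = Σwᵢmᵢ / L and RI = (ΣwᵢGᵢ − L) / (ΣwᵢGᵢ − Σwᵢmᵢ), where mᵢ is the
minimum conceivable steps of character i (observed states − 1 for
unordered, with a greedy set-cover treatment of polymorphic cells;
observed interval span for ordered) and Gᵢ its star-tree length
(n_scored − max state frequency for unordered, crediting polymorphic
cells to any contained state; minimized sum of interval distances to a
common center for ordered). All-missing characters contribute zero to
every sum; when ΣG = Σm the RI is undefined and reported as None.
Autapomorphies are included by default — the common reporting
convention — with an `informative_only` flag for the alternative, since
published index values rarely state which convention was used.

### Bremer support

Decay values come from a suboptimal tree pool, not per-clade constrained
searches: starting from the optimal trees, TBR neighborhoods are visited
breadth-first and every distinct tree within `margin` steps of the
optimum (default 20) is retained, up to a pool cap. For each clade of
the majority-rule reference tree, decay = (shortest pool tree lacking
the clade) − best length; clades never contradicted within the margin
report "≥ margin". Because the pool samples tree space, values are
lower-bound estimates; on small problems (≤ 7 taxa) the pool reaches the
full margin neighborhood and the values are exact, which is how the
tests validate them.

### Consensus

Strict consensus keeps clades present in all trees; majority rule keeps
clades in strictly more than a fraction f (default 0.5, which guarantees
compatibility) and annotates each with its percentage frequency.
Consensus trees may be polytomous; greedy compatible-clade completion is
deliberately not performed.

## Time calibration

The chronogram module implements minimum-age calibration, the simplest
fully reproducible rule for plotting a topology against the geological
time scale: the tree is rooted on the outgroup edge (a new bifurcating
root joins the outgroup and the ingroup), every tip sits at its first
appearance datum (FAD, Ma; larger = older), and every internal node
takes the maximum FAD of its descendant tips, plus an optional uniform
padding at the root only. Zero-length internal edges are permitted and
common. Ghost lineage per tip = parent age − tip FAD, always ≥ 0. The
FAD–LAD range rides along as metadata for rendering. This is a
visual-plotting convention, not a dating method: no branch-length model,
no cal3/fossilized-birth-death, and node ages are minima, so real
divergences are at least as old.

## Synthetic data

The generators provide every pipeline input with known ground truth,
emulating the empirical study conditions where those are stated:

* **Trees**: Yule topologies (dendropy pure-birth simulation), branch
  lengths rescaled to unit maximum root-to-tip depth so the matrix
  generator's `change_rate` reads as expected changes per character per
  tree depth.
* **Matrices**: k-state symmetric Mk evolution
  (p_same = 1/k + (1−1/k)·exp(−k/(k−1)·rt) per branch), uniform root
  state, no rate heterogeneity by default. Missingness is uniform at
  random with an exact-count contract (⌊frac·cells⌋ cells blanked);
  real morphological missingness is structured, so a block-missing
  option blanks whole character blocks for chosen taxa, emulating
  vertebra-only fossils unscorable for cranial characters.
* **Allometric datasets**: widths log-uniform over 5–120 mm, responses
  from the configured model (defaults: the model-C coefficients,
  n = 21 matching the extant comparative sample, log-scale noise
  sd 0.02) with log-normal or Gaussian noise by form.
* **Vertebral series**: a 27-vertebra precloacal column; the anterior
  `atv_fraction` (default 0.2) carries hypapophyses, the rest the
  chisel-shaped process; the size profile ramps deterministically to
  the configured extremes (cL 37.5–62.7 mm, prW 62.4–111.4 mm) so the
  configured maxima are reproduced exactly, with small jitter confined
  to accessory dimensions; prW/cL > 1 throughout.

Everything is deterministic under the configured seed, with stage-level
seeds derived as `SeedSequence([seed, stage])`.

What passing tests on these data do and do not show: the generators have
no character correlation, no clade-structured body size, no
intracolumnar shape model beyond the monotone ramp, and uniform (or
block) missingness only — so green tests demonstrate algorithmic
correctness and statistical calibration under the stated models, not
robustness to the full messiness of real morphological data.

### Recovery experiment calibration

The matrix generator's headline check — heuristic search recovering the
generating tree — was calibrated by pilot runs at the default
conditions (10 taxa, 200 binary characters, rate 0.5 changes per depth,
no missing data, 50 seeded replicates). Yule trees regularly contain
internal edges shorter than 1% of tree depth that no finite character
sample can resolve, and the search provably reaches a tree at least as
short as the generating tree in every pilot run, so full-topology
recovery is bounded by the data, not the algorithm. The frozen check is
therefore split-level: pooled over the 50 runs, ≥ 85% of generating
bipartitions must appear in an optimal tree (pilot value 88.3%).

## Problem sizes used by the test and acceptance runs

Exhaustive oracles run at 6–7 taxa (105 / 945 topologies); the
search-vs-oracle comparison uses 100 seeded 7-taxon, 20-character
matrices at 5 replicates × 10 trees; allometric recovery uses 200
seeded 21-point datasets; the recovery experiment 50 seeded
10-taxon × 200-character matrices. These sizes keep the full suite
around half a minute while leaving every check statistically
meaningful. The published-matrix benchmarks (22 × 656 and 72 × 785)
run only when the supplementary data files are supplied under `data/`.

## Known limitations

* TBR neighborhoods are enumerated in O(n³) per tree; searches beyond
  ~100 taxa need patience or a faster engine.
* Bremer values are pool-based lower bounds (exact only when the pool
  saturates the margin neighborhood).
* Ordered-character maximum steps use the star-tree value; exotic
  weighting schemes (implied weights, step matrices) are unsupported.
* Built-in allometric equations cannot produce prediction intervals
  (no design data); fitted models can.
* The MAPT equation inherits its analogue-taxon assumptions; results
  shift linearly with log TBL_M and proportionally with α.
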