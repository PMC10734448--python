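# Methods

## The analysis model

`straintrack` treats strain identity as a property of consensus marker-gene
sequences. For each species, every sample contributes at most one consensus
sequence per marker (the dominant strain's); uncovered positions are `N`.
The analysis therefore sees only the dominant strain per sample and cannot
detect minority-strain co-carriage — a known property of consensus-based
strain callers that carries over here.

The pipeline is a fixed composition:

1. **breadth filter** — a marker counts as observed in a sample iff
   `100 × breadth ≥ breadth_threshold`, with breadth computed on the
   *untrimmed* sequence (breadth models raw coverage; trimming models
   alignment-edge noise, so it happens after);
2. **trim** — `trim_sequences` bases off both ends (0-based half-open
   slicing); markers whose length is ≤ 2×trim are dropped for *all* samples,
   with a warning, so rows stay aligned;
3. **marker filter** — keep markers observed in
   `≥ marker_in_n_samples` percent of samples;
4. **sample filter / detection** — keep samples with
   `≥ sample_with_n_markers` kept markers;
5. **concatenation** — kept, trimmed markers in lexicographic marker-id
   order; a kept sample's absent markers are filled with `N`, which the SNV
   computation then skips naturally.

All four thresholds are inclusive (≥), and percent comparisons are exact
(`100 × fraction ≥ threshold`, no rounding). Raising any parameter can only
shrink the kept-sample set; the test suite checks this monotonicity on random
fixtures.

## Distances and normalization

The SNV rate for a pair is mismatches over mutually covered positions;
columns with `N`, `-`, or any non-ACGT symbol in either row are excluded,
comparison is case-insensitive. A pair sharing zero positions has an
*undefined* distance (NaN): it is excluded from the median and from binning,
and reported separately rather than imputed. Distances are raw proportions —
no Jukes–Cantor correction — matching the downstream use, which only compares
distances within a species.

Normalization divides by the median over defined off-diagonal values, each
unordered pair counted once, intra and inter pairs pooled (the per-species
median is defined over *all* pairs). The even-count median is the mean of the
two central values. An all-identical cohort (median 0) is an error, not an
infinite matrix.

## Retention calling

Pairs are categorized purely from metadata: intra (same subject, different
timepoints), inter at the same timepoint, inter across timepoints. Bins have
width 0.1 and are half-open `[k·w, (k+1)·w)` — a value exactly at a boundary
goes up. Retention is *strictly below* the threshold, which makes "bins
0.0–0.1" exactly bin {0} and "0.0–0.2" exactly bins {0, 1}; the boundary is
arbitrary at measurement precision, and this rule keeps bins and retention
calls consistent. The retained fraction's denominator is intra pairs with a
defined distance only.

**Threshold suggestion.** The data-driven rule grows the threshold from one
bin upward while (a) the next bin holds a larger fraction of intra pairs than
of inter pairs (the bin is "intra-dominated") and (b) the inter-pair fraction
below the grown threshold stays at or below a cap (default 5%, configurable).
A simple "smallest bin with inter contamination under the cap" rule cannot
work: the inter fraction below t is monotone in t, so it would always stop at
one bin and could never produce the wider two-bin threshold that species with
broader within-host drift need. If even the first bin violates the cap, the
intra and inter distributions overlap and the single-bin threshold is
returned flagged with a warning.

## Clustering and tracks

"Cluster at 0.01 branch length" is implemented as single-linkage
agglomeration on patristic distances: leaves connected by a chain of pairwise
path lengths ≤ 0.01 share a cluster. This reading is reroot-invariant (tip-to-
tip path lengths do not depend on the root), which an edge-cutting reading is
not; the threshold is a parameter, so other values are one call away. Labels
are letters by first appearance in tip order, making reports reproducible.
A neighbor-joining builder (scikit-bio) closes the synthetic pipeline when no
externally built tree is supplied; NJ's occasional tiny negative branch
lengths are clamped to zero. Cluster–MLST agreement is the adjusted Rand
index over samples carrying both labels.

## Benchmarking

Confusion counts are taken over the intersection of samples with both a
detection call and a culture result; culture-NA samples simply drop out, so
per-species denominators vary. Sensitivity/specificity/F1 are kept at full
precision internally and rounded only in formatted reports (integer percents,
F1 to two decimals). Grid ranking pools confusion counts across species into
one overall F1 (micro-average) by default because per-species F1 can be
undefined when a species has no culture positives; a macro-average option
exists. Ties rank by a range-normalized L1 distance to the default parameter
set (each dimension contributes |x−d|/range over the grid bounds; a
zero-range dimension contributes 0). The shipped grid spans breadth 20–80 in
steps of 10, marker-in-n-samples 10–80, sample-with-n-markers {10, 15, 20},
trim fixed at 50 — a reconstruction spanning the plausible ranges, not a
verbatim copy of any particular study's enumerated sets.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
any particular cohort's biology:

- **Genealogy.** Per species there is one reference sequence per marker
  (IID uniform A/C/G/T). A subject's founding lineage mutates the reference
  at `inter_subject_divergence`; at each subsequent visit the lineage is
  retained with probability `retention_prob` (mutated at `drift`) or replaced
  by a fresh lineage drawn from the reference at `replacement_divergence`.
  Mutation is independent-site substitution to one of the other three bases
  uniformly, so two independent lineages at divergence *d* sit at an expected
  raw mismatch rate 2d(1−2d/3); a retained pair sits at the drift rate.
- **Coverage.** A per-sample mean depth is log-normal
  (`coverage_mean` = 8, `coverage_sigma` = 0.6 by default — deep enough that
  breadth is rarely limiting unless deliberately lowered); per-marker depth
  multiplies a Gamma(4, 0.25) factor, and breadth is 1−exp(−depth) (Poisson
  coverage). Masking removes exactly `round((1−breadth)·L)` positions as a
  few non-overlapping contiguous blocks — read dropout is bursty, not IID per
  site — laid out by a stars-and-bars gap draw so the realized breadth equals
  the drawn one.
- **Culture.** Depth maps to a semi-quantitative abundance grade 0–4 via
  fixed cutoffs; culture positivity is Bernoulli with a per-grade probability
  that is monotone in the grade (0.02, 0.45, 0.75, 0.92, 0.99). Non-carriers
  are grade 0.
- **Determinism.** All randomness flows through one
  `numpy.random.Generator` passed explicitly; a fixed seed reproduces FASTA
  and tables byte for byte.

What the generator does *not* emulate: raw reads, host DNA, within-sample
strain mixtures, recombination, marker-specific mutation rates, or any claim
about the true retention process in real infant cohorts. Tests passing on
synthetic cohorts show the estimator recovers the generating process it
assumes — they do not validate the biology of any real data set.

## Validation studies and problem sizes

- **Retention recovery:** cohorts of 50 subjects × 2 visits (10 markers ×
  300 bp), retention probability ∈ {0.2, 0.4, 0.6}, drift 0.001, replacement
  divergence 0.05, 20 replicate seeds per setting; the recovered retained
  fraction is checked against the central 95% binomial interval of the truth.
  At 50 intra pairs the binomial sampling floor on the mean absolute error is
  E|p̂−p| = √(p(1−p)/50)·√(2/π) ≈ 0.055 at p = 0.4, so the tighter MAE ≤ 0.05
  check runs on 200-subject cohorts, where the floor is ≈ 0.028 and the bound
  is attainable by a correct estimator.
- **Cluster recovery:** 10–12 planted lineages (full retention, divergence
  0.05, drift 0.0005), rebuilt via NJ + single linkage at 0.01; cluster count,
  partition and ARI = 1 against lineage truth.
- **Grid study:** 15-subject cohorts at mean depth 1.2 so the default 80%
  breadth threshold loses true carriers and relaxed sets win the ranking.

These sizes keep the full suite around half a minute on one CPU while leaving
the binomial checks well-powered.

## Known limitations

- Dominant-strain-only resolution; co-carriage is invisible.
- The filter order and tie handling are this package's own documented,
  self-consistent choices; bit-compatibility with any external marker-filter
  implementation is not claimed.
- Retention thresholds are on the normalized scale and inherit the cohort's
  median divergence; cohorts with very few inter pairs normalize noisily.
- The NJ fallback is plumbing: for publication-grade trees supply an
  externally built newick.
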