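# Methods

`motupipe` implements a reverse-taxonomy workflow for COI barcode surveys:
sequences are clustered into molecular operational taxonomic units (MOTUs)
first, and morphological identities are attached afterwards as quality
control.  This note documents the models, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Sequence screening

Nuclear mitochondrial pseudogenes are screened by translation: a record
passes if at least one of the three forward reading frames contains no
internal stop codon under the invertebrate mitochondrial code (NCBI table
5).  Reverse-complement frames are not tried, because PCR primers fix the
orientation of barcode reads; accepting any forward frame avoids
over-rejecting fragments whose frame offset is unknown.  A stop in the
final (possibly incomplete) codon of a frame is not counted as internal.
The screen is idempotent and runs before clustering by default.

## Pairwise alignment, identity and distances

A self-contained global aligner (Needleman–Wunsch with affine gaps;
defaults match +1, mismatch −1, gap open −2, gap extend −0.5, first
optimal alignment taken) substitutes for an external multiple alignment;
when a user-supplied MSA is present, pairwise columns are extracted from it
instead, and the two modes are never mixed within one run.

Identity follows the greedy-clustering convention: identical unambiguous
columns divided by the unambiguous length of the shorter sequence, so a
fragment nested in a longer sequence can reach identity 1.  Ambiguity
codes and gaps never count as matches and are excluded from all site
counts (pairwise deletion).  Distances are the uncorrected p-distance and
the Kimura 2-parameter distance
d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q), with P and Q the transition and
transversion proportions.  Saturated pairs (non-positive log arguments)
carry a NaN sentinel; neighbor joining refuses matrices containing
sentinels rather than guessing.

**Equal-length fast path.**  For two ungapped sequences of equal length,
identity and distances are computed on the column-wise (ungapped) global
alignment, vectorized over numpy arrays.  For substitution-only pairs —
which is what COI fragments trimmed to a common read window, and all
generator output, are — the ungapped alignment is the optimal global
alignment under the default scoring (a gap pair costs at least two gap
openings and shifts the frame onto near-random matches), so the values are
exact while clustering hundreds of sequences stays interactive.  Pairs of
unequal length always go through the full affine-gap aligner.

## Greedy MOTU clustering

The classic incremental algorithm: sort by decreasing length (ties stable
in input order); the longest sequence founds cluster 1 and becomes its
representative; each subsequent sequence joins the FIRST existing
representative (in cluster-creation order) with identity ≥ threshold and
aligned overlap ≥ the minimum coverage, otherwise it founds a new cluster.
Defaults: threshold 0.97, minimum coverage 400 bp, which doubles as the
minimum admission length — shorter sequences are excluded with a logged
warning.  No word-filter heuristics are used; identities are exact, so the
partition is deterministic for a fixed input order.  First-hit (not
best-hit) assignment is deliberate: it is the published behaviour of the
incremental greedy clusterers this reproduces.  Clustering is run
separately per taxon group.

## Neighbor joining and rooting

Classical Saitou–Nei NJ with the Studier–Keppler criterion
Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k); ties broken by the lowest
(row, column) position; branch lengths by the standard formulas with
negative estimates clamped to zero; the final three lineages resolved by
the exact closed form.  Trees are built on p-distance matrices per taxon
group.  The unrooted tree is midpoint-rooted before UniFrac: UniFrac needs
a root and abyssal surveys rarely have an outgroup.  Midpoint rooting is a
convention, not an inference; sensitivity to it should be reported when it
matters.

## Unweighted UniFrac

U(a,b) = (branch length subtending tips of exactly one of the two
samples) / (branch length subtending tips of either), with branches
subtending no tip of either sample ignored and branches above the lowest
common ancestor of the present tips excluded from numerator and
denominator alike (they subtend every present tip and carry no contrast).
Samples are stations; the license-area grouping enters only at the
ANOSIM/nMDS stage.  Stations contributing no tips to a tree are dropped
with a warning.  The abundance-weighted variant is out of scope.

## Community statistics

* **Cosine similarity** between station abundance vectors,
  S = x·y/(‖x‖‖y‖) ∈ [0,1] for counts.  It measures collinearity, not
  magnitude, which suits singleton-heavy, non-quantitative sledge samples.
* **Geographic distance**: plain Euclidean on decimal degrees by default
  (the convention being reproduced); great-circle km available because
  degrees are anisotropic at low latitudes (the two areas sit near
  12–14° N).
* **nMDS**: non-metric SMACOF (scikit-learn) behind the module surface;
  Kruskal stress-1 is recomputed in-package from the final configuration
  via isotonic regression.  Defaults: k = 2, 50 seeded restarts, tolerance
  1e−7, 300 iterations; the best restart is returned with coordinates
  centered at the origin.
* **ANOSIM**: Clarke's R = (r̄_between − r̄_within)/(M/2), M = n(n−1)/2
  ranked dissimilarities, average ranks for ties; p by permuting group
  labels (default 999 permutations).
* **Mantel**: Pearson r over lower triangles; null by simultaneous
  row/column permutation of the second matrix (default 5000
  permutations).  Matrices are correlated exactly as given: feeding a
  similarity matrix against a distance matrix legitimately yields negative
  r, and no sign is ever flipped silently.  The default tail is one-sided
  in the direction of the observed r; two-sided is available.

All permutation p-values use the add-one convention
p = (#{permuted ≥ observed} + 1)/(n_permutations + 1) and are
bit-reproducible given (seed, n_permutations).  Both tests also offer an
exhaustive mode that enumerates every label permutation (identity
included) and returns the exact fraction — feasible for n ≤ 7 and used to
validate the sampled p-values.

## Richness extrapolation

Chao1 (abundance) and Chao2 (incidence) in their classic forms
S_obs + F1²/(2F2) and S_obs + Q1²/(2Q2), switching to the bias-corrected
forms S_obs + F1(F1−1)/(2(F2+1)) when the doubleton count is zero;
standard deviations from the classical Chao variance formulas; first-order
jackknife S_obs + Q1·(m−1)/m with no SD (none is conventionally
reported for it).  Percent-registration is 100·S_obs/estimate, rounded
half-up to one decimal.  Richness is reported per license area, both per
taxon group and pooled across groups, labeled accordingly.  Chao
estimators are lower bounds; the calibration tests check coverage, not
exactness.

## Concordance between MOTUs and morpho-species

Only MOTUs with more than one specimen are examined (singletons constrain
nothing); members labeled "species indet" are skipped with a warning but
retained in clustering.  A MOTU is *concordant* only if all its labeled
members share one morpho-label and that label occurs in no other
multi-member MOTU — a one-to-one criterion, because a purity-only
definition would mask lumping.  Impure MOTUs are *lumped*; pure MOTUs
whose label spans several MOTUs are *split* (the cryptic-lineage
signature).  The adjusted Rand index over labeled multi-member sequences
summarizes global agreement.  A threshold sweep (default 0.97 → 0.90 →
0.80, descending) re-clusters the same input per threshold; the cluster
count is monotone non-increasing down the sweep.  Irreducible conflicts
are reported, never auto-corrected.

## Synthetic data generator

The generator emulates the statistical structure of a two-region abyssal
sledge survey, so that every stage has a test substrate with known ground
truth:

* **Geometry.** 10 stations scattered around 12° N/117.6° W and 5 tightly
  clustered around 14.07° N/130.09° W (~1300 km apart), depths ~4200 m and
  ~5020 m.
* **Sequences.** 650 bp coding fragments evolved under K80 with
  transition/transversion rate ratio κ = 4.  MOTU ancestors sit at
  expected pairwise K2P divergences spanning ~0.09–0.42 (ancestor branches
  uniform on 0.045–0.21 from a common root), matching the observed span of
  between-cluster distances; within-MOTU variation is a star genealogy
  with expected pairwise divergence 0.01 — inside the stated ≤ 2% regime
  and separated from the smallest between-MOTU divergence by an enforced
  ≥ 0.03 margin, so a 0.97 identity threshold cleanly separates the two
  scales.  Substitutions that would create a frame-0 stop codon (TAA/TAG,
  invertebrate mitochondrial code) are redirected to a stop-breaking base
  drawn from the same K80 row, preserving the substitution count exactly;
  the generator is calibrated (K2P estimates unbiased within 3 SE at
  d ∈ {0.02, 0.1, 0.3}).
* **Abundances.** A regional pool of S_true MOTUs per taxon group receives
  log-series weights (shape parameter 0.7); N individuals are drawn
  multinomially.  Defaults — polychaetes S_true = 260, N = 180; isopods
  S_true = 130, N = 80 — were calibrated once so that 60–70% of sampled
  MOTUs are singletons, the regime of deep-sea macrofaunal barcoding
  surveys, at a desk-scale sample size (the real survey's 556 + 150
  sequences are scaled to 180 + 80 to keep hundred-seed replication
  interactive).  Per-area sampling intensities mirror the observed
  436/120 (polychaete) and 76/74 (isopod) splits.
* **Spatial structure.** Each MOTU is allowed in both areas with
  probability `shared_fraction` (default 0.3) and otherwise in one;
  individuals are placed around a home station with exponential
  distance-decay weights exp(−λ·d) on degree distances (default λ = 0.8),
  so compositional similarity falls with distance.  Setting
  `shared_fraction = 1`, λ = 0 and equal per-station intensity yields an
  exchangeable null used for permutation-test size checks.
* **Star genealogies, no indels, no selection.**  Within-MOTU coalescent
  structure, indel evolution, codon usage and rate variation are not
  modeled: the pipeline tests identity-threshold behaviour and community
  statistics, not demographic inference.  Passing tests therefore show
  that the machinery is correct and calibrated under these conditions;
  they do not show robustness to alignment ambiguity, heterogeneous
  fragment lengths, or non-neutral evolution in real data.

## Problem sizes and numerical conventions

Replication counts used by the test suite and the acceptance script —
100 seeds for clustering recovery, 200 random trees for the UniFrac
oracle, 200 replicates for null uniformity, 60 for distance-decay power,
500 K80 pairs per calibration point — are the package's chosen balance
between statistical resolution and interactive runtimes.  Permutation
defaults are 999 (ANOSIM) and 5000 (Mantel); calibration runs use fewer
(499/999) since only rates and uniformity are scored.  Degenerate inputs
fail loudly: empty sequences, duplicate ids, all-zero abundance rows,
zero-variance triangles, singleton ANOSIM groups and sentinel-bearing
distance matrices are all hard errors rather than silent coercions.
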