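# Methods

This note records the models, parameter choices and numerical decisions
behind `chartmetrics`, and what the synthetic experiments do and do not
establish about real survey data.

## Chart geometry and the ground metric

The stimulus chart is the standard 330-cell WCS layout: 10 achromatic
chips (rows A–J at column 0) and 320 chromatic chips (rows B–I × hue
columns 1–40). Internally chips are indexed 0..329 in a fixed order —
grey scale first, then chromatic rows scanned left to right — while all
file formats use the 1-based `chip_id`.

Published chip coordinates can be loaded from a TSV
(`chip_id, L, a, b`); for self-contained work the synthetic embedding
places rows on linearly spaced lightness levels (L\* from 90 down to 20,
A lightest) and chromatic chips on a hue circle of radius 40 (hue angle
2π(column−1)/40). This preserves the chart's qualitative structure —
constant ΔE between neighbouring hue columns, antipodal hues opposite,
grey scale orthogonal to hue — but it is an idealization: the real
Munsell chip set is not a perfect cylinder in L\*a\*b\*, chroma varies by
chip, and real ΔE values are irregular. Conclusions that depend only on
ordinal geometry (near versus far, adjacent versus antipodal) transfer;
exact distances do not.

ΔE is the CIELAB-76 definition (plain Euclidean distance in L\*a\*b\*).
Later ΔE revisions (ΔE94, ΔE2000) are deliberately out of scope: the
pipeline treats the ground metric as pluggable, and CIELAB-76 keeps the
metric an exact Euclidean distance, which the kernel's positive
semidefiniteness and the EMD triangle inequality both lean on.

## Similarity kernel

`K_ij = exp(−ΔE_ij / σ)`. The bandwidth σ (CIELAB units) sets how far
perceptual coupling reaches; σ = 30 is the default because on the
synthetic table it gives off-diagonal similarities spanning roughly
0.04–0.81 — small enough that remote chips decouple, large enough that
neighbouring chips correlate strongly. The exponential of a Euclidean
metric is positive semidefinite; the constructor reports the numerically
smallest eigenvalue as a diagnostic (≈ 0.096 on the default table, so
factorization needs no regularization; a jitter of 1e−10·I is available
as a one-shot fallback for borderline user-supplied tables).

## Distribution metrics

**Normalization.** Charts are scaled to unit mass before EMD and
Quadratic χ² by default (language vectors have wildly different totals;
without normalization the partial-matching EMD moves only
min(ΣP, ΣQ) mass). A `normalize=False` escape hatch exists for users who
want partial matching. The baseline Euclidean used in ranking and
pairwise matrices normalizes the same way so that metric comparisons see
identical inputs; the raw `euclidean_distance` function does not.

**EMD.** Solved with `scipy.optimize.linprog` (HiGHS) on a dense flow
formulation restricted to nonzero-mass bins — row/column inequality
constraints plus one total-flow equality, which covers the unequal-mass
case uniformly. Desk-scale charts have supports of tens of chips, so each
LP is small; a full 330×330-bin pair remains comfortably solvable. The
week-scale industrial computation of complete survey-sized distance
matrices is explicitly not a target. Two independent oracles guard the
implementation: the closed-form 1-D identity (EMD under the line metric
equals the L1 distance of CDFs) and a separately written dense
equality-form transportation LP.

**Quadratic χ².** Implemented per the Pele–Werman definition with the
0/0 := 0 convention and a clamp for radicands in (−1e−12, 0); more
negative radicands raise, since they indicate a non-PSD similarity
matrix. The exponent default is m = 0.9, the value recommended in the
original formulation; it is configurable.

**Pearson.** Reported as a similarity in [−1, 1]; rankings convert it to
the dissimilarity 1 − r. Constant charts have no defined correlation and
raise rather than silently returning 0.

## De-correlation

Upper-triangular `R` from the Cholesky factorization `K = RᵀR`, applied
as `x ↦ Rx`. Either triangular orientation satisfies the bilinear-form
identity ⟨Rx, Ry⟩ = xᵀKy; upper is fixed for determinism. The kernel
(not the distance matrix) is factored — a metric's distance matrix is
never PSD, so the similarity form is the only object the factorization
applies to. Euclidean distance after the transform equals the
kernel-induced distance sqrt(xᵀKx − 2xᵀKy + yᵀKy), which is what makes
plain k-means on transformed charts metric-aware.

## Clustering

k-means is a small in-package Lloyd iteration rather than a library
call, for one load-bearing reason: the restart-agreement analysis needs
principled behaviour on duplicate points (at low simulation temperature
many speaker charts are bit-identical), and the common library strategy
for empty clusters can converge with fewer than k distinct centroids in
that regime. Here an empty cluster is re-seeded at the data point
farthest from its assigned centroid, never stealing a cluster's last
member; with zero-radius blobs this provably escapes duplicate-centroid
stalls. The implementation is cross-checked against scikit-learn's
KMeans on non-degenerate blob data in the test suite.

Restarts initialize centers as k distinct observations chosen uniformly
at random (k-means++ available via `init="k-means++"`). The reported
solution is the best of `restarts` (default 100) runs; stability is the
fraction of restarts whose centroid set, after minimum-cost bipartite
matching (`scipy.optimize.linear_sum_assignment`), coincides with the
winner's within a relative L2 tolerance of 1e−6 per centroid — exact
agreement is the intent, the tolerance only absorbs floating point.

The hierarchy sweeps k independently and matches the k centroids of each
level into the k+1 of the next by optimal partial assignment. A
split-and-re-merge event is flagged when a persistence chain's centroid
leaves its earlier position by more than a tolerance and a later level
returns within tolerance of the abandoned position; the default
tolerance is a tenth of the median pairwise centroid distance at the
deepest level — coarse enough to ignore drift, fine enough that a
dissolved-and-reborn cluster registers.

One structural caveat discovered while validating: on *equally spaced
ring* data the flagged events can be genuine properties of k-means
itself, not artifacts. A ring has no intrinsic hierarchy, so the global
optima at consecutive k need not nest — e.g. with per-term weights
(4,5,3,6,8,4,8,7) and equal adjacent-blob distances, the optimal single
merge is {t01,t02} but the optimal double merge is {t00,t01}+{t02,t03},
so {t01,t02} splits and later re-merges even though every per-k solution
is exactly optimal. Hierarchy persistence is therefore a property of
data with genuinely nested structure (irregular, well-separated
clusters), and that is the regime in which the no-event invariant is
tested; on ring geometry the detector fires for a substantial fraction
of simulation seeds and is reported, not suppressed.

Cluster displays always sum the *original* response charts per cluster —
clustering runs in transformed space, but figures stay interpretable as
response frequencies on the Munsell layout (darker = more mass).

## Synthetic data

The generator emulates the WCS elicitation: every speaker names every
chip with exactly one term. Term probabilities follow
p(t | chip) ∝ exp(−ΔE(chip, focal_t)² / T²); T = 0 is the ΔE-Voronoi
partition of the focals. Defaults: 8 terms, 20 speakers, T = 10 CIELAB
units — a mid-sized lexicon with disagreement confined to chips near
term boundaries. Ring mode places focals at equally spaced hue columns
on the middle-lightness row E, so adjacent/antipodal term pairs exist by
construction; random mode samples distinct chromatic chips.

Two regimes matter for the experiments, both fixed by the mechanism they
probe:

* **Disjoint-support regime (T = 5)** for the ranking experiment: the
  entrywise metrics' failure mode concerns disjoint charts, where their
  value depends only on chart norms. At T = 5 adjacent charts share
  essentially no chips but support sizes fluctuate across seeds, so the
  Euclidean ranking of adjacent versus antipodal terms is decided by
  noise while EMD/QC/de-correlated rankings follow hue distance.
* **Zero-spread regime (T = 0.5)** for the stability experiment: chip
  namings are deterministic except for the 10 achromatic chips, which
  are exactly equidistant from all ring focals and hence named uniformly
  at random at any T > 0. The chromatic-only analysis therefore applies
  the achromatic-exclusion filter first (the same preprocessing used
  when clustering chromatic naming patterns), leaving bit-identical
  charts per term — the setting in which 100 restarts are expected to
  agree exactly.

What the synthetic data does **not** model: non-response and synonym
competition, term salience and frequency asymmetries beyond boundary
noise, irregular Munsell geometry, or inter-speaker dialect variation.
Passing tests establish the machinery's correctness and the qualitative
geometry of the metric comparisons — not any empirical claim about
particular languages.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path: 200-pair oracle comparisons on 6–8 bins, hundreds of random
sparse-chart triples on the full 330-chip grid for the metric axioms,
100 random pairs for the bilinear-form oracle, 100-restart clustering on
~40 filtered speaker charts, and 5-seed ranking experiments. Every
stochastic component takes an explicit integer seed (numpy `Generator` /
`SeedSequence` throughout); identical seeds give byte-identical TSV/JSON
outputs.
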