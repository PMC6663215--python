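# Methods

This note records the conventions, defaults, and design choices behind
`shapegraph`, in the spirit of a model-description appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Mapper construction

**Lens.** `apply_lens` supports identity column selection, PCA
(scikit-learn, full SVD solver for determinism), t-SNE (seed mandatory,
`init="pca"`), and user callables.  Clustering always happens in the
original feature space; the lens is only used to slice the data, so a lossy
lens is acceptable and often desirable.

**Cover.** For resolution `R ≥ 2` and gain `G ≥ 1` over a lens range
`[lo, hi]` of length `range`:

* interval width `w = G · range / (R − 1 + G)`,
* interval `i` starts at `lo + i·w/G` (`i = 0 … R−1`),
* hence adjacent intervals intersect on `w·(G−1)/G` — gain 3 ⇔ 66.7 %
  overlap, gain 5 ⇔ 80 % — and the union spans `[lo, hi]` exactly.

The last interval's endpoint is clamped up to the data maximum to absorb
floating-point shortfall (≤ 1 ulp), so the extremes are always covered.
Intervals are **closed on both ends**: a sample on a shared boundary joins
both intervals.  This guarantees total coverage; it also means a sample at
an exact interior boundary can touch `G+1` intervals, a measure-zero event
for continuous data.  A zero-range lens dimension degenerates to a single
zero-width interval with a `RuntimeWarning` instead of failing.  `R` and `G`
accept scalars (broadcast over lens dimensions) or per-dimension lists.

An important geometric consequence: because interval starts are spaced
`w/G`, every interior sample lies in exactly `G` intervals per dimension.
For `G > 2` the cover is therefore *multi-overlapping* — with a 2-D lens at
`G = 5` a sample can occupy up to 25 bins, and all clusters containing it
are pairwise linked.  Shape graphs at high gain are thus densely linked
"thickened" complexes: a circle-shaped dataset yields a connected ring of
overlapping clusters, not a bare degree-2 cycle.  Degree-2 cycles only
appear when each sample belongs to at most 2 bins (`G ≤ 2` under this
convention).  This is inherent to defining overlap as intersection/width;
conventions that define the overlap percentage relative to the interval
*spacing* (width = (1+p)·spacing) cap multiplicity at 2 for any p < 1 and
produce visually cleaner cycles, but are inconsistent with this package's
gain anchors and are not used.

**Clustering.** Default: single-linkage agglomerative clustering
(`scipy.cluster.hierarchy`) on within-bin pairwise distances (Euclidean by
default, any `pdist` metric name accepted), cut at the left edge of the
first empty bin of a `k = 10` bin histogram of merge heights.  If the
histogram has no empty bin, or all distances are zero (duplicate rows), the
bin is one cluster; singleton bins yield singleton clusters.  The heuristic
is deterministic and parameter-light but trigger-happy on smooth
arc-like data (it can split a uniform arc where sampling density varies);
any callable `(values, member_indices) -> clusters` can be substituted.

**Nerve.** One node per cluster; an undirected, deduplicated edge whenever
two clusters share at least one sample (computed by incidence-matrix
product).  Bin adjacency is deliberately not consulted: under a
multi-overlapping cover, clusters from non-adjacent bins can legitimately
share samples and must be linked for the temporal projection to be correct.

## Temporal connectivity

`build_tcm` encodes the rule "frames are connected iff they share a node or
occupy edge-adjacent nodes" as `M^T (A + I) M > 0` with `M` the node×frame
incidence matrix and `A` the node adjacency; the diagonal is forced to 1
(frames that fell in no node are still self-connected).  Normalized degree
divides off-diagonal nonzeros per row by `T − 1` (a one-frame series has
degree 0).  Category similarity is the mean of TCM entries over ordered
frame pairs of the two categories, excluding `i = j` pairs on the diagonal
so the forced unit diagonal cannot inflate same-category similarity;
single-frame categories yield NaN and are flagged rather than failing.
Rest frames are included by default and excludable by flag.  These choices
(binary entries, unit diagonal, `T − 1` normalization, mean-TCM similarity)
are the package's own concrete definitions of quantities that are usually
described only verbally.

## Anchoring

Feature columns map to the nonzero voxels of a 3-D binary mask in ascending
C-order flat-index order; this ordering is recorded in the `VoxelMask` and
makes extract → unmask an exact identity on the mask support.  Node
activation maps are plain unweighted means of the member frames' rows, with
graph neighbors included by default and each frame counted once; no spatial
modeling, detrending, or standardization is applied — preprocessing is the
caller's explicit choice (`normalize_frames` for correlation geometry).

## Synthetic generators

**Trefoil.** `x = sin φ + 2 sin 2φ`, `y = cos φ − 2 cos 2φ`,
`z = −sin 3φ`, with `φ` evenly spaced on `[0, 2π)`; optional isotropic
Gaussian noise.  This is the standard closed trefoil parameterization; the
(x, y) projection self-intersects, so only clustering in the full 3-D space
separates the crossing strands.

**Block-design fMRI.** Emulates a visual block-design session: K category
blocks (default 24 s) at TR 2.5 s separated by rest (default 15 s, plus one
lead-in rest frame), block order permuted per session under the seed.  Each
category activates a disjoint voxel support (`V/K` voxels) with amplitude
`pattern_strength` (default 1.0); the regressor is a frame-level boxcar or,
by default, its convolution with a canonical double-gamma HRF (gamma shapes
6 and 16, undershoot ratio 1/6, unit scale; sampled at the TR, unit-sum
normalized, peak-rescaled so plateaus reach the pattern amplitude); i.i.d.
Gaussian noise (default SD 0.1, i.e., an amplitude-to-noise ratio of 10,
a clean but not noiseless regime) is added everywhere.  Durations are
floored against the TR, so a 24-s block contains 9 fully acquired frames.
The `haxby_like_preset` fixes K = 8 named categories, 577 voxels, and two
sessions of 121 frames (242 total); the 15-s rest blocks and single lead-in
rest frame are this package's schedule choice to realize 121 frames per
session, since only the block length, TR, and per-session frame count are
externally constrained.

What the generator does *not* emulate: spatially overlapping category
patterns, spontaneous/resting-state fluctuations, autocorrelated or
physiological noise, scanner drift, and motion.  Consequently rest frames
are pure noise — mutually uncorrelated after frame normalization — and
tests passing on this generator demonstrate the pipeline's mechanics, not
robustness to real fMRI confounds.

## Transition-detection conventions

The block-transition analysis (example 02, and the corresponding acceptance
test) makes three standing choices:

1. **Frame normalization.** Rows are scaled to unit norm before Mapper, so
   distances reflect pattern shape (correlation geometry), the standard
   treatment for multivoxel patterns.  Without it, high-dimensional noise
   magnitude dominates Euclidean distances and washes out the ramps.
2. **Hemodynamic alignment.** Stimulus labels are shifted forward by
   2 frames (5 s ≈ the double-gamma rise time) before comparing connectivity
   against block structure, mirroring the usual label-shift practice in
   block-design decoding.
3. **Boundary definition.** Within each maximal run of identical non-rest
   aligned labels, the first and last frames are *boundary* (onset/offset)
   frames and the remainder are *interior*.  The detection claim is that
   mean normalized TCM degree is higher over interior than boundary frames,
   and that category-similarity is higher on the diagonal than off it.

## Numerical and API choices

* Determinism: every stochastic component (t-SNE, generators) takes an
  explicit seed; reruns with identical config produce identical graphs, and
  the resolved config is embedded in `graph.provenance` and in the CLI's
  `provenance.json`.
* Dominant node label ties break lexicographically; pie-slice and category
  orders are lexicographic for stable output.
* Graph and document JSON schemas are versioned (`shapegraph-graph/1`,
  `shapegraph-document/1`); the HTML export embeds the document verbatim so
  the page doubles as an archive.
* Problem sizes in the test suite (e.g., 242×577 simulations, 200-graph
  oracle sweeps, ≤50-point nerve checks) are chosen to keep the full suite
  in the tens of seconds while still exercising every contract at realistic
  scale.

## Known limitations

* The histogram-gap clusterer can shatter smooth arcs (see above); for
  uniform manifold data a fixed-threshold or density-based clusterer may be
  preferable.
* High-gain covers produce dense nerves (see the cover section); topological
  claims at `G > 2` should be phrased in terms of connectivity and coarse
  structure, not node degrees.
* TCM construction is dense `O(T²)`; fine for hundreds of frames, wasteful
  for tens of thousands.
* Category similarity is TCM-based; it reflects graph connectivity, not raw
  pattern correlation, and inherits the Mapper parameters' granularity.
* The optional real-data loader (`fetch_haxby_masked`) requires network
  access and nilearn, and is exercised by no test.
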