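# Methods

This note documents the model choices, parameter defaults and numerical
conventions behind `protoview`, and what the synthetic experiments do and
do not demonstrate.

## Structure handling

`structure_io.read_pdb` keeps the heavy atoms of the first MODEL block of
a PDB file (hydrogens, waters and alternate locations other than blank/'A'
are dropped) and attaches per-element van der Waals display radii
(C 1.7 Å, N 1.55 Å, O 1.52 Å, S/P 1.8 Å, default 1.7 Å). The package
compares rendered envelopes, so the space-filling heavy-atom
representation is the natural choice; cartoon or ribbon rendering would
require secondary-structure assignment and is out of scope.

`normalize_model` centers the atom centroid at the origin and rescales
positions and radii isotropically so that max‖p‖ + max r = 1: every model
exactly fills the unit bounding sphere. Normalization is idempotent and
invariant to input translation and uniform scaling, and preserves all
pairwise distance ratios — but it deliberately discards absolute size:
two structures differing only by scale render identically. A single-atom
model normalizes to a unit sphere; two or more exactly coincident atoms
are rejected as degenerate, since they carry no shape.

## Multiview rendering

Cameras sit on the 14 octahedral directions (6 axis vertices, 8 face
normals) and look at the origin. Projection is orthographic: it has no
focal-length parameter and makes the symmetry invariants exact (antipodal
views are exact mirror images; a 90° model rotation about an axis equals
a 90° image rotation, bit-for-bit). Image roll is fixed deterministically:
axis views use +z as up (+y for the ±z cameras); oblique views use the
projection of +z onto the view plane.

Atoms are drawn as depth-shaded sphere impostors with a z-buffer. A
foreground pixel's intensity is 0.25 + 0.75·(z + 1)/2 where z ∈ [−1, 1]
is the depth of the nearest sphere surface along the view direction — a
range image. The floor of 0.25 keeps every silhouette edge at contrast
≥ 0.25 against the exact-zero background, which matters because the
feature detector needs gray-level structure. The unit sphere spans 90 %
of the frame (fill factor 0.9), leaving a margin so boundary features are
not clipped. Default image side: 100 pixels. Raster convention: row 0 at
the top, x right, y down, pixel centers at half-integers.

Per-pixel offsets are computed as `(half-integer) − t`, never
`pixel − (center + t)`; the former negates exactly under mirroring, which
is what makes the rotation/antipodal tests exact rather than
almost-exact.

## SURF

The detector and descriptor are implemented from scratch on integral
images (cumulative-sum tables; any box sum in four lookups).

* **Scale space.** The classical filter-size ladder (octave o, interval
  i: size = 3·2^(o+1) + 3 + 6·2^o·i; 9, 15, 21, 27, 15, 27, … for 4
  octaves × 4 intervals) is deduplicated and sorted into one global
  stack. Non-maximum suppression is a strict 3×3×3 comparison in that
  stack. Reference implementations suppress per octave, which detects
  one isolated blob two or three times in overlapping octaves; the
  global stack yields exactly one detection per isolated extremum and is
  equally deterministic. Plateau ties produce no detection
  (conservative).
* **Response.** det H = Dxx·Dyy − (0.9·Dxy)², box filters normalized by
  1/size², Laplacian sign from Dxx + Dyy. Default determinant threshold
  4e-4 on [0, 1] intensities — the classical OpenSURF operating point; it
  also suppresses the weak secondary lobes (≈ 2e-4) that a box-filter
  determinant produces around an isolated Gaussian blob.
* **Refinement.** Up to 5 rounds of 3D quadratic interpolation; a
  candidate whose refined offset exceeds half a cell in any dimension
  after that is discarded. The scale axis of the stack is non-uniform, so
  interpolation happens in index space and the offset is mapped back with
  the local size step.
* **Orientation.** Haar responses (side 4s) on a radius-6s disk sampled
  at steps of s, Gaussian-weighted with σ = 2s; dominant direction over a
  π/3 window slid in 0.15 rad steps. Upright mode (orientation ≡ 0) is a
  flag; oriented is the default because view images of the same fold can
  appear rotated.
* **Descriptor.** 20s × 20s window, 4 × 4 subregions × 5 × 5 samples,
  Haar side 2s, Gaussian weight σ = 3.3s, responses rotated into the
  point's frame, (Σdx, Σ|dx|, Σdy, Σ|dy|) per subregion, L2-normalized.
  Haar filters snap to the nearest pixel *boundary* rather than pixel
  center, so their footprint is symmetric about the sample; responses
  over a mirror-symmetric patch are then exactly antisymmetric instead of
  carrying a half-pixel bias. Points whose sampling window leaves the
  image, and zero-energy windows, are dropped silently.
* **Matching** (for robustness experiments, not retrieval): nearest and
  second-nearest neighbor ratio test at 0.7, best-pair-per-target
  deduplication, absolute cutoff 0.5 when the target set has a single
  member.

Everything in this stage is deterministic; identical images give
bit-identical features.

## Vocabulary and histograms

Descriptors pooled across all views of the training models (subsampled
uniformly without replacement to a 100 000 cap) are clustered by k-means
— k-means++ initialization with an explicit seed, Lloyd iterations,
Euclidean metric — via scikit-learn; empty clusters are re-seeded so the
codebook always has exactly k words. One *global* codebook serves all 14
viewpoints: pooling is the standard bag-of-visual-features reading, and a
per-view vocabulary would fragment the training pool. Default k = 3000;
the desk-scale experiments use k = 50–200, where accuracy is already
saturated (see below). Quantization is an exhaustive linear nearest-
centroid search (ties to the lowest index), verified in the tests against
an independent brute-force loop.

A model's histogram is the bin-wise **sum** of its 14 view count
histograms. Summing (rather than concatenating) yields a k-vector, makes
the representation tolerant to which octahedral view a given surface
patch lands in, and matches the divergence's single n-dimensional pair;
concatenation is available via `PipelineConfig(combination="concat")`.
Counts are smoothed by adding ε = 1 (Laplace) to every bin before L1
normalization. Smoothing is mandatory: at k = 3000 most bins of any model
are zero and the divergence's logarithm is undefined at zero. A
consequence worth noting: with fixed ε the combined histogram is exactly
scale-invariant in the view counts only when ε is scaled along with them;
for realistic feature counts (hundreds per model) the effect of ε is
marginal.

## Divergence

D(x, y) = Σ (yᵢ − xᵢ) ln(yᵢ/xᵢ) is symmetric (it is the Jeffreys sum of
the forward and reverse Kullback–Leibler divergences), non-negative
term-by-term, and zero iff the histograms are equal. The one-sided KL
Σ xᵢ ln(xᵢ/yᵢ) is exposed as `kld(..., symmetric=False)` for comparison.
Ranking ties are broken by model identifier for determinism.

## Evaluation

* Nearest-neighbor accuracy is leave-query-out: the query is removed from
  its own ranked list, and a query whose class has no other member counts
  as incorrect.
* Precision–recall is the 11-point interpolated curve (max precision at
  recall ≥ level), averaged over all queries.
* AUC is the rank-based (Mann–Whitney) statistic with ties credited 0.5,
  computed per query and averaged.

## Synthetic databases

The generator emulates a superfamily-level shape benchmark: classes must
differ in gross geometry while members of a class share it. Five families
of carbon pseudo-atom chains at CA-trace spacing (3.8 Å between
residues), all meeting a 50-residue floor: a three-helix bundle (75
atoms), a 3-layer stacked sheet slab (96), a quasi-uniform spherical
globule (80), a closed wobbled ring (64) and a long thin twisted rod
(60). Each model applies per-atom Gaussian jitter (σ = 0.4 Å) and a
uniform random rigid rotation, so class members differ in pose and
detail; beyond five classes the families are recycled with perturbed
dimensions. Everything is deterministic in (family, seed).

What this does *not* emulate: real CATH/SCOP superfamilies differ far
more subtly than these families — surface texture, domain architecture,
partial similarity — and real range images of atomic surfaces carry
high-frequency detail the smooth impostor rendering lacks. Perfect
accuracy on the synthetic databases therefore demonstrates that the
pipeline is implemented correctly and that the representation separates
genuinely distinct shapes; it does not predict accuracy on a real
benchmark.

## Experiment scales

The shipped experiments use a 5-class × 10-model database (700 views),
a 100-word codebook, and sweeps over k ∈ {50, 100, 200} and codebook
training sets of {20, 35, 50} models; the view-count law is exercised on
2 000 five-atom models (28 000 views). These sizes keep a full run in the
tens of seconds to low minutes on a single CPU while leaving each
pipeline stage statistically meaningful. At these scales leave-query-out
nearest-neighbor accuracy is saturated (1.0 across every sweep setting),
so the stability claim — accuracy moves by at most 0.1 across codebook
and training sizes — holds trivially; a harder synthetic benchmark with
overlapping families would be needed to see codebook-size effects.

## Known limitations

* Scale (absolute molecular size) is normalized away by design; two
  structures differing only in size are indistinguishable.
* The octahedral view set tolerates but does not eliminate pose
  dependence: a rotation that is not an octahedral symmetry changes the
  view images, and the summed histogram only damps the effect.
* Descriptor windows leaving the image are dropped, so features of very
  large scale (relative to the 100 px frame) near the silhouette are
  under-represented.
* k-means with a single seeded initialization is reproducible but not
  globally optimal; different seeds give slightly different codebooks
  (the sweeps show the effect on accuracy is nil at these scales).
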