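# Methods

This note documents the models, parameter choices and known limitations
of `cochleamap`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic benchmarks do and
do not demonstrate.

## Synthetic cochlea phantoms

**Geometry.** The organ of Corti is modelled as a conical spiral around
a straight modiolar (z) axis: radius shrinks linearly from base to apex
while the curve descends.  The full-size preset uses 2.0 turns, radii
500 → 250 µm and a 450 µm descent, which yields 550–650 IHCs at the
configured 8.0 ± 0.35 µm spacing and ~2000 OHCs in three rows at
7.0 ± 0.3 µm spacing — the counts and organ footprint (~1200 × 1200 ×
800 µm) of a young adult mouse cochlea.  The reduced preset (the
default test fixture) is a 0.94-turn spiral, radii 230 → 170 µm, ~150
IHCs and ~500 OHCs, chosen so the whole pipeline runs in well under a
minute per phantom; its per-cell statistics (spacings, row offsets,
blob sizes, SNR) are identical to full scale, only the organ is
shorter.  OHC rows sit 18/26/34 µm outward (radially) of the IHC row.
Placement jitter (0.5 µm SD) is applied only perpendicular to the row
so the > 6 µm consecutive-spacing constraint holds by construction.

**Rendering.** Cells are anisotropic 3D Gaussian blobs.  σ_xy = 2.5 µm,
σ_z = 3.5 µm: at the 7 µm OHC pitch, σ_xy = 3 µm would merge a dim cell
into a bright neighbour (the dim centre stops being a regional
maximum), defeating the requirement that a zero-noise render is
recoverable by local-maximum detection; 2.5 µm is the largest value
that keeps every centroid a maximum across the amplitude range.
Per-cell peak amplitudes are drawn uniformly from 0.55–1.0 (16-bit full
scale 20 000 counts).  Background is 0.05, additive Gaussian noise
σ = 0.04 of full scale (peak SNR ≈ 15–25, a realistic figure for
cleared-tissue two-photon stacks; the true SNR of such data is not
standardized, so this is an explicit calibration knob in
`PhantomSpec`).  Depth attenuation is exponential along z
(length 200 µm, ~35% loss over a 90 µm stack), emulating the
depth-dependent excitation/detection losses that real acquisitions
show.  Tiles are 256 × 256 × 96 voxels at (0.99, 0.99, 1.0) µm with
25% overlap (valid range 10–40%); each tile carries its own noise
realization.  No optics model beyond the Gaussian blob (no PSF
convolution, no stereocilia substructure, single channel).

**Loss injection** shares the probability-matrix machinery of the loss
model (below) on the (row, rank) grid of OHCs, so generated "pathology"
has the same formal structure the fitting stage assumes.  Defaults for
benchmark phantoms: 15 neighborhood-clustered losses (~3% of OHCs),
within the 1.7–8.1% range reported for young-adult and noise-exposed
cochleae.

## Stitching

Registration is translational only.  For each overlapping tile pair a
compact high-signal template (≤ 32 × 64 × 32 voxels around the
brightest spot of the overlap) from one tile is matched exhaustively by
normalized cross-correlation within the search radius (default 20% of
the tile extent; the pipeline uses 5 µm since nominal stage offsets are
trusted).  Corner-only overlaps are skipped — edge pairs already
connect the layout.  Pairwise shifts are reconciled by linear least
squares over the whole adjacency graph with tile 0 anchored; with loops
present this is better conditioned than accumulating along a spanning
tree, and reduces to it on a tree.  Fusion uses separable linear
distance-to-border ramp weights, normalized per voxel, so overlap
intensities are convex combinations and single-tile regions are passed
through bit-exactly.  Pairs scoring below 0.2 NCC are dropped (a
pure-noise overlap scores ≈ 0).

## Linearization

Peaks are 26-connected regional maxima above a robust background
threshold (median + 6·1.4826·MAD).  An Otsu default was rejected
during implementation: hair-cell somata occupy ~1% of the volume, so a
histogram-split threshold lands inside the background noise and yields
millions of spurious maxima; the robust statistic admits essentially
none at the default SNR.  Single-linkage clustering (25 µm maximal
link) isolates the hair-cell band; clusters below 10 peaks are
discarded as noise.

Band points are ordered by graph geodesics (k-NN graph, double-sweep
diameter estimate), divided into ~250 µm chords (midpoint of the
200–300 µm segment-length range), and each segment gets an orthogonal
least-squares plane (SVD) plus an in-plane circle (algebraic fit with
Gauss–Newton refinement of the radial residuals; collinear segments
fall back to a line with an infinite-radius flag).  Arc samples are
chained head-to-tail, smoothed across joins with a short moving
average, reparameterized by arc length at 1 µm, and extended 15 µm
tangentially at both ends so end cells are not clipped (the reported
spiral length excludes the extension).  Frames are (tangent, radial,
vertical = plane normal) with radial oriented away from the arc
centres, i.e. away from the modiolus; s = 0 is placed at the
larger-radius (basal) end.

The straightened slab is trilinear (`map_coordinates`, order 1) over
r ∈ [−30, 60] µm × v ∈ [−25, 25] µm at 1 µm spacing; out-of-source
samples are zero-filled and masked.  Detection geometry is established
in two passes: an initial band spiral is shifted radially onto the
innermost intensity mode (the IHC row), a narrow slab (r ∈ ±14 µm) is
straightened to detect the IHC chain quickly, and the spiral is then
refitted through the detected IHC positions — the fine readjustment —
before the full slab is resampled with the IHC row at r = 0.  During
training the refit uses the true surviving IHC positions (teacher
forcing); at inference it uses the pass-1 chain, which is within a
micrometre of truth on the benchmark phantoms.

## Detection

The cell template is built from the sample itself: the 100 brightest
regional maxima of the straightened volume are cropped (9³ voxels: at
the 7 µm within-row pitch a wider template overlaps both neighbours and
a dim cell between bright ones loses its correlation maximum) and
averaged, then mean-subtracted.  Correlation peaks above 0.3 are
grouped by 26-connectivity into candidates.  Stage-1 features: group
area, barycentre (s, r, v), maximum correlation, maximum intensity, the
same six features of the nearest neighbouring group and its relative
position (15 predictors).  Stage 1 is a gradient-boosted tree ensemble
with 300 boosting stages (`HistGradientBoostingClassifier`; the exact
boosting flavour is not essential and this implementation is orders of
magnitude faster than classic gradient boosting on one CPU).  The
stage-1 cutoff is a posterior threshold of 0.1 rather than a fixed
"keep the top ~2%" quantile: on real stacks noise candidates outnumber
cells ~50:1 and a quantile works, but phantom candidate pools are far
cleaner, and a quantile would discard true cells.  Stage 2 is a
300-tree random forest over expanded predictors: stage-1 score of the
candidate, score and relative position of the nearest candidate in
each of six 60° sectors of the s–r plane (40 µm horizon, sentinel −1
for empty sectors), and the local intensity distribution — a 21 × 69
crop of the v-MIP centred on the barycentre, resized to 7 × 23 and
flattened to 161 values.  Stage-2 training uses leave-one-phantom-out
stage-1 scores so the score distribution matches inference.  Candidate
labels: positive within 4 µm of a true surviving cell (≈ half a cell
radius).

IHC candidates accepted by stage 2 are chained by a dynamic program
that maximizes total score subject to strictly > 6 µm consecutive
spacing.  OHC candidates get a row (1–3) from a convolutional
classifier (one 5 × 5 convolution stage with 60 feature maps, ReLU,
fully connected, softmax over 3 classes) fed 39 × 69 v-MIP crops
centred on the candidate, so the vertical position of the three-row
band inside the crop encodes the row; a sanity check remaps labels if
mean r is not monotone in row index.  Within each row, gaps exceeding
1.5× the average spacing (strict inequality) are probed at equally
spaced positions by a second convolutional classifier (two convolution
stages, 60 then 20 maps); positives recover the nearest unused
correlation peak, flagged `gap_recovered`.  Both classifiers are
implemented as a compact numpy CNN (im2col convolutions, softmax
cross-entropy, SGD with momentum) — no deep-learning framework is
required, and the few-thousand-sample training sets train in seconds
to minutes.  All training is seeded; models serialize to a directory
(pickled ensembles, `.npz` network weights, JSON metadata).

The watershed baseline smooths (σ 1.5), thresholds at the robust
background statistic, seeds markers at local maxima (min distance 2)
and runs a 3D watershed; segment centroids are its cells.  It is
evaluated with exactly the same greedy one-to-one 4 µm matching as the
staged detector.

## Loss mapping

The normalized template integrates 1/(local median within-row OHC
spacing) along s (10 µm knots, 60 µm window; spacings > 3× the median
are excluded as loss gaps) so one u unit is one intercellular distance
everywhere, and maps the three OHC row centres to w = 1, 2, 3 by a
linear fit of mean row r.  Occupancy squares are exactly one unit wide
— on an intact lattice they tile the band leaving no pixels, which is
the property the void method needs.  The raster is 10 px/unit over
w ∈ [0.5, 3.5]; empty 8-connected groups smaller than half a cell are
discarded; each void contributes round(area / unit area) lost cells
(rounding, not flooring: the estimator is then unbiased on random
removals) placed at the template lattice nodes its pixels cover.
Longitudinal profiles use 50 µm bins (u is mapped back to s through
the monotone spacing integral); the 13 × 15 segment matrix divides the
normalized band area equally; PCA across samples is a centered SVD of
the flattened matrices.  Basal-end trimming for samples whose basal
extremity is ambiguous is a caller-side concern: profiles are computed
on whatever s range the cell map covers.

## Morphometry

The modiolar axis minimizes the scatter of circle centres fitted to
consecutive chunks of the (ordered) IHC row after projection
perpendicular to a trial direction; a coarse spherical grid is refined
by Nelder–Mead.  Fewer than 50 cells or less than one turn flags the
fit low-confidence (the reduced phantom, at 0.94 turns, is flagged).
Radial profile: Euclidean distance of each IHC to the axis.  Axial
profile: mean axis projection of consecutive 25-cell blocks (an
incomplete final block is dropped), min–max normalized per sample.
All summaries are rigid-motion equivariant.

## Loss model

Cell and probability matrices are 3 rows × 600 columns.  One cell is
removed per step with probability proportional to the (renormalized)
probability matrix; removed cells get probability zero; each removal
adds `w_neigh` to the 8-connected neighbours (switchable to
4-connectivity).  The position effect sets all three entries of a
column to `P(x) = 0.1·p·x^(1−0.1·p)` with x ~ U(0, 1) — the exponent
grouping of this expression is genuinely ambiguous in print, so the
interpretation is isolated in one function (`position_effect_values`);
p = 0 means a flat profile.  Under this grouping the effect strength is
*non-monotone* in p: p = 10 is exactly flat again, mild bounded
profiles live at 0 < p < 10, and heavy-tailed longitudinal
concentration requires p > 10.  The default 4 × 4 weight grid is
therefore w ∈ {0, 2, 5, 10} × p ∈ {0, 5, 12, 18}, spanning none → mild
→ strong for both effects with 16 genuinely distinct settings.  The
column profile is Gaussian-filtered (σ = 2 columns) to broaden peaks
and normalized to mean 1 so w_neigh is in comparable units.

Cluster-size histograms over 500 repetitions per grid point are scored
against the measured histogram by the sum of squared differences to
the mean simulated histogram (zero-padded common support).  The
relative contribution is the weighted average of the three
lowest-score grid points, weights ∝ 1/error (ε-guarded), with each
point's "neighborhood fraction" defined as w̄/(w̄+p̄) on grid-normalized
weights (0/0 → 0.5).  The uniform null band is the central 99%
Monte-Carlo interval of cluster count and mean cluster size.

## Problem sizes and numerical choices

- Reduced benchmark: 15 phantoms (~150 IHCs, ~500 OHCs each), models
  trained on 5, evaluated on 10; one phantom processes end to end in
  ~25 s and the whole benchmark in ~15 min on one CPU.
- Parameter-recovery experiment: n_lost = 40 on the 3 × 600 grid,
  5 trials per mechanism at (w = 10, p = 0) and (w = 0, p = 18),
  reps = 500, the 16-point default grid.
- Tolerances: detection matching 4 µm; circle-fit Gauss–Newton stops at
  1e−10 step norm; chain spacing strictly > 6 µm; gap flagging strictly
  > 1.5× average spacing; void filter ≥ 0.5 cell areas.
- Ties and degeneracies: collinear segments → line fit with infinite
  radius; row-label permutations corrected by the mean-r monotonicity
  invariant; empty sectors and lone candidates carry sentinel features.

## What the synthetic benchmarks show — and do not

Phantoms share the generator's assumptions: Gaussian somata of uniform
size, exact three-row lattice geometry, additive Gaussian noise,
exponential depth falloff, translational-only tile misalignment.  Real
cleared-tissue stacks add soma shape variation, labeling heterogeneity,
vasculature and debris, refractive distortions and non-rigid tissue
deformation, none of which are modelled.  Passing the benchmarks
demonstrates the pipeline's correctness and internal consistency
(geometry recovery, metric definitions, estimator calibration,
model-fit identifiability) at realistic SNR and cell density — not
field performance on arbitrary tissue.  The detection thresholds most
likely to need retuning on real data are the correlation peak threshold
(0.3), the robust-threshold multiplier (6 MAD) and the stage-1 cutoff
(0.1), all exposed in the API.
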