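# Methods

This note documents the models, conventions and numerical choices behind
arenatrack, and what the synthetic validation does and does not establish.

## Detection and tracking

The animal is modeled as the largest compact region whose intensity deviates
from an animal-free reference frame. Per frame and arena:

1. grayscale conversion (luma weights 0.299/0.587/0.114 for RGB input);
2. signed difference against the background — `bg − frame` for a dark
   animal on a light box (`polarity="darker"`, the default), reversed or
   absolute otherwise;
3. binarization at `threshold` (default 50 intensity units: far below the
   ~200-unit contrast of a dark mouse on a white box, far above sensor
   noise at typical exposure);
4. optional binary opening + closing with a disk of
   `morphology_radius_px` (default 0; raise to 1–2 for noisy video);
5. connected components; those below `min_blob_area_px` (default 20 px,
   well under any adult mouse at usual resolutions but above specks and
   droppings) are dropped; the centroid of the largest survivor is the
   position.

The background comes from the recording's leader segment (protocols record
several animal-free seconds before placing the animals), an external photo,
or a per-pixel median over a frame range — the median is correct whenever
the animal occupies each pixel less than half the time.

Coordinates are pixels, origin top-left, x right, y down, 0-based frames;
windows are half-open `[start_frame, end_frame)`. Frames with no detection
carry the last position forward (never inflating distance), and
`fill_gaps` optionally replaces runs of up to `max_gap_frames` missed
frames with linear interpolation, flagged as such. Frame rate comes from
container metadata, overridable by `fps_override`; with neither, tracking
refuses to guess.

On noiseless synthetic video the centroid of the rasterized ellipse sits
within 0.5 px of the scripted center for every frame tested, and with noise
up to threshold/3 the detection rate stays ≥ 99%. These bounds are
properties of the renderer's idealized blob; real fur, shadows and
occlusions will degrade them, which is why `threshold`,
`morphology_radius_px` and `min_blob_area_px` are exposed.

## Behavioral metrics

Calibration is isotropic: `scale = real_length_cm / ‖a − b‖` from two
reference points. Zone membership is decided by the centroid (the only
quantity the tracker produces); boundary points belong to the explicitly
drawn ROI rather than the complement, and among overlapping drawn ROIs the
first declared wins. A step's distance is attributed to the zone of its
earlier frame. These conventions make two conservation laws exact, not
approximate: per-ROI times sum to the window duration and per-ROI distances
to the total distance. Mean speed per ROI is distance/time (not the mean of
instantaneous speeds); an unvisited ROI reports speed 0 with
`speed_defined=False` rather than NaN.

Transitions are counted by a debounced automaton: a zone change counts only
once the new zone has persisted `debounce_frames` consecutive frames
(default 1 = raw changes); unconfirmed excursions leave the current zone
unchanged. Counting on centroid crossing (not full-body crossing) is a
convention and is stated as such.

Optional teleport filtering: steps longer than `max_step_px` (off by
default) contribute zero distance and are logged, protecting distance sums
from single-frame mislocalizations.

## Trajectory clustering

DTW here is the classic unnormalized recurrence with no band by default
(both the Sakoe–Chiba radius and the local cost are configurable). The
implementation fills the DP table along anti-diagonals, which vectorizes
the recursion in numpy; its correctness is established in the test suite by
exhaustive enumeration of all monotone warping paths on short sequences.
Sequences are not resampled to equal length — time warping is the point of
DTW — so tracks with dropped frames compare fine.

"Adjusting to the same area" is a per-axis affine map of the arena
rectangle to the unit square. It is deliberately anisotropic: the arenas it
serves are square, and per-axis scaling is what makes paths from arenas of
different pixel sizes directly comparable.

k-means needs a vector space, so it runs on a 2-D metric MDS embedding of
the DTW matrix (SMACOF with classical-scaling initialization, which makes
the embedding of Euclidean-embeddable matrices essentially exact and the
whole pipeline deterministic under a seed). The silhouette score is
computed in the same embedding, k is scanned over 2…min(n−1, 10) with ties
going to the smaller k, and k-means uses 10 seeded restarts. Because MDS
compresses the DTW geometry into two dimensions, each cluster additionally
reports its medoid in the *original* DTW metric — the member minimizing
summed DTW distance to its co-members.

## Angle clustering

The heading of displacement (Δx, Δy) is the angle of (Δx, −Δy): flipping y
makes angles counterclockwise-positive with 0° = rightward despite raster
coordinates. Displacements below `min_step_px` reuse the previous heading —
sub-pixel jitter carries no directional information. Headings are then
unwrapped (±360° multiples added so successive differences lie in
(−180°, 180°]); all smoothing, DTW and averaging operate on the unwrapped
curves, avoiding the 359°→1° artifact, and re-wrapping recovers the raw
headings exactly.

Gaussian smoothing with "kernel size k" means a normalized window of
2k+1 taps with σ = k/2 and reflect padding; output length equals input
length, constant series are fixed points, and total variation is
non-increasing in k.

Hierarchical clustering applies the Lance–Williams recurrences (via scipy)
to the DTW distance matrix for Ward, single, complete, average and centroid
linkage. Ward and centroid formally assume squared-Euclidean input;
applying them to DTW dissimilarities follows common practice and is kept
deliberately, as a documented caveat rather than an error. Flat clusters
come from a raw merge-height cutoff in the same units as the accumulated
DTW distances (degrees × samples, which is why realistic cutoffs are in the
thousands for degree-valued series); `cutoff_for_k` places the cutoff
midway between the merge heights bracketing a desired cluster count — the
scripted equivalent of drawing the line on a dendrogram.

Cluster profiles resample members linearly to the shortest member's length
and report the pointwise mean and *population* SD (a singleton cluster has
SD ≡ 0). Between-cluster cost matrices are the full accumulated DTW tables
between cluster mean curves (a flagged alternative compares medoid members
instead); the bottom-right cell is the between-cluster distance.

## Synthetic data: what it emulates and what it does not

The renderer emulates the geometry and photometry that matter to a
background-subtraction tracker: a static bright background (level 230), up
to four disjoint rectangular arenas, one dark axis-aligned ellipse
(14 × 8 px, intensity 20) per arena moving at constant speed along a
scripted polyline, a 2 s blob-free leader, and i.i.d. per-pixel Gaussian
noise clipped to [0, 255]. Default fixtures are 160×120 or 320×240 at
10 fps with 5–6 s of motion — small enough that the full
simulate→track→metrics→cluster chain runs in seconds on one CPU, large
enough that blob rasterization, arena containment and window arithmetic are
all exercised. It does not model fur texture, limbs, shadows, lens
distortion, compression artifacts or occlusion, so passing tests certify
the algorithmic pipeline, not robustness to difficult footage.

Planted populations: trajectory archetypes (straight run, left arc, right
arc, inward spiral; 60 samples ≈ 30 s at an effective 2 Hz; noise σ = 0.02
in unit-square coordinates, small relative to the ≥ 0.1 separation between
archetypes) and angle archetypes (constant heading, 360° linear ramp,
±90° oscillation; 120 samples; noise in degrees). Five members per cluster
mirrors small-cohort group sizes. With zero noise all members equal their
archetype, making within-cluster dissimilarity exactly zero under any
metric — the degenerate case every clustering stage must handle.

## Numerical choices and degenerate inputs

- DTW of empty sequences, coincident calibration points, degenerate
  (zero-area) arenas, windows outside the track, and unknown
  archetypes/linkages/polarities raise `ValueError`; an arena with zero
  detections yields a flagged empty track and a warning, not a crash.
- A stationary scripted path (single waypoint) has analytic length 0; the
  tracker's recovered distance is then bounded only by sub-pixel centroid
  jitter, so fidelity there is asserted on localization, not relative
  distance error.
- Silhouette/k selection ties break to the smaller k; label numbering is
  0-based in first-appearance order for hierarchical results and k-means
  order otherwise.
- All randomness (rendering noise, population noise, MDS init, k-means
  restarts) flows from explicit integer seeds; reruns are bit-identical,
  including the rendered TIFF bytes.

## Known limitations

Single animal per arena (no identity tracking), rectangular arenas for the
renderer (analysis ROIs may be arbitrary polygons), centroid-based zone
logic, no body-axis orientation by default (heading is movement direction;
an ellipse-fit orientation would be the natural extension), and Ward on DTW
distances inherits the usual caveat noted above.
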