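# Methods

This note records the models and procedures behind the two quantification
engines, the parameters that matter, what the synthetic generators do and
do not emulate, and the numerical choices made where the design was open.

## 1. Calibrated image model

All computation happens on floating-point copies of the data; intensity
dtype is preserved only at I/O. Axis order is fixed as (z, y, x) for stacks
and (row, col) for 2D images, and every physical quantity passes through
the per-axis voxel size, so anisotropy (typically dz > dx in spinning-disk
stacks) is handled once, in one place. Coordinates are 0-based indices;
the physical position of a voxel is its center, `index · voxel_size_um`.
TIFF round trips are lossless: intensities bit-exact, voxel sizes to
≤ 1e−6 µm (stored as JSON in the image description).

## 2. ELISPOT spot calling

Pipeline: grayscale collapse → adaptive threshold → morphology →
connected components → size filter → measurement.

* **Grayscale collapse.** Membranes may be photographed in color. The
  default rule is the pixelwise minimum across RGB channels: a dark spot is
  dark in at least every channel it stains, so the minimum preserves spot
  contrast regardless of substrate hue. Luminance and single-channel rules
  are available.
* **Adaptive threshold.** Foreground iff `I < local_mean − offset` over a
  (2r+1)² window with reflected boundary padding (comparison flipped for
  light-on-dark polarity). The local mean was chosen over a
  Gaussian-weighted mean as the simplest statistic that adapts to
  illumination gradients; all three knobs (statistic window radius, offset,
  polarity) are explicit. Defaults r = 25 px, offset = 5 intensity units.
  Two sizing rules matter in practice:
  - the *offset* must exceed the noise level (≈ 2–3 noise SDs), or noise
    pixels percolate into the mask;
  - the *window diameter* must exceed the largest object to be captured,
    or the local mean dips inside large objects and their interiors and
    rims fragment. For 3 µm/px membranes with smears up to ~120 µm across,
    r = 40 px is appropriate; the conservative default r = 25 px suits
    spot-sized objects only.
* **Morphology.** Fixed order opening (radius 1) → closing (radius 1) →
  hole fill, disk-shaped elements, radius 0 skipping a step. Opening
  removes speckle smaller than the structuring element; closing bridges
  1-px gaps; hole filling makes annular staining solid so area is
  meaningful.
* **Connected components.** 4- or 8-connectivity (default 8, so diagonal
  pixel chains do not split a spot); labels are assigned in raster-scan
  order of each component's first pixel, making the labeling deterministic.
* **Size filter.** Accepted iff `min_area ≤ area_um2 ≤ max_area`,
  inclusive. The default range [40, 4000] µm² corresponds to spot
  diameters of roughly 7–71 µm, bracketing typical ELISPOT spots; because
  no universal range exists, the range in force is echoed into every
  report rather than left implicit. The partition
  (accepted / rejected-small / rejected-large) is exhaustive and disjoint,
  and `n_labeled = n_accepted + n_rejected_small + n_rejected_large` is
  enforced as a report invariant.
* **Measurement.** Per component: pixel and physical area, unweighted
  centroid (px and µm), equivalent diameter `2·sqrt(area/π)`, mean
  intensity over member pixels, and eccentricity of the second-moment
  ellipse. Spots touching the border are kept by default (`exclude_border`
  drops them). Merged/confluent spots are *not* split (no watershed): a
  merged pair is counted once, which is the main known bias at high spot
  density.

## 3. 3D infiltration quantification

* **T-cell detection.** The T-cell channel is smoothed with an anisotropic
  Gaussian whose per-axis σ follows the blob-matching relation
  σ = diameter / (2√3), with diameters (10, 5, 5) µm in (z, y, x) by
  default, converted to voxels per axis. Detections are local maxima of
  the smoothed response within an ellipsoidal footprint of one expected
  diameter per axis (which enforces the minimum separation), above a
  detection floor. The floor is the maximum of (a) the
  `min_intensity_quantile` quantile of the response (default 0.99) and
  (b) median + 6.5 robust SDs (1.4826·MAD). The clamp (b) exists because a
  quantile alone cannot reject a blank stack — the global maximum of pure
  noise is always a local maximum above any sub-maximal quantile — and
  6.5 σ clears the expected extreme value of a smoothed noise field with
  ~10⁵–10⁶ effectively independent samples (≈ 5 σ), while genuine cells at
  the default scene contrast sit tens of σ above the median. Peaks within
  2 σ (of the smoothing kernel) of a stack face are discarded: reflected
  padding correlates noise there and inflates the response. Peak voxel
  centers are reported in µm; with symmetric blobs this is within one
  voxel of the true center.
* **Organoid segmentation.** Otsu threshold on the organoid channel by
  default (the organoid is the single dominant bright body, so the
  histogram is bimodal); a fixed threshold is available. The largest
  26-connected component is kept, internal holes are filled (organoid
  lumens count toward volume), volume is voxel count × voxel volume, and a
  closed triangle surface is extracted by marching cubes at physical
  spacing (the mask is padded by one voxel first so bodies touching the
  stack border still yield closed meshes). Mesh volume tracks voxel volume
  to within a few tenths of a percent for bodies tens of voxels across.
* **Signed distance.** `d = EDT(¬mask) − EDT(mask)` with the Euclidean
  distance transforms computed at the true (dz, dy, dx) sampling: positive
  outside, negative inside. Each cell reads the field at its nearest
  voxel, so the sign agrees *exactly* with mask membership; the price is a
  quantization error bounded by one voxel diagonal, which is the tolerance
  used in all closed-form tests. Distances are centroid-to-surface; the
  original surface-to-surface convention can be approximated by
  subtracting a nominal cell radius (~2.5 µm) from outside distances, a
  documented flag left off by default because centroid distances are
  exactly testable against closed forms.
* **Classification.** Infiltrated iff d_min ≤ d ≤ d_max with inclusive
  bounds, default window [−200, 0] µm: 0 µm includes cells in contact with
  the surface; −200 µm is the literal depth cutoff. Cells deeper than
  d_min are classified `excluded_deep`, not infiltrated; `include_deep`
  merges them for analyses that read the deep bound as descriptive rather
  than exclusionary. Window semantics are monotone: enlarging the window
  never decreases the infiltrated count.
* **Pooling.** Mean and SEM (sample SD / √n, ddof = 1) of the infiltrated
  count and fraction across chips of one condition; pooling fewer than 2
  chips is refused.

## 4. Synthetic generators

One RNG stream per call, derived from the seed: identical seeds give
bit-identical images and ground truth.

**Wells.** Background plane + linear illumination gradient along x; dark
disks rendered with anti-aliased subpixel coverage
(`clip(R − d + 0.5, 0, 1)`), so planted areas are meaningful at small
diameters; Gaussian optical blur; additive Gaussian noise. Defaults
emulate a plate-imager field: 768×768 px at 3 µm/px, background 200, spot
depth 60, noise SD 10 (SNR 6), blur σ 2 µm, spot diameters 15–50 µm
(areas 177–1963 µm², inside the default filter). Artifacts are planted
strictly outside the paired size filter: specks of 2–3.5 µm diameter and
smears of 1.5–3× the maximum accepted area. Placement is rejection
sampling with radius-aware separation
(`max(min_sep, r_i + r_j + clearance)`), so distinct objects never merge.
Additive Gaussian noise (not Poisson) was chosen so SNR is directly
controllable; the deficit of each rendered disk equals depth × area to
within the anti-aliasing error, and blur conserves it.

**Scenes.** Organoid channel: analytic sphere or ellipsoid evaluated at
voxel centers, plus noise. T-cell channel: anisotropic Gaussian blobs of
FWHM (10, 5, 5) µm at positions solved so the signed distance to the body
is *exact* — radially for spheres (position radius = R + d), along the
outward surface normal for ellipsoids. Normal offsets are exact for a
convex body as long as |d| stays below the minimal curvature radius
(c²/a); the spec validator rejects deeper requests. Defaults: (80, 160,
160) voxels at (4, 2, 2) µm (a 320³ µm chamber), sphere radius 100 µm,
cell amplitude 120 over background 10, noise SD 8, pairwise cell
separation ≥ 12 µm.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: membrane texture and staining granularity,
non-Gaussian (Poisson/speckle) noise, optical PSF structure beyond a
Gaussian, confluent or overlapping spots, irregular (non-ellipsoidal)
organoid shapes, touching T-cell clusters, z-dependent attenuation, and
scattering inside the organoid. Recovery results on synthetic data bound
the algorithmic error only; parameter choices for real acquisitions still
need the usual per-batch QC (the mask/overlay outputs exist for that).

## 5. Problem sizes in the verification suite

The shipped tests and the acceptance script run: 1,000 random 32×32 masks
(both connectivities) against a BFS labeling oracle; 100 synthetic wells
of 0–150 spots and 0–20 artifacts; a 90×180×180 sphere scene at (2, 1, 1)
µm for volumetry and distance closed forms; 10 chamber scenes of 50 cells
each for end-to-end recovery; and dense-sampling checks (2×10⁵ surface
points) of the ellipsoid ground truth. These sizes were chosen to exercise
every code path at realistic object densities while keeping a full run in
the minutes range on a single core.

## 6. Known limitations

* No splitting of merged spots or touching cells; counts are biased low at
  extreme densities.
* Otsu assumes the organoid dominates its channel; debris brighter than
  the organoid would need the fixed threshold.
* The signed distance is voxel-quantized (≤ one voxel diagonal); cells
  within that distance of the window bounds can flip classification.
* Spot detection reports peak-voxel centroids; no subvoxel refinement.
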