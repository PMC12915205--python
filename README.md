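# spotchip

Image quantification for two readouts of antigen-specific T-cell activity:

1. **ELISPOT spot counting** — each dark spot on an ELISPOT membrane marks
   one cytokine (e.g. IFN-γ) secreting cell, so the per-well spot count
   measures the frequency of reactive T-cells. `spotchip` calls spots with
   adaptive thresholding, morphological cleanup, connected-component
   labeling, and a size-filtration step that separates true spots from
   debris and smears, and emits a per-well report with the count, size
   distribution, and per-spot morphometry.
2. **3D T-cell infiltration** — in tumor-on-a-chip co-cultures of
   patient-derived organoids (PDOs) and T-cells, two-channel confocal
   z-stacks show T-cells as ~5 µm (XY) × 10 µm (Z) blobs around one large
   organoid body. `spotchip` detects the cells with anisotropy-matched blob
   detection, segments the organoid (Otsu threshold, largest component,
   hole fill, marching-cubes surface, voxel volume), computes each cell's
   signed Euclidean distance *d* to the organoid surface (negative =
   inside), and classifies a cell as **infiltrated** when
   −200 µm ≤ *d* ≤ 0 µm — in contact with the surface or up to 200 µm
   deep. Per-chip results are pooled (mean ± SEM, minimum 2 chips per
   condition).

Both engines are deterministic and operate in physical units (µm, µm²,
µm³) throughout, which matters because confocal voxels are anisotropic
(dz > dx). A synthetic-data module generates both input classes with exact
ground truth — planted spot counts, cell positions with analytically exact
signed distances, and analytic organoid volumes — and is the basis of the
test suite.

Intended users: immunology/organoid labs that want a scriptable,
inspectable alternative to point-and-click spot counters and commercial 3D
analysis suites, and anyone benchmarking such pipelines against known
ground truth.

## The core quantities

For a binarized well image, connected components C₁…C_K are measured in
physical units, `area_um2 = |Cᵢ| · p²` for pixel size p, and accepted iff
`A_min ≤ area_um2 ≤ A_max` (inclusive; default [40, 4000] µm²). The
threshold is local: pixel x is foreground iff
`I(x) < mean_{w×w}(x) − offset` for dark spots (window w = 2r+1).

For a chamber stack, the T-cell response is a Gaussian-smoothed volume with
per-axis σ matched to the expected cell extents (σ = diameter / 2√3); cells
are the local maxima above a noise-aware floor. The signed distance field is
`d(x) = EDT_outside(x) − EDT_inside(x)` with the Euclidean distance
transforms sampled at the true voxel spacings, and

    infiltrated(cell)  ⇔  d_min ≤ d(cell) ≤ d_max,   default [−200, 0] µm.

## Worked example

```python
import numpy as np
import spotchip as sc

# --- ELISPOT: 37 planted spots, 8 planted artifacts, noise SD 10
spec = sc.SyntheticWellSpec(n_spots=37, n_artifacts_small=4, n_artifacts_large=4, seed=1)
image, truth = sc.generate_well(spec)
rep = sc.count_spots(image, sc.ElispotParams(offset=25.0, window_radius_px=40))
print(f"well {rep.well_id}: n_labeled={rep.n_labeled} n_accepted={rep.n_accepted} "
      f"n_rejected_small={rep.n_rejected_small} n_rejected_large={rep.n_rejected_large}")

# --- 3D: 8 cells planted 10-90 um deep, 12 outside, sphere organoid R=100 um
rng = np.random.default_rng(5)
spec3 = sc.SyntheticSceneSpec3D(cells_inside=list(rng.uniform(-90, -10, 8)),
                                cells_outside=list(rng.uniform(10, 60, 12)), seed=5)
stack, truth3 = sc.generate_scene(spec3)
res = sc.quantify_chamber(stack)
print(f"chamber {res.chamber_id}: n_cells_total={res.n_cells_total} "
      f"n_infiltrated={res.n_infiltrated} infiltrated_fraction={res.infiltrated_fraction:.2f} "
      f"organoid_volume_um3={res.organoid_volume_um3:.3e}")
```

prints

```
well synthetic-1: n_labeled=41 n_accepted=37 n_rejected_small=0 n_rejected_large=4
chamber synthetic-5: n_cells_total=20 n_infiltrated=8 infiltrated_fraction=0.40 organoid_volume_um3=4.192e+06
```

All 37 planted spots are accepted and the 4 large smears rejected by the
size filter (the 4 tiny specks fall below the adaptive threshold and are
never labeled); in 3D, exactly the 8 cells planted inside the depth window
are classified infiltrated, and the segmented organoid volume (4.192×10⁶
µm³) is within 0.1% of the analytic sphere volume (4/3)π·100³ ≈ 4.189×10⁶
µm³.

## Command line

```
simulate well  --spec spec.json --out well.tif --truth truth.json
elispot count  --input well.tif --pixel-size 3 --min-area 40 --max-area 4000 \
               --offset 25 --window 40 --out report.json
simulate scene --spec scene.json --out chamber.tif --truth truth.json
infiltrate run  --stack chamber.tif --voxel 4,2,2 --xy-diam 5 --z-height 10 \
                --window -200,0 --out result.json
infiltrate pool result1.json result2.json --min-chips 2 --out pooled.csv
```

`elispot count` also accepts a directory for batch mode (one CSV row per
well plus per-well JSON reports). Every parameter that affects results is
echoed into the report; reports are byte-reproducible from (input, config,
seed).

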