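# cortimap

Sub-voxel cortical thickness mapping of the tibial diaphysis from clinical
CT, with anatomical-frame regional morphometry and the group-comparison and
reliability statistics used for regional reference data.

## Who this is for

Researchers in bone morphometry and orthopaedic imaging who need regional
cortical-thickness reference values from routine (low-resolution) CT: the
cortex of a long bone is only a few voxels thick, so apparent thickness from
thresholding is badly biased, while model-based line-profile fitting
(cortical bone mapping, CBM) recovers thickness accurately below the voxel
scale.

## What it computes

At every vertex of a sub-pixel outer cortical surface, CT values are sampled
along a short line perpendicular to the cortex and fit with a blurred
three-level density model

```
m(x) = y0 + (y1 − y0)·Φ((x − x0)/σ) + (y2 − y1)·Φ((x − x1)/σ),   t = x1 − x0
```

(Φ the standard normal CDF; y0/y1/y2 background, cortical, trabecular HU;
x0/x1 the periosteal/endosteal edges; σ the scanner blur).  A two-pass scheme
— free fits, robust global cortical density from thick-cortex fits, then
density-constrained refits — keeps thin-cortex estimates identifiable below
the blur scale.

Thickness maps are summarized over 12 standardized regions: three height
bands of the diaphysis (distal 30–43%, central 43–57%, proximal 57–70% of
tibial length, measured in an anatomical frame built from two diaphyseal
circle fits and bony landmarks) × four 90° sectors (medial, anterior,
lateral, posterior), with thickness standardized by tibial length
(reported ×10⁻³).  A statistics layer provides one-way ANOVA with Tukey HSD
(from raw samples *or* printed summary statistics via t-based CI→SD
inversion), observed power via the noncentral F distribution, repeat-
measurement precision, and ICC.

Synthetic CT phantoms with analytically known thickness (and synthetic
cohorts of regional values) make the whole pipeline testable end to end; see
`docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
import numpy as np
import cortimap as cm
from cortimap.phantom import (PhantomSpec, make_phantom, constant_radius,
                              sinusoidal_thickness_field)

spec = PhantomSpec(bone_length=120.0,
                   outer_radius_profile=constant_radius(11.0),
                   thickness_field=sinusoidal_thickness_field(5.5, 2.5),
                   psf_sigma=0.6, noise_sd=20.0,
                   voxel_spacing=(0.7, 0.7, 1.0), seed=42)
volume, truth = make_phantom(spec)
surface = cm.extract_surface(volume, target_vertices=(1500, 2500))
tmap = cm.map_thickness(volume, surface, cm.CBMParams())
frame = cm.build_frame(surface, truth.landmarks)
summary = cm.summarize(surface, tmap, frame, truth.landmarks)

print("global cortical density: %.0f HU" % tmap.global_density)
err = tmap.thickness[tmap.valid] - truth.thickness_at(surface.vertices)[tmap.valid]
print("MAE vs truth: %.3f mm" % np.mean(np.abs(err)))
print(summary.table[["region", "n_points", "actual_mm", "standardized_e3"]]
      .round(2).to_string(index=False))
```

prints

```
global cortical density: 1500 HU
MAE vs truth: 0.048 mm
            region  n_points  actual_mm  standardized_e3
   proximal-medial        72       3.28            27.29
 proximal-anterior        72       5.65            47.07
  proximal-lateral        64       7.77            64.72
proximal-posterior        72       5.64            46.98
    central-medial        72       3.28            27.32
  central-anterior        72       5.65            47.06
   central-lateral        64       7.76            64.68
 central-posterior        72       5.63            46.90
     distal-medial        72       3.28            27.29
   distal-anterior        72       5.65            47.08
    distal-lateral        64       7.77            64.71
  distal-posterior        72       5.63            46.95
```

The phantom's wall is 5.5 + 2.5·sin(θ) mm (3 mm medially, 8 mm laterally on
this right tibia), blurred with a 0.6 mm PSF and overlaid with 20 HU noise at
clinical voxel size.  The recovered cortical density is the phantom's 1500 HU;
the map's mean absolute error against the analytic truth is 0.048 mm —
an order of magnitude below the voxel size.  Sector means match the analytic
sector averages of the sinusoid (5.5 ± 2.25 mm), and standardized values are
actual/120 mm × 10³.

A `cortimap` command-line interface wraps the same stages
(`cortimap all --config run.yaml`, `cortimap tables-demo`, …) with a single
YAML config, per-stage logging and a run manifest.

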