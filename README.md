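# inrfqa

Full-reference image and video quality metrics built on a nonlinear
receptive-field image transform, together with the standard SRCC/PLCC
evaluation protocol and a grid-search parameter optimizer.

## What it does

The core transform maps a luminance image `I` to

```
O(x) = (m * I)(x) - lambda * sum_i w_i S(I(y_i) - (g * I)(x))
```

where `m`, `w`, `g` are unit-sum isotropic Gaussian kernels (standard
deviations `sigma_m`, `sigma_w`, `sigma_g`), `S` is an `atan` sigmoid whose
operating point shifts per pixel with the local mean `(g * I)(x)`, and `*`
is 2D convolution with mirror boundary handling. The transform acts as a
perceptual linearization, so quality is measured by plain MSE in the
transformed domain:

- **Image metric** — `inrf_iqa(ref, dist) = MSE(O_ref, O_dist)`.
- **Video metric** — the image metric applied frame-by-frame after
  (a) equalizing frame counts (dropping reference frames by default, or
  duplicating distorted frames) and (b) scaling the three kernel widths by
  `f = frame_width / 512`; per-frame scores are mean-pooled.
- **Evaluation** — Spearman correlation against subjective scores, and
  Pearson correlation after mapping metric scores through a fitted
  four-parameter logistic.
- **Optimization** — exhaustive grid search of
  `(sigma_m, sigma_w, sigma_g, lambda)` maximizing the chosen correlation.

Default parameters are the published optimum `sigma_m=1.74, sigma_w=25,
sigma_g=1, lambda=3`.

Because the shifted sigmoid is not a convolution, the exact transform is
`O(N K^2)`. The default fast path discretizes the shift into `n_levels`
values (each an ordinary convolution) and interpolates linearly per pixel;
the exact per-pixel evaluation remains available (`exact=True` /
`--exact`) and is used as the test oracle.

A synthetic-fixture module (`inrfqa.synth`) generates seeded test images,
parametric distortions (noise, blur, contrast, quantization, blockiness),
videos, and scored datasets with a planted metric-opinion relationship, so
everything is testable without downloading any benchmark dataset.

## Library usage

```python
import numpy as np
from inrfqa import INRFParams, inrf_iqa, inrf_vqa, scale_params
from inrfqa.synth import make_image, apply_distortion, DistortionSpec, make_video

ref = make_image("filtered_noise", size=64, seed=0)
dist = apply_distortion(ref, DistortionSpec("gaussian_noise", 0.05, seed=1))
score = inrf_iqa(ref, dist)                 # default published parameters

video_ref = make_video(ref, n_frames=8, motion="pan", fps=60)
video_dist = make_video(dist, n_frames=4, motion="pan", fps=30)
result = inrf_vqa(video_ref, video_dist)    # drop_reference alignment
result.value, result.per_frame, result.params.scale_factor
```

## CLI

```sh
inrfqa iqa REF.png DIST.png [--sigma-m 1.74 --sigma-w 25 --sigma-g 1 --lambda 3]
           [--luminance {luma601,y}] [--exact] [--rmse]
inrfqa vqa REF DIST [--align {drop,dup}] [--base-width 512] [--output scores.csv]
           # REF/DIST: frame directory, .y4m, or raw .yuv with a JSON sidecar
inrfqa eval SCORES.csv [--no-sigmoid]       # columns: id, objective, subjective
inrfqa grid DATASET.csv --grid GRID.json    # columns: ref_path, dist_path, subjective
inrfqa synth {image,video,dataset} ...
```

Exit codes: 0 success, 2 usage/config, 3 input-shape mismatch, 4 fit
failure.

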