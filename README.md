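# hotspotseg

Detection and segmentation of metastatic **hot spots** — focal
high-signal lesions — in 2-D spinal MRI slices.  The package implements
a four-stage cascade of the kind used for computer-aided reading of
bone-metastasis scans, aimed at researchers in medical image analysis
who want a fully reproducible, desk-scale testbed for this class of
pipeline:

1. **Sparse-coding features** — a patch dictionary Φ = {φ_j} is learned
   unsupervised by alternating minimization of
   `Σ_i ‖x_i − Σ_j c_ij φ_j‖² + λ Σ_ij |c_ij|`,
   and every image is described by max/mean-pooled code magnitudes.
2. **Three-level triage** — discrete AdaBoost over depth-3 CART trees
   produces a signed confidence `Result = Σ_t α_t h_t(x)`; slices are
   called level I (`Result > θ`, hot spot certain), level II
   (`|Result| ≤ θ`, uncertain) or level III (`Result < −θ`, no hot
   spot).  Level-III slices stop the pipeline.
3. **Multi-instance hot-spot map** — MILBoost trains instance-level
   decision stumps from *bag-level* labels only (a positive slice
   contains at least one lesion patch) by descending the bag-level
   negative log-likelihood under a noisy-OR bag probability; a sliding
   window scan turns the detector into a per-pixel probability map.
4. **Chan-Vese level-set segmentation** — the map is binarized at ρ into
   an initial field φ and evolved by explicit Euler steps (Δt = 0.13) to
   minimize the two-phase piecewise-constant energy
   `λ_a ∫_{Ω_a} (P − g_a)² + λ_b ∫_{Ω_b} (P − g_b)²`.

Otsu thresholding and seeded region growing are included as baseline
segmenters, and Dice/Jaccard overlap scoring
(`D = 2|M∩N|/(|M|+|N|)`, `J = |M∩N|/|M∪N|`) with three-level triage
reports closes the loop.

Clinical MRI of this kind is not publicly available, so the `phantom`
module generates synthetic spine-like slices — banded vertebra/disc
background, smooth bias field, Gaussian noise, planted bright lesions —
with exact ground-truth masks and three-level gold labels.  All training
and evaluation in the tests and the reproduction script run on these
phantoms.  See `docs/methods.md` for the model details and the limits of
what phantom results imply about clinical data.

## Worked example

```python
import numpy as np
from hotspotseg import (PhantomSpec, generate_cohort, scan_probability_map,
                        segment_all_methods, benchmark_methods)
from hotspotseg.pipeline import study_config, train_models

config = study_config(seed=1)
spec = PhantomSpec()                       # 128x128, 2 lesions, sigma=0.08
train = generate_cohort((20, 0, 14), spec, seed=100)
calib = generate_cohort((5, 3, 4), spec, seed=200)
models = train_models(train, config, calibration_cases=calib)

suite = generate_cohort((12, 0, 0), spec, seed=300)
masks = {"chan_vese": [], "region_growing": [], "otsu": []}
for case in suite:
    pm = scan_probability_map(models.mil, case.image, models.dictionary, stride=2)
    for name, mask in segment_all_methods(case.image, pm, config).items():
        masks[name].append(mask)
report = benchmark_methods(suite, masks)
for name in report["ranking"]:
    print(name, round(report["methods"][name]["mean_dice"], 3))
```

prints (training takes about half a minute on one CPU):

```
chan_vese 0.937
region_growing 0.796
otsu 0.739
```

i.e. on lesion-bearing phantoms the level-set segmenter recovers the
planted lesions best (mean Dice ≈ 0.94), region growing is hurt by
boundary leakage and missed seeds, and Otsu thresholding by noise
speckle — the ranking expected for these methods on noisy, non-uniform
backgrounds.

A command-line interface mirrors the library:

```bash
hotspotseg phantom --counts 45 19 23 --seed 0 --out-dir cohort/
hotspotseg train --manifest cohort/manifest.csv --out-dir models/
hotspotseg run --manifest cohort/manifest.csv --model-dir models/ --out-dir results/
```

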