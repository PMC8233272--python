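# lsfmatlas

Quantitative whole-brain analysis for light-sheet fluorescence microscopy
(LSFM) of cleared mouse brains: building a population-average anatomy
template from autofluorescence volumes, transferring hierarchical atlas
annotations onto it block by block, detecting c-Fos-positive cells in a
marker-specific channel with an autofluorescence false-positive veto,
rendering cell-density heatmaps, scoring registration quality, and testing
per-region cell counts with negative-binomial regression.

It is aimed at labs that image iDISCO+-cleared brains and need a tested,
scriptable pipeline from raw channel pairs to per-region statistics —
without any manual intermediate steps.  Every stage can be exercised on
synthetic phantom brains with known ground truth, so the whole pipeline is
verifiable on a laptop with no microscope data.

## What it computes

**Template construction.**  Volumes are conditioned (down-sampling to an
isotropic 20 µm grid, multiplicative bias-field correction, histogram
normalization, CLAHE) and then averaged iteratively: each subject is
registered to the current reference — one affine step followed by five
B-spline refinements, Mattes mutual information, multi-resolution — and the
registered volumes are averaged voxelwise.  The final template can be
symmetrized by mirroring one hemisphere and merging with a sigmoidal blend,
which makes the output exactly mirror-invariant.

**Annotation transfer.**  Labels move from an annotated reference atlas to
the template in two passes: a whole-brain registration, then one masked
registration per parental block (cerebral cortex, cerebral nuclei,
hindbrain, cerebellum, septal regions, interbrain+midbrain).  Block results
are recombined with a nearest-claimed-voxel rule so every in-mask voxel
carries exactly one label.

**Cell detection.**  The dual-channel detector aligns the specific channel
to the autofluorescence channel slice by slice, removes background with a
per-slice disk top-hat, subtracts the scaled shared signal
(`clamp(spec − s·auto, 0)`, with `s` estimated robustly from shared-bright
voxels), seeds on local intensity maxima found with a 5×5×3 filter cube,
grows segments by seeded watershed above an intensity cutoff of 800, and
keeps segments of 8–194 voxels.  Heatmaps sum uniform spheres of 20 µm
radius around atlas-space cell centers.

**Evaluation and statistics.**  Registration quality is measured by
deformation magnitude, per-region intensity variance across registered
volumes (the NIREP criterion), and landmark distances compared with Welch's
t-test.  Per-region counts are modeled as negative binomial
(`Var = μ + μ²/θ`, θ estimated per region by Pearson-χ² matching), each
treatment is compared to control with a Dunnett many-to-one adjustment, and
Benjamini–Hochberg FDR is applied across regions.  Model diagnostics
(deviance-residual screens, Cook's distance, low-count flags) are reported,
never silently acted on.

## Worked example

Detect cells in a synthetic phantom with 50 implanted cells and 10
artifacts shared between the channels:

```python
import numpy as np
from scipy.spatial import cKDTree
from lsfmatlas import synth
from lsfmatlas.celldetect import DetectConfig, detect_cells

auto, labels, ontology = synth.make_phantom((48, 96, 96), n_regions=6, seed=3)
per_region = {rid: 0 for rid in labels.present_labels()}
for i in range(50):
    rid = labels.present_labels()[i % 6]
    per_region[rid] += 1
spec, truth = synth.implant_cells(labels, per_region, peak_intensity=3000.0,
                                  seed=4, anatomy=auto)
auto, spec, artifacts = synth.add_shared_artifacts(auto, spec, 10,
                                                   intensity=2500.0, seed=5,
                                                   avoid=truth.cell_centers)

cells = detect_cells(auto, spec, DetectConfig(), seed=1)
detected = cells[["z", "y", "x"]].to_numpy()
d, _ = cKDTree(detected).query(truth.cell_centers)
print(f"detected {len(cells)} cells, recall {(d <= 2).mean():.2f}")
```

prints

```
detected 50 cells, recall 1.00
```

— all 50 implanted cells are recovered within 2 voxels of their true
centers, and none of the 10 shared artifacts survives the autofluorescence
veto (rerun with `DetectConfig(autofluor_removal=False)` to watch all ten
reappear as false positives).

The same operations are available from the shell:

```bash
lsfmatlas synth --out phantom/ --seed 3
lsfmatlas detect-cells --auto phantom/autofluorescence.tif \
    --spec phantom/specific.tif --atlas-labels phantom/labels.tif \
    --out-cells cells.csv --out-counts counts.csv
lsfmatlas stats --counts counts.csv --design design.csv --control vehicle \
    --out stats.csv
```

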