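import warnings

import numpy as np
import pytest

from lsfmatlas import synth

# SimpleITK registration emits benign convergence warnings on phantoms
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_phantom():
    """Shared 32x48x48 phantom: (auto volume, label volume, ontology)."""
    return synth.make_phantom((32, 48, 48), 5, seed=10)


@pytest.fixture(scope="session")
def detection_phantom():
    """Dual-channel phantom with 50 implanted cells and 10 shared artifacts."""
    auto, lab, ont = synth.make_phantom((48, 96, 96), 6, seed=3)
    rids = lab.present_labels()
    per_region: dict[int, int] = {}
    for i in range(50):
        rid = rids[i % len(rids)]
        per_region[rid] = per_region.get(rid, 0) + 1
    spec, cell_truth = synth.implant_cells(
        lab, per_region, peak_intensity=3000.0, seed=4, anatomy=auto
    )
    auto2, spec2, artifact_truth = synth.add_shared_artifacts(
        auto, spec, 10, intensity=2500.0, seed=5, avoid=cell_truth.cell_centers
    )
    return auto2, spec2, lab, cell_truth, artifact_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
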