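import numpy as np
import pytest

from mrbodycomp import phantom as ph


@pytest.fixture(scope="session")
def anatomy96():
    """One default anatomy slice at 96 px (5 mm pixels)."""
    return ph.make_anatomy(ph.default_spec(96), seed=7)


@pytest.fixture(scope="session")
def rendered96(anatomy96):
    img = ph.render_intensities(anatomy96.labels, ph.IntensityModel(), seed=11)
    sl = ph.LabeledSlice(image=img, labels=anatomy96.labels.copy(),
                         spacing=anatomy96.spacing,
                         imat_sites_mm=anatomy96.imat_sites_mm,
                         imat_cluster_radius_mm=anatomy96.imat_cluster_radius_mm)
    return sl


@pytest.fixture(scope="session")
def training_slices():
    """30 independent rendered phantom slices at 96 px (the desk-scale
    segmentation dataset)."""
    spec = ph.default_spec(96)
    rng = np.random.default_rng(42)
    out = []
    for i in range(30):
        s = ph.make_anatomy(ph._vary_spec(spec, rng), seed=1000 + i)
        s.image = ph.render_intensities(s.labels, ph.IntensityModel(),
                                        seed=2000 + i)
        out.append(s)
    return out
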