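import numpy as np
import pytest

from omiflim import (
    DecayCube,
    apply_qc,
    build_feature_table,
    build_scene,
    contrast_pair,
    fit_image,
    make_irf,
)


@pytest.fixture(scope="session")
def irf220():
    """220 ps FWHM Gaussian IRF centered at 1 ns on the default time axis."""
    return make_irf(fwhm=220.0, center=1000.0)


@pytest.fixture(scope="session")
def small_scene():
    """A small two-type field of view with ground truth (fast to fit)."""
    return build_scene(
        contrast_pair(2.0), field_size=(96, 96), n_cells=10, rng_seed=3
    )


@pytest.fixture(scope="session")
def small_pipeline(small_scene):
    """The small scene run through fitting, extraction and QC."""
    scene = small_scene
    fitmaps, cubes = {}, {}
    for ch, bf in [("nadph", 2), ("fad", 3)]:
        cubes[ch] = DecayCube(scene.cubes[ch], scene.bin_width, ch)
        fitmaps[ch] = fit_image(cubes[ch], scene.irfs[ch], bin_factor=bf, min_photons=2500)
    types = dict(zip(scene.truth_table.cell_id, scene.truth_table.cell_type))
    table = apply_qc(
        build_feature_table(fitmaps, cubes, scene.label_image, cell_types=types)
    )
    return {"scene": scene, "fitmaps": fitmaps, "cubes": cubes, "table": table}
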