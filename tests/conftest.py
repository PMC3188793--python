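import numpy as np
import pytest

import chipmeta as cm


@pytest.fixture(scope="session")
def seq_library_d100():
    """One synthetic d=100 library with matched control and truth sites."""
    design = cm.SeqLibraryDesign(n_sites=2000, tags_per_site=20, d=100, seed=5)
    chip, control, sites = cm.make_seq_library(design)
    return design, chip, control, sites


@pytest.fixture(scope="session")
def spikein_benchmark():
    """Three-platform spike-in tracks with ground truth."""
    design = cm.SpikeInDesign(seed=42)
    tracks, truth = cm.make_spikein_tracks(design)
    return design, tracks, truth


@pytest.fixture()
def tiny_track():
    return cm.ScoreTrack(
        dataset_id="tiny",
        platform="test",
        data={"chr1": (np.array([100, 135]), np.array([2.0, 4.0]))},
        resolution=35,
        max_interp_dist=50,
    )
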