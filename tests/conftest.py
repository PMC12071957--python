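import numpy as np
import pytest

from nucleiseg.synthetic import SceneSpec, render_scene


@pytest.fixture(scope="session")
def small_records():
    """Eight 96x96 synthetic scenes, both polarities, modest crowding."""
    specs = [
        SceneSpec(image_size=96, n_instances=(4, 10), axis_range=(4.0, 9.0),
                  seed=100 + i,
                  polarity="bright_on_dark" if i % 2 == 0 else "dark_on_bright")
        for i in range(8)
    ]
    return [render_scene(s) for s in specs]


@pytest.fixture(scope="session")
def small_arrays(small_records):
    X = np.stack([r.image for r in small_records]).astype(np.float32)
    y = np.stack([r.merged_mask for r in small_records]).astype(np.float32)
    return X, y


@pytest.fixture(scope="session")
def dsb_tree(tmp_path_factory):
    """A tiny generated dataset in the DSB folder layout."""
    from nucleiseg.synthetic import generate_dataset
    root = tmp_path_factory.mktemp("dsb")
    spec = SceneSpec(image_size=64, n_instances=(3, 7), axis_range=(3.0, 6.0))
    manifest = generate_dataset(6, spec, seed=11, out_dir=root / "train", force=True)
    return root / "train", manifest
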