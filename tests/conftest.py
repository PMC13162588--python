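"""Shared fixtures: a small synthetic dataset rendered once per session."""

import pytest

from cattleact.config import tiny_run_config
from cattleact.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Eight short videos (one keyframe each), half protective, 32x32."""
    root = tmp_path_factory.mktemp("tiny_data")
    spec = SyntheticSpec(n_videos=8, frames_per_video=8, fps=8,
                         frame_size=(32, 32), imbalance=0.5, seed=21)
    manifest = generate_dataset(spec, root)
    return root, manifest


@pytest.fixture()
def tiny_cfg():
    return tiny_run_config(seed=0, max_epochs=1)
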