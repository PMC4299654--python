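"""Shared fixtures: small on-disk stacks with known contents."""

import numpy as np
import pytest

from calstack import StackHeader, open_binary_stack, open_stack
from calstack.synthetic import SimConfig, generate_and_open


def write_raw_blocks(tmp_path, data, frames_per_file, name="blk"):
    """Write an eager (rows, cols, frames, channels) array as raw blocks."""
    paths = []
    start = 0
    for k, nf in enumerate(frames_per_file):
        path = tmp_path / f"{name}_{k}.bin"
        chunk = np.moveaxis(data[:, :, start:start + nf, :], 2, 0)
        path.write_bytes(np.ascontiguousarray(chunk).tobytes())
        paths.append(str(path))
        start += nf
    return paths


@pytest.fixture
def raw_stack_pair(tmp_path):
    """A 3-block uint8 stack on disk plus its eager in-memory oracle."""
    rng = np.random.default_rng(42)
    eager = rng.integers(0, 256, size=(12, 14, 20, 2), dtype=np.uint8)
    frames_per_file = [7, 9, 4]
    paths = write_raw_blocks(tmp_path, eager, frames_per_file)
    header = StackHeader(
        n_rows=12, n_cols=14, n_channels=2, dtype="u8",
        frames_per_file=frames_per_file,
    )
    return open_binary_stack(paths, header), eager


@pytest.fixture(scope="session")
def tuned_experiment(tmp_path_factory):
    """Small noiseless tuned experiment with a leading all-blank block.

    4 stimulus directions, 2 trials, 3 Gaussian-profile cells, no noise
    or motion — every response has a closed form in the ground truth.
    """
    out = tmp_path_factory.mktemp("tuned")
    cfg = SimConfig(
        n_rows=48, n_cols=48, n_channels=1, n_blocks=3, n_stimuli=4,
        stimulus_duration=1.0, blank_time=0.5, n_cells=3, cell_radius=3,
        frame_rate=8.0, amplitudes=1.0, noise_sd=0.0, seed=1,
        orders=[[], [3, 1, 4, 2], [2, 4, 1, 3]],
    )
    stack, gt = generate_and_open(cfg, str(out))
    return stack, gt


@pytest.fixture
def reopen():
    """Re-open a generated experiment from its files."""

    def _reopen(paths, header_path):
        return open_stack(paths, header_path)

    return _reopen
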