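import numpy as np
import pytest

from mdr21 import segmentation as seg


SMALL_SYNTH = {
    "cohort_sizes": {"breast": 8, "lung": 6, "melanoma": 5, "wilms": 4},
    "n_probes": {"breast": 60, "lung": 60, "melanoma": 80, "wilms": 100},
}


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Compile the permutation kernel once so timings are per-test-stable."""
    x = np.random.default_rng(0).normal(0, 1, 30)
    seg.permutation_pvalue(
        x, 1.0, seg.SegmentationParams(seed=0, n_permutations=100)
    )


@pytest.fixture
def step_series():
    """20 points: first half N(0, 0.1), second half N(-1, 0.1)."""
    rng = np.random.default_rng(42)
    values = np.concatenate(
        [rng.normal(0, 0.1, 10), rng.normal(-1, 0.1, 10)]
    )
    positions = np.arange(20) * 1000 + 500
    return positions, values


@pytest.fixture
def small_config(tmp_path):
    from mdr21 import pipeline as pl

    def make(seed=5, out="run", **overrides):
        synth_opts = dict(SMALL_SYNTH)
        synth_opts.update(overrides.pop("synthetic", {}))
        return pl.PipelineConfig(
            seed=seed, out_dir=str(tmp_path / out), synthetic=synth_opts,
            **overrides,
        )

    return make
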