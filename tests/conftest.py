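import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from npcradiomics import CohortSpec, RunConfig, run_all
from npcradiomics.preprocess import QuantizedRoi


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def make_qroi():
    """Factory for small random quantized ROIs (levels on a 64-level axis)."""

    def _make(seed=0, shape=(8, 8, 8), n_used=6, mask_fraction=0.7, n_levels=64):
        r = np.random.default_rng(seed)
        levels = r.integers(1, n_used + 1, size=shape)
        mask = r.random(shape) < mask_fraction
        levels = np.where(mask, levels, 0).astype(np.int64)
        if (levels > 0).sum() < 2:  # ensure a usable ROI
            levels[0, 0, 0] = 1
            levels[0, 0, 1] = 2
        included = levels[levels > 0].astype(np.float64)
        return QuantizedRoi(
            level_grid=levels,
            included_values=included,
            m=float(included.mean()),
            s=float(included.std()),
            n_excluded=0,
            n_levels=n_levels,
            spacing_mm=(1.0, 1.0, 1.0),
        )

    return _make


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Reduced cohort for fast unit/integration tests (not the study conditions)."""
    return CohortSpec(n_ifr=3, n_npd=3, seed=7)


@pytest.fixture(scope="session")
def seed_sweep():
    """Full-pipeline results over the 20-seed sweep at the default study
    conditions (11 IFR + 16 NPD). Shared across the tests that assert the
    cascade-power and classifier-accuracy properties."""
    results = []
    for seed in range(20):
        cfg = RunConfig(seed=seed)
        cfg.cohort.seed = seed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, _, report, cv = run_all(cfg)
        results.append(
            {
                "n_significant": len(report.significant_features),
                "accuracy": {m: cv.metrics[m]["accuracy"] for m in cv.metrics}
                if cv is not None
                else {m: 0.0 for m in ("ANN", "KNN", "SVM")},
            }
        )
    return results
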