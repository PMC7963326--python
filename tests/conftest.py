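import numpy as np
import pandas as pd
import pytest

from cryptmosaic.synthetic_cohort import IntensityConfig, generate_intensity_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Small three-genotype cohort used by classifier and pipeline tests."""
    cfg = IntensityConfig(n_mice_per_genotype=3, crypts_per_mouse=80, seed=7)
    return generate_intensity_cohort(cfg)


@pytest.fixture(scope="session")
def control_cohort() -> pd.DataFrame:
    """Pure wild-type cohort (4 mice x 200 crypts)."""
    cfg = IntensityConfig(
        n_mice_per_genotype=4,
        crypts_per_mouse=200,
        category_probs={"+/+": (1.0, 0.0, 0.0, 0.0)},
        seed=11,
    )
    return generate_intensity_cohort(cfg)


def toy_glmm_frame(rng: np.random.Generator, n_groups: int = 3, max_obs: int = 10) -> pd.DataFrame:
    """Random small count dataset for quadrature-oracle comparisons."""
    rows = []
    for g in range(n_groups):
        n = int(rng.integers(2, max_obs + 1))
        x = rng.integers(0, 2, n).astype(float)
        x[:2] = (0.0, 1.0)  # keep the design full rank
        expo = rng.integers(5, 30, n).astype(float)
        y = rng.poisson(np.exp(0.5 * x) * expo * 0.2)
        for xi, ei, yi in zip(x, expo, y):
            rows.append({"y": int(yi), "x": xi, "expo": ei, "mouse_id": f"g{g}"})
    return pd.DataFrame(rows)
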