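import numpy as np
import pandas as pd
import pytest

from reefpressure.impact_model import (
    CATEGORIES,
    HabitatLayer,
    StressorLayer,
    VulnerabilityMatrix,
)
from reefpressure.synthetic_world import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_config():
    return WorldConfig(grid_shape=(48, 48), n_countries=4, n_bcus=5, seed=11)


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


def random_impact_inputs(seed, shape=(5, 5), n_stressors=4, n_habitats=3):
    """Random stressor/habitat/vulnerability triple on a tiny grid."""
    rng = np.random.default_rng(seed)
    cats = [CATEGORIES[i % 3] for i in range(n_stressors)]
    stressors = [
        StressorLayer(
            name=f"s{i}", category=cats[i], period=2013,
            intensity=rng.uniform(0, 1, shape),
        )
        for i in range(n_stressors)
    ]
    habitats = [
        HabitatLayer(name=f"h{j}", presence=(rng.random(shape) < 0.6).astype(float))
        for j in range(n_habitats)
    ]
    mu = pd.DataFrame(
        rng.uniform(0, 2, (n_habitats, n_stressors)),
        index=[f"h{j}" for j in range(n_habitats)],
        columns=[f"s{i}" for i in range(n_stressors)],
    )
    return stressors, habitats, VulnerabilityMatrix(mu)


def impact_oracle(stressors, habitats, vuln, habitat_agg="mean"):
    """Naive cell-by-cell / stressor-by-stressor / habitat-by-habitat loop."""
    shape = stressors[0].intensity.shape
    per_stressor = {s.name: np.zeros(shape) for s in stressors}
    for r in range(shape[0]):
        for c in range(shape[1]):
            n_present = sum(1 for h in habitats if h.presence[r, c] == 1)
            for s in stressors:
                acc = 0.0
                for h in habitats:
                    if h.presence[r, c] == 1:
                        acc += vuln.weight(h.name, s.name)
                if habitat_agg == "mean":
                    acc /= max(1, n_present)
                x = s.intensity[r, c]
                per_stressor[s.name][r, c] = (0.0 if np.isnan(x) else x) * acc
    total = np.sum(list(per_stressor.values()), axis=0)
    per_category = {
        cat: np.sum(
            [per_stressor[s.name] for s in stressors if s.category == cat]
            or [np.zeros(shape)],
            axis=0,
        )
        for cat in CATEGORIES
    }
    return total, per_category, per_stressor
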