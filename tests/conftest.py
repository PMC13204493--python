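import numpy as np
import pytest

from carfind import (
    SceneConfig,
    make_object_library,
    train_classifier,
)

LIBRARY_SEED = 20240101


@pytest.fixture(scope="session")
def small_library():
    """Compact labeled-crop library shared across tests (40/20 per class)."""
    train, test = make_object_library(n_per_class=60, split=(40, 20), seed=LIBRARY_SEED)
    return train, test


@pytest.fixture(scope="session")
def trained_model(small_library):
    train, _ = small_library
    labeled = [(cand.features, cls) for cand, cls in train]
    return train_classifier(labeled, seed=LIBRARY_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def blank_tile(rng, shape=(512, 512), background=30000.0, noise_sd=300.0):
    return np.clip(background + rng.normal(0.0, noise_sd, shape), 0, 65535)


def cart_scene(n_cells: int, crowding: float = 95.0, **kwargs) -> SceneConfig:
    densities = {"CART": float(n_cells), "PLATELET": 0.0, "RBC": 0.0, "OTHER": 0.0}
    return SceneConfig(densities=densities, crowding=crowding, exact_counts=True, **kwargs)


def match_candidates(candidates, truth_centers, radius_px=5.0):
    """Greedy one-to-one matching of candidates to ground-truth centers."""
    matched = 0
    used: set[int] = set()
    for row, col in truth_centers:
        best, best_d = None, radius_px
        for i, cand in enumerate(candidates):
            if i in used:
                continue
            d = np.hypot(cand.center[0] - row, cand.center[1] - col)
            if d <= best_d:
                best, best_d = i, d
        if best is not None:
            used.add(best)
            matched += 1
    return matched
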