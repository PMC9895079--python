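import numpy as np
import pytest

from grazegrid import LandscapeConfig, generate_landscape


@pytest.fixture(scope="session")
def small_truth():
    """A small landscape exercising every pipeline stage quickly."""
    return generate_landscape(
        LandscapeConfig(grid_rows=30, grid_cols=30, n_counties=8, n_years=2, seed=1))


@pytest.fixture(scope="session")
def default_truth():
    """The default study landscape: 60x60 grid, 25 counties, seed 42."""
    return generate_landscape(LandscapeConfig(seed=42))


def mahalanobis_oracle(D: np.ndarray) -> np.ndarray:
    """Brute-force Mahalanobis distance of each row of D from the row mean."""
    u = D.mean(axis=0)
    cov = np.cov(D, rowvar=False).reshape(D.shape[1], D.shape[1])
    cov_inv = np.linalg.inv(cov)
    return np.array([float(np.sqrt((d - u) @ cov_inv @ (d - u))) for d in D])


def dbi_oracle(values, labels) -> float:
    """Term-by-term Davies-Bouldin index: mean over groups of the worst
    pairwise (spread_x + spread_y) / |centroid_x - centroid_y| ratio."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = list(np.unique(labels))
    cent = {g: values[labels == g].mean() for g in groups}
    spread = {g: np.abs(values[labels == g] - cent[g]).mean() for g in groups}
    total = 0.0
    for x in groups:
        ratios = []
        for y in groups:
            if y == x:
                continue
            sep = abs(cent[x] - cent[y])
            if sep == 0:
                return float("inf")
            ratios.append((spread[x] + spread[y]) / sep)
        total += max(ratios)
    return total / len(groups)
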