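import numpy as np
import pandas as pd
import pytest

from msfr.synthetic_data import default_ground_truth


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth(seed=7)


@pytest.fixture(scope="session")
def small_tables(ground_truth):
    """One small synthetic stranding/otolith pair reused across tests."""
    from msfr.synthetic_data import generate_strandings_and_stomachs

    rng = np.random.default_rng(11)
    return generate_strandings_and_stomachs(ground_truth, n_strandings=60, rng=rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def brute_force_mec(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive minimum enclosing circle over all 2- and 3-point support sets.

    Vectorised over candidate circles; independent of the Welzl implementation.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(pts)
    if n == 1:
        return pts[0], 0.0
    centers = []
    # all pairs: midpoint circles
    i, j = np.triu_indices(n, k=1)
    centers.append((pts[i] + pts[j]) / 2.0)
    # all triples: circumcenters
    if n >= 3:
        ii, jj, kk = np.array(
            [(x, y, z) for x in range(n) for y in range(x + 1, n) for z in range(y + 1, n)]
        ).T
        A, B, C = pts[ii], pts[jj], pts[kk]
        d = 2.0 * (
            A[:, 0] * (B[:, 1] - C[:, 1])
            + B[:, 0] * (C[:, 1] - A[:, 1])
            + C[:, 0] * (A[:, 1] - B[:, 1])
        )
        ok = np.abs(d) > 1e-12
        A, B, C, d = A[ok], B[ok], C[ok], d[ok]
        a2 = (A**2).sum(axis=1)
        b2 = (B**2).sum(axis=1)
        c2 = (C**2).sum(axis=1)
        ux = (a2 * (B[:, 1] - C[:, 1]) + b2 * (C[:, 1] - A[:, 1]) + c2 * (A[:, 1] - B[:, 1])) / d
        uy = (a2 * (C[:, 0] - B[:, 0]) + b2 * (A[:, 0] - C[:, 0]) + c2 * (B[:, 0] - A[:, 0])) / d
        centers.append(np.column_stack([ux, uy]))
    centers = np.vstack(centers)
    # radius of each candidate = max distance to any point; the MEC is the
    # candidate with the smallest such radius
    d2 = ((centers[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    radii = np.sqrt(d2.max(axis=1))
    best = int(np.argmin(radii))
    return centers[best], float(radii[best])
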