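import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def leaf_population():
    from attamech.synthetic import generate_leaf_population

    return generate_leaf_population(n=100_000, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    from attamech.synthetic import CohortParams, generate_cohort

    return generate_cohort(CohortParams(n_ants=1000, seed=5))


def brute_force_local_thickness(data: np.ndarray) -> np.ndarray:
    """Exhaustive all-spheres oracle for the local-thickness definition:
    integer radii r(p) = floor(min distance to a background centre), voxel q
    takes the largest 2 r(p) over closed balls containing it."""
    fg = np.argwhere(data)
    bg = np.argwhere(~data)
    assert fg.size and bg.size
    dmin = np.sqrt(((fg[:, None, :] - bg[None, :, :]) ** 2).sum(-1)).min(axis=1)
    r = np.floor(dmin + 1e-9).astype(int)
    dist = np.sqrt(((fg[:, None, :] - fg[None, :, :]) ** 2).sum(-1))
    covered = dist <= r[:, None] + 1e-9  # [p, q]: q inside sphere at p
    thick = np.where(covered, 2 * r[:, None], 0).max(axis=0)
    out = np.zeros(data.shape)
    out[tuple(fg.T)] = thick
    return out
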