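import numpy as np
import pytest

from mrtad import (
    CallerConfig,
    ContactMap,
    estimate_distance_decay,
    solve_effective_coverage,
)
from mrtad.synthetic_hic import SyntheticSpec, generate_map, standard_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """The named standard fixtures (F4, F200, F500, FNEST)."""
    return standard_fixtures()


@pytest.fixture(scope="session")
def toy_map(fixtures):
    """The 4-bin two-block toy map."""
    return fixtures["F4"][0]


@pytest.fixture(scope="session")
def toy_model(toy_map):
    decay = estimate_distance_decay(toy_map)
    return solve_effective_coverage(toy_map, decay)


@pytest.fixture(scope="session")
def f200(fixtures):
    cmap, truth = fixtures["F200"]
    decay = estimate_distance_decay(cmap)
    model = solve_effective_coverage(cmap, decay)
    return cmap, truth, model


@pytest.fixture(scope="session")
def f500(fixtures):
    cmap, truth = fixtures["F500"]
    decay = estimate_distance_decay(cmap)
    model = solve_effective_coverage(cmap, decay)
    return cmap, truth, model


def random_small_map(seed: int, n: int | None = None) -> ContactMap:
    """A small random planted-domain map for oracle tests."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(4, 13))
    n_domains = int(rng.integers(1, max(2, n // 2)))
    cmap, _ = generate_map(
        SyntheticSpec(
            n_bins=n,
            n_domains=n_domains,
            within_enrichment=float(rng.uniform(1.0, 3.0)),
            depth=float(rng.uniform(2e3, 2e4)),
            coverage_sigma=float(rng.uniform(0.0, 0.5)),
            seed=seed,
        )
    )
    return cmap


def solved(cmap):
    decay = estimate_distance_decay(cmap)
    return solve_effective_coverage(cmap, decay)
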