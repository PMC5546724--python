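"""Synthetic Hi-C contact maps with planted, optionally nested, domains.

The generator emulates the salient statistics of real intra-chromosomal
maps: a power-law distance decay (``d**-alpha``, near ``d**-1`` as observed
in mammalian Hi-C at intermediate distances), heterogeneous per-bin
visibility (log-normal), block-diagonal enrichment of within-domain
contacts, and Poisson-distributed read counts.  The expectation is

    mu_ij = v_i v_j * max(|i-j|, 1)**(-alpha)
            * beta**[same domain] * beta**[same sub-domain]

(so bins sharing a sub-domain are enriched ``beta**2``-fold), rescaled so
the expected total read-pair count equals ``depth``; the diagonal is zero,
matching ICE-style processed maps.  Counts are sampled Poisson on the
upper triangle and mirrored, so every generated map is exactly symmetric
and fully reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_map import ContactMap
from .tad_caller import Partition

__all__ = ["SyntheticSpec", "GroundTruth", "generate_map", "standard_fixtures"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic map.

    Either ``domain_boundaries`` (internal cut points, strictly increasing
    in ``(0, n_bins)``) or ``n_domains`` (equal-size split) defines the
    planted domains.  ``nested`` optionally lists additional internal cut
    points, each strictly inside a domain, defining sub-domains.
    """

    n_bins: int
    domain_boundaries: list[int] | None = None
    n_domains: int | None = None
    nested: list[int] | None = None
    decay_exponent: float = 1.0
    within_enrichment: float = 2.0
    coverage_sigma: float = 0.25
    depth: float = 2e6
    seed: int = 0
    chrom: str = "chrS"
    bin_size: int = 40_000

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.domain_boundaries is None:
            if self.n_domains is None:
                raise ValueError("give domain_boundaries or n_domains")
            edges = np.linspace(0, self.n_bins, self.n_domains + 1).round().astype(int)
            self.domain_boundaries = list(edges[1:-1])
        bs = list(self.domain_boundaries)
        if bs != sorted(set(bs)) or (bs and (bs[0] <= 0 or bs[-1] >= self.n_bins)):
            raise ValueError("domain boundaries must be strictly increasing within (0, n_bins)")
        if self.nested is not None:
            cuts = set(bs)
            for c in self.nested:
                if not 0 < c < self.n_bins or c in cuts:
                    raise ValueError(f"nested cut {c} is not strictly inside a domain")
            if list(self.nested) != sorted(set(self.nested)):
                raise ValueError("nested cuts must be strictly increasing")
        if self.within_enrichment < 1:
            raise ValueError("within_enrichment must be >= 1")
        if not self.depth > 0:
            raise ValueError("depth must be positive")
        if self.coverage_sigma < 0:
            raise ValueError("coverage_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure of a generated map."""

    partition: Partition
    sub_partition: Partition | None
    expectation: np.ndarray | None
    visibility: np.ndarray | None


def _labels_from_cuts(n: int, internal_cuts: list[int]) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    cuts = [0] + list(internal_cuts) + [n]
    for k, (s, e) in enumerate(zip(cuts[:-1], cuts[1:])):
        labels[s:e] = k
    return labels


def generate_map(spec: SyntheticSpec) -> tuple[ContactMap, GroundTruth]:
    """Sample one contact map and return it with its planted ground truth."""
    n = spec.n_bins
    rng = np.random.default_rng(spec.seed)
    if spec.coverage_sigma > 0:
        v = np.exp(rng.normal(0.0, spec.coverage_sigma, size=n))
    else:
        v = np.ones(n)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    decay = np.maximum(d, 1).astype(float) ** (-spec.decay_exponent)
    dom = _labels_from_cuts(n, spec.domain_boundaries)
    beta = spec.within_enrichment
    enrich = np.where(np.equal.outer(dom, dom), beta, 1.0)
    sub_labels = None
    if spec.nested is not None:
        all_cuts = sorted(set(spec.domain_boundaries) | set(spec.nested))
        sub_labels = _labels_from_cuts(n, all_cuts)
        enrich = enrich * np.where(np.equal.outer(sub_labels, sub_labels), beta, 1.0)
    mu = np.outer(v, v) * decay * enrich
    np.fill_diagonal(mu, 0.0)
    mu *= 2.0 * spec.depth / mu.sum()
    iu, ju = np.triu_indices(n, k=1)
    counts = rng.poisson(mu[iu, ju])
    W = np.zeros((n, n))
    W[iu, ju] = counts
    W[ju, iu] = counts
    cmap = ContactMap(chrom=spec.chrom, bin_size=spec.bin_size, W=W)
    truth = GroundTruth(
        partition=Partition(dom),
        sub_partition=Partition(sub_labels) if sub_labels is not None else None,
        expectation=mu,
        visibility=v,
    )
    return cmap, truth


#: the literal two-block toy map used across the test suite
F4_MATRIX = np.array(
    [
        [0.0, 10.0, 1.0, 1.0],
        [10.0, 0.0, 1.0, 1.0],
        [1.0, 1.0, 0.0, 10.0],
        [1.0, 1.0, 10.0, 0.0],
    ]
)


def _fnest_cuts() -> tuple[list[int], list[int]]:
    """FNEST geometry: 300 bins, 6 domains of 50, split into 2 or 3 sub-domains."""
    domains = [50 * k for k in range(1, 6)]
    nested: list[int] = []
    for k in range(6):
        start = 50 * k
        if k % 2 == 0:  # split in two
            nested.append(start + 25)
        else:  # split in three
            nested.extend([start + 17, start + 34])
    return domains, nested


def standard_fixtures() -> dict[str, tuple[ContactMap, GroundTruth]]:
    """Named deterministic fixtures used throughout the test suite.

    ``F4``   — the literal two-block 4-bin toy map (within-block weight 10,
               cross-block 1, zero diagonal);
    ``F200`` — 200 bins, 8 equal planted domains, enrichment 2, depth 2e6;
    ``F500`` — 500 bins, 12 domains, enrichment 2, depth 5e6, log-normal
               visibility spread 0.5, seed 7;
    ``FNEST`` — 300 bins, 6 domains each split into 2-3 sub-domains,
               enrichment 1.8 (sub-domains 1.8**2).
    """
    fixtures: dict[str, tuple[ContactMap, GroundTruth]] = {}
    f4 = ContactMap(chrom="chrS", bin_size=40_000, W=F4_MATRIX.copy())
    fixtures["F4"] = (
        f4,
        GroundTruth(
            partition=Partition(np.array([0, 0, 1, 1])),
            sub_partition=None,
            expectation=None,
            visibility=None,
        ),
    )
    fixtures["F200"] = generate_map(
        SyntheticSpec(n_bins=200, n_domains=8, within_enrichment=2.0, depth=2e6, seed=7)
    )
    fixtures["F500"] = generate_map(
        SyntheticSpec(
            n_bins=500,
            n_domains=12,
            within_enrichment=2.0,
            depth=5e6,
            coverage_sigma=0.5,
            seed=7,
        )
    )
    domains, nested = _fnest_cuts()
    fixtures["FNEST"] = generate_map(
        SyntheticSpec(
            n_bins=300,
            domain_boundaries=domains,
            nested=nested,
            within_enrichment=1.8,
            depth=3e6,
            seed=7,
        )
    )
    return fixtures
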