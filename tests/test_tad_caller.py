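import numpy as np
import pytest

from mrtad import (
    CallerConfig,
    ContactMap,
    DistanceDecay,
    Partition,
    boundary_scores,
    call_tads,
    consensus_tads,
    modularity_score,
    expected_map,
    normalized_mutual_information,
    run_louvain_trial,
    solve_effective_coverage,
    sweep_resolutions,
)
from mrtad.tad_caller import UNASSIGNED, BoundaryScoreTrack
from conftest import random_small_map, solved


def test_config_validation():
    with pytest.raises(ValueError):
        CallerConfig(n_trials=0)
    with pytest.raises(ValueError):
        CallerConfig(cutoff=1.5)


def test_toy_map_recovers_two_blocks(toy_map, toy_model):
    """The two-block toy map partitions into {[0,1],[2,3]} in every trial."""
    cfg = CallerConfig(seed=0)
    for seed in range(5):
        rng = np.random.default_rng(seed)
        part, q = run_louvain_trial(toy_map, toy_model, cfg, rng)
        assert np.array_equal(part.labels, [0, 0, 1, 1])
        assert q > 0


def test_toy_boundary_track(toy_map):
    tads, track, _ = call_tads(toy_map, CallerConfig(seed=1))
    assert np.array_equal(track.scores, [1.0, 0.0, 1.0, 0.0, 1.0])
    assert tads.intervals == [(0, 2), (2, 4)]


def test_noise_free_map_q_is_zero():
    """With W equal to the factorized null, every trial scores Q ~ 0."""
    from scipy.linalg import toeplitz

    rng = np.random.default_rng(0)
    n = 30
    kappa = rng.lognormal(0, 0.3, n)
    f = 40.0 / (1 + np.arange(n))
    W = np.outer(kappa, kappa) * toeplitz(f)
    cm = ContactMap(chrom="c", bin_size=1, W=W)
    model = solve_effective_coverage(cm, DistanceDecay(f=f), tol=1e-10)
    _, q = run_louvain_trial(cm, model, CallerConfig(), np.random.default_rng(1))
    assert abs(q) < 1e-6


@pytest.mark.parametrize("seed", range(4))
def test_trials_are_contiguous_and_beat_singletons(seed):
    cmap = random_small_map(seed, n=40)
    model = solved(cmap)
    part, q = run_louvain_trial(cmap, model, CallerConfig(), np.random.default_rng(seed))
    assert part.is_contiguous()
    singleton_q = modularity_score(
        cmap, expected_map(model), np.arange(cmap.n)
    )
    assert q >= singleton_q - 1e-12


def test_n2_degenerate():
    W = np.array([[0.0, 6.0], [6.0, 0.0]])
    cm = ContactMap(chrom="c", bin_size=1, W=W)
    model = solve_effective_coverage(cm, DistanceDecay(f=np.array([0.0, 6.0])))
    part, q = run_louvain_trial(cm, model, CallerConfig(), np.random.default_rng(0))
    assert part.is_contiguous()
    # best of {1 domain, 2 domains}
    E = expected_map(model)
    q1 = modularity_score(cm, E, np.zeros(2, int))
    q2 = modularity_score(cm, E, np.arange(2))
    assert q == pytest.approx(max(q1, q2), abs=1e-12)


class TestBoundaryScores:
    def test_unanimous_trials_score_zero_or_one(self):
        trials = [Partition(np.array([0, 0, 1, 1]))] * 10
        track = boundary_scores(trials)
        assert set(np.unique(track.scores)) <= {0.0, 1.0}

    def test_direct_counting(self):
        """Trials AABB, AABB, AAAB give internal scores (0, 2/3, 1/3)."""
        trials = [
            Partition(np.array([0, 0, 1, 1])),
            Partition(np.array([0, 0, 1, 1])),
            Partition(np.array([0, 0, 0, 1])),
        ]
        track = boundary_scores(trials)
        assert np.allclose(track.scores, [1, 0, 2 / 3, 1 / 3, 1])

    def test_relabel_invariance(self):
        rng = np.random.default_rng(0)
        trials = [Partition(np.sort(rng.integers(0, 4, 12))) for _ in range(6)]
        relabeled = [Partition(100 - t.labels * 7) for t in trials]
        assert np.array_equal(
            boundary_scores(trials).scores, boundary_scores(relabeled).scores
        )

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            boundary_scores([Partition(np.zeros(3, int)), Partition(np.zeros(4, int))])

    def test_scores_are_multiples_of_one_over_trials(self, f200):
        cmap, _, model = f200
        cfg = CallerConfig(seed=2, n_trials=7)
        _, track, _ = call_tads(cmap, cfg, model=model)
        assert np.allclose(track.scores * 7, np.round(track.scores * 7))


class TestConsensus:
    def make_map(self, n, coverage_zero=()):
        rng = np.random.default_rng(0)
        A = rng.gamma(2.0, 5.0, size=(n, n)) + 0.5
        W = (A + A.T) / 2
        for z in coverage_zero:
            W[z, :] = 0.0
            W[:, z] = 0.0
        return ContactMap(chrom="c", bin_size=10, W=W)

    def test_threshold_application(self):
        cm = self.make_map(4)
        track = BoundaryScoreTrack(np.array([1.0, 0.2, 0.95, 0.1, 1.0]), 20)
        tads = consensus_tads(track, cm, 0.9)
        assert tads.intervals == [(0, 2), (2, 4)]

    def test_exact_cutoff_counts_as_boundary(self):
        """9 of 10 trials is exactly the 0.9 cutoff and is kept."""
        cm = self.make_map(4)
        track = BoundaryScoreTrack(np.array([1.0, 0.0, 9 / 10, 0.0, 1.0]), 10)
        tads = consensus_tads(track, cm, 0.9)
        assert tads.intervals == [(0, 2), (2, 4)]

    def test_no_internal_boundary_gives_single_tad(self):
        cm = self.make_map(6)
        track = BoundaryScoreTrack(np.r_[1.0, np.full(5, 0.4), 1.0], 10)
        tads = consensus_tads(track, cm, 0.9)
        assert tads.intervals == [(0, 6)]

    def test_zero_coverage_bins_trimmed_and_dropped(self):
        cm = self.make_map(6, coverage_zero=(0, 3))
        scores = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        tads = consensus_tads(BoundaryScoreTrack(scores, 10), cm, 0.9)
        # run [0,2) trims bin 0; run [2,4) trims bin 3; run [4,6) intact
        assert tads.intervals == [(1, 2), (2, 3), (4, 6)]
        part = tads.to_partition(6)
        assert part.labels[0] == UNASSIGNED and part.labels[3] == UNASSIGNED

    def test_bad_cutoff_rejected(self):
        cm = self.make_map(4)
        track = BoundaryScoreTrack(np.ones(5), 10)
        with pytest.raises(ValueError):
            consensus_tads(track, cm, 0.0)


def test_call_tads_deterministic(f200):
    cmap, _, model = f200
    cfg = CallerConfig(seed=123)
    a = call_tads(cmap, cfg, model=model)
    b = call_tads(cmap, cfg, model=model)
    assert a[0].intervals == b[0].intervals
    assert np.array_equal(a[1].scores, b[1].scores)
    assert a[2] == b[2]


def test_seed_robustness_of_consensus(f200):
    cmap, _, model = f200
    a, _, _ = call_tads(cmap, CallerConfig(seed=11), model=model)
    b, _, _ = call_tads(cmap, CallerConfig(seed=99), model=model)
    nmi = normalized_mutual_information(a.to_partition(cmap.n), b.to_partition(cmap.n))
    assert nmi >= 0.99


class TestSweep:
    def test_single_gamma_equals_call(self, f200):
        cmap, _, model = f200
        cfg = CallerConfig(seed=5)
        results, summary = sweep_resolutions(cmap, [1.0], cfg)
        direct, _, _ = call_tads(cmap, cfg, model=model)
        assert results[1.0].intervals == direct.intervals
        assert summary.loc[0, "n_tads"] == len(direct)

    def test_gamma_trend_on_nested_fixture(self, fixtures):
        """Higher resolution gives more, smaller domains on the nested map."""
        cmap, _ = fixtures["FNEST"]
        results, summary = sweep_resolutions(cmap, [0.75, 3.0], CallerConfig(seed=6))
        assert summary.loc[1, "n_tads"] >= summary.loc[0, "n_tads"]
        assert summary.loc[1, "median_size_bp"] <= summary.loc[0, "median_size_bp"]

    def test_bad_gamma_lists(self, toy_map):
        with pytest.raises(ValueError):
            sweep_resolutions(toy_map, [], CallerConfig())
        with pytest.raises(ValueError):
            sweep_resolutions(toy_map, [2.0, 1.0], CallerConfig())
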