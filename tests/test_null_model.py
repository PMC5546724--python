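import numpy as np
import pytest
from scipy.linalg import toeplitz
from scipy.stats import linregress, pearsonr

from mrtad import (
    ContactMap,
    DistanceDecay,
    MapValidationError,
    estimate_distance_decay,
    expected_map,
    solve_effective_coverage,
)
from mrtad.null_model import read_null_model, smoothing_window, write_null_model
from mrtad.synthetic_hic import SyntheticSpec, generate_map


def constant_map(n=10, a=4.0):
    W = np.full((n, n), a)
    np.fill_diagonal(W, 0.0)
    return ContactMap(chrom="c", bin_size=1, W=W)


def test_constant_map_decay_is_flat():
    """All off-diagonal entries equal -> f(d) = a for every d >= 1, f(0) = 0."""
    cm = constant_map(a=4.0)
    decay = estimate_distance_decay(cm, span=0.3)
    assert decay.f[0] == 0.0
    assert np.allclose(decay.f[1:], 4.0)


def test_smoothing_window_is_one_percent():
    assert smoothing_window(1000, 0.01) == 10
    assert smoothing_window(100, 0.01) == 3  # floored


def test_decay_recovers_power_law_exponent():
    """Poisson map with mean ~ 1/d: log-log slope of f within 0.15 of -1."""
    cm, _ = generate_map(
        SyntheticSpec(n_bins=300, n_domains=1, within_enrichment=1.0,
                      decay_exponent=1.0, coverage_sigma=0.0, depth=2e6, seed=3)
    )
    decay = estimate_distance_decay(cm)
    d = np.arange(3, 60)
    fit = linregress(np.log(d), np.log(decay.f[d]))
    assert abs(fit.slope - (-1.0)) < 0.15


def test_too_small_map_rejected():
    cm = ContactMap(chrom="c", bin_size=1, W=np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValueError):
        estimate_distance_decay(cm)


class TestSolver:
    def test_symmetric_fixed_point(self):
        """n=3, uniform off-diagonal a: kappa = 1 and E = W."""
        cm = constant_map(n=3, a=5.0)
        decay = estimate_distance_decay(cm, span=0.5)
        model = solve_effective_coverage(cm, decay)
        assert model.converged
        assert np.allclose(model.kappa, 1.0, atol=1e-5)
        assert np.allclose(expected_map(model), cm.W, atol=1e-4)

    def test_coverage_constraints_on_planted_map(self):
        cm, _ = generate_map(SyntheticSpec(n_bins=50, n_domains=3, depth=2e5, seed=4))
        model = solve_effective_coverage(cm, estimate_distance_decay(cm), tol=1e-6)
        assert model.converged
        E = expected_map(model)
        c = cm.coverage
        pos = c > 0
        assert (np.abs(E.sum(1) - c)[pos] / np.maximum(c[pos], 1)).max() <= 1e-6

    def test_sum_E_matches_2N(self):
        cm, _ = generate_map(SyntheticSpec(n_bins=80, n_domains=4, depth=5e5, seed=9))
        model = solve_effective_coverage(cm, estimate_distance_decay(cm), tol=1e-6)
        E = expected_map(model)
        twoN = 2 * cm.total_reads
        assert abs(E.sum() - twoN) / twoN <= 1e-5

    def test_kappa_tracks_coverage(self):
        """Log-normally heterogeneous visibility: Pearson(kappa, c) >= 0.95."""
        cm, _ = generate_map(
            SyntheticSpec(n_bins=200, n_domains=8, coverage_sigma=0.5, depth=2e6, seed=12)
        )
        model = solve_effective_coverage(cm, estimate_distance_decay(cm))
        r, _ = pearsonr(model.kappa, cm.coverage)
        assert r >= 0.95

    def test_exact_recovery_of_factorized_map(self):
        """Noise-free W = kappa_i kappa_j f(|i-j|) is reproduced element-wise."""
        rng = np.random.default_rng(7)
        n = 60
        kappa_true = rng.lognormal(0.0, 0.4, size=n)
        f_true = 50.0 / (1.0 + np.arange(n))
        W = np.outer(kappa_true, kappa_true) * toeplitz(f_true)
        cm = ContactMap(chrom="c", bin_size=1, W=W)
        model = solve_effective_coverage(cm, DistanceDecay(f=f_true), tol=1e-10)
        E = expected_map(model)
        assert np.abs(E / W - 1.0).max() < 1e-4

    def test_zero_coverage_bin_pinned(self):
        cm, _ = generate_map(SyntheticSpec(n_bins=40, n_domains=2, depth=1e5, seed=2))
        W = cm.W.copy()
        W[7, :] = 0.0
        W[:, 7] = 0.0
        cm2 = ContactMap(chrom="c", bin_size=1, W=W)
        model = solve_effective_coverage(cm2, estimate_distance_decay(cm2))
        assert model.kappa[7] == 0.0
        assert expected_map(model)[7].sum() == 0.0

    def test_all_zero_map_rejected(self):
        cm = ContactMap(chrom="c", bin_size=1, W=np.zeros((5, 5)))
        with pytest.raises(MapValidationError):
            solve_effective_coverage(cm, DistanceDecay(f=np.ones(5)))

    def test_scale_consistency(self):
        """Scaling W by lambda scales E by lambda (null model is scale-covariant)."""
        cm, _ = generate_map(SyntheticSpec(n_bins=60, n_domains=3, depth=3e5, seed=5))
        model1 = solve_effective_coverage(cm, estimate_distance_decay(cm), tol=1e-8)
        lam = 3.7
        cm2 = ContactMap(chrom=cm.chrom, bin_size=cm.bin_size, W=lam * cm.W)
        model2 = solve_effective_coverage(cm2, estimate_distance_decay(cm2), tol=1e-8)
        assert np.allclose(expected_map(model2), lam * expected_map(model1), rtol=1e-5)


def test_expected_row_matches_dense():
    cm, _ = generate_map(SyntheticSpec(n_bins=30, n_domains=2, depth=1e5, seed=8))
    model = solve_effective_coverage(cm, estimate_distance_decay(cm))
    E = expected_map(model)
    for i in (0, 13, 29):
        assert np.array_equal(model.expected_row(i), E[i])


def test_null_model_io_bitexact(tmp_path):
    cm, _ = generate_map(SyntheticSpec(n_bins=30, n_domains=2, depth=1e5, seed=8))
    model = solve_effective_coverage(cm, estimate_distance_decay(cm))
    kp, dp = tmp_path / "kappa.tsv", tmp_path / "decay.tsv"
    write_null_model(model, kp, dp)
    back = read_null_model(kp, dp)
    assert np.array_equal(back.kappa, model.kappa)
    assert np.array_equal(back.decay.f, model.decay.f)
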