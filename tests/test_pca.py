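"""Ensemble PCA, deformation vectors, overlaps and distance histograms."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from heatdyn import (
    Ensemble, EnsemblePCA, align_ensemble, correlation_cosine,
    cumulative_overlap, deformation_vector, distance_histogram,
    end_to_end_series,
)
from heatdyn.pca import DeformationVector
from heatdyn.structures import Residue, Structure

from conftest import make_cloud


def _rigid_copies(coords, n, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n):
        rot = Rotation.random(random_state=rng).as_matrix()
        frames.append(coords @ rot.T + rng.normal(scale=10, size=3))
    return np.stack(frames)


def test_align_ensemble_collapses_rigid_copies():
    base = make_cloud(12, seed=1)
    ens = Ensemble(base.residues, _rigid_copies(base.coords, 5))
    out = align_ensemble(ens, base)
    for f in range(out.n_frames):
        assert np.allclose(out.frames[f], base.coords, atol=1e-9)


def test_align_ensemble_idempotent_and_variance_reducing(planted_ensemble,
                                                         solenoid_pair):
    compact, _, _ = solenoid_pair
    once = align_ensemble(planted_ensemble, compact)
    twice = align_ensemble(once, compact)
    assert np.allclose(once.frames, twice.frames, atol=1e-9)
    var = lambda e: np.sum((e.frames - e.frames.mean(0)) ** 2)
    assert var(once) <= var(planted_ensemble) + 1e-9


def test_pca_rank1_analytic():
    """Frames mean + t*d for t in {-1, 0, 1}: PC1 = +/-d, eigenvalue 2/3."""
    base = make_cloud(6, seed=2)
    rng = np.random.default_rng(3)
    d = rng.normal(size=18)
    d /= np.linalg.norm(d)
    frames = np.stack([base.coords.ravel() + t * d
                       for t in (-1.0, 0.0, 1.0)]).reshape(3, 6, 3)
    res = EnsemblePCA(Ensemble(base.residues, frames)).fit(2)
    assert res.eigenvalues[0] == pytest.approx(2.0 / 3.0)
    assert abs(res.component(1) @ d) == pytest.approx(1.0)


def test_pca_isotropic_cloud_flat_spectrum():
    """For F >> 3N isotropic Gaussian frames the eigenvalue spread follows
    the Marchenko-Pastur law: with q = 3N/F the extreme eigenvalues lie
    near (1 +/- sqrt(q))^2 times the noise variance."""
    rng = np.random.default_rng(12345)
    n, f, sigma = 4, 4000, 1.0
    residues = [Residue("A", i + 1, "GLY") for i in range(n)]
    frames = rng.normal(scale=sigma, size=(f, n, 3))
    res = EnsemblePCA(Ensemble(residues, frames)).fit(3 * n)
    q = (3 * n) / f
    lo, hi = (1 - np.sqrt(q)) ** 2, (1 + np.sqrt(q)) ** 2
    # allow a modest margin beyond the asymptotic support
    margin = 3 * np.sqrt(q)
    assert res.eigenvalues[0] <= sigma ** 2 * (hi + margin)
    assert res.eigenvalues[-1] >= sigma ** 2 * (lo - margin)


def test_pca_reconstruction_completeness(planted_ensemble):
    sub = Ensemble(planted_ensemble.residues, planted_ensemble.frames[:30])
    res = EnsemblePCA(sub).fit(29)
    flat = sub.frames.reshape(30, -1)
    centered = flat - flat.mean(0)
    coeffs = centered @ res.components
    recon = coeffs @ res.components.T
    assert np.allclose(recon, centered, atol=1e-8)


def test_pca_eigenvalues_frame_order_invariant(planted_ensemble):
    sub = Ensemble(planted_ensemble.residues, planted_ensemble.frames[:50])
    res1 = EnsemblePCA(sub).fit(5)
    rng = np.random.default_rng(0)
    perm = rng.permutation(50)
    res2 = EnsemblePCA(Ensemble(sub.residues, sub.frames[perm])).fit(5)
    assert np.allclose(res1.eigenvalues, res2.eigenvalues, rtol=1e-10)


def test_pca_single_frame_rejected(solenoid_pair):
    compact, _, _ = solenoid_pair
    with pytest.raises(ValueError, match="2 frames"):
        EnsemblePCA(Ensemble(compact.residues, compact.coords[None]))


def test_deformation_vector_identical_and_shifted(solenoid_pair):
    compact, _, _ = solenoid_pair
    assert deformation_vector(compact, compact).norm == pytest.approx(0.0,
                                                                      abs=1e-9)
    shifted = Structure(compact.residues, compact.coords + [2.0, 0, 0])
    assert deformation_vector(compact, shifted).norm == pytest.approx(
        0.0, abs=1e-9)


def test_deformation_vector_roster_intersection():
    a = Structure([Residue("A", i, "GLY") for i in (1, 2, 3, 4)],
                  [[0, 0, 0], [4, 0, 0], [8, 3, 0], [12, 0, 5]])
    b = Structure([Residue("A", i, "GLY") for i in (2, 3, 4, 5)],
                  [[4, 0, 0], [8, 3, 0], [12, 0, 5], [16, 0, 0]])
    dv = deformation_vector(a, b)
    assert len(dv.roster) == 3
    assert dv.norm == pytest.approx(0.0, abs=1e-9)
    small = Structure([Residue("B", 9, "GLY"), Residue("B", 10, "GLY")],
                      [[0, 0, 0], [5, 0, 0]])
    with pytest.raises(ValueError, match="common roster too small"):
        deformation_vector(a, small)


def test_planted_deformation_recovered_exactly(solenoid_pair):
    compact, extended, planted = solenoid_pair
    again = deformation_vector(compact, extended)
    assert again.norm == pytest.approx(planted.norm, abs=1e-6)
    assert np.allclose(again.vector, planted.vector, atol=1e-6)


def test_correlation_cosine_analytic(solenoid_pair):
    _, _, planted = solenoid_pair
    d = planted.unit
    assert correlation_cosine(d, planted) == pytest.approx(1.0)
    # build an orthogonal unit vector
    rng = np.random.default_rng(4)
    g = rng.normal(size=d.size)
    g -= (g @ d) * d
    g /= np.linalg.norm(g)
    assert correlation_cosine(g, planted) == pytest.approx(0.0, abs=1e-12)
    mix = (d + g) / np.sqrt(2)
    assert correlation_cosine(mix, planted) == pytest.approx(
        1 / np.sqrt(2))
    # sign flips of either argument change nothing
    flipped = DeformationVector(-planted.vector, planted.roster)
    assert correlation_cosine(-mix, flipped) == pytest.approx(
        1 / np.sqrt(2))


def test_zero_deformation_vector_rejected(solenoid_pair):
    compact, _, _ = solenoid_pair
    zero = DeformationVector(np.zeros(3 * compact.n_residues),
                             compact.residues)
    with pytest.raises(ValueError, match="zero deformation"):
        correlation_cosine(np.ones(3 * compact.n_residues), zero)


def test_cumulative_overlap_pythagorean(solenoid_pair):
    """Two orthonormal vectors at cosines 0.6 and 0.8 to the deformation
    direction span it entirely: cumulative overlap 1."""
    _, _, planted = solenoid_pair
    d = planted.unit
    rng = np.random.default_rng(5)
    g = rng.normal(size=d.size)
    g -= (g @ d) * d
    g /= np.linalg.norm(g)
    p1 = 0.6 * d + 0.8 * g
    p2 = 0.8 * d - 0.6 * g
    assert correlation_cosine(p1, planted) == pytest.approx(0.6)
    assert correlation_cosine(p2, planted) == pytest.approx(0.8)
    assert cumulative_overlap([p1, p2], planted) == pytest.approx(1.0)
    # single-vector consistency
    assert cumulative_overlap([p1], planted) == pytest.approx(0.6)


def test_cumulative_overlap_monotone_nondecreasing(planted_ensemble,
                                                   solenoid_pair):
    compact, _, planted = solenoid_pair
    res = EnsemblePCA(align_ensemble(planted_ensemble, compact)).fit(6)
    vals = [cumulative_overlap([res.component(k + 1) for k in range(m)],
                               planted)
            for m in range(1, 7)]
    assert np.all(np.diff(vals) >= -1e-12)
    assert vals[-1] <= 1.0 + 1e-12


def test_cumulative_overlap_full_basis_is_one():
    rng = np.random.default_rng(6)
    q, _ = np.linalg.qr(rng.normal(size=(9, 9)))
    residues = [Residue("A", i + 1, "GLY") for i in range(3)]
    dv = DeformationVector(rng.normal(size=9), residues)
    assert cumulative_overlap(list(q.T), dv) == pytest.approx(1.0)


def test_cumulative_overlap_rejects_non_orthonormal(solenoid_pair):
    _, _, planted = solenoid_pair
    d = planted.unit
    with pytest.raises(ValueError, match="orthonormal"):
        cumulative_overlap([d, d], planted)


def test_planted_mode_recovery(planted_ensemble, solenoid_pair):
    """PC1 of a 10:1 planted-mode ensemble recovers the planted direction
    with correlation cosine >= 0.95."""
    compact, _, planted = solenoid_pair
    res = EnsemblePCA(align_ensemble(planted_ensemble, compact)).fit(5)
    pc1 = correlation_cosine(res.component(1), planted)
    assert pc1 >= 0.95
    cum = cumulative_overlap([res.component(1), res.component(2)], planted)
    assert cum >= pc1


def test_end_to_end_series_contracts(solenoid_pair):
    compact, extended, planted = solenoid_pair
    n = compact.n_residues
    static = Ensemble(compact.residues, np.repeat(compact.coords[None],
                                                  4, axis=0))
    s = end_to_end_series(static, 1, n)
    assert len(s) == 4 and s.nunique() == 1
    # linear interpolation between conformers gives a monotone series
    ts = np.linspace(0, 1, 11)
    frames = np.stack([
        compact.coords + t * planted.vector.reshape(n, 3) for t in ts])
    interp = Ensemble(compact.residues, frames, frame_spacing=0.1)
    series = end_to_end_series(interp, 1, n)
    assert np.all(np.diff(series.to_numpy()) > 0)
    assert series.index.name == "time_ns"


def test_distance_histogram_constant_series():
    out = distance_histogram([np.full(200, 50.0)])
    assert out.mean == pytest.approx(50.0)
    assert out.sd == 0.0
    assert len(out.peaks) == 1
    assert abs(out.peaks[0] - 50.0) <= 1.0


def test_distance_histogram_two_gaussians():
    rng = np.random.default_rng(77)
    s1 = rng.normal(60, 2, 20000)
    s2 = rng.normal(80, 2, 20000)
    out = distance_histogram([s1, s2], bin_width=1.0)
    assert len(out.peaks) == 2
    assert abs(out.peaks[0] - 60) <= 1.0
    assert abs(out.peaks[1] - 80) <= 1.0
    # pooled mean equals the weighted mean of per-series means
    w = np.array([s1.size, s2.size], dtype=float)
    expect = (s1.mean() * w[0] + s2.mean() * w[1]) / w.sum()
    assert out.mean == pytest.approx(expect)


def test_distance_histogram_validation():
    with pytest.raises(ValueError, match="bin_width"):
        distance_histogram([np.ones(5)], bin_width=0)
    with pytest.raises(ValueError, match="nonempty"):
        distance_histogram([np.array([])])
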