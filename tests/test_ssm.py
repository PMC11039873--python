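"""Shape-model construction: PCA oracle, Eq.-style mode reconstruction,
projection round-trips and the subject-count convergence analysis."""

import numpy as np
import pytest

from canalssm import (CanalParams, CanalSSMError, ParameterError, TopologyError,
                      TriMesh, build_ssm, convergence_analysis,
                      explained_variance, generate_canal, n_modes_for, project,
                      reconstruct_from_weights, reconstruct_mode)


@pytest.fixture(scope="module")
def base_mesh():
    return generate_canal(CanalParams(), 16, 31)


def _rigid_free_field(base: TriMesh, seed: int) -> np.ndarray:
    """Random displacement field orthogonal to infinitesimal rigid motions,
    so rigid Procrustes re-alignment leaves it untouched to first order."""
    rng = np.random.default_rng(seed)
    v = base.vertices
    f = rng.normal(size=v.shape)
    c = v - v.mean(axis=0)
    basis = []
    for k in range(3):
        t = np.zeros_like(v)
        t[:, k] = 1.0
        basis.append(t.ravel())
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        basis.append(np.cross(e, c).ravel())
    Q, _ = np.linalg.qr(np.array(basis).T)
    flat = f.ravel() - Q @ (Q.T @ f.ravel())
    flat /= np.linalg.norm(flat)
    return flat.reshape(v.shape)


def _cohort(base: TriMesh, fields, amps) -> list:
    """amps: (Nt, n_fields) amplitudes applied to unit fields."""
    out = []
    for a in amps:
        v = base.vertices.copy()
        for coeff, fld in zip(a, fields):
            v = v + coeff * fld
        out.append(TriMesh(v, base.faces))
    return out


class TestBuildSSM:
    def test_identical_meshes_zero_variance(self, base_mesh):
        model = build_ssm([base_mesh.copy() for _ in range(3)])
        assert np.allclose(model.mean_shape, base_mesh.vertices, atol=1e-9)
        assert np.all(model.eigenvalues < 1e-18)

    def test_rank_one_cohort(self, base_mesh):
        field = _rigid_free_field(base_mesh, 0)
        amps = np.random.default_rng(1).normal(0.0, 0.8, size=(20, 1))
        model = build_ssm(_cohort(base_mesh, [field], amps))
        sample_var = np.var(amps[:, 0], ddof=1)
        assert abs(model.eigenvalues[0] - sample_var) / sample_var < 1e-3
        assert np.all(model.eigenvalues[1:] < 1e-6 * model.eigenvalues[0])
        cos = abs(model.components[0] @ field.ravel())
        assert cos > 0.999

    def test_two_factor_explained_variance(self, base_mesh):
        f1 = _rigid_free_field(base_mesh, 0)
        f2 = _rigid_free_field(base_mesh, 1)
        f2 = f2 - (f2.ravel() @ f1.ravel()) * f1   # orthogonalize
        f2 /= np.linalg.norm(f2)
        rng = np.random.default_rng(2)
        amps = np.c_[rng.normal(0, 2.0, 200), rng.normal(0, 1.0, 200)]
        model = build_ssm(_cohort(base_mesh, [f1, f2], amps), align=False)
        # brute-force oracle: eigendecomposition of the 2x2 amplitude covariance
        lam = np.sort(np.linalg.eigvalsh(np.cov(amps.T)))[::-1]
        fr, _ = explained_variance(model)
        expected = lam / lam.sum()
        assert abs(fr[0] - expected[0]) < 1e-9
        assert abs(fr[1] - expected[1]) < 1e-9
        assert abs(fr[0] - 0.8) < 0.03      # sampling tolerance at n = 200
        assert n_modes_for(model, 0.90) == 2

    def test_matches_brute_force_pca(self):
        """SVD route equals explicit covariance eigendecomposition."""
        rng = np.random.default_rng(3)
        base = rng.normal(size=(30, 3)) * 10.0
        faces = np.array([[i, i + 1, i + 2] for i in range(28)])
        meshes = [TriMesh(base + rng.normal(0, 0.5, size=base.shape), faces)
                  for _ in range(8)]
        model = build_ssm(meshes, align=False)
        D = np.stack([m.vertices.reshape(-1) for m in meshes])
        D = D - D.mean(axis=0)
        lam, vec = np.linalg.eigh(D.T @ D / (len(meshes) - 1))
        lam = lam[::-1][: len(model.eigenvalues)]
        vec = vec[:, ::-1]
        assert np.allclose(model.eigenvalues, lam, rtol=1e-8, atol=1e-10)
        for i in range(len(model.eigenvalues)):
            if lam[i] > 1e-10:
                assert abs(abs(model.components[i] @ vec[:, i]) - 1.0) < 1e-8

    def test_component_orthonormality(self, base_mesh):
        fields = [_rigid_free_field(base_mesh, s) for s in range(3)]
        amps = np.random.default_rng(4).normal(0, 1.0, size=(12, 3))
        model = build_ssm(_cohort(base_mesh, fields, amps))
        G = model.components @ model.components.T
        assert np.allclose(G, np.eye(len(G)), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        total = np.sum(model.eigenvalues)
        D = model.aligned.reshape(model.n_subjects, -1)
        D = D - D.mean(axis=0)
        assert abs(total - np.sum(D ** 2) / (model.n_subjects - 1)) / total < 1e-6

    def test_too_few_subjects(self, base_mesh):
        with pytest.raises(ParameterError):
            build_ssm([base_mesh, base_mesh])

    def test_topology_mismatch(self, base_mesh):
        other = generate_canal(CanalParams(), 16, 30)
        with pytest.raises(TopologyError):
            build_ssm([base_mesh, base_mesh, other])


@pytest.fixture(scope="module")
def rank_one_model(base_mesh):
    field = _rigid_free_field(base_mesh, 5)
    amps = np.random.default_rng(6).normal(0, 1.5, size=(15, 1))
    return build_ssm(_cohort(base_mesh, [field], amps)), field


class TestReconstructMode:

    def test_zero_multiplier_is_mean(self, rank_one_model):
        model, _ = rank_one_model
        assert np.array_equal(reconstruct_mode(model, 1, 0.0).vertices,
                              model.mean_shape)

    def test_plus_minus_average_to_mean(self, rank_one_model):
        model, _ = rank_one_model
        plus = reconstruct_mode(model, 1, +2.0).vertices
        minus = reconstruct_mode(model, 1, -2.0).vertices
        assert np.abs((plus + minus) / 2.0 - model.mean_shape).max() < 1e-9

    def test_rank_one_closed_form(self, rank_one_model):
        model, field = rank_one_model
        sigma = np.sqrt(model.eigenvalues[0])
        sign = np.sign(model.components[0] @ field.ravel())
        expected = model.mean_shape + 2.0 * sigma * sign * field
        assert np.abs(reconstruct_mode(model, 1, +2.0).vertices - expected).max() < 1e-6

    def test_degenerate_mode_returns_mean(self, base_mesh):
        model = build_ssm([base_mesh.copy() for _ in range(4)])
        out = reconstruct_mode(model, 1, 2.0)
        assert np.array_equal(out.vertices, model.mean_shape)

    def test_index_out_of_range(self, rank_one_model):
        model, _ = rank_one_model
        with pytest.raises(ParameterError):
            reconstruct_mode(model, 99, 1.0)


@pytest.fixture(scope="module")
def two_mode_model(base_mesh):
    fields = [_rigid_free_field(base_mesh, s) for s in (8, 9)]
    amps = np.random.default_rng(10).normal(0, 1.0, size=(10, 2))
    return build_ssm(_cohort(base_mesh, fields, amps))


class TestProjection:

    def test_mean_projects_to_zero(self, two_mode_model):
        assert np.abs(project(two_mode_model, two_mode_model.mean_mesh())).max() < 1e-9

    def test_mode_shape_projects_to_its_weight(self, two_mode_model):
        w = project(two_mode_model, reconstruct_mode(two_mode_model, 1, +2.0))
        assert abs(w[0] - 2.0 * np.sqrt(two_mode_model.eigenvalues[0])) < 1e-9
        assert np.abs(w[1:]).max() < 1e-9

    def test_in_sample_round_trip(self, two_mode_model):
        x = two_mode_model.aligned[3]
        back = reconstruct_from_weights(two_mode_model, project(two_mode_model, x))
        assert np.abs(back.vertices - x).max() < 1e-6

    def test_shape_mismatch(self, two_mode_model):
        with pytest.raises(TopologyError):
            project(two_mode_model, np.zeros((5, 3)))


class TestExplainedVariance:
    def test_all_zero_eigenvalues(self, base_mesh):
        model = build_ssm([base_mesh.copy() for _ in range(3)])
        with pytest.raises(CanalSSMError):
            explained_variance(model)

    def test_threshold_one_counts_nonzero_modes(self, base_mesh):
        fields = [_rigid_free_field(base_mesh, s) for s in (12, 13)]
        f1, f2 = fields
        f2 = f2 - (f2.ravel() @ f1.ravel()) * f1
        f2 /= np.linalg.norm(f2)
        amps = np.random.default_rng(14).normal(0, 1.0, size=(9, 2))
        model = build_ssm(_cohort(base_mesh, [f1, f2], amps), align=False)
        nonzero = int(np.sum(model.eigenvalues > 1e-12 * model.eigenvalues[0]))
        assert n_modes_for(model, 1.0) == nonzero


@pytest.fixture(scope="module")
def toy_cohort(base_mesh):
    fields = [_rigid_free_field(base_mesh, s) for s in (20, 21, 22)]
    amps = np.random.default_rng(23).normal(0, 1.0, size=(40, 3))
    return _cohort(base_mesh, fields, amps)


class TestConvergenceAnalysis:

    def test_full_size_is_exact(self, toy_cohort):
        table = convergence_analysis(toy_cohort, sizes=[len(toy_cohort)],
                                     reps=3, seed=0)
        assert table.mean_rms_mm.iloc[0] < 1e-9
        assert abs(table.mean_var_ratio.iloc[0] - 1.0) < 1e-9

    def test_statistic_decreases_with_size(self, toy_cohort):
        table = convergence_analysis(toy_cohort, sizes=[5, 10, 20, 40],
                                     reps=10, seed=1)
        rms = table.mean_rms_mm.to_numpy()
        assert np.all(np.diff(rms) <= 1e-12)

    def test_seed_reproducibility(self, toy_cohort):
        a = convergence_analysis(toy_cohort, sizes=[5, 10], reps=5, seed=2)
        b = convergence_analysis(toy_cohort, sizes=[5, 10], reps=5, seed=2)
        assert a.equals(b)
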