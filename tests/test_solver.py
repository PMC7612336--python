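"""Strain kinematics primitives and the explicit dynamics solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sulcalstrain import geometry as G
from sulcalstrain import kinematics as K
from sulcalstrain import solver as S


def make_trace(lin=(0.0, 0.0, 0.0), rot=(0.0, 0.0, 0.0), A=1.0, T=6e-3,
               tail=2e-3):
    """Half-sine pulse along fixed directions."""
    t = np.arange(0.0, T + tail, K.TRACE_DT)
    env = np.where(t <= T, A * np.sin(np.pi * t / np.maximum(T, 1e-9)), 0.0)
    return K.KinematicsTrace(t=t, lin_acc=np.outer(env, lin),
                             rot_acc=np.outer(env, rot))


class TestDeformationGradient:
    def test_identity(self, unit_quad):
        F = S.deformation_gradient(unit_quad, unit_quad)
        assert np.allclose(F, np.eye(2), atol=1e-14)

    def test_uniform_stretch(self, unit_quad):
        cur = unit_quad * np.array([1.2, 1.0])
        F = S.deformation_gradient(unit_quad, cur)
        assert np.allclose(F, np.diag([1.2, 1.0]), atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_affine_exactness(self, seed):
        """Bilinear quads reproduce any affine map exactly at the centroid."""
        rng = np.random.default_rng(seed)
        ref = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        ref += rng.uniform(-0.2, 0.2, size=(4, 2))  # distorted but valid
        A = rng.uniform(-1.0, 1.0, size=(2, 2))
        while np.linalg.det(A) < 0.1:
            A = rng.uniform(-1.0, 1.0, size=(2, 2))
        c = rng.uniform(-1.0, 1.0, size=2)
        cur = ref @ A.T + c
        F = S.deformation_gradient(ref, cur)
        assert np.allclose(F, A, atol=1e-10)

    def test_degenerate_reference_rejected(self):
        ref = np.array([[0, 0], [1, 0], [0, 0], [0, 1]], float)
        with pytest.raises(ValueError):
            S.deformation_gradient(ref, ref)


class TestGreenLagrange:
    def test_identity_gives_zero(self):
        assert np.allclose(S.green_lagrange(np.eye(2)), 0.0)

    def test_uniaxial_stretch(self):
        E = S.green_lagrange(np.diag([1.2, 1.0]))
        assert np.allclose(E, np.diag([0.22, 0.0]))

    def test_simple_shear(self):
        E = S.green_lagrange(np.array([[1.0, 0.5], [0.0, 1.0]]))
        assert np.allclose(E, [[0.0, 0.25], [0.25, 0.125]])

    def test_rigid_rotation_gives_zero(self):
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert np.abs(S.green_lagrange(R)).max() < 1e-14

    def test_uniaxial_patch_analytic(self, unit_quad):
        """Prescribed stretch λ on a one-element patch: E_max = (λ²−1)/2."""
        for lam in (0.8, 1.05, 1.5):
            cur = unit_quad * np.array([lam, 1.0])
            E = S.green_lagrange(S.deformation_gradient(unit_quad, cur))
            assert S.max_principal(E) == pytest.approx(
                (lam ** 2 - 1) / 2 if lam > 1 else 0.0, abs=1e-6)


class TestMaxPrincipal:
    def test_diagonal(self):
        assert S.max_principal(np.diag([0.22, 0.0])) == pytest.approx(0.22)

    def test_zero(self):
        assert S.max_principal(np.zeros((2, 2))) == 0.0

    def test_simple_shear_closed_form(self):
        # eigenvalues of E for γ=0.5 via (tr ± sqrt(tr²−4 det)) / 2
        E = np.array([[0.0, 0.25], [0.25, 0.125]])
        tr, det = np.trace(E), np.linalg.det(E)
        expected = (tr + np.sqrt(tr * tr - 4 * det)) / 2
        assert S.max_principal(E) == pytest.approx(expected, abs=1e-12)
        assert S.max_principal(E) == pytest.approx(0.320194, abs=1e-6)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            S.max_principal(np.array([[0.0, 1.0], [0.0, 0.0]]))

    def test_3x3_matches_eigvalsh(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(3, 3))
        T = 0.5 * (M + M.T)
        assert S.max_principal(T) == pytest.approx(
            np.linalg.eigvalsh(T)[-1])


class TestStrainRate:
    def test_equal_tensors_zero_rate(self):
        E = np.array([[0.1, 0.02], [0.02, 0.05]])
        assert S.strain_rate(E, E, 1e-5) == 0.0

    def test_linear_growth(self):
        D = np.array([[3.0, 1.0], [1.0, 2.0]])
        for t in (0.1, 0.5):
            rate = S.strain_rate((t + 1e-5) * D, t * D, 1e-5)
            assert rate == pytest.approx(np.linalg.eigvalsh(D)[-1], rel=1e-9)

    def test_random_pair_bruteforce(self):
        rng = np.random.default_rng(42)
        A, B = rng.normal(size=(2, 2, 2))
        A, B = 0.5 * (A + A.T), 0.5 * (B + B.T)
        dt = 1e-5
        brute = np.linalg.eigvalsh((A - B) / dt)[-1]
        assert S.strain_rate(A, B, dt) == pytest.approx(brute)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            S.strain_rate(np.zeros((2, 2)), np.zeros((2, 2)), 0.0)


def square_patch_mesh(n=2, size=0.01):
    """Small structured brain-only patch for constitutive tests."""
    xs = np.linspace(0.0, size, n + 1)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    elems = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            elems.append([a, a + (n + 1), a + (n + 1) + 1, a + 1])
    mesh = G.Mesh(nodes=nodes, elements=np.array(elems),
                  material=np.full(n * n, "brain"),
                  skull_nodes=np.array([], dtype=int))
    return mesh


class TestInternalForces:
    def test_zero_for_undeformed_state(self, materials):
        mesh = square_patch_mesh()
        state = S.SimState(u=np.zeros_like(mesh.nodes),
                           v=np.zeros_like(mesh.nodes),
                           a=np.zeros_like(mesh.nodes), time=0.0,
                           peak_strain=np.zeros(mesh.n_elements),
                           peak_strain_rate=np.zeros(mesh.n_elements),
                           E_prev=np.zeros((mesh.n_elements, 2, 2)))
        f = S.internal_forces(mesh, materials, state)
        # round-off floor is set by the 50 MPa volumetric term, not by mu
        assert np.abs(f).max() < 1e-8

    def test_small_shear_matches_linear_elasticity(self, materials):
        """γ = 1e-4 homogeneous shear: forces within 1% of the linear model."""
        mesh = square_patch_mesh()
        gamma = 1e-4
        u = np.zeros_like(mesh.nodes)
        u[:, 0] = gamma * mesh.nodes[:, 1]
        model = S._Model(mesh, materials, hourglass_coeff=0.0)
        _, f, _, _ = model.strain_and_forces(u)

        # independent small-strain assembly: sigma = 2 mu eps + lam tr(eps) I
        mat = materials["brain"]
        eps = np.array([[0.0, gamma / 2], [gamma / 2, 0.0]])
        sigma = 2 * mat.shear_modulus * eps
        f_lin = np.zeros_like(u)
        area = G.element_areas(mesh)
        B, _ = S._b_matrix(mesh.element_coords())
        fe = np.einsum("m,ac,mic->mia", area, sigma, B)
        np.add.at(f_lin, mesh.elements.ravel(), fe.reshape(-1, 2))
        scale = np.abs(f_lin).max()
        assert np.abs(f - f_lin).max() < 0.01 * scale

    def test_prony_relaxation_toward_long_term_modulus(self):
        """Held shear: force decays to (1−g) of instantaneous within ~1%."""
        g, tau = 0.4, 2e-3
        mats = {"brain": S.MaterialModel(1040.0, 2.5e3, 50e6,
                                         prony=((g, tau),))}
        mesh = square_patch_mesh(n=1)
        model = S._Model(mesh, mats, hourglass_coeff=0.0)
        gamma = 0.01
        u = np.zeros_like(mesh.nodes)
        u[:, 0] = gamma * mesh.nodes[:, 1]
        dt = tau / 200
        visco = np.zeros((1, mesh.n_elements, 2, 2))
        S_dev_prev = np.zeros((mesh.n_elements, 2, 2))
        f0 = None
        for step in range(int(8 * tau / dt)):
            _, f, visco, S_dev_prev = model.strain_and_forces(
                u, visco, S_dev_prev, dt)
            if f0 is None:
                f0 = np.abs(f).max()
        f_inf = np.abs(f).max()
        assert f_inf / f0 == pytest.approx(1 - g, rel=0.02)

    def test_invalid_prony_rejected(self):
        with pytest.raises(ValueError):
            S.MaterialModel(1000.0, 1e3, 1e6, prony=((0.7, 0.01), (0.5, 0.01)))


class TestStableTimestep:
    def test_halving_element_size_halves_dt(self, materials):
        dt1 = S.stable_timestep(square_patch_mesh(n=2, size=0.01), materials)
        dt2 = S.stable_timestep(square_patch_mesh(n=4, size=0.01), materials)
        assert dt1 / dt2 == pytest.approx(2.0, rel=1e-6)

    def test_quadrupling_bulk_halves_dt(self):
        mesh = square_patch_mesh()
        m1 = {"brain": S.MaterialModel(1000.0, 1.0, 1e6)}
        m4 = {"brain": S.MaterialModel(1000.0, 1.0, 4e6)}
        ratio = S.stable_timestep(mesh, m1) / S.stable_timestep(mesh, m4)
        assert ratio == pytest.approx(2.0, rel=1e-3)

    def test_matches_bruteforce_element_minimum(self, coarse_mesh, materials):
        mesh, _ = coarse_mesh
        dt = S.stable_timestep(mesh, materials, safety=0.5)
        assert np.isfinite(dt) and dt > 0
        area = G.element_areas(mesh)
        coords = mesh.element_coords()
        best = np.inf
        for e in range(mesh.n_elements):
            edges = np.linalg.norm(np.roll(coords[e], -1, axis=0) - coords[e],
                                   axis=1)
            h = area[e] / edges.max()
            c = materials[str(mesh.material[e])].wave_speed
            best = min(best, 0.5 * h / c)
        assert dt == pytest.approx(best, rel=1e-12)


class TestSimulateImpact:
    def test_zero_trace_quiescent(self, materials):
        mesh, _ = G.build_sulcal_mesh(element_size=6e-3)
        sf = S.simulate_impact(mesh, materials, make_trace(), duration=2e-3)
        assert sf.peak_strain.max() <= 1e-10
        assert sf.peak_strain_rate.max() <= 1e-6

    def test_rigid_motion_produces_no_strain(self, coarse_mesh):
        """Forcing the whole mesh through a rigid motion leaves E at zero."""
        mesh, _ = coarse_mesh
        th, shift = 0.4, np.array([0.02, -0.01])
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        cur = (mesh.nodes @ R.T + shift)[mesh.elements]
        E = S.green_lagrange(
            S.deformation_gradient(mesh.element_coords(), cur))
        assert np.abs(S.max_principal_2x2_fast(E)).max() <= 1e-8

    def test_rotational_amplitude_monotonicity(self, materials):
        """Doubling a small rotational pulse increases the p90 strain."""
        mesh, _ = G.build_sulcal_mesh(element_size=6e-3)
        brain = mesh.material == "brain"
        p90 = []
        for amp in (200.0, 400.0):
            trace = make_trace(rot=(0, 0, 1), A=amp, T=6e-3)
            sf = S.simulate_impact(mesh, materials, trace, duration=8e-3)
            p90.append(np.percentile(sf.peak_strain[brain], 90))
        assert 0 < p90[0] < p90[1]

    def test_history_written_to_hdf5(self, materials, tmp_path):
        import h5py
        mesh, _ = G.build_sulcal_mesh(element_size=6e-3)
        trace = make_trace(rot=(0, 0, 1), A=300.0, T=4e-3)
        path = tmp_path / "history.h5"
        sf = S.simulate_impact(mesh, materials, trace, duration=5e-3,
                               history_path=path, history_stride=100)
        with h5py.File(path) as fh:
            t = fh["time"][:]
            E = fh["max_principal_strain"][:]
            assert fh["displacement"].shape == (t.size, mesh.n_nodes, 2)
            assert E.shape == (t.size, mesh.n_elements)
            # recorded snapshots never exceed the reported running peaks
            assert np.all(E.max(axis=0) <= sf.peak_strain + 1e-12)

    def test_peaks_are_running_maxima(self, materials):
        """A shorter window never reports larger peaks than a longer one."""
        mesh, _ = G.build_sulcal_mesh(element_size=6e-3)
        trace = make_trace(rot=(0, 0, 1), A=300.0, T=6e-3)
        sf_short = S.simulate_impact(mesh, materials, trace, duration=4e-3)
        sf_long = S.simulate_impact(mesh, materials, trace, duration=8e-3)
        assert np.all(sf_long.peak_strain >= sf_short.peak_strain - 1e-12)
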