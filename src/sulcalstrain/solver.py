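"""Explicit-dynamics finite-element solver for the sulcated brain model.

The brain/CSF continuum is advanced with central-difference time integration
and lumped mass while the skull boundary nodes follow the rigid motion
obtained by twice-integrating a head kinematics trace (planar rotation about
the domain centroid plus the in-plane translation).  The constitutive model is
a nearly incompressible neo-Hookean solid (plane strain) with an optional
one-term Prony shear-relaxation series.  Per-element running peaks of the
maximum principal Green-Lagrange strain E = ½(FᵀF − I) and of the maximum
principal value of the finite-difference dE/dt are recorded at every time
step.

Elements use single-point quadrature with stiffness-based (Flanagan–
Belytschko) hourglass control; the hourglass shape vectors are orthogonal to
all affine displacement fields, so rigid motions produce neither strain nor
hourglass force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .geometry import Mesh, element_areas
from .kinematics import KinematicsTrace

__all__ = [
    "MaterialModel",
    "SimState",
    "StrainField",
    "DivergenceError",
    "default_materials",
    "deformation_gradient",
    "green_lagrange",
    "max_principal",
    "strain_rate",
    "internal_forces",
    "stable_timestep",
    "simulate_impact",
]


class DivergenceError(RuntimeError):
    """Raised when the explicit integration blows up; carries the failure time."""

    def __init__(self, time: float, message: str | None = None):
        self.time = time
        super().__init__(message or f"simulation diverged at t = {time:.6g} s")


@dataclass(frozen=True)
class MaterialModel:
    """Nearly incompressible hyperelastic solid.

    ``prony`` lists (modulus fraction g_i, time constant tau_i [s]) pairs for
    shear relaxation; fractions must sum to <= 1 (the remainder is the
    long-term modulus).
    """

    density: float        # kg/m³
    shear_modulus: float  # Pa
    bulk_modulus: float   # Pa
    prony: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if min(self.density, self.shear_modulus, self.bulk_modulus) <= 0:
            raise ValueError("density and moduli must be positive")
        gsum = sum(g for g, _ in self.prony)
        if any(not (0 < g <= 1) or tau <= 0 for g, tau in self.prony) or gsum > 1:
            raise ValueError("Prony fractions must be in (0,1], sum <= 1, tau > 0")

    @property
    def lame_lambda(self) -> float:
        return self.bulk_modulus - 2.0 * self.shear_modulus / 3.0

    @property
    def wave_speed(self) -> float:
        """Dilatational wave speed sqrt((K + 4μ/3)/ρ)."""
        return np.sqrt(
            (self.bulk_modulus + 4.0 * self.shear_modulus / 3.0) / self.density)


def default_materials() -> dict[str, MaterialModel]:
    """Brain: μ = 2.5 kPa, K = 50 MPa; CSF: μ = 1 kPa, same bulk.

    The CSF layer is a soft solid, as in most explicit head models; its shear
    modulus is chosen high enough that the film couples skull rotation into
    the cortex of the smooth control mesh as well as the sulcated one (a
    water-like modulus would let the smooth film slip freely and the control
    comparison would measure film slip, not cortical folding).
    """
    return {
        "brain": MaterialModel(density=1040.0, shear_modulus=2.5e3,
                               bulk_modulus=50e6),
        "csf": MaterialModel(density=1000.0, shear_modulus=1.0e3,
                             bulk_modulus=50e6),
    }


# ---------------------------------------------------------------------------
# kinematic / strain primitives

_DN_CENTER = 0.25 * np.array([[-1.0, -1.0],
                              [1.0, -1.0],
                              [1.0, 1.0],
                              [-1.0, 1.0]])


def _b_matrix(ref_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients w.r.t. reference coords at the centroid.

    ``ref_coords`` is (..., 4, 2); returns (B, detJ) with B (..., 4, 2) such
    that F = x_eᵀ B, and detJ the centroid Jacobian determinant.
    """
    J = np.einsum("...ia,ib->...ab", ref_coords, _DN_CENTER)
    detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
    inv = np.empty_like(J)
    inv[..., 0, 0] = J[..., 1, 1]
    inv[..., 1, 1] = J[..., 0, 0]
    inv[..., 0, 1] = -J[..., 0, 1]
    inv[..., 1, 0] = -J[..., 1, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = inv / detJ[..., None, None]  # caller validates detJ > 0
    B = np.einsum("ia,...ab->...ib", _DN_CENTER, inv)
    return B, detJ


def deformation_gradient(ref_coords: np.ndarray,
                         cur_coords: np.ndarray) -> np.ndarray:
    """Centroid deformation gradient F of one or many 4-node quads.

    Both arguments are (..., 4, 2).  F = I when current equals reference, and
    equals A exactly for any affine map x = A X + c (bilinear shape functions
    are affine-exact).
    """
    ref_coords = np.asarray(ref_coords, float)
    cur_coords = np.asarray(cur_coords, float)
    B, detJ = _b_matrix(ref_coords)
    if np.any(detJ <= 0):
        raise ValueError("degenerate reference element (non-positive Jacobian)")
    return np.einsum("...ia,...ib->...ab", cur_coords, B)


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = ½(FᵀF − I)."""
    F = np.asarray(F, float)
    C = np.einsum("...ka,...kb->...ab", F, F)
    return 0.5 * (C - np.eye(F.shape[-1]))


def max_principal(T: np.ndarray, sym_tol: float = 1e-8) -> np.ndarray | float:
    """Largest eigenvalue of a symmetric tensor (2×2 closed form, 3×3 eigh)."""
    T = np.asarray(T, float)
    scale = max(1.0, float(np.abs(T).max()))
    if np.abs(T - np.swapaxes(T, -1, -2)).max() > sym_tol * scale:
        raise ValueError("tensor is not symmetric within tolerance")
    d = T.shape[-1]
    if d == 2:
        mean = 0.5 * (T[..., 0, 0] + T[..., 1, 1])
        rad = np.sqrt((0.5 * (T[..., 0, 0] - T[..., 1, 1])) ** 2
                      + T[..., 0, 1] ** 2)
        out = mean + rad
    else:
        out = np.linalg.eigvalsh(0.5 * (T + np.swapaxes(T, -1, -2)))[..., -1]
    return float(out) if out.ndim == 0 else out


def strain_rate(E_now: np.ndarray, E_prev: np.ndarray,
                dt: float) -> np.ndarray | float:
    """Max principal value of the finite-difference time derivative of E."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return max_principal((np.asarray(E_now, float) - np.asarray(E_prev, float)) / dt)


# ---------------------------------------------------------------------------
# assembled model

@dataclass
class SimState:
    """Mutable solver state (displacements from the reference configuration)."""

    u: np.ndarray        # (n_nodes, 2) m
    v: np.ndarray        # (n_nodes, 2) m/s
    a: np.ndarray        # (n_nodes, 2) m/s²
    time: float
    peak_strain: np.ndarray        # (n_elem,) running max principal E
    peak_strain_rate: np.ndarray   # (n_elem,) 1/s
    E_prev: np.ndarray             # (n_elem, 2, 2)
    visco: np.ndarray | None = None   # (n_terms, n_elem, 2, 2) Prony history
    S_dev_prev: np.ndarray | None = None


@dataclass
class StrainField:
    """Per-element peaks over the simulated impact."""

    peak_strain: np.ndarray
    peak_strain_rate: np.ndarray


class _Model:
    """Precomputed per-element arrays for fast assembly."""

    def __init__(self, mesh: Mesh, materials: dict[str, MaterialModel],
                 hourglass_coeff: float = 0.05):
        self.mesh = mesh
        ref = mesh.element_coords()
        self.B, detJ = _b_matrix(ref)
        if np.any(detJ <= 0):
            raise ValueError("mesh has degenerate elements")
        self.area = element_areas(mesh)
        mats = [materials[str(m)] for m in mesh.material]
        self.mu = np.array([m.shear_modulus for m in mats])
        self.lam = np.array([m.lame_lambda for m in mats])
        self.rho = np.array([m.density for m in mats])
        self.wave = np.array([m.wave_speed for m in mats])
        # Prony: support a common term structure across materials
        terms = max((len(materials[k].prony) for k in materials), default=0)
        self.n_prony = terms
        if terms:
            self.g = np.zeros((terms, len(mats)))
            self.tau = np.ones((terms, len(mats)))
            for e, m in enumerate(mats):
                for i, (g, tau) in enumerate(m.prony):
                    self.g[i, e] = g
                    self.tau[i, e] = tau

        # lumped mass: ρ A / 4 to each corner node
        self.mass = np.zeros(mesh.n_nodes)
        np.add.at(self.mass, mesh.elements.ravel(),
                  np.repeat(self.rho * self.area / 4.0, 4))

        # Flanagan-Belytschko hourglass shape vectors (orthogonal to affine fields)
        h = np.array([1.0, -1.0, 1.0, -1.0])
        hX = np.einsum("i,mia->ma", h, ref)              # (m, 2)
        self.gamma = h[None, :] - np.einsum("ma,mia->mi", hX, self.B)
        bsq = np.einsum("mia,mia->m", self.B, self.B)
        self.k_hg = hourglass_coeff * self.mu * self.area * bsq

    # -- constitutive ------------------------------------------------------
    def strain_and_forces(self, u: np.ndarray,
                          visco: np.ndarray | None = None,
                          S_dev_prev: np.ndarray | None = None,
                          dt: float | None = None):
        """E, internal nodal forces and updated viscoelastic state at ``u``."""
        mesh = self.mesh
        x = mesh.nodes + u
        cur = x[mesh.elements]                             # (m, 4, 2)
        F = np.einsum("mia,mib->mab", cur, self.B)
        C = np.einsum("mka,mkb->mab", F, F)
        E = 0.5 * (C - np.eye(2))

        J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
        if np.any(J <= 0):
            raise DivergenceError(np.nan, "element inversion (det F <= 0)")
        Cinv = np.empty_like(C)
        Cinv[:, 0, 0] = C[:, 1, 1]
        Cinv[:, 1, 1] = C[:, 0, 0]
        Cinv[:, 0, 1] = -C[:, 0, 1]
        Cinv[:, 1, 0] = -C[:, 1, 0]
        Cinv /= (J ** 2)[:, None, None]

        # 2nd Piola-Kirchhoff: shear μ(I − C⁻¹) + volumetric λ lnJ C⁻¹
        S_dev = self.mu[:, None, None] * (np.eye(2) - Cinv)
        S_vol = (self.lam * np.log(J))[:, None, None] * Cinv

        new_visco = visco
        S_shear = S_dev
        if self.n_prony and visco is not None and dt is not None:
            new_visco = np.empty_like(visco)
            relax = np.zeros_like(S_dev)
            for i in range(self.n_prony):
                decay = np.exp(-dt / self.tau[i])[:, None, None]
                half = np.exp(-0.5 * dt / self.tau[i])[:, None, None]
                new_visco[i] = (decay * visco[i]
                                + self.g[i][:, None, None] * half
                                * (S_dev - S_dev_prev))
                relax += self.g[i][:, None, None] * S_dev - new_visco[i]
            S_shear = S_dev - relax

        S = S_shear + S_vol
        P = np.einsum("mab,mbc->mac", F, S)
        f_el = np.einsum("m,mac,mic->mia", self.area, P, self.B)

        # hourglass resistance (generalized stiffness on the hourglass mode)
        q = np.einsum("mi,mia->ma", self.gamma, u[mesh.elements])
        f_hg = self.k_hg[:, None, None] * self.gamma[:, :, None] * q[:, None, :]

        forces = np.zeros_like(u)
        np.add.at(forces, mesh.elements.ravel(),
                  (f_el + f_hg).reshape(-1, 2))
        return E, forces, new_visco, S_dev


def internal_forces(mesh: Mesh, materials: dict[str, MaterialModel],
                    state: SimState) -> np.ndarray:
    """Internal nodal force vector (N per unit thickness) at the state's
    displacements: hyperelastic stress divergence plus hourglass resistance.
    Zero for the undeformed, quiescent state."""
    if not np.all(np.isfinite(state.u)):
        raise DivergenceError(state.time, "non-finite displacements")
    model = _Model(mesh, materials)
    _, forces, _, _ = model.strain_and_forces(
        state.u, state.visco, state.S_dev_prev,
        dt=None if state.visco is None else 1.0)
    return forces


def stable_timestep(mesh: Mesh, materials: dict[str, MaterialModel],
                    safety: float = 0.5) -> float:
    """CFL-limited explicit time step: safety × min(h_e / c_e).

    h_e is the element area divided by its longest edge (captures thin
    elements); c_e the material dilatational wave speed.
    """
    area = element_areas(mesh)
    coords = mesh.element_coords()
    edges = np.linalg.norm(np.roll(coords, -1, axis=1) - coords, axis=2)
    h = area / edges.max(axis=1)
    wave = np.array([materials[str(m)].wave_speed for m in mesh.material])
    return float(safety * np.min(h / wave))


def _rigid_motion_tables(trace: KinematicsTrace):
    """Translation u(t) (in-plane) and rotation angle θ(t) from the trace.

    Beyond the end of the trace the motion continues at the final velocities
    (free coasting), so simulations may outlast the recorded pulse without an
    artificial stop.
    """
    t = trace.t
    a_xy = trace.lin_acc[:, :2]
    v_xy = cumulative_trapezoid(a_xy, t, axis=0, initial=0.0)
    u_xy = cumulative_trapezoid(v_xy, t, axis=0, initial=0.0)
    alpha = np.linalg.norm(trace.rot_acc, axis=1)
    omega = cumulative_trapezoid(alpha, t, initial=0.0)
    theta = cumulative_trapezoid(omega, t, initial=0.0)
    horizon = 10.0  # seconds; far beyond any simulated window
    t = np.append(t, t[-1] + horizon)
    u_xy = np.vstack([u_xy, u_xy[-1] + horizon * v_xy[-1]])
    theta = np.append(theta, theta[-1] + horizon * omega[-1])
    return t, u_xy, theta


def simulate_impact(mesh: Mesh, materials: dict[str, MaterialModel],
                    trace: KinematicsTrace,
                    duration: float | None = None,
                    damping: float = 0.0,
                    safety: float = 0.5,
                    hourglass_coeff: float = 0.05,
                    return_state: bool = False,
                    history_path=None,
                    history_stride: int = 50):
    """Drive the mesh with a kinematics trace and record per-element peaks.

    Skull nodes follow the rigid motion obtained by twice integrating the
    trace (planar rotation about the domain centroid from the resultant
    rotational acceleration; translation from the in-plane linear
    acceleration).  Interior nodes evolve under internal forces with
    central-difference integration.  Peaks of the maximum principal
    Green-Lagrange strain and its finite-difference rate are updated every
    step (strain-rate peaks are cadence-sensitive, so there is no decimation).

    ``damping`` is a mass-proportional coefficient (1/s, default 0).
    With ``history_path`` the full time histories (time grid, nodal
    displacements, per-element max-principal strain) are written to HDF5
    every ``history_stride`` steps.
    """
    if duration is None:
        duration = trace.duration
    model = _Model(mesh, materials, hourglass_coeff=hourglass_coeff)
    dt = stable_timestep(mesh, materials, safety=safety)
    n_steps = int(np.ceil(duration / dt))

    t_tab, u_tab, th_tab = _rigid_motion_tables(trace)
    centroid = mesh.nodes.mean(axis=0)

    def skull_disp(time: float) -> np.ndarray:
        ux = np.interp(time, t_tab, u_tab[:, 0])
        uy = np.interp(time, t_tab, u_tab[:, 1])
        th = np.interp(time, t_tab, th_tab)
        X = mesh.nodes[mesh.skull_nodes] - centroid
        c, s = np.cos(th), np.sin(th)
        rot = np.column_stack([c * X[:, 0] - s * X[:, 1],
                               s * X[:, 0] + c * X[:, 1]])
        return rot + centroid + np.array([ux, uy]) - mesh.nodes[mesh.skull_nodes]

    n = mesh.n_nodes
    u = np.zeros((n, 2))
    v = np.zeros((n, 2))
    m_elem = mesh.n_elements
    visco = (np.zeros((model.n_prony, m_elem, 2, 2)) if model.n_prony else None)
    S_dev_prev = np.zeros((m_elem, 2, 2)) if model.n_prony else None
    E_prev = np.zeros((m_elem, 2, 2))
    peak_E = np.zeros(m_elem)
    peak_rate = np.zeros(m_elem)
    mass = model.mass[:, None]
    skull = mesh.skull_nodes
    interior = np.setdiff1d(np.arange(n), skull)
    domain_scale = float(np.abs(mesh.nodes).max())

    u_s_prev = skull_disp(0.0)
    u[skull] = u_s_prev

    hist_t, hist_u, hist_E = [], [], []

    time = 0.0
    for step in range(n_steps):
        E, f_int, visco_new, S_dev = model.strain_and_forces(
            u, visco, S_dev_prev, dt)
        if model.n_prony:
            visco, S_dev_prev = visco_new, S_dev

        emax = max_principal_2x2_fast(E)
        if history_path is not None and step % history_stride == 0:
            hist_t.append(step * dt)
            hist_u.append(u.copy())
            hist_E.append(emax.copy())
        np.maximum(peak_E, emax, out=peak_E)
        if step > 0:
            rate = max_principal_2x2_fast((E - E_prev) / dt)
            np.maximum(peak_rate, rate, out=peak_rate)
        E_prev = E

        accel = (-f_int) / mass - damping * v
        v[interior] += dt * accel[interior]
        u[interior] += dt * v[interior]

        time = (step + 1) * dt
        u_s = skull_disp(time)
        v[skull] = (u_s - u_s_prev) / dt
        u[skull] = u_s
        u_s_prev = u_s

        if step % 200 == 0 or step == n_steps - 1:
            if not np.all(np.isfinite(u)):
                raise DivergenceError(time, f"non-finite displacement at t={time:.6g}s")
            if np.abs(u[interior]).max() > 50.0 * domain_scale:
                raise DivergenceError(time, f"displacement blow-up at t={time:.6g}s")

    if history_path is not None:
        import h5py

        with h5py.File(history_path, "w") as fh:
            fh.create_dataset("time", data=np.array(hist_t))
            fh.create_dataset("displacement", data=np.array(hist_u))
            fh.create_dataset("max_principal_strain", data=np.array(hist_E))
            fh.attrs["dt"] = dt
            fh.attrs["history_stride"] = history_stride

    result = StrainField(peak_strain=peak_E, peak_strain_rate=peak_rate)
    if return_state:
        state = SimState(u=u, v=v, a=np.zeros_like(u), time=time,
                         peak_strain=peak_E, peak_strain_rate=peak_rate,
                         E_prev=E_prev, visco=visco, S_dev_prev=S_dev_prev)
        return result, state
    return result


def max_principal_2x2_fast(E: np.ndarray) -> np.ndarray:
    """Closed-form largest eigenvalue of batched symmetric 2×2 tensors."""
    mean = 0.5 * (E[:, 0, 0] + E[:, 1, 1])
    rad = np.sqrt((0.5 * (E[:, 0, 0] - E[:, 1, 1])) ** 2 + E[:, 0, 1] ** 2)
    return mean + rad
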