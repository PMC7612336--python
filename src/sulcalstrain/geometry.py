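"""Idealized sulcated brain cross-section meshes.

The simulation domain is a 2D plane-strain disc: a brain whose outer
(cortical) surface is radially modulated by ``n_folds`` sinusoidal folds —
crests are gyri, troughs are sulci — covered by a uniform cerebrospinal-fluid
(CSF) film whose outer face is the rigid skull boundary (conforming to the
folds, reaching ``outer_radius`` at the crests).  The disc centre is filled by
a structured square-to-circle ("butterfly") block, so there is no free inner
boundary to slosh under linear acceleration.  A matching region-of-interest
atlas labels each brain element as sulcal, gyral or deep, with one ROI per
fold so region-level means can be computed the way surface-atlas parcellations
are used on real anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Mesh",
    "RegionInfo",
    "ROIAtlas",
    "build_sulcal_mesh",
    "build_smooth_mesh",
    "element_jacobians",
    "min_jacobian",
    "element_areas",
    "element_centroids",
    "quad_interior_angles",
]

# reserved atlas labels
LABEL_BACKGROUND = 0
LABEL_DEEP = 1
LABEL_CSF = 2
LABEL_SMOOTH_CORTEX = 300
SULCAL_BASE = 100
GYRAL_BASE = 200


@dataclass
class Mesh:
    """2D quad mesh: nodes in metres, CCW 4-node connectivity.

    ``material`` holds "brain"/"csf" per element; ``skull_nodes`` indexes the
    outer-boundary nodes whose motion the solver prescribes rigidly.
    """

    nodes: np.ndarray          # (n_nodes, 2) metres
    elements: np.ndarray       # (n_elem, 4) int, counter-clockwise
    material: np.ndarray       # (n_elem,) "brain" | "csf"
    skull_nodes: np.ndarray    # (n_skull,) int

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_coords(self) -> np.ndarray:
        """(n_elem, 4, 2) reference coordinates of every element."""
        return self.nodes[self.elements]


@dataclass(frozen=True)
class RegionInfo:
    name: str
    cls: str  # "sulcal" | "gyral" | "other"


@dataclass
class ROIAtlas:
    """Integer region label per element plus a label → (name, class) table."""

    region_label: np.ndarray            # (n_elem,) int
    region_table: dict[int, RegionInfo] = field(default_factory=dict)

    def labels_of_class(self, cls: str) -> list[int]:
        return [lab for lab, info in self.region_table.items() if info.cls == cls]

    def element_mask(self, cls: str) -> np.ndarray:
        labs = self.labels_of_class(cls)
        return np.isin(self.region_label, labs)


def _butterfly_core(core_radius: float, m: int):
    """Structured square-to-circle ("butterfly") grid filling the disc centre.

    Returns core nodes ((m+1)², 2), core quads (m², 4) and the CCW-ordered
    perimeter node indices (4m,) starting at the node of smallest
    non-negative angle.
    """
    u = np.linspace(-1.0, 1.0, m + 1)
    U, V = np.meshgrid(u, u, indexing="ij")
    # elliptic square-to-disc map: boundary lands exactly on the circle
    X = U * np.sqrt(1.0 - 0.5 * V ** 2) * core_radius
    Y = V * np.sqrt(1.0 - 0.5 * U ** 2) * core_radius
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (m + 1) + j

    ii, jj = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    quads = np.column_stack([nid(ii, jj), nid(ii + 1, jj),
                             nid(ii + 1, jj + 1), nid(ii, jj + 1)])

    # perimeter walk, CCW starting at corner (u=1, v=-1), i.e. angle −45°
    per = []
    per += [nid(m, j) for j in range(m)]          # right side, v −1→1
    per += [nid(i, m) for i in range(m, 0, -1)]   # top, u 1→−1
    per += [nid(0, j) for j in range(m, 0, -1)]   # left, v 1→−1
    per += [nid(i, 0) for i in range(0, m)]       # bottom, u −1→1
    per = np.array(per)
    ang = np.mod(np.arctan2(nodes[per, 1], nodes[per, 0]), 2.0 * np.pi)
    start = int(np.argmin(ang))
    per = np.roll(per, -start)
    return nodes, quads, per


def _laplacian_smooth(nodes: np.ndarray, elements: np.ndarray,
                      fixed: np.ndarray, iterations: int = 10) -> np.ndarray:
    """Move free nodes toward the mean of their edge-neighbours."""
    edges = np.vstack([elements[:, [0, 1]], elements[:, [1, 2]],
                       elements[:, [2, 3]], elements[:, [3, 0]]])
    edges = np.vstack([edges, edges[:, ::-1]])
    out = nodes.copy()
    free = ~fixed
    for _ in range(iterations):
        acc = np.zeros_like(out)
        cnt = np.zeros(out.shape[0])
        np.add.at(acc, edges[:, 0], out[edges[:, 1]])
        np.add.at(cnt, edges[:, 0], 1.0)
        mean = acc / cnt[:, None]
        out[free] = mean[free]
    return out


def _build(n_folds: int, sulcal_depth: float, csf_thickness: float,
           outer_radius: float, element_size: float,
           inner_radius: float, cortical_depth: float) -> tuple[Mesh, ROIAtlas]:
    # mean cortical-surface radius; the rigid boundary conforms to the folded
    # surface at a uniform csf_thickness offset, peaking at outer_radius
    r_surf_mean = outer_radius - csf_thickness - sulcal_depth / 2.0
    if r_surf_mean <= inner_radius + element_size:
        raise ValueError("outer_radius too small for the requested inner radius")
    mid = 0.5 * (inner_radius + outer_radius)
    n_theta = max(16, int(round(2.0 * np.pi * mid / element_size)))
    n_theta = 4 * int(np.ceil(n_theta / 4))  # butterfly core needs 4m sides
    m = n_theta // 4

    core_nodes, core_quads, perim = _butterfly_core(inner_radius, m)
    theta = np.mod(np.arctan2(core_nodes[perim, 1], core_nodes[perim, 0]),
                   2.0 * np.pi)

    n_brain = max(2, int(round((r_surf_mean - inner_radius) / element_size)))
    n_csf = max(1, int(round(csf_thickness / element_size)))
    n_layers = n_brain + n_csf
    r_surf = r_surf_mean + 0.5 * sulcal_depth * np.cos(n_folds * theta)

    frac_brain = np.linspace(0.0, 1.0, n_brain + 1)[1:]
    frac_csf = np.linspace(0.0, 1.0, n_csf + 1)[1:]
    radii = np.empty((n_theta, n_layers))
    radii[:, :n_brain] = inner_radius + frac_brain[None, :] * (
        r_surf[:, None] - inner_radius)
    radii[:, n_brain:] = r_surf[:, None] + frac_csf[None, :] * csf_thickness

    n_core = core_nodes.shape[0]
    ring_nodes = np.empty((n_theta * n_layers, 2))
    ct, st = np.cos(theta), np.sin(theta)
    ring_nodes[:, 0] = (radii * ct[:, None]).ravel()
    ring_nodes[:, 1] = (radii * st[:, None]).ravel()
    nodes = np.vstack([core_nodes, ring_nodes])

    def rid(j, i):
        """node id at angular line j (mod n_theta), radial station i>=0."""
        j = j % n_theta
        if i == 0:
            return perim[j]
        return n_core + j * n_layers + (i - 1)

    ring_elems = []
    for j in range(n_theta):
        for i in range(n_layers):
            ring_elems.append([rid(j, i), rid(j, i + 1),
                               rid(j + 1, i + 1), rid(j + 1, i)])
    elements = np.vstack([core_quads, np.array(ring_elems)]).astype(np.int64)

    layer = np.concatenate([np.full(core_quads.shape[0], -1),
                            np.tile(np.arange(n_layers), n_theta)])
    material = np.where(layer < n_brain, "brain", "csf")
    skull_nodes = np.array([rid(j, n_layers) for j in range(n_theta)])

    # smooth interior brain/core nodes (fix surface, CSF and skull nodes) to
    # relax the skewed ring elements at the butterfly-core corners
    fixed = np.zeros(nodes.shape[0], dtype=bool)
    for j in range(n_theta):
        for i in range(n_brain, n_layers + 1):
            fixed[rid(j, i)] = True
    nodes = _laplacian_smooth(nodes, elements, fixed, iterations=10)

    mesh = Mesh(nodes=nodes, elements=elements,
                material=material, skull_nodes=skull_nodes)

    # --- atlas -------------------------------------------------------------
    cent = element_centroids(mesh)
    th_c = np.mod(np.arctan2(cent[:, 1], cent[:, 0]), 2.0 * np.pi)

    label = np.full(mesh.n_elements, LABEL_DEEP, dtype=np.int64)
    label[material == "csf"] = LABEL_CSF
    # cortical ribbon: outermost brain element layers spanning cortical_depth
    # (topological rule — robust to layer thickness varying with the folds)
    n_cort = max(1, int(round(cortical_depth / element_size)))
    cortical = (material == "brain") & (layer >= n_brain - n_cort)

    table: dict[int, RegionInfo] = {
        LABEL_DEEP: RegionInfo("deep_brain", "other"),
        LABEL_CSF: RegionInfo("csf", "other"),
    }
    if sulcal_depth > 0:
        phase = np.cos(n_folds * th_c)
        # deeper half of the trough-to-crest span -> sulcal (fundus + walls)
        sulcal = cortical & (phase < 0)
        gyral = cortical & (phase >= 0)
        k_s = np.floor(n_folds * th_c / (2.0 * np.pi)).astype(int) % n_folds
        k_g = np.round(n_folds * th_c / (2.0 * np.pi)).astype(int) % n_folds
        label[sulcal] = SULCAL_BASE + k_s[sulcal]
        label[gyral] = GYRAL_BASE + k_g[gyral]
        for k in range(n_folds):
            table[SULCAL_BASE + k] = RegionInfo(f"sulcus_{k:02d}", "sulcal")
            table[GYRAL_BASE + k] = RegionInfo(f"gyrus_{k:02d}", "gyral")
    else:
        label[cortical] = LABEL_SMOOTH_CORTEX
        table[LABEL_SMOOTH_CORTEX] = RegionInfo("smooth_cortex", "other")
    # drop table entries for labels that got no elements
    present = set(np.unique(label).tolist())
    table = {lab: info for lab, info in table.items() if lab in present}
    return mesh, ROIAtlas(region_label=label, region_table=table)


def build_sulcal_mesh(n_folds: int = 12,
                      sulcal_depth: float = 12e-3,
                      csf_thickness: float = 2e-3,
                      outer_radius: float = 80e-3,
                      element_size: float = 1e-3,
                      inner_radius: float = 40e-3,
                      cortical_depth: float = 4e-3) -> tuple[Mesh, ROIAtlas]:
    """Sulcated disc with per-fold sulcal/gyral ROIs.

    The brain surface radius is r(θ) = r̄ + (d/2)·cos(n_folds·θ); a uniform
    CSF film of ``csf_thickness`` separates it from the rigid skull boundary,
    which conforms to the folds and reaches ``outer_radius`` at the crests.
    Elements in the cortical band whose local surface lies in the deeper half
    of the fold span are sulcal, crest-adjacent elements gyral.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if sulcal_depth < 0:
        raise ValueError("sulcal_depth must be non-negative")
    if sulcal_depth >= outer_radius / 2:
        raise ValueError("sulcal_depth must be < outer_radius/2")
    if element_size <= 0 or csf_thickness <= 0:
        raise ValueError("element_size and csf_thickness must be positive")
    r_surf_mean = outer_radius - csf_thickness - sulcal_depth / 2.0
    fold_width = 2.0 * np.pi * r_surf_mean / n_folds
    if fold_width / element_size < 4:
        raise ValueError(
            f"element_size {element_size} does not resolve the fold width "
            f"{fold_width:.4g} m: need >= 4 elements across a fold")
    return _build(n_folds, sulcal_depth, csf_thickness, outer_radius,
                  element_size, inner_radius, cortical_depth)


def build_smooth_mesh(csf_thickness: float = 2e-3,
                      outer_radius: float = 80e-3,
                      element_size: float = 1e-3,
                      inner_radius: float = 40e-3,
                      cortical_depth: float = 4e-3,
                      n_folds: int = 12) -> tuple[Mesh, ROIAtlas]:
    """Smooth-cortex control: same annulus with an unmodulated surface.

    All cortical-band elements carry the "smooth_cortex" label (class other);
    there are no sulcal-class elements by construction.
    """
    return build_sulcal_mesh(
        n_folds=n_folds, sulcal_depth=0.0, csf_thickness=csf_thickness,
        outer_radius=outer_radius, element_size=element_size,
        inner_radius=inner_radius, cortical_depth=cortical_depth)


# ---------------------------------------------------------------------------
# element geometry helpers

# bilinear shape-function derivatives at the four Gauss points (±1/√3)
_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)


def _shape_grads(xi: float, eta: float) -> np.ndarray:
    """dN/d(xi,eta) for the 4-node quad, shape (4, 2)."""
    return 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [(1 - eta), -(1 + xi)],
        [(1 + eta), (1 + xi)],
        [-(1 + eta), (1 - xi)],
    ])


def element_jacobians(mesh: Mesh) -> np.ndarray:
    """det(J) of the isoparametric map at the 4 Gauss points, (n_elem, 4)."""
    coords = mesh.element_coords()  # (m, 4, 2)
    dets = np.empty((mesh.n_elements, 4))
    for g, (xi, eta) in enumerate(_GP):
        dN = _shape_grads(xi, eta)  # (4, 2)
        J = np.einsum("mia,ib->mab", coords, dN)  # (m, 2, 2)
        dets[:, g] = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    return dets


def min_jacobian(mesh: Mesh) -> float:
    return float(element_jacobians(mesh).min())


def element_areas(mesh: Mesh) -> np.ndarray:
    """Element areas via the shoelace formula (exact for straight-edged quads)."""
    c = mesh.element_coords()
    x, y = c[..., 0], c[..., 1]
    xn, yn = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
    return 0.5 * np.abs(np.sum(x * yn - xn * y, axis=1))


def element_centroids(mesh: Mesh) -> np.ndarray:
    return mesh.element_coords().mean(axis=1)


def quad_interior_angles(mesh: Mesh) -> np.ndarray:
    """Interior angles in degrees, (n_elem, 4)."""
    c = mesh.element_coords()
    prev = np.roll(c, 1, axis=1) - c
    nxt = np.roll(c, -1, axis=1) - c
    dot = np.sum(prev * nxt, axis=2)
    nrm = np.linalg.norm(prev, axis=2) * np.linalg.norm(nxt, axis=2)
    return np.degrees(np.arccos(np.clip(dot / nrm, -1.0, 1.0)))
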