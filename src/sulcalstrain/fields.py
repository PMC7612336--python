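"""Rasterization of per-element fields to NIfTI voxel volumes.

Per-element peak strain / strain-rate fields are transferred to a regular
voxel grid by nearest-element (piecewise-constant) lookup — each in-brain
voxel takes the value of the element containing its centre — and written as
single-slice NIfTI-1 volumes (float32, RAS+ affine, millimetre units).  The
ROI atlas is rasterized onto the identical grid, so atlas registration is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy.spatial import cKDTree

from .geometry import Mesh, element_centroids

__all__ = ["VoxelField", "rasterize", "write_nifti", "read_nifti"]

SLICE_THICKNESS_MM = 1.0


@dataclass
class VoxelField:
    """3D scalar raster (2D fields as single-slice volumes) with affine."""

    data: np.ndarray     # (nx, ny, nz)
    affine: np.ndarray   # 4×4 voxel-to-world, mm
    background: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, float)
        if self.data.ndim != 3:
            raise ValueError("VoxelField data must be 3-D")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def congruent_with(self, other: "VoxelField") -> bool:
        return (self.data.shape == other.data.shape
                and np.allclose(self.affine, other.affine, atol=1e-6))


def _point_in_quad(points: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Vectorized test of points (k, 2) against one CCW quad (4, 2)."""
    inside = np.ones(points.shape[0], dtype=bool)
    for i in range(4):
        a, b = quad[i], quad[(i + 1) % 4]
        edge = b - a
        rel = points - a
        cross = edge[0] * rel[:, 1] - edge[1] * rel[:, 0]
        inside &= cross >= -1e-12
    return inside


def _locate(points_m: np.ndarray, mesh: Mesh, k: int = 16) -> np.ndarray:
    """Element index containing each point (metres), or -1."""
    cents = element_centroids(mesh)
    tree = cKDTree(cents)
    k = min(k, mesh.n_elements)
    _, cand = tree.query(points_m, k=k)
    cand = np.atleast_2d(cand)
    coords = mesh.element_coords()
    out = np.full(points_m.shape[0], -1, dtype=np.int64)
    undecided = np.arange(points_m.shape[0])
    for col in range(k):
        if undecided.size == 0:
            break
        elems = cand[undecided, col]
        quads = coords[elems]                      # (u, 4, 2)
        rel = points_m[undecided][:, None, :] - quads
        edges = np.roll(quads, -1, axis=1) - quads
        cross = edges[..., 0] * rel[..., 1] - edges[..., 1] * rel[..., 0]
        hits = (cross >= -1e-12).all(axis=1)
        out[undecided[hits]] = elems[hits]
        undecided = undecided[~hits]
    return out


def rasterize(values: np.ndarray, mesh: Mesh, voxel_size: float,
              background: float = 0.0, brain_only: bool = True,
              integer: bool = False,
              element_index: np.ndarray | None = None) -> VoxelField:
    """Piecewise-constant transfer of a per-element field to a voxel grid.

    ``voxel_size`` in mm (must not exceed the element size so every element is
    sampled).  With ``brain_only`` CSF elements are treated as background.
    ``element_index`` allows reusing a precomputed voxel→element lookup for
    congruent rasterizations of the same mesh.
    """
    values = np.asarray(values)
    if values.shape[0] != mesh.n_elements:
        raise ValueError("need one value per element")
    vs_m = voxel_size * 1e-3
    lo = mesh.nodes.min(axis=0) - vs_m
    hi = mesh.nodes.max(axis=0) + vs_m
    nx = int(np.ceil((hi[0] - lo[0]) / vs_m))
    ny = int(np.ceil((hi[1] - lo[1]) / vs_m))
    if nx < 1 or ny < 1:
        raise ValueError("voxel grid does not cover the mesh")

    if element_index is None:
        xs = lo[0] + (np.arange(nx) + 0.5) * vs_m
        ys = lo[1] + (np.arange(ny) + 0.5) * vs_m
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        element_index = _locate(pts, mesh)

    elem = element_index
    dtype = np.int16 if integer else np.float32
    flat = np.full(elem.shape[0], background, dtype=dtype)
    found = elem >= 0
    if brain_only:
        brain_elem = mesh.material == "brain"
        found = found & np.where(elem >= 0, brain_elem[np.clip(elem, 0, None)],
                                 False)
    flat[found] = values[elem[found]].astype(dtype)
    data = flat.reshape(nx, ny, 1)

    affine = np.eye(4)
    affine[0, 0] = voxel_size
    affine[1, 1] = voxel_size
    affine[2, 2] = SLICE_THICKNESS_MM
    # world origin at the centre of voxel (0, 0, 0), in mm
    affine[0, 3] = (lo[0] + 0.5 * vs_m) * 1e3
    affine[1, 3] = (lo[1] + 0.5 * vs_m) * 1e3
    return VoxelField(data=data, affine=affine, background=background)


def voxel_element_index(mesh: Mesh, voxel_size: float) -> np.ndarray:
    """Precompute the voxel-centre → element lookup used by :func:`rasterize`."""
    vs_m = voxel_size * 1e-3
    lo = mesh.nodes.min(axis=0) - vs_m
    hi = mesh.nodes.max(axis=0) + vs_m
    nx = int(np.ceil((hi[0] - lo[0]) / vs_m))
    ny = int(np.ceil((hi[1] - lo[1]) / vs_m))
    xs = lo[0] + (np.arange(nx) + 0.5) * vs_m
    ys = lo[1] + (np.arange(ny) + 0.5) * vs_m
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return _locate(np.column_stack([gx.ravel(), gy.ravel()]), mesh)


def write_nifti(field: VoxelField, path) -> None:
    """Write as NIfTI-1: float32 data (int16 for label volumes), mm units."""
    data = field.data
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, field.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_nifti(path) -> VoxelField:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several format errors
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        data = data[:, :, None]
    return VoxelField(data=data, affine=img.affine)
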