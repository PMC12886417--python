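"""Cortical depth coordinate system and volume <-> surface transfer.

Conventions, used everywhere in the package: world coordinates in mm, voxel
indices 0-based, cortical depth indexed from the GM/WM boundary (relative
depth 0) to the GM/CSF boundary (relative depth 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class SurfaceMesh:
    """Triangle mesh in the volume's world frame.

    ``labels`` is an optional per-vertex region tag (e.g. V1 / V2a / V3b);
    meshes belonging to one :class:`LayerStack` share vertex count, ordering
    and face list.
    """

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float)
        self.faces = np.asarray(self.faces, int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.vertices):
                raise ValueError("labels must be per-vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def save_txt(self, prefix):
        """Write plain-text vertex and face tables (<prefix>_vertices.txt /
        <prefix>_faces.txt, plus <prefix>_labels.txt when labels exist)."""
        prefix = Path(prefix)
        np.savetxt(f"{prefix}_vertices.txt", self.vertices,
                   header="x_mm y_mm z_mm")
        np.savetxt(f"{prefix}_faces.txt", self.faces, fmt="%d",
                   header="v0 v1 v2")
        if self.labels is not None:
            np.savetxt(f"{prefix}_labels.txt",
                       np.asarray(self.labels, dtype=float), fmt="%g")

    @classmethod
    def load_txt(cls, prefix) -> "SurfaceMesh":
        prefix = Path(prefix)
        vertices = np.loadtxt(f"{prefix}_vertices.txt")
        faces = np.loadtxt(f"{prefix}_faces.txt", dtype=int)
        labels_path = Path(f"{prefix}_labels.txt")
        labels = np.loadtxt(labels_path) if labels_path.exists() else None
        return cls(vertices, np.atleast_2d(faces), labels)

    def to_gifti(self):
        """Convert to a GIFTI surface image (nibabel)."""
        import nibabel.gifti as gii

        darrays = [
            gii.GiftiDataArray(self.vertices.astype(np.float32),
                               intent="NIFTI_INTENT_POINTSET"),
            gii.GiftiDataArray(self.faces.astype(np.int32),
                               intent="NIFTI_INTENT_TRIANGLE"),
        ]
        return gii.GiftiImage(darrays=darrays)


@dataclass
class LayerStack:
    """Ordered surfaces from GM/WM (index 0) to GM/CSF (last)."""

    surfaces: list
    relative_depths: np.ndarray

    def __post_init__(self):
        self.relative_depths = np.asarray(self.relative_depths, float)
        if len(self.surfaces) != len(self.relative_depths):
            raise ValueError("one depth per surface required")
        d = self.relative_depths
        if d[0] != 0 or d[-1] != 1 or np.any(np.diff(d) <= 0):
            raise ValueError("relative_depths must increase from 0 to 1")
        n = {s.n_vertices for s in self.surfaces}
        if len(n) != 1:
            raise ValueError("surfaces must share vertex count")

    @property
    def n_layers(self) -> int:
        return len(self.surfaces)

    def __iter__(self):
        return iter(self.surfaces)


def equidistant_layers(white: SurfaceMesh, pial: SurfaceMesh,
                       n_intermediate: int = 9) -> LayerStack:
    """Equidistant cortical layers between matched boundary surfaces.

    Layer k (k = 0 .. n_intermediate+1) has vertices
    ``white + k/(n_intermediate+1) * (pial - white)``; with the default nine
    intermediate surfaces this yields 11 layers.
    """
    if white.n_vertices != pial.n_vertices:
        raise ValueError("white and pial vertex counts differ")
    if n_intermediate < 0:
        raise ValueError("n_intermediate must be >= 0")
    fracs = np.linspace(0.0, 1.0, n_intermediate + 2)
    surfaces = [
        SurfaceMesh(white.vertices + f * (pial.vertices - white.vertices),
                    white.faces, white.labels)
        for f in fracs
    ]
    return LayerStack(surfaces, fracs)


def _vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """One third of the summed area of the triangles incident to each vertex."""
    v = mesh.vertices
    f = mesh.faces
    tri_area = 0.5 * np.linalg.norm(
        np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1)
    areas = np.zeros(mesh.n_vertices)
    for col in range(3):
        np.add.at(areas, f[:, col], tri_area / 3.0)
    return areas


def equivolume_layers(white: SurfaceMesh, pial: SurfaceMesh,
                      n_intermediate: int = 9) -> LayerStack:
    """Equivolume layering (offered for comparison; equidistant is the
    default everywhere).

    Assumes the local surface area varies linearly between the boundaries and
    places each layer so that equal cortical volume fractions lie between
    consecutive layers (the standard closed form for a linear area profile).
    """
    if white.n_vertices != pial.n_vertices:
        raise ValueError("white and pial vertex counts differ")
    aw = _vertex_areas(white)
    ap = _vertex_areas(pial)
    fracs = np.linspace(0.0, 1.0, n_intermediate + 2)
    surfaces = []
    for frac in fracs:
        with np.errstate(invalid="ignore", divide="ignore"):
            x = (-aw + np.sqrt((1 - frac) * aw**2 + frac * ap**2)) / (ap - aw)
        x = np.where(np.abs(ap - aw) < 1e-12 * (aw + ap + 1e-30), frac, x)
        surfaces.append(SurfaceMesh(
            white.vertices + x[:, None] * (pial.vertices - white.vertices),
            white.faces, white.labels))
    return LayerStack(surfaces, fracs)


def sample_volume_to_surface(volume: np.ndarray, affine: np.ndarray,
                             surface: SurfaceMesh) -> np.ndarray:
    """Trilinear interpolation of a 3D or 4D volume at the surface vertices.

    Vertices outside the volume's field of view are flagged with NaN and
    should be excluded downstream.  Returns (n_vertices,) for a 3D volume or
    (n_vertices, t) for a 4D one.
    """
    volume = np.asarray(volume)
    affine = np.asarray(affine, float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("singular affine")
    inv = np.linalg.inv(affine)
    world = np.column_stack([surface.vertices,
                             np.ones(surface.n_vertices)])
    vox = (inv @ world.T).T[:, :3]
    dims = np.array(volume.shape[:3])
    eps = 1e-9
    inside = np.all((vox >= -eps) & (vox <= dims - 1 + eps), axis=1)
    vox = np.clip(vox, 0, dims - 1)
    i0 = np.floor(vox).astype(int)
    i0 = np.minimum(i0, dims - 2)
    i0 = np.maximum(i0, 0)
    w = vox - i0  # fractional offsets in [0, 1]

    squeeze = volume.ndim == 3
    vol4 = volume[..., None] if squeeze else volume
    out = np.zeros((surface.n_vertices, vol4.shape[3]))
    for dx in (0, 1):
        wx = (1 - w[:, 0]) if dx == 0 else w[:, 0]
        for dy in (0, 1):
            wy = (1 - w[:, 1]) if dy == 0 else w[:, 1]
            for dz in (0, 1):
                wz = (1 - w[:, 2]) if dz == 0 else w[:, 2]
                weight = (wx * wy * wz)[:, None]
                out += weight * vol4[i0[:, 0] + dx, i0[:, 1] + dy,
                                     i0[:, 2] + dz, :]
    out[~inside] = np.nan
    return out[:, 0] if squeeze else out


def label_min_distances(surface: SurfaceMesh, from_label, to_label):
    """Distribution of minimum Euclidean distances (mm) from every vertex
    carrying ``from_label`` to the nearest vertex carrying ``to_label``.

    Returns (distances, mean distance).
    """
    if surface.labels is None:
        raise ValueError("surface carries no labels")
    src = surface.vertices[surface.labels == from_label]
    dst = surface.vertices[surface.labels == to_label]
    if len(src) == 0 or len(dst) == 0:
        raise ValueError("empty label set")
    d, _ = cKDTree(dst).query(src)
    return d, float(d.mean())
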