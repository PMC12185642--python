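"""Mesh containers for the luminal volume and wall surface.

The volume is a tetrahedral mesh carrying nodal velocity vectors; the wall is
a triangulated surface carrying nodal wall-shear-stress vectors, outward unit
normals and lumped association areas used to discretise surface integrals.
Node indexing is 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MeshError(ValueError):
    """Raised for invalid mesh topology or geometry."""


def tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volume of each tetrahedron under the stored orientation."""
    p = points[tets]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    d3 = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0


def triangle_areas_normals(points: np.ndarray, tris: np.ndarray):
    """Per-triangle area and unit normal (right-hand rule on node order)."""
    p = points[tris]
    cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    nrm = np.linalg.norm(cr, axis=1)
    if np.any(nrm <= 0.0):
        raise MeshError("degenerate (zero-area) triangle")
    return 0.5 * nrm, cr / nrm[:, None]


@dataclass
class VolumeMesh:
    """Tetrahedral mesh of the fluid domain.

    Parameters
    ----------
    points : (n_nodes, 3) float array, coordinates in metres.
    tets : (n_cells, 4) int array, node indices; orientation is fixed on
        construction so every signed volume is positive.
    cell_regions : optional mapping of ROI name -> cell-index array.
    """

    points: np.ndarray
    tets: np.ndarray
    cell_regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshError("points must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshError("tets must be (m, 4)")
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.points)):
            raise MeshError("tet index out of range")
        # enforce positive orientation by swapping the last two nodes
        vol = tet_volumes(self.points, self.tets)
        flip = vol < 0
        if np.any(flip):
            self.tets[flip, 2], self.tets[flip, 3] = (
                self.tets[flip, 3].copy(),
                self.tets[flip, 2].copy(),
            )
            vol = tet_volumes(self.points, self.tets)
        if np.any(vol <= 0.0):
            raise MeshError("degenerate (zero-volume) tetrahedron")
        self._volumes = vol
        for name, idx in self.cell_regions.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= len(self.tets)):
                raise MeshError(f"ROI {name!r}: cell index out of range")
            self.cell_regions[name] = idx

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.tets)

    @property
    def cell_volumes(self) -> np.ndarray:
        return self._volumes

    @property
    def total_volume(self) -> float:
        return float(self._volumes.sum())

    def same_topology(self, other: "VolumeMesh") -> bool:
        return (
            self.points.shape == other.points.shape
            and self.tets.shape == other.tets.shape
            and np.array_equal(self.tets, other.tets)
            and np.allclose(self.points, other.points, rtol=0.0, atol=1e-12)
        )


@dataclass
class SurfaceMesh:
    """Triangulated lumen surface with outward normals and nodal areas.

    ``node_areas`` is the lumped association area: one third of the summed
    areas of the triangles incident to each node, so that nodal surface
    integrals sum to the exact total area.
    """

    points: np.ndarray
    tris: np.ndarray
    node_normals: np.ndarray | None = None
    rois: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tris = np.asarray(self.tris, dtype=np.int64)
        if self.tris.ndim != 2 or self.tris.shape[1] != 3:
            raise MeshError("tris must be (m, 3)")
        if self.tris.size and (self.tris.min() < 0 or self.tris.max() >= len(self.points)):
            raise MeshError("triangle index out of range")
        areas, cell_n = triangle_areas_normals(self.points, self.tris)
        self.cell_areas = areas
        self.cell_normals = cell_n
        # lumped nodal association areas: 1/3 of incident triangle areas
        na = np.zeros(len(self.points))
        np.add.at(na, self.tris.ravel(), np.repeat(areas / 3.0, 3))
        self.node_areas = na
        if self.node_normals is None:
            nn = np.zeros_like(self.points)
            np.add.at(nn, self.tris.ravel(), np.repeat(areas[:, None] * cell_n, 3, axis=0))
            norm = np.linalg.norm(nn, axis=1)
            norm[norm == 0.0] = 1.0
            self.node_normals = nn / norm[:, None]
        else:
            self.node_normals = np.asarray(self.node_normals, dtype=float)
            norm = np.linalg.norm(self.node_normals, axis=1)
            if np.any(np.abs(norm - 1.0) > 1e-9):
                raise MeshError("node normals must be unit length")
        for name, idx in self.rois.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= len(self.tris)):
                raise MeshError(f"ROI {name!r}: cell index out of range")
            self.rois[name] = idx

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.tris)

    @property
    def total_area(self) -> float:
        return float(self.cell_areas.sum())

    def cell_centroids(self) -> np.ndarray:
        return self.points[self.tris].mean(axis=1)

    def same_topology(self, other: "SurfaceMesh") -> bool:
        return (
            self.points.shape == other.points.shape
            and self.tris.shape == other.tris.shape
            and np.array_equal(self.tris, other.tris)
            and np.allclose(self.points, other.points, rtol=0.0, atol=1e-12)
        )
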