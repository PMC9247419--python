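"""Triangulated hemisphere surfaces with optional left-right correspondence.

Meshes stand in for pial-surface reconstructions.  A right hemisphere can
carry a ``mirror_index``: for each of its vertices, the index of the
corresponding left-hemisphere vertex (a bijection), which is what allows a
parcellation to be projected contralaterally and homolog region pairs to be
defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra


@dataclass
class SurfaceMesh:
    """Triangle mesh: coordinates in mm, faces as vertex-index triples."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int
    hemisphere: str = "left"
    mirror_index: np.ndarray | None = None  # (V,) int, this-vertex -> partner-vertex

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if self.mirror_index is not None:
            mi = np.asarray(self.mirror_index, dtype=int)
            if sorted(mi) != list(range(len(self.vertices))):
                raise ValueError("mirror correspondence must be a bijection")
            self.mirror_index = mi

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def euler_characteristic(self) -> int:
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + len(self.faces)

    def edge_graph(self) -> sparse.csr_matrix:
        """Sparse symmetric graph of mesh edges weighted by Euclidean length."""
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        edges = np.unique(edges, axis=0)
        w = np.linalg.norm(self.vertices[edges[:, 0]] - self.vertices[edges[:, 1]], axis=1)
        i = np.concatenate([edges[:, 0], edges[:, 1]])
        j = np.concatenate([edges[:, 1], edges[:, 0]])
        g = sparse.csr_matrix(
            (np.concatenate([w, w]), (i, j)), shape=(self.n_vertices, self.n_vertices)
        )
        return g

    def geodesic_from(self, sources: np.ndarray, graph: sparse.csr_matrix | None = None) -> np.ndarray:
        """Shortest-path distances on the edge graph from one or more vertices."""
        g = graph if graph is not None else self.edge_graph()
        d = dijkstra(g, directed=False, indices=np.atleast_1d(sources))
        return d.min(axis=0) if d.ndim == 2 else d

    def assert_connected(self) -> None:
        n_comp, labels = connected_components(self.edge_graph(), directed=False)
        if n_comp != 1:
            sizes = np.bincount(labels)
            raise ValueError(
                f"mesh is disconnected: {n_comp} components with sizes {sizes.tolist()}"
            )

    def surface_area(self) -> float:
        tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        return float(tm.area)

    # --- ASCII PLY IO (via trimesh) -------------------------------------
    def to_ply(self, path: str | Path) -> None:
        tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        Path(path).write_bytes(data)

    @classmethod
    def from_ply(cls, path: str | Path, hemisphere: str = "left") -> "SurfaceMesh":
        tm = trimesh.load(str(path), file_type="ply", process=False)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), hemisphere=hemisphere)


def write_correspondence(mesh_right: SurfaceMesh, path: str | Path) -> None:
    """Two-column table: right-vertex index, corresponding left-vertex index."""
    if mesh_right.mirror_index is None:
        raise ValueError("mesh has no mirror correspondence")
    arr = np.column_stack([np.arange(mesh_right.n_vertices), mesh_right.mirror_index])
    np.savetxt(path, arr, fmt="%d", delimiter="\t", header="right\tleft", comments="")


def read_correspondence(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter="\t", skiprows=1, dtype=int)
    order = np.argsort(arr[:, 0])
    return arr[order, 1]
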