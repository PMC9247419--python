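"""Random, evenly dispersed parcellation of a hemisphere surface.

No biologically informed atlas maps homologous regions across all primate
species, so regions are defined geometrically: a fixed number of region
centers is placed evenly over the cortical mantle by farthest-point
sampling on geodesic (mesh edge-graph) distance, and every vertex joins its
nearest center.  The default resolution is 50 regions per hemisphere (25
and 100 are supported).  The left-hemisphere parcellation is projected onto
the right through the meshes' vertex correspondence so that region r on the
right is the spatial homolog of region r on the left.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import SurfaceMesh

SUPPORTED_RESOLUTIONS = (25, 50, 100)


@dataclass
class Parcellation:
    """Per-vertex region labels, contiguous 1..R, every region non-empty."""

    labels: np.ndarray  # (V,) int in 1..R
    n_regions: int
    hemisphere: str = "left"
    center_vertices: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.n_regions + 1)):
            raise ValueError(
                f"labels must cover 1..{self.n_regions} with no empty region; "
                f"found {present.tolist()[:10]}..."
            )

    @property
    def region_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_regions + 1)[1:]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"vertex": np.arange(len(self.labels)), "label": self.labels}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, hemisphere: str = "left") -> "Parcellation":
        df = pd.read_csv(path, sep="\t")
        labels = df.sort_values("vertex")["label"].to_numpy()
        return cls(labels=labels, n_regions=int(labels.max()), hemisphere=hemisphere)


def random_parcellation(
    mesh: SurfaceMesh,
    n_regions: int,
    seed: int,
    metric: str = "geodesic",
) -> Parcellation:
    """Farthest-point-sampled centers, nearest-center vertex assignment.

    The first center is a seeded uniform draw; each subsequent center is
    the vertex farthest (geodesic distance) from all centers chosen so far.
    Assignment ties go to the lowest center index.  Deterministic given
    (mesh, n_regions, seed).
    """
    V = mesh.n_vertices
    if n_regions < 1 or n_regions > V:
        raise ValueError(f"n_regions={n_regions} must be in 1..{V}")
    if metric not in ("geodesic", "euclidean"):
        raise ValueError("metric must be 'geodesic' or 'euclidean'")
    mesh.assert_connected()
    rng = np.random.default_rng(seed)
    first = int(rng.integers(V))
    centers = [first]

    if metric == "geodesic":
        graph = mesh.edge_graph()
        mindist = mesh.geodesic_from(np.array([first]), graph)
        for _ in range(1, n_regions):
            nxt = int(np.argmax(mindist))
            centers.append(nxt)
            mindist = np.minimum(mindist, mesh.geodesic_from(np.array([nxt]), graph))
        dists = np.vstack([mesh.geodesic_from(np.array([c]), graph) for c in centers])
    else:
        coords = mesh.vertices
        mindist = np.linalg.norm(coords - coords[first], axis=1)
        for _ in range(1, n_regions):
            nxt = int(np.argmax(mindist))
            centers.append(nxt)
            mindist = np.minimum(mindist, np.linalg.norm(coords - coords[nxt], axis=1))
        dists = np.vstack([np.linalg.norm(coords - coords[c], axis=1) for c in centers])

    # argmin returns the first (lowest-index) minimiser: the tie rule
    labels = np.argmin(dists, axis=0) + 1
    return Parcellation(
        labels=labels,
        n_regions=n_regions,
        hemisphere=mesh.hemisphere,
        center_vertices=np.asarray(centers),
    )


def project_contralateral(
    parc: Parcellation, mesh_left: SurfaceMesh, mesh_right: SurfaceMesh
) -> Parcellation:
    """Copy left-hemisphere labels to the right via the mirror bijection."""
    if mesh_right.mirror_index is None:
        raise ValueError("right mesh has no mirror correspondence to the left")
    if len(parc.labels) != mesh_left.n_vertices:
        raise ValueError("parcellation does not match the left mesh")
    labels_right = parc.labels[mesh_right.mirror_index]
    return Parcellation(
        labels=labels_right, n_regions=parc.n_regions, hemisphere="right"
    )


def region_centroids(mesh: SurfaceMesh, parc: Parcellation) -> pd.DataFrame:
    """Mean member-vertex coordinates per region; R rows, columns x/y/z (mm)."""
    if len(parc.labels) != mesh.n_vertices:
        raise ValueError("parcellation does not match mesh")
    rows = []
    for r in range(1, parc.n_regions + 1):
        members = mesh.vertices[parc.labels == r]
        rows.append(members.mean(axis=0))
    return pd.DataFrame(
        np.asarray(rows), columns=["x", "y", "z"], index=pd.RangeIndex(1, parc.n_regions + 1, name="region")
    )
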