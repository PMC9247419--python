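import numpy as np
import pandas as pd
import pytest

from connscale import Connectome, SurfaceMesh, parse_newick
from connscale.synthetic import generate_hemisphere_pair


def star_tree(n: int, depth: float = 1.0):
    """Star phylogeny: n leaves hanging directly off the root."""
    leaves = ",".join(f"sp{i:02d}:{depth}" for i in range(1, n + 1))
    return parse_newick(f"({leaves});")


def build_connectome(
    n_per_hemisphere: int,
    left_edges: dict[tuple[int, int], float],
    right_edges: dict[tuple[int, int], float] | None = None,
    ap_extent: float = 100.0,
    lengths: dict[tuple[int, int], float] | None = None,
    species: str = "toy",
) -> Connectome:
    """Small two-hemisphere connectome built directly from edge dicts.

    Edge keys are 0-based within-hemisphere region indices; the right
    hemisphere defaults to an exact mirror of the left.  Homolog of left
    region k is right region k.
    """
    R = n_per_hemisphere
    if right_edges is None:
        right_edges = dict(left_edges)
    n = 2 * R
    W = np.zeros((n, n))
    L = np.zeros((n, n))
    for offset, edges in ((0, left_edges), (R, right_edges)):
        for (i, j), w in edges.items():
            a, b = offset + i, offset + j
            W[a, b] = W[b, a] = w
            length = (lengths or {}).get((i, j), 10.0 * abs(i - j) + 5.0)
            L[a, b] = L[b, a] = length
    # simple collinear centroids along the AP (y) axis
    ys = np.arange(R) * (ap_extent / max(R - 1, 1))
    regions = pd.DataFrame(
        {
            "region": [f"L{k:03d}" for k in range(1, R + 1)]
            + [f"R{k:03d}" for k in range(1, R + 1)],
            "hemisphere": ["left"] * R + ["right"] * R,
            "x": [-10.0] * R + [10.0] * R,
            "y": np.concatenate([ys, ys]),
            "z": np.zeros(n),
            "homolog": [f"R{k:03d}" for k in range(1, R + 1)]
            + [f"L{k:03d}" for k in range(1, R + 1)],
        }
    )
    return Connectome(
        regions=regions, weights=W, lengths=L, ap_extent=ap_extent, species=species
    )


@pytest.fixture(scope="session")
def small_mesh_pair() -> tuple[SurfaceMesh, SurfaceMesh]:
    """162-vertex mirrored hemisphere pair (fast fixture)."""
    return generate_hemisphere_pair(100.0, ap_elongation=1.4, subdivisions=2)


@pytest.fixture(scope="session")
def uniform_icosphere() -> SurfaceMesh:
    """2562-vertex unstretched icosphere for parcel-uniformity checks."""
    from connscale.synthetic import generate_hemisphere_mesh

    return generate_hemisphere_mesh(100.0, ap_elongation=1.0, subdivisions=4)
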