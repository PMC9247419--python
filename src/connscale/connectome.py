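"""Per-species two-hemisphere structural connectomes.

Nodes are parcellation regions; connection strength is the number of
streamlines (NOS) linking two regions, and connection length is the mean
physical distance (mm) traveled by those streamlines (centroid distance
for synthetic connectomes, where no streamlines exist).  Comparative
analyses use the intrahemispheric subnetworks of the left and right
hemispheres.

Connection lengths are compared across species on a brain-size-normalized
scale: each species' connection-length distribution is split into 10 equal
bins spanning 0 mm to the anterior-posterior extent of the brain, so each
bin covers 10% of AP length; connections longer than the AP extent fall in
the last bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_LENGTH_BINS = 10


@dataclass
class Connectome:
    """Symmetric weighted graph over parcellation regions of both hemispheres.

    ``regions`` has one row per node with columns ``region`` (unique id),
    ``hemisphere`` ('left'|'right'), centroid ``x, y, z`` in mm and
    ``homolog`` (the region id of the contralateral partner).  ``weights``
    (NOS) and ``lengths`` (mm) are square, symmetric, zero-diagonal, indexed
    like ``regions``.
    """

    regions: pd.DataFrame
    weights: np.ndarray
    lengths: np.ndarray
    ap_extent: float
    species: str = "unknown"
    ap_axis: str = "y"

    def __post_init__(self):
        n = len(self.regions)
        self.weights = np.asarray(self.weights, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        for name, m in (("weights", self.weights), ("lengths", self.lengths)):
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{name} must have zero diagonal")
        if self.regions["region"].duplicated().any():
            raise ValueError("region ids must be unique")
        present = self.weights > 0
        if np.any(present & (self.lengths <= 0)):
            raise ValueError("every present connection needs a positive length")
        if self.ap_extent <= 0:
            raise ValueError("anterior-posterior extent must be positive")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def hemisphere_nodes(self, hemisphere: str) -> np.ndarray:
        mask = (self.regions["hemisphere"] == hemisphere).to_numpy()
        if not mask.any():
            raise ValueError(f"no nodes in hemisphere {hemisphere!r}")
        return np.flatnonzero(mask)

    def hemisphere_adjacency(self, hemisphere: str, binary: bool = True) -> np.ndarray:
        idx = self.hemisphere_nodes(hemisphere)
        sub = self.weights[np.ix_(idx, idx)]
        return (sub > 0).astype(float) if binary else sub

    def homolog_pairs(self) -> list[tuple[int, int]]:
        """(left node index, right node index) for every homolog pair."""
        id_to_idx = {rid: i for i, rid in enumerate(self.regions["region"])}
        pairs = []
        for i, row in self.regions.iterrows():
            if row["hemisphere"] == "left":
                partner = row["homolog"]
                if partner not in id_to_idx:
                    raise ValueError(f"homolog {partner!r} of region {row['region']!r} missing")
                pairs.append((id_to_idx[row["region"]], id_to_idx[partner]))
        if not pairs:
            raise ValueError("no homolog pairing defined")
        return pairs

    def copy(self) -> "Connectome":
        return Connectome(
            regions=self.regions.copy(),
            weights=self.weights.copy(),
            lengths=self.lengths.copy(),
            ap_extent=self.ap_extent,
            species=self.species,
            ap_axis=self.ap_axis,
        )

    # --- IO --------------------------------------------------------------
    def write(self, directory: str | Path, prefix: str | None = None) -> None:
        """Write weight/length matrices and the region sidecar as TSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.species
        ids = self.regions["region"].astype(str)
        for name, m in (("weights", self.weights), ("lengths", self.lengths)):
            pd.DataFrame(m, index=ids, columns=ids).to_csv(
                directory / f"{prefix}.{name}.tsv", sep="\t"
            )
        sidecar = self.regions.copy()
        sidecar["ap_extent"] = self.ap_extent
        sidecar.to_csv(directory / f"{prefix}.regions.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, directory: str | Path, prefix: str) -> "Connectome":
        directory = Path(directory)
        regions = pd.read_csv(directory / f"{prefix}.regions.tsv", sep="\t")
        ap = float(regions.pop("ap_extent").iloc[0])
        w = pd.read_csv(directory / f"{prefix}.weights.tsv", sep="\t", index_col=0).to_numpy()
        ln = pd.read_csv(directory / f"{prefix}.lengths.tsv", sep="\t", index_col=0).to_numpy()
        return cls(regions=regions, weights=w, lengths=ln, ap_extent=ap, species=prefix)


@dataclass
class LengthBins:
    """Proportions of connections in 10 AP-normalized length bins."""

    proportions: np.ndarray
    bin_width_mm: float

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (N_LENGTH_BINS,):
            raise ValueError(f"exactly {N_LENGTH_BINS} bins required")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("bin proportions must sum to 1")
        self.proportions = p


@dataclass
class DiscardLog:
    unassigned_endpoint: int = 0
    within_region: int = 0
    counted: int = 0

    @property
    def discarded(self) -> int:
        return self.unassigned_endpoint + self.within_region


UNASSIGNED = -1  # streamline endpoint that hit no region


def _is_unassigned(label) -> bool:
    if isinstance(label, float) and np.isnan(label):
        return True
    return label == UNASSIGNED or str(label) == str(UNASSIGNED)


def streamlines_to_connectome(
    streamlines: pd.DataFrame,
    regions: pd.DataFrame,
    ap_extent: float,
    species: str = "unknown",
) -> tuple[Connectome, DiscardLog]:
    """Aggregate a streamline table into NOS weights and mean-length matrix.

    ``streamlines`` needs columns ``region_a``, ``region_b`` (region ids, or
    ``UNASSIGNED``) and ``length_mm``.  Streamlines with an unassigned
    endpoint or with both endpoints in one region are dropped and tallied in
    the returned :class:`DiscardLog`.
    """
    n = len(regions)
    id_to_idx = {rid: i for i, rid in enumerate(regions["region"])}
    W = np.zeros((n, n))
    Lsum = np.zeros((n, n))
    log = DiscardLog()
    if len(streamlines) == 0:
        warnings.warn("empty streamline table: connectome has no connections")
    for a, b, length in streamlines[["region_a", "region_b", "length_mm"]].itertuples(index=False):
        if length <= 0:
            raise ValueError("streamline arclength must be positive")
        if _is_unassigned(a) or _is_unassigned(b):
            log.unassigned_endpoint += 1
            continue
        if a == b:
            log.within_region += 1
            continue
        if a not in id_to_idx or b not in id_to_idx:
            raise ValueError(f"streamline references unknown region {a!r} or {b!r}")
        i, j = id_to_idx[a], id_to_idx[b]
        W[i, j] += 1
        W[j, i] += 1
        Lsum[i, j] += length
        Lsum[j, i] += length
        log.counted += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        L = np.where(W > 0, Lsum / np.maximum(W, 1), 0.0)
    return (
        Connectome(regions=regions, weights=W, lengths=L, ap_extent=ap_extent, species=species),
        log,
    )


def network_density(conn: Connectome, scope: str = "whole") -> float:
    """Observed connections / possible region pairs, within the given scope.

    ``scope`` is 'left', 'right' (intrahemispheric pairs only) or 'whole'.
    """
    if scope in ("left", "right"):
        idx = conn.hemisphere_nodes(scope)
        sub = conn.weights[np.ix_(idx, idx)]
    elif scope == "whole":
        sub = conn.weights
    else:
        raise ValueError(f"unknown scope {scope!r}")
    n = sub.shape[0]
    if n < 2:
        raise ValueError("density needs at least 2 regions in scope")
    possible = n * (n - 1) / 2
    observed = np.count_nonzero(np.triu(sub, 1))
    return observed / possible


def _ranked_edges(weights: np.ndarray, idx: np.ndarray) -> list[tuple[float, int, int]]:
    """Intra-scope edges sorted by (descending weight, ascending pair)."""
    edges = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            if weights[i, j] > 0:
                edges.append((weights[i, j], i, j))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    return edges


def equalize_density(
    conns: list[Connectome], target: str | float = "min"
) -> list[Connectome]:
    """Threshold every network to a common per-hemisphere density.

    Each hemisphere of each species retains its strongest-NOS connections
    down to the target edge count (ties at the cutoff broken by higher
    weight, then lexicographic node-pair order).  ``target='min'`` uses the
    minimum per-hemisphere density across the set; a float gives a fixed
    fraction, which must not exceed any network's density.
    """
    hemis = ("left", "right")
    densities = {
        (c.species, h): network_density(c, h) for c in conns for h in hemis
    }
    if target == "min":
        target_density = min(densities.values())
    else:
        target_density = float(target)
        for (sp, h), d in densities.items():
            if target_density > d + 1e-12:
                raise ValueError(
                    f"target density {target_density:.3f} exceeds {sp} {h} density {d:.3f}"
                )
    out = []
    for conn in conns:
        new = conn.copy()
        for h in hemis:
            idx = conn.hemisphere_nodes(h)
            n = len(idx)
            keep = int(round(target_density * n * (n - 1) / 2))
            edges = _ranked_edges(conn.weights, idx)
            for _, i, j in edges[keep:]:
                new.weights[i, j] = new.weights[j, i] = 0.0
                new.lengths[i, j] = new.lengths[j, i] = 0.0
        out.append(new)
    return out


def length_bin_distribution(conn: Connectome) -> LengthBins:
    """Bin connection (not streamline) lengths into 10 AP-normalized bins."""
    iu = np.triu_indices(conn.n_regions, 1)
    present = conn.weights[iu] > 0
    lengths = conn.lengths[iu][present]
    if lengths.size == 0:
        raise ValueError("connectome has no connections to bin")
    width = conn.ap_extent / N_LENGTH_BINS
    bins = np.minimum((lengths / width).astype(int), N_LENGTH_BINS - 1)
    counts = np.bincount(bins, minlength=N_LENGTH_BINS)
    return LengthBins(proportions=counts / counts.sum(), bin_width_mm=width)


def short_long_contrast(bins: LengthBins) -> tuple[float, float]:
    """Proportion in bins 1-2 (shortest) vs bins 3-10 (longer)."""
    short = float(bins.proportions[:2].sum())
    return short, 1.0 - short


def to_edge_list(conn: Connectome) -> pd.DataFrame:
    """Weighted edge list (region_i, region_j, nos, length_mm)."""
    iu = np.triu_indices(conn.n_regions, 1)
    mask = conn.weights[iu] > 0
    ids = conn.regions["region"].to_numpy()
    return pd.DataFrame(
        {
            "region_i": ids[iu[0][mask]],
            "region_j": ids[iu[1][mask]],
            "nos": conn.weights[iu][mask],
            "length_mm": conn.lengths[iu][mask],
        }
    )
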