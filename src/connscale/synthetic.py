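"""Synthetic comparative datasets with known ground truth.

Generates everything a cross-species connectome scaling analysis consumes:
an ultrametric pure-birth phylogeny, log-scale traits evolving by Brownian
motion with configurable allometric exponents, mirrored two-hemisphere
ellipsoid surface meshes, and distance-dependent connectomes whose density,
distance-decay scale and hemispheric asymmetry can vary with brain size.

The default generating exponents are the observed primate point estimates
(surface~volume 0.85, WM~GM 1.10, CC~surface 0.88) over a ~350-fold
cerebral volume range, so recovery tests target realistic values.  The
"bottleneck" configuration makes the connection-distance decay length
shrink relative to brain size, density fall, and asymmetry rise as brains
get larger — the qualitative regime the analysis pipeline is meant to
detect; the size-independent configuration is the matched null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
import trimesh

from .connectome import Connectome
from .mesh import SurfaceMesh
from .parcellation import Parcellation, project_contralateral, random_parcellation, region_centroids
from .phylo import PhyloTree
from .traits import TraitTable


def child_seed(master: int, *key: int) -> int:
    """Deterministic sub-seed (< 2^31) derived from a master seed and a key."""
    ss = np.random.SeedSequence((int(master),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, birth_rate: float = 0.05, seed: int = 0) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with leaf labels sp01, sp02, ...

    ``birth_rate`` is in events per lineage per million years; the default
    yields root-to-tip depths of some tens of Myr for ~14 taxa.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        active.append((child, 0.0))
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node, born = active.pop(k)
        node.edge.length = t - born
        for _ in range(2):
            active.append((node.new_child(), t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    # leaf order by left-to-right position for stable labeling
    for i, (node, born) in enumerate(active):
        node.edge.length = t_end - born
        node.taxon = taxa.new_taxon(f"sp{i + 1:02d}")
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _bm_realization(tree: PhyloTree, rng: np.random.Generator) -> np.ndarray:
    """One Brownian-motion draw (unit rate, root 0) at the leaves, in leaf order."""
    dtree = tree.dendropy_tree
    value = {dtree.seed_node: 0.0}
    out = {}
    for node in dtree.preorder_node_iter():
        if node is not dtree.seed_node:
            bl = node.edge.length or 0.0
            value[node] = value[node.parent_node] + rng.normal(0.0, np.sqrt(bl))
        if node.is_leaf():
            out[node.taxon.label] = value[node]
    return np.array([out[lab] for lab in tree.leaf_labels])


def _scaled_deviation(
    tree: PhyloTree,
    rng: np.random.Generator,
    target_sd: float,
    noise_model: str,
) -> np.ndarray:
    """Zero-mean residual with SD ``target_sd``: BM on the tree, or i.i.d."""
    n = tree.n_leaves
    if target_sd == 0:
        return np.zeros(n)
    if noise_model == "bm":
        dev = _bm_realization(tree, rng)
    elif noise_model == "iid":
        dev = rng.standard_normal(n)
    else:
        raise ValueError("noise_model must be 'bm' or 'iid'")
    sd = dev.std(ddof=1)
    if sd == 0:
        return np.zeros(n)
    return (dev - dev.mean()) / sd * target_sd


@dataclass
class SpeciesSpec:
    """Generating parameters for a synthetic comparative study.

    Rules that depend on brain size are (value_at_smallest,
    value_at_largest) pairs, interpolated linearly in normalized log10
    cerebral volume.  ``decay_fraction`` is the connection-probability
    decay length d0 as a fraction of the anterior-posterior extent;
    ``density`` the target intrahemispheric network density; ``asymmetry``
    the SD of the multiplicative log-normal perturbation applied to
    right-hemisphere weights.
    """

    n_species: int = 14
    volume_range_cm3: tuple[float, float] = (2.5, 900.0)
    exponent_surface_volume: float = 0.85
    exponent_wm_gm: float = 1.10
    exponent_cc_surface: float = 0.88
    noise_sd_fraction: float = 0.05  # residual SD as fraction of predictor SD
    noise_model: str = "bm"
    decay_fraction: tuple[float, float] = (0.40, 0.15)
    density: tuple[float, float] = (0.52, 0.33)
    asymmetry: tuple[float, float] = (0.02, 0.35)
    n_regions: int = 50
    mesh_subdivisions: int = 3
    ap_elongation: float = 1.6
    birth_rate: float = 0.05
    weight_log_mu: float = 2.0
    weight_log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.volume_range_cm3[0] <= 0 or self.volume_range_cm3[1] <= self.volume_range_cm3[0]:
            raise ValueError("volume range must be positive and increasing")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise SD must be >= 0")
        for name in ("exponent_surface_volume", "exponent_wm_gm", "exponent_cc_surface"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def bottleneck_off(cls, **kwargs) -> "SpeciesSpec":
        """Matched null: no size dependence in decay, density or asymmetry."""
        defaults = dict(
            decay_fraction=(0.25, 0.25), density=(0.40, 0.40), asymmetry=(0.15, 0.15)
        )
        defaults.update(kwargs)
        return cls(**defaults)

    def rule_at(self, rule: tuple[float, float], u: float) -> float:
        return rule[0] + (rule[1] - rule[0]) * u


# fixed log10 intercepts anchoring the trait system at realistic values:
# galago-scale brains have ~11 cm^2 of surface at 2.6 cm^3 of cerebrum,
# ~1 cm^2 of CC per 90 cm^2 of surface, ~half the cerebrum as cortical GM,
# and ~37% of cerebral volume as WM.
_INTERCEPT_SURFACE = 0.69
_INTERCEPT_CC = -1.83
_GM_FRACTION = 0.5
_INTERCEPT_WM = -0.143


def simulate_traits(tree: PhyloTree, spec: SpeciesSpec, seed: int | None = None) -> TraitTable:
    """Log-scale traits under BM with the spec's allometric exponents.

    log10 cerebral volume follows a BM realization rescaled to span the
    requested volume range; each dependent trait is exponent × its
    predictor (log10) plus an anchoring intercept plus a BM (or i.i.d.)
    residual whose SD is ``noise_sd_fraction`` × SD of the predictor.
    """
    rng = np.random.default_rng(child_seed(spec.seed, 1) if seed is None else seed)
    lo, hi = np.log10(spec.volume_range_cm3[0]), np.log10(spec.volume_range_cm3[1])
    raw = _bm_realization(tree, rng)
    if np.ptp(raw) == 0:
        raise ValueError("degenerate BM realization (zero-depth tree?)")
    log_v = lo + (raw - raw.min()) / np.ptp(raw) * (hi - lo)

    def dependent(exponent, predictor_log, intercept):
        dev = _scaled_deviation(
            tree, rng, spec.noise_sd_fraction * predictor_log.std(ddof=1), spec.noise_model
        )
        return exponent * predictor_log + intercept + dev

    log_gm = np.log10(_GM_FRACTION) + log_v  # isometric cortical GM share
    log_surface = dependent(spec.exponent_surface_volume, log_v, _INTERCEPT_SURFACE)
    log_wm = dependent(spec.exponent_wm_gm, log_gm, _INTERCEPT_WM)
    log_cc = dependent(spec.exponent_cc_surface, log_surface, _INTERCEPT_CC)

    df = pd.DataFrame(
        {
            "cerebral_volume": 10**log_v,
            "gray_matter_volume": 10**log_gm,
            "white_matter_volume": 10**log_wm,
            "cortical_surface_area": 10**log_surface,
            "cc_area": 10**log_cc,
        },
        index=pd.Index(tree.leaf_labels, name="species"),
    )
    return TraitTable(df)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def generate_hemisphere_mesh(
    surface_area_cm2: float,
    ap_elongation: float = 1.6,
    subdivisions: int = 3,
    side: str = "left",
) -> SurfaceMesh:
    """Subdivided icosphere stretched into an AP-elongated ellipsoid.

    The mesh is scaled so its total face area equals ``surface_area_cm2``
    (in mm²: 1 cm² = 100 mm²); the anterior-posterior axis is y and is the
    longest.  The two hemispheres sit side by side along x; the right
    hemisphere is the exact mirror of the left (x → −x) and carries the
    identity vertex correspondence.
    """
    if surface_area_cm2 <= 0:
        raise ValueError("surface area must be positive")
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(base.vertices).copy()
    v[:, 1] *= ap_elongation
    faces = np.asarray(base.faces)
    area = trimesh.Trimesh(v, faces, process=False).area
    scale = np.sqrt(surface_area_cm2 * 100.0 / area)
    v *= scale
    offset = 1.2 * scale  # separate the hemispheres along x
    v[:, 0] -= offset
    if side == "left":
        return SurfaceMesh(v, faces, hemisphere="left")
    if side == "right":
        vr = v.copy()
        vr[:, 0] = -vr[:, 0]
        faces_r = faces[:, [0, 2, 1]]  # restore outward orientation
        return SurfaceMesh(
            vr, faces_r, hemisphere="right", mirror_index=np.arange(len(vr))
        )
    raise ValueError("side must be 'left' or 'right'")


def generate_hemisphere_pair(
    total_surface_area_cm2: float, ap_elongation: float = 1.6, subdivisions: int = 3
) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Left and mirrored right hemisphere, each with half the total area."""
    half = total_surface_area_cm2 / 2.0
    left = generate_hemisphere_mesh(half, ap_elongation, subdivisions, side="left")
    right = generate_hemisphere_mesh(half, ap_elongation, subdivisions, side="right")
    return left, right


# ---------------------------------------------------------------------------
# connectomes
# ---------------------------------------------------------------------------

def _calibrate_density(dist: np.ndarray, d0: float, target: float) -> np.ndarray:
    """Scale c such that mean(min(1, c·exp(−d/d0))) equals the target density."""
    if not 0 < target <= 1:
        raise ValueError(f"target density {target} outside (0, 1]")
    base = np.exp(-dist / d0)

    def mean_p(c):
        return np.minimum(1.0, c * base).mean()

    lo_c, hi_c = 1e-12, 1e12
    if mean_p(hi_c) < target - 1e-9:
        raise ValueError(
            f"target density {target} unreachable (max {mean_p(hi_c):.3f})"
        )
    for _ in range(200):
        mid = np.sqrt(lo_c * hi_c)
        if mean_p(mid) < target:
            lo_c = mid
        else:
            hi_c = mid
    return np.minimum(1.0, hi_c * base)


def generate_connectome(
    centroids_left: pd.DataFrame,
    centroids_right: pd.DataFrame,
    ap_extent: float,
    d0_mm: float,
    target_density: float,
    asymmetry_level: float,
    seed: int,
    species: str = "synthetic",
    weight_log_mu: float = 2.0,
    weight_log_sigma: float = 1.0,
) -> Connectome:
    """Distance-decay connectome with a mirrored, optionally perturbed right.

    Left intrahemispheric edges are selected with probability
    p(d) = min(1, c·exp(−d/d0)) (c calibrated so the expected density hits
    the target; the realized edge count is then fixed to exactly
    round(target × pairs), selecting the pairs with the smallest u/p for
    seeded uniform u, so the achieved density always lands within one edge
    of the target).  NOS weights are a discretized lognormal.  The right
    hemisphere copies the mirrored topology; its weights are multiplied by
    exp(asymmetry_level · N(0,1)) and re-discretized, so asymmetry 0 means
    an exact mirror.  Connection lengths are centroid distances.
    """
    R = len(centroids_left)
    if len(centroids_right) != R:
        raise ValueError("hemisphere centroid tables must match in length")
    rng = np.random.default_rng(seed)
    coords_l = centroids_left[["x", "y", "z"]].to_numpy()
    coords_r = centroids_right[["x", "y", "z"]].to_numpy()

    iu = np.triu_indices(R, 1)
    dist_l = np.linalg.norm(coords_l[iu[0]] - coords_l[iu[1]], axis=1)
    p = _calibrate_density(dist_l, d0_mm, target_density)
    k = int(round(target_density * len(dist_l)))
    u = rng.random(len(dist_l))
    with np.errstate(divide="ignore"):
        score = np.where(p > 0, u / p, np.inf)
    chosen = np.argsort(score, kind="stable")[:k]

    n = 2 * R
    W = np.zeros((n, n))
    L = np.zeros((n, n))
    w_left = np.maximum(
        1, np.round(np.exp(rng.normal(weight_log_mu, weight_log_sigma, size=k)))
    )
    if asymmetry_level > 0:
        w_right = np.maximum(
            1, np.round(w_left * np.exp(asymmetry_level * rng.standard_normal(k)))
        )
    else:
        w_right = w_left.copy()
    dist_r = np.linalg.norm(coords_r[iu[0]] - coords_r[iu[1]], axis=1)
    for e, edge in enumerate(chosen):
        i, j = iu[0][edge], iu[1][edge]
        W[i, j] = W[j, i] = w_left[e]
        L[i, j] = L[j, i] = dist_l[edge]
        ri, rj = R + i, R + j
        W[ri, rj] = W[rj, ri] = w_right[e]
        L[ri, rj] = L[rj, ri] = dist_r[edge]

    regions = pd.DataFrame(
        {
            "region": [f"L{r:03d}" for r in range(1, R + 1)]
            + [f"R{r:03d}" for r in range(1, R + 1)],
            "hemisphere": ["left"] * R + ["right"] * R,
            "x": np.concatenate([coords_l[:, 0], coords_r[:, 0]]),
            "y": np.concatenate([coords_l[:, 1], coords_r[:, 1]]),
            "z": np.concatenate([coords_l[:, 2], coords_r[:, 2]]),
            "homolog": [f"R{r:03d}" for r in range(1, R + 1)]
            + [f"L{r:03d}" for r in range(1, R + 1)],
        }
    )
    return Connectome(
        regions=regions,
        weights=W,
        lengths=L,
        ap_extent=ap_extent,
        species=species,
    )


# ---------------------------------------------------------------------------
# full datasets
# ---------------------------------------------------------------------------

@dataclass
class GeneratedDataset:
    """A complete synthetic comparative study with its ground truth."""

    tree: PhyloTree
    traits: TraitTable
    meshes: dict[str, tuple[SurfaceMesh, SurfaceMesh]]
    parcellations: dict[str, tuple[Parcellation, Parcellation]]
    centroids: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    connectomes: dict[str, Connectome]
    ground_truth: dict = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return self.tree.leaf_labels

    def write(self, directory) -> None:
        from pathlib import Path
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        self.traits.to_tsv(directory / "traits.tsv")
        for sp, conn in self.connectomes.items():
            conn.write(directory / "connectomes", prefix=sp)
        for sp, (left, right) in self.meshes.items():
            mesh_dir = directory / "meshes"
            mesh_dir.mkdir(exist_ok=True)
            left.to_ply(mesh_dir / f"{sp}.left.ply")
            right.to_ply(mesh_dir / f"{sp}.right.ply")
        for sp, (pl, pr) in self.parcellations.items():
            parc_dir = directory / "parcellations"
            parc_dir.mkdir(exist_ok=True)
            pl.to_tsv(parc_dir / f"{sp}.left.tsv")
            pr.to_tsv(parc_dir / f"{sp}.right.tsv")
        (directory / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2, default=float) + "\n"
        )


def generate_dataset(spec: SpeciesSpec) -> GeneratedDataset:
    """Tree, traits, meshes, parcellations and connectomes for one spec.

    All randomness derives from ``spec.seed`` through named sub-seeds, so
    regeneration from the recorded ground truth is bitwise identical.
    """
    tree = simulate_tree(spec.n_species, spec.birth_rate, seed=child_seed(spec.seed, 0))
    traits = simulate_traits(tree, spec, seed=child_seed(spec.seed, 1))

    log_v = np.log10(traits.column("cerebral_volume").to_numpy())
    u_all = (log_v - log_v.min()) / max(np.ptp(log_v), 1e-12)

    meshes, parcellations, centroids, connectomes = {}, {}, {}, {}
    per_species = {}
    for i, sp in enumerate(tree.leaf_labels):
        area = float(traits.column("cortical_surface_area")[sp])
        left, right = generate_hemisphere_pair(
            area, spec.ap_elongation, spec.mesh_subdivisions
        )
        parc_seed = child_seed(spec.seed, 2, i)
        parc_left = random_parcellation(left, spec.n_regions, seed=parc_seed)
        parc_right = project_contralateral(parc_left, left, right)
        cen_l = region_centroids(left, parc_left)
        cen_r = region_centroids(right, parc_right)
        ap = float(
            max(left.vertices[:, 1].max(), right.vertices[:, 1].max())
            - min(left.vertices[:, 1].min(), right.vertices[:, 1].min())
        )
        u = float(u_all[i])
        d0 = spec.rule_at(spec.decay_fraction, u) * ap
        dens = spec.rule_at(spec.density, u)
        asym = spec.rule_at(spec.asymmetry, u)
        conn_seed = child_seed(spec.seed, 3, i)
        conn = generate_connectome(
            cen_l,
            cen_r,
            ap_extent=ap,
            d0_mm=d0,
            target_density=dens,
            asymmetry_level=asym,
            seed=conn_seed,
            species=sp,
            weight_log_mu=spec.weight_log_mu,
            weight_log_sigma=spec.weight_log_sigma,
        )
        meshes[sp] = (left, right)
        parcellations[sp] = (parc_left, parc_right)
        centroids[sp] = (cen_l, cen_r)
        connectomes[sp] = conn
        per_species[sp] = {
            "ap_extent_mm": ap,
            "d0_mm": d0,
            "target_density": dens,
            "asymmetry_level": asym,
            "parcellation_seed": parc_seed,
            "connectome_seed": conn_seed,
        }

    ground_truth = {"spec": asdict(spec), "per_species": per_species}
    return GeneratedDataset(
        tree=tree,
        traits=traits,
        meshes=meshes,
        parcellations=parcellations,
        centroids=centroids,
        connectomes=connectomes,
        ground_truth=ground_truth,
    )
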