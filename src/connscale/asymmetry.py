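"""Homotopic connectivity asymmetry between the two hemispheres.

For a left-hemisphere region A and its spatial homolog A' on the right,
the connectivity profile of A is the vector of connection strengths from A
to the other left-hemisphere regions (and likewise for A', indexed through
the homolog mapping).  The pair's asymmetry score is the mean absolute
difference in connection strength over connections present in both
profiles; 0 means perfectly symmetric profiles.  Scores are averaged over
all homolog pairs with at least one shared connection to give a
species-level total.

Because raw NOS scales differ enormously across species, weights are first
resampled within each hemisphere to a common normal reference distribution
(mean 1, SD 0.2) by a rank-preserving quantile map, so the score reflects
relative weight structure only.  A permutation null (shuffling weights
among existing edges within each hemisphere) calibrates the association
between asymmetry and brain size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import Connectome
from .pgls import PGLSFit, fit_pgls, z_transform
from .phylo import PhyloTree


@dataclass
class AsymmetryConfig:
    target_mean: float = 1.0
    target_sd: float = 0.2
    mode: str = "weighted"  # or "binary" (presence/absence variant)
    n_permutations: int = 1000
    seed: int = 0
    resample: bool = True

    def __post_init__(self):
        if self.target_sd <= 0:
            raise ValueError("target SD must be positive")
        if self.n_permutations < 1:
            raise ValueError("permutation count must be >= 1")
        if self.mode not in ("weighted", "binary"):
            raise ValueError("mode must be 'weighted' or 'binary'")


@dataclass
class AsymmetryResult:
    pair_scores: pd.DataFrame  # columns: left_region, right_region, score, n_shared
    species_mean: float
    species: str
    config: AsymmetryConfig = field(repr=False, default=None)


def _hemisphere_edges(conn: Connectome, hemisphere: str) -> tuple[np.ndarray, np.ndarray]:
    idx = conn.hemisphere_nodes(hemisphere)
    sub = conn.weights[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), 1)
    present = sub[iu] > 0
    return idx, (iu[0][present], iu[1][present])


def resample_weights_to_normal(conn: Connectome, config: AsymmetryConfig | None = None) -> Connectome:
    """Rank-preserving quantile map of each hemisphere's weights onto N(M, SD).

    The k-th smallest of the m intrahemispheric edge weights becomes the
    normal quantile at (k − 0.5)/m.  Both hemispheres end with the same
    target moments; topology and within-hemisphere weight ranks are
    unchanged, and any common monotone rescaling of the inputs gives an
    identical result.
    """
    config = config or AsymmetryConfig()
    out = conn.copy()
    for hemisphere in ("left", "right"):
        idx, (ei, ej) = _hemisphere_edges(conn, hemisphere)
        m = len(ei)
        if m < 2:
            raise ValueError(f"{hemisphere} hemisphere has {m} edge(s); need >= 2 to resample")
        gi, gj = idx[ei], idx[ej]
        w = conn.weights[gi, gj]
        order = np.argsort(w, kind="stable")
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(m)
        new = config.target_mean + config.target_sd * stats.norm.ppf((ranks + 0.5) / m)
        out.weights[gi, gj] = new
        out.weights[gj, gi] = new
    return out


def pair_asymmetry(
    profile_a: np.ndarray,
    profile_aprime: np.ndarray,
    mode: str = "weighted",
) -> tuple[float | None, int]:
    """Asymmetry of two homologously indexed connectivity profiles.

    Weighted mode: mean |w_A(t) − w_A'(t')| over targets present in both
    profiles; returns ``(None, 0)`` when no connection is shared (the pair
    is then excluded from the species mean).  Binary mode: 1 − |shared| /
    |union| over present connections.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_aprime, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must be homologously indexed (same length)")
    present_a = a > 0
    present_b = b > 0
    shared = present_a & present_b
    n_shared = int(shared.sum())
    if mode == "binary":
        union = int((present_a | present_b).sum())
        if union == 0:
            return None, 0
        return 1.0 - n_shared / union, n_shared
    if n_shared == 0:
        return None, 0
    return float(np.abs(a[shared] - b[shared]).mean()), n_shared


def total_asymmetry(conn: Connectome, config: AsymmetryConfig | None = None) -> AsymmetryResult:
    """Mean asymmetry over all homolog region pairs of one species.

    Weights are resampled to the normal reference first (unless
    ``config.resample`` is False, for callers that already did).  Pairs
    with no shared connection are recorded with score NaN and excluded
    from the species mean.
    """
    config = config or AsymmetryConfig()
    work = resample_weights_to_normal(conn, config) if config.resample else conn

    left_nodes = work.hemisphere_nodes("left")
    pairs = work.homolog_pairs()
    homolog_of = dict(pairs)  # left node -> right node
    ids = work.regions["region"].to_numpy()

    rows = []
    for li, ri in pairs:
        targets_l = np.array([t for t in left_nodes if t != li])
        targets_r = np.array([homolog_of[t] for t in targets_l])
        prof_a = work.weights[li, targets_l]
        prof_b = work.weights[ri, targets_r]
        score, n_shared = pair_asymmetry(prof_a, prof_b, mode=config.mode)
        rows.append(
            {
                "left_region": ids[li],
                "right_region": ids[ri],
                "score": np.nan if score is None else score,
                "n_shared": n_shared,
            }
        )
    df = pd.DataFrame(rows)
    eligible = df["score"].dropna()
    if eligible.empty:
        raise ValueError("no homolog pair has a shared connection")
    return AsymmetryResult(
        pair_scores=df,
        species_mean=float(eligible.mean()),
        species=conn.species,
        config=config,
    )


def _shuffle_weights_within_hemispheres(conn: Connectome, rng: np.random.Generator) -> Connectome:
    """Permute edge weights among existing edges, per hemisphere; topology fixed."""
    out = conn.copy()
    for hemisphere in ("left", "right"):
        idx, (ei, ej) = _hemisphere_edges(conn, hemisphere)
        gi, gj = idx[ei], idx[ej]
        w = conn.weights[gi, gj]
        perm = rng.permutation(len(w))
        out.weights[gi, gj] = w[perm]
        out.weights[gj, gi] = w[perm]
    return out


@dataclass
class PermutationResult:
    observed_beta: float
    null_betas: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    observed_fit: PGLSFit = field(repr=False, default=None)


def asymmetry_permutation_test(
    connectomes: dict[str, Connectome],
    trait: dict[str, float],
    tree: PhyloTree,
    config: AsymmetryConfig | None = None,
) -> PermutationResult:
    """Permutation null for the asymmetry-vs-trait standardized PGLS slope.

    Each permutation shuffles connection weights among existing edges
    within each hemisphere of each species, recomputes every species'
    total asymmetry, and refits the z-transformed PGLS slope against the
    trait.  Empirical p = (1 + #{null ≥ observed}) / (1 + n_perm).
    """
    config = config or AsymmetryConfig()
    species = tree.leaf_labels
    if len(species) < 3:
        raise ValueError("permutation test requires >= 3 species")
    missing = set(species) - set(connectomes)
    if missing:
        raise ValueError(f"connectomes missing for species: {sorted(missing)}")

    trait_vec = np.array([trait[s] for s in species], dtype=float)
    x = z_transform(trait_vec)

    def beta_for(conns: dict[str, Connectome]) -> tuple[float, PGLSFit]:
        scores = np.array([total_asymmetry(conns[s], config).species_mean for s in species])
        fit = fit_pgls(z_transform(scores), x, tree=tree, lambda_mode="ml", transform="z")
        return fit.slope, fit

    observed, fit = beta_for(connectomes)
    rng = np.random.default_rng(config.seed)
    null_betas = np.empty(config.n_permutations)
    for k in range(config.n_permutations):
        shuffled = {
            s: _shuffle_weights_within_hemispheres(connectomes[s], rng) for s in species
        }
        null_betas[k], _ = beta_for(shuffled)
    if np.any(np.isnan(null_betas)):
        raise ValueError(
            f"only {np.count_nonzero(~np.isnan(null_betas))} of "
            f"{config.n_permutations} permutations completed"
        )
    p = (1 + int(np.sum(null_betas >= observed))) / (1 + config.n_permutations)
    return PermutationResult(
        observed_beta=observed,
        null_betas=null_betas,
        p_value=p,
        n_permutations=config.n_permutations,
        seed=config.seed,
        observed_fit=fit,
    )
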