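"""End-to-end comparative scaling pipeline.

Sequences the analysis stages in their methodological order: generate (or
load) data → parcellate → build connectomes → density → length-bin
distributions → density equalization → normalized network metrics →
connectivity asymmetry (with permutation null) → PGLS scaling fits.
Density equalization precedes path length, clustering and asymmetry but
not the density analysis itself.  Left and right hemispheres are analyzed
separately.  All outputs are tab-separated tables plus a JSON manifest
recording the configuration hash and every derived seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import AsymmetryConfig, asymmetry_permutation_test, total_asymmetry
from .connectome import (
    Connectome,
    equalize_density,
    length_bin_distribution,
    network_density,
    short_long_contrast,
)
from .metrics import NullModelConfig, normalized_metrics
from .pgls import PGLSFit, fit_pgls, z_transform
from .phylo import PhyloTree
from .synthetic import SpeciesSpec, child_seed, generate_dataset
from .traits import TraitTable

logger = logging.getLogger("connscale")

DEFAULT_TRAIT_PAIRS = [
    ("cortical_surface_area", "cerebral_volume"),
    ("white_matter_volume", "gray_matter_volume"),
    ("cortical_surface_area", "white_matter_volume"),
    ("cc_area", "cortical_surface_area"),
]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; hash + seed determine all outputs."""

    n_species: int = 14
    resolution: int = 50  # regions per hemisphere: 25 | 50 | 100
    bottleneck: bool = True
    n_nulls: int = 1000
    swaps_per_edge: int = 10
    n_permutations: int = 1000
    run_permutation_test: bool = True
    asymmetry_mean: float = 1.0
    asymmetry_sd: float = 0.2
    density_target: str | float = "min"
    output_dir: str = "connscale_output"
    seed: int = 0
    verbosity: int = 1
    # optional external inputs (otherwise the generator supplies them)
    tree_path: str | None = None
    traits_path: str | None = None
    connectome_dir: str | None = None

    def __post_init__(self):
        from .parcellation import SUPPORTED_RESOLUTIONS

        if self.resolution not in SUPPORTED_RESOLUTIONS:
            raise ValueError(
                f"parcellation resolution {self.resolution} not in {SUPPORTED_RESOLUTIONS}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScalingReport:
    trait_fits: pd.DataFrame
    fold_ranges: pd.DataFrame
    species_metrics: pd.DataFrame  # long format per species/hemisphere/metric
    metric_fits: pd.DataFrame  # standardized β per metric
    length_bins: pd.DataFrame  # species × 10 bins, ordered by cerebral volume
    permutation: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _fit_row(name_y: str, name_x: str, fit: PGLSFit) -> dict:
    return {
        "trait_y": name_y,
        "trait_x": name_x,
        "b": fit.slope,
        "ci_lo": fit.ci_low,
        "ci_hi": fit.ci_high,
        "r2_adj": fit.r2_adj,
        "lambda": fit.lam,
        "p": fit.p_value,
        "n": fit.n,
        "transform": fit.transform,
    }


def trait_scaling_summary(
    traits: TraitTable,
    tree: PhyloTree,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PGLS scaling exponents for trait pairs plus per-trait fold ranges.

    Both traits are log10-transformed so the slope is the allometric
    scaling exponent b.
    """
    pairs = pairs if pairs is not None else DEFAULT_TRAIT_PAIRS
    species = tree.leaf_labels
    table = traits.restrict(species)
    rows = []
    for trait_y, trait_x in pairs:
        y = np.log10(table.column(trait_y).to_numpy())
        x = np.log10(table.column(trait_x).to_numpy())
        fit = fit_pgls(y, x, tree=tree, lambda_mode="ml", transform="log10")
        rows.append(_fit_row(trait_y, trait_x, fit))
    folds = pd.DataFrame(
        {
            "trait": list(table.data.columns),
            "fold_range": [table.fold_range(c) for c in table.data.columns],
            "min": [table.column(c).min() for c in table.data.columns],
            "max": [table.column(c).max() for c in table.data.columns],
        }
    )
    return pd.DataFrame(rows), folds


def _metric_beta(values: np.ndarray, log_volume: np.ndarray, tree: PhyloTree) -> PGLSFit:
    if np.std(values, ddof=1) <= 1e-12 * max(abs(float(np.mean(values))), 1.0):
        # a metric constant across species has no association with size
        return PGLSFit(
            slope=0.0, intercept=0.0, slope_se=0.0, intercept_se=0.0,
            ci_low=np.nan, ci_high=np.nan, r2_adj=np.nan, lam=0.0,
            loglik=np.nan, p_value=np.nan, n=len(values), transform="z",
            degenerate_variance=True,
        )
    return fit_pgls(
        z_transform(values), z_transform(log_volume), tree=tree, lambda_mode="ml", transform="z"
    )


def run_pipeline(config: PipelineConfig, dataset=None) -> ScalingReport:
    """Execute every stage and write all tables under ``config.output_dir``."""
    level = logging.WARNING if config.verbosity == 0 else logging.INFO
    logging.basicConfig(stream=sys.stderr, level=level, format="%(asctime)s %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    def stage(name):
        logger.info("=== stage: %s ===", name)

    try:
        stage("generate/load")
        if dataset is None:
            paths = (config.tree_path, config.traits_path, config.connectome_dir)
            if any(paths) and not all(paths):
                raise ValueError(
                    "file-based input needs tree_path, traits_path and connectome_dir together"
                )
            if all(paths):
                tree = PhyloTree.from_newick(Path(config.tree_path).read_text())
                traits = TraitTable.from_tsv(config.traits_path)
                connectomes = {
                    sp: Connectome.read(config.connectome_dir, sp) for sp in tree.leaf_labels
                }
            else:
                spec_cls = SpeciesSpec if config.bottleneck else SpeciesSpec.bottleneck_off
                spec = spec_cls(
                    n_species=config.n_species,
                    n_regions=config.resolution,
                    seed=child_seed(config.seed, 10),
                )
                dataset = generate_dataset(spec)
                tree, traits, connectomes = dataset.tree, dataset.traits, dataset.connectomes
        else:
            tree, traits, connectomes = dataset.tree, dataset.traits, dataset.connectomes
        species = tree.leaf_labels
        log_volume = np.log10(traits.restrict(species).column("cerebral_volume").to_numpy())
        volume_order = [species[i] for i in np.argsort(log_volume)]

        stage("density and connection lengths")
        metric_rows = []
        bin_rows = {}
        for sp in species:
            conn = connectomes[sp]
            for hemi in ("left", "right"):
                metric_rows.append(
                    {"species": sp, "hemisphere": hemi, "metric": "density",
                     "raw": network_density(conn, hemi), "null_mean": np.nan,
                     "null_sd": np.nan, "normalized": np.nan, "n_nulls": 0, "seed": config.seed}
                )
            bins = length_bin_distribution(conn)
            bin_rows[sp] = bins.proportions
            short, _ = short_long_contrast(bins)
            metric_rows.append(
                {"species": sp, "hemisphere": "both", "metric": "short_proportion",
                 "raw": short, "null_mean": np.nan, "null_sd": np.nan,
                 "normalized": np.nan, "n_nulls": 0, "seed": config.seed}
            )
        length_bins = pd.DataFrame(
            {sp: bin_rows[sp] for sp in volume_order},
            index=pd.Index(range(1, 11), name="bin"),
        ).T

        stage("density equalization")
        eq_list = equalize_density([connectomes[sp] for sp in species], config.density_target)
        equalized = dict(zip(species, eq_list))

        stage("network metrics with rewired nulls")
        for si, sp in enumerate(species):
            for hi, hemi in enumerate(("left", "right")):
                adj = equalized[sp].hemisphere_adjacency(hemi)
                null_seed = child_seed(config.seed, 20, si, hi)
                results = normalized_metrics(
                    adj,
                    NullModelConfig(
                        n_reference=config.n_nulls,
                        swaps_per_edge=config.swaps_per_edge,
                        seed=null_seed,
                    ),
                    scope=hemi,
                )
                for name, r in results.items():
                    metric_rows.append(
                        {"species": sp, "hemisphere": hemi, "metric": name,
                         "raw": r.raw, "null_mean": r.null_mean, "null_sd": r.null_sd,
                         "normalized": r.normalized, "n_nulls": r.n_nulls, "seed": null_seed}
                    )

        stage("connectivity asymmetry")
        asym_config = AsymmetryConfig(
            target_mean=config.asymmetry_mean,
            target_sd=config.asymmetry_sd,
            n_permutations=config.n_permutations,
            seed=child_seed(config.seed, 30),
        )
        for sp in species:
            res = total_asymmetry(equalized[sp], asym_config)
            excluded = int(res.pair_scores["score"].isna().sum())
            if excluded:
                warnings_log.append(f"{sp}: {excluded} homolog pair(s) without shared connections excluded")
            metric_rows.append(
                {"species": sp, "hemisphere": "both", "metric": "asymmetry",
                 "raw": res.species_mean, "null_mean": np.nan, "null_sd": np.nan,
                 "normalized": np.nan, "n_nulls": 0, "seed": asym_config.seed}
            )

        species_metrics = pd.DataFrame(metric_rows)

        stage("PGLS scaling fits")
        trait_fits, fold_ranges = trait_scaling_summary(traits, tree)
        fit_rows = []
        def metric_vector(metric, hemi):
            sub = species_metrics[
                (species_metrics["metric"] == metric) & (species_metrics["hemisphere"] == hemi)
            ].set_index("species")
            col = "normalized" if metric in ("path_length", "clustering") else "raw"
            return np.array([sub.loc[sp, col] for sp in species])

        for metric, hemis in [
            ("density", ("left", "right")),
            ("short_proportion", ("both",)),
            ("path_length", ("left", "right")),
            ("clustering", ("left", "right")),
            ("asymmetry", ("both",)),
        ]:
            for hemi in hemis:
                fit = _metric_beta(metric_vector(metric, hemi), log_volume, tree)
                row = _fit_row(f"{metric}[{hemi}]", "log10_cerebral_volume", fit)
                row["metric"], row["hemisphere"] = metric, hemi
                fit_rows.append(row)
        metric_fits = pd.DataFrame(fit_rows)

        permutation = {}
        if config.run_permutation_test:
            stage("asymmetry permutation null")
            perm = asymmetry_permutation_test(
                equalized,
                dict(zip(species, log_volume)),
                tree,
                asym_config,
            )
            permutation = {
                "observed_beta": perm.observed_beta,
                "p": perm.p_value,
                "n_perm": perm.n_permutations,
                "seed": perm.seed,
            }
            pd.DataFrame(
                {"perm_index": np.arange(1, len(perm.null_betas) + 1),
                 "null_slope": perm.null_betas}
            ).to_csv(out / "asymmetry_permutations.tsv", sep="\t", index=False)

        stage("write report")
        trait_fits.to_csv(out / "trait_scaling.tsv", sep="\t", index=False)
        fold_ranges.to_csv(out / "fold_ranges.tsv", sep="\t", index=False)
        species_metrics.to_csv(out / "species_metrics.tsv", sep="\t", index=False)
        metric_fits.to_csv(out / "metric_scaling.tsv", sep="\t", index=False)
        length_bins.to_csv(out / "length_bins.tsv", sep="\t", index_label="species")
        manifest = {
            "package_version": __version__,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "master_seed": config.seed,
            "n_species": len(species),
            "warnings": warnings_log,
            "permutation": permutation,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        return ScalingReport(
            trait_fits=trait_fits,
            fold_ranges=fold_ranges,
            species_metrics=species_metrics,
            metric_fits=metric_fits,
            length_bins=length_bins,
            permutation=permutation,
            manifest=manifest,
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        logger.error("pipeline aborted: %s", exc)
        raise
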