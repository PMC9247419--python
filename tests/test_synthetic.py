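import numpy as np
import pytest

from connscale import (
    SpeciesSpec,
    fit_pgls,
    generate_connectome,
    generate_dataset,
    generate_hemisphere_mesh,
    generate_hemisphere_pair,
    length_bin_distribution,
    network_density,
    short_long_contrast,
    simulate_traits,
    simulate_tree,
    total_asymmetry,
)
from connscale.parcellation import project_contralateral, random_parcellation, region_centroids


class TestSimulateTree:
    def test_ultrametric_with_requested_taxa(self):
        tree = simulate_tree(14, seed=0)
        assert tree.n_leaves == 14
        assert tree.is_ultrametric(tol=1e-9)

    def test_deterministic_newick(self):
        assert simulate_tree(10, seed=5).to_newick() == simulate_tree(10, seed=5).to_newick()
        assert simulate_tree(10, seed=5).to_newick() != simulate_tree(10, seed=6).to_newick()

    def test_two_taxa_cherry(self):
        tree = simulate_tree(2, seed=1)
        assert tree.n_leaves == 2
        assert tree.is_ultrametric()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)
        with pytest.raises(ValueError):
            simulate_tree(5, birth_rate=0.0, seed=0)


class TestSimulateTraits:
    def test_zero_noise_recovers_exponents_exactly(self):
        tree = simulate_tree(14, seed=2)
        spec = SpeciesSpec(noise_sd_fraction=0.0, seed=2)
        traits = simulate_traits(tree, spec)
        cases = [
            ("cortical_surface_area", "cerebral_volume", spec.exponent_surface_volume),
            ("white_matter_volume", "gray_matter_volume", spec.exponent_wm_gm),
            ("cc_area", "cortical_surface_area", spec.exponent_cc_surface),
        ]
        for trait_y, trait_x, expected in cases:
            y = np.log10(traits.column(trait_y).to_numpy())
            x = np.log10(traits.column(trait_x).to_numpy())
            fit = fit_pgls(y, x, tree=tree, lambda_mode="fixed", lam=0.0)
            assert fit.slope == pytest.approx(expected, abs=1e-8)
            assert fit.degenerate_variance

    def test_volume_spans_requested_range(self):
        tree = simulate_tree(20, seed=3)
        spec = SpeciesSpec(n_species=20, volume_range_cm3=(2.5, 900.0), seed=3)
        traits = simulate_traits(tree, spec)
        v = traits.column("cerebral_volume")
        assert v.min() == pytest.approx(2.5)
        assert v.max() == pytest.approx(900.0)
        assert (traits.data > 0).all().all()


class TestHemisphereMesh:
    def test_requested_area_achieved(self):
        mesh = generate_hemisphere_mesh(250.0, subdivisions=3)
        assert abs(mesh.surface_area() - 250.0 * 100) / (250.0 * 100) < 0.005

    def test_icosphere_vertex_count(self):
        # 10·4^n + 2 vertices for an n-times subdivided icosphere
        assert generate_hemisphere_mesh(100.0, subdivisions=3).n_vertices == 642
        assert generate_hemisphere_mesh(100.0, subdivisions=2).n_vertices == 162

    def test_mirror_pair_differs_only_in_x_sign(self):
        left, right = generate_hemisphere_pair(200.0, subdivisions=2)
        flipped = left.vertices.copy()
        flipped[:, 0] *= -1
        assert np.allclose(right.vertices[right.mirror_index], flipped)
        assert left.euler_characteristic() == 2
        assert right.euler_characteristic() == 2

    def test_ap_axis_is_longest(self):
        mesh = generate_hemisphere_mesh(100.0, ap_elongation=1.6, subdivisions=2)
        extents = np.ptp(mesh.vertices, axis=0)
        assert extents[1] == max(extents)


@pytest.fixture(scope="module")
def geometry():
    left, right = generate_hemisphere_pair(150.0, subdivisions=3)
    parc = random_parcellation(left, 50, seed=0)
    proj = project_contralateral(parc, left, right)
    cl = region_centroids(left, parc)
    cr = region_centroids(right, proj)
    ap = float(np.ptp(left.vertices[:, 1]))
    return cl, cr, ap


class TestGenerateConnectome:

    def test_mirror_when_asymmetry_zero(self, geometry):
        cl, cr, ap = geometry
        conn = generate_connectome(cl, cr, ap, d0_mm=0.3 * ap, target_density=0.4,
                                   asymmetry_level=0.0, seed=1)
        assert total_asymmetry(conn).species_mean == 0.0

    @pytest.mark.parametrize("target", [0.3, 0.45, 0.6])
    def test_density_calibration(self, geometry, target):
        cl, cr, ap = geometry
        conn = generate_connectome(cl, cr, ap, d0_mm=0.25 * ap, target_density=target,
                                   asymmetry_level=0.1, seed=2)
        for hemi in ("left", "right"):
            assert abs(network_density(conn, hemi) - target) <= 0.02

    def test_stronger_decay_shifts_mass_to_short_bins(self, geometry):
        """Mean bins-1-2 proportion grows as the decay length shrinks.

        At fixed density the selection saturates for very strong decay
        (the network approaches the k-shortest-pairs graph), so adjacent
        decay settings are weakly ordered and the extremes strictly.
        """
        cl, cr, ap = geometry
        shorts = []
        for d0_frac in (0.4, 0.2, 0.1):
            vals = []
            for seed in range(20):
                conn = generate_connectome(cl, cr, ap, d0_mm=d0_frac * ap,
                                           target_density=0.35, asymmetry_level=0.0, seed=seed)
                short, _ = short_long_contrast(length_bin_distribution(conn))
                vals.append(short)
            shorts.append(np.mean(vals))
        assert shorts[0] <= shorts[1] <= shorts[2] + 1e-9
        assert shorts[0] < shorts[2]

    def test_unreachable_density_rejected(self, geometry):
        cl, cr, ap = geometry
        with pytest.raises(ValueError):
            generate_connectome(cl, cr, ap, d0_mm=0.3 * ap, target_density=1.5,
                                asymmetry_level=0.0, seed=0)

    def test_deterministic_per_seed(self, geometry):
        cl, cr, ap = geometry
        a = generate_connectome(cl, cr, ap, d0_mm=0.3 * ap, target_density=0.4,
                                asymmetry_level=0.2, seed=7)
        b = generate_connectome(cl, cr, ap, d0_mm=0.3 * ap, target_density=0.4,
                                asymmetry_level=0.2, seed=7)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.lengths, b.lengths)


@pytest.fixture(scope="module")
def small_spec():
    return SpeciesSpec(n_species=5, n_regions=15, mesh_subdivisions=2, seed=4)


class TestGenerateDataset:

    def test_components_consistent(self, small_spec):
        ds = generate_dataset(small_spec)
        assert set(ds.connectomes) == set(ds.species) == set(ds.traits.species)
        for sp in ds.species:
            assert ds.connectomes[sp].n_regions == 2 * small_spec.n_regions

    def test_regeneration_is_bitwise_identical(self, small_spec):
        ds1 = generate_dataset(small_spec)
        ds2 = generate_dataset(SpeciesSpec(**ds1.ground_truth["spec"]))
        assert ds1.tree.to_newick() == ds2.tree.to_newick()
        assert ds1.traits.data.equals(ds2.traits.data)
        for sp in ds1.species:
            assert np.array_equal(ds1.connectomes[sp].weights, ds2.connectomes[sp].weights)
            assert np.array_equal(ds1.connectomes[sp].lengths, ds2.connectomes[sp].lengths)

    def test_written_dataset_loads_back(self, small_spec, tmp_path):
        from connscale import Connectome, PhyloTree, TraitTable

        ds = generate_dataset(small_spec)
        ds.write(tmp_path / "study")
        tree = PhyloTree.from_newick((tmp_path / "study" / "tree.nwk").read_text())
        assert sorted(tree.leaf_labels) == sorted(ds.species)
        traits = TraitTable.from_tsv(tmp_path / "study" / "traits.tsv")
        assert np.allclose(traits.data.to_numpy(), ds.traits.data.to_numpy())
        sp = ds.species[0]
        conn = Connectome.read(tmp_path / "study" / "connectomes", sp)
        assert np.allclose(conn.weights, ds.connectomes[sp].weights)
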