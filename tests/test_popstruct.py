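import itertools

import dendropy
import numpy as np
import pytest

from soyepi import popstruct as ps
from tests.conftest import make_genotypes


class TestIBS:
    def test_duplicated_sample_has_similarity_one(self):
        G = make_genotypes([[0, 1, 2, 1], [0, 1, 2, 1]])
        ibs, dist = ps.ibs_matrix(G)
        assert ibs[0, 1] == 1.0
        assert dist.values[0, 1] == 0.0

    def test_opposite_homozygotes_have_similarity_zero(self):
        G = make_genotypes([[0, 0, 0], [2, 2, 2]])
        ibs, _ = ps.ibs_matrix(G)
        assert ibs[0, 1] == 0.0

    def test_hand_case(self):
        # per-locus shared-allele fractions: 1, 0, 1, 0.5 -> mean 0.625
        G = make_genotypes([[0, 2, 1, 1], [0, 0, 1, 2]])
        ibs, _ = ps.ibs_matrix(G)
        assert ibs[0, 1] == pytest.approx(0.625)

    def test_ibs_plus_normalized_manhattan_is_one(self):
        rng = np.random.default_rng(0)
        G = make_genotypes(rng.integers(0, 3, size=(6, 40)))
        ibs, _ = ps.ibs_matrix(G)
        manhattan = np.abs(
            G.dosages[:, None, :].astype(int) - G.dosages[None, :, :]
        ).sum(axis=2) / (2.0 * G.n_markers)
        assert np.allclose(ibs + manhattan, 1.0)


class TestK2P:
    def test_identical_samples_have_zero_distance(self):
        G = make_genotypes([[0, 2, 0], [0, 2, 0]])
        d = ps.k2p_distance(G)
        assert d.values[0, 1] == 0.0

    def test_transversion_only_closed_form(self):
        # 20 compared homozygous sites, 2 transversion differences: Q = 0.1
        dosages = np.zeros((2, 20), dtype=int)
        dosages[1, :2] = 2
        G = make_genotypes(dosages, refs=["A"] * 20, alts=["C"] * 20)
        d = ps.k2p_distance(G)
        expected = -0.5 * np.log(0.9 * np.sqrt(0.8))
        assert d.values[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_transition_only_closed_form(self):
        # 20 compared sites, 1 transition difference: P = 0.05
        dosages = np.zeros((2, 20), dtype=int)
        dosages[1, 0] = 2
        G = make_genotypes(dosages, refs=["A"] * 20, alts=["G"] * 20)
        d = ps.k2p_distance(G)
        assert d.values[0, 1] == pytest.approx(-0.5 * np.log(0.9), rel=1e-12)

    def test_heterozygous_sites_excluded_from_comparison(self):
        # het at site 0 for sample 1: only site 1 compared, identical there
        G = make_genotypes([[0, 2], [1, 2]])
        assert ps.k2p_distance(G).values[0, 1] == 0.0

    def test_saturation_capped_with_warning(self):
        dosages = np.zeros((2, 4), dtype=int)
        dosages[1] = 2  # every compared site differs by transversion: Q = 1
        G = make_genotypes(dosages, refs=["A"] * 4, alts=["C"] * 4)
        with pytest.warns(UserWarning, match="saturated"):
            d = ps.k2p_distance(G, saturation_cap=7.5)
        assert d.values[0, 1] == 7.5


class TestClassicalMDS:
    def test_exact_triangle_reconstruction(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, explained = ps.pca_from_distance(
            ps.DistanceMatrix(["a", "b", "c"], D), n_components=2
        )
        recon = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(recon, D, atol=1e-9)
        assert explained.sum() == pytest.approx(1.0)

    def test_identical_samples_share_coordinates(self):
        D = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.warns(UserWarning):
            coords, _ = ps.pca_from_distance(ps.DistanceMatrix(list("abc"), D), 2)
        assert np.allclose(coords[0], coords[1])

    def test_truncation_warning_when_components_exceed_rank(self):
        pts = np.array([[0.0], [1.0], [2.0], [5.0]])
        D = np.abs(pts - pts.T)
        with pytest.warns(UserWarning, match="truncating"):
            coords, _ = ps.pca_from_distance(ps.DistanceMatrix(list("abcd"), D), 4)
        assert coords.shape[1] < 4


class TestBIONJ:
    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        newick = ps.bionj_tree(ps.DistanceMatrix(["a", "b", "c"], D))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)  # = 1
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)  # = 2
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)  # = 3

    def test_additive_four_taxon_tree_recovered_exactly(self):
        # distances additive on ((A:1,B:2):0.5,(C:3,D:4))
        names = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0.0, 3.0, 4.5, 5.5],
                [3.0, 0.0, 5.5, 6.5],
                [4.5, 5.5, 0.0, 7.0],
                [5.5, 6.5, 7.0, 0.0],
            ]
        )
        newick = ps.bionj_tree(ps.DistanceMatrix(names, D))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for a, b in itertools.combinations(names, 2):
            patristic = pdm.patristic_distance(taxa[a], taxa[b])
            assert patristic == pytest.approx(
                D[names.index(a), names.index(b)], abs=1e-9
            )

    def test_zero_distance_pair_are_siblings(self):
        names = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0.0, 0.0, 2.0, 3.0],
                [0.0, 0.0, 2.0, 3.0],
                [2.0, 2.0, 0.0, 3.0],
                [3.0, 3.0, 3.0, 0.0],
            ]
        )
        newick = ps.bionj_tree(ps.DistanceMatrix(names, D))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
        assert leaves["A"].parent_node is leaves["B"].parent_node
        assert leaves["A"].edge.length == pytest.approx(0.0)
        assert leaves["B"].edge.length == pytest.approx(0.0)


class TestLDDecay:
    def test_perfect_correlation_and_anticorrelation(self):
        g = np.array([0, 0, 1, 2, 2, 1, 0, 2])
        G = make_genotypes(
            np.column_stack([g, g, 2 - g]), positions=[100, 101, 102]
        )
        curve = ps.ld_decay(G, max_distance=10, bin_width=10)
        assert curve.mean_r2[0] == pytest.approx(1.0)
        assert curve.pair_counts[0] == 3

    def test_matches_naive_pearson(self):
        a = np.array([0, 0, 1, 2, 2])
        b = np.array([0, 1, 1, 2, 0])
        G = make_genotypes(np.column_stack([a, b]), positions=[100, 200])
        curve = ps.ld_decay(G, max_distance=1000, bin_width=1000)
        r = np.corrcoef(a, b)[0, 1]
        assert curve.mean_r2[0] == pytest.approx(r ** 2, rel=1e-12)

    def test_monomorphic_pairs_skipped_and_counted(self):
        a = np.array([0, 1, 2, 1])
        mono = np.zeros(4, dtype=int)
        G = make_genotypes(np.column_stack([a, mono]), positions=[100, 200])
        curve = ps.ld_decay(G, max_distance=1000, bin_width=1000)
        assert curve.pair_counts.sum() == 0
        assert curve.n_skipped_monomorphic == 1

    def test_cross_chromosome_pairs_excluded(self):
        rng = np.random.default_rng(1)
        G = make_genotypes(
            rng.integers(0, 3, size=(10, 2)),
            chromosomes=["Chr01", "Chr02"],
            positions=[100, 120],
        )
        curve = ps.ld_decay(G, max_distance=1000, bin_width=1000)
        assert curve.pair_counts.sum() == 0


class TestPiWindows:
    def test_monomorphic_window_is_zero(self):
        G = make_genotypes(np.zeros((4, 3), dtype=int), positions=[10, 20, 30])
        windows = ps.pi_windows(G, window_size=100, window_step=100)
        assert windows[0].value == 0.0

    def test_single_site_hand_value(self):
        # 50 diploids, allele counts 50/50 at one site, 100 kb window:
        # pi = (50*50/4950)/100000
        dosages = np.zeros((50, 2), dtype=int)
        dosages[:25, 0] = 2
        dosages[:, 1] = 2  # second site monomorphic, defines chromosome span
        G = make_genotypes(dosages, positions=[500, 100_000])
        windows = ps.pi_windows(G, window_size=100_000, window_step=100_000)
        expected = (50 * 50 / 4950) / 100_000
        assert windows[0].value == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(5.0505e-6, rel=1e-4)

    def test_doubling_window_halves_single_site_density(self):
        dosages = np.zeros((10, 2), dtype=int)
        dosages[:5, 0] = 2
        G = make_genotypes(dosages, positions=[500, 200_000])
        w1 = ps.pi_windows(G, window_size=100_000, window_step=100_000)
        w2 = ps.pi_windows(G, window_size=200_000, window_step=200_000)
        assert w2[0].value == pytest.approx(w1[0].value / 2)

    def test_windows_advance_by_step(self):
        G = make_genotypes(np.zeros((4, 2), dtype=int), positions=[1, 250_000])
        windows = ps.pi_windows(G, window_size=100_000, window_step=10_000)
        starts = [w.start for w in windows]
        assert starts[:3] == [1, 10_001, 20_001]
        assert all(
            w.end - w.start + 1 == 100_000 for w in windows if not w.truncated
        )


class TestInbreeding:
    def test_fully_homozygous_sample_has_f_one(self):
        dosages = np.array([[0, 2, 0, 2], [0, 1, 1, 2], [2, 1, 0, 0], [0, 1, 2, 1]])
        f = ps.inbreeding_f(make_genotypes(dosages))
        assert f[0] == pytest.approx(1.0)

    def test_heterozygous_everywhere_gives_negative_f(self):
        # frequencies 0.5 at both sites
        dosages = np.array([[1, 1], [0, 0], [2, 2], [1, 1]])
        f = ps.inbreeding_f(make_genotypes(dosages))
        assert f[0] < 0

    def test_hand_case_matches_direct_arithmetic(self):
        dosages = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 0], [0, 2, 2]])
        f = ps.inbreeding_f(make_genotypes(dosages))
        # independent spreadsheet-style evaluation
        n2 = 8
        p = dosages.sum(axis=0) / n2
        e_site = 1 - 2 * p * (1 - p) * n2 / (n2 - 1)
        e_hom = e_site.sum()
        for i in range(4):
            o_hom = np.sum(dosages[i] != 1)
            assert f[i] == pytest.approx((o_hom - e_hom) / (3 - e_hom))


class TestFst:
    def test_fixed_difference_gives_fst_one(self):
        dosages = np.vstack([np.zeros((3, 1)), np.full((3, 1), 2)]).astype(int)
        G = make_genotypes(dosages)
        labels = np.array(["g1"] * 3 + ["g2"] * 3)
        _, genome = ps.fst_windows(G, labels)
        assert genome == pytest.approx(1.0)

    def test_identical_groups_give_nonpositive_fst(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 3, size=(5, 50))
        G = make_genotypes(np.vstack([block, block]))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        _, genome = ps.fst_windows(G, labels)
        assert genome <= 0.0

    def test_requires_exactly_two_groups(self):
        G = make_genotypes(np.zeros((4, 2), dtype=int))
        with pytest.raises(ValueError):
            ps.fst_windows(G, np.array(["a", "b", "c", "a"]))

    def test_balding_nichols_simulation_recovers_target(self, structured_panel):
        G, _, labels, spec = structured_panel
        _, genome = ps.fst_windows(G, labels)
        assert abs(genome - spec.target_fst) < 0.02
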