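"""Overlap matrices, NMI, modular spectra, group distances, dendrograms."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesoconn import (
    GroupSpectrum,
    Partition,
    group_distance_matrices,
    group_spectrum,
    modular_distance,
    module_summary,
    nmi,
    overlap_matrix,
)
from mesoconn.compare import dendrogram_path_lengths, linkage_to_newick

from conftest import make_net


class TestOverlapMatrix:
    def test_groups_identical_to_modules_is_diagonal(self):
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        ov = overlap_matrix(p, p)
        assert np.allclose(ov.counts.values, np.diag([2, 2]))

    def test_crossed_partitions_all_ones(self):
        p1 = {"g1": {"a", "b"}, "g2": {"c", "d"}}
        p2 = Partition({"a": 0, "c": 0, "b": 1, "d": 1})
        ov = overlap_matrix(p1, p2)
        assert np.allclose(ov.counts.values, 1)

    def test_row_sums_are_group_sizes(self, synth_bundle):
        net, planted = synth_bundle["net"], synth_bundle["planted"]
        groups = net.ganglia()
        ov = overlap_matrix(groups, planted)
        for g, members in groups.items():
            assert ov.row_sums[g] == len(members)

    def test_unknown_member_listed(self):
        p = Partition({"a": 0})
        with pytest.raises(ValueError, match="zz"):
            overlap_matrix({"g": {"zz"}}, p)


class TestNMI:
    def test_self_comparison_is_one(self, synth_bundle):
        p = synth_bundle["planted"]
        assert nmi(p, p) == pytest.approx(1.0, abs=1e-12)

    def test_independent_partitions_zero(self):
        p1 = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        p2 = Partition({"a": 0, "c": 0, "b": 1, "d": 1})
        assert nmi(p1, p2) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(7)
        nodes = [f"n{i}" for i in range(30)]
        p1 = Partition({n: int(rng.integers(3)) for n in nodes})
        p2 = Partition({n: int(rng.integers(4)) for n in nodes})
        assert nmi(p1, p2) == pytest.approx(nmi(p2, p1), abs=1e-12)
        shuffled = Partition({n: (p2.assignment[n] + 2) % 4 for n in nodes})
        assert nmi(p1, shuffled) == pytest.approx(nmi(p1, p2), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_sklearn_arithmetic_nmi(self, seed):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(50)]
        a = {n: int(rng.integers(4)) for n in nodes}
        b = {n: int(rng.integers(3)) for n in nodes}
        expected = sklearn_metrics.normalized_mutual_info_score(
            [a[n] for n in nodes], [b[n] for n in nodes], average_method="arithmetic"
        )
        assert nmi(Partition(a), Partition(b)) == pytest.approx(expected, abs=1e-10)

    def test_degenerate_single_block(self):
        one = Partition({"a": 0, "b": 0, "c": 0})
        split = Partition({"a": 0, "b": 1, "c": 1})
        assert nmi(one, split) == 0.0
        assert nmi(one, one) == 1.0


class TestSpectra:
    def test_group_inside_one_module(self):
        p = Partition({"a": 0, "b": 1, "c": 2, "d": 1})
        s = group_spectrum({"b", "d"}, p)
        assert np.allclose(s.fractions, [0, 1, 0])

    def test_three_to_one_split(self):
        p = Partition({c: 0 for c in "abc"} | {"d": 1, "e": 2})
        s = group_spectrum({"a", "b", "c", "d"}, p)
        assert np.allclose(s.fractions, [0.75, 0.25, 0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_spectrum(set(), Partition({"a": 0}))

    def test_distance_identical_and_orthogonal(self):
        s1 = GroupSpectrum("x", np.array([1.0, 0.0]), 3)
        s2 = GroupSpectrum("y", np.array([0.0, 1.0]), 3)
        assert modular_distance(s1, s1) == 0.0
        assert modular_distance(s1, s2) == pytest.approx(np.sqrt(2))
        with pytest.raises(ValueError):
            modular_distance(s1, GroupSpectrum("z", np.array([1.0]), 1))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
            min_size=3,
            max_size=3,
        )
    )
    def test_triangle_inequality(self, raw):
        specs = [
            GroupSpectrum(str(i), np.array(v) / np.sum(v), 1)
            for i, v in enumerate(raw)
        ]
        d01 = modular_distance(specs[0], specs[1])
        d12 = modular_distance(specs[1], specs[2])
        d02 = modular_distance(specs[0], specs[2])
        assert d02 <= d01 + d12 + 1e-12


class TestModuleSummary:
    def test_two_cliques(self):
        edges = [(a, b, 1) for a in "abc" for b in "abc" if a < b]
        edges += [(a, b, 1) for a in "def" for b in "def" if a < b]
        net = make_net(undirected_edges=edges)
        p = Partition.from_modules([set("abc"), set("def")])
        dens, comp = module_summary(net, p)
        assert np.allclose(np.diag(dens), 1.0)
        assert np.allclose(dens.values - np.diag(np.diag(dens)), 0.0)
        assert comp.values.sum() == 6

    def test_planted_densities_match_generator(self, synth_bundle):
        net, planted, params = (
            synth_bundle["net"],
            synth_bundle["planted"],
            synth_bundle["params"],
        )
        dens, _ = module_summary(net, planted)
        sizes = {m: len(v) for m, v in planted.modules().items()}
        for a in dens.index:
            for b in dens.columns:
                p_exp = params.p_in if a == b else params.p_out
                n_pairs = (
                    sizes[a] * (sizes[a] - 1) if a == b else sizes[a] * sizes[b]
                )
                sd = np.sqrt(p_exp * (1 - p_exp) / n_pairs)
                assert abs(dens.loc[a, b] - p_exp) < 3 * sd + 1e-9

    def test_diagonal_exceeds_global_density_on_modular_net(self, synth_bundle):
        net, planted = synth_bundle["net"], synth_bundle["planted"]
        dens, _ = module_summary(net, planted)
        n = net.n_nodes
        global_density = net.L / (n * (n - 1))
        assert (np.diag(dens) > global_density).all()


class TestGroupDistances:
    def test_identical_spectra_merge_first(self):
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1, "e": 1, "f": 0})
        # g1 and g2 both have spectrum (1/2, 1/2); g3 = {e} is (0, 1)
        groups = {"g1": {"a", "c"}, "g2": {"b", "d"}, "g3": {"e"}}
        pos = {n: i / 6 for i, n in enumerate("abcdef")}
        gd = group_distance_matrices(groups, p, pos)
        assert gd.modular.loc["g1", "g2"] == 0.0
        # zero-distance pair merges first: path length between them is 2
        paths = dendrogram_path_lengths(gd.modular_linkage, 3)
        i, j = gd.labels.index("g1"), gd.labels.index("g2")
        assert paths[i, j] == 2

    def test_hand_built_spectra_distances(self):
        p = Partition(
            {"a": 0, "b": 0, "c": 1, "d": 1, "e": 2, "f": 2, "g": 0, "h": 1}
        )
        groups = {"G1": {"a", "b"}, "G2": {"c", "d"}, "G3": {"e", "g"}}
        pos = {n: 0.1 * i for i, n in enumerate("abcdefgh")}
        gd = group_distance_matrices(groups, p, pos)
        # spectra: G1=(1,0,0), G2=(0,1,0), G3=(.5,0,.5)
        assert gd.modular.loc["G1", "G2"] == pytest.approx(np.sqrt(2))
        assert gd.modular.loc["G1", "G3"] == pytest.approx(np.sqrt(0.5))
        assert gd.modular.loc["G2", "G3"] == pytest.approx(np.sqrt(1.5))

    def test_physical_distance_is_mean_abs_position_difference(self):
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        groups = {"x": {"a", "b"}, "y": {"c", "d"}}
        pos = {"a": 0.0, "b": 0.2, "c": 0.6, "d": 1.0}
        gd = group_distance_matrices(groups, p, pos)
        expected = np.mean([0.6, 1.0, 0.4, 0.8])
        assert gd.physical.loc["x", "y"] == pytest.approx(expected)

    def test_newick_parses_with_four_leaves(self, synth_bundle):
        dendropy = pytest.importorskip("dendropy")
        p = synth_bundle["planted"]
        groups = {
            f"g{i}": members
            for i, members in enumerate(
                np.array_split(sorted(p.assignment), 4)
            )
        }
        pos = {n: 0.01 * i for i, n in enumerate(sorted(p.assignment))}
        gd = group_distance_matrices(groups, p, pos)
        tree = dendropy.Tree.get(data=gd.newick("modular"), schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == sorted(groups)

    def test_empty_group_rejected(self):
        p = Partition({"a": 0, "b": 1})
        with pytest.raises(ValueError):
            group_distance_matrices({"g": set()}, p, {"a": 0, "b": 1})


def test_linkage_to_newick_singleton_free():
    import scipy.cluster.hierarchy as sch
    import scipy.spatial.distance as ssd

    d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
    z = sch.linkage(ssd.squareform(d), method="average")
    nwk = linkage_to_newick(z, ["a", "b", "c"])
    assert nwk.count("(") == 2 and nwk.endswith(";")
    paths = dendrogram_path_lengths(z, 3)
    assert paths[0, 1] == 2 and paths[0, 2] == 3
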