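import math

import numpy as np
import pytest

from msnsim import morphology as M


@pytest.fixture()
def synthetic_tree():
    return M.build_synthetic_morphology()


class TestSwcIO:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 8 -1\n2 3 10 0 0 1 1\n3 3 20 0 0 1 2\n")
        tree = M.read_swc(p)
        assert len(tree.nodes) == 3
        assert tree.root.label == "soma"
        assert tree.node(3).parent_id == 2

    def test_orphan_node_rejected(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 8 -1\n2 3 10 0 0 1 99\n")
        with pytest.raises(M.MorphologyError, match="missing parent"):
            M.read_swc(p)

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 8 -1\n2 3 ten 0 0 1 1\n")
        with pytest.raises(M.SwcParseError, match="line 2"):
            M.read_swc(p)

    def test_roundtrip_lossless(self, tmp_path, synthetic_tree):
        tree, _ = M.attach_spine(synthetic_tree, 25.0)
        p = tmp_path / "rt.swc"
        M.write_swc(tree, p)
        back = M.read_swc(p)
        for a, b in zip(tree.nodes, back.nodes):
            assert (a.id, a.parent_id, a.label) == (b.id, b.parent_id, b.label)
            assert np.allclose([a.x, a.y, a.z, a.radius],
                               [b.x, b.y, b.z, b.radius])


class TestSyntheticMorphology:
    def test_default_has_four_branches_and_spine_sites(self, synthetic_tree):
        root = synthetic_tree.root
        assert len(synthetic_tree.children(root.id)) == 4
        # nodes at 25 and 100 um path distance must be resolvable
        for site in (25.0, 100.0):
            t2, _ = M.attach_spine(synthetic_tree, site)
            head = t2.nodes[-1]
            assert head.label == "spine_head"
            assert abs(t2.path_distance(head.parent_id) - site) < 3.0

    def test_soma_only(self):
        tree = M.build_synthetic_morphology(n_primary_dendrites=0)
        assert len(tree.nodes) == 1
        g = M.discretize(tree)
        assert g.n == 1

    def test_zero_taper_constant_diameter(self):
        tree = M.build_synthetic_morphology(initial_diameter_um=1.5,
                                            final_diameter_um=1.5)
        radii = {n.radius for n in tree.nodes if n.label == "dendrite"}
        assert radii == {0.75}


class TestSpines:
    def test_standard_spine_volume_is_one_cubic_micron(self, synthetic_tree):
        _, vol = M.attach_spine(synthetic_tree, 25.0, diameter_um=1.0,
                                length_um=1.273)
        assert vol == pytest.approx(1.0, rel=1e-3)

    def test_closed_form_volume(self, synthetic_tree):
        _, vol = M.attach_spine(synthetic_tree, 25.0, diameter_um=1.0,
                                length_um=4.0 / math.pi)
        assert vol == pytest.approx(1.0, rel=1e-12)

    def test_two_spines_on_same_branch(self, synthetic_tree):
        t, _ = M.attach_spine(synthetic_tree, 25.0)
        t, _ = M.attach_spine(t, 100.0)
        heads = [n for n in t.nodes if n.label == "spine_head"]
        assert len(heads) == 2
        dists = sorted(t.path_distance(h.parent_id) for h in heads)
        assert abs(dists[0] - 25.0) < 3.0 and abs(dists[1] - 100.0) < 3.0

    def test_site_beyond_dendrite_rejected(self, synthetic_tree):
        with pytest.raises(M.MorphologyError, match="beyond"):
            M.attach_spine(synthetic_tree, 500.0)


class TestCoupling:
    def test_hand_evaluated_series_formula(self):
        # two identical cylinders d=1 um, l=50 um, g_a=0.01 S*cm:
        # 1/g = 2*50e-4/(0.01*pi*(1e-4)^2) * 2  ->  g = 1.5708e-8 S
        g = M.coupling_conductance(50.0, 1.0, 50.0, 1.0, 0.01)
        assert g == pytest.approx(1.5707963e-8, rel=1e-6)

    def test_symmetry(self):
        a = M.coupling_conductance(30.0, 1.2, 70.0, 0.6, 0.01)
        b = M.coupling_conductance(70.0, 0.6, 30.0, 1.2, 0.01)
        assert a == b

    def test_doubling_lengths_halves_conductance(self):
        g1 = M.coupling_conductance(50.0, 1.0, 50.0, 1.0, 0.01)
        g2 = M.coupling_conductance(100.0, 1.0, 100.0, 1.0, 0.01)
        assert g2 == pytest.approx(g1 / 2.0)

    def test_zero_diameter_invalid(self):
        with pytest.raises(M.MorphologyError, match="geometry"):
            M.coupling_conductance(50.0, 0.0, 50.0, 1.0, 0.01)


class TestDiscretize:
    def test_halving_f_lambda_never_decreases_count(self, synthetic_tree):
        n1 = M.discretize(synthetic_tree, f_lambda=0.2).n
        n2 = M.discretize(synthetic_tree, f_lambda=0.1).n
        n3 = M.discretize(synthetic_tree, f_lambda=0.05).n
        assert n1 <= n2 <= n3

    def test_tiny_section_single_compartment(self):
        nodes = [
            M.SegmentNode(1, None, 0, 0, 0, 5.0, "soma"),
            M.SegmentNode(2, 1, 1.0, 0, 0, 0.5, "dendrite"),
        ]
        g = M.discretize(M.SegmentTree(nodes))
        assert g.n == 2  # soma + one compartment for the 1 um section

    def test_region_labels_follow_boundaries(self, synthetic_tree):
        g = M.discretize(synthetic_tree)
        for c in g.compartments:
            if c.region == "soma":
                continue
            if c.dist_um <= 50:
                assert c.region == "proximal"
            elif c.dist_um <= 100:
                assert c.region == "middle"
            else:
                assert c.region == "distal"

    def test_parent_ordering_for_tree_solve(self, synthetic_tree):
        t, _ = M.attach_spine(synthetic_tree, 25.0)
        g = M.discretize(t)
        assert all(g.parent[j] < j for j in range(1, g.n))
        assert g.parent[0] == -1

    def test_invalid_f_lambda(self, synthetic_tree):
        with pytest.raises(M.MorphologyError):
            M.discretize(synthetic_tree, f_lambda=1.5)


class TestSpineCorrection:
    def test_default_region_factors(self, synthetic_tree):
        g = M.apply_spine_correction(M.discretize(synthetic_tree))
        by_region = {c.region: c.spine_factor for c in g.compartments}
        assert by_region["proximal"] == 1.0
        assert by_region["middle"] == 1.3
        assert by_region["distal"] == 3.0

    def test_identity_when_all_one(self, synthetic_tree):
        g0 = M.discretize(synthetic_tree)
        g1 = M.apply_spine_correction(
            g0, {"proximal": 1.0, "middle": 1.0, "distal": 1.0})
        assert np.allclose(g0.C_nF, g1.C_nF)
        assert np.allclose(g0.g_leak_uS, g1.g_leak_uS)

    def test_distal_capacitance_scaled_threefold(self, synthetic_tree):
        g0 = M.discretize(synthetic_tree)
        g1 = M.apply_spine_correction(g0)
        distal = [i for i, c in enumerate(g1.compartments)
                  if c.region == "distal"]
        assert np.allclose(g1.C_nF[distal], 3.0 * g0.C_nF[distal])

    def test_unknown_region_rejected(self, synthetic_tree):
        g = M.discretize(synthetic_tree)
        with pytest.raises(M.MorphologyError, match="unknown region"):
            M.apply_spine_correction(g, {"axon": 2.0})

    def test_factor_below_one_rejected(self, synthetic_tree):
        g = M.discretize(synthetic_tree)
        with pytest.raises(M.MorphologyError):
            M.apply_spine_correction(g, {"distal": 0.5})

    def test_corrected_area_conserved_under_rediscretization(self, synthetic_tree):
        a1 = M.apply_spine_correction(
            M.discretize(synthetic_tree, f_lambda=0.1)).total_corrected_area_um2()
        a2 = M.apply_spine_correction(
            M.discretize(synthetic_tree, f_lambda=0.05)).total_corrected_area_um2()
        assert abs(a1 - a2) / a1 < 0.01
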