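import numpy as np
import pytest

from veinscape import (
    BridgingJunction,
    SinusModel,
    VeinBranch,
    VeinTree,
    classify_drainage,
    confluence_angle,
    confluence_angle_3d,
    count_bridging_veins,
    group_angle_stats,
    standard_view,
)
from veinscape.anatomy import load_tree, save_tree, terminal_direction


@pytest.fixture
def straight_sinus():
    """Straight anterior->posterior sinus along -y, 90 mm long, at z = 0."""
    y = np.linspace(45.0, -45.0, 10)
    return SinusModel(np.column_stack([np.zeros(10), y, np.zeros(10)]))


def junction_at(sinus, frac, side="L", group="anterior frontal", branch_index=0):
    return BridgingJunction(branch_index=branch_index,
                            arc_position_mm=frac * sinus.arc_length,
                            side=side, group=group)


def vein_from(sinus, arc_pos, direction, length=15.0):
    p0 = sinus.point_at(arc_pos)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return VeinBranch(points=np.array([p0, p0 + length * d]))


class TestCountTable:
    def test_no_junctions_all_zero(self, straight_sinus):
        df = count_bridging_veins(VeinTree(branches=[]), straight_sinus)
        assert df[["frontal", "middle", "occipital"]].to_numpy().sum() == 0

    def test_hand_assigned_junctions(self, straight_sinus):
        # arc fractions {0.1L, 0.2L | 0.4R | 0.5L | 0.9L, 0.95R}
        layout = [(0.1, "L"), (0.2, "L"), (0.4, "R"), (0.5, "L"), (0.9, "L"), (0.95, "R")]
        branches = [vein_from(straight_sinus, f * straight_sinus.arc_length, [-1, 0, 0])
                    for f, _ in layout]
        junctions = [junction_at(straight_sinus, f, side=s, branch_index=i)
                     for i, (f, s) in enumerate(layout)]
        tree = VeinTree(branches=branches, junctions=junctions)
        df = count_bridging_veins(tree, straight_sinus)
        assert list(df.loc["L", ["frontal", "middle", "occipital"]]) == [2, 1, 1]
        assert list(df.loc["R", ["frontal", "middle", "occipital"]]) == [0, 1, 1]

    def test_boundary_goes_to_posterior_interval(self, straight_sinus):
        L = straight_sinus.arc_length
        assert straight_sinus.third_of(L / 3.0) == "middle"
        assert straight_sinus.third_of(2.0 * L / 3.0) == "occipital"
        assert straight_sinus.third_of(L) == "occipital"

    def test_side_totals_conserved(self, straight_sinus):
        rng = np.random.default_rng(2)
        fracs = rng.uniform(0, 1, 17)
        sides = rng.choice(["L", "R"], 17)
        branches = [vein_from(straight_sinus, f * straight_sinus.arc_length, [1, 0, 0])
                    for f in fracs]
        junctions = [junction_at(straight_sinus, f, side=s, branch_index=i)
                     for i, (f, s) in enumerate(zip(fracs, sides))]
        df = count_bridging_veins(VeinTree(branches=branches, junctions=junctions),
                                  straight_sinus)
        assert (df["total"] == df[["frontal", "middle", "occipital"]].sum(axis=1)).all()
        assert df["total"].sum() == 17

    def test_out_of_range_arc_rejected(self, straight_sinus):
        branch = vein_from(straight_sinus, 0.0, [1, 0, 0])
        bad = BridgingJunction(branch_index=0, arc_position_mm=1e4,
                               side="L", group="occipital")
        with pytest.raises(ValueError):
            count_bridging_veins(VeinTree(branches=[branch], junctions=[bad]),
                                 straight_sinus)


class TestConfluenceAngle:
    def test_perpendicular_vein_is_90(self, straight_sinus):
        arc = 0.5 * straight_sinus.arc_length
        tree = VeinTree(branches=[vein_from(straight_sinus, arc, [-1, 0, 0])],
                        junctions=[junction_at(straight_sinus, 0.5)])
        a = confluence_angle(tree, tree.junctions[0], straight_sinus, standard_view(1))
        assert a == pytest.approx(90.0, abs=1e-9)

    def test_posterior_vein_is_0(self, straight_sinus):
        arc = 0.5 * straight_sinus.arc_length
        tree = VeinTree(branches=[vein_from(straight_sinus, arc, [0, -1, 0])],
                        junctions=[junction_at(straight_sinus, 0.5)])
        a = confluence_angle(tree, tree.junctions[0], straight_sinus, standard_view(1))
        assert a == pytest.approx(0.0, abs=1e-9)

    def test_anterior_vein_is_180(self, straight_sinus):
        arc = 0.5 * straight_sinus.arc_length
        tree = VeinTree(branches=[vein_from(straight_sinus, arc, [0, 1, 0])],
                        junctions=[junction_at(straight_sinus, 0.5)])
        a = confluence_angle(tree, tree.junctions[0], straight_sinus, standard_view(1))
        assert a == pytest.approx(180.0, abs=1e-9)

    def test_45_degree_vein(self, straight_sinus):
        arc = 0.5 * straight_sinus.arc_length
        tree = VeinTree(branches=[vein_from(straight_sinus, arc, [-1, -1, 0])],
                        junctions=[junction_at(straight_sinus, 0.5)])
        a = confluence_angle(tree, tree.junctions[0], straight_sinus, standard_view(1))
        assert a == pytest.approx(45.0, abs=1e-9)

    def test_scale_invariant(self, straight_sinus):
        arc = 0.5 * straight_sinus.arc_length
        tree = VeinTree(branches=[vein_from(straight_sinus, arc, [-1, -2, 0])],
                        junctions=[junction_at(straight_sinus, 0.5)])
        a1 = confluence_angle(tree, tree.junctions[0], straight_sinus, standard_view(1))
        scaled_sinus = SinusModel(straight_sinus.centerline * 3.0)
        scaled_tree = VeinTree(
            branches=[VeinBranch(points=tree.branches[0].points * 3.0)],
            junctions=[BridgingJunction(0, 3.0 * arc, "L", "anterior frontal")],
        )
        a2 = confluence_angle(scaled_tree, scaled_tree.junctions[0],
                              scaled_sinus, standard_view(1))
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_in_plane_3d_angle_matches_projected(self, straight_sinus):
        arc = 0.5 * straight_sinus.arc_length
        tree = VeinTree(branches=[vein_from(straight_sinus, arc, [-2, -1, 0])],
                        junctions=[junction_at(straight_sinus, 0.5)])
        proj = confluence_angle(tree, tree.junctions[0], straight_sinus, standard_view(1))
        full = confluence_angle_3d(tree, tree.junctions[0], straight_sinus)
        assert proj == pytest.approx(full, abs=1e-9)

    def test_vein_along_view_axis_degenerate(self, straight_sinus):
        arc = 0.5 * straight_sinus.arc_length
        tree = VeinTree(branches=[vein_from(straight_sinus, arc, [0, 0, -1])],
                        junctions=[junction_at(straight_sinus, 0.5)])
        with pytest.raises(ValueError):
            confluence_angle(tree, tree.junctions[0], straight_sinus, standard_view(1))

    def test_terminal_direction_uses_first_window(self):
        # kinked vein: direction estimated before the kink at 6 mm
        pts = np.array([[0, 0, 0], [5, 0, 0], [6, 0, 0], [6, 30, 0.0]])
        d = terminal_direction(VeinBranch(points=pts), window_mm=5.0)
        np.testing.assert_allclose(d, [1, 0, 0], atol=1e-12)


class TestGroupStats:
    def test_hand_computed_mean_and_mad(self):
        stats = group_angle_stats([("occipital", 100.0), ("occipital", 110.0),
                                   ("occipital", 105.0)])
        s = stats["occipital"]
        assert s.mean_deg == pytest.approx(105.0)
        assert s.mad_deg == pytest.approx(10.0 / 3.0)

    def test_equal_angles_zero_mad(self):
        stats = group_angle_stats([("medial frontal", 85.0)] * 4)
        assert stats["medial frontal"].mad_deg == 0.0

    def test_total_record_bookkeeping(self):
        from veinscape.anatomy import GROUPS

        counts = (46, 45, 45, 44, 46, 41)
        records = [(g, 50.0) for g, n in zip(GROUPS, counts) for _ in range(n)]
        stats = group_angle_stats(records)
        assert sum(s.n for s in stats.values()) == 267

    def test_empty_group_warns_and_excluded(self):
        with pytest.warns(UserWarning):
            stats = group_angle_stats([("occipital", 10.0)])
        assert set(stats) == {"occipital"}


class TestDrainage:
    def make_tree(self, trolard, labbe, sylvian):
        return VeinTree(branches=[], anastomotic_calibers={
            "L": {"trolard": trolard, "labbe": labbe, "sylvian": sylvian}})

    @pytest.mark.parametrize("cal,expected", [
        ((2.0, 2.0, 2.0), "I"),
        ((4.0, 1.0, 1.0), "II"),
        ((1.0, 4.0, 1.0), "III"),
        ((1.0, 1.0, 4.0), "IV"),
        ((2.0, 2.0, 0.2), "V"),
    ])
    def test_rule_table(self, cal, expected):
        profile = classify_drainage(self.make_tree(*cal), "L")
        assert profile.assessable and profile.type == expected

    def test_missing_calibers_unassessable(self):
        profile = classify_drainage(VeinTree(branches=[]), "R")
        assert not profile.assessable and profile.type is None

    def test_one_absent_but_unbalanced_falls_to_dominant(self):
        profile = classify_drainage(self.make_tree(4.0, 1.0, 0.2), "L")
        assert profile.type == "II"


def test_tree_json_round_trip(tmp_path, straight_sinus):
    branches = [vein_from(straight_sinus, 10.0, [-1, -1, 0])]
    tree = VeinTree(branches=branches,
                    junctions=[junction_at(straight_sinus, 0.1)],
                    anastomotic_calibers={"L": {"trolard": 2.0, "labbe": 1.0,
                                                "sylvian": 1.5}})
    save_tree(tree, straight_sinus, tmp_path / "tree.json")
    tree2, sinus2 = load_tree(tmp_path / "tree.json")
    np.testing.assert_allclose(sinus2.centerline, straight_sinus.centerline)
    np.testing.assert_allclose(tree2.branches[0].points, branches[0].points)
    assert tree2.junctions == tree.junctions
    assert tree2.anastomotic_calibers == tree.anastomotic_calibers
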