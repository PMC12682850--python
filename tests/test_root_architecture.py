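"""Diameter classification, class-length conservation, link analysis, root order."""

import numpy as np
import pandas as pd
import pytest

from rootshift.root_architecture import (
    RootTopologyError,
    aggregate_longevity,
    assign_lr_order,
    classify_diameter,
    classify_segments,
    link_analysis,
    summarize_root_types,
)
from rootshift.synthetic_data import RootSimConfig, gen_root_system


def seg_table(rows):
    """rows: (segment_id, parent_or_None, length_mm, diameter_mm)"""
    return pd.DataFrame(
        [("P1", sid, parent, length, diam) for sid, parent, length, diam in rows],
        columns=["plant_id", "segment_id", "parent_segment_id", "length_mm", "diameter_mm"],
    )


class TestClassify:
    @pytest.mark.parametrize(
        "diameter,expected",
        [
            (0.10, "S_type"),
            (0.30, "L_type"),
            (0.15, "S_type"),  # closed upper bound of S band
            (0.37, "L_type"),  # closed upper bound of L band
            (0.38, "axial"),
        ],
    )
    def test_boundaries_closed_above(self, diameter, expected):
        assert classify_diameter(diameter) == expected

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            classify_diameter(0.0)

    def test_partition_every_segment_classified(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0.01, 1.0, size=500)
        classes = classify_diameter(d)
        assert set(classes) <= {"S_type", "L_type", "axial"}
        assert len(classes) == 500


class TestSummarize:
    def test_proportions_from_known_lengths(self):
        t = seg_table(
            [("a", None, 70.0, 0.5), ("b", "a", 20.0, 0.3), ("c", "a", 10.0, 0.1)]
        )
        out = summarize_root_types(t)
        assert out.loc[0, "prop_axial"] == pytest.approx(0.7)
        assert out.loc[0, "prop_L"] == pytest.approx(0.2)
        assert out.loc[0, "prop_S"] == pytest.approx(0.1)

    def test_class_lengths_sum_exactly_to_total(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(1, 60))
            t = seg_table(
                [
                    (f"s{i}", None, float(rng.uniform(0.1, 50)), float(rng.uniform(0.01, 1)))
                    for i in range(n)
                ]
            )
            out = summarize_root_types(t)
            d = t["diameter_mm"].to_numpy()
            length = t["length_mm"].to_numpy()
            assert out.loc[0, "length_S"] == float(length[d <= 0.15].sum())
            assert out.loc[0, "length_L"] == float(length[(d > 0.15) & (d <= 0.37)].sum())
            assert out.loc[0, "length_axial"] == float(length[d > 0.37].sum())
            assert out.loc[0, "length_total"] == (
                out.loc[0, "length_S"] + out.loc[0, "length_L"] + out.loc[0, "length_axial"]
            )
            assert out.loc[0, ["prop_S", "prop_L", "prop_axial"]].sum() == pytest.approx(
                1.0, abs=1e-9
            )

    def test_empty_plant_flags_undefined_proportions(self):
        t = seg_table([("a", None, 0.0, 0.5)])
        t.loc[0, "length_mm"] = 0.0
        out = summarize_root_types(t)
        assert not out.loc[0, "proportions_defined"]
        assert np.isnan(out.loc[0, "prop_S"])


class TestLinkAnalysis:
    def test_hand_countable_tree(self):
        # axial chain of 4 segments; 3 unbranched S laterals of 5/7/9 mm
        t = seg_table(
            [
                ("a1", None, 10.0, 0.5),
                ("a2", "a1", 10.0, 0.5),
                ("a3", "a2", 10.0, 0.5),
                ("a4", "a3", 10.0, 0.5),  # bare axial tip
                ("s1", "a1", 5.0, 0.1),
                ("s2", "a2", 7.0, 0.1),
                ("s3", "a3", 9.0, 0.1),
            ]
        )
        out = link_analysis(t)
        assert out.external_links == 4  # 3 S tips + axial tip
        assert out.internal_links == 3
        assert out.mean_s_lateral_length_mm == pytest.approx(7.0)

    def test_second_order_single_s_tip(self):
        t = seg_table(
            [
                ("a1", None, 10.0, 0.5),
                ("l1", "a1", 30.0, 0.3),
                ("s1", "l1", 4.0, 0.1),
            ]
        )
        out = link_analysis(t)
        assert out.n_s_tips == 1
        assert out.mean_s_lateral_length_mm == pytest.approx(4.0)

    def test_no_s_tips_gives_undefined_marker(self):
        t = seg_table([("a1", None, 10.0, 0.5)])
        assert link_analysis(t).mean_s_lateral_length_mm is None

    def test_links_partition_segments(self):
        cfg = RootSimConfig(seed=4)
        seg, _ = gen_root_system(cfg, "well_watered")
        out = link_analysis(seg)
        assert out.external_links + out.internal_links == len(seg)
        assert out.external_links >= cfg.n_axial  # at least one tip per tree

    def test_cycle_rejected(self):
        t = seg_table([("a", "b", 1.0, 0.5), ("b", "a", 1.0, 0.5)])
        with pytest.raises(RootTopologyError, match="cycle"):
            link_analysis(t)


def oracle_orders(segments):
    """Root-to-tip path walk, written independently of the implementation:
    for each lateral, walk DOWN from the forest root along its ancestor path
    and track the last non-own-class lateral seen since the axial part."""
    seg = classify_segments(segments)
    parent = dict(zip(seg["segment_id"], seg["parent_segment_id"]))
    cls = dict(zip(seg["segment_id"], seg["root_class"]))
    out = {}
    for sid in seg["segment_id"]:
        if cls[sid] == "axial":
            out[sid] = None
            continue
        # full ancestor path from the root down to sid (exclusive)
        path = []
        cur = parent[sid]
        while cur is not None and not (isinstance(cur, float) and np.isnan(cur)):
            path.append(cur)
            cur = parent[cur]
        path.reverse()
        # strip sid's own contiguous chain from the tip end
        while path and cls[path[-1]] == cls[sid]:
            path.pop()
        decision = None
        for anc in reversed(path):
            if cls[anc] == "axial":
                decision = "first"
                break
            if cls[anc] == "L_type" and cls[sid] != "L_type":
                decision = "second"
                break
        out[sid] = decision
    return out


class TestAssignLrOrder:
    def test_s_on_axial_is_first_order(self):
        t = seg_table([("a1", None, 10.0, 0.5), ("s1", "a1", 5.0, 0.1)])
        out = assign_lr_order(t)
        assert out.set_index("segment_id").loc["s1", "lr_order"] == "first"

    def test_s_on_l_is_second_order(self):
        t = seg_table(
            [("a1", None, 10.0, 0.5), ("l1", "a1", 30.0, 0.3), ("s1", "l1", 5.0, 0.1)]
        )
        out = assign_lr_order(t)
        assert out.set_index("segment_id").loc["s1", "lr_order"] == "second"

    def test_matches_path_walk_oracle_on_random_trees(self):
        for seed in range(20):
            seg, _ = gen_root_system(RootSimConfig(seed=seed), "drought")
            got = assign_lr_order(seg).set_index("segment_id")["lr_order"]
            expected = oracle_orders(seg)
            for sid, exp in expected.items():
                if exp is None:
                    assert pd.isna(got[sid])
                else:
                    assert got[sid] == exp


class TestAggregateLongevity:
    def test_uniform_scores(self):
        scores = pd.DataFrame(
            {
                "plant_id": ["P1"] * 3,
                "root_class": ["main"] * 3,
                "photo_id": ["f1", "f2", "f3"],
                "score": [5, 5, 5],
            }
        )
        out = aggregate_longevity(scores)
        assert out.loc[0, "mean_score"] == 5.0

    def test_two_stage_mean_photos_then_roots(self):
        # root A photos [2, 4] -> 3.0; root B photo [5] -> 5.0; group mean 4.0
        scores = pd.DataFrame(
            {
                "plant_id": ["P1", "P1", "P2"],
                "root_class": ["S_type"] * 3,
                "photo_id": ["f1", "f2", "f3"],
                "score": [2, 4, 5],
            }
        )
        out = aggregate_longevity(scores)
        assert out.loc[0, "mean_score"] == pytest.approx(4.0)
        assert out.loc[0, "n_roots"] == 2
        assert out.loc[0, "n_photos"] == 3

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(
            {
                "plant_id": rng.choice(["P1", "P2", "P3"], size=60),
                "root_class": rng.choice(["main", "S_type", "L_type"], size=60),
                "photo_id": [f"f{i}" for i in range(60)],
                "score": rng.integers(0, 6, size=60),
            }
        )
        a = aggregate_longevity(scores)
        b = aggregate_longevity(scores.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(a, b)

    def test_out_of_scale_score_rejected(self):
        scores = pd.DataFrame(
            {"plant_id": ["P1"], "root_class": ["main"], "photo_id": ["f1"], "score": [6]}
        )
        with pytest.raises(ValueError, match="0..5"):
            aggregate_longevity(scores)
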