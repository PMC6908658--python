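import numpy as np
import pandas as pd
import pytest

from phyllocom.datamodel import CountTable
from phyllocom.occupancy import (ALLREAD, global_shared_fraction, host_overlap,
                                 occupancy_depth_curve, organ_overlap,
                                 presence_profile)

from conftest import make_meta


def build_presence_dataset():
    """3 hosts x 2 organs, one sample each, with a hand-built OTU layout.

    OTU occupancy by construction (8-region structure over hosts on leaves):
      o_all   : everywhere
      o_ab    : hosts a+b leaves only
      o_a     : host a leaves only
      o_leaf  : all leaves, no flowers
    """
    hosts = ["a", "a", "b", "b", "c", "c"]
    organs = ["leaf", "flower"] * 3
    ids = [f"{h}_{o}" for h, o in zip(hosts, organs)]
    otus = ["o_all", "o_ab", "o_a", "o_leaf"]
    rows = []
    for h, o in zip(hosts, organs):
        rows.append([
            500,
            500 if (h in "ab" and o == "leaf") else 0,
            500 if (h == "a" and o == "leaf") else 0,
            500 if o == "leaf" else 0,
        ])
    table = CountTable(pd.DataFrame(rows, index=ids, columns=otus))
    meta = make_meta(ids, host=hosts, organ=organs)
    return table, meta


class TestPresenceProfile:
    def test_reference_depth_must_be_on_grid(self):
        table, _ = build_presence_dataset()
        with pytest.raises(ValueError):
            presence_profile(table, [100, 200], reference_depth=500)

    def test_absent_otu_absent_everywhere(self):
        table, _ = build_presence_dataset()
        table = CountTable(table.data.assign(o_ghost=0))
        profile = presence_profile(table, [100, 500], reference_depth=500)
        assert "o_ghost" not in profile.allread.columns
        for depth in profile.depth_grid:
            assert not profile.presence[depth]["o_ghost"].any()

    def test_allread_set_equals_reference_detection(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 6, (6, 40)) * rng.integers(0, 2, (6, 40))
        counts[:, 0] += 300  # dominant OTU keeps library sizes up
        table = CountTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(6)],
                         columns=[f"o{j}" for j in range(40)])
        )
        profile = presence_profile(table, [50, 100], reference_depth=100,
                                   rng_seed=3)
        ref = profile.presence[100]
        assert set(profile.allread.columns) == set(ref.columns[ref.any(axis=0)])
        # rare OTUs with raw counts that were never drawn stay excluded
        raw_present = set(table.data.columns[(table.data > 0).any(axis=0)])
        assert set(profile.allread.columns) <= raw_present

    def test_allread_uses_unrarefied_counts(self):
        table, _ = build_presence_dataset()
        profile = presence_profile(table, [100, 500], reference_depth=500)
        # at the all-read layer every positive raw count of a kept OTU counts
        kept = profile.allread.columns
        assert (profile.allread == (table.data[kept] > 0)).all().all()


class TestOverlaps:
    def test_organ_overlap_counts(self):
        table, meta = build_presence_dataset()
        profile = presence_profile(table, [100, 500], reference_depth=500)
        s = organ_overlap(profile, meta, "a")
        assert s.venn_region_counts == {"leaf_only": 3, "flower_only": 0, "both": 1}
        assert s.shared_fraction == pytest.approx(0.25)

    def test_organ_overlap_all_shared(self):
        table, meta = build_presence_dataset()
        only_all = table.select_otus(["o_all"])
        profile = presence_profile(only_all, [100, 500], reference_depth=500)
        s = organ_overlap(profile, meta, "b")
        assert s.shared_fraction == 1.0

    def test_organ_overlap_requires_both_organs(self):
        table, meta = build_presence_dataset()
        leafs = meta.df.index[meta.df["organ"] == "leaf"]
        profile = presence_profile(table.select_samples(leafs), [100, 500],
                                   reference_depth=500)
        with pytest.raises(ValueError):
            organ_overlap(profile, meta, "a")

    def test_host_overlap_region_structure(self):
        table, meta = build_presence_dataset()
        profile = presence_profile(table, [100, 500], reference_depth=500)
        s = host_overlap(profile, meta, "leaf")
        assert s.venn_region_counts["a&b&c"] == 2  # o_all, o_leaf
        assert s.venn_region_counts["a&b"] == 1  # o_ab
        assert s.venn_region_counts["a"] == 1  # o_a
        assert s.shared_fraction == pytest.approx(3 / 4)
        assert sum(s.venn_region_counts.values()) == s.total_otus

    def test_host_overlap_single_host_errors(self):
        table, meta = build_presence_dataset()
        a_ids = meta.df.index[meta.df["host"] == "a"]
        profile = presence_profile(table.select_samples(a_ids), [100, 500],
                                   reference_depth=500)
        with pytest.raises(ValueError):
            host_overlap(profile, meta, "leaf")

    def test_global_fraction_double_count_check(self):
        table, meta = build_presence_dataset()
        profile = presence_profile(table, [100, 500], reference_depth=500)
        # o_a occupies exactly one host x organ cell; the other three do not
        assert global_shared_fraction(profile, meta) == pytest.approx(3 / 4)

    def test_region_counts_invariant_to_ordering(self):
        table, meta = build_presence_dataset()
        shuffled = table.select_samples(table.sample_ids[::-1]).select_otus(
            table.otu_ids[::-1]
        )
        p1 = presence_profile(table, [100, 500], reference_depth=500, rng_seed=1)
        p2 = presence_profile(shuffled, [100, 500], reference_depth=500, rng_seed=1)
        s1 = host_overlap(p1, meta, "leaf")
        s2 = host_overlap(p2, meta, "leaf")
        assert s1.venn_region_counts == s2.venn_region_counts


class TestDepthCurve:
    def test_nested_mode_curve_is_monotone(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 8, (8, 30))
        counts[:, 0] += 400
        ids = [f"s{i}" for i in range(8)]
        table = CountTable(pd.DataFrame(counts, index=ids,
                                        columns=[f"o{j}" for j in range(30)]))
        meta = make_meta(ids, host="a", organ=["leaf", "flower"] * 4)
        profile = presence_profile(table, [50, 150, 400], reference_depth=400,
                                   rng_seed=5, draw_mode="nested")
        # detection sets nest across depths, so every Venn region that feeds
        # the curve can only gain OTUs with depth
        prev_both = -1
        for depth in profile.depth_grid:
            s = organ_overlap(profile, meta, "a", depth=depth)
            assert s.venn_region_counts["both"] >= prev_both
            prev_both = s.venn_region_counts["both"]
            layer = profile.presence[depth]
            ref = profile.presence[profile.reference_depth]
            assert not (layer & ~ref).any().any()
        curve = occupancy_depth_curve(profile, meta, "organ-within-host", "a")
        assert len(curve) == len(profile.depth_grid) + 1

    def test_grid_of_length_one_gives_two_points(self):
        table, meta = build_presence_dataset()
        profile = presence_profile(table, [500], reference_depth=500)
        curve = occupancy_depth_curve(profile, meta, "organ-within-host", "a")
        assert len(curve) == 2
        assert list(curve["depth"]) == [500, ALLREAD]
        assert "spread" in curve.attrs
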