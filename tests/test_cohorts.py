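import numpy as np
import pytest

from promarch import (
    PartitionRule,
    PromoterRecord,
    WindowParams,
    background_distribution,
    classify_intermediary,
    compare_groups,
    summarize_group,
    summarize_promoter,
    window_profile,
)
from promarch.patterns import PromoterSummary


def make_summary(pid, phenotype, kic, cg, gene=None):
    return PromoterSummary(
        promoter_id=pid,
        gene=gene,
        phenotype=phenotype,
        mean_kic=kic,
        median_kic=kic,
        cg_total=cg,
        mean_cg_window=cg / 2,
        center_of_weight=(cg / 2, kic),
    )


@pytest.fixture
def two_clouds(rng):
    """Well-separated synthetic clouds: group A low KIC/CG, group B high."""
    a = [
        make_summary(f"a{i}", "T1D", 26 + rng.normal(0, 1), 27 + rng.normal(0, 2), f"GA{i}")
        for i in range(15)
    ]
    b = [
        make_summary(f"b{i}", "T2D", 33 + rng.normal(0, 1), 47 + rng.normal(0, 2), f"GB{i}")
        for i in range(16)
    ]
    return a, b


class TestSummarizeGroup:
    def test_single_promoter_group(self):
        s = make_summary("x", "T1D", 30.0, 40.0, "GX")
        g = summarize_group([s], "T1D")
        assert g.n == 1
        assert g.mean_kic == g.median_kic == 30.0
        assert g.kic_range == ((30.0, "GX"), (30.0, "GX"))

    def test_statistics_match_brute_force(self, two_clouds):
        a, _ = two_clouds
        g = summarize_group(a, "T1D")
        kics = [s.mean_kic for s in a]
        cgs = [s.cg_total for s in a]
        assert g.mean_kic == pytest.approx(np.mean(kics))
        assert g.median_kic == pytest.approx(np.median(kics))
        assert g.mean_cg == pytest.approx(np.mean(cgs))
        assert g.kic_range[0][0] == min(kics) and g.kic_range[1][0] == max(kics)
        assert g.cg_range[0][0] == min(cgs) and g.cg_range[1][0] == max(cgs)
        assert g.kic_range[1][1] == a[int(np.argmax(kics))].gene
        assert g.kic_range[0][0] <= g.median_kic <= g.kic_range[1][0]

    def test_empty_group_errors(self, two_clouds):
        with pytest.raises(ValueError, match="IDM"):
            summarize_group(two_clouds[0], "IDM")


class TestCompareGroups:
    def test_identical_groups_give_p_one(self, two_clouds):
        a, _ = two_clouds
        res = compare_groups(a, list(a))
        assert res.p_value == 1.0

    def test_separated_groups_significant(self, two_clouds):
        res = compare_groups(*two_clouds, axis="mean_kic")
        assert res.p_value < 0.01
        assert res.statistic_name == "mannwhitney_u"

    def test_welch_variant(self, two_clouds):
        res = compare_groups(*two_clouds, test="welch")
        assert res.statistic_name == "welch_t"
        assert res.p_value < 0.01

    def test_joint_axis_holm_adjusts(self, two_clouds):
        a, b = two_clouds
        joint = compare_groups(a, b, axis="joint")
        single = min(
            compare_groups(a, b, axis="mean_kic").p_value,
            compare_groups(a, b, axis="cg_total").p_value,
        )
        assert joint.axis == "joint"
        # Holm with two tests doubles the smaller p (capped at the larger)
        assert joint.p_value >= single
        assert joint.p_value <= min(1.0, 2 * single) + 1e-12

    def test_undersized_group_errors(self, two_clouds):
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups(two_clouds[0][:1], two_clouds[1])


class TestClassifyIntermediary:
    def test_core_points_keep_their_label(self, two_clouds):
        a, b = two_clouds
        part = classify_intermediary(a + b)
        labels = [part.labels[s.promoter_id] for s in a + b]
        accuracy = np.mean(
            [
                lab == f"CORE_{s.phenotype}"
                for lab, s in zip(labels, a + b)
            ]
        )
        assert accuracy >= 0.9

    def test_point_between_clouds_is_intermediary(self, two_clouds):
        a, b = two_clouds
        mid = make_summary("mid", "T1D", 29.5, 37.0)
        part = classify_intermediary(a + b + [mid])
        assert part.labels["mid"] == "INTERMEDIARY"

    def test_point_inside_other_box_takes_other_core_label(self, two_clouds):
        a, b = two_clouds
        stray = make_summary("stray", "T1D", 33.0, 47.0)  # in the T2D core
        part = classify_intermediary(a + b + [stray])
        assert part.labels["stray"] == "CORE_T2D"

    def test_deterministic_and_serializable(self, two_clouds):
        a, b = two_clouds
        rule = PartitionRule(whisker=0.8)
        p1 = classify_intermediary(a + b, rule)
        p2 = classify_intermediary(a + b, rule)
        assert p1.labels == p2.labels
        assert p1.rule_params == rule.to_dict()
        assert p1.rule_params["whisker"] == 0.8

    def test_label_permutation_consistency(self, two_clouds):
        """Swapping the two phenotype names permutes output labels consistently."""
        a, b = two_clouds
        part = classify_intermediary(a + b)
        swap = {"T1D": "T2D", "T2D": "T1D"}
        swapped = [
            make_summary(s.promoter_id, swap[s.phenotype], s.mean_kic, s.cg_total, s.gene)
            for s in a + b
        ]
        part_sw = classify_intermediary(swapped)
        rename = {"CORE_T1D": "CORE_T2D", "CORE_T2D": "CORE_T1D", "INTERMEDIARY": "INTERMEDIARY"}
        assert part_sw.labels == {k: rename[v] for k, v in part.labels.items()}

    def test_every_promoter_gets_exactly_one_label(self, two_clouds):
        a, b = two_clouds
        part = classify_intermediary(a + b)
        assert set(part.labels) == {s.promoter_id for s in a + b}
        assert set(part.labels.values()) <= {"CORE_T1D", "CORE_T2D", "INTERMEDIARY"}

    def test_degenerate_box_falls_back_with_warning(self):
        a = [make_summary(f"a{i}", "T1D", 26.0, 27.0) for i in range(4)]
        b = [make_summary(f"b{i}", "T2D", 33.0 + i, 47.0 + i) for i in range(4)]
        with pytest.warns(UserWarning, match="degenerate"):
            part = classify_intermediary(a + b)
        assert len(part.labels) == 8

    def test_requires_exactly_two_groups(self, two_clouds):
        with pytest.raises(ValueError, match="two phenotype groups"):
            classify_intermediary(two_clouds[0])


class TestBackgroundDistribution:
    def test_points_match_individual_centers(self, rng):
        records = [
            PromoterRecord(id=f"r{i}", sequence="".join(rng.choice(list("ACGT"), size=60)))
            for i in range(3)
        ]
        points = background_distribution(records)
        assert len(points) == 3
        for rec, (pid, x, y) in zip(records, points):
            s = summarize_promoter(window_profile(rec), rec)
            assert pid == rec.id
            assert (x, y) == s.center_of_weight

    def test_homopolymer_maps_to_corner(self):
        rec = PromoterRecord(id="h", sequence="T" * 100)
        assert background_distribution([rec]) == [("h", 0.0, 100.0)]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            background_distribution([])
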