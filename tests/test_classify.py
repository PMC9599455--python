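"""Confidence classes, threshold calibration, tree routing, proteome summary."""

import numpy as np
import pytest
from scipy import stats

from hcafold.classify import (
    ConfidenceClass,
    FeatureThresholds,
    SegmentFeatures,
    build_tree,
    calibrate_thresholds,
    confidence_class,
    paper_default_thresholds,
    summarize_proteome,
)
from hcafold.sequence import FoldableSegment


def seg(start, end, pid="p"):
    return FoldableSegment(pid, start, end)


class TestConfidenceClass:
    @pytest.mark.parametrize(
        "plddt, expected",
        [
            ([45.0] * 5, ConfidenceClass.FULL_VL),
            ([95.0] * 5, ConfidenceClass.FULL_VH),
            ([95.0] * 4 + [89.0], ConfidenceClass.MIXED),  # "entirely" is strict
            ([50.0] * 5, ConfidenceClass.FULL_VL),  # boundary: <= 50 is VL
            ([90.0] * 5, ConfidenceClass.MIXED),  # boundary: > 90 required for VH
            ([90.0001] * 5, ConfidenceClass.FULL_VH),
            ([50.0001] * 5, ConfidenceClass.MIXED),
        ],
    )
    def test_boundaries(self, plddt, expected):
        assert confidence_class(seg(1, len(plddt)), plddt) is expected

    def test_track_must_cover_segment(self):
        with pytest.raises(ValueError):
            confidence_class(seg(1, 10), [50.0] * 5)


def feats(rss=50.0, acc=40.0, dis=10.0, dep=100.0):
    return SegmentFeatures(rss_pct=rss, access_pct=acc, disorder_pct=dis, mean_depth=dep)


class TestCalibration:
    def test_counting_definition_on_1_to_100(self):
        values = [feats(dis=v) for v in range(1, 101)]
        thr = calibrate_thresholds(values)
        assert thr.disorder_max == 95.0
        assert thr.provenance == "calibrated"

    def test_constant_feature_gives_constant_threshold(self):
        thr = calibrate_thresholds([feats(dis=7.0, acc=3.0, dep=11.0)] * 25)
        assert (thr.disorder_max, thr.access_max, thr.depth_min) == (7.0, 3.0, 11.0)

    def test_depth_is_lower_bound(self):
        values = [feats(dep=v) for v in range(1, 101)]
        thr = calibrate_thresholds(values)
        assert thr.depth_min == 6.0  # 95 of 100 values are >= 6

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds([feats()] * 19)

    def test_paper_defaults(self):
        thr = paper_default_thresholds()
        assert (thr.disorder_max, thr.access_max, thr.depth_min) == (33.4, 82.9, 23.5)
        assert thr.provenance == "paper_defaults"

    def test_coverage_guarantee_holds_after_calibration(self):
        rng = np.random.default_rng(17)
        values = [
            feats(
                dis=float(rng.uniform(0, 60)),
                acc=float(rng.uniform(20, 100)),
                dep=float(rng.exponential(50)),
            )
            for _ in range(500)
        ]
        thr = calibrate_thresholds(values, coverage=0.95)
        dis = np.array([f.disorder_pct for f in values])
        acc = np.array([f.access_pct for f in values])
        dep = np.array([f.mean_depth for f in values])
        assert np.mean(dis <= thr.disorder_max) >= 0.95
        assert np.mean(acc <= thr.access_max) >= 0.95
        assert np.mean(dep >= thr.depth_min) >= 0.95

    def test_recovers_true_percentiles_of_known_distribution(self):
        """On 10,000 i.i.d. draws the calibrated cutoffs approach the true
        95th/5th percentiles within twice the quantile sampling error."""
        rng = np.random.default_rng(20260927)
        n = 10_000
        dis = rng.normal(20.0, 5.0, n)
        acc = rng.normal(60.0, 10.0, n)
        dep = rng.normal(100.0, 20.0, n)
        values = [
            feats(dis=float(d), acc=float(a), dep=float(p))
            for d, a, p in zip(dis, acc, dep)
        ]
        thr = calibrate_thresholds(values, coverage=0.95)

        def qse(sigma, q):  # asymptotic sd of the sample quantile
            z = stats.norm.ppf(q)
            f = stats.norm.pdf(z) / sigma
            return np.sqrt(q * (1 - q) / n) / f

        assert abs(thr.disorder_max - stats.norm.ppf(0.95, 20.0, 5.0)) <= 2 * qse(5.0, 0.95)
        assert abs(thr.access_max - stats.norm.ppf(0.95, 60.0, 10.0)) <= 2 * qse(10.0, 0.95)
        assert abs(thr.depth_min - stats.norm.ppf(0.05, 100.0, 20.0)) <= 2 * qse(20.0, 0.95)

    def test_outward_rounding_preserves_coverage(self):
        values = [feats(dis=v + 0.123) for v in range(1, 101)]
        thr = calibrate_thresholds(values, decimals=1)
        dis = np.array([f.disorder_pct for f in values])
        assert np.mean(dis <= thr.disorder_max) >= 0.95


class TestTree:
    def test_hand_routed_segments_land_in_expected_leaves(self):
        thr = paper_default_thresholds()
        cases = {
            "folded": feats(rss=60, acc=40, dis=10, dep=100),  # all folded-side
            "no_rss": feats(rss=0, acc=40, dis=10, dep=100),
            "exposed": feats(rss=60, acc=95, dis=10, dep=100),
            "orphan": feats(rss=60, acc=40, dis=50, dep=2),
        }
        tree = build_tree(cases, thr)
        assert tree.leaves[(True, True, True, True)] == ["folded"]
        assert tree.leaves[(False, True, True, True)] == ["no_rss"]
        assert tree.leaves[(True, False, True, True)] == ["exposed"]
        assert tree.leaves[(True, True, False, False)] == ["orphan"]
        assert len(tree.leaves) == 4

    def test_identical_segments_single_leaf(self):
        tree = build_tree({f"s{i}": feats() for i in range(10)}, paper_default_thresholds())
        assert len(tree.leaves) == 1
        assert tree.root_count == 10

    def test_leaf_counts_sum_to_root(self):
        rng = np.random.default_rng(23)
        items = {
            f"s{i}": feats(
                rss=float(rng.choice([0, 50])),
                acc=float(rng.uniform(0, 100)),
                dis=float(rng.uniform(0, 100)),
                dep=float(rng.uniform(0, 50)),
            )
            for i in range(200)
        }
        tree = build_tree(items, paper_default_thresholds())
        assert sum(tree.leaf_counts().values()) == tree.root_count == 200
        # internal-node conservation as printed on the figures
        assert tree.node_count((True,)) + tree.node_count((False,)) == 200

    def test_ties_follow_printed_comparators(self):
        thr = FeatureThresholds(disorder_max=33.4, access_max=82.9, depth_min=23.5)
        at_threshold = feats(rss=0.0, acc=82.9, dis=33.4, dep=23.5)
        tree = build_tree({"s": at_threshold}, thr)
        # <= passes on disorder/accessibility; > fails for depth; rss=0 is absence
        assert list(tree.leaves) == [(False, True, True, False)]

    def test_missing_feature_excluded_and_counted(self, caplog):
        items = {"ok": feats(), "partial": SegmentFeatures(rss_pct=10.0)}
        with caplog.at_level("WARNING"):
            tree = build_tree(items, paper_default_thresholds())
        assert tree.root_count == 1
        assert tree.excluded == ["partial"]
        assert "partial" in caplog.text

    def test_routing_is_deterministic(self):
        items = {f"s{i}": feats(dis=float(i)) for i in range(50)}
        t1 = build_tree(items, paper_default_thresholds())
        t2 = build_tree(items, paper_default_thresholds())
        assert t1.leaf_counts() == t2.leaf_counts()


class TestProteomeSummary:
    def test_toy_accounting(self):
        entries = {"a": 60, "b": 40}
        segments = [FoldableSegment("a", 1, 40, hca_score=1.0),
                    FoldableSegment("b", 1, 24, hca_score=1.0)]
        classes = {"a:1-40": ConfidenceClass.FULL_VH, "b:1-24": ConfidenceClass.FULL_VL}
        tracks = {"a": [95.0] * 60, "b": [40.0] * 40}
        df = summarize_proteome(entries, segments, classes, tracks)
        row = df.iloc[0]
        assert row.pct_residues_in_fs == 64.0
        assert row.n_full_vh == 1 and row.n_full_vl == 1
        assert row.mean_len_full_vh == 40.0 and row.mean_len_full_vl == 24.0
        assert row.pct_vh_residues_in_full_vh == 100.0

    def test_empty_proteome(self):
        df = summarize_proteome({"a": 100}, [], {}, {})
        row = df.iloc[0]
        assert row.pct_residues_in_fs == 0.0
        assert row.n_full_vl == 0 and row.n_full_vh == 0
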