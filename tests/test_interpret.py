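"""Attention reports, BH-FDR, discriminative edges, cross-atlas overlap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlasfuse.atlas import AtlasSpec
from atlasfuse.fc_graphs import FCMatrix
from atlasfuse.interpret import (
    AttentionReport,
    bh_fdr,
    cross_atlas_overlap,
    discriminative_edges,
    region_map_from_centroids,
    roi_attention,
    subject_roi_attention,
    top_k_rois,
)


def bh_stepup_oracle(p):
    """Hand-written Benjamini-Hochberg step-up, straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = running_min
    return np.clip(q, 0.0, 1.0)


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_textbook_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr(np.ones(7)), np.ones(7))

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 101))
            p = rng.random(m)
            np.testing.assert_allclose(bh_fdr(p), bh_stepup_oracle(p), atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_stepup_property_holds_for_arbitrary_p_vectors(self, p):
        q = bh_fdr(p)
        np.testing.assert_allclose(q, bh_stepup_oracle(p), atol=1e-12)
        assert (q >= 0).all() and (q <= 1).all()

    def test_monotone_in_rank(self, rng):
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestAttention:
    def test_subject_attention_arithmetic_oracle(self):
        # two layers, two heads, 4 nodes with hand-set attention matrices
        a1 = np.stack([np.full((4, 4), 0.25), np.eye(4)])
        a2 = np.stack([np.eye(4), np.eye(4)])
        w = subject_roi_attention([a1, a2])
        # layer1: head means -> (uniform .25 + diag .25)/2; layer2: diag .25
        expected = (np.full(4, 0.25) + np.full(4, 0.25)) / 2 / 2 + np.full(4, 0.25) / 2
        np.testing.assert_allclose(w, expected)
        assert w.sum() == pytest.approx(1.0)

    def test_uniform_attention_gives_equal_weights(self):
        a = np.full((2, 5, 5), 0.2)
        np.testing.assert_allclose(subject_roi_attention([a]), 0.2)

    def test_single_node_gets_all_mass(self):
        a = np.ones((1, 1, 1))
        np.testing.assert_allclose(subject_roi_attention([a]), [1.0])

    def test_untrained_model_refused(self, rng):
        from atlasfuse.fusion import MultiAtlasClassifier
        from atlasfuse.sat import SATConfig
        from conftest import random_graph

        model = MultiAtlasClassifier(
            {"a": 6},
            SATConfig(k_hops=1, n_layers=1, hidden_dim=4, n_heads=2, gnn_layers=1),
            fusion_dim=4,
            clf_hidden=4,
        )
        with pytest.raises(RuntimeError, match="trained"):
            roi_attention(model, [{"a": random_graph(rng, 6)}], "a")


class TestTopK:
    def _report(self, weights):
        n = len(weights)
        atlas = AtlasSpec.generic("t", n)
        return AttentionReport("t", atlas.roi_labels, np.asarray(weights, dtype=float))

    def test_full_ranking_when_k_equals_n(self):
        top = top_k_rois(self._report([0.1, 0.4, 0.2]), k=3)
        assert [i for i, _, _ in top] == [1, 2, 0]

    def test_ties_break_toward_lower_index(self):
        top = top_k_rois(self._report([0.3, 0.5, 0.5, 0.1]), k=2)
        assert [i for i, _, _ in top] == [1, 2]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            top_k_rois(self._report([0.1, 0.2]), k=3)


def make_fc_cohort(rng, n_rois, n_per_group, shift_edge=None, shift=0.0):
    atlas = AtlasSpec.generic("edge", n_rois)
    mats, labels = [], []
    for label in (0, 1):
        for s in range(n_per_group):
            x = rng.standard_normal((n_rois, n_rois)) * 0.1
            sym = (x + x.T) / 2
            if label == 1 and shift_edge is not None:
                i, j = shift_edge
                sym[i, j] += shift
                sym[j, i] += shift
            np.fill_diagonal(sym, 1.0)
            mats.append(FCMatrix(f"s{label}{s}", atlas, np.clip(sym, -1, 1), label=label))
            labels.append(label)
    return mats, np.array(labels)


class TestDiscriminativeEdges:
    def test_identical_groups_no_significant_edges(self, rng):
        atlas = AtlasSpec.generic("e5", 5)
        base = []
        for s in range(4):
            x = rng.standard_normal((5, 5)) * 0.1
            sym = (x + x.T) / 2
            np.fill_diagonal(sym, 1.0)
            base.append(sym)
        mats = [FCMatrix(f"a{s}", atlas, m) for s, m in enumerate(base)] + [
            FCMatrix(f"b{s}", atlas, m.copy()) for s, m in enumerate(base)
        ]
        labels = np.array([0] * 4 + [1] * 4)
        edges = discriminative_edges(mats, labels, list(range(5)))
        assert not any(e.significant for e in edges)

    def test_planted_shift_detected_and_controlled(self, rng):
        # one edge shifted by ~5 pooled SDs in a 10-ROI subset, 20 vs 20
        mats, labels = make_fc_cohort(rng, 10, 20, shift_edge=(2, 7), shift=0.35)
        edges = discriminative_edges(mats, labels, list(range(10)))
        assert len(edges) == 45  # C(10, 2)
        sig = {e.roi_pair for e in edges if e.significant}
        assert (2, 7) in sig
        assert len(sig) <= 3  # false positives controlled at the BH level

    def test_zero_variance_edge_flagged(self):
        atlas = AtlasSpec.generic("z3", 3)
        mats = []
        for s in range(8):
            m = np.eye(3)
            m[0, 1] = m[1, 0] = 0.5  # constant in both groups
            m[0, 2] = m[2, 0] = 0.1 * s
            m[1, 2] = m[2, 1] = 0.05 * s
            mats.append(FCMatrix(f"s{s}", atlas, m))
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        edges = discriminative_edges(mats, labels, [0, 1, 2])
        flagged = {e.roi_pair: e for e in edges}
        assert flagged[(0, 1)].degenerate and flagged[(0, 1)].p_value == 1.0

    def test_too_few_subjects_rejected(self, rng):
        mats, labels = make_fc_cohort(rng, 4, 1)
        with pytest.raises(ValueError):
            discriminative_edges(mats, labels, [0, 1, 2])


class TestCrossAtlasOverlap:
    def _top(self, labels):
        return [(i, lab, 1.0) for i, lab in enumerate(labels)]

    def test_identical_label_sets_all_three_atlas(self):
        region_map = {(a, l): l for a in ("x", "y", "z") for l in ("r1", "r2")}
        tops = {a: self._top(["r1", "r2"]) for a in ("x", "y", "z")}
        buckets = cross_atlas_overlap(tops, region_map)
        assert {r for r, _ in buckets["three_atlas"]} == {"r1", "r2"}
        assert not buckets["two_atlas"] and not buckets["singleton"]

    def test_disjoint_sets_all_singletons(self):
        region_map = {("x", "a"): "a", ("y", "b"): "b", ("z", "c"): "c"}
        tops = {"x": self._top(["a"]), "y": self._top(["b"]), "z": self._top(["c"])}
        buckets = cross_atlas_overlap(tops, region_map)
        assert len(buckets["singleton"]) == 3

    def test_exactly_one_common_region(self):
        region_map = {
            ("x", "a"): "common", ("y", "b"): "common", ("z", "c"): "common",
            ("x", "d"): "d", ("y", "e"): "e",
        }
        tops = {"x": self._top(["a", "d"]), "y": self._top(["b", "e"]), "z": self._top(["c"])}
        buckets = cross_atlas_overlap(tops, region_map)
        assert [r for r, _ in buckets["three_atlas"]] == ["common"]

    def test_unmapped_labels_reported_not_dropped(self):
        buckets = cross_atlas_overlap({"x": self._top(["mystery"])}, {})
        assert buckets["unmatched"] == [("x", "mystery")]

    def test_viewer_files_roundtrip(self, tmp_path):
        from atlasfuse.interpret import EdgeStats, write_viewer_files

        atlas = AtlasSpec(
            "v3", 3, ("a", "b", "c"),
            centroids=np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]]),
        )
        edges = [
            EdgeStats((0, 1), 3.2, 0.001, 0.003, True),
            EdgeStats((0, 2), 0.4, 0.7, 0.7, False),
        ]
        write_viewer_files(
            atlas, np.array([0.5, 0.3, 0.2]), edges,
            tmp_path / "nodes.txt", tmp_path / "edges.txt",
        )
        mat = np.loadtxt(tmp_path / "edges.txt")
        assert mat[0, 1] == pytest.approx(3.2) and mat[1, 0] == pytest.approx(3.2)
        assert mat[0, 2] == 0.0  # non-significant edge not drawn
        assert len((tmp_path / "nodes.txt").read_text().strip().splitlines()) == 3

    def test_centroid_region_map_groups_nearby_rois(self):
        a1 = AtlasSpec("a1", 2, ("p", "q"), centroids=np.array([[0, 0, 0], [50, 0, 0]]))
        a2 = AtlasSpec(
            "a2", 2, ("u", "v"), centroids=np.array([[2, 0, 0], [48, 0, 0]])
        )
        mapping = region_map_from_centroids([a1, a2], threshold_mm=10.0)
        assert mapping[("a2", "u")] == "p"
        assert mapping[("a2", "v")] == "q"
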