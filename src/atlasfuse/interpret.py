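"""Interpretability: ROI attention, top-k rankings, discriminative edges.

Three outputs mirror how connectome classifiers are usually interrogated:

1. per-ROI attention weights — the attention mass each ROI *receives*
   inside the SAT layers, averaged over heads, layers and subjects — with a
   top-10 ranking per atlas;
2. cross-atlas overlap of the top-ranked regions (matched by a region map:
   centroid proximity when centroids exist, else label matching);
3. edge statistics among the top ROIs: Welch two-sample t-tests on FC
   values between groups, Benjamini-Hochberg corrected, significant at
   q < 0.05.

The attention definition (received mass, all layers) is one convention
among several; it is isolated in :func:`subject_roi_attention` so it can be
swapped without touching the reporting code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fc_graphs import BrainGraph, FCMatrix
from .fusion import MultiAtlasClassifier


@dataclass
class AttentionReport:
    """Per-ROI mean attention weights for one atlas, with a top-k ranking."""

    atlas_name: str
    roi_labels: tuple[str, ...]
    roi_weights: np.ndarray
    top_k: list[tuple[int, str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rank = (-self.roi_weights).argsort(kind="stable")
        ranks = np.empty_like(rank)
        ranks[rank] = np.arange(1, len(rank) + 1)
        return pd.DataFrame(
            {
                "atlas": self.atlas_name,
                "roi_index": np.arange(len(self.roi_weights)),
                "roi_label": list(self.roi_labels),
                "mean_weight": self.roi_weights,
                "rank": ranks,
            }
        )


@dataclass
class EdgeStats:
    """Group-difference statistics for one ROI pair (i < j)."""

    roi_pair: tuple[int, int]
    t_statistic: float
    p_value: float
    q_value: float
    significant: bool
    degenerate: bool = False


def subject_roi_attention(attentions: list[np.ndarray]) -> np.ndarray:
    """Attention mass received by each node, averaged over layers and heads.

    Each layer contributes an (n_heads, n, n) matrix with rows on the
    simplex; column means give the mass node j receives, which sums to 1
    over nodes.  Layers and heads are averaged uniformly.
    """
    if not attentions:
        raise ValueError("no attention matrices supplied")
    per_layer = [a.mean(axis=(0, 1)) for a in attentions]  # mean over heads, queries
    return np.mean(per_layer, axis=0)


def roi_attention(
    model: MultiAtlasClassifier,
    cohort_graphs: list[dict[str, BrainGraph]],
    atlas_name: str,
    k: int = 10,
) -> AttentionReport:
    """Average per-ROI attention over all subjects of a (training) cohort."""
    if not getattr(model, "trained", False):
        raise RuntimeError("model has not been trained; attention is meaningless")
    weights = []
    roi_labels = None
    for graphs in cohort_graphs:
        graph = graphs[atlas_name]
        roi_labels = graph.atlas.roi_labels
        _, _, attention = model.forward(graphs, rng=None, collect_attention=True)
        weights.append(subject_roi_attention(attention[atlas_name]))
    report = AttentionReport(atlas_name, roi_labels, np.mean(weights, axis=0))
    report.top_k = top_k_rois(report, k)
    return report


def top_k_rois(report: AttentionReport, k: int = 10) -> list[tuple[int, str, float]]:
    """Top-k ROIs by mean attention; ties break toward the lower ROI index."""
    n = len(report.roi_weights)
    if k > n:
        raise ValueError(f"k={k} exceeds n_rois={n}")
    order = np.lexsort((np.arange(n), -report.roi_weights))[:k]
    return [(int(i), report.roi_labels[i], float(report.roi_weights[i])) for i in order]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def discriminative_edges(
    fc_matrices: list[FCMatrix],
    labels: np.ndarray,
    roi_subset: list[int],
    alpha: float = 0.05,
) -> list[EdgeStats]:
    """Welch t-tests on every FC edge within ``roi_subset``, BH-corrected.

    Significance is declared at q < ``alpha`` over the C(k, 2) tested pairs
    jointly (one BH family per atlas).  An edge constant in both groups is
    recorded with p = 1 and flagged degenerate.
    """
    labels = np.asarray(labels)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    stack = np.stack([fc.values for fc in fc_matrices])
    cases, controls = stack[labels == 1], stack[labels == 0]
    pairs = list(combinations(sorted(roi_subset), 2))
    t_vals, p_vals, degenerate = [], [], []
    for i, j in pairs:
        a, b = cases[:, i, j], controls[:, i, j]
        if a.std() == 0.0 and b.std() == 0.0:
            t_vals.append(0.0)
            p_vals.append(1.0)
            degenerate.append(True)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        t_vals.append(float(t))
        p_vals.append(float(p))
        degenerate.append(False)
    q_vals = bh_fdr(p_vals)
    return [
        EdgeStats((i, j), t, p, float(q), bool(q < alpha), deg)
        for (i, j), t, p, q, deg in zip(pairs, t_vals, p_vals, q_vals, degenerate)
    ]


def edge_stats_to_frame(edge_stats: list[EdgeStats], atlas_name: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "atlas": atlas_name,
            "roi_i": [e.roi_pair[0] for e in edge_stats],
            "roi_j": [e.roi_pair[1] for e in edge_stats],
            "t": [e.t_statistic for e in edge_stats],
            "p": [e.p_value for e in edge_stats],
            "q": [e.q_value for e in edge_stats],
            "significant": [e.significant for e in edge_stats],
        }
    )


# -- cross-atlas overlap ------------------------------------------------------
def region_map_from_centroids(atlases, threshold_mm: float = 10.0) -> dict[tuple[str, str], str]:
    """Match ROIs across atlases whose centroids lie within ``threshold_mm``.

    Regions are grouped greedily around the first atlas's ROIs; the group
    key is that anchor ROI's label.  Atlases without centroids cannot use
    this map.
    """
    mapping: dict[tuple[str, str], str] = {}
    anchor = atlases[0]
    if anchor.centroids is None:
        raise ValueError("centroid mapping requires centroids on every atlas")
    for atlas in atlases:
        if atlas.centroids is None:
            raise ValueError(f"atlas {atlas.name!r} has no centroids")
        d = np.linalg.norm(
            atlas.centroids[:, None, :] - anchor.centroids[None, :, :], axis=-1
        )
        nearest = d.argmin(axis=1)
        for i, (j, dist) in enumerate(zip(nearest, d[np.arange(len(nearest)), nearest])):
            if dist <= threshold_mm:
                mapping[(atlas.name, atlas.roi_labels[i])] = anchor.roi_labels[j]
    return mapping


def cross_atlas_overlap(
    top_lists: dict[str, list[tuple[int, str, float]]],
    region_map: dict[tuple[str, str], str],
) -> dict[str, list]:
    """Group top-ranked regions by how many atlases agree on them.

    Returns buckets ``three_atlas`` (region in all three lists),
    ``two_atlas``, ``singleton`` and ``unmatched`` (labels absent from the
    region map — reported, never silently dropped).
    """
    seen: dict[str, set[str]] = {}
    unmatched: list[tuple[str, str]] = []
    for atlas_name, entries in top_lists.items():
        for _, label, _ in entries:
            key = region_map.get((atlas_name, label))
            if key is None:
                unmatched.append((atlas_name, label))
            else:
                seen.setdefault(key, set()).add(atlas_name)
    buckets: dict[str, list] = {"three_atlas": [], "two_atlas": [], "singleton": [], "unmatched": unmatched}
    for region, atlas_set in sorted(seen.items()):
        count = len(atlas_set)
        if count >= 3:
            buckets["three_atlas"].append((region, sorted(atlas_set)))
        elif count == 2:
            buckets["two_atlas"].append((region, sorted(atlas_set)))
        else:
            buckets["singleton"].append((region, sorted(atlas_set)))
    return buckets


def write_viewer_files(
    atlas, roi_weights: np.ndarray, edge_stats: list[EdgeStats], node_path, edge_path
) -> None:
    """Plain-text node/edge files for brain-network viewers.

    Node rows: x, y, z, weight, label (centroids required).  The edge file
    is a full n x n matrix holding the t-statistic of significant edges and
    zero elsewhere.
    """
    if atlas.centroids is None:
        raise ValueError("viewer node files require atlas centroids")
    with open(node_path, "w") as fh:
        for (x, y, z), w, label in zip(atlas.centroids, roi_weights, atlas.roi_labels):
            fh.write(f"{x:.2f}\t{y:.2f}\t{z:.2f}\t{w:.6f}\t{label}\n")
    mat = np.zeros((atlas.n_rois, atlas.n_rois))
    for e in edge_stats:
        if e.significant:
            i, j = e.roi_pair
            mat[i, j] = mat[j, i] = e.t_statistic
    np.savetxt(edge_path, mat, fmt="%.6f", delimiter="\t")
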