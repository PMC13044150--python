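"""Functional-connectivity matrices and KNN-sparsified brain graphs.

Pipeline: per-subject ROI time series -> Pearson functional-connectivity
(FC) matrix -> K-nearest-neighbor sparsification (K = 15 by default) ->
undirected weighted graph whose node features are the FC row profiles.

Conventions (documented because the field has no single standard):

* neighbor ranking uses the *signed* correlation by default, keeping the
  strongest positive couplings; ``metric="absolute"`` ranks by magnitude;
* directed KNN selections are symmetrized by union, so every node keeps
  degree >= K;
* ties at the K-th neighbor break toward the lower ROI index, making graph
  construction deterministic across platforms;
* correlations are used raw (no Fisher z-transform) for both edge weights
  and node features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasSpec

logger = logging.getLogger(__name__)

DEFAULT_K = 15  #: KNN sparsification parameter


class DegenerateSignalError(ValueError):
    """An ROI time series has zero variance, so its correlations are undefined."""


class CohortFormatError(ValueError):
    """A cohort file violates the expected schema."""


@dataclass
class SubjectTimeSeries:
    """One subject's ROI time series under one atlas (timepoints x n_rois)."""

    subject_id: str
    atlas: AtlasSpec
    data: np.ndarray
    label: int

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise CohortFormatError(
                f"subject {self.subject_id}: need a 2-D array with >= 2 timepoints"
            )
        if self.data.shape[1] != self.atlas.n_rois:
            raise CohortFormatError(
                f"subject {self.subject_id}: {self.data.shape[1]} columns but atlas "
                f"{self.atlas.name!r} has {self.atlas.n_rois} ROIs"
            )
        if not np.isfinite(self.data).all():
            raise CohortFormatError(
                f"subject {self.subject_id}: non-finite values in time series"
            )
        if self.label not in (0, 1):
            raise CohortFormatError(
                f"subject {self.subject_id}: label must be 0 (control) or 1 (case)"
            )


@dataclass
class FCMatrix:
    """Symmetric ROI x ROI Pearson-correlation matrix — the connectome."""

    subject_id: str
    atlas: AtlasSpec
    values: np.ndarray
    label: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.atlas.n_rois
        if self.values.shape != (n, n):
            raise ValueError(f"FC matrix must be {n}x{n}")


@dataclass
class BrainGraph:
    """KNN-sparsified undirected graph consumed by the encoder.

    ``adjacency`` is the symmetric weighted matrix (zero diagonal);
    ``edges`` lists each undirected edge once as (i, j, weight) with i < j.
    """

    subject_id: str
    atlas: AtlasSpec
    adjacency: np.ndarray
    node_features: np.ndarray
    label: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        iu, ju = np.nonzero(np.triu(self.adjacency != 0.0, k=1))
        return [(int(i), int(j), float(self.adjacency[i, j])) for i, j in zip(iu, ju)]

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.edges}


def compute_fc(ts: SubjectTimeSeries) -> FCMatrix:
    """Pearson correlation between every pair of ROI time series.

    Raises :class:`DegenerateSignalError` naming the first constant ROI, since
    a zero-variance signal has no defined correlation with anything.
    """
    sd = ts.data.std(axis=0)
    dead = np.nonzero(sd == 0.0)[0]
    if dead.size:
        label = ts.atlas.roi_labels[dead[0]]
        raise DegenerateSignalError(
            f"subject {ts.subject_id}: ROI {label!r} (column {dead[0]}) has zero "
            "variance; correlation is undefined"
        )
    values = np.corrcoef(ts.data, rowvar=False)
    np.clip(values, -1.0, 1.0, out=values)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0
    return FCMatrix(ts.subject_id, ts.atlas, values, label=ts.label)


def knn_sparsify(fc: FCMatrix, k: int = DEFAULT_K, metric: str = "signed") -> BrainGraph:
    """Keep each node's K most similar neighbors; symmetrize by union.

    Similarity is the signed correlation (``metric="signed"``, default) or
    its absolute value (``metric="absolute"``).  Edge weights are the raw
    correlation values.  Ties at the K-th rank break toward the lower index.
    """
    n = fc.atlas.n_rois
    if not 1 <= k <= n - 1:
        raise ValueError(f"K must be in [1, n_rois-1] = [1, {n - 1}], got {k}")
    if metric not in ("signed", "absolute"):
        raise ValueError(f"unknown knn metric {metric!r}")
    sim = fc.values.copy() if metric == "signed" else np.abs(fc.values)
    np.fill_diagonal(sim, -np.inf)  # a node never selects itself
    # stable ranking: descending similarity, ascending index on ties
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), -sim), axis=1)
    selected = order[:, :k]
    directed = np.zeros((n, n), dtype=bool)
    np.put_along_axis(directed, selected, True, axis=1)
    keep = directed | directed.T
    adjacency = np.where(keep, fc.values, 0.0)
    np.fill_diagonal(adjacency, 0.0)
    return BrainGraph(
        fc.subject_id, fc.atlas, adjacency, build_node_features(fc), fc.label
    )


def build_node_features(fc: FCMatrix) -> np.ndarray:
    """Node features are the FC row profiles: feature of ROI i = row i."""
    return fc.values.copy()


def graph_from_timeseries(
    ts: SubjectTimeSeries, k: int = DEFAULT_K, metric: str = "signed"
) -> BrainGraph:
    """Convenience: ``compute_fc`` then ``knn_sparsify``."""
    return knn_sparsify(compute_fc(ts), k=k, metric=metric)


def _read_timeseries_file(path: Path, atlas: AtlasSpec) -> np.ndarray:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    first = pd.read_csv(path, sep=sep, nrows=1, header=None)
    has_header = not np.issubdtype(first.to_numpy().dtype, np.number)
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    data = df.to_numpy(dtype=float)
    if data.shape[1] != atlas.n_rois:
        raise CohortFormatError(
            f"{path.name}: {data.shape[1]} columns, atlas {atlas.name!r} "
            f"expects {atlas.n_rois}"
        )
    return data


def timeseries_path(timeseries_dir, subject_id: str, atlas_name: str) -> Path:
    """Canonical layout: ``<dir>/<atlas>/<subject_id>.tsv``."""
    return Path(timeseries_dir) / atlas_name / f"{subject_id}.tsv"


def load_cohort(
    timeseries_dir,
    phenotype_csv,
    atlases: list[AtlasSpec],
) -> dict[str, list[SubjectTimeSeries]]:
    """Load an aligned multi-atlas cohort.

    The phenotype CSV must have ``subject_id`` and ``label`` (0/1) columns.
    Subjects missing a time-series file for any requested atlas are dropped
    with a logged warning; the returned lists are aligned (same subject
    order) across atlases.
    """
    pheno = pd.read_csv(phenotype_csv, dtype={"subject_id": str})
    if not {"subject_id", "label"}.issubset(pheno.columns):
        raise CohortFormatError("phenotype table needs subject_id and label columns")
    bad = set(pheno["label"].unique()) - {0, 1}
    if bad:
        raise CohortFormatError(f"labels must be 0/1, found {sorted(bad)}")
    cohort: dict[str, list[SubjectTimeSeries]] = {a.name: [] for a in atlases}
    for _, row in pheno.iterrows():
        sid, label = str(row["subject_id"]), int(row["label"])
        paths = {a.name: timeseries_path(timeseries_dir, sid, a.name) for a in atlases}
        missing = [name for name, p in paths.items() if not p.exists()]
        if missing:
            logger.warning(
                "subject %s dropped: missing time series for atlas(es) %s",
                sid,
                ", ".join(missing),
            )
            continue
        for a in atlases:
            data = _read_timeseries_file(paths[a.name], a)
            cohort[a.name].append(SubjectTimeSeries(sid, a, data, label))
    return cohort
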