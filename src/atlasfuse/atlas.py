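"""Brain-parcellation (atlas) descriptors.

An atlas partitions the brain into named regions of interest (ROIs); each
subject contributes one time series per ROI per atlas.  The framework is
atlas-agnostic: common choices are AAL (116 ROIs), Craddock-200 (200) and
Brainnetome (246), but any parcellation with unique ROI labels works.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AtlasSpec:
    """Static description of one parcellation.

    Parameters
    ----------
    name:
        Short identifier, e.g. ``"aal116"``.
    n_rois:
        Number of regions in the parcellation.
    roi_labels:
        One unique label per ROI, in column order of the time-series files.
    centroids:
        Optional (n_rois, 3) array of ROI centroid coordinates in a common
        reference space (used for cross-atlas region matching).
    lobe_tags:
        Optional anatomical-lobe label per ROI.
    """

    name: str
    n_rois: int
    roi_labels: tuple[str, ...]
    centroids: np.ndarray | None = field(default=None, compare=False)
    lobe_tags: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_rois <= 0:
            raise ValueError("n_rois must be positive")
        if len(self.roi_labels) != self.n_rois:
            raise ValueError(
                f"atlas {self.name!r}: {len(self.roi_labels)} labels for "
                f"{self.n_rois} ROIs"
            )
        if len(set(self.roi_labels)) != self.n_rois:
            raise ValueError(f"atlas {self.name!r}: ROI labels must be unique")
        if self.centroids is not None:
            cent = np.asarray(self.centroids, dtype=float)
            if cent.shape != (self.n_rois, 3):
                raise ValueError(
                    f"atlas {self.name!r}: centroids must be (n_rois, 3)"
                )
            object.__setattr__(self, "centroids", cent)
        if self.lobe_tags is not None and len(self.lobe_tags) != self.n_rois:
            raise ValueError(f"atlas {self.name!r}: one lobe tag per ROI required")

    @classmethod
    def generic(cls, name: str, n_rois: int) -> "AtlasSpec":
        """An anonymous parcellation with auto-generated ROI labels."""
        return cls(name, n_rois, tuple(f"{name}_roi{i + 1}" for i in range(n_rois)))

    @classmethod
    def from_csv(cls, name: str, path) -> "AtlasSpec":
        """Read an atlas descriptor CSV.

        Expected columns: ``roi_index`` (1-based), ``roi_label``, optional
        ``x, y, z`` centroid coordinates and optional ``lobe``.
        """
        df = pd.read_csv(path)
        df = df.sort_values("roi_index")
        if not (df["roi_index"].to_numpy() == np.arange(1, len(df) + 1)).all():
            raise ValueError(f"{path}: roi_index must be contiguous and 1-based")
        labels = tuple(str(x) for x in df["roi_label"])
        centroids = None
        if {"x", "y", "z"}.issubset(df.columns):
            centroids = df[["x", "y", "z"]].to_numpy(dtype=float)
        lobes = tuple(str(x) for x in df["lobe"]) if "lobe" in df.columns else None
        return cls(name, len(df), labels, centroids=centroids, lobe_tags=lobes)

    def to_csv(self, path) -> None:
        data = {
            "roi_index": np.arange(1, self.n_rois + 1),
            "roi_label": list(self.roi_labels),
        }
        if self.centroids is not None:
            data["x"], data["y"], data["z"] = self.centroids.T
        if self.lobe_tags is not None:
            data["lobe"] = list(self.lobe_tags)
        pd.DataFrame(data).to_csv(path, index=False)
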