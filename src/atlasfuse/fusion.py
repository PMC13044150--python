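"""Lightweight attentional feature fusion (LAFF) across atlases + classifier.

Instead of pairwise query-key-value attention (quadratic in the number of
atlases), each projected atlas embedding is scored by one shared learned
affine map; scores pass through a softmax to give nonnegative per-atlas
weights summing to 1, and the fused representation is the weighted sum.
The cost is linear in the number of atlases, and the weights themselves are
the interpretable "which atlas mattered" output.

The diagnosis head is a one-hidden-layer MLP (ReLU, dropout) with a 2-unit
softmax output; class 0 is the control group, class 1 the case group, and
prediction ties break toward control.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .fc_graphs import BrainGraph
from .nn import Params, dropout, linear, linear_params, mlp2, softmax
from .sat import SATConfig, encode_graph, sat_params

CHECKPOINT_VERSION = 1

# instrumentation: number of scalar scoring operations performed by
# laff_weights since the last reset (used to verify linear cost in atlases)
_SCORE_OPS = [0]


def reset_score_op_count() -> None:
    _SCORE_OPS[0] = 0


def score_op_count() -> int:
    return _SCORE_OPS[0]


@dataclass
class FusionWeights:
    """Per-atlas attention weights on the simplex (nonnegative, sum to 1)."""

    atlas_names: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.atlas_names) != self.weights.size:
            raise ValueError("one weight per atlas required")
        if (self.weights < -1e-9).any() or abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("fusion weights must be nonnegative and sum to 1")


@dataclass
class FusedRepresentation:
    subject_id: str
    vector: np.ndarray
    weights: FusionWeights


def laff_weights(embeddings: list[Tensor], params: Params, prefix: str = "laff") -> Tensor:
    """Score each atlas embedding with the shared affine map; softmax-normalize.

    All embeddings must already live in the common fusion dimension.  A
    single atlas degenerates to weight 1.0.
    """
    if not embeddings:
        raise ValueError("at least one atlas embedding required")
    scores = []
    for emb in embeddings:
        scores.append(linear(emb.reshape(1, -1), params, f"{prefix}.score").reshape(1))
        _SCORE_OPS[0] += 1
    return softmax(ad.concatenate(scores, axis=0), axis=0)


def fuse(embeddings: list[Tensor], weights: Tensor) -> Tensor:
    """Weighted sum of atlas embeddings (linear in the embeddings)."""
    if len(embeddings) != weights.shape[0]:
        raise ValueError("one weight per embedding required")
    out = embeddings[0] * weights.gather_rows(np.array([0]))
    for m in range(1, len(embeddings)):
        out = out + embeddings[m] * weights.gather_rows(np.array([m]))
    return out


def classify(
    rep: Tensor,
    params: Params,
    drop: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Two-class probabilities from the fused representation."""
    logits = mlp2(rep.reshape(1, -1), params, "clf", drop, rng).reshape(2)
    return softmax(logits, axis=0)


def predict_label(probabilities: np.ndarray) -> int:
    """Argmax decision; an exact tie breaks toward the control class (0)."""
    return int(probabilities[1] > probabilities[0])


class MultiAtlasClassifier:
    """SAT encoders per atlas + LAFF fusion + MLP diagnosis head.

    Parameters are a flat name->Tensor dictionary initialized from one seed;
    ``rng=None`` in the forward pass selects evaluation mode (no dropout,
    bit-reproducible outputs).
    """

    def __init__(
        self,
        atlas_dims: dict[str, int],
        sat_config: SATConfig | None = None,
        fusion_dim: int = 32,
        clf_hidden: int = 32,
        seed: int = 0,
    ):
        self.atlas_names = tuple(atlas_dims)
        self.atlas_dims = dict(atlas_dims)
        self.sat_config = sat_config or SATConfig()
        self.fusion_dim = fusion_dim
        self.clf_hidden = clf_hidden
        self.seed = seed
        self.trained = False
        rng = np.random.default_rng(seed)
        p: Params = {}
        for name, in_dim in atlas_dims.items():
            p.update(sat_params(rng, in_dim, self.sat_config, f"enc.{name}"))
            p.update(
                linear_params(rng, self.sat_config.hidden_dim, fusion_dim, f"proj.{name}")
            )
        p.update(linear_params(rng, fusion_dim, 1, "laff.score"))
        p.update(linear_params(rng, fusion_dim, clf_hidden, "clf.fc1"))
        p.update(linear_params(rng, clf_hidden, 2, "clf.fc2"))
        self.params = p

    # -- forward -------------------------------------------------------------
    def forward(
        self,
        graphs: dict[str, BrainGraph],
        rng: np.random.Generator | None = None,
        collect_attention: bool = False,
        uniform_fusion: bool = False,
    ) -> tuple[Tensor, Tensor, dict[str, list[np.ndarray]]]:
        """One subject through the full model.

        Returns (class probabilities, fusion weights, per-atlas attention
        matrices).  ``graphs`` maps atlas name -> that subject's graph.
        ``uniform_fusion`` bypasses the learned scorer and fuses with equal
        weights — used for balanced warm-up so no atlas branch is starved
        of gradient before the scorer has seen trained embeddings.
        """
        projected, attention = [], {}
        for name in self.atlas_names:
            emb, attns = encode_graph(
                graphs[name], self.sat_config, self.params, f"enc.{name}", rng
            )
            projected.append(linear(emb.reshape(1, -1), self.params, f"proj.{name}").reshape(-1))
            if collect_attention:
                attention[name] = attns
        if uniform_fusion:
            m = len(projected)
            weights = Tensor(np.full(m, 1.0 / m))
        else:
            weights = laff_weights(projected, self.params)
        fused = fuse(projected, weights)
        fused = dropout(fused, self.sat_config.dropout_rate, rng)
        probs = classify(fused, self.params, self.sat_config.dropout_rate, rng)
        return probs, weights, attention

    def predict_proba(self, graphs: dict[str, BrainGraph]) -> np.ndarray:
        probs, _, _ = self.forward(graphs, rng=None)
        return probs.data.copy()

    def fusion_weights(self, graphs: dict[str, BrainGraph]) -> FusionWeights:
        _, w, _ = self.forward(graphs, rng=None)
        return FusionWeights(self.atlas_names, w.data.copy())

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        header = {
            "version": CHECKPOINT_VERSION,
            "atlas_dims": self.atlas_dims,
            "sat_config": vars(self.sat_config) | {},
            "fusion_dim": self.fusion_dim,
            "clf_hidden": self.clf_hidden,
            "seed": self.seed,
        }
        arrays = {k.replace("/", "_"): v.data for k, v in self.params.items()}
        with open(path, "wb") as fh:
            np.savez(fh, __header__=np.frombuffer(
                json.dumps(header).encode(), dtype=np.uint8
            ), **arrays)

    @classmethod
    def load(cls, path) -> "MultiAtlasClassifier":
        with np.load(path) as archive:
            header = json.loads(bytes(archive["__header__"]).decode())
            if header["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {header['version']}")
            model = cls(
                header["atlas_dims"],
                SATConfig(**header["sat_config"]),
                fusion_dim=header["fusion_dim"],
                clf_hidden=header["clf_hidden"],
                seed=header["seed"],
            )
            for key in model.params:
                model.params[key].data = archive[key].copy()
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k].data = state[k].copy()


def report_atlas_attention(
    model: MultiAtlasClassifier,
    cohort_graphs: list[dict[str, BrainGraph]],
    task: str = "task",
) -> pd.DataFrame:
    """Mean +- sd of per-subject LAFF weights over an evaluation cohort.

    One row per atlas: columns task, atlas, mean_weight, sd_weight.
    """
    all_w = np.stack(
        [model.fusion_weights(graphs).weights for graphs in cohort_graphs]
    )
    return pd.DataFrame(
        {
            "task": task,
            "atlas": list(model.atlas_names),
            "mean_weight": all_w.mean(axis=0),
            "sd_weight": all_w.std(axis=0, ddof=0),
        }
    )
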