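"""Synthetic multi-atlas cohorts with planted connectivity pathologies.

The generative model emulates what a multi-atlas resting-state study sees:
a shared latent brain signal, observed through several parcellations.

* ``n_latent`` zero-mean unit-variance Gaussian sources share a baseline
  correlation matrix; in cases, the coupling of designated source pairs
  (``effect_edges``) is shifted by ``effect_delta`` (hypo-connectivity for
  negative deltas), and the shifted matrix is repaired to the nearest valid
  correlation matrix.
* every ROI of every atlas is assigned to exactly one source
  (``loading_map``); its time series is the source series plus independent
  Gaussian noise of standard deviation ``noise_sd``.

Consequences used by the tests: the expected ROI-level correlation between
ROIs on sources s and t is ``C[s, t] / (1 + noise_sd**2)`` (and
``1 / (1 + noise_sd**2)`` for two ROIs on the same source), so the planted
group difference lands only on ROI pairs bridging affected sources, and its
size is known in closed form.  The exact planted ROI sets are recorded as
ground truth for recovery scoring.

The default "toy" scenario uses three small atlases (20/34/42 ROIs) over 12
sources so the full nested-CV recovery experiment runs on one CPU in
minutes; ``full_scale_atlases`` provides 116/200/246-ROI parcellations for
slower optional runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

from .atlas import AtlasSpec
from .fc_graphs import SubjectTimeSeries, timeseries_path

DEFAULT_TIMEPOINTS = 195  #: matches a typical resting-state acquisition length
DEFAULT_NOISE_SD = 0.5
DEFAULT_EFFECT_DELTA = -0.4
DEFAULT_BASELINE_COUPLING = 0.2


@dataclass
class SimSpec:
    """Full description of a synthetic two-group multi-atlas cohort."""

    n_cases: int
    n_controls: int
    atlases: list[AtlasSpec]
    loading_map: dict[str, np.ndarray]
    effect_edges: list[tuple[int, int]]
    effect_delta: float = DEFAULT_EFFECT_DELTA
    noise_sd: float = DEFAULT_NOISE_SD
    n_timepoints: int = DEFAULT_TIMEPOINTS
    n_latent: int = 12
    baseline_coupling: float = DEFAULT_BASELINE_COUPLING
    seed: int = 0

    def __post_init__(self):
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for atlas in self.atlases:
            lm = np.asarray(self.loading_map[atlas.name], dtype=int)
            if lm.shape != (atlas.n_rois,):
                raise ValueError(
                    f"loading map for {atlas.name!r} must assign every ROI a source"
                )
            if lm.min() < 0 or lm.max() >= self.n_latent:
                raise ValueError(f"loading map for {atlas.name!r}: source out of range")
            self.loading_map[atlas.name] = lm
        for s, t in self.effect_edges:
            if not (0 <= s < self.n_latent and 0 <= t < self.n_latent and s != t):
                raise ValueError(f"invalid effect edge ({s}, {t})")


@dataclass
class GroundTruth:
    spec: SimSpec
    planted_rois: dict[str, list[int]]


@dataclass
class SyntheticCohort:
    subjects: dict[str, list[SubjectTimeSeries]]  # atlas name -> aligned list
    ground_truth: GroundTruth

    @property
    def labels(self) -> np.ndarray:
        first = next(iter(self.subjects.values()))
        return np.array([ts.label for ts in first])


def source_correlation(spec: SimSpec, group: int) -> np.ndarray:
    """Latent-source correlation matrix for controls (0) or cases (1).

    Cases get ``effect_delta`` added on every effect edge; the result is
    repaired to the nearest correlation matrix.  If the repair has to move
    any entry by more than 0.01 the requested effect is deemed infeasible.
    """
    c = np.full((spec.n_latent, spec.n_latent), spec.baseline_coupling)
    np.fill_diagonal(c, 1.0)
    if group == 1:
        for s, t in spec.effect_edges:
            c[s, t] += spec.effect_delta
            c[t, s] += spec.effect_delta
    if np.abs(c[~np.eye(spec.n_latent, dtype=bool)]).max() > 1.0:
        raise ValueError("effect_delta pushes a coupling outside [-1, 1]")
    eigmin = np.linalg.eigvalsh(c).min()
    if eigmin < 1e-10:
        repaired = corr_nearest(c, threshold=1e-8, n_fact=200)
        if np.abs(repaired - c).max() > 0.01:
            raise ValueError(
                "planted effect not repairable to a valid correlation matrix; "
                "use a smaller |effect_delta|"
            )
        c = repaired
    return c


def expected_fc(spec: SimSpec, atlas: AtlasSpec, group: int) -> np.ndarray:
    """Closed-form expected ROI-level FC under the generative model."""
    c = source_correlation(spec, group)
    lm = spec.loading_map[atlas.name]
    atten = 1.0 / (1.0 + spec.noise_sd**2)
    fc = c[np.ix_(lm, lm)] * atten
    same = lm[:, None] == lm[None, :]
    fc[same] = atten
    np.fill_diagonal(fc, 1.0)
    return fc


def planted_roi_sets(spec: SimSpec) -> dict[str, list[int]]:
    """ROIs (per atlas) whose latent source participates in any effect edge."""
    affected = {s for edge in spec.effect_edges for s in edge}
    return {
        atlas.name: sorted(
            int(i) for i in np.nonzero(np.isin(spec.loading_map[atlas.name], list(affected)))[0]
        )
        for atlas in spec.atlases
    }


def generate_cohort(spec: SimSpec) -> SyntheticCohort:
    """Draw the cohort.  All randomness comes from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    chol = {}
    for group in (0, 1):
        c = source_correlation(spec, group)
        chol[group] = np.linalg.cholesky(c + 1e-12 * np.eye(spec.n_latent))
    labels = np.concatenate(
        [np.zeros(spec.n_controls, dtype=int), np.ones(spec.n_cases, dtype=int)]
    )
    subjects: dict[str, list[SubjectTimeSeries]] = {a.name: [] for a in spec.atlases}
    for idx, label in enumerate(labels):
        sid = f"sub-{idx:04d}"
        latent = rng.standard_normal((spec.n_timepoints, spec.n_latent)) @ chol[label].T
        for atlas in spec.atlases:
            lm = spec.loading_map[atlas.name]
            noise = spec.noise_sd * rng.standard_normal((spec.n_timepoints, atlas.n_rois))
            data = latent[:, lm] + noise
            subjects[atlas.name].append(SubjectTimeSeries(sid, atlas, data, int(label)))
    return SyntheticCohort(subjects, GroundTruth(spec, planted_roi_sets(spec)))


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write the delimited-text layout that :func:`fc_graphs.load_cohort` reads.

    One TSV per subject per atlas (header row = ROI labels), one phenotype
    CSV, one atlas descriptor CSV per atlas, and the ground truth as JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort.ground_truth.spec
    pheno_rows = []
    first_atlas = spec.atlases[0].name
    for ts in cohort.subjects[first_atlas]:
        pheno_rows.append({"subject_id": ts.subject_id, "label": ts.label})
    pd.DataFrame(pheno_rows).to_csv(out / "phenotype.csv", index=False)
    for atlas in spec.atlases:
        (out / atlas.name).mkdir(exist_ok=True)
        atlas.to_csv(out / f"atlas_{atlas.name}.csv")
        for ts in cohort.subjects[atlas.name]:
            path = timeseries_path(out, ts.subject_id, atlas.name)
            pd.DataFrame(ts.data, columns=list(atlas.roi_labels)).to_csv(
                path, sep="\t", index=False
            )
    truth = {
        "planted_rois": cohort.ground_truth.planted_rois,
        "effect_edges": [list(e) for e in spec.effect_edges],
        "effect_delta": spec.effect_delta,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))


# -- shipped scenarios --------------------------------------------------------
def _loading(counts: dict[int, int], n_rois: int, rng: np.random.Generator) -> np.ndarray:
    """Expand {source: n_rois_on_source} into a per-ROI source vector.

    The assignment is shuffled (deterministically) so that ROI index order
    carries no information about source membership — otherwise any ranking
    that breaks ties toward low indices would look spuriously good at
    recovering the planted ROIs.
    """
    lm = np.concatenate([np.full(n, s) for s, n in sorted(counts.items())])
    if lm.size != n_rois:
        raise ValueError("loading counts do not sum to n_rois")
    return rng.permutation(lm)


def toy_atlases(n_latent: int = 12, seed: int = 12345) -> tuple[list[AtlasSpec], dict[str, np.ndarray]]:
    """Three toy parcellations (20/34/42 ROIs) of the same 12-source brain.

    Synthetic centroids place every ROI near its source's location (sources
    on a 40 mm grid, ROI jitter <= 3 mm), so centroid-based cross-atlas
    region matching behaves like it does with real atlas tables.  The
    42-ROI atlas maps the most ROIs onto the first two sources and thus
    carries the strongest planted signal in the default recovery scenario.
    """
    rng = np.random.default_rng(seed)
    source_xyz = np.stack(
        np.meshgrid(np.arange(3) * 40.0, np.arange(2) * 40.0, np.arange(2) * 40.0),
        axis=-1,
    ).reshape(-1, 3)[:n_latent]
    counts = {
        "toyA20": {0: 2, 1: 2, 2: 2, 3: 2, 4: 2, 5: 2, 6: 2, 7: 2, 8: 1, 9: 1, 10: 1, 11: 1},
        "toyB34": {0: 3, 1: 3, 2: 3, 3: 3, 4: 3, 5: 3, 6: 3, 7: 3, 8: 3, 9: 3, 10: 2, 11: 2},
        "toyC42": {0: 5, 1: 5, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3, 7: 3, 8: 3, 9: 3, 10: 3, 11: 3},
    }
    atlases, loading = [], {}
    for name, cnt in counts.items():
        n_rois = sum(cnt.values())
        lm = _loading(cnt, n_rois, rng)
        centroids = source_xyz[lm] + rng.uniform(-3.0, 3.0, size=(n_rois, 3))
        atlases.append(
            AtlasSpec(
                name,
                n_rois,
                tuple(f"{name}_s{s}_r{i}" for i, s in enumerate(lm)),
                centroids=centroids,
            )
        )
        loading[name] = lm
    return atlases, loading


def full_scale_atlases(n_latent: int = 12, seed: int = 12345) -> tuple[list[AtlasSpec], dict[str, np.ndarray]]:
    """116/200/246-ROI parcellations of the same latent brain (slow runs)."""
    rng = np.random.default_rng(seed)
    source_xyz = np.stack(
        np.meshgrid(np.arange(3) * 40.0, np.arange(2) * 40.0, np.arange(2) * 40.0),
        axis=-1,
    ).reshape(-1, 3)[:n_latent]
    atlases, loading = [], {}
    for name, n_rois in (("scale116", 116), ("scale200", 200), ("scale246", 246)):
        base, extra = divmod(n_rois, n_latent)
        cnt = {s: base + (1 if s < extra else 0) for s in range(n_latent)}
        lm = _loading(cnt, n_rois, rng)
        centroids = source_xyz[lm] + rng.uniform(-3.0, 3.0, size=(n_rois, 3))
        atlases.append(
            AtlasSpec(
                name,
                n_rois,
                tuple(f"{name}_s{s}_r{i}" for i, s in enumerate(lm)),
                centroids=centroids,
            )
        )
        loading[name] = lm
    return atlases, loading


def recovery_spec(
    seed: int = 0,
    n_cases: int = 60,
    n_controls: int = 60,
    effect_delta: float = DEFAULT_EFFECT_DELTA,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> SimSpec:
    """The default planted-effect recovery scenario (hypo-connectivity
    between sources 0 and 1, toy atlases)."""
    atlases, loading = toy_atlases()
    return SimSpec(
        n_cases=n_cases,
        n_controls=n_controls,
        atlases=atlases,
        loading_map=loading,
        effect_edges=[(0, 1)],
        effect_delta=effect_delta,
        noise_sd=noise_sd,
        seed=seed,
    )


def null_spec(seed: int = 0, n_cases: int = 60, n_controls: int = 60) -> SimSpec:
    """Same cohort with no planted effect (labels are uninformative)."""
    return recovery_spec(seed=seed, n_cases=n_cases, n_controls=n_controls, effect_delta=0.0)
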