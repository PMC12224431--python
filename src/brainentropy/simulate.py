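"""Synthetic cohorts with the statistical structure the pipeline assumes.

Each node time series is a stationary AR(1) process

    x_t = phi * x_{t-1} + eps_t,   eps_t ~ N(0, 1)

because a single coefficient gives a monotone handle on regularity: larger
phi means a more predictable signal and hence lower sample entropy.  A
"stimulation" effect is modelled as a switch of phi from ``phi_baseline``
to ``phi_effect`` in a designated node set, in the POST session of the
active condition only; the control condition never changes.  Per-subject
heterogeneity enters as Gaussian jitter on phi (drawn once per
subject-node, shared by all sessions, so a null cohort is exactly null).

Behavioral scores emulate a craving-focused withdrawal battery: the active
condition reduces the craving subscale total by ``craving_drop_mean`` on
average, with between-subject SD ``behavior_noise_sd``; optionally the
per-subject drop is coupled to that subject's mean entropy reduction in the
effect nodes (``behavior_coupling``).  Defaults reproduce the scale of the
study the pipeline is designed for: 42 subjects, 419 nodes, 588 timepoints,
craving totals near 22 falling by about 1.5 points under active
stimulation.

The generators also build tiny NIfTI image + atlas fixtures so the
image-extraction stage shares one code path with real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .prep import (
    NodeTimeSeriesMatrix,
    ParcellationAtlas,
    default_label_table,
    default_roi_sets,
    generic_label_table,
    normalize_matrix,
)
from .sampen import SampEnParams, compute_sampen

__all__ = ["SyntheticCohortConfig", "CohortData", "simulate_cohort", "make_image_fixture"]

CONDITIONS = ("dlPFC", "v5")
SESSIONS = ("pre", "post")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full recipe for a simulated pre/post stimulation study."""

    n_subjects: int = 42
    n_nodes: int = 419
    n_timepoints: int = 588
    phi_baseline: float = 0.2
    phi_effect: float = 0.6
    effect_nodes: tuple[int, ...] = field(default_factory=lambda: default_roi_sets().union)
    between_subject_sd: float = 0.05
    behavior_coupling: float = 0.0
    behavior_noise_sd: float = 4.0
    craving_drop_mean: float = 1.55
    n_craving_items: int = 5
    active_condition: str = "dlPFC"
    conditions: tuple[str, ...] = CONDITIONS
    burn_in: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (abs(self.phi_baseline) < 1 and abs(self.phi_effect) < 1):
            raise ValueError("AR(1) coefficients must satisfy |phi| < 1 for stationarity")
        if self.n_subjects < 1 or self.n_nodes < 1:
            raise ValueError("cohort must have at least one subject and one node")
        if self.n_timepoints < 5:
            raise ValueError("need at least 5 timepoints")
        bad = [n for n in self.effect_nodes if not (1 <= n <= self.n_nodes)]
        if bad:
            raise ValueError(f"effect nodes outside 1..{self.n_nodes}: {bad[:10]}")
        if self.active_condition not in CONDITIONS:
            raise ValueError(f"active condition must be one of {CONDITIONS}")
        unknown = set(self.conditions) - set(CONDITIONS)
        if not self.conditions or unknown:
            raise ValueError(f"conditions must be a non-empty subset of {CONDITIONS}")


@dataclass
class CohortData:
    """One simulated cohort: raw scan matrices, behavior table, ground truth."""

    matrices: list[NodeTimeSeriesMatrix]
    behavior: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticCohortConfig


def _ar1_panel(phi: np.ndarray, n_timepoints: int, burn_in: int,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) panel: one column per entry of ``phi``."""
    k = phi.size
    total = n_timepoints + burn_in
    eps = rng.standard_normal((total, k))
    x = np.empty((total, k))
    x[0] = eps[0]
    for t in range(1, total):
        x[t] = phi * x[t - 1] + eps[t]
    return x[burn_in:]


def simulate_cohort(config: SyntheticCohortConfig = SyntheticCohortConfig()) -> CohortData:
    """Simulate raw node matrices, behavioral records and ground truth.

    Fully reproducible from ``config.seed``: the same config yields
    bit-identical arrays and tables.
    """
    rng = np.random.default_rng(config.seed)
    n_sub, n_node, n_t = config.n_subjects, config.n_nodes, config.n_timepoints
    node_ids = np.arange(1, n_node + 1, dtype=np.int64)
    effect_mask = np.isin(node_ids, np.asarray(config.effect_nodes, dtype=np.int64))
    subjects = [f"sub-{i + 1:03d}" for i in range(n_sub)]

    # one jitter per subject-node, shared across conditions and sessions
    jitter = rng.normal(0.0, config.between_subject_sd, size=(n_sub, n_node))
    phi_base = np.clip(config.phi_baseline + jitter, -0.99, 0.99)
    phi_post_active = phi_base.copy()
    phi_post_active[:, effect_mask] = np.clip(
        config.phi_effect + jitter[:, effect_mask], -0.99, 0.99
    )

    matrices: list[NodeTimeSeriesMatrix] = []
    for s, sid in enumerate(subjects):
        for condition in config.conditions:
            for session in SESSIONS:
                active_post = condition == config.active_condition and session == "post"
                phi = phi_post_active[s] if active_post else phi_base[s]
                values = _ar1_panel(phi, n_t, config.burn_in, rng)
                matrices.append(NodeTimeSeriesMatrix(
                    values=values, node_ids=node_ids, subject_id=sid,
                    condition=condition, session=session, normalized=False,
                ))

    behavior = _simulate_behavior(config, matrices, subjects, effect_mask, rng)

    has_effect = effect_mask & (config.phi_effect != config.phi_baseline)
    truth = pd.DataFrame({
        "node_id": node_ids,
        "is_effect": has_effect,
        "affected_condition": np.where(has_effect, config.active_condition, ""),
        "phi_pre": np.full(n_node, config.phi_baseline),
        "phi_post_active": np.where(effect_mask, config.phi_effect, config.phi_baseline),
    })
    return CohortData(matrices=matrices, behavior=behavior, truth=truth, config=config)


def _mean_entropy_reduction(matrices: list[NodeTimeSeriesMatrix], subject: str,
                            condition: str, effect_ids: set[int],
                            params: SampEnParams) -> float:
    by_session: dict[str, float] = {}
    for mat in matrices:
        if mat.subject_id != subject or mat.condition != condition:
            continue
        norm = normalize_matrix(mat)
        cols = [c for c, nid in enumerate(norm.node_ids) if int(nid) in effect_ids]
        vals = [compute_sampen(norm.values[:, c], params).value for c in cols]
        by_session[mat.session] = float(np.nanmean(vals))
    return by_session["pre"] - by_session["post"]


def _simulate_behavior(config: SyntheticCohortConfig, matrices, subjects,
                       effect_mask, rng: np.random.Generator) -> pd.DataFrame:
    """Craving/withdrawal scores; entropy coupling only when requested."""
    effect_ids = {int(n) for n in config.effect_nodes}
    params = SampEnParams()
    rows = []
    for sid in subjects:
        for condition in config.conditions:
            active = condition == config.active_condition
            craving_pre = max(float(rng.normal(22.0, 8.25)), float(config.n_craving_items))
            sjws_noncraving_pre = max(float(rng.normal(33.0, 9.0)), 0.0)
            uts_pre = max(float(rng.normal(45.0, 12.0)), 0.0)
            drop = float(rng.normal(0.0, config.behavior_noise_sd))
            if active:
                drop += config.craving_drop_mean
            if config.behavior_coupling != 0.0:
                reduction = _mean_entropy_reduction(matrices, sid, condition,
                                                    effect_ids, params)
                drop += config.behavior_coupling * reduction
            uts_change = float(rng.normal(0.0, 3.0))
            sjws_nc_change = float(rng.normal(0.0, 3.0))
            for session in SESSIONS:
                craving = craving_pre if session == "pre" else craving_pre - drop
                uts = uts_pre if session == "pre" else uts_pre - uts_change
                sjws_nc = (sjws_noncraving_pre if session == "pre"
                           else sjws_noncraving_pre - sjws_nc_change)
                rows.append(dict(
                    subject_id=sid, condition=condition, session=session,
                    sjws_total=sjws_nc + craving,
                    sjws_craving_total=craving,
                    sjws_craving_average=craving / config.n_craving_items,
                    uts_score=uts,
                ))
    return pd.DataFrame(rows)


def make_image_fixture(
    n_labels: int,
    grid: tuple[int, int, int],
    n_timepoints: int,
    seed: int = 0,
    noise_sd: float = 0.0,
    node_series: np.ndarray | None = None,
    label_table: pd.DataFrame | None = None,
    phi: float = 0.2,
) -> tuple[nib.Nifti1Image, ParcellationAtlas]:
    """Block-labelled 4D image whose node means recover known series.

    The grid is partitioned into ``n_labels`` contiguous voxel blocks (plus
    background for any remainder); every voxel of label k carries node k's
    series plus independent Gaussian voxel noise, so extraction recovers
    the series up to noise averaging (residual SD ~ noise_sd / sqrt(block
    size)).
    """
    n_vox = int(np.prod(grid))
    if n_vox < n_labels:
        raise ValueError(f"grid {grid} has {n_vox} voxels; cannot host {n_labels} labels")
    rng = np.random.default_rng(seed)
    if node_series is None:
        node_series = _ar1_panel(np.full(n_labels, phi), n_timepoints, 200, rng)
    node_series = np.asarray(node_series, dtype=np.float64)
    if node_series.shape != (n_timepoints, n_labels):
        raise ValueError(
            f"node series must have shape {(n_timepoints, n_labels)}, got {node_series.shape}"
        )
    block = n_vox // n_labels
    flat_labels = np.zeros(n_vox, dtype=np.int16)
    for k in range(n_labels):
        flat_labels[k * block:(k + 1) * block] = k + 1
    labels = flat_labels.reshape(grid)
    data = np.zeros(grid + (n_timepoints,), dtype=np.float64)
    flat_data = data.reshape(n_vox, n_timepoints)
    for k in range(n_labels):
        rows = slice(k * block, (k + 1) * block)
        flat_data[rows] = node_series[:, k]
        if noise_sd > 0:
            flat_data[rows] += rng.normal(0.0, noise_sd, size=(block, n_timepoints))
    if label_table is None:
        label_table = default_label_table() if n_labels == 419 else generic_label_table(n_labels)
    image = nib.Nifti1Image(data, affine=np.eye(4))
    atlas = ParcellationAtlas(label_volume=labels, label_table=label_table)
    return image, atlas
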