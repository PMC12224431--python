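"""From a preprocessed 4D volume and an integer-label parcellation to the
normalized timepoints-by-nodes matrix the entropy stage consumes.

Pipeline order is fixed: extract node means, detrend each node for cubic
trends, z-score normalize.  Because SampEn defines its tolerance relative to
the series SD, z-scoring does not change entropy values; after z-scoring the
tolerance ``r * SD`` equals the absolute tolerance ``r``.

Inputs must already be registered to a common grid: no resampling is
performed here, and a grid mismatch between image and atlas is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .sampen import DegenerateSeriesError

__all__ = [
    "ParcellationAtlas",
    "RoiNodeSets",
    "NodeTimeSeriesMatrix",
    "default_label_table",
    "default_roi_sets",
    "extract_node_series",
    "detrend_cubic",
    "zscore",
    "normalize_matrix",
]

LABEL_TABLE_COLUMNS = ("node_id", "name", "hemisphere", "network")

# A-priori regions of interest: parcellation node ids overlapping the
# bilateral insula and the left dorsolateral prefrontal cortex.
LEFT_INSULA_NODES = (35, 98, 99, 100, 143)
RIGHT_INSULA_NODES = (234, 235, 236, 302, 303, 304, 305, 340)
LEFT_DLPFC_NODES = (137, 138, 139, 140, 141, 142)

# 7 cortical networks in atlas node order, with per-hemisphere block sizes
# (LH nodes 1-200, RH nodes 201-400).
_NETWORK_BLOCKS_LH = (
    ("Visual", 31),
    ("SomatoMotor", 37),
    ("DorsalAttention", 23),
    ("Salience", 22),
    ("Limbic", 13),
    ("Control", 22),
    ("Default", 52),
)
_NETWORK_BLOCKS_RH = (
    ("Visual", 30),
    ("SomatoMotor", 40),
    ("DorsalAttention", 23),
    ("Salience", 25),
    ("Limbic", 13),
    ("Control", 30),
    ("Default", 39),
)

_SUBCORTICAL_NAMES = (
    "Accumbens", "Amygdala", "Caudate", "Hippocampus",
    "Pallidum", "Putamen", "Thalamus", "VentralDC",
)


@dataclass
class RoiNodeSets:
    """The a-priori node sets: bilateral insula and left dlPFC."""

    left_insula: tuple[int, ...] = LEFT_INSULA_NODES
    right_insula: tuple[int, ...] = RIGHT_INSULA_NODES
    left_dlpfc: tuple[int, ...] = LEFT_DLPFC_NODES

    @property
    def union(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.left_insula) | set(self.right_insula) | set(self.left_dlpfc)))


def default_roi_sets() -> RoiNodeSets:
    """The default a-priori ROI node sets (19 nodes in total)."""
    return RoiNodeSets()


def default_label_table() -> pd.DataFrame:
    """Synthetic 419-node label table emulating the study parcellation layout.

    400 cortical nodes (left hemisphere 1-200, right 201-400) assigned to 7
    networks in contiguous blocks approximating the ordering of a 400-region
    local-global cortical parcellation, plus 16 subcortical (8 structures x 2
    hemispheres, nodes 401-416) and 3 cerebellar nodes (417-419).  The
    network boundaries are a synthetic stand-in chosen so that the a-priori
    insula nodes fall in somatomotor/salience blocks and the dlPFC nodes in
    the control block; node ids, hemisphere split and total counts are exact.
    """
    rows: list[tuple[int, str, str, str]] = []
    node = 1
    for hemi, blocks in (("L", _NETWORK_BLOCKS_LH), ("R", _NETWORK_BLOCKS_RH)):
        for network, size in blocks:
            for i in range(1, size + 1):
                rows.append((node, f"{hemi}H_{network}_{i}", hemi, network))
                node += 1
    for name in _SUBCORTICAL_NAMES:
        for hemi in ("L", "R"):
            rows.append((node, f"{hemi}H_{name}", hemi, "Subcortical"))
            node += 1
    for i, hemi in enumerate(("L", "R", "V"), start=1):
        rows.append((node, f"Cerebellum_{i}", hemi, "Cerebellum"))
        node += 1
    table = pd.DataFrame(rows, columns=list(LABEL_TABLE_COLUMNS))
    assert len(table) == 419
    return table


def generic_label_table(n_nodes: int, n_networks: int = 3) -> pd.DataFrame:
    """Minimal label table for an arbitrary node count (toy atlases)."""
    ids = np.arange(1, n_nodes + 1)
    return pd.DataFrame({
        "node_id": ids,
        "name": [f"node_{k}" for k in ids],
        "hemisphere": ["L" if k % 2 else "R" for k in ids],
        "network": [f"net_{(k - 1) % n_networks + 1}" for k in ids],
    })


@dataclass
class ParcellationAtlas:
    """Integer-label volume (0 = background) plus its node label table."""

    label_volume: np.ndarray
    label_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got shape {self.label_volume.shape}")
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValueError("label volume must be an integer array")
        missing = set(LABEL_TABLE_COLUMNS) - set(self.label_table.columns)
        if missing:
            raise ValueError(f"label table is missing columns: {sorted(missing)}")
        present = set(np.unique(self.label_volume)) - {0}
        known = set(int(i) for i in self.label_table["node_id"])
        orphans = present - known
        if orphans:
            raise ValueError(f"labels present in volume but absent from table: {sorted(orphans)[:10]}")
        if not present:
            raise ValueError("atlas contains no nonzero labels")

    @property
    def node_ids(self) -> np.ndarray:
        return self.label_table["node_id"].to_numpy(dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.label_table)

    def networks(self) -> pd.Series:
        return self.label_table.set_index("node_id")["network"]


@dataclass
class NodeTimeSeriesMatrix:
    """One scan's timepoints-by-nodes matrix with its session labels.

    ``empty_nodes`` lists node ids with no voxels in the atlas (columns are
    NaN); ``degenerate_nodes`` lists node ids whose column had zero variance
    at normalization time.
    """

    values: np.ndarray
    node_ids: np.ndarray
    subject_id: str
    condition: str
    session: str
    normalized: bool = False
    empty_nodes: tuple[int, ...] = field(default_factory=tuple)
    degenerate_nodes: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if self.values.shape[1] != self.node_ids.size:
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but {self.node_ids.size} node ids"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


def _image_data(image) -> np.ndarray:
    if isinstance(image, nib.spatialimages.SpatialImage):
        return np.asarray(image.dataobj, dtype=np.float64)
    return np.asarray(image, dtype=np.float64)


def extract_node_series(
    image,
    atlas: ParcellationAtlas,
    subject_id: str = "",
    condition: str = "",
    session: str = "",
) -> NodeTimeSeriesMatrix:
    """Mean time series per atlas node from a 4D volume.

    Column ``k`` at time ``t`` is the mean over voxels labeled with node
    ``k`` of the image at volume ``t``.  Nodes with no voxels on the grid
    are flagged in ``empty_nodes`` and carry NaN columns; they are never
    silently dropped or fabricated.
    """
    data = _image_data(image)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D image, got shape {data.shape}")
    labels = atlas.label_volume
    if data.shape[:3] != labels.shape:
        raise ValueError(
            f"image grid {data.shape[:3]} does not match atlas grid {labels.shape}"
        )
    t = data.shape[3]
    node_ids = atlas.node_ids
    flat_labels = labels.reshape(-1)
    # timepoints-by-voxels view; one bincount-style reduction per node block
    frames = data.reshape(-1, t).T  # (T, V)
    n_bins = int(flat_labels.max()) + 1
    counts = np.bincount(flat_labels, minlength=n_bins)
    sums = np.zeros((t, n_bins))
    for ti in range(t):
        sums[ti] = np.bincount(flat_labels, weights=frames[ti], minlength=n_bins)
    values = np.full((t, node_ids.size), np.nan)
    empty: list[int] = []
    for col, nid in enumerate(node_ids):
        if nid < n_bins and counts[nid] > 0:
            values[:, col] = sums[:, nid] / counts[nid]
        else:
            empty.append(int(nid))
    return NodeTimeSeriesMatrix(
        values=values,
        node_ids=node_ids,
        subject_id=subject_id,
        condition=condition,
        session=session,
        normalized=False,
        empty_nodes=tuple(empty),
    )


def _cubic_basis(n: int) -> np.ndarray:
    # time index scaled to [0, 1] for conditioning; residuals are identical
    # to those of a fit on the raw index 0..n-1
    t = np.linspace(0.0, 1.0, n)
    return np.vander(t, 4, increasing=True)


def detrend_cubic(series: np.ndarray) -> np.ndarray:
    """Residuals of an ordinary least-squares cubic fit on the time index.

    Accepts a 1-D series or a 2-D timepoints-by-nodes matrix (each column is
    detrended independently).  Residuals are orthogonal to {1, t, t^2, t^3}.
    """
    x = np.asarray(series, dtype=np.float64)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError(f"expected 1-D or 2-D input, got shape {x.shape}")
    n = x.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 timepoints to remove a cubic trend, got {n}")
    basis = _cubic_basis(n)
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    resid = x - basis @ coef
    return resid[:, 0] if one_d else resid


def zscore(series: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Center to mean 0 and scale to SD 1 (sample SD, ``ddof=1``)."""
    x = np.asarray(series, dtype=np.float64)
    sd = np.std(x, ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSeriesError("cannot z-score a zero-variance series")
    return (x - np.mean(x)) / sd


def normalize_matrix(matrix: NodeTimeSeriesMatrix) -> NodeTimeSeriesMatrix:
    """Detrend (cubic) then z-score every column of a node matrix.

    Columns that are empty or end up with zero variance after detrending are
    set to NaN and recorded in ``degenerate_nodes`` so that the entropy
    stage can flag them rather than crash.
    """
    if matrix.normalized:
        return matrix
    values = matrix.values
    out = np.full_like(values, np.nan)
    degenerate: list[int] = []
    finite = np.all(np.isfinite(values), axis=0)
    if finite.any():
        resid = detrend_cubic(values[:, finite])
        sd = np.std(resid, axis=0, ddof=1)
        # residual SD indistinguishable from float fuzz of the original
        # column (e.g. a constant or pure-cubic node) counts as degenerate
        scale = np.sqrt(np.mean(values[:, finite] ** 2, axis=0)) + 1.0
        good = sd > 1e-10 * scale
        cols = np.flatnonzero(finite)
        ok_cols = cols[good]
        out[:, ok_cols] = (resid[:, good] - np.mean(resid[:, good], axis=0)) / sd[good]
        degenerate.extend(int(matrix.node_ids[c]) for c in cols[~good])
    empty = set(matrix.empty_nodes)
    degenerate.extend(
        int(nid) for c, nid in enumerate(matrix.node_ids)
        if not finite[c] and int(nid) not in empty
    )
    return NodeTimeSeriesMatrix(
        values=out,
        node_ids=matrix.node_ids,
        subject_id=matrix.subject_id,
        condition=matrix.condition,
        session=matrix.session,
        normalized=True,
        empty_nodes=matrix.empty_nodes,
        degenerate_nodes=tuple(sorted(degenerate)),
    )
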