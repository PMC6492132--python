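"""Node time-series extraction from voxel-level data.

Two extractors are provided: parcel averaging over hard labels, and spatial
multiple regression of every data volume onto a set of weighted spatial maps
(the first step of dual regression).  Both demean each node series in time,
since every downstream dependency measure is moment-based.

Voxel inputs are generic voxel-by-time numeric matrices; an adapter flattens
4D NIfTI images and 3D integer label volumes.  Geometry, masking and
registration are upstream concerns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass(frozen=True)
class Parcellation:
    """Hard labels or weighted spatial maps defining the nodes.

    In ``hard_labels`` mode, ``labels`` holds one integer per voxel in
    1..n_nodes with every parcel non-empty; in ``weighted_maps`` mode,
    ``maps`` is voxel-by-node with no all-zero column.
    """

    mode: str  # {"hard_labels", "weighted_maps"}
    labels: np.ndarray | None = None
    maps: np.ndarray | None = None
    node_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode == "hard_labels":
            if self.labels is None:
                raise ValueError("hard_labels mode requires a label vector")
            labels = np.asarray(self.labels, dtype=int)
            object.__setattr__(self, "labels", labels)
            if labels.min() < 0:
                raise ValueError("parcel ids must be in 1..n_nodes (0 = unassigned)")
            present = np.unique(labels)
            expected = np.arange(1, self.n_nodes + 1)
            missing = np.setdiff1d(expected, present)
            if missing.size:
                raise ValueError(f"empty parcel(s): {missing.tolist()}")
        elif self.mode == "weighted_maps":
            if self.maps is None:
                raise ValueError("weighted_maps mode requires a maps matrix")
            maps = np.asarray(self.maps, dtype=float)
            object.__setattr__(self, "maps", maps)
            if np.any(np.all(maps == 0, axis=0)):
                raise ValueError("maps contain an all-zero column")
        else:
            raise ValueError(f"unknown parcellation mode {self.mode!r}")
        if self.node_names is not None and len(self.node_names) != self.n_nodes:
            raise ValueError("node_names length inconsistent with node count")

    @property
    def n_nodes(self) -> int:
        if self.mode == "hard_labels":
            return int(np.asarray(self.labels).max())
        return int(np.asarray(self.maps).shape[1])


def _demean(ts: np.ndarray) -> np.ndarray:
    return ts - ts.mean(axis=1, keepdims=True)


def parcel_mean_timeseries(voxel_data: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Node series = mean over voxels of each parcel, demeaned in time."""
    if parcellation.mode != "hard_labels":
        raise ValueError("parcel_mean_timeseries requires a hard-label parcellation")
    voxel_data = np.asarray(voxel_data, dtype=float)
    labels = parcellation.labels
    if labels.shape[0] != voxel_data.shape[0]:
        raise ValueError(
            f"label vector has {labels.shape[0]} voxels, data has {voxel_data.shape[0]}"
        )
    n_nodes = parcellation.n_nodes
    out = np.empty((n_nodes, voxel_data.shape[1]))
    for k in range(1, n_nodes + 1):
        members = labels == k
        if not members.any():  # unreachable for a validated Parcellation
            raise ValueError(f"parcel {k} is empty")
        out[k - 1] = voxel_data[members].mean(axis=0)
    return _demean(out)


def spatial_regression_timeseries(voxel_data: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Node series by OLS regression of each volume onto all maps jointly.

    The first step of dual regression: for every timepoint the voxel vector
    is regressed onto the map columns simultaneously; overlapping (correlated)
    maps are thereby unmixed, unlike with parcel averaging.  Output is
    demeaned per node.
    """
    if parcellation.mode != "weighted_maps":
        raise ValueError("spatial_regression_timeseries requires weighted maps")
    voxel_data = np.asarray(voxel_data, dtype=float)
    maps = parcellation.maps
    if maps.shape[0] != voxel_data.shape[0]:
        raise ValueError(
            f"maps have {maps.shape[0]} voxels, data has {voxel_data.shape[0]}"
        )
    rank = np.linalg.matrix_rank(maps)
    if rank < maps.shape[1]:
        raise ValueError(
            f"spatial maps are rank-deficient (rank {rank} < {maps.shape[1]}): "
            "duplicated or degenerate maps"
        )
    beta, *_ = np.linalg.lstsq(maps, voxel_data, rcond=None)
    return _demean(beta)


def extract_timeseries(voxel_data: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Dispatch on parcellation mode."""
    if parcellation.mode == "hard_labels":
        return parcel_mean_timeseries(voxel_data, parcellation)
    return spatial_regression_timeseries(voxel_data, parcellation)


class TimeSeriesExtractor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: voxel-by-time -> node-by-time.

    Stateless; the parcellation is a constructor parameter, ``fit`` a no-op.
    """

    def __init__(self, parcellation: Parcellation | None = None):
        self.parcellation = parcellation

    def fit(self, X, y=None):
        if self.parcellation is None:
            raise ValueError("a Parcellation must be provided")
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            return extract_timeseries(X, self.parcellation)
        return np.stack([extract_timeseries(x, self.parcellation) for x in X])


# ---------------------------------------------------------------------------
# NIfTI adapter
# ---------------------------------------------------------------------------


def load_nifti_series(path: str | Path) -> np.ndarray:
    """Flatten a 4D NIfTI image to voxel-by-time."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got shape {data.shape}")
    return data.reshape(-1, data.shape[-1])


def load_nifti_labels(path: str | Path) -> np.ndarray:
    """Flatten a 3D integer label NIfTI volume to a voxel vector."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got shape {data.shape}")
    return np.rint(data).astype(int).reshape(-1)
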