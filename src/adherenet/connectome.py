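"""Weighted Pearson connectomes and their binarization over a threshold sweep.

Each participant's timepoints x ROI matrix becomes a symmetric ROI x ROI
matrix of pairwise Pearson correlations (diagonal zeroed). Binarization keeps
an edge wherever r > T for a predefined correlation threshold T; the standard
sweep runs T = 0.05 ... 0.50 in steps of 0.05, since no single threshold is
canonical and consistency across a range is the accepted check. Thresholding
is signed by default: negative correlations never create edges. An
absolute-value variant (|r| > T) is available behind a flag for sensitivity
analyses and is named in results metadata whenever used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UndefinedCorrelationError, ZeroVarianceError
from .io_formats import RoiTimeSeriesSet


@dataclass(frozen=True)
class WeightedConnectome:
    """Symmetric matrix of pairwise Pearson r with zero diagonal."""

    r_matrix: np.ndarray
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.r_matrix, dtype=float)
        object.__setattr__(self, "r_matrix", r)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        n = r.shape[0]
        if r.ndim != 2 or r.shape[1] != n:
            raise ValueError("r_matrix must be square")
        if len(self.roi_labels) != n:
            raise ValueError("roi_labels length must match matrix size")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("r_matrix must be symmetric")
        if np.abs(np.diag(r)).max(initial=0.0) > 0:
            raise ValueError("diagonal must be zero")
        off = r[~np.eye(n, dtype=bool)]
        if off.size and (np.abs(off) > 1 + 1e-12).any():
            raise ValueError("off-diagonal entries must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.r_matrix.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Unweighted, undirected graph from thresholding a connectome at T."""

    adjacency: np.ndarray
    roi_labels: tuple[str, ...]
    threshold: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.dtype != np.int8:
            a = a.astype(np.int8)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        n = a.shape[0]
        if a.ndim != 2 or a.shape[1] != n:
            raise ValueError("adjacency must be square")
        if len(self.roi_labels) != n:
            raise ValueError("roi_labels length must match adjacency size")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValueError("diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def pearson_connectome(ts: RoiTimeSeriesSet) -> WeightedConnectome:
    """Pairwise Pearson correlation matrix of the ROI time series.

    Raises :class:`ZeroVarianceError` naming any constant ROI and
    :class:`UndefinedCorrelationError` for fewer than 3 timepoints.
    """
    series = ts.series
    if series.shape[0] < 3:
        raise UndefinedCorrelationError(
            f"participant {ts.participant_id}: need >= 3 timepoints for correlation"
        )
    # ptp is exact for a constant column where std suffers rounding
    flat = np.flatnonzero(np.ptp(series, axis=0) == 0)
    if flat.size:
        names = [ts.roi_labels[j] for j in flat[:5]]
        raise ZeroVarianceError(
            f"participant {ts.participant_id}: constant ROI series {names}"
        )
    r = np.corrcoef(series, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return WeightedConnectome(r, ts.roi_labels)


def binarize(w: WeightedConnectome, threshold: float,
             absolute: bool = False) -> BinaryGraph:
    """Keep edges where r > T (strict; ties and negatives go to 0).

    With ``absolute=True`` the rule becomes |r| > T.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if not 0.05 <= threshold <= 0.5:
        warnings.warn(
            f"threshold {threshold} outside the recommended [0.05, 0.5] range",
            UserWarning,
            stacklevel=2,
        )
    values = np.abs(w.r_matrix) if absolute else w.r_matrix
    a = (values > threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return BinaryGraph(a, w.roi_labels, float(threshold))


def threshold_sweep(w: WeightedConnectome, grid: Sequence[float],
                    absolute: bool = False) -> list[BinaryGraph]:
    """One BinaryGraph per threshold, in grid order.

    Edge sets are nested: at any higher threshold the edges are a subset of
    those at any lower one, so edge counts are non-increasing along an
    increasing grid.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    return [binarize(w, t, absolute=absolute) for t in grid]
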