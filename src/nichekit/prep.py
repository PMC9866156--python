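"""Occurrence cleaning, spatial thinning, pseudo-absence sampling, raster
extraction, and collinearity filtering.

The preparation chain mirrors the standard presence-background SDM
workflow: duplicate/centroid removal, one-record-per-cell thinning,
uniform random background sampling outside presence cells, nearest-cell
predictor extraction, and a greedy |r| filter that keeps the
highest-priority member of every highly correlated variable pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occurrences import OccurrenceSet
from .raster import EnvStack

logger = logging.getLogger(__name__)

__all__ = [
    "SampleMatrix",
    "clean",
    "thin_to_grid",
    "sample_pseudo_absence",
    "extract",
    "build_sample_matrix",
    "filter_collinear",
    "resample_layer",
]


@dataclass
class SampleMatrix:
    """Predictor values per point with a presence (1) / pseudo-absence (0) label."""

    data: pd.DataFrame
    label: np.ndarray
    variables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=int)
        if not self.variables:
            self.variables = list(self.data.columns)
        if set(self.label) - {0, 1}:
            raise ValueError("labels must be 0/1")
        if len(self.data) != len(self.label):
            raise ValueError("data/label length mismatch")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[self.variables].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.label

    def select(self, variables: list[str]) -> "SampleMatrix":
        return SampleMatrix(self.data[variables].copy(), self.label, list(variables))


def clean(
    occ: OccurrenceSet,
    exclude: list[tuple[float, float]] | None = None,
    tol: float = 1e-9,
) -> OccurrenceSet:
    """Drop exact duplicate coordinates (per range label) and any record
    matching a user-supplied exclusion list of (lon, lat) pairs — e.g.
    administrative-centroid coordinates. Order is otherwise preserved."""
    df = occ.records
    keep = ~df.duplicated(subset=["lon", "lat", "range_label"], keep="first")
    if exclude:
        ex = np.asarray(exclude, dtype=float)
        lon = df["lon"].to_numpy()[:, None]
        lat = df["lat"].to_numpy()[:, None]
        hit = ((np.abs(lon - ex[:, 0]) <= tol) & (np.abs(lat - ex[:, 1]) <= tol)).any(axis=1)
        keep &= ~hit
    return occ.subset(keep.to_numpy())


def thin_to_grid(
    occ: OccurrenceSet,
    cell_size: float,
    x_origin: float = -180.0,
    y_origin: float = 90.0,
) -> OccurrenceSet:
    """Keep at most one record per grid cell (first encountered wins).

    Cell assignment is ``floor((coord - origin) / cell_size)``; the
    operation is idempotent. Thinning to the analysis grid removes the bulk
    of spatial clustering bias before model fitting.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    col = np.floor((occ.lon - x_origin) / cell_size).astype(int)
    row = np.floor((y_origin - occ.lat) / cell_size).astype(int)
    key = pd.DataFrame({"row": row, "col": col, "lab": occ.records["range_label"]})
    keep = ~key.duplicated(keep="first")
    return occ.subset(keep.to_numpy())


def sample_pseudo_absence(
    stack: EnvStack,
    presences: OccurrenceSet,
    n: int = 1000,
    seed: int = 0,
) -> OccurrenceSet:
    """Draw ``n`` distinct background cells uniformly at random.

    Candidate cells are valid (no nodata in any layer) and do not contain a
    presence record; points are placed at cell centers. Deterministic given
    ``seed``.
    """
    valid = stack.valid_mask()
    inside = presences.subset(stack.contains(presences.lon, presences.lat))
    prow, pcol = stack.point_to_rowcol(inside.lon, inside.lat)
    occupied = np.zeros(stack.shape, dtype=bool)
    occupied[prow, pcol] = True
    candidates = np.flatnonzero((valid & ~occupied).ravel())
    if len(candidates) < n:
        raise ValueError(
            f"insufficient background cells: need {n}, have {len(candidates)} "
            f"(short by {n - len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n, replace=False)
    row, col = np.unravel_index(chosen, stack.shape)
    lon, lat = stack.cell_center(row, col)
    return OccurrenceSet.from_points(lon, lat, range_label="background", source="pseudo-absence")


def extract(stack: EnvStack, points: OccurrenceSet) -> pd.DataFrame:
    """Nearest-cell predictor values per point.

    Rows hitting nodata in any layer are dropped (count logged); a point
    outside the raster extent is an error naming its index.
    """
    inside = stack.contains(points.lon, points.lat)
    if not inside.all():
        bad = np.flatnonzero(~inside)
        raise ValueError(f"points outside raster extent at indices {list(bad[:10])}")
    row, col = stack.point_to_rowcol(points.lon, points.lat)
    out = pd.DataFrame({name: stack.layers[name][row, col] for name in stack.names})
    ok = np.ones(len(out), dtype=bool)
    for name in stack.names:
        ok &= np.isfinite(out[name]) & (out[name] != stack.nodata)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("extract: dropped %d rows hitting nodata", dropped)
        warnings.warn(f"extract: dropped {dropped} rows hitting nodata", stacklevel=2)
    return out.loc[ok].reset_index(drop=True)


def build_sample_matrix(
    stack: EnvStack,
    presences: OccurrenceSet,
    absences: OccurrenceSet,
    variables: list[str] | None = None,
) -> SampleMatrix:
    """Extract presences (label 1) and pseudo-absences (label 0) into one matrix."""
    pres = extract(stack, presences)
    absn = extract(stack, absences)
    data = pd.concat([pres, absn], ignore_index=True)
    label = np.concatenate([np.ones(len(pres), int), np.zeros(len(absn), int)])
    variables = variables or stack.names
    return SampleMatrix(data[variables], label, list(variables))


def filter_collinear(
    matrix: SampleMatrix | pd.DataFrame,
    threshold: float = 0.8,
    priority: list[str] | None = None,
) -> list[str]:
    """Greedy collinearity filter.

    Scanning variables in ``priority`` order (default: column order), a
    variable is retained iff its absolute Pearson correlation with every
    already-retained variable is <= ``threshold``. The retained set
    therefore has all pairwise |r| <= threshold, and every dropped variable
    has |r| > threshold with some retained one. Zero-variance columns are
    excluded with a warning (their correlation is undefined).
    """
    df = matrix.data if isinstance(matrix, SampleMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if len(df) < 3:
        raise ValueError("need at least 3 rows")
    priority = list(priority) if priority else list(df.columns)
    unknown = set(priority) - set(df.columns)
    if unknown:
        raise ValueError(f"priority names unknown variables {sorted(unknown)}")
    corr = df[priority].corr().abs()
    retained: list[str] = []
    for var in priority:
        if df[var].std(ddof=0) == 0:
            warnings.warn(f"zero-variance variable {var!r} excluded", stacklevel=2)
            continue
        if all(corr.loc[var, kept] <= threshold for kept in retained):
            retained.append(var)
    return retained


def resample_layer(
    arr: np.ndarray,
    factor: int,
    method: str = "block_mean",
    nodata: float = -9999.0,
) -> np.ndarray:
    """Coarsen a layer by an integer factor (resolution unification).

    ``block_mean`` averages valid cells per block (the default for
    continuous layers); ``nearest`` picks the top-left member.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nrow, ncol = arr.shape
    nrow2, ncol2 = nrow // factor, ncol // factor
    a = np.asarray(arr, dtype=float)[: nrow2 * factor, : ncol2 * factor]
    if method == "nearest":
        return a[::factor, ::factor].copy()
    if method != "block_mean":
        raise ValueError(f"unknown method {method!r}")
    blocks = a.reshape(nrow2, factor, ncol2, factor)
    valid = np.isfinite(blocks) & (blocks != nodata)
    s = np.where(valid, blocks, 0.0).sum(axis=(1, 3))
    cnt = valid.sum(axis=(1, 3))
    out = np.full((nrow2, ncol2), nodata)
    np.divide(s, cnt, out=out, where=cnt > 0)
    return out
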