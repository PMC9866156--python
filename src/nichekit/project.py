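"""Scenario projection and geographic bookkeeping: suitability maps on the
0-1000 scale, class areas in km^2 on the sphere, gain/loss change maps,
and suitable-area centroids with great-circle shift distances.

All areas use the exact spherical cell area R^2 * dlambda * (sin(top) -
sin(bottom)) with R = 6371 km; centroids are area-weighted means of
suitable cell centers (unweighted and p-weighted variants available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import ClassificationScheme, EnsembleModel, binarize, classify4, ensemble_predict
from .raster import EnvStack, haversine_km

__all__ = [
    "SuitabilityMap",
    "ChangeMap",
    "Centroid",
    "project",
    "area_by_class",
    "change",
    "centroid",
    "shift",
]

CHANGE_STATES = ("stable-unsuitable", "gain", "loss", "stable-suitable")


@dataclass
class SuitabilityMap:
    """Continuous ensemble suitability p in [0, 1000] on a geographic grid."""

    p: np.ndarray  # float array; NaN = nodata
    stack: EnvStack  # grid geometry + scenario tag

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != self.stack.shape:
            raise ValueError("p shape does not match grid")
        finite = self.p[np.isfinite(self.p)]
        if finite.size and (finite.min() < 0 or finite.max() > 1000):
            raise ValueError("p values must lie in [0, 1000]")

    @property
    def scenario(self) -> str:
        return self.stack.scenario

    def binary(self, cutoff: float) -> np.ndarray:
        return binarize(self.p, cutoff)

    def classes(self, scheme: ClassificationScheme) -> np.ndarray:
        return classify4(self.p, scheme)


@dataclass
class ChangeMap:
    """Per-cell transition between two binary maps of one geometry."""

    state: np.ndarray  # int codes 0-3 per CHANGE_STATES; -1 nodata
    stack: EnvStack
    gain_km2: float
    loss_km2: float


@dataclass
class Centroid:
    lon: float
    lat: float
    scenario: str = ""


def project(em: EnsembleModel, stack: EnvStack) -> SuitabilityMap:
    """Cellwise ensemble prediction over a scenario stack; nodata propagates."""
    missing = [v for v in em.variables if v not in stack.layers]
    if missing:
        raise ValueError(f"stack missing ensemble variables {missing}")
    mat, idx = stack.to_matrix(em.variables)
    p = np.full(stack.shape[0] * stack.shape[1], np.nan)
    if len(idx):
        feats = pd.DataFrame(mat, columns=em.variables)
        p[idx] = ensemble_predict(em, feats)
    return SuitabilityMap(p.reshape(stack.shape), stack)


def area_by_class(classmap: np.ndarray, stack: EnvStack) -> dict[int, float]:
    """Spherical area (km^2) per class code; nodata (-1 or NaN) excluded."""
    cm = np.asarray(classmap)
    areas = stack.cell_areas_km2()
    if np.issubdtype(cm.dtype, np.floating):
        valid = np.isfinite(cm)
        cm = np.where(valid, cm, -1).astype(int)
    else:
        valid = cm >= 0
    out: dict[int, float] = {}
    for cls in np.unique(cm[valid]):
        out[int(cls)] = float(areas[valid & (cm == cls)].sum())
    return out


def suitable_area_km2(binary: np.ndarray, stack: EnvStack) -> float:
    areas = area_by_class(binary, stack)
    return areas.get(1, 0.0)


def change(binary_now: np.ndarray, binary_future: np.ndarray, stack: EnvStack) -> ChangeMap:
    """Transition map between two binary suitability maps.

    gain = unsuitable -> suitable; loss = suitable -> unsuitable. Areas via
    the same spherical accounting as :func:`area_by_class`, so
    gain - loss equals the suitable-area difference exactly.
    """
    b0 = np.asarray(binary_now, dtype=float)
    b1 = np.asarray(binary_future, dtype=float)
    if b0.shape != b1.shape or b0.shape != stack.shape:
        raise ValueError("geometry mismatch between binary maps")
    valid = np.isfinite(b0) & np.isfinite(b1)
    state = np.full(b0.shape, -1, dtype=int)
    state[valid & (b0 == 0) & (b1 == 0)] = 0
    state[valid & (b0 == 0) & (b1 == 1)] = 1
    state[valid & (b0 == 1) & (b1 == 0)] = 2
    state[valid & (b0 == 1) & (b1 == 1)] = 3
    areas = area_by_class(state, stack)
    return ChangeMap(
        state=state,
        stack=stack,
        gain_km2=areas.get(1, 0.0),
        loss_km2=areas.get(2, 0.0),
    )


def centroid(
    binary: np.ndarray,
    stack: EnvStack,
    weights: str = "area",
    p: np.ndarray | None = None,
) -> Centroid:
    """Weighted mean position of suitable cells.

    ``weights`` is ``"area"`` (spherical cell areas, default), ``"none"``
    (plain mean of cell centers) or ``"p"`` (area x suitability, requires
    ``p``). Longitudes are averaged arithmetically; a suitable region
    straddling the antimeridian is rejected.
    """
    b = np.asarray(binary, dtype=float)
    mask = np.isfinite(b) & (b == 1)
    if not mask.any():
        raise ValueError("no suitable cells")
    rows, cols = np.nonzero(mask)
    lon, lat = stack.cell_center(rows, cols)
    if lon.max() - lon.min() > 180.0:
        raise ValueError("suitable region straddles the antimeridian")
    if weights == "area":
        w = stack.cell_areas_km2()[rows, cols]
    elif weights == "none":
        w = np.ones(len(rows))
    elif weights == "p":
        if p is None:
            raise ValueError("p weighting requires the continuous surface")
        w = stack.cell_areas_km2()[rows, cols] * np.asarray(p, dtype=float)[rows, cols]
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    w = w / w.sum()
    return Centroid(lon=float(lon @ w), lat=float(lat @ w), scenario=stack.scenario)


def shift(c1: Centroid, c2: Centroid) -> dict[str, float]:
    """Great-circle distance (km, R = 6371) and initial bearing c1 -> c2."""
    dist = haversine_km(c1.lon, c1.lat, c2.lon, c2.lat)
    p1, p2 = np.radians(c1.lat), np.radians(c2.lat)
    dlam = np.radians(c2.lon - c1.lon)
    x = np.sin(dlam) * np.cos(p2)
    y = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    bearing = float(np.degrees(np.arctan2(x, y)) % 360.0)
    return {"distance_km": float(dist), "bearing_deg": bearing}
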