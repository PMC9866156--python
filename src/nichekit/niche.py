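"""Niche dynamics in environmental space: PCA-env, availability-corrected
occupancy grids, Schoener's D overlap, the COUE decomposition
(expansion / stability / unfilling), and equivalency / similarity
permutation tests.

The two ranges are compared in a shared 2-D space: a PCA calibrated on the
pooled background environments of both ranges. On an R x R grid spanning
the pooled scores, each range gets a kernel-smoothed occurrence density o
and background density e; occupancy z is proportional to o/e wherever both
densities reach levels their samples genuinely attain (5th-percentile
quantile cuts evaluated at the sample points), normalized to sum 1.
Schoener's D = 1 - 0.5 * sum |z1 - z2|.

Within the analog environment (cells with background support in both
ranges, densities renormalized there), expansion E is the invasive
occupancy mass on cells the native niche does not occupy, stability
S = 1 - E, and unfilling U is the native mass on cells the invasive niche
does not occupy. Occupied means z > 0 after the quantile cuts.

The equivalency test re-splits the pooled occurrences at random; the
similarity test rigidly relocates one range's occurrence density within
its own background support. Both use the +1-corrected permutation p-value,
so p is never exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "NicheSpace",
    "OccupancyGrid",
    "COUEResult",
    "pca_env",
    "occupancy",
    "schoener_d",
    "coue",
    "equivalency_test",
    "similarity_test",
    "pno_profile",
    "compare_niches",
]


@dataclass
class NicheSpace:
    """Two PCA axes fitted on pooled backgrounds, plus the score grid."""

    loadings: np.ndarray  # (2, n_vars)
    mean: np.ndarray
    scale: np.ndarray
    variables: list[str]
    explained: np.ndarray  # explained-variance fractions of the 2 axes
    xmin: float
    xmax: float
    ymin: float
    ymax: float
    resolution: int = 100

    def transform(self, env: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = (
            env[self.variables].to_numpy(dtype=float)
            if isinstance(env, pd.DataFrame)
            else np.asarray(env, dtype=float)
        )
        return ((X - self.mean) / self.scale) @ self.loadings.T

    def grid_centers(self) -> tuple[np.ndarray, np.ndarray]:
        R = self.resolution
        xs = self.xmin + (np.arange(R) + 0.5) * (self.xmax - self.xmin) / R
        ys = self.ymin + (np.arange(R) + 0.5) * (self.ymax - self.ymin) / R
        return xs, ys

    def grid_points(self) -> np.ndarray:
        xs, ys = self.grid_centers()
        XX, YY = np.meshgrid(xs, ys)
        return np.column_stack([XX.ravel(), YY.ravel()])


@dataclass
class OccupancyGrid:
    """Availability-corrected occupancy z on the niche-space grid."""

    z: np.ndarray  # (R, R), sums to 1
    occ_density: np.ndarray
    bg_density: np.ndarray
    support: np.ndarray  # bool: background support
    space: NicheSpace
    support_floor: float = 0.0


@dataclass
class COUEResult:
    d: float
    expansion: float
    stability: float
    unfilling: float
    p_equivalency: float = float("nan")
    p_equivalency_upper: float = float("nan")
    p_similarity_nat_inv: float = float("nan")
    p_similarity_inv_nat: float = float("nan")
    n_reps: int = 0


def pca_env(
    native_bg: pd.DataFrame,
    invasive_bg: pd.DataFrame,
    native_occ: pd.DataFrame,
    invasive_occ: pd.DataFrame,
    resolution: int = 100,
) -> tuple[NicheSpace, dict[str, np.ndarray]]:
    """Calibrate the 2-D niche space on pooled backgrounds and project all
    four point sets onto it.

    Variables are centered and scaled on the pooled background; constant
    variables are dropped with a warning. Returns the space and scores for
    keys ``native_bg``, ``invasive_bg``, ``native_occ``, ``invasive_occ``.
    """
    if len(native_bg) < 3 or len(invasive_bg) < 3:
        raise ValueError("need at least 3 background points per range")
    variables = [c for c in native_bg.columns if c in invasive_bg.columns]
    pooled = pd.concat([native_bg[variables], invasive_bg[variables]], ignore_index=True)
    keep = []
    for v in variables:
        if pooled[v].std(ddof=0) == 0:
            warnings.warn(f"constant variable {v!r} dropped from PCA-env", stacklevel=2)
        else:
            keep.append(v)
    if len(keep) < 2:
        raise ValueError("PCA-env needs at least 2 non-constant variables")
    mean = pooled[keep].mean().to_numpy()
    scale = pooled[keep].std(ddof=0).to_numpy()
    Z = (pooled[keep].to_numpy() - mean) / scale
    pca = PCA(n_components=2, svd_solver="full").fit(Z)
    loadings = pca.components_
    space = NicheSpace(
        loadings=loadings,
        mean=mean,
        scale=scale,
        variables=keep,
        explained=pca.explained_variance_ratio_.copy(),
        xmin=0.0, xmax=1.0, ymin=0.0, ymax=1.0,
        resolution=resolution,
    )
    bg_scores = Z @ loadings.T
    space.xmin, space.xmax = float(bg_scores[:, 0].min()), float(bg_scores[:, 0].max())
    space.ymin, space.ymax = float(bg_scores[:, 1].min()), float(bg_scores[:, 1].max())
    scores = {
        "native_bg": bg_scores[: len(native_bg)],
        "invasive_bg": bg_scores[len(native_bg):],
        "native_occ": space.transform(native_occ[keep]),
        "invasive_occ": space.transform(invasive_occ[keep]),
    }
    return space, scores


def _cell_index(points: np.ndarray, space: "NicheSpace") -> np.ndarray:
    """Flat (row-major y, x) grid-cell index of each score point."""
    R = space.resolution
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cx = ((pts[:, 0] - space.xmin) / (space.xmax - space.xmin) * R).astype(int)
    cy = ((pts[:, 1] - space.ymin) / (space.ymax - space.ymin) * R).astype(int)
    return np.clip(cy, 0, R - 1) * R + np.clip(cx, 0, R - 1)


class _GridKDE:
    """Gaussian KDE with a diagonal bandwidth (Silverman's rule per axis).

    The axis-aligned kernel makes evaluation on the rectangular niche grid
    separable: an (R x n) kernel matrix per axis and one matrix product,
    instead of n x R^2 pairwise distances. ``bandwidth`` is "silverman"
    or a positive scalar multiplier on the Silverman per-axis widths.
    """

    def __init__(self, points: np.ndarray, bandwidth="silverman"):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        self.pts = pts
        n, d = pts.shape
        sd = pts.std(axis=0, ddof=1) if n > 1 else np.zeros(d)
        sd = np.where(sd > 0, sd, 1e-6)  # degenerate cloud: point-mass width
        factor = n ** (-1.0 / (d + 4))
        mult = 1.0 if bandwidth == "silverman" else float(bandwidth)
        self.h = sd * factor * mult
        self.norm = 1.0 / (n * (2.0 * np.pi) ** (d / 2) * np.prod(self.h))

    def on_grid(self, space: "NicheSpace") -> np.ndarray:
        """Density at the R x R grid centers, flattened row-major (y, x)."""
        xs, ys = space.grid_centers()
        kx = np.exp(-0.5 * ((xs[None, :] - self.pts[:, 0][:, None]) / self.h[0]) ** 2)
        ky = np.exp(-0.5 * ((ys[None, :] - self.pts[:, 1][:, None]) / self.h[1]) ** 2)
        dens = ky.T @ kx  # (R_y, R_x)
        return self.norm * dens.ravel()

    def at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        u = (pts[:, None, :] - self.pts[None, :, :]) / self.h
        return self.norm * np.exp(-0.5 * (u**2).sum(axis=2)).sum(axis=1)


def occupancy(
    scores_occ: np.ndarray,
    scores_bg: np.ndarray | None,
    space: NicheSpace,
    bandwidth="silverman",
    background: OccupancyGrid | None = None,
    support_quantile: float = 0.05,
) -> OccupancyGrid:
    """Kernel occupancy grid for one range.

    Gaussian KDE for occurrences (o) and background (e) on the R x R grid
    (bandwidth default: Silverman's rule). The background support is the
    set of cells where e reaches the ``support_quantile`` of the density
    observed at the background points themselves — a level the available
    environment genuinely attains, which keeps the o/e correction from
    amplifying kernel tails over empty environment. z is proportional to
    o/e inside the support (e floored there) and 0 outside; z is
    normalized to sum 1. Passing a previously built ``background`` grid
    reuses e and its support (permutation tests).
    """
    scores_occ = np.atleast_2d(np.asarray(scores_occ, dtype=float))
    if len(scores_occ) < 5:
        raise ValueError("need at least 5 occurrence points")
    R = space.resolution
    if background is not None:
        e = background.bg_density.ravel()
        floor = background.support_floor
        support = background.support.ravel()
    else:
        if scores_bg is None:
            raise ValueError("scores_bg or background grid required")
        pts = np.asarray(scores_bg, dtype=float)
        kde = _GridKDE(pts, bandwidth)
        e = kde.on_grid(space)
        # density the background attains: nearest-cell lookup of e at the
        # background points (the grid already resolves the density field)
        at_points = e[_cell_index(pts, space)]
        floor = float(np.quantile(at_points[at_points > 0], support_quantile))
        support = e >= floor
    occ_kde = _GridKDE(scores_occ, bandwidth)
    o = occ_kde.on_grid(space)
    # symmetric quantile cut on o: densities the occurrence sample never
    # attains are kernel tails, and dividing them by a floored e would
    # smear occupancy over empty environment
    o_at_points = o[_cell_index(scores_occ, space)]
    o_floor = np.quantile(o_at_points[o_at_points > 0], support_quantile)
    z = np.where(support & (o >= o_floor), o / np.maximum(e, floor), 0.0)
    total = z.sum()
    if total == 0:
        raise ValueError("all occurrences fall outside background support")
    z = z / total
    return OccupancyGrid(
        z=z.reshape(R, R),
        occ_density=o.reshape(R, R),
        bg_density=e.reshape(R, R),
        support=support.reshape(R, R),
        space=space,
        support_floor=floor,
    )


def schoener_d(z1: OccupancyGrid | np.ndarray, z2: OccupancyGrid | np.ndarray) -> float:
    """Schoener's D = 1 - 0.5 * sum |z1 - z2|, in [0, 1]."""
    a = z1.z if isinstance(z1, OccupancyGrid) else np.asarray(z1, dtype=float)
    b = z2.z if isinstance(z2, OccupancyGrid) else np.asarray(z2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("occupancy grids have different shapes")
    return float(1.0 - 0.5 * np.abs(a - b).sum())


def coue(z_native: OccupancyGrid, z_invasive: OccupancyGrid) -> tuple[float, float, float]:
    """Expansion, stability and unfilling within the analog environment.

    Analog cells have background support in both ranges; both occupancies
    are renormalized there. E is the invasive mass on cells with zero
    native occupancy, S = 1 - E exactly, and U is the native mass on cells
    with zero invasive occupancy.
    """
    if z_native.z.shape != z_invasive.z.shape:
        raise ValueError("occupancy grids have different shapes")
    analog = z_native.support & z_invasive.support
    if not analog.any():
        raise ValueError("empty analog-environment mask")
    zn = np.where(analog, z_native.z, 0.0)
    zi = np.where(analog, z_invasive.z, 0.0)
    if zn.sum() == 0 or zi.sum() == 0:
        raise ValueError("no occupancy mass inside the analog environment")
    zn = zn / zn.sum()
    zi = zi / zi.sum()
    expansion = float(zi[zn == 0].sum())
    stability = 1.0 - expansion
    unfilling = float(zn[zi == 0].sum())
    return expansion, stability, unfilling


def _perm_p(count_extreme: int, reps: int) -> float:
    return (count_extreme + 1) / (reps + 1)


def equivalency_test(
    scores_occ1: np.ndarray,
    scores_occ2: np.ndarray,
    bg1: OccupancyGrid,
    bg2: OccupancyGrid,
    reps: int = 100,
    seed: int = 0,
    bandwidth="silverman",
) -> tuple[float, np.ndarray, float, float]:
    """Niche equivalency by random re-splits of the pooled occurrences.

    Each rep pools both occurrence score sets, shuffles, re-splits into the
    original sample sizes and recomputes D. Returns (observed D, null Ds,
    lower-tail p, upper-tail p); the lower tail asks whether the observed
    overlap is smaller than under exchangeability (niche conservatism
    violated).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    space = bg1.space
    occ1 = np.atleast_2d(scores_occ1)
    occ2 = np.atleast_2d(scores_occ2)
    z1 = occupancy(occ1, None, space, bandwidth, background=bg1)
    z2 = occupancy(occ2, None, space, bandwidth, background=bg2)
    observed = schoener_d(z1, z2)
    pooled = np.vstack([occ1, occ2])
    n1 = len(occ1)
    rng = np.random.default_rng(seed)
    nulls = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(len(pooled))
        s1 = pooled[perm[:n1]]
        s2 = pooled[perm[n1:]]
        g1 = occupancy(s1, None, space, bandwidth, background=bg1)
        g2 = occupancy(s2, None, space, bandwidth, background=bg2)
        nulls[r] = schoener_d(g1, g2)
    p_lower = _perm_p(int((nulls <= observed).sum()), reps)
    p_upper = _perm_p(int((nulls >= observed).sum()), reps)
    return observed, nulls, p_lower, p_upper


def similarity_test(
    scores_occ_test: np.ndarray,
    bg_test: OccupancyGrid,
    z_fixed: OccupancyGrid,
    reps: int = 100,
    seed: int = 0,
    bandwidth="silverman",
) -> tuple[float, np.ndarray, float]:
    """Niche similarity: random rigid relocation of the test range's density.

    Each rep translates the test occurrences so their centroid lands on a
    uniformly drawn background-support cell of the test range, recomputes
    occupancy against the unchanged background, and takes D against the
    fixed other range. p = P(null D >= observed D) with the +1 correction:
    small p means the niches overlap more than random placement explains.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    space = bg_test.space
    occ = np.atleast_2d(scores_occ_test)
    z_test = occupancy(occ, None, space, bandwidth, background=bg_test)
    observed = schoener_d(z_test, z_fixed)
    support_idx = np.flatnonzero(bg_test.support.ravel())
    if support_idx.size < 2:
        raise ValueError("background support too small to shift the niche")
    grid = space.grid_points()
    centroid = occ.mean(axis=0)
    rng = np.random.default_rng(seed)
    nulls = np.empty(reps)
    for r in range(reps):
        target = grid[rng.choice(support_idx)]
        shifted = occ + (target - centroid)
        g = occupancy(shifted, None, space, bandwidth, background=bg_test)
        nulls[r] = schoener_d(g, z_fixed)
    p = _perm_p(int((nulls >= observed).sum()), reps)
    return observed, nulls, p


def pno_profile(
    weights: np.ndarray,
    variable_values: np.ndarray,
    n_bins: int = 20,
    bin_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Predicted-niche-occupancy profile of one environmental variable.

    Histogram of the variable weighted by suitability/occupancy mass,
    normalized to sum 1. Returns columns (bin_center, mass).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    w = np.asarray(weights, dtype=float).ravel()
    v = np.asarray(variable_values, dtype=float).ravel()
    if w.shape != v.shape:
        raise ValueError("weights and variable values must align")
    ok = np.isfinite(w) & np.isfinite(v) & (w >= 0)
    hist, edges = np.histogram(v[ok], bins=n_bins, range=bin_range, weights=w[ok])
    total = hist.sum()
    if total > 0:
        hist = hist / total
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin_center": centers, "mass": hist})


def compare_niches(
    native_bg: pd.DataFrame,
    invasive_bg: pd.DataFrame,
    native_occ: pd.DataFrame,
    invasive_occ: pd.DataFrame,
    reps: int = 100,
    seed: int = 0,
    resolution: int = 100,
    bandwidth="silverman",
    run_tests: bool = True,
) -> COUEResult:
    """End-to-end niche comparison between a native and an invaded range.

    Fits PCA-env on the pooled backgrounds, builds both occupancy grids,
    and computes Schoener's D, the COUE indices, and (optionally) the
    equivalency and both-direction similarity permutation tests.
    """
    space, scores = pca_env(native_bg, invasive_bg, native_occ, invasive_occ, resolution)
    z_nat = occupancy(scores["native_occ"], scores["native_bg"], space, bandwidth)
    z_inv = occupancy(scores["invasive_occ"], scores["invasive_bg"], space, bandwidth)
    d = schoener_d(z_nat, z_inv)
    e, s, u = coue(z_nat, z_inv)
    result = COUEResult(d=d, expansion=e, stability=s, unfilling=u, n_reps=reps)
    if run_tests:
        rng = np.random.default_rng(seed)
        _, _, p_lo, p_hi = equivalency_test(
            scores["native_occ"], scores["invasive_occ"], z_nat, z_inv,
            reps=reps, seed=int(rng.integers(2**31)), bandwidth=bandwidth,
        )
        _, _, p_ni = similarity_test(
            scores["invasive_occ"], z_inv, z_nat,
            reps=reps, seed=int(rng.integers(2**31)), bandwidth=bandwidth,
        )
        _, _, p_in = similarity_test(
            scores["native_occ"], z_nat, z_inv,
            reps=reps, seed=int(rng.integers(2**31)), bandwidth=bandwidth,
        )
        result.p_equivalency = p_lo
        result.p_equivalency_upper = p_hi
        result.p_similarity_nat_inv = p_ni
        result.p_similarity_inv_nat = p_in
    return result
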