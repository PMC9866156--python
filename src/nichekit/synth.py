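"""Synthetic landscapes and virtual species with known ground truth.

This module manufactures everything the modelling pipeline consumes in the
real-world workflow — multi-layer spatially autocorrelated climate fields,
a virtual species with parametric Gaussian response curves, presence
samples in a "native" and an "invaded" region with a controllable niche
offset, and perturbed "future" climate stacks — so that every downstream
estimate (variable importance, suitable ranges, niche overlap, COUE
indices) can be checked against a known truth.

Autocorrelated fields are produced by Gaussian-kernel smoothing of seeded
white noise, then re-standardized; all generators are pure functions of
their seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .occurrences import OccurrenceSet
from .raster import EnvStack

__all__ = [
    "VirtualSpecies",
    "ScenarioSet",
    "default_species",
    "generate_landscape",
    "suitability_surface",
    "sample_occurrences",
    "make_range_pair",
    "perturb_stack",
]


@dataclass
class VirtualSpecies:
    """A species with known per-variable Gaussian responses.

    ``response_params`` maps a variable name to ``(optimum, breadth)`` in
    predictor units; ``breadth = inf`` encodes a flat (nuisance) response.
    Per-variable responses ``exp(-(x - opt)^2 / (2 * breadth^2))`` are
    combined by the ``aggregation`` rule (default cellwise product), giving
    a suitability in [0, 1] that is maximal at the joint optimum.
    """

    response_params: dict[str, tuple[float, float]]
    aggregation: str = "product"
    prevalence: float | None = None

    def shifted(self, offset: dict[str, float]) -> "VirtualSpecies":
        """A copy with optima shifted by ``offset`` (per variable, predictor units)."""
        params = dict(self.response_params)
        for var, delta in offset.items():
            if var not in params:
                raise KeyError(f"offset names unknown variable {var!r}")
            opt, br = params[var]
            params[var] = (opt + delta, br)
        return VirtualSpecies(params, self.aggregation, self.prevalence)


@dataclass
class ScenarioSet:
    """Stacks keyed by scenario tag; the near-current tag must be present."""

    stacks: dict[str, EnvStack]
    perturbation: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    baseline: str = "near-current"

    def __post_init__(self) -> None:
        if self.baseline not in self.stacks:
            raise ValueError(f"baseline scenario {self.baseline!r} missing")
        base = self.stacks[self.baseline]
        for tag, st in self.stacks.items():
            if not st.same_grid(base) or st.names != base.names:
                raise ValueError(f"scenario {tag!r} grid/layers differ from baseline")


def default_species(
    driving: tuple[str, str] = ("env1", "env2"),
    nuisance: tuple[str, ...] = ("noise1", "noise2"),
    breadth: float = 0.25,
) -> VirtualSpecies:
    """Two driving variables with Gaussian responses at the landscape mean,
    plus flat-response nuisance variables — the ground-truth configuration
    for variable-importance and response-curve recovery experiments.

    The default breadth (0.25 landscape standard deviations) encodes a
    climatic specialist: suitability >= 0.5 on only a few percent of cells,
    which is the regime where presence-background models are informative.
    """
    params: dict[str, tuple[float, float]] = {v: (0.0, breadth) for v in driving}
    params.update({v: (0.0, np.inf) for v in nuisance})
    return VirtualSpecies(params)


def generate_landscape(
    n_layers: int,
    shape: tuple[int, int] = (50, 50),
    autocorr_range: float = 5.0,
    seed: int = 0,
    layer_names: list[str] | None = None,
    x_origin: float = 0.0,
    y_origin: float = 0.0,
    cell_size: float = 0.1,
    mean: float = 0.0,
    sd: float = 1.0,
    scenario: str = "near-current",
) -> EnvStack:
    """Simulate a stack of spatially autocorrelated standardized fields.

    Each layer is white noise smoothed with a Gaussian kernel whose sigma is
    ``autocorr_range`` cells, then rescaled to the requested mean/sd.
    ``autocorr_range = 0`` yields per-cell independent noise. Deterministic
    given ``seed``.
    """
    nrow, ncol = shape
    if nrow < 2 or ncol < 2:
        raise ValueError(f"degenerate grid {shape}: both dimensions must be >= 2")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if layer_names is None:
        layer_names = [f"env{i + 1}" for i in range(n_layers)]
    if len(layer_names) != n_layers:
        raise ValueError("layer_names length must equal n_layers")
    rng = np.random.default_rng(seed)
    layers = {}
    for name in layer_names:
        field_ = rng.standard_normal((nrow, ncol))
        if autocorr_range > 0:
            field_ = ndimage.gaussian_filter(field_, sigma=autocorr_range, mode="reflect")
        field_ = (field_ - field_.mean()) / field_.std()
        layers[name] = mean + sd * field_
    return EnvStack(
        layers=layers,
        x_origin=x_origin,
        y_origin=y_origin,
        cell_size=cell_size,
        scenario=scenario,
    )


def suitability_surface(species: VirtualSpecies, stack: EnvStack) -> np.ndarray:
    """Cellwise aggregated Gaussian responses, in [0, 1].

    Product aggregation (default) multiplies per-variable responses, so the
    surface is bounded above by the smallest member response.
    """
    surf = np.ones(stack.shape)
    for var, (opt, breadth) in species.response_params.items():
        if var not in stack.layers:
            raise KeyError(f"response variable {var!r} not in stack layers {stack.names}")
        if np.isinf(breadth):
            continue
        x = stack.layers[var]
        resp = np.exp(-((x - opt) ** 2) / (2.0 * breadth**2))
        if species.aggregation == "product":
            surf = surf * resp
        elif species.aggregation == "min":
            surf = np.minimum(surf, resp)
        else:
            raise ValueError(f"unknown aggregation {species.aggregation!r}")
    return surf


def sample_occurrences(
    surface: np.ndarray,
    stack: EnvStack,
    n: int,
    mode: str = "probabilistic",
    seed: int = 0,
    range_label: str = "native",
    threshold: float = 0.5,
    jitter: bool = False,
) -> OccurrenceSet:
    """Draw ``n`` occurrence points from a suitability surface.

    Probabilistic mode draws cells (with replacement) with probability
    proportional to suitability; threshold mode draws ``n`` distinct cells
    uniformly among those with suitability >= ``threshold``. Points land on
    cell centers unless ``jitter`` adds uniform within-cell noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    surface = np.asarray(surface, dtype=float)
    if surface.shape != stack.shape:
        raise ValueError("surface shape does not match stack grid")
    flat = surface.ravel()
    if not np.any(flat > 0):
        raise ValueError("surface is identically zero")
    rng = np.random.default_rng(seed)
    if mode == "probabilistic":
        p = flat / flat.sum()
        cells = rng.choice(flat.size, size=n, replace=True, p=p)
    elif mode == "threshold":
        eligible = np.flatnonzero((flat >= threshold) & (flat > 0))
        if len(eligible) < n:
            raise ValueError(
                f"threshold mode: only {len(eligible)} eligible cells for n={n}"
            )
        cells = rng.choice(eligible, size=n, replace=False)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    row, col = np.unravel_index(cells, surface.shape)
    lon, lat = stack.cell_center(row, col)
    if jitter:
        lon = lon + (rng.random(n) - 0.5) * stack.cell_size
        lat = lat + (rng.random(n) - 0.5) * stack.cell_size
    return OccurrenceSet.from_points(lon, lat, range_label=range_label)


def make_range_pair(
    species: VirtualSpecies | None = None,
    niche_offset: dict[str, float] | float = 0.0,
    n_native: int = 300,
    n_invasive: int = 300,
    seed: int = 0,
    shape: tuple[int, int] = (100, 100),
    autocorr_range: float = 2.0,
    cell_size: float = 0.1,
) -> tuple[OccurrenceSet, OccurrenceSet, EnvStack, EnvStack]:
    """Native and invaded ranges of one species, with a known niche offset.

    Two spatially disjoint landscapes are simulated; invasive occurrences
    are drawn from a species whose optima are shifted by ``niche_offset``
    (a scalar applies to the first driving variable, in predictor units).
    ``niche_offset = 0`` gives two samples of the identical niche — the
    null case for equivalency testing.

    The default species here has the two driving variables only: niche
    comparison operates on predictors that passed collinearity filtering
    and actually structure the distribution, so the default range pair
    carries no flat-response layers (pass a species with nuisance
    variables explicitly to study their effect).
    """
    if n_native < 1 or n_invasive < 1:
        raise ValueError("n_native and n_invasive must be >= 1")
    if species is None:
        species = default_species(nuisance=())
    names = list(species.response_params)
    if np.isscalar(niche_offset):
        offset = {names[0]: float(niche_offset)}
    else:
        offset = dict(niche_offset)
        unknown = set(offset) - set(names)
        if unknown:
            raise ValueError(f"offset length/names mismatch: unknown {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    s_native = int(rng.integers(2**31))
    s_invasive = int(rng.integers(2**31))
    nrow, ncol = shape
    # disjoint extents: invaded region sits east of the native one
    native_stack = generate_landscape(
        len(names), shape, autocorr_range, seed=s_native,
        layer_names=names, x_origin=0.0, y_origin=0.0, cell_size=cell_size,
    )
    invasive_stack = generate_landscape(
        len(names), shape, autocorr_range, seed=s_invasive,
        layer_names=names, x_origin=ncol * cell_size + 10.0, y_origin=0.0,
        cell_size=cell_size,
    )
    shifted = species.shifted(offset)
    occ_native = sample_occurrences(
        suitability_surface(species, native_stack), native_stack, n_native,
        seed=int(rng.integers(2**31)), range_label="native",
    )
    occ_invasive = sample_occurrences(
        suitability_surface(shifted, invasive_stack), invasive_stack, n_invasive,
        seed=int(rng.integers(2**31)), range_label="invasive",
    )
    return occ_native, occ_invasive, native_stack, invasive_stack


def perturb_stack(
    stack: EnvStack,
    shifts: dict[str, tuple[float, float]],
    scenario: str,
) -> EnvStack:
    """A "future" stack: per-layer additive/multiplicative perturbation.

    ``shifts`` maps layer name to ``(add, mult)``; unlisted layers are
    copied unchanged (the analog of holding altitude/HII constant across
    climate scenarios).
    """
    layers = {}
    for name, arr in stack.layers.items():
        add, mult = shifts.get(name, (0.0, 1.0))
        layers[name] = arr * mult + add
    return EnvStack(
        layers=layers,
        x_origin=stack.x_origin,
        y_origin=stack.y_origin,
        cell_size=stack.cell_size,
        nodata=stack.nodata,
        scenario=scenario,
        crs=stack.crs,
    )
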