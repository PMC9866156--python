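"""Run configuration: one YAML/dataclass holding every pipeline setting.

Defaults follow the standard ensemble-SDM protocol: 75/25 stratified
splits repeated 10 times, 1000 pseudo-absences, |r| <= 0.8 collinearity
threshold, top-3 family selection, class boundaries at 400/600 on the
0-1000 scale, and 100-rep niche permutation tests. Sub-seeds for every
stochastic stage are derived from the master seed by hashing the stage
name, so a run is reproducible across machines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .models import FAMILIES

__all__ = ["RunConfig", "load_config", "stage_seed"]


@dataclass
class RunConfig:
    # inputs (omitted => synthetic bundle is generated)
    occurrences: str | None = None
    stacks: dict[str, str] = field(default_factory=dict)  # scenario tag -> dir

    # synthetic bundle settings
    synth_shape: tuple[int, int] = (60, 60)
    synth_autocorr: float = 2.0
    synth_n_native: int = 500
    synth_n_invasive: int = 300
    synth_offset: float = 0.0
    synth_future_shift: float = 0.5  # additive shift on the first driving layer

    # prep
    thinning_cell_size: float | None = None  # default: analysis grid cell size
    collinearity_threshold: float = 0.8
    priority: list[str] | None = None
    n_pseudo_absence: int = 1000

    # modelling
    families: list[str] = field(default_factory=lambda: list(FAMILIES))
    split: float = 0.75
    reps: int = 10
    k: int = 3
    combination_rule: str = "mean"

    # classification
    class_bounds: tuple[float, float] = (400.0, 600.0)

    # niche
    niche_reps: int = 100
    niche_resolution: int = 100

    seed: int = 0

    def __post_init__(self) -> None:
        bad = [f for f in self.families if f.upper() not in FAMILIES]
        if bad:
            raise ValueError(f"unknown families {bad}; choose from {FAMILIES}")
        self.families = [f.upper() for f in self.families]
        if not 0 < self.split < 1:
            raise ValueError("split must be in (0,1)")
        if self.reps < 1 or self.k < 1 or self.niche_reps < 1:
            raise ValueError("reps, k and niche_reps must be >= 1")
        if not self.class_bounds[0] < self.class_bounds[1]:
            raise ValueError("class bounds must be strictly increasing")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("synth_shape", "class_bounds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage sub-seed: sha256(master, stage, index) mod 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
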