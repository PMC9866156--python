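"""Occurrence point sets: (lon, lat) records with a range label.

Thin wrapper over a pandas DataFrame with columns ``lon``, ``lat``,
``range_label`` (``native`` or ``invasive``) and ``source``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

COLUMNS = ["lon", "lat", "range_label", "source"]

__all__ = ["OccurrenceSet", "read_occurrences"]


@dataclass
class OccurrenceSet:
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        if "range_label" not in df:
            df["range_label"] = "native"
        if "source" not in df:
            df["source"] = "unknown"
        missing = [c for c in ("lon", "lat") if c not in df]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        bad = df.index[
            ~np.isfinite(df["lon"])
            | ~np.isfinite(df["lat"])
            | (df["lon"] < -180)
            | (df["lon"] >= 180)
            | (df["lat"] < -90)
            | (df["lat"] > 90)
        ]
        if len(bad):
            raise ValueError(f"malformed coordinates at rows {list(bad[:10])}")
        self.records = df[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.records["lat"].to_numpy(dtype=float)

    def subset(self, mask) -> "OccurrenceSet":
        return OccurrenceSet(self.records.loc[np.asarray(mask)].reset_index(drop=True))

    @classmethod
    def from_points(
        cls, lon, lat, range_label: str = "native", source: str = "synthetic"
    ) -> "OccurrenceSet":
        return cls(
            pd.DataFrame(
                {
                    "lon": np.asarray(lon, dtype=float),
                    "lat": np.asarray(lat, dtype=float),
                    "range_label": range_label,
                    "source": source,
                }
            )
        )

    def write(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read a CSV with header lon, lat[, range_label][, source]."""
    return OccurrenceSet(pd.read_csv(path))
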