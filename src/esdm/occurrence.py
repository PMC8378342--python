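"""Presence records: ingestion, extent filtering, grid thinning, pseudo-absences.

Presence-only occurrence data (e.g. GBIF/OBIS exports) arrive as lon/lat CSV
tables.  They are clipped to the study extent, thinned to one record per grid
cell to limit sampling bias, and complemented with pseudo-absence points drawn
from sea cells in contrasting environmental conditions — by default, cells
whose environmental vector falls outside the presence surface range envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env_stack import GridSpec, LayerStack, normalize_lon
from .sdm_core import sre_fit, sre_predict

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceSet",
    "BackgroundSet",
    "read_points_csv",
    "write_points_csv",
    "filter_extent",
    "thin_to_grid",
    "generate_pseudo_absences",
]


@dataclass
class PresenceSet:
    """Georeferenced presence records (lon/lat degrees, optional source ids)."""

    lon: np.ndarray
    lat: np.ndarray
    source_id: np.ndarray | None = None

    def __post_init__(self):
        self.lon = np.atleast_1d(np.asarray(self.lon, dtype=float))
        self.lat = np.atleast_1d(np.asarray(self.lat, dtype=float))
        if self.lon.shape != self.lat.shape:
            raise ValueError("lon and lat lengths differ")
        if not (np.all(np.isfinite(self.lon)) and np.all(np.isfinite(self.lat))):
            raise ValueError("coordinates must be finite")
        if np.any(np.abs(self.lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
        if self.source_id is not None:
            self.source_id = np.atleast_1d(np.asarray(self.source_id))

    def __len__(self) -> int:
        return len(self.lon)

    def take(self, idx) -> "PresenceSet":
        sid = None if self.source_id is None else self.source_id[idx]
        return PresenceSet(self.lon[idx], self.lat[idx], sid)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"lon": self.lon, "lat": self.lat})
        if self.source_id is not None:
            df["source_id"] = self.source_id
        return df


@dataclass
class BackgroundSet:
    """Pseudo-absence points at sea-cell centers."""

    lon: np.ndarray
    lat: np.ndarray
    label: str = "pseudo-absence"

    def __post_init__(self):
        self.lon = np.atleast_1d(np.asarray(self.lon, dtype=float))
        self.lat = np.atleast_1d(np.asarray(self.lat, dtype=float))

    def __len__(self) -> int:
        return len(self.lon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lon": self.lon, "lat": self.lat})


def read_points_csv(path) -> PresenceSet:
    """Read a lon/lat CSV (header with ``lon`` and ``lat`` columns required)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "lon" not in cols or "lat" not in cols:
        raise ValueError(f"{path!r}: CSV must have 'lon' and 'lat' columns")
    sid = df[cols["source_id"]].to_numpy() if "source_id" in cols else None
    return PresenceSet(df[cols["lon"]].to_numpy(), df[cols["lat"]].to_numpy(), sid)


def write_points_csv(points, path) -> None:
    points.to_frame().to_csv(path, index=False)


def filter_extent(presences: PresenceSet, grid: GridSpec | None = None) -> PresenceSet:
    """Keep only records inside the grid's half-open extent (idempotent)."""
    grid = grid or GridSpec()
    keep = grid.contains(presences.lon, presences.lat)
    out = presences.take(np.nonzero(keep)[0])
    logger.info("extent filter: %d of %d records retained", len(out), len(presences))
    if len(out) == 0:
        logger.warning("extent filter removed every record")
    return out


def thin_to_grid(presences: PresenceSet, grid: GridSpec | None = None) -> PresenceSet:
    """At most one record per grid cell; the first record in input order wins."""
    grid = grid or GridSpec()
    rows, cols = grid.cell_of(presences.lon, presences.lat)
    seen: set[tuple[int, int]] = set()
    keep = []
    for i, rc in enumerate(zip(rows, cols)):
        if rc not in seen:
            seen.add(rc)
            keep.append(i)
    out = presences.take(np.asarray(keep, dtype=int))
    logger.info("grid thinning: %d of %d records retained", len(out), len(presences))
    return out


def generate_pseudo_absences(
    stack: LayerStack,
    presences: PresenceSet,
    n: int = 5000,
    envelope_quantile: float = 0.025,
    seed: int = 0,
    strategy: str = "sre",
) -> BackgroundSet:
    """Sample ``n`` pseudo-absence points from sea cells (seeded, reproducible).

    ``strategy='sre'`` (default) restricts candidates to jointly valid cells
    whose environmental vector falls *outside* the presence surface range
    envelope at ``envelope_quantile`` — i.e. contrasting environmental
    conditions.  ``strategy='random'`` uses every valid non-presence cell.
    Points are placed at cell centers, never in a cell occupied by a presence.
    If fewer eligible cells than ``n`` exist, sampling is with replacement
    (logged); zero eligible cells is an error.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(presences) == 0:
        raise ValueError("presences must be non-empty")
    if not stack.layers:
        raise ValueError("stack must have at least one predictor layer")

    env_table, rows, cols = stack.table()
    pres_rows, pres_cols = stack.grid.cell_of(presences.lon, presences.lat)
    pres_cells = set(zip(pres_rows.tolist(), pres_cols.tolist()))
    not_presence = np.fromiter(
        ((r, c) not in pres_cells for r, c in zip(rows, cols)), dtype=bool, count=len(rows)
    )

    if strategy == "sre":
        pres_env = stack.extract(pres_rows, pres_cols)
        ok = ~pres_env.isna().any(axis=1)
        if not ok.any():
            raise ValueError("no presence falls on a valid cell")
        envelope = sre_fit(pres_env[ok], quantile=envelope_quantile)
        outside = sre_predict(envelope, env_table) == 0.0
        eligible = outside & not_presence
        if not eligible.any():
            raise ValueError(
                "no cell lies outside the presence envelope; "
                "use strategy='random' instead"
            )
    elif strategy == "random":
        eligible = not_presence
        if not eligible.any():
            raise ValueError("no valid non-presence cell available")
    else:
        raise ValueError(f"unknown pseudo-absence strategy {strategy!r}")

    idx = np.nonzero(eligible)[0]
    rng = np.random.default_rng(seed)
    if len(idx) < n:
        logger.warning(
            "only %d eligible cells for %d pseudo-absences; sampling with replacement",
            len(idx),
            n,
        )
        chosen = rng.choice(idx, size=n, replace=True)
    else:
        chosen = rng.choice(idx, size=n, replace=False)
    lon = stack.grid.lon_of_col(cols[chosen])
    lat = stack.grid.lat_of_row(rows[chosen])
    logger.info("pseudo-absences: sampled %d points from %d eligible cells", n, len(idx))
    return BackgroundSet(lon=lon, lat=lat)
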