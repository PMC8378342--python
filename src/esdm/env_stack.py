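"""Gridded environmental layers: data model, GeoTIFF I/O, collinearity screening.

A :class:`LayerStack` holds the named predictor grids (temperature, salinity,
current velocity, ice thickness, ocean depth, distance to shore, ...) on a
shared geographic grid.  All statistics are computed over the *jointly valid*
sea cells; land / nodata cells carry NaN and are excluded everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridSpec",
    "EnvLayer",
    "LayerStack",
    "read_layer",
    "write_layer",
    "read_stack",
    "pearson_matrix",
    "select_uncorrelated",
]

#: 5 arc-minute cells, the native resolution of the source layers.
DEFAULT_CELL_SIZE = 1.0 / 12.0

# Default study extent: Indo-West Pacific, 50°E–180°E, 50°S–50°N.
DEFAULT_EXTENT = (50.0, 180.0, -50.0, 50.0)


def normalize_lon(lon):
    """Map longitudes from [-180, 360) onto [-180, 180)."""
    lon = np.asarray(lon, dtype=float)
    if np.any(lon < -180.0) or np.any(lon >= 360.0):
        raise ValueError("longitude outside [-180, 360)")
    out = np.where(lon >= 180.0, lon - 360.0, lon)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GridSpec:
    """A regular geographic grid with cell centers at ``min + (i+0.5)*cell_size``.

    Rows run north→south (row 0 touches ``lat_max``), columns west→east,
    matching single-band raster conventions.  Cell intervals are half-open:
    a point on the eastern/northern boundary falls outside.
    """

    lon_min: float = DEFAULT_EXTENT[0]
    lon_max: float = DEFAULT_EXTENT[1]
    lat_min: float = DEFAULT_EXTENT[2]
    lat_max: float = DEFAULT_EXTENT[3]
    cell_size: float = DEFAULT_CELL_SIZE

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("extent is empty")

    @property
    def n_cols(self) -> int:
        return round((self.lon_max - self.lon_min) / self.cell_size)

    @property
    def n_rows(self) -> int:
        return round((self.lat_max - self.lat_min) / self.cell_size)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_of_col(self, col):
        return self.lon_min + (np.asarray(col) + 0.5) * self.cell_size

    def lat_of_row(self, row):
        return self.lat_max - (np.asarray(row) + 0.5) * self.cell_size

    def contains(self, lon, lat):
        """Half-open membership test for points (vectorized)."""
        lon = normalize_lon(lon)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon < self.lon_max)
            & (lat >= self.lat_min)
            & (lat < self.lat_max)
        )

    def cell_of(self, lon, lat):
        """(row, col) indices of the cells containing the given points."""
        lon = np.atleast_1d(normalize_lon(lon))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        col = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        row = np.floor((self.lat_max - lat) / self.cell_size).astype(int)
        return row, col

    def approx_equal(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            abs(self.lon_min - other.lon_min) < tol
            and abs(self.lon_max - other.lon_max) < tol
            and abs(self.lat_min - other.lat_min) < tol
            and abs(self.lat_max - other.lat_max) < tol
            and abs(self.cell_size - other.cell_size) < tol * self.cell_size
        )


@dataclass
class EnvLayer:
    """One named environmental grid; invalid cells are NaN and masked out."""

    name: str
    grid: GridSpec
    values: np.ndarray
    valid_mask: np.ndarray | None = None
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= grid shape {self.grid.shape}"
            )
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("valid_mask and values shapes differ")
        self.values = np.where(self.valid_mask, self.values, np.nan)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


@dataclass
class LayerStack:
    """Ordered, uniquely named layers on one shared grid."""

    layers: list[EnvLayer] = field(default_factory=list)
    scenario_label: str = "current"

    def __post_init__(self):
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names in stack")
        for l in self.layers[1:]:
            self._check_grid(l)

    def _check_grid(self, layer: EnvLayer):
        if self.layers and not layer.grid.approx_equal(self.grid):
            raise ValueError(
                f"grid mismatch: layer {layer.name!r} has {layer.grid}, "
                f"stack has {self.grid}"
            )

    @property
    def grid(self) -> GridSpec:
        if not self.layers:
            raise ValueError("empty stack has no grid")
        return self.layers[0].grid

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __getitem__(self, name: str) -> EnvLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def add(self, layer: EnvLayer):
        if layer.name in self.names:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        self._check_grid(layer)
        self.layers.append(layer)

    @property
    def joint_mask(self) -> np.ndarray:
        """Intersection of per-layer masks: cells valid in *every* layer."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for l in self.layers:
            mask &= l.valid_mask
        return mask

    def extract(self, rows, cols, names: list[str] | None = None) -> pd.DataFrame:
        """Predictor values at cell indices, one column per layer."""
        names = self.names if names is None else names
        return pd.DataFrame({n: self[n].values[rows, cols] for n in names})

    def table(self, names: list[str] | None = None):
        """(DataFrame of predictor values on jointly valid cells, rows, cols)."""
        rows, cols = np.nonzero(self.joint_mask)
        return self.extract(rows, cols, names), rows, cols

    def subset(self, names: list[str]) -> "LayerStack":
        return LayerStack([self[n] for n in names], self.scenario_label)

    def relabel(self, label: str) -> "LayerStack":
        return LayerStack(list(self.layers), label)


# ---------------------------------------------------------------------------
# GeoTIFF I/O (single band, EPSG:4326, float32, NaN nodata)
# ---------------------------------------------------------------------------

_GEOKEYS_WGS84 = (
    1, 1, 0, 3,          # version, revision, minor, number of keys
    1024, 0, 1, 2,       # GTModelTypeGeoKey = geographic
    1025, 0, 1, 1,       # GTRasterTypeGeoKey = PixelIsArea
    2048, 0, 1, 4326,    # GeographicTypeGeoKey = WGS84
)


def write_layer(layer: EnvLayer, path) -> None:
    """Write one layer as a single-band EPSG:4326 GeoTIFF (NaN = nodata)."""
    g = layer.grid
    extratags = [
        (33550, "d", 3, (g.cell_size, g.cell_size, 0.0)),            # pixel scale
        (33922, "d", 6, (0.0, 0.0, 0.0, g.lon_min, g.lat_max, 0.0)),  # tiepoint
        (34735, "H", len(_GEOKEYS_WGS84), _GEOKEYS_WGS84),            # geokeys
        (42113, "s", 0, "nan"),                                       # GDAL nodata
    ]
    tifffile.imwrite(
        str(path),
        layer.values.astype(np.float32),
        extratags=extratags,
        metadata=None,
    )


def read_layer(path, name: str, units: str = "") -> EnvLayer:
    """Read a single-band georeferenced GeoTIFF into an :class:`EnvLayer`.

    The grid is inferred from the ModelPixelScale / ModelTiepoint tags; NaN
    (or the declared GDAL nodata value) cells are masked.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(float)
            tags = {t.code: t.value for t in page.tags}
    except (OSError, ValueError, IndexError) as exc:
        raise OSError(f"cannot read raster {path!r}: {exc}") from exc
    if values.ndim != 2:
        raise ValueError(f"{path!r}: expected a single-band raster, got shape {values.shape}")
    if 33550 not in tags or 33922 not in tags:
        raise ValueError(f"{path!r}: missing georeferencing tags (not a GeoTIFF?)")
    sx, sy = float(tags[33550][0]), float(tags[33550][1])
    tie = tags[33922]
    lon0, lat0 = float(tie[3]), float(tie[4])  # upper-left corner
    n_rows, n_cols = values.shape
    grid = GridSpec(
        lon_min=lon0,
        lon_max=lon0 + n_cols * sx,
        lat_min=lat0 - n_rows * sy,
        lat_max=lat0,
        cell_size=sx,
    )
    nodata = tags.get(42113)
    if nodata is not None and str(nodata).strip().lower() not in ("nan", ""):
        values = np.where(values == float(nodata), np.nan, values)
    return EnvLayer(name=name, grid=grid, values=values, units=units)


def read_stack(manifest: dict, scenario_label: str = "current") -> LayerStack:
    """Build a stack from a manifest ``{name: path}`` or ``{name: {path, units}}``.

    Raises a grid-mismatch error naming both grids if layers disagree.
    """
    stack = LayerStack([], scenario_label)
    for name, entry in manifest.items():
        if isinstance(entry, dict):
            layer = read_layer(entry["path"], name, entry.get("units", ""))
        else:
            layer = read_layer(entry, name)
        stack.add(layer)
    return stack


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

def pearson_matrix(
    stack: LayerStack,
    sample_cells: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlations between layers over jointly valid cells.

    A constant layer has undefined correlation: its off-diagonal entries are
    NaN (never 0).  ``sample_cells`` draws a seeded random subset of the
    jointly valid cells, for very large grids.
    """
    if len(stack.layers) < 2:
        raise ValueError("need at least two layers")
    table, rows, _ = stack.table()
    if len(rows) < 3:
        raise ValueError("need at least 3 jointly valid cells")
    X = table.to_numpy()
    if sample_cells is not None and sample_cells < X.shape[0]:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=sample_cells, replace=False)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=stack.names, columns=stack.names)


def select_uncorrelated(
    corr: pd.DataFrame,
    threshold: float = 0.7,
    priority: list[str] | None = None,
) -> list[str]:
    """Greedy low-collinearity subset: scan in priority order, keep a layer iff
    |r| < threshold against every layer already kept.

    An undefined (NaN) correlation counts as a violation, so a constant layer
    is kept only if it comes first.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    names = list(corr.index)
    priority = names if priority is None else list(priority)
    if set(priority) != set(names):
        raise ValueError("priority must cover exactly the layers in the matrix")
    kept: list[str] = []
    for name in priority:
        r = corr.loc[name, kept].to_numpy(dtype=float) if kept else np.array([])
        ok = np.isfinite(r) & (np.abs(r) < threshold)
        if kept and not ok.all():
            continue
        kept.append(name)
    return kept
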