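"""Virtual-species generator: synthetic environments, presences, scenarios, truth.

Every pipeline stage is testable offline against a species whose niche is
known exactly.  The generator emulates:

* smooth, spatially autocorrelated environmental fields over the Indo-West
  Pacific study extent, with a synthetic land–sea boundary from which ocean
  depth and distance-to-shore are derived;
* a shallow-water, coastal species whose suitability is dominated by depth
  and distance to shore, with moderate temperature/salinity effects and a
  negligible ice effect;
* presence-only sampling (Bernoulli draws on true suitability, without
  replacement, to a target count);
* future scenarios as additive shifts of the dynamic layers (temperature,
  salinity, current velocity, ice), with depth and distance to shore constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .env_stack import EnvLayer, GridSpec, LayerStack
from .occurrence import PresenceSet
from .projection import BinaryMap, ScenarioDelta

__all__ = [
    "LayerSpec",
    "NicheSpec",
    "Response",
    "TruthMap",
    "generate_env_stack",
    "generate_virtual_species",
    "default_niche",
    "default_scenarios",
    "DEFAULT_LAYER_SPECS",
]

#: Current-period target mean and spread for the noise-driven layers.
DEFAULT_LAYER_SPECS: dict[str, tuple[float, float]] = {
    "T": (22.72, 4.0),     # mean sea temperature, °C
    "Sal": (34.51, 1.2),   # salinity, PSS
    "CV": (0.10, 0.08),    # current velocity, m/s (clipped at 0)
    # Ice handled separately: ~0 except near the poleward edges
}

#: nominal distance to shore (km) of the cell farthest from the coastline.
MAX_DSHORE_KM = 1000.0


@dataclass(frozen=True)
class LayerSpec:
    mean: float
    sd: float
    clip_min: float | None = None


def _smooth_field(shape, smoothness: float, rng) -> np.ndarray:
    """Seeded Gaussian noise smoothed to the given correlation length (cells)."""
    z = rng.standard_normal(shape)
    if smoothness > 0:
        z = ndimage.gaussian_filter(z, sigma=smoothness, mode="reflect")
    return z


def _standardize(z: np.ndarray, mask: np.ndarray, mean: float, sd: float) -> np.ndarray:
    v = z[mask]
    z = (z - v.mean()) / (v.std() + 1e-12)
    return mean + sd * z


def generate_env_stack(
    grid: GridSpec | None = None,
    layer_specs: dict | None = None,
    smoothness: float = 6.0,
    seed: int = 0,
    land_fraction: float = 0.3,
) -> LayerStack:
    """Six-layer synthetic environment on a synthetic land–sea geometry.

    T/Sal/CV are smoothed seeded noise (T with a latitudinal gradient)
    rescaled to the stated mean/sd over sea cells; Ice is near-zero except
    toward the poleward edges; Depth and Dshore derive from the distance to
    the synthetic coastline.  Land cells are NaN in every layer.
    """
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    shape = grid.shape

    # synthetic land-sea boundary from an independent smooth field
    coast_field = _smooth_field(shape, max(smoothness, 2.0), rng)
    sea = coast_field <= np.quantile(coast_field, 1.0 - land_fraction)
    if sea.all() or not sea.any():
        raise ValueError("degenerate land-sea split")

    lat = grid.lat_of_row(np.arange(grid.n_rows))[:, None]
    lat_term = np.cos(np.deg2rad(lat)) * np.ones(shape)

    def noise_layer(name, mean, sd, clip_min=None, gradient=0.0):
        z = _smooth_field(shape, smoothness, rng) + gradient * lat_term
        v = _standardize(z, sea, mean, sd)
        if clip_min is not None:
            v = np.clip(v, clip_min, None)
        return EnvLayer(name=name, grid=grid, values=np.where(sea, v, np.nan))

    specs = dict(DEFAULT_LAYER_SPECS)
    if layer_specs:
        specs.update(layer_specs)

    t_layer = noise_layer("T", *specs["T"], gradient=1.5)
    sal_layer = noise_layer("Sal", *specs["Sal"])
    cv_layer = noise_layer("CV", *specs["CV"], clip_min=0.0)

    # ice: zero except poleward of ±45°, where a non-negative ramp applies
    ice_ramp = np.clip((np.abs(lat) - 45.0) / 5.0, 0.0, 1.0) * np.ones(shape)
    ice_noise = np.abs(_smooth_field(shape, smoothness, rng))
    ice = ice_ramp * ice_noise * 0.2
    ice_layer = EnvLayer(name="Ice", grid=grid, values=np.where(sea, ice, np.nan))

    # depth and distance to shore from the coastline geometry; both are
    # functions of the normalized distance to the coast so their value
    # ranges do not depend on the grid resolution
    dist_cells = ndimage.distance_transform_edt(sea)
    d_norm = dist_cells / max(dist_cells.max(), 1.0)
    depth_noise = _standardize(_smooth_field(shape, smoothness, rng), sea, 0.0, 50.0)
    depth = np.clip(10.0 + 5990.0 * d_norm**1.5 + depth_noise, 1.0, None)
    dshore = d_norm * MAX_DSHORE_KM
    depth_layer = EnvLayer(
        name="Depth", grid=grid, values=np.where(sea, depth, np.nan), units="m"
    )
    dshore_layer = EnvLayer(
        name="Dshore", grid=grid, values=np.where(sea, dshore, np.nan), units="km"
    )

    return LayerStack(
        [t_layer, sal_layer, cv_layer, ice_layer, depth_layer, dshore_layer],
        scenario_label="current",
    )


# ---------------------------------------------------------------------------
# Niche model and virtual species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Response:
    """One predictor's contribution to suitability.

    ``gaussian``: exp(−((x−optimum)/width)²/2).
    ``logistic``: 1/(1+exp((x−midpoint)/slope)) — decreasing in x for
    slope > 0 (suitable below the midpoint), increasing for slope < 0.
    ``flat``: constant 1 (no effect).
    """

    shape: str
    optimum: float = 0.0
    width: float = 1.0
    weight: float = 1.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            return np.exp(-0.5 * ((x - self.optimum) / self.width) ** 2)
        if self.shape == "logistic":
            return 1.0 / (1.0 + np.exp(np.clip((x - self.optimum) / self.width, -500, 500)))
        if self.shape == "flat":
            return np.ones_like(x)
        raise ValueError(f"unknown response shape {self.shape!r}")


@dataclass(frozen=True)
class NicheSpec:
    """Weighted-product niche: suitability = Π response_i(x_i)^weight_i."""

    responses: dict  # predictor name -> Response
    gamma: float = 1.0
    n_presences: int = 82

    def __post_init__(self):
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if any(r.weight < 0 for r in self.responses.values()):
            raise ValueError("response weights must be >= 0")

    def suitability(self, X) -> np.ndarray:
        """Suitability in [0, 1] for a table of predictor values."""
        log_s = np.zeros(len(X), dtype=float)
        for name, resp in self.responses.items():
            if resp.weight == 0:
                continue
            r = resp(np.asarray(X[name], dtype=float))
            log_s += resp.weight * np.log(np.clip(r, 1e-300, 1.0))
        return np.exp(log_s)


def default_niche(n_presences: int = 82) -> NicheSpec:
    """Coastal shallow-water species: depth/distance-to-shore dominated,
    moderate temperature and salinity effects, weak current effect, no ice
    effect.  Relative weights ~ Dshore 0.47, Depth 0.44, T 0.23, Sal 0.14,
    CV 0.08, Ice 0."""
    return NicheSpec(
        responses={
            "Dshore": Response("logistic", optimum=200.0, width=20.0, weight=0.47),
            "Depth": Response("logistic", optimum=400.0, width=50.0, weight=0.44),
            "T": Response("gaussian", optimum=22.0, width=5.0, weight=0.23),
            "Sal": Response("gaussian", optimum=34.51, width=2.0, weight=0.14),
            "CV": Response("gaussian", optimum=0.10, width=0.15, weight=0.08),
            "Ice": Response("flat", weight=0.0),
        },
        n_presences=n_presences,
    )


@dataclass
class TruthMap:
    """Ground-truth suitability and binary range for a generated species."""

    grid: GridSpec
    suitability: np.ndarray
    mask: np.ndarray
    threshold: float = 0.5

    @property
    def binary(self) -> BinaryMap:
        with np.errstate(invalid="ignore"):
            suitable = (self.suitability >= self.threshold) & self.mask
        return BinaryMap(
            grid=self.grid,
            suitable=suitable,
            mask=self.mask,
            threshold=self.threshold,
            scenario_label="truth",
        )


def generate_virtual_species(
    stack: LayerStack,
    niche: NicheSpec | None = None,
    seed: int = 0,
    truth_threshold: float = 0.5,
) -> tuple[PresenceSet, TruthMap]:
    """Sample presence-only records from a known niche on the given stack.

    Each jointly valid cell receives one Bernoulli draw with
    p = suitability^gamma; accepted cells (in seeded random order, without
    replacement) become presence points at cell centers until the target
    count is reached.  Raises if fewer cells are accepted than the target,
    reporting the achieved count.
    """
    niche = niche or default_niche()
    missing = [n for n in niche.responses if n not in stack and niche.responses[n].weight > 0]
    if missing:
        raise ValueError(f"niche predictors {missing} not in stack")

    X, rows, cols = stack.table()
    suit = niche.suitability(X)
    values = np.full(stack.grid.shape, np.nan)
    values[rows, cols] = suit
    mask = np.zeros(stack.grid.shape, dtype=bool)
    mask[rows, cols] = True
    truth = TruthMap(
        grid=stack.grid, suitability=values, mask=mask, threshold=truth_threshold
    )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(suit))
    accept = rng.uniform(size=len(suit)) < suit**niche.gamma
    accepted = order[accept[order]]
    if len(accepted) < niche.n_presences:
        raise ValueError(
            f"only {len(accepted)} cells accepted; target {niche.n_presences} unreachable"
        )
    chosen = accepted[: niche.n_presences]
    presences = PresenceSet(
        lon=stack.grid.lon_of_col(cols[chosen]),
        lat=stack.grid.lat_of_row(rows[chosen]),
    )
    return presences, truth


# ---------------------------------------------------------------------------
# Climate scenarios: additive shifts of the dynamic layers
# ---------------------------------------------------------------------------

#: Mean changes of the dynamic predictors per scenario (2050s, then 2100s).
_SCENARIO_SHIFTS = {
    "RCP26_2050s": {"T": 0.72, "Sal": -0.061, "CV": 0.00, "Ice": 0.00},
    "RCP45_2050s": {"T": 0.96, "Sal": -0.07, "CV": 0.24, "Ice": 0.00},
    "RCP60_2050s": {"T": 0.77, "Sal": -0.07, "CV": 0.25, "Ice": 0.00},
    "RCP85_2050s": {"T": 1.10, "Sal": -0.07, "CV": 0.00, "Ice": 0.00},
    "RCP26_2100s": {"T": 0.63, "Sal": -0.09, "CV": 0.24, "Ice": 0.00},
    "RCP45_2100s": {"T": 1.21, "Sal": -0.13, "CV": 0.13, "Ice": 0.00},
    "RCP60_2100s": {"T": 1.68, "Sal": -0.16, "CV": 0.13, "Ice": 0.00},
    "RCP85_2100s": {"T": 2.87, "Sal": -0.26, "CV": 0.23, "Ice": 0.00},
}


def default_scenarios() -> list[ScenarioDelta]:
    """The eight RCP × horizon scenarios as additive mean shifts.

    Depth and distance to shore are constant (zero shift) in every scenario.
    """
    return [
        ScenarioDelta(scenario_id=sid, shifts=dict(shifts))
        for sid, shifts in _SCENARIO_SHIFTS.items()
    ]
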