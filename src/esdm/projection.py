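"""Projection onto environmental stacks, binarization, range-change accounting.

A fitted model (or ensemble) is projected cell-by-cell onto a current or
future layer stack, thresholded into a suitable/unsuitable binary map at the
TSS-maximizing threshold learned on the current period, and compared between
periods: cells lost, gained, and stable relative to the present-day suitable
range.  Range sizes are valid-cell counts by default; a cos(latitude)
area-weighted variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .env_stack import EnvLayer, GridSpec, LayerStack

__all__ = [
    "SuitabilityMap",
    "BinaryMap",
    "RangeChangeSummary",
    "ScenarioDelta",
    "project",
    "binarize",
    "range_change",
    "apply_scenario",
    "range_change_table",
]


@dataclass
class SuitabilityMap:
    """Continuous habitat suitability in [0, 1] on the stack's valid cells."""

    grid: GridSpec
    values: np.ndarray          # NaN outside the mask
    mask: np.ndarray
    scenario_label: str = "current"

    def __post_init__(self):
        v = self.values[self.mask]
        if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9):
            raise ValueError("suitability values outside [0, 1]")


@dataclass
class BinaryMap:
    """Suitable (True) / unsuitable (False) cells, from one threshold."""

    grid: GridSpec
    suitable: np.ndarray        # bool; meaningful only where mask is True
    mask: np.ndarray
    threshold: float = 0.5
    scenario_label: str = "current"

    @property
    def n_suitable(self) -> int:
        return int((self.suitable & self.mask).sum())


@dataclass(frozen=True)
class RangeChangeSummary:
    """Loss/gain/stability percentages relative to the current suitable range.

    PercLoss + PercStable = 100 exactly, and
    SpeciesRangeChange = PercGain − PercLoss = 100 · (future − current) / current.
    """

    scenario_label: str
    n_current: int
    n_lost: int
    n_gained: int
    n_stable: int

    @property
    def perc_loss(self) -> float:
        return 100.0 * self.n_lost / self.n_current

    @property
    def perc_gain(self) -> float:
        return 100.0 * self.n_gained / self.n_current

    @property
    def perc_stable(self) -> float:
        return 100.0 * self.n_stable / self.n_current

    @property
    def species_range_change(self) -> float:
        return self.perc_gain - self.perc_loss

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario_label,
            "PercLoss": self.perc_loss,
            "PercGain": self.perc_gain,
            "PercStable": self.perc_stable,
            "SpeciesRangeChange": self.species_range_change,
        }


@dataclass(frozen=True)
class ScenarioDelta:
    """Additive per-predictor shifts for one climate scenario.

    Depth and distance to shore are assumed constant in the future, so any
    shift on them must be identically zero.
    """

    scenario_id: str
    shifts: dict = field(default_factory=dict)  # name -> scalar or 2-D field
    constant_layers: tuple = ("Depth", "Dshore")

    def __post_init__(self):
        for name in self.constant_layers:
            s = self.shifts.get(name, 0.0)
            if np.any(np.asarray(s) != 0.0):
                raise ValueError(f"{name} must remain constant (zero shift)")


def project(model, stack: LayerStack) -> SuitabilityMap:
    """Predict suitability on every jointly valid cell of the stack."""
    missing = [p for p in model.predictors if p not in stack]
    if missing:
        raise ValueError(f"stack is missing predictor layer(s) {missing}")
    X, rows, cols = stack.subset(model.predictors).table()
    values = np.full(stack.grid.shape, np.nan)
    values[rows, cols] = model.predict(X)
    mask = np.zeros(stack.grid.shape, dtype=bool)
    mask[rows, cols] = True
    return SuitabilityMap(
        grid=stack.grid, values=values, mask=mask, scenario_label=stack.scenario_label
    )


def binarize(smap: SuitabilityMap, threshold: float) -> BinaryMap:
    """Suitable iff suitability ≥ threshold (threshold in [0, 1])."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    with np.errstate(invalid="ignore"):
        suitable = (smap.values >= threshold) & smap.mask
    return BinaryMap(
        grid=smap.grid,
        suitable=suitable,
        mask=smap.mask.copy(),
        threshold=threshold,
        scenario_label=smap.scenario_label,
    )


def _cell_weights(grid: GridSpec, area_weighted: bool) -> np.ndarray:
    if not area_weighted:
        return np.ones(grid.shape)
    lat = grid.lat_of_row(np.arange(grid.n_rows))
    return np.repeat(
        np.cos(np.deg2rad(lat))[:, None], grid.n_cols, axis=1
    )


def range_change(
    current: BinaryMap, future: BinaryMap, area_weighted: bool = False
) -> RangeChangeSummary:
    """Range-change bookkeeping between two binary maps on one grid.

    lost = suitable now ∧ unsuitable in the future; gained = the reverse;
    stable = suitable in both.  All percentages are relative to the current
    suitable range, so the net change equals
    100 · (future range − current range) / current range.
    """
    if not current.grid.approx_equal(future.grid):
        raise ValueError("current and future grids differ")
    if not np.array_equal(current.mask, future.mask):
        raise ValueError("current and future masks differ")
    cur = current.suitable & current.mask
    fut = future.suitable & future.mask
    w = _cell_weights(current.grid, area_weighted)
    n_current = w[cur].sum()
    if n_current <= 0:
        raise ValueError("no currently suitable cells; range change undefined")
    summary = RangeChangeSummary(
        scenario_label=future.scenario_label,
        n_current=int(round(n_current)) if not area_weighted else n_current,
        n_lost=int(round(w[cur & ~fut].sum())) if not area_weighted else w[cur & ~fut].sum(),
        n_gained=int(round(w[~cur & fut].sum())) if not area_weighted else w[~cur & fut].sum(),
        n_stable=int(round(w[cur & fut].sum())) if not area_weighted else w[cur & fut].sum(),
    )
    return summary


def apply_scenario(stack: LayerStack, delta: ScenarioDelta) -> LayerStack:
    """Shift each dynamic layer additively; constant layers copy unchanged."""
    missing = [n for n in delta.shifts if n not in stack]
    if missing:
        raise ValueError(f"delta refers to missing layer(s) {missing}")
    layers = []
    for layer in stack.layers:
        shift = delta.shifts.get(layer.name, 0.0)
        shift = np.asarray(shift, dtype=float)
        if shift.ndim == 2 and shift.shape != layer.values.shape:
            raise ValueError(f"delta field for {layer.name!r} has wrong shape")
        layers.append(
            EnvLayer(
                name=layer.name,
                grid=layer.grid,
                values=np.where(layer.valid_mask, layer.values + shift, np.nan),
                valid_mask=layer.valid_mask.copy(),
                units=layer.units,
            )
        )
    return LayerStack(layers, scenario_label=delta.scenario_id)


def range_change_table(summaries: list[RangeChangeSummary]) -> pd.DataFrame:
    """Scenario × {PercLoss, PercGain, PercStable, SpeciesRangeChange} table.

    Statistics are rows and scenarios are columns, matching the conventional
    range-change table layout.
    """
    cols = {
        s.scenario_label: [
            s.perc_loss,
            s.perc_gain,
            s.perc_stable,
            s.species_range_change,
        ]
        for s in summaries
    }
    return pd.DataFrame(
        cols, index=["PercLoss", "PercGain", "PercStable", "SpeciesRangeChange"]
    )
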