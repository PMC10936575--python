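"""Minimal stochastic fire-spread simulator on a raster landscape.

This module generates paired factual/counterfactual fire-size
ensembles with the statistical structure that landscape fire-growth
experiments produce — one scenario stochastically yielding larger
fires than another — without any fire-behavior physics. Fires spread
by percolation on a square lattice: each burning cell attempts, once,
to ignite each 4-neighbor with a probability set by the *target*
cell's fuel state (fuel treatment slows fire entering treated fuel),
scaled by a per-fire "weather" multiplier. Near the lattice's
percolation threshold, small changes in effective spread probability
move the extreme tail of the fire-size distribution strongly, which is
exactly the regime where treatment-extent comparisons are
interesting.

Scenarios are coupled by common random numbers: each fire index draws
one weather multiplier, one ignition site, and one uniform variate per
directed lattice edge, shared across scenarios. A treated landscape
can then only shrink (never grow) a given fire, so treatment effects
are isolated from between-fire noise.

The simulator exists to make the attribution pipeline testable end to
end; it does not predict real fires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .ensembles import FireSizeEnsemble
from .errors import SimulationError

UNTREATED, TREATED, NONBURNABLE = 0, 1, 2


@dataclass(frozen=True)
class LandscapeGrid:
    """Raster fuel landscape.

    ``fuel_state`` is an int array (height x width) with values
    UNTREATED (0), TREATED (1) or NONBURNABLE (2); ``cell_area_ha`` is
    the area of one cell in hectares.
    """

    fuel_state: np.ndarray = field(repr=False)
    cell_area_ha: float = 10.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.fuel_state)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise SimulationError("fuel_state must be a 2-D grid")
        if self.cell_area_ha <= 0:
            raise SimulationError("cell_area_ha must be > 0")
        if not np.isin(arr, [UNTREATED, TREATED, NONBURNABLE]).all():
            raise SimulationError("fuel_state values must be 0, 1 or 2")
        object.__setattr__(self, "fuel_state", arr.astype(np.int8))

    @classmethod
    def uniform(cls, height: int, width: int,
                cell_area_ha: float = 10.0) -> "LandscapeGrid":
        """All-burnable, untreated landscape."""
        return cls(np.zeros((height, width), dtype=np.int8), cell_area_ha)

    @property
    def height(self) -> int:
        return self.fuel_state.shape[0]

    @property
    def width(self) -> int:
        return self.fuel_state.shape[1]

    @property
    def burnable_mask(self) -> np.ndarray:
        return self.fuel_state != NONBURNABLE

    @property
    def treated_fraction(self) -> float:
        burnable = self.burnable_mask
        if not burnable.any():
            return 0.0
        return float((self.fuel_state == TREATED).sum() / burnable.sum())


@dataclass(frozen=True)
class SpreadParams:
    """Stochastic spread settings.

    p_spread_untreated : per-neighbor ignition probability into
        untreated fuel, in (0, 1). The default sits just above the
        square-lattice bond-percolation threshold (0.5) so the
        fire-size distribution has a heavy upper tail.
    treatment_multiplier : factor in [0, 1] applied to the spread
        probability into treated cells.
    weather_sigma : log-standard-deviation of a per-fire lognormal
        multiplier (median 1) on spread probability, emulating
        between-event weather variability.
    max_steps : hard cap on spread iterations.
    """

    p_spread_untreated: float = 0.55
    treatment_multiplier: float = 0.3
    weather_sigma: float = 0.3
    max_steps: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_spread_untreated < 1.0 + 1e-12:
            raise SimulationError("p_spread_untreated must be in [0, 1]")
        if not 0.0 <= self.treatment_multiplier <= 1.0:
            raise SimulationError("treatment_multiplier must be in [0, 1]")
        if self.weather_sigma < 0:
            raise SimulationError("weather_sigma must be >= 0")
        if self.max_steps < 1:
            raise SimulationError("max_steps must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Ensemble-level settings: how many fires, where they start, seed."""

    n_fires: int = 2000
    seed: int = 0
    ignition: tuple[int, int] | str = "random"

    def __post_init__(self) -> None:
        if self.n_fires < 1:
            raise SimulationError(f"n_fires must be >= 1, got {self.n_fires}")


def apply_random_treatment(landscape: LandscapeGrid, fraction: float,
                           seed: int) -> LandscapeGrid:
    """Treat a uniformly random subset of burnable cells.

    Exactly round(fraction * #burnable) cells are switched to TREATED,
    chosen by taking a prefix of a seeded random permutation of the
    burnable cells. Using the same seed for several fractions therefore
    yields *nested* treated sets (the 5% treatment is a subset of the
    25% one), which is the natural coupling for comparing treatment
    extents. The input landscape is untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise SimulationError(f"fraction must be in [0, 1], got {fraction}")
    fuel = landscape.fuel_state.copy()
    burnable_idx = np.flatnonzero(fuel.ravel() != NONBURNABLE)
    k = int(round(fraction * burnable_idx.size))
    if k:
        perm = np.random.default_rng(seed).permutation(burnable_idx)
        fuel.ravel()[perm[:k]] = TREATED
    return LandscapeGrid(fuel, landscape.cell_area_ha)


def _effective_spread(landscape: LandscapeGrid, params: SpreadParams,
                      weather: float) -> np.ndarray:
    """Per-cell probability of catching fire from a burning neighbor."""
    base = np.where(
        landscape.fuel_state == TREATED,
        params.p_spread_untreated * params.treatment_multiplier,
        params.p_spread_untreated,
    )
    base[landscape.fuel_state == NONBURNABLE] = 0.0
    return np.clip(base * weather, 0.0, 1.0)


def simulate_fire(landscape: LandscapeGrid, params: SpreadParams,
                  ignition: tuple[int, int],
                  rng: np.random.Generator,
                  return_mask: bool = False):
    """Spread one fire and return its final size in hectares.

    Discrete-time percolation: every newly burning cell attempts, once,
    to ignite each of its 4-neighbors with probability equal to the
    target cell's effective spread probability times the fire's weather
    multiplier; burned cells never reburn; spread stops when no new
    ignitions occur or ``max_steps`` is hit.

    The per-fire randomness (weather, then one uniform per directed
    edge) is drawn up front in a fixed order, so running the same rng
    state on two landscapes couples the fires by common random numbers:
    lowering any cell's spread probability can only shrink the burned
    set.
    """
    h, w = landscape.height, landscape.width
    r, c = ignition
    if not (0 <= r < h and 0 <= c < w):
        raise SimulationError(f"ignition {ignition} outside the grid")
    if landscape.fuel_state[r, c] == NONBURNABLE:
        raise SimulationError(f"ignition cell {ignition} is nonburnable")
    weather = (float(rng.lognormal(0.0, params.weather_sigma))
               if params.weather_sigma > 0 else 1.0)
    # One uniform per (source cell, direction); fixed shape keeps draws
    # identical across scenarios for a given rng state.
    edge_u = rng.random((h * w, 4))
    p_cell = _effective_spread(landscape, params, weather).ravel()

    burned = np.zeros(h * w, dtype=bool)
    start = r * w + c
    burned[start] = True
    frontier = np.array([start], dtype=np.int64)
    offsets = np.array([-w, w, -1, 1], dtype=np.int64)
    for _ in range(params.max_steps):
        ignited = []
        cols = frontier % w
        for d, off in enumerate(offsets):
            tgt = frontier + off
            if d == 0:
                ok = frontier >= w
            elif d == 1:
                ok = frontier < (h - 1) * w
            elif d == 2:
                ok = cols > 0
            else:
                ok = cols < w - 1
            src = frontier[ok]
            tgt = tgt[ok]
            hit = (~burned[tgt]) & (edge_u[src, d] < p_cell[tgt])
            ignited.append(tgt[hit])
        new = np.unique(np.concatenate(ignited)) if ignited else \
            np.array([], dtype=np.int64)
        new = new[~burned[new]]
        if new.size == 0:
            break
        burned[new] = True
        frontier = new
    size = float(burned.sum() * landscape.cell_area_ha)
    if return_mask:
        return size, burned.reshape(h, w)
    return size


def run_paired_experiment(base: LandscapeGrid,
                          fractions: list[float],
                          params: SpreadParams = SpreadParams(),
                          config: SimConfig = SimConfig()
                          ) -> dict[str, FireSizeEnsemble]:
    """Simulate one ensemble per treatment fraction under common
    random numbers.

    For each treatment fraction a landscape is derived from ``base``
    with :func:`apply_random_treatment` (one shared treatment seed, so
    treated sets are nested across fractions). Fire index i uses the
    same ignition site, weather draw, and edge uniforms on every
    landscape, so per-fire sizes are directly comparable across
    scenarios and ordered in treatment fraction. Labels are
    ``"untreated"`` for fraction 0 and ``"randN"`` for N% treatment.

    Returns a mapping from scenario label to ensemble, ready for the
    attribution pipeline.
    """
    scenarios: list[tuple[str, LandscapeGrid]] = []
    labels_seen = set()
    for f in fractions:
        label = "untreated" if f == 0 else f"rand{100 * f:g}"
        if label in labels_seen:  # e.g. fractions [0, 0] in a null test
            label = f"{label}_{len(labels_seen)}"
        labels_seen.add(label)
        scenarios.append(
            (label, apply_random_treatment(base, f, config.seed))
        )

    burnable_idx = np.flatnonzero(base.burnable_mask.ravel())
    if burnable_idx.size == 0:
        raise SimulationError("landscape has no burnable cells")
    w = base.width
    children = np.random.SeedSequence(config.seed).spawn(config.n_fires)

    out: dict[str, FireSizeEnsemble] = {}
    for label, scape in scenarios:
        sizes = np.empty(config.n_fires)
        for i in range(config.n_fires):
            rng = np.random.default_rng(children[i])
            if config.ignition == "random":
                cell = int(burnable_idx[rng.integers(burnable_idx.size)])
                ign = (cell // w, cell % w)
            else:
                ign = tuple(config.ignition)  # type: ignore[arg-type]
            sizes[i] = simulate_fire(scape, params, ign, rng)
        out[label] = FireSizeEnsemble(label, sizes)
    return out


def params_to_dict(params: SpreadParams, config: SimConfig) -> dict:
    """Serializable record of a simulation setup (for config files)."""
    d = {**asdict(params), **asdict(config)}
    if isinstance(d["ignition"], tuple):
        d["ignition"] = list(d["ignition"])
    return d
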