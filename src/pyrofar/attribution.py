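"""Fraction of attributable risk (FAR) and relative risk (RR).

Given exceedance probabilities for the same fire-size threshold on a
reference scenario (p0) and a comparison scenario (p1),

    FAR = 1 - p0 / p1        RR = p1 / p0

FAR is the fraction of the event's probability attributable to the
condition that differs between the scenarios: 0 means no relationship,
0.5 means the event is twice as likely in the comparison world, and
values near 1 mean the event essentially cannot happen in the
reference world. RR says how many times more likely the event is in
the comparison world. The two are dual: FAR = 1 - 1/RR wherever both
are finite.

Edge cases are *flagged*, never raised, so curves stay total over the
grid: p1 at or below the numerical floor makes FAR undefined (NaN);
p0 at or below the floor with p1 above it makes RR +inf; both below
makes RR undefined (NaN). The floor (1e-12) separates true zeros of
the empirical estimator from KDE tail dust.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .density import (
    BandwidthRule,
    DEFAULT_GRID_POINTS,
    DEFAULT_PAD_BANDWIDTHS,
    ExceedanceCurve,
    empirical_exceedance,
    kde_exceedance,
    make_shared_grid,
    percentile_event_size,
)
from .ensembles import FireSizeEnsemble, ScenarioPair
from .errors import DegenerateEnsembleError, LevelNotAttainedError

#: Denominator floor distinguishing true zeros from numerical tail dust.
PROBABILITY_FLOOR = 1e-12


def far(p0, p1, floor: float = PROBABILITY_FLOOR):
    """FAR = 1 - p0/p1; NaN-flagged where p1 <= floor.

    Accepts scalars or arrays; NaN is the explicit undefined flag (a
    fire that cannot occur in either world has no attributable
    fraction).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    out = np.full(np.broadcast_shapes(p0.shape, p1.shape), np.nan)
    valid = p1 > floor
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(valid, 1.0 - p0 / np.where(valid, p1, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def rr(p0, p1, floor: float = PROBABILITY_FLOOR):
    """RR = p1/p0; +inf where p0 <= floor < p1, NaN where both <= floor."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p0b, p1b = np.broadcast_arrays(p0, p1)
    out = np.full(p0b.shape, np.nan)
    ok = p0b > floor
    out[ok] = p1b[ok] / p0b[ok]
    inf_mask = (~ok) & (p1b > floor)
    out[inf_mask] = np.inf
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CurveSettings:
    """Reproducible settings for one attribution analysis.

    estimator is "kde" (Gaussian KDE integrated to exceedance) or
    "empirical" (strict-exceedance counting); bandwidth is "scott",
    "silverman", or an explicit value in hectares.
    """

    estimator: str = "kde"
    bandwidth: BandwidthRule = "scott"
    n_points: int = DEFAULT_GRID_POINTS
    pad_bandwidths: float = DEFAULT_PAD_BANDWIDTHS

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AttributionCurve:
    """Aligned p0/p1/FAR/RR over one shared fire-size grid.

    ``valid_mask`` marks grid points where p1 exceeded the numerical
    floor so FAR is defined; RR additionally needs p0 above the floor
    and is +inf-flagged where only p1 is.
    """

    grid: np.ndarray = field(repr=False)
    p0: np.ndarray = field(repr=False)
    p1: np.ndarray = field(repr=False)
    far: np.ndarray = field(repr=False)
    rr: np.ndarray = field(repr=False)
    valid_mask: np.ndarray = field(repr=False)
    p0_label: str = "p0"
    p1_label: str = "p1"

    # Threshold lookups interpolate the exceedance probabilities (the
    # monotone primitives) and apply the metric, so FAR = 1 - 1/RR
    # holds at off-grid sizes too.
    def far_at(self, size: float) -> float:
        return float(far(np.interp(size, self.grid, self.p0),
                         np.interp(size, self.grid, self.p1)))

    def rr_at(self, size: float) -> float:
        return float(rr(np.interp(size, self.grid, self.p0),
                        np.interp(size, self.grid, self.p1)))

    def p0_curve(self) -> ExceedanceCurve:
        return ExceedanceCurve(self.grid, self.p0, "derived", self.p0_label)

    def p1_curve(self) -> ExceedanceCurve:
        return ExceedanceCurve(self.grid, self.p1, "derived", self.p1_label)


def _exceedance(ensemble: FireSizeEnsemble, grid: np.ndarray,
                settings: CurveSettings) -> ExceedanceCurve:
    if settings.estimator == "kde":
        return kde_exceedance(ensemble, grid, settings.bandwidth)
    if settings.estimator == "empirical":
        return empirical_exceedance(ensemble, grid)
    raise ValueError(f"unknown estimator {settings.estimator!r}")


def attribution_curves(pair: ScenarioPair,
                       settings: CurveSettings = CurveSettings()
                       ) -> AttributionCurve:
    """Full FAR and RR curves for a scenario pair.

    Builds one shared grid spanning both ensembles, computes both
    exceedance curves with identical settings, and applies FAR/RR
    pointwise.
    """
    grid = make_shared_grid(
        [pair.p0_ensemble, pair.p1_ensemble],
        n_points=settings.n_points,
        pad_bandwidths=settings.pad_bandwidths,
        bandwidth_rule=settings.bandwidth
        if settings.estimator == "kde" else "scott",
    )
    c0 = _exceedance(pair.p0_ensemble, grid, settings)
    c1 = _exceedance(pair.p1_ensemble, grid, settings)
    return _curves_from_probs(grid, c0.prob, c1.prob,
                              pair.p0_ensemble.label, pair.p1_ensemble.label)


def _curves_from_probs(grid, p0, p1, p0_label="p0",
                       p1_label="p1") -> AttributionCurve:
    return AttributionCurve(
        grid=grid, p0=p0, p1=p1,
        far=far(p0, p1), rr=rr(p0, p1),
        valid_mask=p1 > PROBABILITY_FLOOR,
        p0_label=p0_label, p1_label=p1_label,
    )


def far_crossing(curve: AttributionCurve, level: float) -> float:
    """Smallest fire size at which the FAR curve first reaches ``level``.

    Scans upward in size over the valid region and linearly
    interpolates between the bracketing grid points. FAR curves need
    not be monotone, so "first attainment" is the defining convention.
    """
    f = np.where(curve.valid_mask, curve.far, np.nan)
    finite = np.isfinite(f)
    if not finite.any():
        raise LevelNotAttainedError("FAR curve is undefined everywhere")
    at_or_above = finite & (f >= level)
    if not at_or_above.any():
        lo, hi = np.nanmin(f), np.nanmax(f)
        raise LevelNotAttainedError(
            f"FAR never reaches {level}; attained range is "
            f"[{lo:.4g}, {hi:.4g}]"
        )
    i = int(np.argmax(at_or_above))
    if i == 0 or not finite[i - 1] or f[i] == level:
        return float(curve.grid[i])
    g0, g1 = curve.grid[i - 1], curve.grid[i]
    f0, f1 = f[i - 1], f[i]
    return float(g0 + (level - f0) * (g1 - g0) / (f1 - f0))


@dataclass(frozen=True)
class BootstrapBands:
    """Pointwise percentile intervals for FAR and RR curves.

    ``available`` flags grid points where the band could be formed
    (the replicate statistic was defined in at least half the
    replicates); elsewhere the band arrays hold NaN.
    """

    grid: np.ndarray = field(repr=False)
    far_lo: np.ndarray = field(repr=False)
    far_hi: np.ndarray = field(repr=False)
    rr_lo: np.ndarray = field(repr=False)
    rr_hi: np.ndarray = field(repr=False)
    available: np.ndarray = field(repr=False)
    level: float
    replicates: int
    seed: int


def bootstrap_bands(pair: ScenarioPair,
                    settings: CurveSettings = CurveSettings(),
                    replicates: int = 1000,
                    seed: int = 0,
                    band_level: float = 0.95) -> BootstrapBands:
    """Nonparametric bootstrap bands for the attribution curves.

    Each replicate resamples both ensembles with replacement
    (independently), recomputes exceedance and FAR/RR on the *same*
    grid as the point estimate with the same settings, and pointwise
    percentile intervals at coverage ``band_level`` are taken over
    replicates. The seed is mandatory-explicit: identical seeds give
    identical bands. Replicates whose resample has zero variance (KDE
    undefined) contribute undefined values; a grid point undefined in
    more than half the replicates is flagged unavailable.
    """
    if replicates < 100:
        raise ValueError(f"replicates must be >= 100, got {replicates}")
    point = attribution_curves(pair, settings)
    grid = point.grid
    rng = np.random.default_rng(seed)
    fars = np.full((replicates, grid.size), np.nan)
    rrs = np.full((replicates, grid.size), np.nan)
    for b in range(replicates):
        try:
            e0 = FireSizeEnsemble(
                pair.p0_ensemble.label,
                rng.choice(pair.p0_ensemble.sizes, pair.p0_ensemble.n),
            )
            e1 = FireSizeEnsemble(
                pair.p1_ensemble.label,
                rng.choice(pair.p1_ensemble.sizes, pair.p1_ensemble.n),
            )
            p0 = _exceedance(e0, grid, settings).prob
            p1 = _exceedance(e1, grid, settings).prob
        except DegenerateEnsembleError:
            continue
        fars[b] = far(p0, p1)
        with np.errstate(invalid="ignore"):
            r = rr(p0, p1)
        rrs[b] = np.where(np.isfinite(r), r, np.nan)
    alpha = (1.0 - band_level) / 2.0
    qs = [100 * alpha, 100 * (1 - alpha)]

    def bands(mat):
        defined = np.isfinite(mat).sum(axis=0)
        ok = defined > replicates / 2
        lo = np.full(grid.size, np.nan)
        hi = np.full(grid.size, np.nan)
        if ok.any():
            with np.errstate(all="ignore"):
                lo[ok], hi[ok] = np.nanpercentile(mat[:, ok], qs, axis=0)
        return lo, hi, ok

    far_lo, far_hi, far_ok = bands(fars)
    rr_lo, rr_hi, rr_ok = bands(rrs)
    return BootstrapBands(grid, far_lo, far_hi, rr_lo, rr_hi,
                          far_ok & rr_ok, band_level, replicates, seed)


@dataclass
class AttributionReport:
    """Aggregated attribution statistics with full provenance.

    Every statistic is recomputable from ``settings`` plus the input
    ensembles; ``direction_note`` records which landscape plays which
    role.
    """

    labels: dict
    direction_note: str
    event_threshold: float
    far_at_threshold: float
    rr_at_threshold: float
    thresholds: list
    percentile_events: dict
    far_crossings: dict
    settings: dict
    bootstrap: dict | None = None

    def to_dict(self) -> dict:
        return {
            "labels": dict(self.labels),
            "direction_note": self.direction_note,
            "event_threshold": self.event_threshold,
            "far_at_threshold": self.far_at_threshold,
            "rr_at_threshold": self.rr_at_threshold,
            "thresholds": [dict(t) for t in self.thresholds],
            "percentile_events": {
                str(k): dict(v) for k, v in self.percentile_events.items()
            },
            "far_crossings": {
                str(k): v for k, v in self.far_crossings.items()
            },
            "settings": dict(self.settings),
            "bootstrap": self.bootstrap,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AttributionReport":
        return cls(
            labels=dict(d["labels"]),
            direction_note=d.get("direction_note", ""),
            event_threshold=d["event_threshold"],
            far_at_threshold=d.get("far_at_threshold", float("nan")),
            rr_at_threshold=d.get("rr_at_threshold", float("nan")),
            thresholds=[dict(t) for t in d.get("thresholds", [])],
            percentile_events={
                float(k): dict(v)
                for k, v in d.get("percentile_events", {}).items()
            },
            far_crossings={
                float(k): v for k, v in d.get("far_crossings", {}).items()
            },
            settings=dict(d.get("settings", {})),
            bootstrap=d.get("bootstrap"),
        )


def build_report(pair: ScenarioPair,
                 settings: CurveSettings = CurveSettings(),
                 thresholds: Sequence[float] = (),
                 percentiles: Sequence[float] = (0.5, 0.9),
                 far_levels: Sequence[float] = (0.5,),
                 bootstrap_replicates: int = 0,
                 seed: int = 0,
                 band_level: float = 0.95) -> AttributionReport:
    """One report aggregating thresholds, percentile events, crossings
    and (optionally) bootstrap bands for a scenario pair.

    The first entry of ``thresholds`` is the headline event threshold;
    if none is given, the 90th-percentile size on the p0 curve is used
    (the conventional "extreme event" definition).
    """
    curve = attribution_curves(pair, settings)
    p0_curve, p1_curve = curve.p0_curve(), curve.p1_curve()
    if not thresholds:
        thresholds = [percentile_event_size(p0_curve, 0.9)]
    threshold_rows = []
    for t in thresholds:
        threshold_rows.append({
            "size_ha": float(t),
            "p0": float(np.interp(t, curve.grid, curve.p0)),
            "p1": float(np.interp(t, curve.grid, curve.p1)),
            "far": curve.far_at(t),
            "rr": curve.rr_at(t),
        })
    pct_events = {}
    for p in percentiles:
        row = {}
        for name, c in (("p0_size_ha", p0_curve), ("p1_size_ha", p1_curve)):
            try:
                row[name] = percentile_event_size(c, p)
            except Exception:
                row[name] = float("nan")
        pct_events[float(p)] = row
    crossings = {}
    for lev in far_levels:
        try:
            crossings[float(lev)] = far_crossing(curve, lev)
        except LevelNotAttainedError:
            crossings[float(lev)] = None
    boot = None
    if bootstrap_replicates:
        b = bootstrap_bands(pair, settings, bootstrap_replicates, seed,
                            band_level)
        boot = {
            "level": b.level,
            "replicates": b.replicates,
            "seed": b.seed,
            "grid": b.grid.tolist(),
            "far_lo": b.far_lo.tolist(),
            "far_hi": b.far_hi.tolist(),
            "rr_lo": b.rr_lo.tolist(),
            "rr_hi": b.rr_hi.tolist(),
            "available": b.available.astype(bool).tolist(),
        }
    head = threshold_rows[0]
    return AttributionReport(
        labels={"p0": pair.p0_ensemble.label, "p1": pair.p1_ensemble.label},
        direction_note=pair.direction_note,
        event_threshold=head["size_ha"],
        far_at_threshold=head["far"],
        rr_at_threshold=head["rr"],
        thresholds=threshold_rows,
        percentile_events=pct_events,
        far_crossings=crossings,
        settings={
            **settings.to_dict(),
            "seed": seed,
            "bootstrap_replicates": bootstrap_replicates,
            "band_level": band_level,
        },
        bootstrap=boot,
    )
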