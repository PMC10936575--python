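"""Fire-size ensembles: containers, CSV input/output, and the bundled
Las Conchas reanalysis data.

An *ensemble* is one scenario's sample of simulated final fire sizes
(hectares) — e.g. ten replays of the same fire on the actual landscape.
Attribution always compares two ensembles arranged as a
:class:`ScenarioPair`; the caller must say which scenario plays the
reference role ``p0`` and which the comparison role ``p1``, because the
role assignment flips between retrospective analyses (actual landscape
is p0, counterfactual-untreated is p1) and prospective ones
(hypothetically-treated is p0, actual-untreated is p1). The library
never guesses.

CSV format: UTF-8, comma-separated, required header ``fire_size_ha``;
an optional ``scenario`` column lets one file carry several ensembles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    EnsembleTooSmallError,
    EnsembleValidationError,
    NonNumericDataError,
    NonPositiveSizeError,
)

SIZE_COLUMN = "fire_size_ha"
SCENARIO_COLUMN = "scenario"


@dataclass(frozen=True)
class FireSizeEnsemble:
    """A labeled sample of final fire sizes for one scenario.

    Parameters
    ----------
    label : str
        Scenario name (free text, e.g. ``"actual"`` or ``"rand25"``).
    sizes : array-like of float
        Final fire sizes in hectares, all strictly positive and finite.
        Row order of the source file is preserved.
    """

    label: str
    sizes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.sizes, dtype=float)
        if arr.ndim != 1:
            raise EnsembleValidationError(
                f"ensemble {self.label!r}: sizes must be one-dimensional"
            )
        if arr.size < 2:
            raise EnsembleTooSmallError(
                f"ensemble {self.label!r} too small: {arr.size} row(s); "
                "at least 2 fire sizes are required"
            )
        bad = np.flatnonzero(~np.isfinite(arr) | (arr <= 0))
        if bad.size:
            raise NonPositiveSizeError(
                f"ensemble {self.label!r}: non-positive or non-finite fire "
                f"size {arr[bad[0]]!r} at row {bad[0] + 1}"
            )
        object.__setattr__(self, "sizes", arr)

    @property
    def n(self) -> int:
        return int(self.sizes.size)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class ScenarioPair:
    """Two ensembles with declared attribution roles.

    ``p0_ensemble`` is the reference (mitigated) scenario whose
    exceedance probability enters FAR/RR as p0; ``p1_ensemble`` is the
    comparison (unmitigated / counterfactual) scenario providing p1.
    ``direction_note`` records, in words, which real-world landscape
    plays which role — it travels into reports so a reader of the
    output can audit the convention used.
    """

    p0_ensemble: FireSizeEnsemble
    p1_ensemble: FireSizeEnsemble
    direction_note: str = ""

    def __post_init__(self) -> None:
        if self.p0_ensemble is self.p1_ensemble:
            raise EnsembleValidationError(
                "p0 and p1 must be distinct ensemble objects"
            )
        if self.p0_ensemble.label == self.p1_ensemble.label:
            raise EnsembleValidationError(
                f"p0 and p1 labels must differ (both {self.p0_ensemble.label!r})"
            )


def read_ensemble(path: str | Path, label: str | None = None,
                  scenario: str | None = None) -> FireSizeEnsemble:
    """Read one fire-size ensemble from a CSV file.

    Parameters
    ----------
    path : path
        CSV with a header row containing ``fire_size_ha`` (hectares).
    label : str, optional
        Label for the returned ensemble. Defaults to ``scenario`` if
        given, else the file stem.
    scenario : str, optional
        If the file has a ``scenario`` column, select this scenario's
        rows; otherwise all rows are used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ensemble file not found: {path}")
    df = pd.read_csv(path)
    if SIZE_COLUMN not in df.columns:
        raise EnsembleValidationError(
            f"{path}: missing required column {SIZE_COLUMN!r} "
            f"(found {list(df.columns)})"
        )
    if scenario is not None:
        if SCENARIO_COLUMN not in df.columns:
            raise EnsembleValidationError(
                f"{path}: no {SCENARIO_COLUMN!r} column to select "
                f"{scenario!r} from"
            )
        df = df[df[SCENARIO_COLUMN] == scenario]
    raw = df[SIZE_COLUMN]
    sizes = pd.to_numeric(raw, errors="coerce")
    bad = sizes.index[sizes.isna() & raw.notna()]
    if len(bad):
        raise NonNumericDataError(
            f"{path}: non-numeric fire size {raw.loc[bad[0]]!r} "
            f"(data row {bad[0] + 1})"
        )
    if sizes.isna().any():
        row = int(sizes.index[sizes.isna()][0]) + 1
        raise NonNumericDataError(f"{path}: empty fire size at data row {row}")
    return FireSizeEnsemble(label or scenario or path.stem,
                            sizes.to_numpy(dtype=float))


def write_ensemble(ensemble: FireSizeEnsemble, path: str | Path) -> None:
    """Write an ensemble to the package CSV format (with scenario column)."""
    pd.DataFrame(
        {SCENARIO_COLUMN: ensemble.label, SIZE_COLUMN: ensemble.sizes}
    ).to_csv(path, index=False)


def write_ensembles(ensembles: Iterable[FireSizeEnsemble],
                    path: str | Path) -> None:
    """Write several ensembles into one CSV, distinguished by scenario."""
    frames = [
        pd.DataFrame({SCENARIO_COLUMN: e.label, SIZE_COLUMN: e.sizes})
        for e in ensembles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# The 2011 Las Conchas Fire (New Mexico, USA) reanalysis: ten FARSITE
# replays of the fire on the landscape as it was (with prior fuel
# treatments and burns) and ten on a counterfactual landscape without
# them. Bundled verbatim as the package's worked example.
_LAS_CONCHAS_RESOURCE = "las_conchas.csv"
LAS_CONCHAS_DIRECTION_NOTE = (
    "retrospective: p0 = actual landscape (with prior treatment/burns), "
    "p1 = counterfactual untreated landscape"
)


def las_conchas_pair() -> ScenarioPair:
    """The bundled Las Conchas fire-size ensembles as a ScenarioPair.

    The actual landscape is p0 and the counterfactual (no prior
    treatment or disturbance) landscape is p1, matching the
    retrospective attribution convention.
    """
    ref = resources.files("pyrofar.data").joinpath(_LAS_CONCHAS_RESOURCE)
    with resources.as_file(ref) as p:
        actual = read_ensemble(p, scenario="actual")
        counterfactual = read_ensemble(p, scenario="counterfactual")
    return ScenarioPair(actual, counterfactual, LAS_CONCHAS_DIRECTION_NOTE)


# ---------------------------------------------------------------------------
# JSON report round-trip. NaN is not valid JSON, so undefined statistics are
# serialized as null and +/-inf as the strings "inf"/"-inf"; the reader
# restores them.
# ---------------------------------------------------------------------------

def _sanitize(obj):
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return obj
    if isinstance(obj, (np.floating, np.integer)):
        return _sanitize(float(obj))
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    if isinstance(obj, Mapping):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    return obj


def _restore(obj):
    if obj is None:
        return float("nan")
    if obj == "inf":
        return float("inf")
    if obj == "-inf":
        return float("-inf")
    if isinstance(obj, Mapping):
        return {k: _restore(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_restore(v) for v in obj]
    return obj


def write_report(report, path: str | Path) -> None:
    """Serialize an :class:`~pyrofar.attribution.AttributionReport` to JSON.

    Optional sections that are absent (e.g. no bootstrap was run) are
    omitted from the file. Output is deterministic: keys sorted, no
    timestamps.
    """
    payload = _sanitize(report.to_dict())
    payload = {k: v for k, v in payload.items() if v is not None}
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, allow_nan=False) + "\n",
        encoding="utf-8",
    )


def read_report(path: str | Path):
    """Read a JSON report written by :func:`write_report`."""
    from .attribution import AttributionReport  # avoid import cycle

    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return AttributionReport.from_dict(_restore_report_dict(raw))


def _restore_report_dict(raw: dict) -> dict:
    out = {}
    for k, v in raw.items():
        out[k] = _restore(v) if k not in ("labels", "direction_note",
                                          "settings") else v
    return out
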