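"""Plate-reader ingestion, baseline correction, normalization and averaging.

Plate CSVs come in two dialects:

* wide  — column ``time_s`` followed by one signal column per well
* long  — columns ``time_s``, ``well``, ``signal``

The metadata CSV has columns ``well``, ``assay``, ``substrate``,
``substrate_conc_uM``, ``inhibitor``, ``inhibitor_conc_uM``, ``molar_ratio``,
``replicate_group``. Concentrations are ingested in µM and stored in molar.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AggregationTrace",
    "NormalizedTrace",
    "AveragedTrace",
    "PlateLoadError",
    "FlatTraceError",
    "load_plate",
    "baseline_and_normalize",
    "average_replicates",
    "final_intensity",
    "baseline_correct",
    "is_aggregating",
]

METADATA_COLUMNS = [
    "well",
    "assay",
    "substrate",
    "substrate_conc_uM",
    "inhibitor",
    "inhibitor_conc_uM",
    "molar_ratio",
    "replicate_group",
]

#: plateau/baseline amplitude ratio below which a well counts as non-aggregating
FLAT_RATIO_THRESHOLD = 1.2


class PlateLoadError(ValueError):
    """Malformed plate or metadata input."""


class FlatTraceError(ValueError):
    """Trace has no usable transition (plateau <= baseline)."""


@dataclass(frozen=True)
class AggregationTrace:
    """One well's time series plus its assay metadata (molar / seconds)."""

    well_id: str
    times: np.ndarray
    signals: np.ndarray
    assay: str = "ThT"
    substrate: str = ""
    substrate_conc: float = 0.0
    inhibitor_conc: float = 0.0
    molar_ratio: float = 0.0
    replicate_group: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "signals", np.asarray(self.signals, dtype=float))
        if self.times.shape != self.signals.shape or self.times.ndim != 1:
            raise ValueError(f"well {self.well_id}: times/signals shape mismatch")
        if self.times.size < 10:
            raise ValueError(f"well {self.well_id}: need >= 10 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"well {self.well_id}: times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class NormalizedTrace(AggregationTrace):
    """Baseline-corrected, plateau-normalized trace."""

    baseline_used: float = 0.0
    plateau_used: float = 1.0


@dataclass(frozen=True)
class AveragedTrace:
    """Pointwise mean +/- SD over replicates on a shared time grid."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int
    replicate_group: str = ""


def _read_metadata(meta_table: str | Path | pd.DataFrame) -> pd.DataFrame:
    meta = (
        meta_table
        if isinstance(meta_table, pd.DataFrame)
        else pd.read_csv(meta_table)
    )
    missing = [c for c in ("well",) if c not in meta.columns]
    if missing:
        raise PlateLoadError(f"metadata is missing required columns: {missing}")
    return meta.set_index("well", drop=False)


def load_plate(
    data_table: str | Path | pd.DataFrame,
    meta_table: str | Path | pd.DataFrame,
) -> list[AggregationTrace]:
    """Join a plate CSV (wide or long) with well metadata into traces."""
    data = (
        data_table
        if isinstance(data_table, pd.DataFrame)
        else pd.read_csv(data_table)
    )
    if "time_s" not in data.columns:
        raise PlateLoadError("plate table has no 'time_s' column")
    meta = _read_metadata(meta_table)

    if {"well", "signal"} <= set(data.columns):  # long dialect
        wells = list(dict.fromkeys(data["well"]))
        series = {
            w: (g["time_s"].to_numpy(float), g["signal"].to_numpy(float))
            for w, g in data.groupby("well", sort=False)
        }
    else:  # wide dialect
        wells = [c for c in data.columns if c != "time_s"]
        t = data["time_s"].to_numpy(float)
        series = {w: (t, data[w].to_numpy(float)) for w in wells}

    traces = []
    for well in wells:
        if well not in meta.index:
            raise PlateLoadError(f"no metadata row for well {well!r}")
        row = meta.loc[well]
        t, y = series[well]
        if np.any(np.diff(t) <= 0):
            raise PlateLoadError(f"well {well!r}: non-monotone time axis")

        def _conc(col: str) -> float:
            v = row.get(col, np.nan)
            try:
                v = float(v)
            except (TypeError, ValueError) as exc:
                raise PlateLoadError(
                    f"well {well!r}: cannot parse {col}={v!r}"
                ) from exc
            return 0.0 if np.isnan(v) else v * 1e-6  # µM -> M

        sub_conc = _conc("substrate_conc_uM")
        inh_conc = _conc("inhibitor_conc_uM")
        ratio = row.get("molar_ratio", np.nan)
        ratio = float(ratio) if not pd.isna(ratio) else (
            inh_conc / sub_conc if sub_conc > 0 else 0.0
        )
        traces.append(
            AggregationTrace(
                well_id=str(well),
                times=t,
                signals=y,
                assay=str(row.get("assay", "ThT")),
                substrate=str(row.get("substrate", "")),
                substrate_conc=sub_conc,
                inhibitor_conc=inh_conc,
                molar_ratio=ratio,
                replicate_group=str(row.get("replicate_group", "")),
            )
        )
    return traces


def is_aggregating(
    trace: AggregationTrace,
    baseline_window: int = 5,
    plateau_window: int = 10,
    flat_ratio: float = FLAT_RATIO_THRESHOLD,
) -> bool:
    """True when the endpoint rises above the baseline by the flat-ratio margin.

    Wells failing it are excluded from kinetic fits but kept for dose-response
    endpoints.
    """
    base = float(np.mean(trace.signals[:baseline_window]))
    plat = float(np.mean(trace.signals[-plateau_window:]))
    if plat <= base:
        return False
    if base <= 0:
        return True
    return plat / base >= flat_ratio


def baseline_and_normalize(
    trace: AggregationTrace,
    baseline_window: int = 5,
    plateau_window: int = 10,
) -> NormalizedTrace:
    """Subtract the early-window mean, scale by the late-window amplitude."""
    n = trace.n_points
    if baseline_window < 1 or plateau_window < 1 or baseline_window + plateau_window > n:
        raise ValueError("baseline/plateau windows do not fit in the trace")
    baseline = float(np.mean(trace.signals[:baseline_window]))
    plateau = float(np.mean(trace.signals[-plateau_window:]))
    if plateau <= baseline:
        raise FlatTraceError(
            f"well {trace.well_id}: plateau {plateau:g} <= baseline {baseline:g}; "
            "trace flagged as non-aggregating"
        )
    normalized = (trace.signals - baseline) / (plateau - baseline)
    return NormalizedTrace(
        well_id=trace.well_id,
        times=trace.times,
        signals=normalized,
        assay=trace.assay,
        substrate=trace.substrate,
        substrate_conc=trace.substrate_conc,
        inhibitor_conc=trace.inhibitor_conc,
        molar_ratio=trace.molar_ratio,
        replicate_group=trace.replicate_group,
        baseline_used=baseline,
        plateau_used=plateau,
    )


def average_replicates(traces: list[AggregationTrace]) -> AveragedTrace:
    """Pointwise mean and SD over replicates sharing one time grid."""
    if not traces:
        raise ValueError("no traces to average")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise ValueError(
                "replicate time grids differ; interpolate onto a common grid first"
            )
    groups = {tr.replicate_group for tr in traces}
    if len(groups) > 1:
        raise ValueError(f"traces span multiple replicate groups: {sorted(groups)}")
    stack = np.vstack([tr.signals for tr in traces])
    return AveragedTrace(
        times=t0.copy(),
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1) if len(traces) > 1 else np.zeros_like(t0),
        n=len(traces),
        replicate_group=traces[0].replicate_group,
    )


def final_intensity(trace: AggregationTrace, window: int = 10) -> float:
    """Mean of the last ``window`` points of the signal."""
    if window < 1 or window > trace.n_points:
        raise ValueError("window must be within the trace length")
    return float(np.mean(trace.signals[-window:]))


def baseline_correct(trace: AggregationTrace, baseline_window: int = 5) -> AggregationTrace:
    """Subtract the early-window mean without rescaling (turbidity endpoints)."""
    baseline = float(np.mean(trace.signals[:baseline_window]))
    return replace(trace, signals=trace.signals - baseline)
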