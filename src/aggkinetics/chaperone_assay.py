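"""Dose-response analysis of turbidity (non-fibrillar aggregation) assays.

Endpoint intensities are baseline-corrected per well, averaged within each
experiment block, normalized to the block's substrate-alone control mean,
and summarized as mean +/- SD across blocks per chaperone:substrate molar
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace_processing import AggregationTrace, baseline_correct, final_intensity

__all__ = [
    "DoseResponsePoint",
    "dose_response",
    "dose_response_table",
    "compare_chaperones",
    "rescale_concentrations",
]


@dataclass(frozen=True)
class DoseResponsePoint:
    """Normalized final turbidity at one molar ratio (mean over blocks)."""

    molar_ratio: float
    mean_norm_intensity: float
    sd: float
    n_experiments: int

    def __post_init__(self) -> None:
        if self.molar_ratio < 0 or self.mean_norm_intensity < 0:
            raise ValueError("ratio and intensity must be >= 0")


def dose_response(
    traces: list[AggregationTrace],
    control_ratio: float = 0.0,
    baseline_window: int = 5,
    endpoint_window: int = 10,
) -> list[DoseResponsePoint]:
    """Per-block normalized endpoint intensities, pooled across blocks.

    Within each experiment block (identified by ``replicate_group``) the
    within-block replicate wells at one ratio are averaged, then divided by
    that block's mean control (``control_ratio``) intensity; mean +/- SD are
    taken across blocks. Raises when any block lacks control wells.
    """
    blocks: dict[str, list[AggregationTrace]] = {}
    for tr in traces:
        blocks.setdefault(tr.replicate_group, []).append(tr)

    per_block: dict[str, dict[float, float]] = {}
    for block, members in sorted(blocks.items()):
        endpoints: dict[float, list[float]] = {}
        for tr in members:
            corrected = baseline_correct(tr, baseline_window)
            endpoints.setdefault(round(float(tr.molar_ratio), 12), []).append(
                final_intensity(corrected, endpoint_window)
            )
        if control_ratio not in endpoints:
            raise ValueError(
                f"experiment block {block!r} has no control wells "
                f"(ratio {control_ratio:g})"
            )
        control = float(np.mean(endpoints[control_ratio]))
        if control <= 0:
            raise ValueError(f"block {block!r}: non-positive control intensity")
        per_block[block] = {
            ratio: float(np.mean(vals)) / control for ratio, vals in endpoints.items()
        }

    ratios = sorted({r for d in per_block.values() for r in d})
    points = []
    for ratio in ratios:
        vals = np.array([d[ratio] for d in per_block.values() if ratio in d])
        points.append(
            DoseResponsePoint(
                molar_ratio=ratio,
                mean_norm_intensity=float(np.clip(vals.mean(), 0.0, None)),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                n_experiments=int(vals.size),
            )
        )
    return points


def dose_response_table(points: list[DoseResponsePoint]) -> pd.DataFrame:
    """Dose-response points as a CSV-ready table (ratio ascending)."""
    return pd.DataFrame(
        [
            {
                "ratio": p.molar_ratio,
                "mean": p.mean_norm_intensity,
                "sd": p.sd,
                "n": p.n_experiments,
            }
            for p in sorted(points, key=lambda p: p.molar_ratio)
        ]
    )


def compare_chaperones(
    table_a: list[DoseResponsePoint],
    table_b: list[DoseResponsePoint],
) -> pd.DataFrame:
    """Per-ratio mean difference (A - B) with propagated SD.

    Flags ratios where the two mean +/- SD intervals do not overlap.
    """
    a = {p.molar_ratio: p for p in table_a}
    b = {p.molar_ratio: p for p in table_b}
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("dose-response tables share no molar ratios")
    rows = []
    for ratio in shared:
        pa, pb = a[ratio], b[ratio]
        diff = pa.mean_norm_intensity - pb.mean_norm_intensity
        sd = float(np.hypot(pa.sd, pb.sd))
        rows.append(
            {
                "ratio": ratio,
                "difference": diff,
                "sd": sd,
                "non_overlapping": bool(abs(diff) > pa.sd + pb.sd),
            }
        )
    return pd.DataFrame(rows)


def rescale_concentrations(
    points: list[DoseResponsePoint], factor: float
) -> list[DoseResponsePoint]:
    """Multiply molar ratios by a concentration-calibration factor."""
    if factor <= 0:
        raise ValueError("calibration factor must be positive")
    return [
        DoseResponsePoint(
            molar_ratio=p.molar_ratio * factor,
            mean_norm_intensity=p.mean_norm_intensity,
            sd=p.sd,
            n_experiments=p.n_experiments,
        )
        for p in points
    ]
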