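"""Deterministic synthetic plate generators with recorded ground truth.

Two generators mirror the two assay designs the pipeline analyses:

* ThT fibrillization plates following the unseeded nucleation-elongation
  kinetics, with a configurable inhibitor acting multiplicatively on chosen
  microscopic rates;
* turbidity (light-scattering) plates with saturating rises whose plateaus
  are suppressed by a chaperone dose.

Both emit the wide plate-CSV dialect and the metadata CSV that
:mod:`aggkinetics.trace_processing` reads, plus a JSON-serialisable truth
record sufficient to recompute every expected pipeline output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetic_model import (
    RateConstants,
    compute_kappa,
    compute_lambda,
    halftime,
    model_mass_fraction,
)

__all__ = [
    "InhibitorModel",
    "TurbidityModel",
    "generate_tht_plate",
    "generate_turbidity_plate",
    "write_plate",
    "DEFAULT_M0_SERIES_UM",
    "DEFAULT_RATIOS",
]

#: eight-concentration monomer series (µM) used by the multi-load ThT design
DEFAULT_M0_SERIES_UM = (1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 7.0, 9.0)
#: inhibitor:substrate molar ratios of the fixed-load dose-series design
DEFAULT_RATIOS = (0.0, 0.1, 0.3, 0.5, 0.7, 1.0)

_RATE_KEYS = ("kn", "k_plus", "k2")


@dataclass(frozen=True)
class InhibitorModel:
    """Multiplicative dose action on one (or several) microscopic rates.

    ``dose_factor_map`` maps inhibitor dose (any consistent dose variable,
    here molar ratio) to the factor applied to the targeted rate; factors lie
    in (0, 1] and the zero dose maps to 1. For ``target='combo'`` supply
    ``combo_maps`` with one map per rate key.
    """

    target: str
    dose_factor_map: dict[float, float] = field(default_factory=dict)
    combo_maps: dict[str, dict[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target not in (*_RATE_KEYS, "combo", "none"):
            raise ValueError(f"unknown inhibitor target {self.target!r}")
        for m in (self.dose_factor_map, *self.combo_maps.values()):
            for dose, f in m.items():
                if f <= 0:
                    raise ValueError("dose factors must be positive")
                if dose == 0 and f != 1.0:
                    raise ValueError("factor at zero dose must be 1")

    @classmethod
    def null(cls) -> "InhibitorModel":
        return cls(target="none")

    def factors(self, dose: float) -> dict[str, float]:
        """Per-rate multiplicative factors at one dose."""
        out = {k: 1.0 for k in _RATE_KEYS}
        if dose == 0 or self.target == "none":
            return out
        if self.target == "combo":
            for key, m in self.combo_maps.items():
                out[key] = m[dose]
        else:
            out[self.target] = self.dose_factor_map[dose]
        return out

    def apply(self, rc: RateConstants, dose: float) -> RateConstants:
        f = self.factors(dose)
        return RateConstants(
            kn=rc.kn * f["kn"],
            k_plus=rc.k_plus * f["k_plus"],
            k2=rc.k2 * f["k2"],
            nc=rc.nc,
            n2=rc.n2,
        )


@dataclass(frozen=True)
class TurbidityModel:
    """Saturating turbidity rise with dose-suppressed plateau."""

    plateau: float
    rate: float
    onset: float
    residual_fraction_map: dict[float, float]

    def __post_init__(self) -> None:
        if self.plateau <= 0 or self.rate <= 0:
            raise ValueError("plateau and rate must be positive")
        if self.residual_fraction_map.get(0.0, 1.0) != 1.0:
            raise ValueError("residual fraction at ratio 0 must be 1")
        for f in self.residual_fraction_map.values():
            if not (0.0 < f <= 1.0):
                raise ValueError("residual fractions must lie in (0, 1]")

    def curve(self, t: np.ndarray, ratio: float) -> np.ndarray:
        resid = self.residual_fraction_map[ratio]
        z = np.clip(self.rate * (self.onset - t), -700, 700)
        return self.plateau * resid / (1.0 + np.exp(z))


def _well_names(n: int) -> list[str]:
    rows = "ABCDEFGHIJKLMNOP"
    return [f"{rows[i // 24]}{i % 24 + 1:02d}" for i in range(n)]


def generate_tht_plate(
    rc: RateConstants,
    m0_list: list[float] | tuple[float, ...] = (3e-6,),
    inhib: InhibitorModel | None = None,
    doses: list[float] | tuple[float, ...] = (0.0,),
    noise_sd: float = 0.02,
    n_reps: int = 4,
    seed: int = 0,
    F0: float = 0.1,
    A: float = 1.0,
    n_points: int = 400,
    n_halftimes: float = 4.2,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate an unseeded ThT plate; returns (plate, metadata, truth).

    Signal per well is ``F0 + A * M(t)/M(inf)`` plus i.i.d. Gaussian noise of
    SD ``noise_sd * A``. The shared time grid spans ``n_halftimes`` half-times
    of the slowest condition.
    """
    if inhib is None:
        inhib = InhibitorModel.null()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    conditions = [(m0, dose) for m0 in m0_list for dose in doses]
    if not conditions:
        raise ValueError("need at least one (m0, dose) condition")
    rng = np.random.default_rng(seed)

    lam_kap = {}
    halftimes = {}
    for m0, dose in conditions:
        rcd = inhib.apply(rc, dose)
        lam = compute_lambda(rcd, m0)
        kap = compute_kappa(rcd, m0)
        lam_kap[(m0, dose)] = (lam, kap)
        halftimes[(m0, dose)] = halftime(lam, kap, rc.nc, rc.n2)
    t_end = n_halftimes * max(halftimes.values())
    t = np.linspace(0.0, t_end, n_points)

    wells = _well_names(len(conditions) * n_reps)
    plate = {"time_s": t}
    meta_rows = []
    warnings = []
    i = 0
    for m0, dose in conditions:
        lam, kap = lam_kap[(m0, dose)]
        curve = model_mass_fraction(t, lam, kap, rc.nc, rc.n2)
        if halftimes[(m0, dose)] * 2 > t_end:
            warnings.append(
                f"condition m0={m0:g}, dose={dose:g}: half time "
                f"{halftimes[(m0, dose)]:g}s not well inside the grid"
            )
        group = f"m{m0 * 1e6:g}uM_d{dose:g}"
        for rep in range(n_reps):
            well = wells[i]
            i += 1
            noise = rng.normal(0.0, noise_sd * A, size=t.size) if noise_sd else 0.0
            plate[well] = F0 + A * curve + noise
            meta_rows.append(
                {
                    "well": well,
                    "assay": "ThT",
                    "substrate": "Abeta42",
                    "substrate_conc_uM": m0 * 1e6,
                    "inhibitor": "chaperone" if dose else "",
                    "inhibitor_conc_uM": dose * m0 * 1e6,
                    "molar_ratio": dose,
                    "replicate_group": group,
                }
            )
    truth = {
        "kind": "tht",
        "seed": seed,
        "noise_sd": noise_sd,
        "n_reps": n_reps,
        "F0": F0,
        "A": A,
        "nc": rc.nc,
        "n2": rc.n2,
        "sqrt_knkp": rc.sqrt_knkp,
        "sqrt_kpk2": rc.sqrt_kpk2,
        "rates": {"kn": rc.kn, "k_plus": rc.k_plus, "k2": rc.k2},
        "m0_list": list(m0_list),
        "doses": list(doses),
        "dose_factors": {str(d): inhib.factors(d) for d in doses},
        "halftimes_s": {f"{m0:g}|{d:g}": halftimes[(m0, d)] for m0, d in conditions},
        "t_end_s": t_end,
        "warnings": warnings,
    }
    return pd.DataFrame(plate), pd.DataFrame(meta_rows), truth


def generate_turbidity_plate(
    tm: TurbidityModel,
    ratios: list[float] | tuple[float, ...] = DEFAULT_RATIOS,
    n_blocks: int = 3,
    n_reps: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
    block_gain: float = 0.0,
    substrate: str = "CS",
    substrate_conc_uM: float = 0.6,
    t_end: float | None = None,
    n_points: int = 120,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate turbidity blocks; returns (plate, metadata, truth).

    Each of ``n_blocks`` experiment blocks carries one multiplicative gain
    (uniform in 1 +/- ``block_gain``) applied to all its wells, mimicking
    day-to-day instrument variation; noise is additive with SD
    ``noise_sd * plateau``.
    """
    if 0.0 not in ratios:
        raise ValueError("ratio 0 (substrate-alone control) must be included")
    missing = [r for r in ratios if r not in tm.residual_fraction_map]
    if missing:
        raise ValueError(f"no residual fraction defined for ratios {missing}")
    rng = np.random.default_rng(seed)
    if t_end is None:
        t_end = tm.onset + 6.0 / tm.rate
    t = np.linspace(0.0, t_end, n_points)

    gains = 1.0 + block_gain * rng.uniform(-1.0, 1.0, size=n_blocks)
    wells = _well_names(n_blocks * len(ratios) * n_reps)
    plate = {"time_s": t}
    meta_rows = []
    i = 0
    for b in range(n_blocks):
        for ratio in ratios:
            curve = tm.curve(t, ratio) * gains[b]
            for _rep in range(n_reps):
                well = wells[i]
                i += 1
                noise = (
                    rng.normal(0.0, noise_sd * tm.plateau, size=t.size)
                    if noise_sd
                    else 0.0
                )
                plate[well] = curve + noise
                meta_rows.append(
                    {
                        "well": well,
                        "assay": "turbidity",
                        "substrate": substrate,
                        "substrate_conc_uM": substrate_conc_uM,
                        "inhibitor": "chaperone" if ratio else "",
                        "inhibitor_conc_uM": ratio * substrate_conc_uM,
                        "molar_ratio": ratio,
                        "replicate_group": f"expt{b + 1}",
                    }
                )
    truth = {
        "kind": "turbidity",
        "seed": seed,
        "noise_sd": noise_sd,
        "block_gain": block_gain,
        "block_gains": gains.tolist(),
        "n_blocks": n_blocks,
        "n_reps": n_reps,
        "plateau": tm.plateau,
        "rate": tm.rate,
        "onset": tm.onset,
        "residual_fraction_map": {str(k): v for k, v in tm.residual_fraction_map.items()},
        "ratios": list(ratios),
        "t_end_s": t_end,
    }
    return pd.DataFrame(plate), pd.DataFrame(meta_rows), truth


def write_plate(
    plate: pd.DataFrame,
    meta: pd.DataFrame,
    truth: dict,
    outdir: str | Path,
    prefix: str,
) -> dict[str, Path]:
    """Write plate/metadata CSVs and the truth record; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plate": outdir / f"{prefix}_plate.csv",
        "meta": outdir / f"{prefix}_meta.csv",
        "truth": outdir / f"{prefix}_truth.json",
    }
    plate.to_csv(paths["plate"], index=False)
    meta.to_csv(paths["meta"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
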