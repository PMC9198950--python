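"""Quadrant gating of per-well flow events.

Viable events are stratified on log10 intensity into four strata
(negative | Dim | Mid | Bright) by three strictly increasing boundaries.
Intervals are half-open and lower-closed: an event sitting exactly on a
boundary belongs to the stratum whose lower edge it sits on (the upper
stratum).  Dead events are excluded from every readout; viability is
reported separately.  MFI is the arithmetic mean of the *linear* viable
intensities over the whole viable population (negative events included),
with a geometric-mean option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

STRATA = ("negative", "dim", "mid", "bright")


@dataclass(frozen=True)
class GateConfig:
    """Three log10-intensity cut points plus per-well QC floors."""

    boundaries: tuple[float, float, float]
    min_events: int = 200
    min_viable_fraction: float = 0.5
    mfi_scale: str = "linear"  # or "geometric"

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, float)
        if b.shape != (3,):
            raise ValueError("exactly three boundaries required")
        if not (np.diff(b) > 0).all():
            raise ValueError("boundaries must be strictly increasing")
        if self.min_events < 1:
            raise ValueError("min_events must be >= 1")
        if self.mfi_scale not in ("linear", "geometric"):
            raise ValueError("mfi_scale must be linear or geometric")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GateConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["boundaries"] = tuple(doc["boundaries"])
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = dict(
            boundaries=[float(b) for b in self.boundaries],
            min_events=int(self.min_events),
            min_viable_fraction=float(self.min_viable_fraction),
            mfi_scale=self.mfi_scale,
        )
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


WELL_SUMMARY_COLUMNS = [
    "well_key",
    "pct_negative",
    "pct_dim",
    "pct_mid",
    "pct_bright",
    "pct_egfp_pos",
    "mfi",
    "viable_fraction",
    "n_events",
    "qc_pass",
]


def summarize_well(
    intensity: np.ndarray,
    viable: np.ndarray,
    gates: GateConfig,
    well_key: str = "",
) -> dict:
    """Gate one well into a WellSummary record.

    With zero viable events all readouts are missing (NaN) and qc_pass is
    False — missingness is explicit, never silently propagated.
    """
    intensity = np.asarray(intensity, float)
    viable = np.asarray(viable)
    if intensity.size == 0:
        raise ValueError(f"well {well_key}: no events")
    n_events = int(intensity.size)
    keep = viable.astype(bool)
    v = intensity[keep]
    viable_fraction = v.size / n_events

    if v.size == 0:
        return dict(
            well_key=well_key,
            pct_negative=math.nan,
            pct_dim=math.nan,
            pct_mid=math.nan,
            pct_bright=math.nan,
            pct_egfp_pos=math.nan,
            mfi=math.nan,
            viable_fraction=0.0,
            n_events=n_events,
            qc_pass=False,
        )

    logv = np.log10(v)
    # side='right': a value equal to a boundary lands in the upper stratum
    # (lower-closed intervals).
    strata = np.searchsorted(np.asarray(gates.boundaries), logv, side="right")
    counts = np.bincount(strata, minlength=4)
    pct = 100.0 * counts / v.size
    if gates.mfi_scale == "linear":
        mfi = float(v.mean())
    else:
        mfi = float(np.power(10.0, logv.mean()))
    qc = n_events >= gates.min_events and viable_fraction >= gates.min_viable_fraction
    return dict(
        well_key=well_key,
        pct_negative=float(pct[0]),
        pct_dim=float(pct[1]),
        pct_mid=float(pct[2]),
        pct_bright=float(pct[3]),
        pct_egfp_pos=float(pct[1] + pct[2] + pct[3]),
        mfi=mfi,
        viable_fraction=float(viable_fraction),
        n_events=n_events,
        qc_pass=bool(qc),
    )


def summarize_wells(events: pd.DataFrame, gates: GateConfig) -> pd.DataFrame:
    """Gate every well in an event table; one WellSummary row per well,
    sorted by well_key."""
    rows = [
        summarize_well(
            grp["intensity"].to_numpy(),
            grp["viable"].to_numpy(),
            gates,
            well_key=key,
        )
        for key, grp in events.groupby("well_key", sort=True)
    ]
    return pd.DataFrame(rows, columns=WELL_SUMMARY_COLUMNS)


def calibrate_boundaries(
    control_events: Iterable[pd.DataFrame] | pd.DataFrame,
    quantiles: Sequence[float],
    min_pooled_events: int = 1000,
) -> np.ndarray:
    """Place gate boundaries at quantiles of pooled control log10 intensity.

    Pools the viable events of the given control wells; deterministic and
    order-invariant (linear-interpolation quantiles of the sorted pool).
    """
    if isinstance(control_events, pd.DataFrame):
        control_events = [control_events]
    pools = []
    for tbl in control_events:
        keep = tbl["viable"].astype(bool)
        pools.append(tbl.loc[keep, "intensity"].to_numpy(float))
    pooled = np.concatenate(pools) if pools else np.array([])
    if pooled.size < min_pooled_events:
        raise ValueError(
            f"only {pooled.size} pooled control events; "
            f"need >= {min_pooled_events}"
        )
    q = np.asarray(quantiles, float)
    if ((q <= 0) | (q >= 1)).any() or not (np.diff(q) > 0).all():
        raise ValueError("quantiles must be strictly increasing in (0, 1)")
    return np.quantile(np.log10(pooled), q)


def calibrate_gates(
    control_events: Iterable[pd.DataFrame] | pd.DataFrame,
    quantiles: Sequence[float],
    min_pooled_events: int = 1000,
    **gate_kwargs,
) -> GateConfig:
    """Quantile-calibrated GateConfig (three quantiles required)."""
    b = calibrate_boundaries(control_events, quantiles, min_pooled_events)
    if b.size != 3:
        raise ValueError("GateConfig needs exactly three boundaries")
    return GateConfig(boundaries=tuple(b), **gate_kwargs)
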