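"""Screen scoring: plate normalization, Z-scores, average Z, ΔZ,
hit calling, and candidate prioritization.

The scoring chain per replicate (one primary culture, one copy of the
library) and per parameter (gated %Bright or MFI):

1. every target-well readout is divided by the mean readout of the same
   plate's QC-passing nontargeted-control wells, giving the normalized
   value X (nontargeted controls average to X = 1 per plate);
2. Z = (X - mu) / sigma with mu, sigma the mean and sample SD (n-1) of X
   over all scored targets of that replicate (library-wide by default;
   per-plate scope available);
3. per-target Z is averaged over replicates, either over all cultures or
   within the pup / adult groups;
4. ΔZ = |avg Z(pup) - avg Z(adult)| measures age-differential response;
5. hits are targets whose average Z strictly exceeds +t (or falls below
   -t) on one or both parameters; candidates are the union of the top-k
   and bottom-k targets per parameter.

QC-failed wells propagate as missing readouts, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import PlateMap

PARAMETERS = ("bright_pct", "mfi")
_PARAM_COLUMN = {"bright_pct": "pct_bright", "mfi": "mfi"}

Parameter = Literal["bright_pct", "mfi"]


def normalize_screen(
    summaries: pd.DataFrame,
    plate_map: PlateMap,
    parameter: Parameter,
) -> pd.DataFrame:
    """Normalize every QC-passing target well to its plate's nontargeted
    controls.

    Returns one row per scored target well: target_gene, replicate_id,
    culture_age, plate_id, well_key, parameter, X.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    col = _PARAM_COLUMN[parameter]
    df = summaries.merge(plate_map.wells, on="well_key", how="inner",
                         validate="one_to_one")

    controls = df[(df["role"] == "nontargeted_control") & df["qc_pass"]]
    control_mean = controls.groupby("plate_id")[col].mean()

    plates_present = df["plate_id"].unique()
    missing = sorted(set(plates_present) - set(control_mean.index))
    if missing:
        raise ValueError(
            f"plate(s) with no QC-passing nontargeted control: {missing}"
        )
    zero = control_mean[control_mean == 0]
    if len(zero):
        raise ValueError(
            f"control mean of 0 on plate(s): {sorted(zero.index)}"
        )

    targets = df[df["role"] == "target"]
    dropped = targets[~targets["qc_pass"]]
    if len(dropped):
        import logging

        logging.getLogger(__name__).info(
            "%d QC-failing target wells emit no readout", len(dropped)
        )
    targets = targets[targets["qc_pass"]].copy()
    targets["X"] = targets[col] / targets["plate_id"].map(control_mean)
    out = targets[
        ["target_gene", "culture_id", "culture_age", "plate_id", "well_key"]
    ].copy()
    out = out.rename(columns={"culture_id": "replicate_id"})
    out["parameter"] = parameter
    out["X"] = targets["X"].to_numpy()
    return out.reset_index(drop=True)


def zscore_replicate(readouts: pd.DataFrame,
                     mu_sigma_scope: str = "library") -> pd.DataFrame:
    """Z-score the normalized readouts of a single replicate/parameter.

    mu and sigma are computed over the scored targets (sample SD, n-1);
    with ``mu_sigma_scope='plate'`` they are computed within each plate
    instead.  Adds columns z, mu, sigma.
    """
    df = readouts.copy()
    if mu_sigma_scope not in ("library", "plate"):
        raise ValueError("mu_sigma_scope must be 'library' or 'plate'")

    def _score(grp: pd.DataFrame) -> pd.DataFrame:
        if len(grp) < 3:
            raise ValueError("need >= 3 scored targets to form a Z-score")
        mu = grp["X"].mean()
        sigma = grp["X"].std(ddof=1)
        if sigma == 0:
            raise ValueError("degenerate replicate: sigma = 0")
        grp = grp.copy()
        grp["mu"] = mu
        grp["sigma"] = sigma
        grp["z"] = (grp["X"] - mu) / sigma
        return grp

    if mu_sigma_scope == "library":
        return _score(df)
    parts = [_score(g) for _, g in df.groupby("plate_id", sort=True)]
    return pd.concat(parts, ignore_index=True)


def zscore_screen(
    normalized: pd.DataFrame, mu_sigma_scope: str = "library"
) -> pd.DataFrame:
    """Z-score every (replicate, parameter) stratum of a normalized table."""
    parts = [
        zscore_replicate(grp, mu_sigma_scope=mu_sigma_scope)
        for _, grp in normalized.groupby(
            ["replicate_id", "parameter"], sort=True
        )
    ]
    return pd.concat(parts, ignore_index=True)


def average_z(
    zscores: pd.DataFrame, group: str = "all"
) -> pd.DataFrame:
    """Average per-replicate Z within a replicate group.

    group is 'all', 'pup' or 'adult'.  Targets absent from every replicate
    of the group are omitted.  Returns target_gene, parameter, avg_z,
    n_replicates.
    """
    if group not in ("all", "pup", "adult"):
        raise ValueError("group must be all, pup or adult")
    df = zscores if group == "all" else zscores[
        zscores["culture_age"] == group
    ]
    out = (
        df.groupby(["target_gene", "parameter"])["z"]
        .agg(avg_z="mean", n_replicates="count")
        .reset_index()
    )
    return out


def build_zscore_table(
    summaries: pd.DataFrame,
    plate_map: PlateMap,
    mu_sigma_scope: str = "library",
) -> pd.DataFrame:
    """Full ZScoreTable: one row per target x parameter with avg Z for the
    pup, adult and combined replicate groups."""
    norm = pd.concat(
        [
            normalize_screen(summaries, plate_map, p)
            for p in PARAMETERS
        ],
        ignore_index=True,
    )
    z = zscore_screen(norm, mu_sigma_scope=mu_sigma_scope)
    table = average_z(z, "all").rename(
        columns={"avg_z": "avg_z_all", "n_replicates": "n_reps_all"}
    )
    for grp in ("pup", "adult"):
        part = average_z(z, grp).rename(
            columns={"avg_z": f"avg_z_{grp}", "n_replicates": f"n_reps_{grp}"}
        )
        table = table.merge(part, on=["target_gene", "parameter"], how="left")
    return table


def delta_z(
    ztable: pd.DataFrame, mode: str = "absolute"
) -> pd.DataFrame:
    """Age-differential response ΔZ per target x parameter.

    ΔZ = |avg Z(pup) - avg Z(adult)| (or the signed pup-minus-adult
    difference with mode='signed').  Targets missing either group average
    are omitted with a warning.
    """
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be absolute or signed")
    df = ztable.copy()
    ok = df["avg_z_pup"].notna() & df["avg_z_adult"].notna()
    if (~ok).any():
        import logging

        logging.getLogger(__name__).warning(
            "%d target/parameter rows one-sided; omitted from ΔZ",
            int((~ok).sum()),
        )
    df = df[ok]
    d = df["avg_z_pup"] - df["avg_z_adult"]
    out = df[["target_gene", "parameter"]].copy()
    out["delta_z"] = d.abs() if mode == "absolute" else d
    return out.reset_index(drop=True)


@dataclass
class HitList:
    """Targets whose average Z passes a threshold on the configured
    parameter rule."""

    threshold: float
    direction: str  # above / below / either
    parameter_rule: str  # bright_only / mfi_only / union / intersection
    scope: str  # all / pup / adult
    members: list[str]

    def __len__(self) -> int:
        return len(self.members)


def _passing(avg: pd.Series, t: float, direction: str) -> pd.Series:
    if direction == "above":
        return avg > t
    if direction == "below":
        return avg < -t
    if direction == "either":
        return (avg > t) | (avg < -t)
    raise ValueError("direction must be above, below or either")


def call_hits(
    ztable: pd.DataFrame,
    t: float = 1.0,
    direction: str = "either",
    parameter_rule: str = "union",
    scope: str = "all",
) -> HitList:
    """Call hits by strict comparison of average Z to ±t.

    ``scope`` selects which group average to threshold (avg_z_all,
    avg_z_pup or avg_z_adult).  Boundary values (|Z| = t exactly) are
    excluded, matching a strict "Z > t" filter.
    """
    if t <= 0:
        raise ValueError("threshold must be > 0")
    if parameter_rule not in ("bright_only", "mfi_only", "union",
                              "intersection"):
        raise ValueError(f"unknown parameter_rule {parameter_rule!r}")
    col = {"all": "avg_z_all", "pup": "avg_z_pup", "adult": "avg_z_adult"}[
        scope
    ]
    wide = ztable.pivot(index="target_gene", columns="parameter",
                        values=col)
    sets = {}
    for p in PARAMETERS:
        if p in wide:
            avail = wide[p].dropna()
            sets[p] = set(avail.index[_passing(avail, t, direction)])
    if parameter_rule == "bright_only":
        members = sets.get("bright_pct", set())
    elif parameter_rule == "mfi_only":
        members = sets.get("mfi", set())
    elif parameter_rule == "union":
        members = sets.get("bright_pct", set()) | sets.get("mfi", set())
    else:
        members = sets.get("bright_pct", set()) & sets.get("mfi", set())
    return HitList(
        threshold=t,
        direction=direction,
        parameter_rule=parameter_rule,
        scope=scope,
        members=sorted(members),
    )


@dataclass
class CandidateSet:
    """Deduplicated union of the top-k and bottom-k targets per parameter,
    ranked on the all-replicate average Z."""

    k: int
    members: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def rank_candidates(ztable: pd.DataFrame, k: int = 5) -> CandidateSet:
    """Top-k highest and bottom-k lowest avg_z_all per parameter, unioned.

    Ties at rank k break lexicographically on gene symbol (documented,
    deterministic).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    provenance: dict[str, list[str]] = {}
    for p in PARAMETERS:
        part = ztable[ztable["parameter"] == p].dropna(subset=["avg_z_all"])
        top = part.sort_values(
            ["avg_z_all", "target_gene"], ascending=[False, True],
            kind="mergesort",
        ).head(k)["target_gene"]
        bottom = part.sort_values(
            ["avg_z_all", "target_gene"], ascending=[True, True],
            kind="mergesort",
        ).head(k)["target_gene"]
        for g in top:
            provenance.setdefault(g, []).append(f"top_{p}")
        for g in bottom:
            provenance.setdefault(g, []).append(f"bottom_{p}")
    return CandidateSet(k=k, members=sorted(provenance), provenance=provenance)


def hits_union_over_groups(
    ztable: pd.DataFrame, t: float = 1.0
) -> HitList:
    """Union of |avg Z| > t hits over both age groups and both parameters —
    the broadest candidate-regulator list the dual-parameter screen
    supports."""
    members: set[str] = set()
    for scope in ("pup", "adult"):
        members |= set(
            call_hits(ztable, t=t, direction="either",
                      parameter_rule="union", scope=scope).members
        )
    return HitList(
        threshold=t,
        direction="either",
        parameter_rule="union",
        scope="pup+adult",
        members=sorted(members),
    )
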