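"""Readers and writers for screen artifacts.

Canonical formats are plain text: CSV for plate maps and per-event tables,
GMT for gene-set collections, TSV (single header row, floats at 6 significant
digits) for every table the pipeline writes.  Well identity is always the
composite key ``plate_id:well_id``; culture/replicate identity lives in the
plate map, never in file names.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = frozenset(
    {"target", "nontargeted_control", "lipofectamine_only", "internal_control"}
)

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")

PLATE_MAP_COLUMNS = [
    "plate_id",
    "well_id",
    "role",
    "target_gene",
    "culture_id",
    "culture_age",
]


def well_key(plate_id: str, well_id: str) -> str:
    return f"{plate_id}:{well_id}"


@dataclass
class PlateMap:
    """Validated well-level annotation of the whole screen.

    ``wells`` has one row per (plate, well) with columns
    plate_id, well_id, role, target_gene, culture_id, culture_age and a
    derived well_key column.  Each plate_id is specific to one culture
    (one physical transfection of the library), so (plate_id, well_id)
    is unique across the whole map.
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.wells.copy()
        missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"plate map missing columns: {missing}")
        df["target_gene"] = df["target_gene"].fillna("").astype(str)
        dup = df.duplicated(subset=["plate_id", "well_id"])
        if dup.any():
            first = df.loc[dup, ["plate_id", "well_id"]].iloc[0]
            raise ValueError(
                f"duplicate well {first.plate_id}/{first.well_id} in plate map"
            )
        bad_role = set(df["role"]) - ROLES
        if bad_role:
            raise ValueError(f"unknown role(s) in plate map: {sorted(bad_role)}")
        bad_age = set(df["culture_age"]) - {"pup", "adult"}
        if bad_age:
            raise ValueError(f"unknown culture_age(s): {sorted(bad_age)}")
        for plate_id, grp in df.groupby("plate_id", sort=False):
            if not (grp["role"] == "nontargeted_control").any():
                raise ValueError(
                    f"plate {plate_id} has no nontargeted_control well"
                )
        is_target = df["role"] == "target"
        has_gene = df["target_gene"] != ""
        if (is_target != has_gene).any():
            bad = df.loc[is_target != has_gene].iloc[0]
            raise ValueError(
                "role=target must coincide with a nonempty target_gene "
                f"(offending well {bad.plate_id}/{bad.well_id})"
            )
        df["well_key"] = [
            well_key(p, w) for p, w in zip(df["plate_id"], df["well_id"])
        ]
        # canonical order: sorted keys, so downstream iteration is deterministic
        self.wells = df.sort_values("well_key", kind="mergesort").reset_index(
            drop=True
        )

    @property
    def cultures(self) -> pd.DataFrame:
        """One row per culture_id with its age."""
        return (
            self.wells[["culture_id", "culture_age"]]
            .drop_duplicates()
            .sort_values("culture_id")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.wells)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), order-preserving, members deduplicated."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_plate_map(path: str | Path) -> PlateMap:
    """Read a plate-map CSV (columns plate_id,well_id,role,target_gene,
    culture_id,culture_age) and validate it."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return PlateMap(df)


def write_plate_map(plate_map: PlateMap, path: str | Path) -> None:
    plate_map.wells[PLATE_MAP_COLUMNS].to_csv(path, index=False)


def read_events(
    path: str | Path, plate_map: PlateMap | None = None
) -> pd.DataFrame:
    """Read a per-event CSV (well_key,intensity,viable).

    Intensities must be strictly positive; viable is 0/1.  When a plate map
    is supplied every well_key must exist in it.  Events come back grouped
    (stably sorted) by well_key with the original within-well order intact.
    """
    df = pd.read_csv(
        path,
        dtype={"well_key": str, "intensity": float, "viable": np.int8},
        float_precision="round_trip",  # bit-exact intensity round-trips
    )
    missing = {"well_key", "intensity", "viable"} - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if (df["intensity"] <= 0).any():
        bad = df.loc[df["intensity"] <= 0].iloc[0]
        raise ValueError(
            f"nonpositive intensity {bad.intensity} in well {bad.well_key}"
        )
    if not df["viable"].isin([0, 1]).all():
        raise ValueError("viable flag must be 0 or 1")
    if plate_map is not None:
        known = set(plate_map.wells["well_key"])
        unknown = set(df["well_key"]) - known
        if unknown:
            raise ValueError(
                f"event well_key(s) absent from plate map: {sorted(unknown)[:5]}"
            )
    return df.sort_values("well_key", kind="mergesort").reset_index(drop=True)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events[["well_key", "intensity", "viable"]].to_csv(path, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set_name TAB description TAB member...

    Duplicate members within a set are dropped with a logged warning; a line
    with fewer than three fields is a hard error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno} has {len(fields)} field(s); "
                    "need set_name, description, >=1 member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            seen: set[str] = set()
            unique: list[str] = []
            for m in members:
                if m in seen:
                    logger.warning(
                        "GMT set %s: duplicate member %s dropped", name, m
                    )
                    continue
                seen.add(m)
                unique.append(m)
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV, single header row, floats at 6 s.f."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_replicate_readouts(path: str | Path) -> pd.DataFrame:
    """Importer contract for externally deposited per-replicate screen
    readouts (one row per target x replicate x parameter).

    Expected tidy TSV columns: target_gene, replicate_id, culture_age,
    parameter ({bright_pct, mfi}), X (readout already normalized to the
    plate's nontargeted controls).  The result feeds directly into
    :func:`flowscreen.screen.zscore_screen`.
    """
    df = read_table(path)
    required = {"target_gene", "replicate_id", "culture_age", "parameter", "X"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"readout table missing columns: {sorted(missing)}")
    if (df["X"] <= 0).any():
        raise ValueError("normalized readouts X must be positive")
    return df


# ---------------------------------------------------------------------------
# library layout construction


def build_library_layout(
    n_targets: int = 1440,
    targets_per_plate: int = 80,
    cultures: Sequence[tuple[str, str]] = (
        ("pup1", "pup"),
        ("pup2", "pup"),
        ("pup3", "pup"),
        ("adult1", "adult"),
        ("adult2", "adult"),
        ("adult3", "adult"),
    ),
    gene_names: Sequence[str] | None = None,
    n_nontargeted_controls: int = 2,
) -> tuple[PlateMap, pd.DataFrame]:
    """Build the arrayed-library screen layout.

    Each culture receives its own copy of the library plates (plate ids
    ``<culture>-P<nn>``).  Every plate carries ``targets_per_plate`` target
    wells plus four control wells: one lipofectamine-only, two nontargeted
    siRNA controls, and one internal-control well (the positive-control
    reagent configured at simulation time).  The default 1440-target library
    spans 18 plates of 80 targets.

    Returns the validated PlateMap and the library annotation
    (target_gene, plate index, well_id) shared by all cultures.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if gene_names is None:
        gene_names = [f"TF{i + 1:04d}" for i in range(n_targets)]
    if len(gene_names) != n_targets:
        raise ValueError("gene_names length must equal n_targets")

    all_wells = [
        f"{row}{col}" for row in string.ascii_uppercase[:8] for col in range(1, 13)
    ]
    if not (1 <= n_nontargeted_controls <= 14):
        raise ValueError("n_nontargeted_controls must be in 1..14")
    control_wells = {"H9": "lipofectamine_only", "H12": "internal_control"}
    # nontargeted controls fill H10, H11, then G-row wells from G12 down
    slots = ["H10", "H11"] + [f"G{c}" for c in range(12, 0, -1)]
    for pos in slots[:n_nontargeted_controls]:
        control_wells[pos] = "nontargeted_control"
    target_positions = [w for w in all_wells if w not in control_wells][
        :targets_per_plate
    ]
    if len(target_positions) < targets_per_plate:
        raise ValueError("targets_per_plate exceeds available wells")

    n_plates = -(-n_targets // targets_per_plate)
    library_rows = []
    for i, gene in enumerate(gene_names):
        plate_idx = i // targets_per_plate + 1
        pos = target_positions[i % targets_per_plate]
        library_rows.append(
            {"target_gene": gene, "plate_index": plate_idx, "well_id": pos}
        )
    library = pd.DataFrame(library_rows)

    rows = []
    for culture_id, age in cultures:
        for plate_idx in range(1, n_plates + 1):
            plate_id = f"{culture_id}-P{plate_idx:02d}"
            plate_lib = library[library["plate_index"] == plate_idx]
            for rec in plate_lib.itertuples():
                rows.append(
                    dict(
                        plate_id=plate_id,
                        well_id=rec.well_id,
                        role="target",
                        target_gene=rec.target_gene,
                        culture_id=culture_id,
                        culture_age=age,
                    )
                )
            for pos, role in control_wells.items():
                rows.append(
                    dict(
                        plate_id=plate_id,
                        well_id=pos,
                        role=role,
                        target_gene="",
                        culture_id=culture_id,
                        culture_age=age,
                    )
                )
    plate_map = PlateMap(pd.DataFrame(rows))
    return plate_map, library
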