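"""End-to-end screen experiments on synthetic data.

These functions wire the generator, gating and scoring stages into the
standard study designs: the positive-control (Rb1) validation, the all-null
calibration of the Z pipeline, planted-effect recovery, and a full
1440-target screen with the default effect landscape.  Analysis drivers,
the test suite and the acceptance script all run these same entry points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gating import GateConfig, summarize_wells
from .io import PlateMap, build_library_layout
from .screen import (
    build_zscore_table,
    call_hits,
    delta_z,
    hits_union_over_groups,
    rank_candidates,
)
from .simulate import (
    DEFAULT_BOUNDARIES,
    EffectSpec,
    SimConfig,
    default_screen_effects,
    null_screen_fixture,
    rb1_effect,
    simulate_screen,
)

DEFAULT_GATES = GateConfig(boundaries=DEFAULT_BOUNDARIES)


def _validation_plate_map(n_cultures: int, wells_per_arm: int) -> PlateMap:
    """One plate per culture: paired knockdown and nontargeted-control
    wells for a head-to-head validation experiment."""
    rows = []
    for i in range(n_cultures):
        culture = f"v{i + 1}"
        age = "pup" if i % 2 == 0 else "adult"
        plate = f"{culture}-P01"
        for j in range(wells_per_arm):
            rows.append(
                dict(plate_id=plate, well_id=f"A{j + 1}", role="target",
                     target_gene="Rb1", culture_id=culture, culture_age=age)
            )
            rows.append(
                dict(plate_id=plate, well_id=f"B{j + 1}",
                     role="nontargeted_control", target_gene="",
                     culture_id=culture, culture_age=age)
            )
    return PlateMap(pd.DataFrame(rows))


def rb1_validation(
    seed: int,
    n_cultures_bright: int = 4,
    n_cultures_mfi: int = 8,
    wells_per_arm: int = 4,
    n_events_per_well: int = 4000,
) -> dict[str, float]:
    """Re-run the positive-control validation: knock down Rb1 in paired
    wells of several cultures and measure the emergent percent reduction
    of gated %Bright (first ``n_cultures_bright`` cultures) and of MFI
    (all ``n_cultures_mfi`` cultures) relative to nontargeted controls of
    the same culture.

    Returns mean percent *reductions* (positive numbers) and the
    per-culture values."""
    n_cultures = max(n_cultures_bright, n_cultures_mfi)
    plate_map = _validation_plate_map(n_cultures, wells_per_arm)
    config = SimConfig(
        effects={"Rb1": rb1_effect()},
        n_events_per_well=n_events_per_well,
        seed=seed,
    )
    events, _ = simulate_screen(config, plate_map)
    summaries = summarize_wells(events, DEFAULT_GATES)
    df = summaries.merge(plate_map.wells, on="well_key")

    per_culture = {}
    for culture, grp in df.groupby("culture_id"):
        rb1 = grp[grp["role"] == "target"]
        ctrl = grp[grp["role"] == "nontargeted_control"]
        per_culture[culture] = dict(
            bright_reduction=100.0
            * (1.0 - rb1["pct_bright"].mean() / ctrl["pct_bright"].mean()),
            mfi_reduction=100.0
            * (1.0 - rb1["mfi"].mean() / ctrl["mfi"].mean()),
        )
    cultures = sorted(per_culture)
    bright = [per_culture[c]["bright_reduction"]
              for c in cultures[:n_cultures_bright]]
    mfi = [per_culture[c]["mfi_reduction"] for c in cultures[:n_cultures_mfi]]
    return dict(
        bright_reduction_pct=float(np.mean(bright)),
        mfi_reduction_pct=float(np.mean(mfi)),
        bright_by_culture=bright,
        mfi_by_culture=mfi,
    )


def run_screen(
    config: SimConfig,
    plate_map: PlateMap,
    gates: GateConfig = DEFAULT_GATES,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate, gate and score a screen.

    Returns (well summaries, truth table, ZScoreTable)."""
    events, truth = simulate_screen(config, plate_map)
    summaries = summarize_wells(events, gates)
    ztable = build_zscore_table(summaries, plate_map)
    return summaries, truth, ztable


def null_calibration(
    seed: int,
    n_targets: int = 1440,
    n_replicates: int = 3,
    n_events_per_well: int = 2000,
) -> dict:
    """All-null screen: fraction of targets whose average %Bright Z
    exceeds +1, to compare with the independent-replicate normal tail
    1 - Phi(sqrt(R))."""
    config, plate_map = null_screen_fixture(
        n_targets=n_targets, n_replicates=n_replicates, seed=seed,
        n_events_per_well=n_events_per_well,
    )
    _, _, ztable = run_screen(config, plate_map)
    bright = ztable[ztable["parameter"] == "bright_pct"]
    frac = float((bright["avg_z_all"] > 1.0).mean())
    return dict(
        fraction_avg_z_gt1=frac,
        n_targets=len(bright),
        avg_z=bright["avg_z_all"].to_numpy(),
        ztable=ztable,
    )


def planted_recovery(
    seed: int,
    n_targets: int = 1440,
    n_planted: int = 20,
    bright_weight_factor: float = 0.4,
    n_replicates: int = 6,
    threshold: float = 1.0,
    n_events_per_well: int = 2000,
) -> dict:
    """Power check: plant Bright-depleting knockdowns in an otherwise null
    library and measure the sensitivity of the below-threshold Bright hit
    list over all replicates."""
    plate_map, library = build_library_layout(n_targets=n_targets)
    rng = np.random.default_rng(seed)
    planted = sorted(
        rng.choice(library["target_gene"], size=n_planted, replace=False)
    )
    effects = {
        g: EffectSpec(target_gene=g,
                      bright_weight_factor=bright_weight_factor)
        for g in planted
    }
    config = SimConfig(effects=effects, seed=seed,
                       n_events_per_well=n_events_per_well)
    _, _, ztable = run_screen(config, plate_map)
    hits = call_hits(ztable, t=threshold, direction="below",
                     parameter_rule="bright_only", scope="all")
    recovered = set(planted) & set(hits.members)
    return dict(
        sensitivity=len(recovered) / n_planted,
        planted=planted,
        recovered=sorted(recovered),
        n_hits=len(hits),
        ztable=ztable,
    )


def full_screen(
    seed: int,
    n_targets: int = 1440,
    n_events_per_well: int = 2000,
) -> dict:
    """The default full screen: 6 cultures (3 pup, 3 adult), the packaged
    sparse effect landscape plus the Rb1 internal control, scored end to
    end through hits, candidates and the pup-versus-adult ΔZ comparison."""
    plate_map, library = build_library_layout(n_targets=n_targets)
    effects = default_screen_effects(library["target_gene"], seed=seed)
    effects["Rb1"] = rb1_effect()
    config = SimConfig(effects=effects, seed=seed,
                       n_events_per_well=n_events_per_well)
    summaries, truth, ztable = run_screen(config, plate_map)

    union_hits = hits_union_over_groups(ztable, t=1.0)
    candidates = rank_candidates(ztable, k=5)
    dz = delta_z(ztable)
    dz_bright = dz[dz["parameter"] == "bright_pct"]["delta_z"]
    dz_mfi = dz[dz["parameter"] == "mfi"]["delta_z"]

    return dict(
        plate_map=plate_map,
        library=library,
        effects=effects,
        summaries=summaries,
        truth=truth,
        ztable=ztable,
        union_hits=union_hits,
        candidates=candidates,
        delta_z=dz,
        stats=dict(
            n_union_hits=len(union_hits),
            n_candidates=len(candidates),
            mean_delta_z=float(dz["delta_z"].mean()),
            pct_delta_z_lt1=float(100.0 * (dz["delta_z"] < 1.0).mean()),
            pct_delta_z_gt1=float(100.0 * (dz["delta_z"] > 1.0).mean()),
            n_delta_z_gt2_bright=int((dz_bright > 2.0).sum()),
            n_delta_z_gt2_mfi=int((dz_mfi > 2.0).sum()),
        ),
    )
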