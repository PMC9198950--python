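import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flowscreen.io import PlateMap
from flowscreen.screen import (
    average_z,
    build_zscore_table,
    call_hits,
    delta_z,
    hits_union_over_groups,
    normalize_screen,
    rank_candidates,
    zscore_replicate,
    zscore_screen,
)


def _summaries(records):
    """Minimal WellSummary frame: (well_key, pct_bright, mfi[, qc])."""
    rows = []
    for rec in records:
        well_key, bright, mfi, *rest = rec
        rows.append(
            dict(
                well_key=well_key, pct_negative=0.0, pct_dim=0.0,
                pct_mid=0.0, pct_bright=bright, pct_egfp_pos=bright,
                mfi=mfi, viable_fraction=1.0, n_events=1000,
                qc_pass=rest[0] if rest else True,
            )
        )
    return pd.DataFrame(rows)


def _map(rows):
    return PlateMap(pd.DataFrame(rows))


def _plate(culture, age, genes, n_controls=2, plate="P01"):
    plate_id = f"{culture}-{plate}"
    rows = [
        dict(plate_id=plate_id, well_id=f"A{i + 1}", role="target",
             target_gene=g, culture_id=culture, culture_age=age)
        for i, g in enumerate(genes)
    ]
    rows += [
        dict(plate_id=plate_id, well_id=f"H{10 + j}",
             role="nontargeted_control", target_gene="",
             culture_id=culture, culture_age=age)
        for j in range(n_controls)
    ]
    return rows


class TestNormalize:
    def test_ratio_to_control_mean(self):
        pm = _map(_plate("c1", "pup", ["G1", "G2", "G3"]))
        summ = _summaries(
            [
                ("c1-P01:A1", 10.0, 100.0),   # equals control mean -> X=1
                ("c1-P01:A2", 6.8, 50.0),     # 6.8/10 = 0.68
                ("c1-P01:A3", 5.0, 200.0),
                ("c1-P01:H10", 8.0, 100.0),
                ("c1-P01:H11", 12.0, 100.0),  # control mean = 10
            ]
        )
        norm = normalize_screen(summ, pm, "bright_pct")
        x = norm.set_index("target_gene")["X"]
        assert x["G1"] == pytest.approx(1.0)
        assert x["G2"] == pytest.approx(0.68)

    def test_qc_failed_wells_emit_no_readout(self):
        pm = _map(_plate("c1", "pup", ["G1", "G2"]))
        summ = _summaries(
            [
                ("c1-P01:A1", 10.0, 100.0),
                ("c1-P01:A2", 10.0, 100.0, False),
                ("c1-P01:H10", 10.0, 100.0),
                ("c1-P01:H11", 10.0, 100.0),
            ]
        )
        norm = normalize_screen(summ, pm, "bright_pct")
        assert set(norm["target_gene"]) == {"G1"}

    def test_plate_without_passing_controls_is_error(self):
        pm = _map(_plate("c1", "pup", ["G1"]))
        summ = _summaries(
            [
                ("c1-P01:A1", 10.0, 100.0),
                ("c1-P01:H10", 10.0, 100.0, False),
                ("c1-P01:H11", 10.0, 100.0, False),
            ]
        )
        with pytest.raises(ValueError, match="no QC-passing"):
            normalize_screen(summ, pm, "bright_pct")


class TestZScore:
    def test_three_point_example(self):
        df = pd.DataFrame(
            dict(target_gene=list("abc"), X=[1.0, 2.0, 3.0],
                 replicate_id="r1", parameter="bright_pct", plate_id="p")
        )
        z = zscore_replicate(df)
        # mean 2, sample SD 1 -> Z = -1, 0, +1
        assert list(z["z"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one_by_construction(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            dict(target_gene=[f"g{i}" for i in range(100)],
                 X=rng.lognormal(0, 0.2, 100),
                 replicate_id="r1", parameter="mfi", plate_id="p")
        )
        z = zscore_replicate(df)
        assert abs(z["z"].mean()) < 1e-9
        assert z["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(1)
        x = rng.normal(1, 0.1, 50)
        base = pd.DataFrame(
            dict(target_gene=[f"g{i}" for i in range(50)], X=x,
                 replicate_id="r", parameter="mfi", plate_id="p")
        )
        trans = base.assign(X=a * x + b)
        np.testing.assert_allclose(
            zscore_replicate(base)["z"], zscore_replicate(trans)["z"],
            atol=1e-9,
        )

    def test_degenerate_replicate_rejected(self):
        df = pd.DataFrame(
            dict(target_gene=list("abc"), X=[1.0, 1.0, 1.0],
                 replicate_id="r", parameter="mfi", plate_id="p")
        )
        with pytest.raises(ValueError, match="sigma = 0"):
            zscore_replicate(df)

    def test_too_few_targets_rejected(self):
        df = pd.DataFrame(
            dict(target_gene=list("ab"), X=[1.0, 2.0],
                 replicate_id="r", parameter="mfi", plate_id="p")
        )
        with pytest.raises(ValueError, match=">= 3"):
            zscore_replicate(df)


def _ztable(records):
    """rows: (gene, parameter, avg_all, avg_pup, avg_adult)"""
    return pd.DataFrame(
        [
            dict(target_gene=g, parameter=p, avg_z_all=za, n_reps_all=6,
                 avg_z_pup=zp, n_reps_pup=3, avg_z_adult=zad, n_reps_adult=3)
            for g, p, za, zp, zad in records
        ]
    )


class TestAverageAndDeltaZ:
    def test_average_is_arithmetic_mean(self):
        z = pd.DataFrame(
            dict(
                target_gene=["g"] * 3, parameter="bright_pct",
                replicate_id=["r1", "r2", "r3"],
                culture_age=["pup", "pup", "adult"],
                z=[-1.0, 0.0, 1.0],
            )
        )
        assert average_z(z, "all")["avg_z"].iloc[0] == pytest.approx(0.0)
        assert average_z(z, "pup")["avg_z"].iloc[0] == pytest.approx(-0.5)

    def test_delta_z_absolute_difference(self):
        zt = _ztable([("g1", "bright_pct", 0.35, 1.5, -0.8),
                      ("g2", "bright_pct", 0.0, 0.3, 0.3)])
        dz = delta_z(zt).set_index("target_gene")["delta_z"]
        assert dz["g1"] == pytest.approx(2.3)
        assert dz["g2"] == pytest.approx(0.0)

    def test_signed_mode(self):
        zt = _ztable([("g1", "mfi", 0.0, -1.0, 1.0)])
        dz = delta_z(zt, mode="signed")
        assert dz["delta_z"].iloc[0] == pytest.approx(-2.0)

    def test_one_sided_targets_omitted(self):
        zt = _ztable([("g1", "mfi", 0.5, 1.0, np.nan)])
        assert len(delta_z(zt)) == 0

    def test_null_mean_delta_z_matches_folded_normal(self, null_run_6rep):
        """With 3 independent pup and 3 independent adult replicates,
        avgZp - avgZa ~ N(0, 2/3), so E|ΔZ| = sqrt(2*(2/3)/pi) ~ 0.651."""
        zt = null_run_6rep["ztable"]
        dz = delta_z(zt)
        expected = np.sqrt(2 * (2 / 3) / np.pi)
        assert dz["delta_z"].mean() == pytest.approx(expected, rel=0.05)


class TestCallHits:
    def test_empty_when_all_below_threshold(self):
        zt = _ztable([("g1", "bright_pct", 0.5, 0.5, 0.5),
                      ("g1", "mfi", -0.9, -0.9, -0.9)])
        assert call_hits(zt, t=1.0).members == []

    def test_strict_inequality_at_boundary(self):
        zt = _ztable([("g1", "bright_pct", 1.0, 1.0, 1.0),
                      ("g1", "mfi", 0.0, 0.0, 0.0),
                      ("g2", "bright_pct", 1.0001, 0.0, 0.0),
                      ("g2", "mfi", 0.0, 0.0, 0.0)])
        hits = call_hits(zt, t=1.0, parameter_rule="bright_only")
        assert hits.members == ["g2"]

    def test_direction_below(self):
        zt = _ztable([("g1", "bright_pct", -1.5, 0, 0),
                      ("g2", "bright_pct", 1.5, 0, 0)])
        hits = call_hits(zt, t=1.0, direction="below",
                         parameter_rule="bright_only")
        assert hits.members == ["g1"]

    def test_union_superset_of_intersection(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(50):
            recs.append((f"g{i}", "bright_pct", rng.normal(0, 1.2), 0, 0))
            recs.append((f"g{i}", "mfi", rng.normal(0, 1.2), 0, 0))
        zt = _ztable(recs)
        u = call_hits(zt, t=1.0, parameter_rule="union").members
        i_ = call_hits(zt, t=1.0, parameter_rule="intersection").members
        assert set(u) >= set(i_)
        assert set(hits_union_over_groups(zt, t=1.0).members) >= set()

    def test_nonpositive_threshold_rejected(self):
        zt = _ztable([("g1", "mfi", 0.0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="threshold"):
            call_hits(zt, t=0.0)


class TestRankCandidates:
    def _table_10(self):
        # bright avg Z: g0..g9 = 0..9 ; mfi avg Z: reversed
        recs = []
        for i in range(10):
            recs.append((f"g{i}", "bright_pct", float(i), 0, 0))
            recs.append((f"g{i}", "mfi", float(9 - i), 0, 0))
        return _ztable(recs)

    def test_known_ordering_membership(self):
        cs = rank_candidates(self._table_10(), k=2)
        # bright: top {g8,g9} bottom {g0,g1}; mfi: top {g0,g1} bottom {g8,g9}
        assert cs.members == ["g0", "g1", "g8", "g9"]
        assert set(cs.provenance["g9"]) == {"top_bright_pct",
                                            "bottom_mfi"}

    def test_disjoint_lists_give_4k(self):
        recs = []
        # bright extremes on g0..g19, mfi extremes on h0..h19
        for i in range(20):
            recs.append((f"g{i}", "bright_pct", float(i - 10), 0, 0))
            recs.append((f"g{i}", "mfi", 0.0, 0, 0))
            recs.append((f"h{i}", "bright_pct", 0.0, 0, 0))
            recs.append((f"h{i}", "mfi", float(i - 10), 0, 0))
        cs = rank_candidates(_ztable(recs), k=3)
        assert len(cs) == 12

    def test_tie_break_lexicographic(self):
        recs = [(g, "bright_pct", 1.0, 0, 0) for g in ["b", "a", "c"]]
        recs += [(g, "mfi", 0.0, 0, 0) for g in ["b", "a", "c"]]
        cs = rank_candidates(_ztable(recs), k=1)
        assert "a" in cs.provenance and "top_bright_pct" in cs.provenance["a"]

    def test_invalid_k(self):
        with pytest.raises(ValueError, match="k"):
            rank_candidates(self._table_10(), k=0)


class TestPipelineEquivariance:
    def test_plate_relabeling_changes_nothing(self, tiny_plate_map):
        from flowscreen.experiments import DEFAULT_GATES
        from flowscreen.gating import summarize_wells
        from flowscreen.simulate import SimConfig, simulate_screen

        cfg = SimConfig(seed=11, n_events_per_well=800)
        events, _ = simulate_screen(cfg, tiny_plate_map)
        summ = summarize_wells(events, DEFAULT_GATES)
        zt = build_zscore_table(summ, tiny_plate_map)

        relabeled = tiny_plate_map.wells.copy()
        mapping = {"c1-P01": "c1-Q77", "c2-P01": "c2-Q78"}
        relabeled["plate_id"] = relabeled["plate_id"].map(mapping)
        relabeled = relabeled.drop(columns=["well_key"])
        pm2 = PlateMap(relabeled)
        ev2 = events.copy()
        ev2["well_key"] = ev2["well_key"].str.replace("P01", "Q77").where(
            ev2["well_key"].str.startswith("c1"),
            ev2["well_key"].str.replace("P01", "Q78"),
        )
        summ2 = summarize_wells(ev2, DEFAULT_GATES)
        zt2 = build_zscore_table(summ2, pm2)
        merged = zt.merge(zt2, on=["target_gene", "parameter"])
        np.testing.assert_allclose(
            merged["avg_z_all_x"], merged["avg_z_all_y"], atol=1e-12
        )
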