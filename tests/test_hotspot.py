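"""OSAG construction, aging score, PCOA screening, hotspot calling and distance decay."""

import math

import numpy as np
import pandas as pd
import pytest

import ovaspot as ov


def _deg_rows(entries):
    return pd.DataFrame(
        [(t, g, 1.0 if d == "up" else -1.0, 1e-4, 1e-3, d) for (t, g, d) in entries],
        columns=["spot_type", "gene", "log2fc", "pvalue", "fdr", "direction"],
    )


class TestBuildOsag:
    def test_empty_table_gives_empty_osag(self):
        osag = ov.build_osag(_deg_rows([]), ["gA"])
        assert osag.up == [] and osag.down == []

    def test_empty_aging_list_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ov.build_osag(_deg_rows([("SC", "gA", "up")]), [])

    def test_set_algebra_oracle(self):
        table = _deg_rows(
            [("SC", "gA", "up"), ("GC", "gA", "up"), ("SC", "gB", "down"),
             ("SC", "gC", "up"), ("SC", "gD", "down")]
        )
        osag = ov.build_osag(table, ["gA", "gB", "gZ"])
        assert osag.up == ["gA"]
        assert osag.down == ["gB"]
        assert osag.provenance["gA"] == ["GC", "SC"]

    def test_majority_rule_and_tie_drop(self):
        table = _deg_rows(
            [("SC", "gA", "up"), ("GC", "gA", "up"), ("TC", "gA", "down"),
             ("SC", "gB", "up"), ("GC", "gB", "down")]
        )
        osag = ov.build_osag(table, ["gA", "gB"])
        assert osag.up == ["gA"]       # up in 2, down in 1 -> up
        assert "gB" not in osag.up and "gB" not in osag.down  # tie dropped


class TestAgingScore:
    def test_identical_columns_give_zero(self):
        frame = pd.DataFrame({"OSAG_up": [0.2, -0.1], "OSAG_down": [0.2, -0.1]})
        np.testing.assert_allclose(ov.aging_score(frame).to_numpy(), 0.0)

    def test_zero_down_column_returns_up(self):
        frame = pd.DataFrame({"OSAG_up": [0.4, 0.1], "OSAG_down": [0.0, 0.0]})
        np.testing.assert_allclose(ov.aging_score(frame).to_numpy(), [0.4, 0.1])

    def test_arithmetic_fixture(self):
        frame = pd.DataFrame({"OSAG_up": [0.3], "OSAG_down": [-0.1]})
        assert ov.aging_score(frame).iloc[0] == pytest.approx(0.4)

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            ov.aging_score(pd.DataFrame({"OSAG_up": [0.1]}))

    def test_linearity_under_scaling(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"OSAG_up": rng.random(10), "OSAG_down": rng.random(10)})
        scaled = frame * 3.0
        np.testing.assert_allclose(
            ov.aging_score(scaled).to_numpy(), 3.0 * ov.aging_score(frame).to_numpy()
        )


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = ov.pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_orthogonal_by_construction(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        r, _ = ov.pearson_r(x, x**2)  # symmetric in x
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_five_point_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, _ = ov.pearson_r(x, y)
        expected = np.sum((x - 3) * (y - 3)) / np.sqrt(np.sum((x - 3) ** 2) * np.sum((y - 3) ** 2))
        assert r == pytest.approx(expected)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            ov.pearson_r([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            ov.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSelectPcoa:
    def test_self_correlation_selected(self):
        rng = np.random.default_rng(1)
        ref = pd.Series(rng.random(100), index=[f"s{i}" for i in range(100)])
        frame = pd.DataFrame({"cand": ref})
        out = ov.select_pcoa(frame, ref, ["cand"])
        assert bool(out.loc["cand", "selected"])
        assert out.loc["cand", "r"] == pytest.approx(1.0)

    def test_independent_noise_not_selected(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(2000)]
        ref = pd.Series(rng.normal(size=2000), index=ids)
        frame = pd.DataFrame({"noise": rng.normal(size=2000)}, index=ids)
        out = ov.select_pcoa(frame, ref, ["noise"])
        assert abs(out.loc["noise", "r"]) < 0.1
        assert not bool(out.loc["noise", "selected"])

    def test_planted_focus_programs_selected_on_synthetic_ovary(self, default_pipeline):
        pcoa = default_pipeline.pcoa
        selected = set(pcoa.index[pcoa["selected"]])
        assert selected == {"SASP", "fibrosis", "senescence", "inflammatory_response"}


class TestCallHotspots:
    def test_identical_score_vectors_give_single_top_set(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(200)]
        col = pd.Series(rng.random(200), index=ids)
        frame = pd.DataFrame({"aging_score": col, "SASP": col, "fib": col})
        out = ov.call_hotspots(frame, q=0.05)
        assert len(out.hotspot_spot_ids) == math.ceil(0.05 * 200)
        assert set(out.hotspot_spot_ids) == set(out.top_sets["aging_score"])

    def test_top_set_cardinality_is_ceiling(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(137)]
        score = pd.Series(rng.random(137), index=ids)
        assert len(ov.top_quantile_spots(score, 0.05)) == math.ceil(0.05 * 137)

    def test_tie_break_by_barcode(self):
        score = pd.Series([1.0, 1.0, 0.0], index=["b", "a", "c"])
        assert ov.top_quantile_spots(score, 1 / 3) == ["a"]

    def test_independent_scores_intersection_near_binomial_expectation(self):
        rng = np.random.default_rng(5)
        n, k, q = 10000, 3, 0.05
        ids = [f"s{i}" for i in range(n)]
        frame = pd.DataFrame({f"c{j}": rng.random(n) for j in range(k)}, index=ids)
        out = ov.call_hotspots(frame, q=q)
        expected = n * q**k
        sigma = np.sqrt(n * q**k * (1 - q**k))
        assert abs(len(out.hotspot_spot_ids) - expected) <= 3 * sigma + 1

    def test_adding_a_column_never_enlarges_intersection(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(500)]
        frame = pd.DataFrame({"a": rng.random(500), "b": rng.random(500)}, index=ids)
        small = ov.call_hotspots(frame, q=0.1)
        frame["c"] = rng.random(500)
        smaller = ov.call_hotspots(frame, q=0.1)
        assert set(smaller.hotspot_spot_ids) <= set(small.hotspot_spot_ids)

    def test_aging_and_any_mode(self):
        ids = ["a", "b", "c", "d"]
        frame = pd.DataFrame(
            {"aging_score": [4, 3, 2, 1], "p1": [4, 1, 2, 3], "p2": [1, 4, 2, 3]}, index=ids
        )
        out = ov.call_hotspots(frame, q=0.5, mode="aging_and_any")
        # aging top = {a,b}; pathway tops = {a,d} and {b,d}; union = {a,b,d}
        assert out.hotspot_spot_ids == ["a", "b"]

    def test_invalid_q_raises(self):
        frame = pd.DataFrame({"aging_score": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="q"):
            ov.call_hotspots(frame, q=0.0)


class TestComposition:
    def test_single_type_is_one(self):
        ann = pd.DataFrame({"spot_type": ["MT2high"] * 5}, index=[f"s{i}" for i in range(5)])
        comp = ov.hotspot_composition([f"s{i}" for i in range(5)], ann)
        assert comp["MT2high"] == 1.0

    def test_hand_tally(self):
        types = ["MT2high"] * 12 + ["SC"] * 5 + ["OSE"] * 3
        ann = pd.DataFrame({"spot_type": types}, index=[f"s{i}" for i in range(20)])
        comp = ov.hotspot_composition([f"s{i}" for i in range(20)], ann)
        assert comp["MT2high"] == pytest.approx(0.6)
        assert comp["SC"] == pytest.approx(0.25)
        assert comp.sum() == pytest.approx(1.0)

    def test_zero_hotspots_raises(self):
        ann = pd.DataFrame({"spot_type": ["SC"]}, index=["s0"])
        with pytest.raises(ValueError):
            ov.hotspot_composition([], ann)


class TestDistanceDecay:
    @staticmethod
    def _grid(n=40, pitch=100.0):
        xs, ys = np.meshgrid(np.arange(n) * pitch, np.arange(n) * pitch)
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        ids = np.array([f"s{i}" for i in range(len(coords))], dtype=object)
        return ids, coords

    def test_constant_score_reports_undefined(self):
        ids, coords = self._grid(10)
        score = pd.Series(1.0, index=ids)
        out = ov.distance_decay(ids[:3], ids, coords, score)
        assert np.isnan(out.r)

    def test_planted_exponential_field_strongly_negative(self):
        lam = 300.0
        ids, coords = self._grid(40)
        center = coords[len(coords) // 2]
        d = np.linalg.norm(coords - center, axis=1)
        hot = ids[d <= 100.0]
        rng = np.random.default_rng(7)
        score = pd.Series(np.exp(-d / lam) + rng.normal(0, 0.005, len(d)), index=ids)
        out = ov.distance_decay(hot, ids, coords, score, max_distance_um=2.5 * lam)
        assert out.r <= -0.9
        assert out.p < 0.01

    def test_adjacent_spot_distance_equals_pitch(self):
        ids, coords = self._grid(10)
        out = ov.distance_decay(
            [str(ids[0])], ids, coords,
            pd.Series(np.random.default_rng(8).random(len(ids)), index=ids),
            min_spots_per_ring=1,
        )
        # brute-force nearest distances from every non-hotspot spot
        d_all = np.linalg.norm(coords[1:] - coords[0], axis=1)
        assert d_all.min() == pytest.approx(100.0)
        assert out.table["ring_lo_um"].iloc[0] == 100.0

    def test_sparse_rings_dropped(self):
        ids, coords = self._grid(6)
        score = pd.Series(np.arange(len(ids), dtype=float), index=ids)
        out = ov.distance_decay(ids[:1], ids, coords, score, min_spots_per_ring=5)
        assert (out.table["n_spots"] >= 5).all()

    def test_no_non_hotspot_spots_raises(self):
        ids, coords = self._grid(3)
        score = pd.Series(1.0, index=ids)
        with pytest.raises(ValueError):
            ov.distance_decay(ids, ids, coords, score)
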