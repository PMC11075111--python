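"""Rank-sum tests, fold changes, BH correction, shared DEGs and ORA against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import ovaspot as ov

from tests.conftest import make_norm


def _enumerated_two_sided_p(x, y):
    """Brute-force permutation p over all group assignments."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    mu = n1 * len(y) / 2
    base = n1 * (n1 + 1) / 2
    u_obs = ranks[:n1].sum() - base
    combos = list(itertools.combinations(range(len(pooled)), n1))
    hits = sum(abs(ranks[list(c)].sum() - base - mu) >= abs(u_obs - mu) - 1e-9 for c in combos)
    return hits / len(combos)


class TestWilcoxon:
    def test_identical_multisets_give_p_one(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        _, p = ov.wilcoxon_rank_sum(x, list(x))
        assert p == 1.0

    def test_complete_separation_matches_enumeration(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 0.1, 5)
        y = rng.normal(0, 0.1, 5)
        _, p = ov.wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(_enumerated_two_sided_p(x, y))

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_equals_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=4).astype(float)
        y = rng.integers(0, 4, size=4).astype(float)
        _, p = ov.wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(_enumerated_two_sided_p(x, y))

    def test_asymptotic_close_to_exact_for_moderate_n(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 7)
        y = rng.normal(0.4, 1, 7)  # pooled n = 14 -> asymptotic path
        _, p_asym = ov.wilcoxon_rank_sum(x, y)
        p_exact = _enumerated_two_sided_p(x, y)
        assert abs(p_asym - p_exact) < 0.02

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            ov.wilcoxon_rank_sum([], [1.0])


class TestLogFoldChange:
    def test_equal_means_give_zero(self):
        norm = make_norm(np.log2(1 + np.array([[4.0, 4.0, 4.0, 4.0]])))
        lfc = ov.log_fold_change(norm, ["g0"], np.array([True, True, False, False]),
                                 np.array([False, False, True, True]))
        assert lfc["g0"] == pytest.approx(0.0)

    def test_formula_oracle(self):
        # de-logged means 4 and 1, pseudocount 1 -> log2(5/2)
        norm = make_norm(np.log2(1 + np.array([[4.0, 4.0, 1.0, 1.0]])))
        lfc = ov.log_fold_change(norm, ["g0"], np.array([True, True, False, False]),
                                 np.array([False, False, True, True]))
        assert lfc["g0"] == pytest.approx(np.log2(5 / 2))

    def test_swapping_groups_negates(self):
        rng = np.random.default_rng(1)
        norm = make_norm(rng.random((5, 8)) * 3)
        a = np.zeros(8, bool); a[:4] = True
        fwd = ov.log_fold_change(norm, list(norm.gene_ids), a, ~a)
        rev = ov.log_fold_change(norm, list(norm.gene_ids), ~a, a)
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy())


class TestBenjaminiHochberg:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_min_over_tails_formula(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(50)
        q = ov.bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        direct = np.empty(m)
        running = np.inf
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            direct[i] = min(running, 1.0)
        np.testing.assert_allclose(q, direct)


class TestAgingDegs:
    @staticmethod
    def _toy(planted_lfc=2.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(20, size=(30, 2 * n)).astype(float)
        counts[:5, n:] *= 2 ** planted_lfc  # genes 0-4 up in old
        values = np.log2(1 + 6000 * counts / counts.sum(axis=0))
        ids = [f"s{i}" for i in range(2 * n)]
        norm = make_norm(values, spot_ids=ids)
        ann = pd.DataFrame({"cluster": 0, "spot_type": "SC", "region": "non_follicle"}, index=ids)
        meta = pd.DataFrame({"age_group": ["young"] * n + ["old"] * n}, index=ids)
        return norm, ann, meta

    def test_planted_genes_found_as_up(self):
        norm, ann, meta = self._toy()
        degs = ov.aging_degs(norm, ann, meta)
        up = set(degs[degs["direction"] == "up"]["gene"])
        assert {"g0", "g1", "g2", "g3", "g4"} <= up

    def test_cut_is_strict_on_log2fc(self):
        norm, ann, meta = self._toy()
        full = ov.aging_degs(norm, ann, meta, return_full=True)
        lfc_g0 = float(full.loc[full["gene"] == "g0", "log2fc"].iloc[0])
        # passing the observed value itself as the cut excludes the gene
        at_cut = ov.aging_degs(norm, ann, meta, lfc_cut=lfc_g0)
        assert "g0" not in set(at_cut["gene"])

    def test_tightening_cuts_never_adds_degs(self):
        norm, ann, meta = self._toy(seed=2)
        loose = ov.aging_degs(norm, ann, meta, lfc_cut=0.5, fdr_cut=0.05)
        tight = ov.aging_degs(norm, ann, meta, lfc_cut=1.0, fdr_cut=0.01)
        loose_keys = set(zip(loose["spot_type"], loose["gene"]))
        tight_keys = set(zip(tight["spot_type"], tight["gene"]))
        assert tight_keys <= loose_keys

    def test_small_group_skipped_with_empty_result(self):
        norm, ann, meta = self._toy(n=2)
        degs = ov.aging_degs(norm, ann, meta)
        assert degs.empty

    def test_planted_recovery_on_synthetic_ovary(self, default_sim, default_pipeline):
        """Planted aging-up genes (beta=1) recovered as up in their targeted types."""
        cfg, _, truth = default_sim
        degs = default_pipeline.aging_deg_table
        recovered = 0
        for g in truth.aging_up_genes:
            hits = degs[(degs["gene"] == g) & (degs["direction"] == "up")]
            if any(t in truth.aging_targets[g] for t in hits["spot_type"]):
                recovered += 1
        assert recovered / len(truth.aging_up_genes) >= 0.9


class TestMarkers:
    def test_planted_markers_recovered_and_flat_gene_absent(self, default_sim, default_pipeline):
        _, _, truth = default_sim
        res = default_pipeline
        markers = ov.find_markers_one_vs_all(res.norm, res.annotation)
        sc_markers = set(markers[markers["spot_type"] == "SC"]["gene"])
        planted = set(truth.marker_sets["SC"]) & set(res.norm.gene_ids)
        assert len(planted & sc_markers) / len(planted) >= 0.9
        # background genes are nobody's markers
        flat = {g for g in res.norm.gene_ids if str(g).startswith("BG_")}
        assert len(set(markers["gene"]) & flat) / max(len(flat), 1) < 0.02


class TestSharedDegs:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["spot_type", "gene", "log2fc", "pvalue", "fdr", "direction"])

    def test_three_of_nine_types_included(self):
        rows = [(t, "gX", 1.0, 0.001, 0.01, "up") for t in ("SC", "GC", "TC")]
        up, down = ov.shared_degs(self._table(rows), min_types=3)
        assert up == ["gX"] and down == []

    def test_two_types_excluded(self):
        rows = [(t, "gX", 1.0, 0.001, 0.01, "up") for t in ("SC", "GC")]
        up, down = ov.shared_degs(self._table(rows), min_types=3)
        assert up == [] and down == []

    def test_conflicting_directions_cancel(self):
        rows = [(t, "gX", 1.0, 0.001, 0.01, "up") for t in ("SC", "GC", "TC")]
        rows += [(t, "gX", -1.0, 0.001, 0.01, "down") for t in ("IM", "OSE", "SMC")]
        up, down = ov.shared_degs(self._table(rows), min_types=3)
        assert up == [] and down == []

    def test_matches_brute_force_set_computation(self):
        rng = np.random.default_rng(4)
        types = ["T%d" % i for i in range(6)]
        rows = []
        for g in ("g%d" % i for i in range(20)):
            for t in types:
                if rng.random() < 0.4:
                    d = "up" if rng.random() < 0.5 else "down"
                    rows.append((t, g, 1.0 if d == "up" else -1.0, 0.001, 0.01, d))
        table = self._table(rows)
        up, down = ov.shared_degs(table, min_types=3)
        # brute force
        exp_up, exp_down = [], []
        for g in sorted(table["gene"].unique()):
            nu = table[(table.gene == g) & (table.direction == "up")]["spot_type"].nunique()
            nd = table[(table.gene == g) & (table.direction == "down")]["spot_type"].nunique()
            if nu >= 3 and nu > nd:
                exp_up.append(g)
            if nd >= 3 and nd > nu:
                exp_down.append(g)
        assert up == exp_up and down == exp_down


class TestOra:
    def test_list_equals_set_equals_universe_gives_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        coll = ov.GeneSetCollection({"all": genes})
        out = ov.ora(genes, genes, coll)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_list_and_set_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        coll = ov.GeneSetCollection({"s": universe[:5]})
        out = ov.ora(universe[10:], universe, coll)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_matches_direct_hypergeometric_tail_sum(self):
        from math import comb

        universe = [f"g{i}" for i in range(100)]
        gene_set = universe[:10]
        gene_list = universe[5:15]  # overlap 5
        coll = ov.GeneSetCollection({"s": gene_set})
        out = ov.ora(gene_list, universe, coll)
        tail = sum(
            comb(10, k) * comb(90, 10 - k) / comb(100, 10) for k in range(5, 11)
        )
        assert out["pvalue"].iloc[0] == pytest.approx(tail)
        assert out["overlap"].iloc[0] == 5

    def test_genes_outside_universe_dropped(self):
        universe = [f"g{i}" for i in range(20)]
        coll = ov.GeneSetCollection({"s": universe[:5]})
        out = ov.ora(universe[:3] + ["alien"], universe, coll)
        assert out["list_size"].iloc[0] == 3
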