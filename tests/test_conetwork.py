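"""Genus aggregation, filters and the Spearman screening / edge rule."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import gutnetdys as g
from gutnetdys.conetwork import (
    aggregate_genus,
    build_network,
    occurrence_filter,
    run_all_conditions,
    spearman_screen,
)
from gutnetdys.types import ActivityTable, Lineage, RANKS, validate_metadata


def lin(*names):
    return Lineage(tuple(names) + ("",) * (len(RANKS) - len(names)))


L_FULL = lin("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
             "Lactobacillaceae", "Lactobacillus", "Lactobacillus apis")
FAMILY_ONLY = lin("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                  "Lactobacillaceae")


def table(arr, taxa):
    arr = np.asarray(arr, float)
    return ActivityTable(pd.DataFrame(
        arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=taxa
    ))


class TestAggregateGenus:
    def test_congeners_sum(self):
        t = table([[10, 5], [1, 2]], ["asv1", "asv2"])
        out = aggregate_genus(t, {"asv1": L_FULL, "asv2": L_FULL})
        assert out.taxon_ids == ["Lactobacillus"]
        assert list(out.counts["Lactobacillus"]) == [15.0, 3.0]

    def test_one_genus_per_asv_is_relabeling(self):
        other = lin("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                    "Orbales", "Orbaceae", "Gilliamella")
        t = table([[10, 5], [1, 2]], ["asv1", "asv2"])
        out = aggregate_genus(t, {"asv1": L_FULL, "asv2": other})
        assert set(out.taxon_ids) == {"Lactobacillus", "Gilliamella"}
        assert out.counts.to_numpy().sum() == t.counts.to_numpy().sum()

    def test_family_level_asv_gets_bucket_not_genus(self):
        t = table([[10, 5], [1, 2]], ["asv1", "asv2"])
        out = aggregate_genus(t, {"asv1": L_FULL, "asv2": FAMILY_ONLY})
        assert "unassigned_family_Lactobacillaceae" in out.taxon_ids
        assert list(out.counts["Lactobacillus"]) == [10.0, 1.0]

    def test_column_order_is_activity_ranked(self):
        t = table([[1, 100], [1, 100]], ["asv1", "asv2"])
        other = lin("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                    "Orbales", "Orbaceae", "Gilliamella")
        out = aggregate_genus(t, {"asv1": L_FULL, "asv2": other})
        assert out.taxon_ids == ["Gilliamella", "Lactobacillus"]


class TestOccurrenceFilter:
    @pytest.mark.parametrize("present,kept", [(8, True), (7, False), (10, True)])
    def test_threshold_is_strictly_more_than_7_of_10(self, present, kept):
        col = np.zeros(10)
        col[:present] = 5
        t = table(np.column_stack([np.full(10, 3.0), col]), ["always", "patchy"])
        retained = occurrence_filter(t)
        assert ("patchy" in retained) is kept

    def test_tiny_subset_is_error(self):
        t = table(np.ones((3, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="3 samples"):
            occurrence_filter(t)


class TestSpearmanScreen:
    def test_monotone_pair_degenerate(self):
        x = np.arange(1, 11, dtype=float)
        t = table(np.column_stack([x, 2 * x, 30 - 2 * x]), ["a", "b", "c"])
        screen = spearman_screen(t, use_relative=False)
        pairs = screen.pairs.set_index(["a", "b"])
        assert pairs.loc[("a", "b"), "rho"] == 1.0
        assert pairs.loc[("a", "b"), "p_raw"] == 0.0
        assert pairs.loc[("a", "c"), "rho"] == -1.0

    def test_constant_genus_excluded_from_family(self, caplog):
        import logging
        x = np.arange(1, 11, dtype=float)
        t = table(np.column_stack([x, x**2, np.full(10, 4.0)]),
                  ["a", "b", "flat"])
        with caplog.at_level(logging.WARNING, logger="gutnetdys.conetwork"):
            screen = spearman_screen(t, use_relative=False)
        assert screen.n_family == 1
        flat_pairs = screen.pairs[(screen.pairs["a"] == "flat")
                                  | (screen.pairs["b"] == "flat")]
        assert flat_pairs["rho"].isna().all()

    def test_bonferroni_bookkeeping(self, rng):
        t = table(rng.integers(1, 100, size=(10, 5)), list("abcde"))
        screen = spearman_screen(t)
        assert len(screen.pairs) == 10
        assert screen.n_family == 10
        expected = np.minimum(1.0, screen.pairs["p_raw"] * screen.n_family)
        assert np.allclose(screen.pairs["p_bonf"], expected)
        assert (screen.pairs["p_bonf"] >= screen.pairs["p_bh"] - 1e-12).all()
        assert (screen.pairs["p_bh"] >= screen.pairs["p_raw"] - 1e-12).all()

    def test_matches_permutation_oracle(self, rng):
        """rho/p of the t-approximation screen vs a 10⁵-draw Monte-Carlo
        permutation null on a seeded 10×3 table."""
        t = table(rng.integers(1, 1000, size=(10, 3)), list("abc"))
        screen = spearman_screen(t, use_relative=False)
        rel = t.counts.to_numpy()
        # rank transform once; permuting ranks of one column spans the null
        from scipy.stats import rankdata
        ranks = np.apply_along_axis(rankdata, 0, rel)
        n_perm = 100_000
        prng = np.random.default_rng(123)
        for row in screen.pairs.itertuples(index=False):
            i, j = "abc".index(row.a), "abc".index(row.b)
            ri = ranks[:, i] - ranks[:, i].mean()
            rj = ranks[:, j] - ranks[:, j].mean()
            denom = np.linalg.norm(ri) * np.linalg.norm(rj)
            obs = float(ri @ rj / denom)
            assert obs == pytest.approx(row.rho, abs=1e-12)
            idx = prng.random((n_perm, len(rj))).argsort(axis=1)
            perm_stats = rj[idx] @ ri / denom
            p_mc = (np.abs(perm_stats) >= abs(obs) - 1e-12).mean()
            se = np.sqrt(p_mc * (1 - p_mc) / n_perm) + 1e-6
            assert abs(row.p_raw - p_mc) <= max(3 * se, 0.02)

    def test_depth_rescaling_leaves_screen_unchanged(self, rng):
        counts = rng.integers(1, 500, size=(10, 4)).astype(float)
        t1 = table(counts, list("abcd"))
        scaled = counts * rng.uniform(0.5, 20.0, size=(10, 1))
        t2 = table(scaled, list("abcd"))
        s1 = spearman_screen(t1)
        s2 = spearman_screen(t2)
        assert np.allclose(s1.pairs["rho"], s2.pairs["rho"])
        assert np.allclose(s1.pairs["p_bonf"], s2.pairs["p_bonf"])


class TestEdgeRule:
    def make_screen(self, rho, p_raw, p_bh, p_bonf):
        x = np.arange(1, 11, dtype=float)
        t = table(np.column_stack([x, x + 1]), ["A", "B"])
        screen = spearman_screen(t, use_relative=False)
        screen.pairs.loc[:, ["rho", "p_raw", "p_bh", "p_bonf"]] = \
            [rho, p_raw, p_bh, p_bonf]
        return screen, t

    def test_strong_significant_pair_is_positive_edge(self):
        screen, t = self.make_screen(0.95, 1e-5, 1e-4, 0.001)
        net = build_network(screen, t)
        assert net.graph.has_edge("A", "B")
        assert net.graph["A"]["B"]["sign"] == "+"

    def test_rho_threshold_binds_despite_tiny_p(self):
        screen, t = self.make_screen(0.39, 1e-6, 1e-6, 1e-6)
        assert build_network(screen, t).graph.number_of_edges() == 0

    def test_bonferroni_clause_binds(self):
        screen, t = self.make_screen(0.8, 0.004, 0.01, 0.2)
        assert build_network(screen, t).graph.number_of_edges() == 0
        relaxed = build_network(screen, t, bonferroni=False)
        assert relaxed.graph.number_of_edges() == 1

    def test_isolated_retained_genus_stays_as_node(self):
        screen, t = self.make_screen(0.1, 0.9, 0.9, 1.0)
        net = build_network(screen, t)
        assert net.n_nodes == 2
        assert net.graph.number_of_edges() == 0


class TestRunAllConditions:
    def test_full_design_yields_twelve_networks(self, default_run):
        nets, summary = run_all_conditions(
            default_run["genus_table"], default_run["meta"]
        )
        assert len(nets) == 12
        assert len(summary) == 12
        assert set(summary["section"]) == {"midgut", "ileum", "rectum"}

    def test_single_section_yields_four(self, default_run):
        meta = default_run["meta"]
        sub = meta[meta["gut_section"] == "ileum"]
        nets, _ = run_all_conditions(default_run["genus_table"], sub)
        assert len(nets) == 4

    def test_missing_condition_reported(self, default_run):
        meta = default_run["meta"]
        broken = meta[~((meta["gut_section"] == "rectum")
                        & (meta["dose_ppb"] == 1.0))]
        with pytest.raises(ValueError, match="rectum"):
            run_all_conditions(default_run["genus_table"], broken)

    def test_genus_relabeling_invariance(self, default_run):
        gt = default_run["genus_table"]
        meta = default_run["meta"]
        nets1, _ = run_all_conditions(gt, meta)
        renamed = ActivityTable(
            gt.counts.rename(columns=lambda c: f"x_{c}")
        )
        nets2, _ = run_all_conditions(renamed, meta)
        for key in nets1:
            e1 = {tuple(sorted((a, b))) for a, b in nets1[key].graph.edges}
            e2 = {tuple(sorted((a[2:], b[2:]))) for a, b in nets2[key].graph.edges}
            assert e1 == e2
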