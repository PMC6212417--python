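from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from miract import downstream
from miract.downstream import (
    DESignature,
    de_by_activity_group,
    export_cmap_signature,
    geneset_correlation_ks,
    geneset_overlap_fet,
    immune_score_association,
    mutation_activity_association,
    pathway_enrichment,
)
from miract.simulate import SimulationConfig, generate_cohort
from miract.survival import GroupAssignment, dichotomize_by_median


def _groups(n_over, n_under):
    labels = ["overactive"] * n_over + ["underactive"] * n_under
    idx = [f"s{i}" for i in range(n_over + n_under)]
    return GroupAssignment(labels=pd.Series(labels, index=idx), split_value=0.0)


class TestPathwayEnrichment:
    def test_identical_set_brute_force(self):
        """[DERIVED] pathway == target set of size 3 in a 50-gene universe:
        p = 1/C(50,3) = 1/19600, confirmed by enumeration."""
        universe = [f"g{i}" for i in range(50)]
        targets = universe[:3]
        out = pathway_enrichment(targets, {"pw": targets}, universe)
        hits = sum(
            1 for s in combinations(range(50), 3) if set(s) <= set(range(3))
        )
        assert hits == 1
        assert out.loc["pw", "p"] == pytest.approx(1 / 19600, abs=1e-15)

    def test_disjoint_pathway(self):
        universe = [f"g{i}" for i in range(30)]
        out = pathway_enrichment(universe[:5], {"pw": universe[10:15]}, universe)
        assert out.loc["pw", "p"] == 1.0

    def test_shared_kernel_with_screen(self):
        """Same 2x2 -> same p as the screen-side enrichment kernel."""
        from miract.stats import fet_overrep

        universe = [f"g{i}" for i in range(40)]
        targets = universe[:8]
        pw = universe[4:14]
        out = pathway_enrichment(targets, {"pw": pw}, universe)
        assert out.loc["pw", "p"] == fet_overrep(4, 8, 10, 40)

    def test_empty_pathway_in_universe(self):
        universe = [f"g{i}" for i in range(10)]
        out = pathway_enrichment(universe[:3], {"pw": ["zz"]}, universe)
        assert out.loc["pw", "p"] == 1.0
        assert out.loc["pw", "note"] == "empty_in_universe"

    def test_threshold_flag(self):
        universe = [f"g{i}" for i in range(200)]
        out = pathway_enrichment(
            universe[:10], {"pw": universe[:10]}, universe, p_threshold=1e-4
        )
        assert bool(out.loc["pw", "significant"])


class TestGenesetOverlap:
    def test_identical_sets_minimal_p(self):
        universe = [f"g{i}" for i in range(12)]
        s = universe[:4]
        p = geneset_overlap_fet(s, s, universe)
        assert p == pytest.approx(1 / comb(12, 4), abs=1e-12)

    def test_single_overlap_at_expectation(self):
        # 4x3 sets in 12 genes: expectation = 1; p must not be significant
        universe = [f"g{i}" for i in range(12)]
        a = universe[:4]
        b = universe[3:6]
        assert geneset_overlap_fet(a, b, universe) > 0.05

    def test_empty_target_set(self):
        universe = [f"g{i}" for i in range(12)]
        assert geneset_overlap_fet([], universe[:3], universe) == 1.0


class TestGenesetKS:
    def _make_expr(self, rng, n_genes=100, n_samples=60):
        genes = [f"g{i}" for i in range(n_genes)]
        return pd.DataFrame(rng.normal(size=(n_genes, n_samples)), index=genes)

    def test_most_negative_genes_detected(self, rng):
        """[DERIVED] set = the 10 most negatively correlated genes of 100:
        KS statistic equals the CDF-construction oracle value."""
        expr = self._make_expr(rng)
        a = rng.normal(size=60)
        from miract.stats import pearson_rows

        r = pearson_rows(expr.to_numpy(), a)
        order = np.argsort(r)
        gene_set = [expr.index[i] for i in order[:10]]
        stat, p, sign = geneset_correlation_ks(a, expr, gene_set)
        # oracle: direct empirical CDF gap of the two correlation samples
        rs = np.sort(r[order[:10]])
        rb = np.sort(r[order[10:]])
        pooled = np.concatenate([rs, rb])
        gap = max(
            abs(np.searchsorted(rs, v, side="right") / 10
                - np.searchsorted(rb, v, side="right") / 90)
            for v in pooled
        )
        assert stat == pytest.approx(gap, abs=1e-12)
        assert stat == pytest.approx(1.0)  # disjoint supports
        assert sign == -1
        assert p < 1e-6

    def test_random_set_null_calibration(self, rng):
        """[DERIVED] uniformly sampled sets give approximately uniform p."""
        expr = self._make_expr(rng, n_genes=80)
        a = rng.normal(size=60)
        ps = []
        for _ in range(200):
            gene_set = list(rng.choice(expr.index, size=10, replace=False))
            _, p, _ = geneset_correlation_ks(a, expr, gene_set)
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_identical_distributions(self):
        expr = pd.DataFrame(
            np.vstack([np.arange(10.0)] * 6) + np.arange(6)[:, None],
            index=[f"g{i}" for i in range(6)],
        )
        # correlations of set and complement genes are identical (all rows
        # are shifted copies) -> statistic 0
        a = np.arange(10.0)
        stat, p, _ = geneset_correlation_ks(a, expr, ["g0", "g1", "g2"])
        assert stat == 0.0
        assert p == 1.0

    def test_small_set_rejected(self, rng):
        expr = self._make_expr(rng, n_genes=20)
        with pytest.raises(ValueError, match="fewer than 3"):
            geneset_correlation_ks(rng.normal(size=60), expr, ["g0", "g1"])


class TestDEByActivityGroup:
    def test_null_calibration(self, rng):
        """[DERIVED] identical group distributions: significant genes stay
        near or below FDR * n_genes."""
        counts = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            expr = pd.DataFrame(
                r.normal(size=(200, 40)),
                index=[f"g{i}" for i in range(200)],
                columns=[f"s{i}" for i in range(40)],
            )
            sig = de_by_activity_group(
                expr, _groups(20, 20), n_perm=200, seed=seed
            )
            counts.append(len(sig.up_genes) + len(sig.down_genes))
        assert np.mean(counts) <= 0.05 * 200 + 2

    def test_planted_shift_recovered(self):
        """[DERIVED] 3-sigma shift in 20 of 500 genes, 30 per group."""
        r = np.random.default_rng(1)
        expr = pd.DataFrame(
            r.normal(size=(500, 60)),
            index=[f"g{i}" for i in range(500)],
            columns=[f"s{i}" for i in range(60)],
        )
        expr.iloc[:20, :30] += 3.0  # higher in the overactive half
        sig = de_by_activity_group(expr, _groups(30, 30), n_perm=300, seed=2)
        planted = {f"g{i}" for i in range(20)}
        recovered = planted & set(sig.up_genes)
        false_pos = (set(sig.up_genes) | set(sig.down_genes)) - planted
        assert len(recovered) >= 18
        assert len(false_pos) <= 5

    def test_constant_gene_never_listed(self):
        r = np.random.default_rng(3)
        expr = pd.DataFrame(
            r.normal(size=(50, 30)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(30)],
        )
        expr.iloc[0] = 7.0
        expr.iloc[1, :15] += 4.0  # make sure something is significant
        sig = de_by_activity_group(expr, _groups(15, 15), n_perm=200, seed=4)
        assert sig.table.loc["g0", "p"] == 1.0
        assert "g0" not in sig.up_genes + sig.down_genes

    def test_antisymmetry(self):
        """Swapping group labels swaps up and down exactly."""
        r = np.random.default_rng(5)
        expr = pd.DataFrame(
            r.normal(size=(100, 30)),
            index=[f"g{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(30)],
        )
        expr.iloc[:10, :15] += 2.0
        g = _groups(15, 15)
        flipped = GroupAssignment(
            labels=g.labels.map(
                {"overactive": "underactive", "underactive": "overactive"}
            ),
            split_value=0.0,
        )
        a = de_by_activity_group(expr, g, n_perm=200, seed=6)
        b = de_by_activity_group(expr, flipped, n_perm=200, seed=6)
        assert a.up_genes == b.down_genes
        assert a.down_genes == b.up_genes

    def test_small_groups_rejected(self):
        expr = pd.DataFrame(np.ones((5, 4)), columns=[f"s{i}" for i in range(4)])
        with pytest.raises(ValueError, match=">= 3"):
            de_by_activity_group(expr, _groups(2, 2))


class TestCmapExport:
    def test_line_counts_52_77(self, tmp_path):
        sig = DESignature(
            mirna_id="m",
            up_genes=[f"up{i}" for i in range(52)],
            down_genes=[f"dn{i}" for i in range(77)],
            table=pd.DataFrame(),
        )
        up, down = export_cmap_signature(sig, tmp_path)
        assert len(up.read_text().splitlines()) == 52
        assert len(down.read_text().splitlines()) == 77

    def test_uppercase_no_header(self, tmp_path):
        sig = DESignature("m", ["abcD"], ["efG"], pd.DataFrame())
        up, down = export_cmap_signature(sig, tmp_path)
        assert up.read_text() == "ABCD\n"
        assert down.read_text() == "EFG\n"

    def test_duplicates_warn_and_dedupe(self, tmp_path):
        sig = DESignature("m", ["A", "a"], ["B"], pd.DataFrame())
        with pytest.warns(UserWarning, match="duplicate"):
            up, _ = export_cmap_signature(sig, tmp_path)
        assert up.read_text().splitlines() == ["A"]

    def test_round_trip_as_sets(self, tmp_path):
        sig = DESignature("m", ["G1", "G2"], ["G3"], pd.DataFrame())
        up, down = export_cmap_signature(sig, tmp_path)
        assert set(up.read_text().split()) == {"G1", "G2"}
        assert set(down.read_text().split()) == {"G3"}

    def test_empty_rejected(self, tmp_path):
        sig = DESignature("m", [], [], pd.DataFrame())
        with pytest.raises(ValueError, match="empty"):
            export_cmap_signature(sig, tmp_path)

    def test_probe_map(self, tmp_path):
        sig = DESignature("m", ["g1"], ["g2"], pd.DataFrame())
        up, down = export_cmap_signature(
            sig, tmp_path, probe_map={"g1": "1001_at", "g2": "1002_at"}
        )
        assert up.read_text() == "1001_AT\n"

    def test_up_down_disjoint_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            DESignature("m", ["G"], ["G"], pd.DataFrame())


class TestMutationAssociation:
    def test_fet_2_0_0_2(self):
        """[DERIVED] FET table (2,0 / 0,2): p = 1/3 by enumerating the
        C(4,2)=6 equal-margin tables."""
        act = pd.Series([1.0, 2.0, 10.0, 11.0], index=list("abcd"))
        mut = pd.DataFrame([[1, 1, 0, 0]], index=["g"], columns=list("abcd"))
        out = mutation_activity_association(mut, act)
        assert out.loc["g", "fet_p"] == pytest.approx(1 / 3, abs=1e-12)

    def test_all_or_none_skipped(self):
        act = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        mut = pd.DataFrame([[1, 1, 1], [0, 0, 0]], index=["g1", "g2"], columns=list("abc"))
        out = mutation_activity_association(mut, act)
        assert (out["note"] == "all_or_none_mutated").all()

    def test_null_calibration(self):
        """[DERIVED] independent mutations: flagged-gene rate near nominal."""
        flagged = 0
        total = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 100
            act = pd.Series(r.normal(size=n), index=[f"s{i}" for i in range(n)])
            mut = pd.DataFrame(
                (r.random((40, n)) < 0.2).astype(int),
                index=[f"g{i}" for i in range(40)],
                columns=act.index,
            )
            out = mutation_activity_association(mut, act)
            tested = out["note"] == ""
            flagged += int(out.loc[tested, "significant"].sum())
            total += int(tested.sum())
        # two tests at p<0.003 each; generous bound ~ 4x nominal
        assert flagged / total < 0.025

    def test_planted_gene_recovered(self):
        """[DERIVED] the generator's linked gene has the lowest WMW p in
        every seed, and clears the 0.003 flag in most (the flag threshold
        is strict for a 120-sample cohort with few mutated tumors)."""
        flagged = 0
        for seed in range(1, 6):
            c = generate_cohort(
                SimulationConfig(seed=seed, activity_scale=2.0, degradation_effect=0.15)
            )
            act = c.true_activity.iloc[c.config.prognostic_mirna_index][
                c.mutations.columns
            ]
            out = mutation_activity_association(c.mutations, act)
            tested = out[out["note"] == ""]
            assert tested["wmw_p"].idxmin() == c.mutations.index[0]
            flagged += int(out.iloc[0]["significant"])
            # mutated tumors sit at lower activity
            status = c.mutations.iloc[0].astype(bool)
            assert act[status].median() < act[~status].median()
        assert flagged >= 4


class TestImmuneScore:
    def test_identical_groups(self):
        # both groups carry the same score values {3, 6, 9}
        expr = pd.DataFrame(
            np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (3, 1)),
            index=["m1", "m2", "m3"],
            columns=[f"s{i}" for i in range(6)],
        )
        score, t, p = immune_score_association(expr, ["m1", "m2"], _groups(3, 3))
        assert t == 0.0 and p == 1.0

    def test_single_marker_is_row(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["m1"],
            columns=[f"s{i}" for i in range(6)],
        )
        score, _, _ = immune_score_association(expr, ["m1"], _groups(3, 3))
        np.testing.assert_allclose(score, expr.loc["m1"])

    def test_planted_shift_power(self):
        """[DERIVED] 2-sigma shift in all markers, 30 per group -> p < 0.01."""
        r = np.random.default_rng(1)
        expr = pd.DataFrame(
            r.normal(size=(20, 60)),
            index=[f"m{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(60)],
        )
        expr.iloc[:, :30] += 2.0
        _, _, p = immune_score_association(expr, list(expr.index), _groups(30, 30))
        assert p < 0.01

    def test_no_markers_error(self):
        expr = pd.DataFrame([[1.0] * 6], index=["g"], columns=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError, match="no marker genes"):
            immune_score_association(expr, ["zz"], _groups(3, 3))
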