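"""Fisher over-representation, ranked-list construction, pre-ranked GSEA."""

import numpy as np
import pandas as pd
import pytest

from phosrewire import diffreg, enrichment
from phosrewire.datamodel import ValidationError
from phosrewire.enrichment import ContingencyTable
from oracles import gsea_running_sum_oracle, hypergeom_tail_oracle


class TestFisherOnesided:
    def test_zero_overlap_gives_p_one(self):
        assert enrichment.fisher_onesided(
            ContingencyTable(0, 10, 5, 85)) == pytest.approx(1.0)

    def test_derived_combinatorial_example(self):
        # N=100, K=20, n=10, a=5
        table = ContingencyTable(a=5, b=5, c=15, d=75)
        expected = float(hypergeom_tail_oracle(5, 5, 15, 75))
        assert enrichment.fisher_onesided(table) == pytest.approx(
            expected, abs=1e-12)

    def test_every_background_gene_annotated_forces_p_one(self):
        # K = N: the margin forces a = n
        table = ContingencyTable(a=10, b=0, c=90, d=0)
        assert enrichment.fisher_onesided(table) == pytest.approx(1.0)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(-1, 2, 3, 4)

    def test_matches_exact_rational_oracle_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n_total = int(rng.integers(4, 61))
            k_ann = int(rng.integers(1, n_total))
            n_reg = int(rng.integers(1, n_total))
            a_max = min(k_ann, n_reg)
            a_min = max(0, k_ann + n_reg - n_total)
            a = int(rng.integers(a_min, a_max + 1))
            table = ContingencyTable(a, n_reg - a, k_ann - a,
                                     n_total - k_ann - n_reg + a)
            expected = float(hypergeom_tail_oracle(
                table.a, table.b, table.c, table.d))
            assert enrichment.fisher_onesided(table) == pytest.approx(
                expected, abs=1e-10)

    def test_annotated_regulated_gene_never_raises_p(self):
        """Moving one background gene into regulated-and-annotated can only
        strengthen the enrichment."""
        base = ContingencyTable(a=4, b=6, c=10, d=40)
        grown = ContingencyTable(a=5, b=6, c=9, d=40)
        assert (enrichment.fisher_onesided(grown)
                <= enrichment.fisher_onesided(base))


class TestTermEnrichment:
    def test_small_overlap_excluded_before_testing(self):
        background = {f"G{i}" for i in range(40)}
        up = {"G0", "G1", "G2", "G3"}
        sets = {"small": {"G0", "G1", "G30"},   # overlap a=2 < 3
                "big": {"G0", "G1", "G2", "G35"}}
        res = enrichment.term_enrichment(up, set(), background, sets)
        assert {r.term for r in res if r.direction == "up"} == {"big"}

    def test_up_and_down_tested_against_same_background(self):
        background = {f"G{i}" for i in range(30)}
        sets = {"t": {f"G{i}" for i in range(6)}}
        res = enrichment.term_enrichment(
            {"G0", "G1", "G2"}, {"G3", "G4", "G5"}, background, sets)
        assert sorted(r.direction for r in res) == ["down", "up"]
        for r in res:
            assert r.table.n == 30

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            enrichment.term_enrichment(set(), set(), set(), {})

    def test_planted_tf_recovered_top_ranked(self, default_study):
        study = default_study
        prot_calls = diffreg.run_diffreg(study.proteins, study.design,
                                         tau=2.5, loc_min=None)
        up, down = diffreg.gene_direction_sets(prot_calls)
        background = {c.gene for c in prot_calls if c.n_quantified > 0}
        res = enrichment.term_enrichment(up, down, background,
                                         study.annotations.tf_targets)
        planted = study.truth.active_tfs
        for tf, sign in planted.items():
            direction = "up" if sign > 0 else "down"
            block = [r for r in res if r.direction == direction]
            match = next(r for r in block if r.term == tf)
            assert match.p < 0.05
            # planted TFs dominate their direction block
            planted_here = {t for t, s in planted.items()
                            if ("up" if s > 0 else "down") == direction}
            assert {r.term for r in block[:len(planted_here)]} \
                == planted_here


class TestRankedList:
    def _call(self, gene, fc, status, pos):
        return diffreg.RegulationCall(
            unit_key=("P_" + gene, pos, 1), gene=gene, z=(0.0,) * 4,
            n_up=0, n_down=0, n_quantified=4, status=status,
            mean_log2fc=fc)

    def test_most_regulated_peptide_by_abs_value(self):
        calls = [self._call("G1", 1.1, "up", 1),
                 self._call("G1", -2.2, "down", 2)]
        ranked = enrichment.build_ranked_list(calls)
        assert ranked.loc[0, "metric"] == pytest.approx(-2.2)

    def test_fallback_to_highest_ratio_without_regulated_peptide(self):
        calls = [self._call("G1", 0.2, "unchanged", 1),
                 self._call("G1", 0.5, "unchanged", 2)]
        ranked = enrichment.build_ranked_list(calls)
        assert ranked.loc[0, "metric"] == pytest.approx(0.5)

    def test_equal_abs_tie_resolves_positive(self):
        calls = [self._call("G1", 1.5, "up", 1),
                 self._call("G1", -1.5, "down", 2)]
        ranked = enrichment.build_ranked_list(calls)
        assert ranked.loc[0, "metric"] == pytest.approx(1.5)

    def test_one_row_per_gene_strictly_ordered(self, default_calls):
        ranked = enrichment.build_ranked_list(default_calls)
        assert ranked["gene"].is_unique
        metrics = ranked["metric"].to_numpy()
        assert (np.diff(metrics) <= 0).all()


class TestGsea:
    def _ranked(self, genes, metrics):
        return pd.DataFrame({"gene": genes, "metric": metrics})

    def test_single_top_gene_scores_one(self):
        ranked = self._ranked(["A", "B", "C"], [2.0, 1.0, 0.5])
        res = enrichment.gsea_preranked(ranked, {"A"}, n_perm=10, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_bottom_gene_running_sum_oracle(self):
        ranked = self._ranked(["A", "B", "C"], [1.0, 1.0, 1.0])
        res = enrichment.gsea_preranked(ranked, {"C"}, n_perm=10, seed=0)
        sums, es = gsea_running_sum_oracle([1.0, 1.0, 1.0],
                                           [False, False, True])
        assert sums == pytest.approx([-0.5, -1.0, 0.0])
        assert res.es == pytest.approx(es) == pytest.approx(-1.0)

    def test_matches_running_sum_oracle_on_random_lists(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            metrics = np.sort(rng.normal(size=n))[::-1]
            genes = [f"G{i}" for i in range(n)]
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=k, replace=False))
            res = enrichment.gsea_preranked(
                self._ranked(genes, metrics), members, n_perm=1, seed=0)
            _, es = gsea_running_sum_oracle(
                list(metrics), [g in members for g in genes])
            assert res.es == pytest.approx(es)

    def test_es_invariant_to_metric_scaling(self):
        rng = np.random.default_rng(5)
        metrics = np.sort(rng.normal(size=30))[::-1]
        genes = [f"G{i}" for i in range(30)]
        members = set(genes[::4])
        a = enrichment.gsea_preranked(self._ranked(genes, metrics),
                                      members, n_perm=1, seed=0)
        b = enrichment.gsea_preranked(self._ranked(genes, metrics * 10),
                                      members, n_perm=1, seed=0)
        assert a.es == pytest.approx(b.es)

    def test_set_covering_whole_list_is_degenerate(self):
        ranked = self._ranked(["A", "B"], [1.0, 0.5])
        with pytest.raises(ValidationError):
            enrichment.gsea_preranked(ranked, {"A", "B"}, n_perm=10, seed=0)

    def test_planted_set_significant_uniform_set_not(self, default_study,
                                                     default_calls):
        ranked = enrichment.build_ranked_list(default_calls)
        sets = default_study.annotations.gene_sets
        top = enrichment.gsea_preranked(ranked, sets["top_concentrated"],
                                        n_perm=1000, seed=7)
        uni = enrichment.gsea_preranked(ranked, sets["uniform_set"],
                                        n_perm=1000, seed=7)
        assert top.p <= 0.01
        assert uni.p > 0.05

    def test_uniform_random_sets_give_unbiased_p(self):
        """Median permutation p over random sets sits near 0.5."""
        rng = np.random.default_rng(6)
        n = 60
        genes = [f"G{i}" for i in range(n)]
        metrics = np.sort(rng.normal(size=n))[::-1]
        ranked = self._ranked(genes, metrics)
        ps = []
        for rep in range(20):
            members = set(rng.choice(genes, size=8, replace=False))
            ps.append(enrichment.gsea_preranked(
                ranked, members, n_perm=200, seed=rep).p)
        assert 0.3 <= float(np.median(ps)) <= 0.7


def test_overlap_edges_jaccard():
    sets = {"a": {"1", "2", "3", "4"}, "b": {"3", "4", "5", "6"},
            "c": {"9"}}
    df = enrichment.overlap_edges(sets, ["a", "b", "c"], min_jaccard=0.25)
    assert len(df) == 1
    assert df.loc[0, "jaccard"] == pytest.approx(2 / 6)
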