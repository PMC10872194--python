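"""Gene scoring (binned max-BF ranks) and GO-DAG KS enrichment with elim."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from climagea.ontology import (
    GeneScoreTable,
    gene_scores,
    ks_enrichment,
    propagate_annotations,
    run_enrichment,
    snp_count_bin,
)


def score_table_from_gene_db(gene_db: dict) -> GeneScoreTable:
    """One SNP per gene, dB as given."""
    genes = list(gene_db)
    db = pd.Series({f"snp_{g}": v for g, v in gene_db.items()})
    ann = pd.DataFrame({"gene_id": genes, "distance": 0.0},
                       index=pd.Index([f"snp_{g}" for g in genes], name="snp"))
    return gene_scores(db, ann)


class TestSnpCountBin:
    @pytest.mark.parametrize("n,label", [
        (1, "1"), (99, "99"), (100, "100-149"), (120, "100-149"),
        (149, "100-149"), (150, "150-199"), (250, "200-299"),
        (400, "300-499"), (500, ">=500"), (1200, ">=500"),
    ])
    def test_bin_labels(self, n, label):
        assert snp_count_bin(n) == label

    def test_zero_snps_rejected(self):
        with pytest.raises(ValueError):
            snp_count_bin(0)


class TestGeneScores:
    def test_hundred_gene_bin_top_two_scores(self):
        # 100 genes, eight SNPs each; greatest max(BF) scores 1/100, second 2/100
        rng = np.random.default_rng(0)
        rows, db = [], {}
        for g in range(100):
            vals = rng.uniform(0, 30, 8)
            for k, v in enumerate(vals):
                snp = f"s{g:03d}_{k}"
                rows.append({"snp": snp, "gene_id": f"gene{g:03d}"})
                db[snp] = v
        ann = pd.DataFrame(rows).set_index("snp")
        ann["distance"] = 0.0
        table = gene_scores(pd.Series(db), ann).table
        assert (table["bin"] == "8").all()
        ordered = table.sort_values("max_db", ascending=False)
        assert ordered.iloc[0]["score"] == pytest.approx(0.01)
        assert ordered.iloc[1]["score"] == pytest.approx(0.02)

    def test_singleton_bin_scores_one(self):
        st_ = score_table_from_gene_db({"only": 12.3})
        assert st_.scores["only"] == pytest.approx(1.0)

    def test_max_db_is_max_over_gene_snps(self):
        db = pd.Series({"s1": 5.0, "s2": 17.0, "s3": 3.0})
        ann = pd.DataFrame({"gene_id": ["g", "g", "g"], "distance": 0.0},
                           index=pd.Index(["s1", "s2", "s3"], name="snp"))
        table = gene_scores(db, ann).table
        assert table.iloc[0]["max_db"] == 17.0
        assert table.iloc[0]["n_snps"] == 3

    def test_competition_ranks_for_ties(self):
        st_ = score_table_from_gene_db({"a": 10.0, "b": 10.0, "c": 5.0})
        t = st_.table.set_index("gene_id")
        assert t.loc["a", "rank"] == t.loc["b", "rank"] == 1
        assert t.loc["c", "rank"] == 3

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25)
    def test_per_bin_scores_are_rank_fractions(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        st_ = score_table_from_gene_db({f"g{i}": float(v) for i, v in
                                        enumerate(rng.normal(size=n))})
        t = st_.table
        # distinct values -> scores are exactly {1/n, ..., n/n}
        np.testing.assert_allclose(np.sort(t["score"]), np.arange(1, n + 1) / n)
        # smaller score <=> larger max dB
        s = t.sort_values("score")
        assert (np.diff(s["max_db"]) <= 0).all()

    def test_unannotated_only_rejected(self):
        ann = pd.DataFrame({"gene_id": [None], "distance": np.nan},
                           index=pd.Index(["s1"], name="snp"))
        with pytest.raises(ValueError, match="annotated"):
            gene_scores(pd.Series({"s1": 1.0}), ann)


class TestPropagation:
    EDGES = pd.DataFrame({"child": ["GO:2", "GO:3", "GO:4"],
                          "parent": ["GO:1", "GO:2", "GO:2"]})

    def test_true_path_rule_to_root(self):
        g2g = pd.DataFrame({"gene_id": ["gx"], "term": ["GO:3"]})
        dag = propagate_annotations(self.EDGES, g2g, {"gx"})
        for term in ("GO:3", "GO:2", "GO:1"):
            assert "gx" in dag.term_genes[term]
        assert "gx" not in dag.term_genes["GO:4"]

    def test_empty_mapping_gives_empty_sets(self):
        g2g = pd.DataFrame({"gene_id": [], "term": []})
        dag = propagate_annotations(self.EDGES, g2g, {"g1"})
        assert all(len(s) == 0 for s in dag.term_genes.values())

    def test_matches_reachability_oracle_on_random_dag(self):
        rng = np.random.default_rng(5)
        terms = [f"GO:{i}" for i in range(12)]
        edges = []
        for i in range(1, 12):
            for p in rng.choice(i, size=min(i, 2), replace=False):
                edges.append({"child": terms[i], "parent": terms[p]})
        edges = pd.DataFrame(edges)
        genes = [f"g{i}" for i in range(30)]
        g2g = pd.DataFrame({
            "gene_id": rng.choice(genes, 50),
            "term": rng.choice(terms[1:], 50),
        })
        dag = propagate_annotations(edges, g2g, set(genes))

        parents = {}
        for _, r in edges.iterrows():
            parents.setdefault(r["child"], set()).add(r["parent"])

        def reach(term):
            out, stack = set(), [term]
            while stack:
                t = stack.pop()
                if t in out:
                    continue
                out.add(t)
                stack.extend(parents.get(t, ()))
            return out

        expected = {t: set() for t in terms}
        for _, r in g2g.iterrows():
            for t in reach(r["term"]):
                expected[t].add(r["gene_id"])
        for t in terms:
            assert set(dag.term_genes.get(t, set())) == expected[t]


@pytest.fixture(scope="module")
def universe():
    rng = np.random.default_rng(2)
    return score_table_from_gene_db(
        {f"g{i:04d}": float(v) for i, v in enumerate(rng.normal(5, 3, 1000))}
    )


class TestKsEnrichment:
    def test_maximal_statistic_when_term_holds_smallest_scores(self, universe):
        m = 40
        smallest = universe.table.nsmallest(m, "score")["gene_id"].tolist()
        D, p = ks_enrichment(smallest, universe)
        assert D == pytest.approx(1 - m / 1000, abs=1e-12)
        assert p < 1e-10

    def test_null_pvalues_roughly_uniform(self, universe):
        rng = np.random.default_rng(3)
        genes = universe.table["gene_id"].to_numpy()
        ps = [ks_enrichment(rng.choice(genes, 20, replace=False), universe)[1]
              for _ in range(1000)]
        assert np.mean(ps) == pytest.approx(0.5, abs=0.05)

    def test_term_equal_to_universe_rejected(self, universe):
        with pytest.raises(ValueError, match="universe"):
            ks_enrichment(set(universe.table["gene_id"]), universe)

    def test_term_outside_universe_rejected(self, universe):
        with pytest.raises(ValueError, match="outside"):
            ks_enrichment({"not_a_gene"}, universe)


class TestRunEnrichment:
    @staticmethod
    def chain_dag_and_scores(n_genes=500, leaf_size=12, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:04d}" for i in range(n_genes)]
        st_ = score_table_from_gene_db(
            {g: float(v) for g, v in zip(genes, rng.normal(5, 3, n_genes))}
        )
        leaf_genes = st_.table.nsmallest(leaf_size, "score")["gene_id"].tolist()
        mid_extra = rng.choice(
            [g for g in genes if g not in leaf_genes], 25, replace=False
        ).tolist()
        edges = pd.DataFrame({"child": ["GO:mid", "GO:leaf"],
                              "parent": ["GO:root", "GO:mid"]})
        g2g = pd.DataFrame({
            "gene_id": leaf_genes + mid_extra,
            "term": ["GO:leaf"] * len(leaf_genes) + ["GO:mid"] * len(mid_extra),
        })
        dag = propagate_annotations(edges, g2g, set(genes))
        return dag, st_, edges, g2g

    def test_node_size_pruning(self):
        dag, st_, _, _ = self.chain_dag_and_scores(leaf_size=9)
        res = run_enrichment(dag, st_, algorithm="classic", node_size=10)
        assert "GO:leaf" not in set(res["term"])  # 9 genes < node size 10
        assert "GO:mid" in set(res["term"])

    def test_elim_equals_classic_when_nothing_significant(self):
        dag, st_, _, _ = self.chain_dag_and_scores(leaf_size=12)
        classic = run_enrichment(dag, st_, "classic", elim_cutoff=0.01)
        elim = run_enrichment(dag, st_, "elim", elim_cutoff=1e-300)
        merged = classic.merge(elim, on="term", suffixes=("_c", "_e"))
        np.testing.assert_allclose(merged["p_c"], merged["p_e"])
        np.testing.assert_allclose(merged["ks_c"], merged["ks_e"])

    def test_elim_absorbs_leaf_signal_from_ancestor(self):
        dag, st_, _, _ = self.chain_dag_and_scores(leaf_size=12)
        classic = run_enrichment(dag, st_, "classic").set_index("term")
        elim = run_enrichment(dag, st_, "elim").set_index("term")
        assert elim.loc["GO:leaf", "p"] == classic.loc["GO:leaf", "p"]
        assert elim.loc["GO:mid", "p"] > classic.loc["GO:mid", "p"]

    def test_planted_term_ranks_first_under_both_algorithms(self):
        dag, st_, _, _ = self.chain_dag_and_scores(leaf_size=15, seed=4)
        for alg in ("classic", "elim"):
            res = run_enrichment(dag, st_, alg)
            assert res.iloc[0]["term"] == "GO:leaf"

    def test_unknown_algorithm_rejected(self):
        dag, st_, _, _ = self.chain_dag_and_scores()
        with pytest.raises(ValueError, match="algorithm"):
            run_enrichment(dag, st_, algorithm="weight01")

    def test_pvalues_invariant_to_gene_relabeling(self):
        dag, st_, edges, g2g = self.chain_dag_and_scores(seed=6)
        mapping = {g: f"x{g}" for g in st_.table["gene_id"]}
        table2 = st_.table.copy()
        table2["gene_id"] = table2["gene_id"].map(mapping)
        st2 = GeneScoreTable(table=table2)
        g2g2 = g2g.assign(gene_id=g2g["gene_id"].map(mapping))
        dag2 = propagate_annotations(edges, g2g2, set(table2["gene_id"]))
        r1 = run_enrichment(dag, st_, "classic").set_index("term")["p"]
        r2 = run_enrichment(dag2, st2, "classic").set_index("term")["p"]
        np.testing.assert_allclose(r1.sort_index(), r2.sort_index())
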