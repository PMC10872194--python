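"""Gene-level association scores and GO-DAG enrichment.

Gene scores: to avoid over-rewarding genes that simply contain many SNPs,
each gene's statistic is the maximum (over its SNPs) of the min-across-runs
deciban Bayes factor, and genes are ranked *within groups of equal SNP
count* (exact counts below 100, then bins 100-149, 150-199, 200-299,
300-499, >=500).  The gene score is rank / group size, in (0, 1]; the gene
with the greatest max(BF) in a 100-gene group scores 1/100 = 0.01, the
second greatest 2/100 = 0.02, and so on.  Low score = strong association.

Enrichment: annotations are propagated up the GO DAG (true-path rule), terms
with fewer than ``node_size`` annotated genes are pruned, and each term is
tested with a one-sided two-sample Kolmogorov-Smirnov statistic comparing
its genes' scores against the score distribution of the whole gene universe
(alternative: term scores stochastically smaller).  The ``elim`` algorithm
decorrelates the DAG by processing terms from the most specific level upward
and removing the genes of any term with p < cutoff from all of its
ancestors' sets before those are tested.  P-values are reported unadjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

logger = logging.getLogger(__name__)

SNP_COUNT_BINS = ((100, 149), (150, 199), (200, 299), (300, 499))
DEFAULT_NODE_SIZE = 10
DEFAULT_ELIM_CUTOFF = 0.01


# ---------------------------------------------------------------------------
# Binned rank gene scores
# ---------------------------------------------------------------------------

def snp_count_bin(n_snps: int) -> str:
    """Bin label for a gene's SNP count (exact below 100, banded above)."""
    if n_snps < 1:
        raise ValueError("gene with zero SNPs cannot be scored")
    if n_snps < 100:
        return str(n_snps)
    for lo, hi in SNP_COUNT_BINS:
        if lo <= n_snps <= hi:
            return f"{lo}-{hi}"
    return ">=500"


@dataclass
class GeneScoreTable:
    """Per-gene SNP counts, max dB, within-bin competition rank, and score."""

    table: pd.DataFrame  # gene_id, n_snps, bin, max_db, rank, score

    @property
    def scores(self) -> pd.Series:
        return self.table.set_index("gene_id")["score"]

    @property
    def universe(self) -> set[str]:
        return set(self.table["gene_id"])


def gene_scores(scan, annotation_map: pd.DataFrame, covariate: str | None = None) -> GeneScoreTable:
    """Binned rank-based gene scores from a scan and a SNP->gene map.

    ``scan`` may be a SnpScanResult (``covariate`` selects the min-dB track)
    or a Series of per-SNP dB values indexed by SNP id.  Only annotated SNPs
    enter; every annotated gene gets a score.  Ranks are competition ranks
    (ties share the smallest rank) in descending max(dB) order.
    """
    if isinstance(scan, pd.Series):
        min_db = scan
    else:
        if covariate is None:
            raise ValueError("covariate required when passing a SnpScanResult")
        min_db = scan.min_db_series(covariate)
    ann = annotation_map[annotation_map["gene_id"].notna()]
    if ann.empty:
        raise ValueError("no annotated SNPs")
    df = pd.DataFrame({
        "gene_id": ann["gene_id"].to_numpy(),
        "db": min_db.reindex(ann.index).to_numpy(),
    })
    per_gene = df.groupby("gene_id").agg(n_snps=("db", "size"), max_db=("db", "max")).reset_index()
    per_gene["bin"] = per_gene["n_snps"].map(snp_count_bin)

    out = []
    for _, grp in per_gene.groupby("bin", sort=False):
        m = len(grp)
        # competition rank, descending: 1 + number of strictly greater values
        vals = grp["max_db"].to_numpy()
        rank = np.array([1 + int((vals > v).sum()) for v in vals])
        g = grp.copy()
        g["rank"] = rank
        g["score"] = rank / m
        out.append(g)
    table = (
        pd.concat(out, ignore_index=True)
        .sort_values("gene_id", kind="stable")
        .reset_index(drop=True)
    )
    return GeneScoreTable(table=table[["gene_id", "n_snps", "bin", "max_db", "rank", "score"]])


# ---------------------------------------------------------------------------
# Ontology DAG
# ---------------------------------------------------------------------------

@dataclass
class OntologyDAG:
    """GO terms, is_a parent edges, and true-path-propagated gene sets."""

    graph: nx.DiGraph                       # edges child -> parent
    term_genes: dict[str, frozenset]        # propagated over the universe
    namespaces: dict[str, str]
    universe: frozenset

    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by following is_a edges upward."""
        return nx.descendants(self.graph, term)

    def depth(self) -> dict[str, int]:
        """Longest is_a path from each term down to a root (specificity)."""
        order = list(nx.topological_sort(self.graph.reverse()))  # roots first
        d: dict[str, int] = {}
        for node in order:
            parents = list(self.graph.successors(node))
            d[node] = 0 if not parents else 1 + max(d[p] for p in parents)
        return d

    def subset(self, namespace: str) -> "OntologyDAG":
        keep = {t for t, ns in self.namespaces.items() if ns == namespace}
        sub = self.graph.subgraph(keep).copy()
        return OntologyDAG(
            graph=sub,
            term_genes={t: g for t, g in self.term_genes.items() if t in keep},
            namespaces={t: namespace for t in keep},
            universe=self.universe,
        )


def propagate_annotations(
    edges: pd.DataFrame,
    gene2go: pd.DataFrame,
    universe: set[str],
    namespaces: dict[str, str] | None = None,
) -> OntologyDAG:
    """Build the DAG and compute the true-path closure of gene annotations.

    ``edges`` has columns ``child``, ``parent``; ``gene2go`` has ``gene_id``,
    ``term``.  A gene annotated to a term belongs to every ancestor of that
    term.  Mappings outside the universe are dropped; cycles are rejected
    naming one participating term.
    """
    g = nx.DiGraph()
    for _, row in edges.iterrows():
        g.add_edge(row["child"], row["parent"])
    for term in pd.unique(gene2go["term"]):
        g.add_node(term)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology edges contain a cycle involving {cycle[0][0]!r}")

    term_genes: dict[str, set] = {t: set() for t in g.nodes}
    g2g = gene2go[gene2go["gene_id"].isin(universe)]
    dropped = len(gene2go) - len(g2g)
    if dropped:
        logger.info("dropped %d gene2go rows outside the universe", dropped)
    anc_cache: dict[str, set] = {}
    for gene, term in zip(g2g["gene_id"], g2g["term"]):
        if term not in anc_cache:
            anc_cache[term] = {term} | nx.descendants(g, term)
        for t in anc_cache[term]:
            term_genes[t].add(gene)
    ns = namespaces or {t: "biological_process" for t in g.nodes}
    return OntologyDAG(
        graph=g,
        term_genes={t: frozenset(s) for t, s in term_genes.items()},
        namespaces=ns,
        universe=frozenset(universe),
    )


def read_obo(path: str):
    """Load a (minimal) OBO ontology into edges + namespaces via obonet."""
    import obonet

    g = obonet.read_obo(path)
    rows = []
    ns = {}
    for node, data in g.nodes(data=True):
        ns[node] = data.get("namespace", "biological_process")
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            rows.append({"child": child, "parent": parent})
    return pd.DataFrame(rows, columns=["child", "parent"]), ns


# ---------------------------------------------------------------------------
# KS enrichment
# ---------------------------------------------------------------------------

def ks_enrichment(term_genes, score_table: GeneScoreTable) -> tuple[float, float]:
    """One-sided KS test: are the term's gene scores stochastically smaller
    than the universe's score distribution?

    Returns (statistic, p).  If the term's genes hold exactly the m smallest
    of N universe scores the statistic attains its maximum 1 - m/N.
    """
    scores = score_table.scores
    term = set(term_genes)
    if not term:
        raise ValueError("empty term gene set")
    if not term <= set(scores.index):
        raise ValueError("term genes outside the scored universe")
    if term == set(scores.index):
        raise ValueError("term equal to universe: no complement to compare against")
    term_scores = scores.loc[sorted(term)].to_numpy()
    res = ks_2samp(term_scores, scores.to_numpy(), alternative="greater", method="auto")
    return float(res.statistic), float(res.pvalue)


def run_enrichment(
    dag: OntologyDAG,
    score_table: GeneScoreTable,
    algorithm: str = "elim",
    node_size: int = DEFAULT_NODE_SIZE,
    elim_cutoff: float = DEFAULT_ELIM_CUTOFF,
    namespace: str | None = None,
) -> pd.DataFrame:
    """Per-term enrichment over a propagated DAG.

    ``classic`` tests every surviving term independently; ``elim`` walks the
    DAG from the most specific terms upward and, whenever a term's p-value
    falls below ``elim_cutoff``, removes that term's genes from all ancestor
    sets before those are tested.  Terms whose (current) gene set is smaller
    than ``node_size``, or equal to the whole universe, are not tested.
    Returns a DataFrame (term, namespace, n_genes, ks, p, algorithm) sorted
    by p.
    """
    if algorithm not in ("classic", "elim"):
        raise ValueError(f"unknown algorithm {algorithm!r}; expected 'classic' or 'elim'")
    work = dag if namespace is None else dag.subset(namespace)
    universe = set(score_table.scores.index)
    sets = {t: set(g) & universe for t, g in work.term_genes.items()}
    depth = work.depth()
    order = sorted(work.graph.nodes, key=lambda t: (-depth[t], t))

    rows = []
    n_elim = 0
    for term in order:
        genes = sets[term]
        if len(genes) < node_size or genes == universe:
            continue
        stat, p = ks_enrichment(genes, score_table)
        rows.append({
            "term": term,
            "namespace": work.namespaces.get(term, ""),
            "n_genes": len(genes),
            "ks": stat,
            "p": p,
            "algorithm": algorithm,
        })
        if algorithm == "elim" and p < elim_cutoff:
            n_elim += 1
            for anc in work.ancestors(term):
                sets[anc] -= genes
    if algorithm == "elim":
        logger.info("elim removed gene sets of %d significant terms from their ancestors", n_elim)
    return (
        pd.DataFrame(rows, columns=["term", "namespace", "n_genes", "ks", "p", "algorithm"])
        .sort_values(["p", "term"], kind="stable")
        .reset_index(drop=True)
    )
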