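"""Synthetic multi-population SNP data with a climate-driven selection signal.

The generator emulates the structure of a range-wide SNP-chip study of a wild
bird: ~20 weakly differentiated populations (genome-wide FST around 0.01)
whose allele frequencies share a covariance matrix Omega, a site-level climate
table driven by two latent geographic gradients, a minority of SNPs whose
frequencies track the first gradient, missing genotypes, a few close-relative
pairs, sexed individuals with a hemizygous Z chromosome, and a small
"unplaced scaffold" chromosome.  Toy gene models and a toy GO DAG complete the
inputs needed by the downstream annotation and enrichment stages.

Frequency model (matched to the scan's working model): per SNP an ancestral
frequency pi ~ Beta(a, b); population frequencies

    alpha_j = clamp(pi + sqrt(pi (1 - pi)) * m_j,  eps, 1 - eps)

with m ~ N(0, Omega) on the standardized-frequency scale.  SNPs under
climate-driven selection receive an additional shift beta * c_j on the m
scale, where c_j is the standardized focal climate gradient at site j.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

CLAMP_EPS = 1e-4
UNPLACED_CHROM = "chr35"
Z_CHROM = "chrZ"
AUTOSOMES = ("chr1", "chr2", "chr3", "chr4")

#: WorldClim-style variable names used when exactly 22 climate variables are
#: requested (19 bioclim summaries + solar radiation, wind speed, vapour
#: pressure); otherwise generic names are generated.
BIOCLIM_NAMES = [f"bio{i:02d}" for i in range(1, 20)] + ["srad", "wind", "vapr"]


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic dataset."""

    n_populations: int = 20
    n_individuals_per_pop: int = 20
    n_snps: int = 20_000
    n_selected_snps: int = 50
    effect_size_beta: float = 2.0
    omega_spec: object = None  # None -> hierarchical default; newick str; SPD array
    freq_beta_params: tuple[float, float] = (2.0, 2.0)  # chip-like common-variant spectrum
    missing_rate: float = 0.02
    n_related_pairs: int = 3
    n_climate_vars: int = 22
    n_go_terms: int = 120
    genes_per_chrom: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.n_populations < 2:
            raise ValueError("need at least 2 populations")
        if self.n_selected_snps > self.n_snps:
            raise ValueError("n_selected_snps exceeds n_snps")
        a, b = self.freq_beta_params
        if a <= 0 or b <= 0:
            raise ValueError(f"degenerate Beta parameters (a={a}, b={b}); both must be > 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_go_terms < 2:
            raise ValueError("need at least 2 GO terms")


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset (artifact plumbing, not data).

    ``snps`` carries per-SNP selected flags and simulated effect sizes;
    ``related_pairs`` the engineered close-relative pairs; the latent
    population frequencies and the focal standardized gradient are retained so
    tests can verify the generator against its own model.
    """

    snps: pd.DataFrame  # id, selected, beta
    related_pairs: list[tuple[str, str]]
    focal_covariate: pd.Series  # standardized gradient per population
    omega: np.ndarray
    ancestral_freq: np.ndarray  # pi per SNP
    pop_frequencies: np.ndarray  # alpha, (n_snps, J)


# ---------------------------------------------------------------------------
# Omega
# ---------------------------------------------------------------------------

def _omega_from_newick(newick: str, n_populations: int) -> np.ndarray:
    """Brownian covariance of a rooted tree: cov(i, j) = depth of MRCA(i, j)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = list(tree.leaf_node_iter())
    if len(leaves) != n_populations:
        raise ValueError(f"tree has {len(leaves)} leaves, expected {n_populations}")

    depth: dict = {}

    def fill(node, d):
        d = d + (node.edge.length or 0.0)
        depth[node] = d
        for child in node.child_nodes():
            fill(child, d)

    fill(tree.seed_node, 0.0)

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    omega = np.empty((len(leaves), len(leaves)))
    anc = [ancestors(lf) for lf in leaves]
    for i, lf_i in enumerate(leaves):
        omega[i, i] = depth[lf_i]
        set_i = set(anc[i])
        for j in range(i + 1, len(leaves)):
            mrca = next(n for n in anc[j] if n in set_i)
            omega[i, j] = omega[j, i] = depth[mrca]
    return omega


def hierarchical_omega(
    n_populations: int,
    n_clades: int = 4,
    b_own: float = 0.008,
    b_clade: float = 0.003,
    b_root: float = 0.001,
) -> np.ndarray:
    """Clade-structured drift covariance: own + shared-clade + shared-root branches.

    Defaults give diagonal ~0.012, i.e. genome-wide differentiation near the
    FST ~ 0.01 regime of a widespread, weakly structured species.
    """
    J = n_populations
    omega = np.full((J, J), b_root)
    clade = np.array_split(np.arange(J), n_clades)
    for members in clade:
        omega[np.ix_(members, members)] += b_clade
    omega[np.diag_indices(J)] += b_own
    return omega


def generate_omega(omega_spec, n_populations: int, seed: int | None = None) -> np.ndarray:
    """Build/validate a J x J SPD allele-frequency covariance matrix.

    ``omega_spec`` may be None (hierarchical default), a newick string whose
    branch lengths give Brownian drift covariances, or an explicit SPD matrix.
    """
    if n_populations < 2:
        raise ValueError("need at least 2 populations")
    if omega_spec is None:
        omega = hierarchical_omega(n_populations)
    elif isinstance(omega_spec, str):
        omega = _omega_from_newick(omega_spec, n_populations)
    else:
        omega = np.asarray(omega_spec, dtype=float)
        if omega.shape != (n_populations, n_populations):
            raise ValueError(f"explicit matrix has shape {omega.shape}, expected "
                             f"({n_populations}, {n_populations})")
    if not np.allclose(omega, omega.T, atol=1e-10):
        raise ValueError("omega matrix is not symmetric")
    eigvals = np.linalg.eigvalsh(omega)
    if eigvals[0] <= 0:
        raise ValueError(
            f"omega matrix is not positive definite (smallest eigenvalue {eigvals[0]:.3g})"
        )
    return omega


# ---------------------------------------------------------------------------
# Genotypes + climate
# ---------------------------------------------------------------------------

def _chromosome_layout(rng: np.random.Generator, n_snps: int):
    """Assign SNPs to chromosomes: autosomes, ~10% Z, ~2% unplaced (chr35)."""
    chroms = list(AUTOSOMES) + [Z_CHROM, UNPLACED_CHROM]
    weights = np.array([0.22, 0.22, 0.22, 0.22, 0.10, 0.02])
    assignment = rng.choice(len(chroms), size=n_snps, p=weights)
    chrom = np.array(chroms, dtype=object)[assignment]
    span = 1_400_000  # matched to the toy gene layout so most SNPs are genic
    pos = np.zeros(n_snps, dtype=np.int64)
    for c in chroms:
        mask = assignment == chroms.index(c)
        k = int(mask.sum())
        p = rng.choice(np.arange(1, span), size=k, replace=False)
        p.sort()
        pos[mask] = p
    return chrom, pos


def _climate_table(rng: np.random.Generator, config: SimConfig, pops: list[str]):
    """Climate variables as loadings on two latent site gradients plus noise."""
    J = config.n_populations
    g1 = rng.normal(size=J)
    g2 = rng.normal(size=J)
    focal = (g1 - g1.mean()) / g1.std()
    nv = config.n_climate_vars
    n_g1 = int(np.ceil(0.55 * nv))  # gradient 1 dominates -> PC1 tracks it
    data = {}
    names = BIOCLIM_NAMES if nv == 22 else [f"climvar{i:02d}" for i in range(1, nv + 1)]
    for v in range(nv):
        g = g1 if v < n_g1 else g2
        loading = rng.uniform(0.75, 1.0) * rng.choice([-1.0, 1.0])
        x = loading * g + rng.normal(scale=0.35, size=J)
        mu = rng.uniform(-5.0, 20.0)
        scale = 10.0 ** rng.uniform(-1.0, 1.5)  # mixed units
        data[names[v]] = mu + scale * x
    climate = pd.DataFrame(data, index=pd.Index(pops, name="site"))
    return climate, pd.Series(focal, index=pops, name="focal_gradient")


def simulate_dataset(config: SimConfig):
    """Simulate genotypes + metadata, climate table, and the truth table.

    Returns ``(GenotypeMatrix, climate DataFrame, TruthTable)``.  Fully
    deterministic given the config (single RNG stream).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    J, S = config.n_populations, config.n_snps
    pops = [f"pop{j + 1:02d}" for j in range(J)]

    omega = generate_omega(config.omega_spec, J)
    climate, focal = _climate_table(rng, config, pops)
    c = focal.to_numpy()

    a, b = config.freq_beta_params
    pi = rng.beta(a, b, size=S)
    selected = np.zeros(S, dtype=bool)
    chrom, pos = _chromosome_layout(rng, S)
    placed = chrom != UNPLACED_CHROM
    if config.n_selected_snps:
        sel_idx = rng.choice(np.flatnonzero(placed), size=config.n_selected_snps, replace=False)
        selected[sel_idx] = True
        # selection acts on standing mid-frequency variation
        pi[sel_idx] = rng.uniform(0.2, 0.8, size=config.n_selected_snps)

    L = np.linalg.cholesky(omega)
    m = rng.standard_normal((S, J)) @ L.T
    beta = np.where(selected, config.effect_size_beta, 0.0)
    m = m + beta[:, None] * c[None, :]
    s = np.sqrt(pi * (1.0 - pi))
    alpha = np.clip(pi[:, None] + s[:, None] * m, CLAMP_EPS, 1.0 - CLAMP_EPS)

    # individuals
    n_ind = config.n_individuals_per_pop
    sample_rows = []
    for j, p in enumerate(pops):
        for k in range(n_ind):
            sample_rows.append({
                "id": f"{p}_ind{k + 1:03d}",
                "population": p,
                "sex": "M" if rng.random() < 0.5 else "F",
            })
    samples = pd.DataFrame(sample_rows)
    N = len(samples)

    G = np.empty((N, S), dtype=np.int8)
    for j in range(J):
        rows = slice(j * n_ind, (j + 1) * n_ind)
        G[rows, :] = rng.binomial(2, alpha[:, j], size=(n_ind, S)).astype(np.int8)
    # hemizygous females on Z carry a single allele
    z_mask = chrom == Z_CHROM
    female = (samples["sex"] == "F").to_numpy()
    for j in range(J):
        rows = np.arange(j * n_ind, (j + 1) * n_ind)
        frows = rows[female[rows]]
        if frows.size and z_mask.any():
            G[np.ix_(frows, np.flatnonzero(z_mask))] = rng.binomial(
                1, alpha[z_mask, j], size=(frows.size, int(z_mask.sum()))
            ).astype(np.int8)

    # close-relative pairs: copy ~50% of sites wholesale (expected relatedness ~0.5)
    related_pairs: list[tuple[str, str]] = []
    for j in range(min(config.n_related_pairs, J)):
        rows = np.arange(j * n_ind, (j + 1) * n_ind)
        same_sex = rows[samples["sex"].to_numpy()[rows] == samples["sex"].to_numpy()[rows][0]]
        if same_sex.size < 2:
            continue
        a_i, b_i = same_sex[0], same_sex[1]
        copy = rng.random(S) < 0.5
        G[b_i, copy] = G[a_i, copy]
        related_pairs.append((samples["id"].iloc[a_i], samples["id"].iloc[b_i]))

    if config.missing_rate > 0:
        G[rng.random(G.shape) < config.missing_rate] = MISSING

    snps = pd.DataFrame({
        "id": [f"snp{i + 1:06d}" for i in range(S)],
        "chrom": chrom,
        "pos": pos,
        "ref": "A",
        "alt": "G",
    })
    gm = GenotypeMatrix(samples=samples, snps=snps, G=G, z_chrom=Z_CHROM)
    truth = TruthTable(
        snps=pd.DataFrame({"id": snps["id"], "selected": selected, "beta": beta}),
        related_pairs=related_pairs,
        focal_covariate=focal,
        omega=omega,
        ancestral_freq=pi,
        pop_frequencies=alpha,
    )
    return gm, climate, truth


# ---------------------------------------------------------------------------
# Toy gene models + GO DAG
# ---------------------------------------------------------------------------

@dataclass
class SimulatedOntology:
    genes: pd.DataFrame      # gene_id, chrom, start, end, strand
    terms: pd.DataFrame      # term, namespace, level
    edges: pd.DataFrame      # child, parent (is_a)
    gene2go: pd.DataFrame    # gene_id, term


def simulate_ontology(config: SimConfig) -> SimulatedOntology:
    """Toy gene models on the simulated chromosomes plus a toy GO DAG.

    The DAG is acyclic with a single root by construction: terms are placed on
    levels 1..4 and each non-root term draws 1-2 parents from strictly lower
    levels.  A configurable ~85% of genes receive 1-3 term annotations.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])

    gene_rows = []
    counter = 1
    for chrom in list(AUTOSOMES) + [Z_CHROM]:
        cursor = 1
        for _ in range(config.genes_per_chrom):
            cursor += int(rng.integers(2_000, 8_000))
            length = int(rng.integers(10_000, 30_000))
            gene_rows.append({
                "gene_id": f"gene{counter:04d}",
                "chrom": chrom,
                "start": cursor,
                "end": cursor + length - 1,
                "strand": "+" if rng.random() < 0.5 else "-",
            })
            cursor += length
            counter += 1
    genes = pd.DataFrame(gene_rows)

    n_terms = config.n_go_terms
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    level = np.zeros(n_terms, dtype=int)
    for t in range(1, n_terms):
        level[t] = min(t, int(rng.integers(1, 5)))  # first terms seed low levels
    edge_rows = []
    for t in range(1, n_terms):
        shallower = np.flatnonzero(level < level[t])
        n_par = 1 + int(rng.random() < 0.3)
        parents = rng.choice(shallower, size=min(n_par, shallower.size), replace=False)
        for p in parents:
            edge_rows.append({"child": terms[t], "parent": terms[p]})
    edges = pd.DataFrame(edge_rows)
    terms_df = pd.DataFrame({
        "term": terms,
        "namespace": "biological_process",
        "level": level,
    })

    g2g_rows = []
    non_root = terms[1:]
    for gid in genes["gene_id"]:
        if rng.random() < 0.85:
            k = min(int(rng.integers(1, 4)), len(non_root))
            for term in rng.choice(non_root, size=k, replace=False):
                g2g_rows.append({"gene_id": gid, "term": term})
    gene2go = pd.DataFrame(g2g_rows).drop_duplicates().reset_index(drop=True)
    return SimulatedOntology(genes=genes, terms=terms_df, edges=edges, gene2go=gene2go)


# ---------------------------------------------------------------------------
# Writers for the on-disk interfaces
# ---------------------------------------------------------------------------

def write_gff3(genes: pd.DataFrame, path: str) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\tclimagea_sim\tgene\t{g['start']}\t{g['end']}\t."
                f"\t{g['strand']}\t.\tID={g['gene_id']}\n"
            )


def write_ontology_edges(edges: pd.DataFrame, path: str) -> None:
    edges[["child", "parent"]].to_csv(path, sep="\t", index=False)


def write_gene2go(gene2go: pd.DataFrame, path: str) -> None:
    gene2go[["gene_id", "term"]].to_csv(path, sep="\t", index=False)


def write_truth_table(truth: TruthTable, path: str) -> None:
    truth.snps.to_csv(path, sep="\t", index=False)
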