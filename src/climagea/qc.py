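"""Genotype quality control: MAF, call-rate, unplaced chromosomes,
relatedness pruning, Z-chromosome sex handling, minimum population size.

Thresholds default to the usual SNP-chip pipeline values (MAF >= 0.01,
call-rate >= 0.8, relatedness cutoff 0.25, >= 15 individuals per population).
MAF and call-rate thresholds are inclusive keep-thresholds.  The call-rate is
the proportion of *eligible* individuals typed at a SNP: once female Z calls
have been masked, the Z denominator is the number of males.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MAF / SNP filters
# ---------------------------------------------------------------------------

def compute_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency over non-missing alleles (ploidy-aware).

    SNPs with no non-missing calls get NaN (undefined MAF); downstream
    filtering removes them with a logged count.
    """
    observed = gm.G != MISSING
    ploidy = gm.ploidy()
    alt = np.where(observed, gm.G, 0).astype(np.int64)
    n_alt = alt.sum(axis=0)
    n_tot = np.where(observed, ploidy, 0).astype(np.int64).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n_tot > 0, n_alt / np.maximum(n_tot, 1), np.nan)
    maf = np.minimum(af, 1.0 - af)
    n_undef = int(np.isnan(maf).sum())
    if n_undef:
        logger.info("MAF undefined (all calls missing) for %d SNPs", n_undef)
    return maf


def call_rate(gm: GenotypeMatrix) -> np.ndarray:
    """Proportion of eligible individuals typed at each SNP.

    After female Z masking, females are not eligible for Z SNPs.
    """
    observed = (gm.G != MISSING).sum(axis=0)
    denom = np.full(gm.n_snps, gm.n_samples, dtype=float)
    if gm.z_females_masked:
        n_males = int((gm.samples["sex"] == "M").sum())
        denom[gm.is_z()] = n_males
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, observed / np.maximum(denom, 1), 0.0)


def filter_snps(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    callrate_min: float = 0.8,
    drop_unplaced: bool = True,
    unplaced_chroms: tuple[str, ...] = ("chr35",),
):
    """Keep SNPs with MAF >= maf_min, call-rate >= callrate_min, placed chrom.

    Thresholds are inclusive; SNP order is preserved.  Returns the filtered
    matrix and a per-criterion removal report.
    """
    if not (0 <= maf_min <= 1 and 0 <= callrate_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    maf = compute_maf(gm)
    cr = call_rate(gm)
    undefined = np.isnan(maf)
    fail_maf = ~undefined & (maf < maf_min)
    fail_cr = cr < callrate_min
    fail_unplaced = (
        gm.snps["chrom"].isin(unplaced_chroms).to_numpy()
        if drop_unplaced
        else np.zeros(gm.n_snps, dtype=bool)
    )
    keep = ~(undefined | fail_maf | fail_cr | fail_unplaced)
    report = pd.DataFrame(
        {
            "criterion": ["all_missing", "maf", "call_rate", "unplaced_chrom", "kept"],
            "count": [
                int(undefined.sum()),
                int(fail_maf.sum()),
                int(fail_cr.sum()),
                int(fail_unplaced.sum()),
                int(keep.sum()),
            ],
        }
    )
    for _, row in report.iterrows():
        logger.info("filter_snps %s: %d", row["criterion"], row["count"])
    if keep.sum() == 0:
        logger.warning("all SNPs removed by filters")
    return gm.take_snps(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def relatedness_matrix(gm: GenotypeMatrix, autosomes_only: bool = True) -> pd.DataFrame:
    """Method-of-moments pairwise relatedness.

    Entry (k, l) is the mean over informative SNPs of
    ``(x_ik - 2 p_i)(x_il - 2 p_i) / (2 p_i (1 - p_i))`` with ``p_i`` the
    sample alternate-allele frequency.  Monomorphic SNPs and pairs with a
    missing call at a SNP are skipped; Z SNPs are excluded (the estimator
    assumes diploid dosages).  Diagonal entries estimate 1 + inbreeding.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 individuals")
    snp_mask = ~gm.is_z() if autosomes_only else np.ones(gm.n_snps, dtype=bool)
    G = gm.G[:, snp_mask].astype(np.float64)
    obs = G != MISSING
    G[~obs] = np.nan
    n_tot = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(G, axis=0) / n_tot
    poly = (p > 0) & (p < 1) & (n_tot > 0)
    if poly.sum() == 0:
        raise ValueError("no informative (polymorphic) SNPs for relatedness")
    if poly.sum() < 50:
        warnings.warn(
            f"only {int(poly.sum())} informative SNPs for relatedness; "
            "estimates are noisy"
        )
    G = G[:, poly]
    obs = obs[:, poly]
    p = p[poly]
    denom = 2.0 * p * (1.0 - p)
    B = (G - 2.0 * p) / np.sqrt(denom)
    B[~obs] = 0.0
    num = B @ B.T
    counts = obs.astype(np.float64) @ obs.astype(np.float64).T
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(counts > 0, num / np.maximum(counts, 1), np.nan)
    ids = gm.samples["id"].tolist()
    return pd.DataFrame(R, index=ids, columns=ids)


def prune_related(
    relatedness: pd.DataFrame,
    cutoff: float = 0.25,
    call_rates: pd.Series | None = None,
) -> list[str]:
    """Greedy pruning so that no kept pair has relatedness > cutoff.

    Repeatedly removes the individual with the most above-cutoff partners;
    ties are broken by lower call rate, then by removing the lexicographically
    last id.  Returns the kept ids in input order.
    """
    R = relatedness.to_numpy(dtype=float)
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-8, equal_nan=True):
        raise ValueError("relatedness matrix must be square and symmetric")
    ids = list(relatedness.index)
    adj = np.nan_to_num(R) > cutoff
    np.fill_diagonal(adj, False)
    alive = np.ones(len(ids), dtype=bool)
    cr = (
        call_rates.reindex(ids).to_numpy(dtype=float)
        if call_rates is not None
        else np.ones(len(ids))
    )
    while True:
        deg = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max() == 0:
            break
        worst = np.flatnonzero(deg == deg.max())
        if worst.size > 1:
            worst = worst[cr[worst] == cr[worst].min()]
        if worst.size > 1:
            worst = [max(worst, key=lambda i: ids[i])]
        alive[worst[0]] = False
    kept = [ids[i] for i in np.flatnonzero(alive)]
    logger.info("relatedness pruning removed %d of %d individuals", len(ids) - len(kept), len(ids))
    return kept


# ---------------------------------------------------------------------------
# Sample subsetting
# ---------------------------------------------------------------------------

def subset_samples(
    gm: GenotypeMatrix,
    min_pop_size: int = 15,
    z_males_only: bool = True,
) -> GenotypeMatrix:
    """Drop populations below min_pop_size; mask female Z calls.

    Individuals with an unknown sex code are treated as female for the Z
    masking (conservative) and logged.  Autosomal calls are untouched.
    """
    sizes = gm.samples.groupby("population")["id"].count()
    keep_pops = set(sizes[sizes >= min_pop_size].index)
    dropped = sorted(set(sizes.index) - keep_pops)
    if dropped:
        logger.info("dropping %d populations below %d individuals: %s",
                    len(dropped), min_pop_size, ", ".join(dropped))
    idx = np.flatnonzero(gm.samples["population"].isin(keep_pops).to_numpy())
    out = gm.take_samples(idx)
    out = replace(out, G=out.G.copy())
    if z_males_only and out.z_chrom is not None:
        unknown = ~out.samples["sex"].isin(["M", "F"])
        if unknown.any():
            logger.warning("%d individuals with unknown sex treated as female for Z",
                           int(unknown.sum()))
        female = (out.samples["sex"] != "M").to_numpy()
        z = out.is_z()
        if z.any() and female.any():
            out.G[np.ix_(female, z)] = MISSING
        out = replace(out, z_females_masked=True)
    return out


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------

def qc_pipeline(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    callrate_min: float = 0.8,
    rel_cutoff: float = 0.25,
    min_pop_size: int = 15,
    z_males_only: bool = True,
    drop_unplaced: bool = True,
    unplaced_chroms: tuple[str, ...] = ("chr35",),
):
    """Full QC in pipeline order: sample subsetting -> relatedness pruning ->
    SNP filters (so allele frequencies are computed on the final sample set).

    Returns ``(filtered GenotypeMatrix, removal report DataFrame)``.
    """
    gm1 = subset_samples(gm, min_pop_size=min_pop_size, z_males_only=z_males_only)
    R = relatedness_matrix(gm1)
    ind_cr = pd.Series(
        (gm1.G != MISSING).mean(axis=1), index=gm1.samples["id"].tolist()
    )
    kept_ids = prune_related(R, cutoff=rel_cutoff, call_rates=ind_cr)
    keep_idx = np.flatnonzero(gm1.samples["id"].isin(kept_ids).to_numpy())
    gm2 = gm1.take_samples(keep_idx)
    gm3, report = filter_snps(
        gm2,
        maf_min=maf_min,
        callrate_min=callrate_min,
        drop_unplaced=drop_unplaced,
        unplaced_chroms=unplaced_chroms,
    )
    report = pd.concat(
        [
            report,
            pd.DataFrame(
                {
                    "criterion": ["samples_dropped_pop_size", "samples_dropped_related"],
                    "count": [
                        gm.n_samples - gm1.n_samples,
                        gm1.n_samples - gm2.n_samples,
                    ],
                }
            ),
        ],
        ignore_index=True,
    )
    return gm3, report
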