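"""SNP-to-gene annotation: the containing gene, or the nearest gene within a
symmetric window (default 2,500 bp, inclusive at the boundary) on either side.

Distances are measured from the SNP position to the nearest gene edge,
strand-ignored.  Ties are deterministic: among overlapping genes the one with
the smaller start (then id); among equidistant flanking genes the
lexicographically smallest gene id.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 2500


def _validate_gff_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line {lineno}: expected 9 fields, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"malformed GFF3 line {lineno}: non-integer coordinates") from exc
            if start <= 0:
                raise ValueError(f"malformed GFF3 line {lineno}: non-positive start")
            if end < start:
                raise ValueError(f"malformed GFF3 line {lineno}: end < start")


def read_gff_genes(path: str) -> pd.DataFrame:
    """Read gene features from GFF3, keeping 1-based inclusive coordinates.

    Non-gene features (mRNA, exon, ...) are ignored; malformed lines raise
    with their line number; duplicated gene ids are rejected.
    """
    import gffutils

    _validate_gff_lines(path)
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append({
            "gene_id": feat.id,
            "chrom": feat.seqid,
            "start": feat.start,
            "end": feat.end,
            "strand": feat.strand,
        })
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicated gene id {dup!r} in {path}")
    logger.info("read %d gene models from %s", len(genes), path)
    return genes


def _resolve_tie(dist_row: np.ndarray, starts: np.ndarray, gene_ids: np.ndarray) -> int:
    """Index of the winning gene among a candidate row of distances."""
    dmin = dist_row.min()
    tied = np.flatnonzero(dist_row == dmin)
    if tied.size == 1:
        return int(tied[0])
    if dmin == 0:  # overlapping genes: smaller start, then id
        order = sorted(tied, key=lambda t: (starts[t], gene_ids[t]))
        logger.debug("SNP inside %d overlapping genes; choosing %s", tied.size, gene_ids[order[0]])
    else:  # equidistant flanking genes: smallest id
        order = sorted(tied, key=lambda t: gene_ids[t])
    return int(order[0])


def annotate_snps(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Assign each SNP to its containing/nearest gene within ``window`` bp.

    ``snps`` needs columns ``id``, ``chrom``, ``pos`` (1-based).  Returns a
    DataFrame indexed by SNP id with ``gene_id`` (None when unannotated) and
    signed ``distance`` (negative upstream of the gene start, 0 inside,
    positive downstream of the gene end).  SNPs on chromosomes absent from
    the gene set are unannotated, not errors.
    """
    gene_id_out = np.full(len(snps), None, dtype=object)
    distance_out = np.full(len(snps), np.nan)
    by_chrom = {c: g.reset_index(drop=True) for c, g in genes.groupby("chrom")}

    for chrom, snp_idx in snps.groupby("chrom").indices.items():
        g = by_chrom.get(chrom)
        if g is None:
            continue
        starts = g["start"].to_numpy(dtype=np.int64)
        ends = g["end"].to_numpy(dtype=np.int64)
        ids = g["gene_id"].to_numpy(dtype=object)
        pos = snps["pos"].to_numpy(dtype=np.int64)[snp_idx]
        for chunk_start in range(0, len(snp_idx), 4096):
            rows = snp_idx[chunk_start:chunk_start + 4096]
            p = pos[chunk_start:chunk_start + 4096][:, None]
            signed = np.where(p < starts, p - starts, np.where(p > ends, p - ends, 0))
            dist = np.abs(signed)
            dmin = dist.min(axis=1)
            hit = dmin <= window
            arg = np.argmin(dist, axis=1)
            multi = (dist == dmin[:, None]).sum(axis=1) > 1
            for local in np.flatnonzero(hit & multi):
                arg[local] = _resolve_tie(dist[local], starts, ids)
            for local in np.flatnonzero(hit):
                r = rows[local]
                gene_id_out[r] = ids[arg[local]]
                distance_out[r] = signed[local, arg[local]]

    out = pd.DataFrame(
        {"gene_id": gene_id_out, "distance": distance_out},
        index=pd.Index(snps["id"], name="snp"),
    )
    n_un = int(out["gene_id"].isna().sum())
    logger.info("annotated %d of %d SNPs (%d unannotated)", len(out) - n_un, len(out), n_un)
    return out


def write_annotation(ann: pd.DataFrame, path: str) -> None:
    ann.to_csv(path, sep="\t", index=True)


def read_annotation(path: str) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="snp")
    ann["gene_id"] = ann["gene_id"].where(ann["gene_id"].notna(), None)
    return ann
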