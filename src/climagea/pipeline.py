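"""End-to-end pipeline: QC -> climate PCA -> replicated association scan ->
POD calibration -> candidate selection -> annotation -> gene scores -> GO
enrichment, with every stage's outputs and the resolved configuration
written to a run directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import candidates as cand_mod
from . import climate as climate_mod
from . import gea, ontology, pod, qc
from . import simulate as sim_mod
from .io import (
    GenotypeMatrix,
    read_climate_table,
    read_vcf,
    write_climate_table,
    write_sample_metadata,
    write_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the pipeline's standard thresholds
    (MAF 0.01, call-rate 0.8, relatedness 0.25, >=15/pop, 4 climate PCs,
    3 scan seeds, 1% POD alpha, 2,500 bp annotation window, GO node size 10,
    Jeffreys bounds 10/15/20 dB)."""

    outdir: str = "climagea_run"
    # inputs (either simulate, or all paths set)
    simulate: bool = True
    sim: "sim_mod.SimConfig" = field(default_factory=sim_mod.SimConfig)
    vcf: str | None = None
    meta: str | None = None
    climate: str | None = None
    gff: str | None = None
    ontology_edges: str | None = None
    gene2go: str | None = None
    z_chrom: str | None = sim_mod.Z_CHROM
    # qc
    maf_min: float = 0.01
    callrate_min: float = 0.8
    rel_cutoff: float = 0.25
    min_pop_size: int = 15
    unplaced_chroms: tuple[str, ...] = (sim_mod.UNPLACED_CHROM,)
    # climate pca
    n_components: int = 4
    # scan
    seeds: tuple[int, ...] = (1, 2, 3)
    n_mc: int = 1000
    prior_sd: float = 0.2
    covariate_names: tuple[str, ...] | None = None  # default: all retained PCs
    # pod
    n_pod: int = 50_000
    pod_alpha: float = 0.01
    pod_seed: int = 11
    # annotation / enrichment
    window: int = 2500
    node_size: int = 10
    elim_cutoff: float = 0.01

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim_raw:
            cfg = replace(cfg, sim=sim_mod.SimConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in sim_raw.items()
            }))
        return cfg

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        spec = d["sim"].get("omega_spec")
        if isinstance(spec, np.ndarray):
            d["sim"]["omega_spec"] = spec.tolist()
        d["unplaced_chroms"] = list(d["unplaced_chroms"])
        d["seeds"] = list(d["seeds"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, default_flow_style=False, sort_keys=False)


def _stage(summary: dict, name: str, t0: float, **info) -> float:
    # wall times go to the log only, so summary.json is identical across reruns
    t1 = time.perf_counter()
    summary["stages"][name] = dict(info)
    logger.info("stage %s done in %.2fs %s", name, t1 - t0, info)
    return time.perf_counter()


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write all outputs under ``config.outdir``.

    Returns the summary dict (also written as ``summary.json``).  Fully
    deterministic under fixed seeds.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "parameters": asdict(config)}
    t0 = time.perf_counter()

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        gm, climate_df, truth = sim_mod.simulate_dataset(config.sim)
        onto = sim_mod.simulate_ontology(config.sim)
        write_vcf(gm, str(out / "genotypes.vcf"))
        write_sample_metadata(gm.samples, str(out / "samples.tsv"))
        write_climate_table(climate_df, str(out / "climate.tsv"))
        sim_mod.write_gff3(onto.genes, str(out / "genes.gff3"))
        sim_mod.write_ontology_edges(onto.edges, str(out / "ontology_edges.tsv"))
        sim_mod.write_gene2go(onto.gene2go, str(out / "gene2go.tsv"))
        sim_mod.write_truth_table(truth, str(out / "truth.tsv"))
        go_edges, gene2go = onto.edges, onto.gene2go
        genes = onto.genes.rename(columns={})
        gff_path = str(out / "genes.gff3")
        namespaces = dict(zip(onto.terms["term"], onto.terms["namespace"]))
    else:
        for name in ("vcf", "meta", "climate", "gff", "ontology_edges", "gene2go"):
            if getattr(config, name) is None:
                raise ValueError(f"input path {name!r} required when simulate=False")
        gm = read_vcf(config.vcf, config.meta, z_chrom=config.z_chrom)
        climate_df = read_climate_table(config.climate)
        gff_path = config.gff
        go_edges = pd.read_csv(config.ontology_edges, sep="\t")
        gene2go = pd.read_csv(config.gene2go, sep="\t")
        namespaces = None
    t0 = _stage(summary, "inputs", t0, n_samples=gm.n_samples, n_snps=gm.n_snps)

    # --- qc ---------------------------------------------------------------
    gm_f, report = qc.qc_pipeline(
        gm,
        maf_min=config.maf_min,
        callrate_min=config.callrate_min,
        rel_cutoff=config.rel_cutoff,
        min_pop_size=config.min_pop_size,
        unplaced_chroms=config.unplaced_chroms,
    )
    report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    t0 = _stage(summary, "qc", t0, n_samples=gm_f.n_samples, n_snps=gm_f.n_snps)

    # --- climate pca ------------------------------------------------------
    pops = sorted(gm_f.samples["population"].unique())
    pcs = climate_mod.run_climate_pca(climate_df.loc[pops], n_components=config.n_components)
    climate_mod.write_pcs(pcs, str(out / "climate_pcs.tsv"))
    t0 = _stage(
        summary, "pca", t0,
        variance_fraction_retained=float(pcs.variance_fractions[: config.n_components].sum()),
    )

    # --- omega + scan -----------------------------------------------------
    counts = gea.pop_allele_frequencies(gm_f)
    model = gea.estimate_omega(counts)
    np.savetxt(out / "omega.tsv", model.omega, delimiter="\t")
    cov_names = list(config.covariate_names or pcs.scores.columns)
    scan = gea.run_replicates(
        counts, model, pcs.scores[cov_names],
        seeds=config.seeds, n_mc=config.n_mc, prior_sd=config.prior_sd,
    )
    t0 = _stage(summary, "scan", t0, seeds=list(config.seeds), covariates=cov_names)

    # --- pod --------------------------------------------------------------
    null = pod.build_pod_null(
        model, pod.observed_sample_sizes(counts),
        n_snps=config.n_pod, alpha=config.pod_alpha, seed=config.pod_seed,
    )
    scan.attach_outliers(null.threshold)
    pd.DataFrame({"xtx_null": null.values}).to_csv(out / "pod_null.tsv", sep="\t", index=False)
    with open(out / "pod_threshold.json", "w") as fh:
        json.dump({"statistic": null.statistic, "alpha": null.alpha,
                   "n_pod": null.n_pod, "threshold": null.threshold}, fh, indent=2)
    scan.to_frame().to_csv(out / "scan.tsv", sep="\t", index=False)
    n_out = int(np.nansum(scan.outlier))
    t0 = _stage(summary, "pod", t0, threshold=null.threshold, n_outliers=n_out)

    # --- annotation -------------------------------------------------------
    genes_df = annotate_mod.read_gff_genes(gff_path)
    ann = annotate_mod.annotate_snps(gm_f.snps, genes_df, window=config.window)
    annotate_mod.write_annotation(ann, str(out / "annotation.tsv"))
    t0 = _stage(summary, "annotate", t0, n_annotated=int(ann["gene_id"].notna().sum()))

    # --- candidates -------------------------------------------------------
    cands = cand_mod.select_candidates(scan, ann)
    counts_df = cands.counts()
    n_tested = int(np.isfinite(scan.xtx).sum())
    p0 = max(n_out, 1) / max(n_tested, 1)
    pvals = {}
    for _, row in counts_df.iterrows():
        if row["n_annotated"] > 0:
            pvals[row["covariate"]] = cand_mod.overlap_binomial_test(
                int(row["n_annotated_outlier"]), int(row["n_annotated"]), p0
            )
    counts_df.to_csv(out / "candidate_counts.tsv", sep="\t", index=False)
    cand_rows = []
    for cov, d in cands.per_covariate.items():
        k = scan.covariates.index(cov)
        md = pd.Series(scan.min_db[k], index=scan.snp_ids)
        xs = pd.Series(scan.xtx, index=scan.snp_ids)
        ol = pd.Series(scan.outlier, index=scan.snp_ids)
        for snp in d["decisive"]:
            cand_rows.append({
                "snp": snp, "covariate": cov,
                "min_db": float(md.loc[snp]),
                "evidence": "decisive",
                "xtx": float(xs.loc[snp]),
                "outlier": bool(ol.loc[snp]),
                "gene": ann.loc[snp, "gene_id"],
                "distance": ann.loc[snp, "distance"],
            })
    pd.DataFrame(
        cand_rows,
        columns=["snp", "covariate", "min_db", "evidence", "xtx", "outlier", "gene", "distance"],
    ).to_csv(out / "candidates.tsv", sep="\t", index=False)
    t0 = _stage(summary, "candidates", t0, p0=p0,
                counts=counts_df.to_dict(orient="records"), overlap_p=pvals)

    # --- gene scores + enrichment ----------------------------------------
    dag = None
    enrich_counts = {}
    for cov in cov_names:
        st = ontology.gene_scores(scan, ann, covariate=cov)
        st.table.to_csv(out / f"gene_scores_{cov}.tsv", sep="\t", index=False)
        if dag is None:
            dag = ontology.propagate_annotations(
                go_edges, gene2go, st.universe, namespaces=namespaces
            )
        results = []
        for alg in ("classic", "elim"):
            results.append(ontology.run_enrichment(
                dag, st, algorithm=alg,
                node_size=config.node_size, elim_cutoff=config.elim_cutoff,
            ))
        merged = results[0].rename(columns={"p": "p_classic"}).drop(columns=["algorithm"])
        merged = merged.merge(
            results[1][["term", "p"]].rename(columns={"p": "p_elim"}), on="term", how="outer"
        )
        merged.to_csv(out / f"enrichment_{cov}.tsv", sep="\t", index=False)
        enrich_counts[cov] = int(len(merged))
    t0 = _stage(summary, "enrichment", t0, n_terms_tested=enrich_counts)

    # --- manhattan-style output + summary ---------------------------------
    man = {"chrom": scan.chrom, "pos": scan.pos}
    for cov in cov_names:
        k = scan.covariates.index(cov)
        man[f"min_db_{cov}"] = scan.min_db[k]
        man[f"class_{cov}"] = cand_mod.classify_evidence(scan.min_db[k])
    pd.DataFrame(man).to_csv(out / "manhattan.tsv", sep="\t", index=False)

    config.to_yaml(str(out / "resolved_config.yaml"))
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
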