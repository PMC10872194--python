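"""Candidate climate-adaptation loci: Jeffreys evidence classes on the
min-across-runs Bayes factor, intersection with XtX outliers, and a binomial
test of the overlap between association and differentiation calls.

Jeffreys' rule on deciban Bayes factors: 10 < dB <= 15 "strong",
15 < dB <= 20 "very strong", dB > 20 "decisive".  Because the classified
quantity is the minimum dB across replicate runs, a decisive SNP scored
above 20 in every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .gea import SnpScanResult

logger = logging.getLogger(__name__)

EVIDENCE_BOUNDS = (10.0, 15.0, 20.0)
EVIDENCE_CLASSES = ("below_strong", "strong", "very_strong", "decisive")


def classify_evidence(min_db) -> np.ndarray | str:
    """Map min-across-runs dB to Jeffreys evidence classes.

    Half-open intervals: (10, 15] strong, (15, 20] very_strong, > 20
    decisive; anything <= 10 (including NaN, i.e. untestable SNPs) is
    below_strong.  Scalar in, scalar out.
    """
    x = np.asarray(min_db, dtype=float)
    lo, mid, hi = EVIDENCE_BOUNDS
    with np.errstate(invalid="ignore"):
        out = np.select(
            [x > hi, x > mid, x > lo],
            [EVIDENCE_CLASSES[3], EVIDENCE_CLASSES[2], EVIDENCE_CLASSES[1]],
            default=EVIDENCE_CLASSES[0],
        )
    if np.isscalar(min_db) or np.ndim(min_db) == 0:
        return str(out)
    return out


@dataclass
class CandidateSet:
    """Per-covariate decisive SNPs, their annotated and outlier subsets."""

    per_covariate: dict[str, dict] = field(default_factory=dict)

    def counts(self) -> pd.DataFrame:
        rows = []
        for cov, d in self.per_covariate.items():
            rows.append({
                "covariate": cov,
                "n_decisive": len(d["decisive"]),
                "n_annotated": len(d["annotated"]),
                "n_annotated_outlier": len(d["annotated_outlier"]),
            })
        return pd.DataFrame(rows)


def select_candidates(
    scan: SnpScanResult,
    annotation_map: pd.DataFrame,
    covariates: list[str] | None = None,
) -> CandidateSet:
    """Decisive SNPs per covariate, their gene-annotated subset, and the
    annotated SNPs that are also XtX outliers (the best candidates).

    ``annotation_map`` is indexed by SNP id with columns ``gene_id`` (None
    when unannotated) and ``distance``.
    """
    if scan.outlier is None:
        raise ValueError("scan has no outlier flags; attach a POD threshold first")
    covariates = covariates or scan.covariates
    out = CandidateSet()
    ann = annotation_map["gene_id"]
    for cov in covariates:
        if cov not in scan.covariates:
            raise ValueError(f"covariate {cov!r} absent from scan")
        k = scan.covariates.index(cov)
        classes = classify_evidence(scan.min_db[k])
        decisive = scan.snp_ids[classes == "decisive"]
        genes = ann.reindex(decisive)
        annotated = decisive[genes.notna().to_numpy()]
        outl = pd.Series(scan.outlier, index=scan.snp_ids).reindex(annotated)
        annotated_outlier = annotated[outl.to_numpy(dtype=bool)]
        out.per_covariate[cov] = {
            "decisive": list(decisive),
            "annotated": list(annotated),
            "annotated_outlier": list(annotated_outlier),
            "genes": sorted(set(ann.reindex(annotated_outlier).dropna())),
        }
        logger.info(
            "%s: %d decisive, %d in annotated genes, %d also XtX outliers",
            cov, len(decisive), len(annotated), len(annotated_outlier),
        )
    return out


def overlap_binomial_test(k_overlap: int, n_decisive_annotated: int, p0: float) -> float:
    """One-sided exact binomial tail P(X >= k | n, p0).

    Tests whether more of the (annotated) climate-associated SNPs are also
    XtX outliers than expected under the genome-wide outlier rate p0.
    """
    if n_decisive_annotated == 0:
        raise ValueError("overlap test undefined for n = 0")
    if not (0 <= k_overlap <= n_decisive_annotated):
        raise ValueError("require 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    return float(binomtest(k_overlap, n_decisive_annotated, p0, alternative="greater").pvalue)
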