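"""Pseudo-observed-data (POD) null calibration for XtX and Bayes factors.

POD datasets are simulated from the fitted neutral model (Omega, the Beta fit
to the ancestral frequencies, and the observed per-population sample sizes)
so that the null distribution of a statistic reflects the study's actual
demographic structure.  Empirical significance thresholds are order
statistics of the null sample; outlier calls use strict exceedance.  Omega is
deliberately NOT refit on the POD data: the observed-data model is reused on
both sides so the threshold measures SNP-level exceedance, not Omega
uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gea import AlleleCountTable, OmegaModel, xtx_statistics
from .simulate import CLAMP_EPS

logger = logging.getLogger(__name__)


@dataclass
class PodNull:
    """Null sample of a statistic with its empirical threshold."""

    statistic: str
    values: np.ndarray  # sorted ascending
    n_pod: int
    alpha: float
    threshold: float


def simulate_pod(
    model: OmegaModel,
    sample_sizes: np.ndarray,
    n_snps: int,
    seed: int,
) -> AlleleCountTable:
    """Simulate a neutral POD allele-count table from the fitted model.

    Per pseudo-SNP: pi ~ Beta(a, b); population frequencies via the
    truncated-Gaussian Omega model; counts binomial with the observed
    per-population allele totals.
    """
    if n_snps < 1000:
        raise ValueError("n_snps must be at least 1,000 for a POD null")
    sizes = np.asarray(sample_sizes, dtype=np.int64)
    if sizes.shape != (model.n_populations,):
        raise ValueError("sample_sizes must give one allele total per population")
    if (sizes <= 0).any():
        raise ValueError("per-population allele totals must be positive")
    rng = np.random.default_rng(seed)
    a, b = model.beta_params
    pi = rng.beta(a, b, size=n_snps)
    L = np.linalg.cholesky(model.omega)
    m = rng.standard_normal((n_snps, model.n_populations)) @ L.T
    s = np.sqrt(pi * (1 - pi))
    alpha = np.clip(pi[:, None] + s[:, None] * m, CLAMP_EPS, 1 - CLAMP_EPS)
    alt = rng.binomial(sizes[None, :], alpha)
    tot = np.broadcast_to(sizes, alt.shape).copy()
    return AlleleCountTable(
        populations=list(model.populations),
        snp_ids=np.array([f"pod{i + 1:06d}" for i in range(n_snps)]),
        alt=alt,
        tot=tot,
    )


def empirical_threshold(null_values: np.ndarray, alpha: float = 0.01) -> float:
    """Empirical (1 - alpha) threshold: the ceil((1 - alpha) N)-th order statistic.

    Guarantees that the fraction of null values strictly exceeding the
    threshold is at most alpha.
    """
    if not (0 < alpha <= 0.5):
        raise ValueError("alpha must lie in (0, 0.5]")
    values = np.asarray(null_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 100:
        raise ValueError("need at least 100 null values")
    values = np.sort(values)
    k = int(np.ceil((1.0 - alpha) * values.size))
    return float(values[k - 1])


def call_outliers(values: np.ndarray, threshold: float) -> np.ndarray:
    """Outlier flags by strict exceedance (value > threshold); NaN -> False."""
    v = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(v), v > threshold, False)


def build_pod_null(
    model: OmegaModel,
    sample_sizes: np.ndarray,
    n_snps: int = 50_000,
    alpha: float = 0.01,
    seed: int = 11,
) -> PodNull:
    """Simulate a POD table, compute its XtX null, and derive the threshold.

    Monomorphic pseudo-SNPs (undefined XtX) are dropped from the null sample
    before taking the order statistic.
    """
    counts = simulate_pod(model, sample_sizes, n_snps, seed)
    xtx = xtx_statistics(counts, model)
    values = np.sort(xtx[np.isfinite(xtx)])
    threshold = empirical_threshold(values, alpha)
    logger.info(
        "POD null (%d pseudo-SNPs, %d usable): %.1f%% XtX threshold = %.3f",
        n_snps, values.size, 100 * alpha, threshold,
    )
    return PodNull(statistic="XtX", values=values, n_pod=n_snps, alpha=alpha, threshold=threshold)


def observed_sample_sizes(counts: AlleleCountTable) -> np.ndarray:
    """Representative per-population allele totals (rounded mean over SNPs)."""
    sizes = np.rint(counts.tot.mean(axis=0)).astype(np.int64)
    return np.maximum(sizes, 1)
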