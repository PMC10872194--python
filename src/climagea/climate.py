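"""Principal component reduction of the site x climate-variable table.

The 22 climate variables (19 bioclim summaries plus solar radiation, wind
speed and vapour pressure in the motivating design) mix units, so a
correlation PCA is used: variables are standardized to unit variance before
decomposition.  The retained site scores are re-standardized to mean 0, SD 1
(population SD, ddof=0) after truncation, which is the scale on which the
association scan expects its covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class ClimatePCs:
    """Retained climate PCs: standardized site scores, loadings, variance fractions."""

    scores: pd.DataFrame            # sites x PC1..PCk, mean 0 / SD 1 each
    loadings: pd.DataFrame          # variables x PC1..PCk (sign-fixed)
    variance_fractions: np.ndarray  # over ALL components; sums to 1
    _table_mean: np.ndarray = field(repr=False, default=None)
    _table_sd: np.ndarray = field(repr=False, default=None)
    _components: np.ndarray = field(repr=False, default=None)  # all comps x vars
    _raw_scores: np.ndarray = field(repr=False, default=None)  # sites x all comps

    def reconstruct(self) -> pd.DataFrame:
        """Inverse transform using all components: the standardized table."""
        Z = self._raw_scores @ self._components
        return pd.DataFrame(Z, index=self.scores.index, columns=self.loadings.index)


def run_climate_pca(climate: pd.DataFrame, n_components: int = 4) -> ClimatePCs:
    """Correlation PCA of the climate table; retain ``n_components`` PCs.

    Sign convention: each loading vector is flipped so its largest-magnitude
    entry is positive.  Components are ordered by decreasing variance;
    variance fractions are reported over all components and sum to 1.
    """
    if climate.index.duplicated().any():
        raise ValueError("duplicate site ids in climate table")
    if climate.isna().any().any():
        raise ValueError("climate table contains missing cells")
    n_sites, n_vars = climate.shape
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if n_components > min(n_sites - 1, n_vars):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_sites - 1, n_variables) = "
            f"{min(n_sites - 1, n_vars)}"
        )
    X = climate.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"constant variable cannot be standardized: {climate.columns[zero[0]]!r}"
        )
    Z = (X - mean) / sd

    pca = PCA(n_components=None, svd_solver="full")
    raw = pca.fit_transform(Z)                       # sites x all comps
    components = pca.components_                     # all comps x vars
    # fix sign indeterminacy
    for k in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] = -components[k]
            raw[:, k] = -raw[:, k]
    fractions = pca.explained_variance_ratio_

    names = [f"PC{k + 1}" for k in range(n_components)]
    kept = raw[:, :n_components]
    with np.errstate(invalid="ignore", divide="ignore"):
        kept_std = (kept - kept.mean(axis=0)) / kept.std(axis=0)
    scores = pd.DataFrame(kept_std, index=climate.index, columns=names)
    loadings = pd.DataFrame(components[:n_components].T, index=climate.columns, columns=names)
    logger.info(
        "climate PCA: first %d components capture %.1f%% of variance",
        n_components, 100 * fractions[:n_components].sum(),
    )
    return ClimatePCs(
        scores=scores,
        loadings=loadings,
        variance_fractions=fractions,
        _table_mean=mean,
        _table_sd=sd,
        _components=components,
        _raw_scores=raw,
    )


def write_pcs(pcs: ClimatePCs, path: str) -> None:
    pcs.scores.to_csv(path, sep="\t", index=True, index_label="site")


def read_pcs(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site")
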