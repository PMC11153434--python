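"""Spearman correlation structure between radiomic features.

Supports building the feature-feature Spearman matrix over cases, deriving a
reference feature ordering by hierarchical clustering (so matrices from other
settings can be rendered in a fixed order), and a scalar similarity between
two correlation matrices (Pearson correlation of their upper triangles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = ["CorrelationMatrix", "spearman_matrix", "reference_order", "compare_matrices"]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric feature x feature Spearman matrix with its feature ordering."""

    matrix: pd.DataFrame  # features x features
    constant_features: list[str]

    @property
    def features(self) -> list[str]:
        return list(self.matrix.index)

    def reordered(self, order: list[str]) -> "CorrelationMatrix":
        if sorted(order) != sorted(self.features):
            raise ValueError("order must be a permutation of the features")
        return CorrelationMatrix(self.matrix.loc[order, order], self.constant_features)


def spearman_matrix(
    table: pd.DataFrame, feature_cols: list[str] | None = None
) -> CorrelationMatrix:
    """Pairwise Spearman correlations over subjects (rows of ``table``).

    Ties get average ranks.  Constant columns are flagged and their entries
    are NaN (except the unit diagonal).
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in ("case", "method", "mask_style")]
    data = table[feature_cols].to_numpy(dtype=np.float64)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a correlation matrix")

    constant = [c for c, v in zip(feature_cols, data.T) if np.all(v == v[0])]
    # Spearman = Pearson on average ranks; computed directly so constant
    # columns yield NaN entries instead of poisoning the whole matrix
    ranks = np.apply_along_axis(stats.rankdata, 0, data)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=np.float64)
    np.fill_diagonal(rho, 1.0)
    mat = pd.DataFrame(rho, index=feature_cols, columns=feature_cols)
    if constant:
        logger.info("%d constant feature columns flagged", len(constant))
    return CorrelationMatrix(matrix=mat, constant_features=constant)


def reference_order(m: CorrelationMatrix) -> list[str]:
    """Hierarchical-clustering leaf order on distance 1 - |rho| (average linkage).

    Undefined entries are treated as distance 1 (logged).  The returned list
    is a permutation of the features and is deterministic for fixed input.
    """
    rho = m.matrix.to_numpy().copy()
    n_undef = int(np.isnan(rho).sum())
    if n_undef:
        logger.info("%d undefined correlations treated as distance 1", n_undef)
    dist = 1.0 - np.abs(rho)
    dist = np.where(np.isnan(dist), 1.0, dist)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="average")
    order = leaves_list(z)
    return [m.features[i] for i in order]


def compare_matrices(m1: CorrelationMatrix, m2: CorrelationMatrix) -> float:
    """Pearson correlation of the vectorized upper triangles of two matrices.

    Undefined entries are dropped pairwise; 1 means identical structure.
    """
    if m1.features != m2.features:
        if sorted(m1.features) != sorted(m2.features):
            raise ValueError("matrices cover different feature sets")
        m2 = m2.reordered(m1.features)
    a = m1.matrix.to_numpy()
    b = m2.matrix.to_numpy()
    iu = np.triu_indices(len(a), k=1)
    x, y = a[iu], b[iu]
    keep = np.isfinite(x) & np.isfinite(y)
    if not keep.any():
        raise ValueError("no overlapping defined entries")
    x, y = x[keep], y[keep]
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("degenerate (constant) upper triangle")
    return float(stats.pearsonr(x, y).statistic)


def plot_triangle_heatmap(m: CorrelationMatrix, path: str, title: str = "") -> None:
    """Render the lower triangle of the correlation matrix to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rho = m.matrix.to_numpy().copy()
    rho[np.triu_indices(len(rho), k=1)] = np.nan
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(rho, vmin=-1, vmax=1, cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label="Spearman rho")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
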