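"""Global methylation pattern exploration across samples.

Operates on the sites-by-samples percent-methylation matrix of united
CpGs: variance-percentile site selection, 2-D embedding by t-SNE (small
perplexity, suited to a dozen samples) or PCA, Ward hierarchical
clustering and the Pearson sample-correlation matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE


def select_high_variance_sites(pct: pd.DataFrame, percentile: float = 95.0) -> pd.DataFrame:
    """Keep sites whose across-sample variance exceeds the given percentile.

    The cut is strict, so ties at the threshold are excluded; a constant
    matrix therefore yields an empty selection (with a warning).
    Percentile 0 keeps every non-degenerate (varying) site.
    """
    if pct.shape[1] < 2:
        raise ValueError("need at least two samples")
    var = pct.var(axis=1, ddof=1)
    cut = np.percentile(var.to_numpy(), percentile) if percentile > 0 else 0.0
    keep = var > cut
    if not keep.any():
        warnings.warn("variance selection kept no sites (constant matrix?)", stacklevel=2)
    return pct.loc[keep]


def embed_samples(
    pct: pd.DataFrame, method: str = "tsne", perplexity: float = 2.0, seed: int = 0
) -> pd.DataFrame:
    """2-D coordinates per sample, by t-SNE or the first two PCA scores."""
    X = pct.to_numpy().T  # samples x sites
    n = X.shape[0]
    if method == "pca":
        coords = PCA(n_components=2, random_state=seed).fit_transform(X)
    elif method == "tsne":
        if perplexity >= (n - 1) / 3:
            raise ValueError(f"perplexity {perplexity} too large for {n} samples (< (n-1)/3 required)")
        coords = TSNE(
            n_components=2, perplexity=perplexity, random_state=seed, init="pca", method="exact"
        ).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=pct.columns, columns=["dim1", "dim2"])


def cluster_samples(pct: pd.DataFrame):
    """Ward linkage on Euclidean sample distances plus Pearson correlations.

    Returns (linkage matrix in scipy format, correlation DataFrame).
    """
    if pct.shape[1] < 2:
        raise ValueError("need at least two samples")
    if pct.isna().to_numpy().any():
        raise ValueError("matrix contains missing values; unite sites first")
    X = pct.to_numpy().T
    Z = linkage(X, method="ward")
    corr = pct.corr(method="pearson")
    return Z, corr
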