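"""Sample-level embeddings of log-methylation-ratio matrices.

Follows the bisulfite-style workflow: select the most variable sites,
form pairwise sample distances as the root-mean-square difference of
log-methylation-ratios over those sites, then embed with classical
(Torgerson) multidimensional scaling. A site-centered PCA via SVD is
provided as the alternative linear embedding.

Both embeddings fix a sign convention (within each dimension the
largest-magnitude coordinate is made positive) so plots are reproducible
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .export import LogMethylationRatioMatrix

__all__ = [
    "Embedding",
    "select_top_variable_sites",
    "mds_embedding",
    "pca_embedding",
    "DEFAULT_TOP_SITES",
]

DEFAULT_TOP_SITES = 500


@dataclass
class Embedding:
    """Samples x k coordinates plus method metadata.

    ``explained`` holds per-dimension variance-explained fractions for
    PCA (None for MDS); ``degenerate`` flags an all-equal-sample input
    that yields zero coordinates.
    """

    coordinates: pd.DataFrame  # index = sample_ids, columns = dim1..dimk
    method: str
    top_sites: int
    explained: np.ndarray | None = None
    degenerate: bool = False

    @property
    def samples(self) -> list[str]:
        return list(self.coordinates.index)


def _values(matrix) -> pd.DataFrame:
    if isinstance(matrix, LogMethylationRatioMatrix):
        return matrix.values
    return matrix


def select_top_variable_sites(matrix, k: int = DEFAULT_TOP_SITES):
    """Retain the k sites with the largest across-sample variance.

    Variance uses denominator n-1; ties are broken by site coordinate
    order (the selection is a stable sort), and the selected sites are
    returned in their original coordinate order. Sites with zero total
    coverage in any sample are dropped first when coverage information is
    available — their ratios are pure pseudocount. If fewer than k sites
    remain, all are kept.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    values = _values(matrix)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples to rank site variability")
    cov = matrix.coverage if isinstance(matrix, LogMethylationRatioMatrix) else None
    if cov is not None:
        values = values.loc[(cov > 0).all(axis=1)]
    var = values.var(axis=1, ddof=1).to_numpy()
    order = np.argsort(-var, kind="stable")[: min(k, len(var))]
    keep = np.sort(order)  # back to site coordinate order
    reduced = values.iloc[keep]
    if isinstance(matrix, LogMethylationRatioMatrix):
        return LogMethylationRatioMatrix(
            reduced,
            matrix.prior_count,
            None if cov is None else cov.loc[reduced.index],
        )
    return reduced


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


def rms_distances(matrix) -> pd.DataFrame:
    """Pairwise RMS difference of site values between samples."""
    values = _values(matrix)
    X = values.to_numpy(dtype=float).T  # samples x sites
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = X - X[i]
        d[i] = np.sqrt(np.mean(diff * diff, axis=1))
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


def _pairwise_rms_distances(matrix, k: int) -> pd.DataFrame:
    """Per-pair re-selection variant: for each sample pair, the distance is
    the RMS difference over the k sites with the largest absolute difference
    for that pair (two-sample variance ranks coincide with |difference|)."""
    values = _values(matrix)
    X = values.to_numpy(dtype=float).T
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(X[i] - X[j])
            top = np.sort(diff)[-min(k, diff.size):]
            d[i, j] = d[j, i] = np.sqrt(np.mean(top * top))
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


def mds_embedding(
    matrix,
    k_dims: int = 2,
    site_selection: str = "common",
    top_sites: int = DEFAULT_TOP_SITES,
) -> Embedding:
    """Classical (Torgerson) MDS of samples from RMS log-ratio distances.

    Double-centers the squared distance matrix, eigendecomposes it, and
    orders dimensions by eigenvalue. With ``site_selection="common"`` the
    distances use the sites of *matrix* as given (run
    :func:`select_top_variable_sites` first to reduce); ``"pairwise"``
    re-selects the *top_sites* most different sites per sample pair.

    An all-equal-sample input is degenerate: coordinates are zero and the
    embedding is flagged.
    """
    values = _values(matrix)
    n = values.shape[1]
    if n < 3:
        raise ValueError("MDS needs at least 3 samples for 2 dimensions")
    if site_selection == "common":
        D = rms_distances(matrix).to_numpy()
    elif site_selection == "pairwise":
        D = _pairwise_rms_distances(matrix, top_sites).to_numpy()
    else:
        raise ValueError(f"unknown site_selection {site_selection!r}")
    D2 = D**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:k_dims]
    lam = eigval[order]
    if np.all(lam < 1e-12):
        coords = np.zeros((n, k_dims))
        degenerate = True
    else:
        coords = eigvec[:, order] * np.sqrt(np.clip(lam, 0.0, None))
        coords = _fix_signs(coords)
        degenerate = False
    frame = pd.DataFrame(
        coords,
        index=values.columns,
        columns=[f"dim{i + 1}" for i in range(k_dims)],
    )
    return Embedding(frame, "MDS", values.shape[0], degenerate=degenerate)


def pca_embedding(matrix, k_dims: int = 2) -> Embedding:
    """Site-centered PCA of samples via singular value decomposition.

    Each site is centered across samples; coordinates are the projections
    U * S and ``explained`` the squared singular values over their total.
    """
    values = _values(matrix)
    n = values.shape[1]
    if n < 3:
        raise ValueError("PCA needs at least 3 samples for 2 dimensions")
    X = values.to_numpy(dtype=float).T  # samples x sites
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(S**2))
    if total < 1e-24:
        coords = np.zeros((n, k_dims))
        explained = np.zeros(k_dims)
        degenerate = True
    else:
        coords = _fix_signs(U[:, :k_dims] * S[:k_dims])
        explained = (S[:k_dims] ** 2) / total
        degenerate = False
    frame = pd.DataFrame(
        coords,
        index=values.columns,
        columns=[f"dim{i + 1}" for i in range(k_dims)],
    )
    return Embedding(
        frame, "PCA", values.shape[0], explained=explained, degenerate=degenerate
    )
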