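"""Dimension reduction: native PCA and PCoA, delegated t-SNE and UMAP.

PCA mean-centers features (no scaling by default — feature variances are
meaningful for abundance data) and takes the SVD of the centered
samples x features matrix; scores are the projections onto the top
right-singular directions and explained variance is ``lambda_i / sum lambda``.

PCoA is classical metric MDS: Gower double-centering
``B = -1/2 J D^2 J`` with ``J = I - 11'/n``, eigendecomposition, coordinates
``v_i sqrt(lambda_i)`` for the top positive eigenvalues. Negative eigenvalues
(possible for non-Euclidean dissimilarities such as Bray-Curtis) are dropped
and reported as a diagnostic; explained variance is relative to the sum of
positive eigenvalues.

t-SNE and UMAP are delegated to scikit-learn and umap-learn behind a
determinism contract (same seed + same input -> identical embedding); when the
backend is unavailable a :class:`~otukit.errors.CapabilityError` is raised and
the rest of the toolkit keeps working.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import AssayKind, MicrobiomeExperiment, get_assay
from .errors import AnalysisError, CapabilityError, ValidationError
from .transform import upsample_counts


@dataclass(frozen=True)
class Embedding:
    """Low-dimensional sample coordinates with optional explained variance."""

    coordinates: pd.DataFrame  # samples x axes
    method: str
    explained_variance: Optional[np.ndarray] = None  # per-axis fraction
    n_negative_eigenvalues: int = 0
    negative_eigenvalue_magnitude: float = 0.0

    def __post_init__(self):
        if self.explained_variance is not None:
            ev = np.asarray(self.explained_variance, dtype=float)
            if ((ev < -1e-12) | (ev > 1 + 1e-12)).any():
                raise ValidationError("explained-variance fractions must be in [0,1]")
            if (np.diff(ev) > 1e-9).any():
                raise ValidationError("explained variance must be non-increasing")

    @property
    def axis_labels(self) -> list[str]:
        return list(self.coordinates.columns)


def _level_assay_matrix(
    exp: MicrobiomeExperiment, level: str | None, assay: AssayKind | str
) -> pd.DataFrame:
    """Samples x features matrix at the requested level and abundance scale."""
    if level is not None:
        exp = upsample_counts(exp, level)
    return get_assay(exp, assay).T


def _orient_axes(scores: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Flip each axis so its largest-magnitude loading is positive."""
    flips = np.ones(scores.shape[1])
    for k in range(scores.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            flips[k] = -1.0
    return scores * flips


def run_pca(
    exp: MicrobiomeExperiment,
    level: str | None = None,
    assay: AssayKind | str = AssayKind.logcpm,
    k: int = 2,
    scale: bool = False,
) -> Embedding:
    """Principal components of samples on the chosen assay scale."""
    X = _level_assay_matrix(exp, level, assay)
    n, p = X.shape
    if n < 2:
        raise ValidationError("PCA requires >= 2 samples")
    if k > min(n - 1, p):
        raise ValidationError(f"k={k} exceeds min(n_samples-1, n_features)")
    M = X.to_numpy(dtype=float)
    M = M - M.mean(axis=0, keepdims=True)
    if scale:
        sd = M.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        M = M / sd
    if np.allclose(M, 0):
        raise AnalysisError("constant matrix: no variance to decompose")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    lam = S**2
    total = lam.sum()
    scores = U[:, :k] * S[:k]
    scores = _orient_axes(scores, Vt[:k].T)
    cols = [f"PC{i + 1}" for i in range(k)]
    coords = pd.DataFrame(scores, index=X.index, columns=cols)
    return Embedding(coords, "pca", explained_variance=lam[:k] / total)


def run_pcoa(D, k: int = 2) -> Embedding:
    """Classical metric multidimensional scaling of a distance matrix."""
    from .diversity import DistanceMatrix

    if not isinstance(D, DistanceMatrix):
        raise ValidationError("run_pcoa expects a DistanceMatrix")
    n = D.n
    D2 = D.values.astype(float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    lam, vec = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    tol = 1e-9 * max(lam.max(), 1.0)
    pos = lam > tol
    n_neg = int((lam < -tol).sum())
    neg_mag = float(-lam[lam < -tol].sum()) if n_neg else 0.0
    n_pos = int(pos.sum())
    if k > n_pos:
        raise AnalysisError(
            f"k={k} exceeds the {n_pos} positive eigenvalues of the centered matrix"
        )
    lam_pos = lam[pos]
    coords = vec[:, pos][:, :k] * np.sqrt(lam_pos[:k])
    coords = _orient_axes(coords, coords)  # orient by scores (no loadings exist)
    cols = [f"Axis{i + 1}" for i in range(k)]
    frame = pd.DataFrame(coords, index=list(D.sample_ids), columns=cols)
    return Embedding(
        frame,
        "pcoa",
        explained_variance=lam_pos[:k] / lam_pos.sum(),
        n_negative_eigenvalues=n_neg,
        negative_eigenvalue_magnitude=neg_mag,
    )


def run_tsne(
    exp: MicrobiomeExperiment,
    level: str | None = None,
    assay: AssayKind | str = AssayKind.logcpm,
    k: int = 2,
    perplexity: float = 5.0,
    seed: int | None = None,
) -> Embedding:
    """t-SNE embedding via scikit-learn (deterministic under a fixed seed)."""
    if seed is None:
        raise ValidationError("run_tsne requires an explicit seed")
    try:
        from sklearn.manifold import TSNE
    except ImportError as exc:  # pragma: no cover
        raise CapabilityError("t-SNE backend (scikit-learn) unavailable") from exc
    X = _level_assay_matrix(exp, level, assay)
    if X.shape[0] < 4:
        raise ValidationError("t-SNE requires >= 4 samples")
    perplexity = min(perplexity, (X.shape[0] - 1) / 3)
    emb = TSNE(
        n_components=k, perplexity=perplexity, random_state=seed, init="pca",
    ).fit_transform(X.to_numpy(dtype=float))
    cols = [f"tSNE{i + 1}" for i in range(k)]
    return Embedding(pd.DataFrame(emb, index=X.index, columns=cols), "tsne")


def run_umap(
    exp: MicrobiomeExperiment,
    level: str | None = None,
    assay: AssayKind | str = AssayKind.logcpm,
    k: int = 2,
    n_neighbors: int = 15,
    seed: int | None = None,
) -> Embedding:
    """UMAP embedding via umap-learn (optional backend)."""
    if seed is None:
        raise ValidationError("run_umap requires an explicit seed")
    try:
        import umap
    except ImportError as exc:
        raise CapabilityError(
            "UMAP backend unavailable; install the 'umap' extra"
        ) from exc
    X = _level_assay_matrix(exp, level, assay)
    if X.shape[0] < 4:
        raise ValidationError("UMAP requires >= 4 samples")
    n_neighbors = min(n_neighbors, X.shape[0] - 1)
    reducer = umap.UMAP(n_components=k, n_neighbors=n_neighbors, random_state=seed)
    emb = reducer.fit_transform(X.to_numpy(dtype=float))
    cols = [f"UMAP{i + 1}" for i in range(k)]
    return Embedding(pd.DataFrame(emb, index=X.index, columns=cols), "umap")
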