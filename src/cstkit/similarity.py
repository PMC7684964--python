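"""Yue-Clayton theta similarity and Bray-Curtis dissimilarity.

Yue-Clayton's theta measures the similarity of two communities from their
species proportions::

    theta(p, q) = sum(p*q) / (sum((p - q)**2) + sum(p*q))

which is algebraically identical to::

    theta(p, q) = sum(p*q) / (sum(p**2) + sum(q**2) - sum(p*q))

theta is 1.0 when all taxa are shared at identical relative abundances and
0.0 when the two communities share no taxa. Because products and squares of
proportions are involved, the index is dominated by high-abundance taxa —
the property that makes it well suited to nearest-centroid assignment of
vaginal communities, which are typically dominated by one or two species.

Vocabularies are aligned by union: a taxon absent from one vector
contributes proportion 0 there, so taxa unique to either community inflate
the denominator and depress the score rather than being ignored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateCompositionError
from .taxa_io import CentroidSet, union_vocabulary

_SIMPLEX_ATOL = 1e-9


def _as_composition(v, name: str = "vector") -> np.ndarray:
    """Validate and return *v* as a float array on the probability simplex."""
    if isinstance(v, pd.Series):
        arr = v.to_numpy(dtype=float)
    else:
        arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if (arr < 0).any():
        raise DegenerateCompositionError(f"{name} has negative proportions")
    total = arr.sum()
    if total <= 0:
        raise DegenerateCompositionError(f"{name} is all-zero")
    if abs(total - 1.0) > _SIMPLEX_ATOL:
        raise DegenerateCompositionError(
            f"{name} does not sum to 1 (sum={total!r}); normalize counts first"
        )
    return arr


def _align_pair(p, q) -> tuple[np.ndarray, np.ndarray]:
    """Union-align two vectors; pandas Series are matched on their index."""
    if isinstance(p, pd.Series) and isinstance(q, pd.Series):
        vocab = union_vocabulary(p.index, q.index)
        p = p.reindex(vocab, fill_value=0.0)
        q = q.reindex(vocab, fill_value=0.0)
    pa = _as_composition(p, "p")
    qa = _as_composition(q, "q")
    if pa.shape != qa.shape:
        raise ValueError("plain-array inputs must share a vocabulary (same length)")
    return pa, qa


def yue_clayton_theta(p, q) -> float:
    """Yue-Clayton theta similarity between two composition vectors.

    Accepts pandas Series (aligned on the union of their indices, absent
    taxa treated as 0) or equal-length arrays over a shared vocabulary.
    Returns a float in [0, 1]; symmetric in its arguments.
    """
    pa, qa = _align_pair(p, q)
    cross = float(pa @ qa)
    denom = float(pa @ pa) + float(qa @ qa) - cross
    if denom == 0.0:  # unreachable for valid simplex vectors
        raise DegenerateCompositionError("theta denominator is zero")
    return min(max(cross / denom, 0.0), 1.0)


def bray_curtis(p, q) -> float:
    """Bray-Curtis dissimilarity sum|p-q| / sum(p+q) between compositions.

    On the probability simplex this equals half the L1 distance; returns a
    float in [0, 1] with bray_curtis(x, x) == 0.
    """
    pa, qa = _align_pair(p, q)
    return float(np.abs(pa - qa).sum() / (pa + qa).sum())


def theta_matrix(X, C) -> np.ndarray:
    """Vectorized theta between rows of *X* (samples) and rows of *C*.

    DataFrames are union-aligned on columns; arrays must already share a
    vocabulary. Rows must each sum to 1. Returns an (n_samples, n_centroids)
    array.
    """
    if isinstance(X, pd.DataFrame) and isinstance(C, pd.DataFrame):
        vocab = union_vocabulary(X.columns, C.columns)
        X = X.reindex(columns=vocab, fill_value=0.0)
        C = C.reindex(columns=vocab, fill_value=0.0)
    Xa = np.atleast_2d(np.asarray(X, dtype=float))
    Ca = np.atleast_2d(np.asarray(C, dtype=float))
    for name, M in (("X", Xa), ("C", Ca)):
        if (M < 0).any():
            raise DegenerateCompositionError(f"{name} has negative proportions")
        sums = M.sum(axis=1)
        bad = np.abs(sums - 1.0) > _SIMPLEX_ATOL
        if bad.any():
            raise DegenerateCompositionError(
                f"{name} rows {np.flatnonzero(bad).tolist()} are not on the simplex"
            )
    cross = Xa @ Ca.T
    denom = (Xa**2).sum(axis=1)[:, None] + (Ca**2).sum(axis=1)[None, :] - cross
    return np.clip(cross / denom, 0.0, 1.0)


def similarity_profile(sample, centroids: CentroidSet) -> pd.Series:
    """theta of *sample* against every centroid, in centroid-file order.

    Returns a Series indexed by sub-CST label with one score per centroid
    (thirteen for the canonical reference set).
    """
    if len(centroids) == 0:
        raise ValueError("centroid set is empty")
    frame = centroids.centroids
    if isinstance(sample, pd.Series):
        vocab = union_vocabulary(sample.index, frame.columns)
        s = sample.reindex(vocab, fill_value=0.0).to_frame().T
        C = frame.reindex(columns=vocab, fill_value=0.0)
    else:
        s = np.atleast_2d(np.asarray(sample, dtype=float))
        C = frame
    scores = theta_matrix(s, C)[0]
    return pd.Series(scores, index=frame.index, name="theta")
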