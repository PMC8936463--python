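"""Poisson NMF grade-of-membership topic modeling of UMI counts.

Counts are approximated as X ~ Poisson(L F') with non-negative loadings L
(cells x k) and factors F (genes x k), fit by multiplicative updates that
monotonically decrease the Poisson negative log-likelihood
sum_ij (LF')_ij - X_ij log (LF')_ij.  The fitted loadings rows are rescaled
to the simplex (topic probabilities); factors are rescaled to sum 1 across
each gene by default, with the per-topic normalization available behind a
flag.  Batch structure can be removed from the raw counts beforehand by
equalizing per-gene batch means on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

_EPS = 1e-12


def _dense_counts(counts) -> np.ndarray:
    if isinstance(counts, ad.AnnData):
        counts = counts.X
    if sparse.issparse(counts):
        counts = np.asarray(counts.todense())
    return np.asarray(counts, dtype=float)


def batch_correct_counts(counts, batches) -> np.ndarray:
    """Equalize per-gene batch means on the log(count+1) scale.

    Per gene, each cell's log1p count is shifted by (grand mean - its batch
    mean), back-transformed and rounded to the nearest non-negative integer.
    A single batch is returned unchanged with a warning.
    """
    X = _dense_counts(counts)
    batches = np.asarray(batches)
    levels = np.unique(batches)
    if len(levels) < 2:
        warnings.warn("single batch: counts returned unchanged")
        return X.copy()
    Z = np.log1p(X)
    grand = Z.mean(axis=0)
    out = np.empty_like(Z)
    for b in levels:
        mask = batches == b
        out[mask] = Z[mask] - Z[mask].mean(axis=0) + grand
    corrected = np.rint(np.expm1(out))
    return np.maximum(corrected, 0.0)


def poisson_nmf_objective(X: np.ndarray, L: np.ndarray, F: np.ndarray) -> float:
    """sum(LF') - sum(X * log(LF')) over the support of X."""
    R = L @ F.T
    mask = X > 0
    return float(R.sum() - np.sum(X[mask] * np.log(R[mask] + _EPS)))


class PoissonNMF(BaseEstimator, TransformerMixin):
    """Poisson non-negative matrix factorization by multiplicative updates.

    Attributes after fit: ``L_`` (cells x k loadings), ``F_`` (genes x k
    factors), ``objective_trace_`` (non-increasing), ``n_iter_``.
    """

    def __init__(
        self,
        k: int = 3,
        max_iter: int = 300,
        tol: float = 1e-6,
        seed: int = 0,
        init: tuple | None = None,
    ):
        self.k = k
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.init = init  # optional (L0, F0) explicit initialization

    def fit(self, X, y=None):
        V = _dense_counts(X)
        if (V < 0).any():
            raise ValueError("counts must be non-negative")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        row_ok = V.sum(axis=1) > 0
        col_ok = V.sum(axis=0) > 0
        if not row_ok.all() or not col_ok.all():
            warnings.warn(
                f"dropping {int((~row_ok).sum())} empty cells and "
                f"{int((~col_ok).sum())} empty genes before fitting"
            )
        self.kept_cells_ = row_ok
        self.kept_genes_ = col_ok
        V = V[row_ok][:, col_ok]
        n, m = V.shape
        if self.init is not None:
            L0, F0 = self.init
            W = np.asarray(L0, dtype=float)[row_ok].copy()
            H = np.asarray(F0, dtype=float)[col_ok].T.copy()
        else:
            rng = np.random.default_rng(self.seed)
            scale = np.sqrt(V.mean() / self.k)
            W = rng.uniform(0.5, 1.5, size=(n, self.k)) * scale
            H = rng.uniform(0.5, 1.5, size=(self.k, m)) * scale
        trace = [poisson_nmf_objective(V, W, H.T)]
        for it in range(self.max_iter):
            WH = W @ H + _EPS
            W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1)[None, :], _EPS)
            WH = W @ H + _EPS
            H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], _EPS)
            obj = poisson_nmf_objective(V, W, H.T)
            trace.append(obj)
            denom = max(abs(trace[-2]), 1.0)
            if (trace[-2] - obj) / denom < self.tol:
                break
        self.L_ = W
        self.F_ = H.T
        self.objective_trace_ = np.array(trace)
        self.n_iter_ = len(trace) - 1
        return self

    def transform(self, X=None):
        """Per-cell topic probabilities (loadings rows on the simplex)."""
        return to_topic_model(self)[0]


def fit_poisson_nmf(
    counts, k: int, max_iter: int = 300, tol: float = 1e-6, seed: int = 0
) -> PoissonNMF:
    return PoissonNMF(k=k, max_iter=max_iter, tol=tol, seed=seed).fit(counts)


def to_topic_model(fit: PoissonNMF, factor_norm: str = "per_gene"):
    """Rescale a fitted model to (topic probabilities, word probabilities).

    Loadings rows are normalized to sum 1 per cell (all-zero rows become
    uniform, flagged via a warning).  Factors are normalized to sum 1 across
    each gene by default (``per_gene``); ``per_topic`` normalizes each topic's
    gene distribution instead.
    """
    L, F = fit.L_, fit.F_
    rowsum = L.sum(axis=1)
    zero_rows = rowsum <= 0
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} all-zero loading rows set uniform")
    topic = np.where(
        zero_rows[:, None], 1.0 / L.shape[1], L / np.maximum(rowsum, _EPS)[:, None]
    )
    if factor_norm == "per_gene":
        denom = np.maximum(F.sum(axis=1, keepdims=True), _EPS)
        word = F / denom
    elif factor_norm == "per_topic":
        word = F / np.maximum(F.sum(axis=0, keepdims=True), _EPS)
    else:
        raise ValueError("factor_norm must be 'per_gene' or 'per_topic'")
    return topic, word


def top_topic_features(fit: PoissonNMF, n: int = 100, gene_names=None) -> dict:
    """Rank genes by distinctiveness per topic.

    The score of gene j for topic k is the KL divergence between the gene's
    Poisson rate under topic k and its maximum rate under any other topic:
    l1*log(l1/l2) - l1 + l2.  Returns {topic index: ranked gene list}.
    """
    F = fit.F_
    m, K = F.shape
    if gene_names is None:
        gene_names = np.arange(m)
    gene_names = np.asarray(gene_names)
    if n > m:
        warnings.warn(f"n={n} exceeds {m} genes; truncated")
        n = m
    out = {}
    for k in range(K):
        lam1 = F[:, k] + _EPS
        if K == 1:
            score = lam1
        else:
            others = np.delete(F, k, axis=1)
            lam2 = others.max(axis=1) + _EPS
            score = lam1 * np.log(lam1 / lam2) - lam1 + lam2
            score[lam1 <= lam2] = -(lam2 - lam1)[lam1 <= lam2]  # penalize non-distinct
        order = np.argsort(-score, kind="stable")[:n]
        out[k] = list(gene_names[order])
    return out
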