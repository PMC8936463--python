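"""Cell-level QC, log-normalization and nuisance-covariate regression.

QC gates follow the droplet-RNA-seq convention for this design: cells are kept
when they have at least 1000 UMIs, at least 700 detected genes, and at most
25% of counts mapping to mitochondrial genes (boundaries inclusive in the
keep direction).  Expression used by the marker-positivity rules is the
log-normalized matrix with total-UMI and mitochondrial-fraction effects
regressed out per gene, standardized and clipped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin


def _counts(adata: ad.AnnData) -> sparse.csr_matrix:
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    return X.tocsr()


def qc_metrics(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell total UMIs, detected genes and mitochondrial fraction."""
    X = _counts(adata)
    total = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    if "mito" not in adata.var:
        raise ValueError("gene table must carry a 'mito' flag column")
    mito_mask = adata.var["mito"].to_numpy().astype(bool)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.where(total > 0, total, 1), 0.0)
    return pd.DataFrame(
        {"total_umis": total, "n_genes": n_genes, "mito_frac": mito_frac},
        index=adata.obs_names,
    )


def filter_cells(
    adata: ad.AnnData,
    min_umi: int = 1000,
    min_genes: int = 700,
    max_mito: float = 0.25,
) -> ad.AnnData:
    """Drop cells failing any QC gate; counts are left unmodified.

    Keeps cells with total UMIs >= min_umi AND detected genes >= min_genes AND
    mitochondrial fraction <= max_mito.  Raises if nothing survives, reporting
    per-criterion attrition.
    """
    m = qc_metrics(adata)
    keep = (
        (m["total_umis"] >= min_umi)
        & (m["n_genes"] >= min_genes)
        & (m["mito_frac"] <= max_mito)
    )
    if not keep.any():
        raise ValueError(
            "all cells removed by QC: "
            f"{int((m['total_umis'] < min_umi).sum())} below {min_umi} UMIs, "
            f"{int((m['n_genes'] < min_genes).sum())} below {min_genes} genes, "
            f"{int((m['mito_frac'] > max_mito).sum())} above {max_mito:.0%} mito"
        )
    out = adata[keep.to_numpy()].copy()
    out.obs = out.obs.drop(
        columns=[c for c in m.columns if c in out.obs.columns]
    ).join(m.loc[keep])
    return out


def lognormalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """value = ln(1 + count / libsize * scale_factor), stored in a copy."""
    X = _counts(adata)
    libsize = np.asarray(X.sum(axis=1)).ravel()
    if (libsize <= 0).any():
        raise ValueError("cells with zero library size must be filtered first")
    out = adata.copy()
    norm = X.multiply(scale_factor / libsize[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out.layers["lognorm"] = norm
    return out


class ScaleRegress(BaseEstimator, TransformerMixin):
    """Per-gene OLS removal of nuisance covariates, then standardization.

    fit(X, covariates) regresses each gene (column of X, cells x genes) on the
    covariate matrix plus an intercept; transform returns standardized
    residuals (mean 0, unit variance per gene) clipped at +/- ``clip``.
    Constant genes yield a zero vector and are flagged in ``constant_genes_``.
    """

    def __init__(self, clip: float = 10.0):
        self.clip = clip

    def fit(self, X, covariates):
        X = np.asarray(X, dtype=float)
        C = np.column_stack([np.ones(len(X)), np.asarray(covariates, dtype=float)])
        self.coef_, *_ = np.linalg.lstsq(C, X, rcond=None)
        self._design = C
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        resid = X - self._design @ self.coef_
        sd = resid.std(axis=0, ddof=1)
        self.constant_genes_ = sd <= 1e-12
        sd = np.where(self.constant_genes_, 1.0, sd)
        scaled = resid / sd
        scaled[:, self.constant_genes_] = 0.0
        self.residuals_ = scaled.copy()  # pre-clipping, for orthogonality checks
        return np.clip(scaled, -self.clip, self.clip)


def scale_and_regress(
    adata: ad.AnnData,
    covariates: tuple[str, ...] = ("total_umis", "mito_frac"),
    clip: float = 10.0,
) -> ad.AnnData:
    """Regress nuisance covariates out of the log-normalized layer.

    Writes a dense ``scaled`` layer of clipped standardized residuals and
    records the covariates removed in ``.uns``.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("run lognormalize first")
    missing = [c for c in covariates if c not in adata.obs]
    if missing:
        raise ValueError(f"missing covariates in .obs: {missing}")
    Y = np.asarray(adata.layers["lognorm"].todense())
    C = adata.obs[list(covariates)].to_numpy(dtype=float)
    est = ScaleRegress(clip=clip).fit(Y, C)
    out = adata.copy()
    out.layers["scaled"] = est.transform(Y)
    out.uns["scaled_covariates"] = list(covariates)
    out.var["constant_gene"] = est.constant_genes_
    return out
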