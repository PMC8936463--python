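"""Pseudobulk construction and per-gene linear mixed-model differential
expression between species.

Pseudobulk samples are sums of single-cell counts over unique
(cell line, replicate, cell classification) groups.  Genes are filtered
(mitochondrial, ribosomal, mean log2 CPM <= 0), samples TMM-normalized,
observation-level precision weights estimated from the mean-variance trend,
and each gene fit with

    y = b0 + b_species * X_species + b_line + e

where species is a fixed effect and cell line a random intercept shared by
technical replicates.  Estimation is weighted REML with the variance ratio
profiled by 1-D bounded optimization; t-tests use Satterthwaite degrees of
freedom, and genes are called DE at Benjamini-Hochberg FDR < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse, stats, optimize
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


@dataclass
class PseudobulkMatrix:
    """Genes x samples integer sums plus per-sample metadata.

    ``samples`` is indexed by sample id with columns species, line, replicate,
    classification and libsize (column sum).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    @property
    def libsize(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class NormFactors:
    factors: pd.Series
    reference: str


@dataclass
class WeightedExpression:
    """log2-CPM values and precision weights per gene x sample."""

    logcpm: pd.DataFrame
    weights: pd.DataFrame
    trend_x: np.ndarray
    trend_y: np.ndarray


def build_pseudobulk(
    adata: ad.AnnData,
    labels,
    group_keys: tuple[str, ...] = ("line", "replicate"),
    subsample_to: int | None = None,
    seed: int = 0,
) -> PseudobulkMatrix:
    """Sum counts per unique (group_keys..., classification) grouping.

    ``labels`` gives each cell's classification.  With ``subsample_to`` set,
    each group is first downsampled without replacement to that many cells
    (seeded); smaller groups are dropped with a warning.
    """
    labels = pd.Series(labels, index=adata.obs_names, name="classification")
    meta = adata.obs.copy()
    meta["classification"] = labels
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    X = X.tocsr()
    rng = np.random.default_rng(seed)

    keys = list(group_keys) + ["classification"]
    groups = meta.groupby(keys, observed=True, sort=True).indices
    cols, col_meta = [], []
    for key, idx in groups.items():
        idx = np.asarray(idx)
        if len(idx) == 0:
            continue
        if subsample_to is not None:
            if len(idx) < subsample_to:
                warnings.warn(
                    f"group {key} has {len(idx)} < subsample_to={subsample_to} "
                    "cells; dropped"
                )
                continue
            idx = rng.choice(idx, size=subsample_to, replace=False)
        total = np.asarray(X[idx].sum(axis=0)).ravel()
        key = key if isinstance(key, tuple) else (key,)
        sample_id = "|".join(str(k) for k in key)
        cols.append(total)
        rec = dict(zip(keys, key))
        if "species" in meta.columns:
            rec["species"] = meta["species"].iloc[idx[0]]
        elif "species_true" in meta.columns:
            rec["species"] = meta["species_true"].iloc[idx[0]]
        rec["n_cells"] = len(idx)
        col_meta.append((sample_id, rec))
    if not cols:
        raise ValueError("no non-empty groups to pseudobulk")
    counts = pd.DataFrame(
        np.column_stack(cols),
        index=adata.var_names,
        columns=[sid for sid, _ in col_meta],
    )
    samples = pd.DataFrame({sid: rec for sid, rec in col_meta}).T
    samples["libsize"] = counts.sum(axis=0)
    return PseudobulkMatrix(counts=counts, samples=samples)


def log2cpm(counts: pd.DataFrame, libsize=None, prior: float = 0.5) -> pd.DataFrame:
    """log2((count + prior) / (libsize + 1) * 1e6), the precision-weight
    transform's convention, reused for the expression filter."""
    if libsize is None:
        libsize = counts.sum(axis=0)
    return np.log2((counts + prior) / (np.asarray(libsize) + 1.0) * 1e6)


def filter_genes(pb: PseudobulkMatrix, gene_flags: pd.DataFrame) -> PseudobulkMatrix:
    """Drop mito/ribo-flagged genes and genes with mean log2-CPM <= 0."""
    flags = gene_flags.reindex(pb.counts.index)
    drop = flags["mito"].fillna(False).astype(bool) | flags["ribo"].fillna(
        False
    ).astype(bool)
    mean_l2cpm = log2cpm(pb.counts).mean(axis=1)
    keep = (~drop) & (mean_l2cpm > 0)
    if not keep.any():
        raise ValueError("gene filters removed every gene")
    return PseudobulkMatrix(counts=pb.counts.loc[keep], samples=pb.samples)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Trimmed weighted mean of M-values for one sample against the reference
    (the published TMM recipe: 30% trim on M, 5% on A, asymptotic-binomial
    inverse-variance weights)."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if len(obs) == 0:
        return 1.0
    logR = np.log2((obs / n_obs) / (ref / n_ref))
    absE = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(logR) & np.isfinite(absE)
    logR, absE, v = logR[fin], absE[fin], v[fin]
    if len(logR) == 0 or np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = len(logR)
    loL = np.floor(n * logratio_trim) + 1
    hiL = n + 1 - loL
    loS = np.floor(n * sum_trim) + 1
    hiS = n + 1 - loS
    rR = stats.rankdata(logR)
    rS = stats.rankdata(absE)
    keep = (rR >= loL) & (rR <= hiL) & (rS >= loS) & (rS <= hiS)
    if not keep.any():
        return 1.0
    f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(pb: PseudobulkMatrix) -> NormFactors:
    """TMM scaling factors, reference chosen by upper-quartile proximity,
    rescaled to geometric mean 1."""
    counts = pb.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero-libsize samples cannot be normalized")
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    f75 = np.array(
        [np.quantile(counts[:, i] / lib[i], 0.75) for i in range(counts.shape[1])]
    )
    if np.median(f75) < 1e-20:
        ref_i = int(np.argmax(counts.sum(axis=0)))
    else:
        ref_i = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(counts[:, i], counts[:, ref_i], lib[i], lib[ref_i])
            for i in range(counts.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        factors=pd.Series(factors, index=pb.counts.columns),
        reference=str(pb.counts.columns[ref_i]),
    )


def voom_weights(
    pb: PseudobulkMatrix, norm: NormFactors, design: np.ndarray
) -> WeightedExpression:
    """Observation-level precision weights from the mean-variance trend.

    y = log2((count + 0.5) / (effective libsize + 1) * 1e6); per-gene OLS on
    the design; sqrt residual SD is smoothed against average log2 count with
    lowess and the predicted sqrt-SD at each fitted value raised to the -4."""
    counts = pb.counts.to_numpy(dtype=float)
    design = np.asarray(design, dtype=float)
    G, n = counts.shape
    if n <= design.shape[1]:
        raise ValueError("need more samples than design columns")
    lib = counts.sum(axis=0) * norm.factors.to_numpy()
    y = np.log2((counts + 0.5) / (lib + 1.0) * 1e6)
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    fitted = (design @ beta).T
    resid = y - fitted
    dof = n - np.linalg.matrix_rank(design)
    sigma = np.sqrt((resid**2).sum(axis=1) / dof)
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    lo = lowess(sy, sx, frac=0.5, return_sorted=True)
    trend_x, trend_y = lo[:, 0], lo[:, 1]
    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(fitted_logcount, trend_x, trend_y)
    pred_sqrt_sd = np.maximum(pred_sqrt_sd, 1e-4)
    w = pred_sqrt_sd**-4.0
    idx, cols = pb.counts.index, pb.counts.columns
    return WeightedExpression(
        logcpm=pd.DataFrame(y, index=idx, columns=cols),
        weights=pd.DataFrame(w, index=idx, columns=cols),
        trend_x=trend_x,
        trend_y=trend_y,
    )


def _reml_neg2ll_profiled(lam, sw, Xw_t, yw_t):
    """Profiled REML -2 log-likelihood at variance ratio lam, in the
    eigenbasis of the whitened random-effect covariance (sw eigenvalues)."""
    d = 1.0 + lam * sw
    n, p = len(yw_t), Xw_t.shape[1]
    Xd = Xw_t / d[:, None]
    XtVX = Xw_t.T @ Xd
    XtVy = Xd.T @ yw_t
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    r = yw_t - Xw_t @ beta
    q = float(np.sum(r**2 / d))
    if q <= 0:
        return np.inf, None, None
    sig2 = q / (n - p)
    _, logdet_xvx = np.linalg.slogdet(XtVX)
    n2ll = (n - p) * np.log(sig2) + np.sum(np.log(d)) + logdet_xvx + (n - p)
    return n2ll, beta, sig2


def _reml_neg2ll_theta(theta, sw, Xw_t, yw_t):
    """Unprofiled REML -2 log-likelihood at theta = (line variance, residual
    variance), for Satterthwaite curvature."""
    s2b, s2e = theta
    d = s2e + s2b * sw
    if np.any(d <= 0):
        return np.inf
    Xd = Xw_t / d[:, None]
    XtVX = Xw_t.T @ Xd
    try:
        beta = np.linalg.solve(XtVX, Xd.T @ yw_t)
    except np.linalg.LinAlgError:
        return np.inf
    r = yw_t - Xw_t @ beta
    _, logdet_xvx = np.linalg.slogdet(XtVX)
    return float(np.sum(r**2 / d) + np.sum(np.log(d)) + logdet_xvx)


def _coef_var(theta, sw, Xw_t, which: int) -> float:
    """Sampling variance of the chosen fixed-effect coefficient at theta."""
    d = theta[1] + theta[0] * sw
    XtVX = Xw_t.T @ (Xw_t / d[:, None])
    C = np.linalg.inv(XtVX)
    return float(C[which, which])


def _satterthwaite_df(theta, sw, Xw_t, yw_t, which: int, n_minus_p: float) -> float:
    """Satterthwaite df: 2*C^2 / (g' A^{-1} g) with numerical gradient g of the
    coefficient variance and REML observed information A."""
    h = np.maximum(np.abs(theta), 1e-8) * 1e-4
    g = np.zeros(2)
    for j in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] = max(tm[j] - h[j], 1e-12)
        g[j] = (_coef_var(tp, sw, Xw_t, which) - _coef_var(tm, sw, Xw_t, which)) / (
            tp[j] - tm[j]
        )
    # observed information of the REML log-likelihood (0.5 * Hessian of -2ll)
    A = np.zeros((2, 2))
    f0 = _reml_neg2ll_theta(theta, sw, Xw_t, yw_t)
    for j in range(2):
        for k in range(j, 2):
            tpp, tpm, tmp, tmm_ = (theta.copy() for _ in range(4))
            tpp[j] += h[j]; tpp[k] += h[k]
            tpm[j] += h[j]; tpm[k] = max(tpm[k] - h[k], 1e-12)
            tmp[j] = max(tmp[j] - h[j], 1e-12); tmp[k] += h[k]
            tmm_[j] = max(tmm_[j] - h[j], 1e-12); tmm_[k] = max(tmm_[k] - h[k], 1e-12)
            if j == k:
                val = (
                    _reml_neg2ll_theta(tpp, sw, Xw_t, yw_t)
                    - 2 * f0
                    + _reml_neg2ll_theta(tmm_, sw, Xw_t, yw_t)
                ) / ((tpp[j] - theta[j]) * (theta[j] - tmm_[j]) + 1e-300)
            else:
                val = (
                    _reml_neg2ll_theta(tpp, sw, Xw_t, yw_t)
                    - _reml_neg2ll_theta(tpm, sw, Xw_t, yw_t)
                    - _reml_neg2ll_theta(tmp, sw, Xw_t, yw_t)
                    + _reml_neg2ll_theta(tmm_, sw, Xw_t, yw_t)
                ) / ((tpp[j] - tmp[j]) * (tpp[k] - tpm[k]) + 1e-300)
            A[j, k] = A[k, j] = 0.5 * val
    Cvar = _coef_var(theta, sw, Xw_t, which)
    try:
        Ainv_g = np.linalg.solve(A, g)
        denom = float(g @ Ainv_g)
    except np.linalg.LinAlgError:
        denom = 0.0
    if denom <= 0 or not np.isfinite(denom):
        return n_minus_p
    df = 2.0 * Cvar**2 / denom
    return float(np.clip(df, 1.0, n_minus_p + len(sw)))


class MixedModelDE(BaseEstimator):
    """Per-gene weighted-REML mixed model: species fixed, cell line random.

    fit(we, metadata) expects a :class:`WeightedExpression` and sample metadata
    with species and line columns; ``results_`` holds per-gene estimates,
    Satterthwaite t-tests, BH q-values and the DE flag at ``fdr``.
    """

    def __init__(
        self,
        fdr: float = 0.01,
        species_col: str = "species",
        line_col: str = "line",
        reference_species: str = "chimpanzee",
    ):
        self.fdr = fdr
        self.species_col = species_col
        self.line_col = line_col
        self.reference_species = reference_species

    def fit(self, we: WeightedExpression, metadata: pd.DataFrame):
        meta = metadata.loc[we.logcpm.columns]
        species = meta[self.species_col].to_numpy()
        if len(np.unique(species)) != 2:
            raise ValueError("need exactly two species")
        x_species = (species != self.reference_species).astype(float)
        lines = pd.get_dummies(meta[self.line_col]).to_numpy(dtype=float)
        for sp in np.unique(species):
            if meta.loc[species == sp, self.line_col].nunique() < 2:
                raise ValueError(f"need >=2 lines for species {sp!r}")
        X = np.column_stack([np.ones(len(meta)), x_species])
        Y = we.logcpm.to_numpy()
        W = we.weights.to_numpy()
        n, p = X.shape
        G = Y.shape[0]
        out = np.zeros((G, 7))
        converged = np.ones(G, dtype=bool)
        for g in range(G):
            sw_half = np.sqrt(W[g])
            yw = sw_half * Y[g]
            Xw = sw_half[:, None] * X
            Zw = sw_half[:, None] * lines
            s_eig, U = np.linalg.eigh(Zw @ Zw.T)
            s_eig = np.maximum(s_eig, 0.0)
            yt = U.T @ yw
            Xt = U.T @ Xw

            def obj(u):
                return _reml_neg2ll_profiled(np.exp(u), s_eig, Xt, yt)[0]

            res = optimize.minimize_scalar(
                obj, bounds=(-12.0, 8.0), method="bounded",
                options={"xatol": 1e-6},
            )
            n2_zero, beta0, sig0 = _reml_neg2ll_profiled(0.0, s_eig, Xt, yt)
            if res.success and res.fun < n2_zero - 1e-8:
                lam = float(np.exp(res.x))
                _, beta, sig2 = _reml_neg2ll_profiled(lam, s_eig, Xt, yt)
            else:
                lam, beta, sig2 = 0.0, beta0, sig0
                if not res.success:
                    converged[g] = False
            if beta is None:
                converged[g] = False
                out[g] = np.nan
                continue
            theta = np.array([lam * sig2, sig2])
            se = np.sqrt(sig2 * _coef_var(theta / sig2, s_eig, Xt, 1))
            if lam > 1e-10:
                df = _satterthwaite_df(theta, s_eig, Xt, yt, 1, n - p)
            else:
                df = float(n - p)
            tval = beta[1] / se
            pval = 2.0 * stats.t.sf(abs(tval), df)
            out[g] = [beta[0], beta[1], se, df, tval, pval, theta[0]]
        res_df = pd.DataFrame(
            out,
            index=we.logcpm.index,
            columns=["intercept", "beta_species", "se", "df", "t", "pvalue", "var_line"],
        )
        res_df["converged"] = converged
        pv = res_df["pvalue"].fillna(1.0).clip(1e-300, 1.0)
        res_df["qvalue"] = multipletests(pv, method="fdr_bh")[1]
        res_df["de"] = res_df["qvalue"] < self.fdr
        self.results_ = res_df
        return self


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals), method="fdr_bh")[1]


def fit_lmm(we: WeightedExpression, metadata: pd.DataFrame, fdr: float = 0.01,
            **kwargs) -> pd.DataFrame:
    """Fit the per-gene mixed model and return the results table."""
    return MixedModelDE(fdr=fdr, **kwargs).fit(we, metadata).results_
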