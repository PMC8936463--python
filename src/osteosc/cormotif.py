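"""Correlation-motif joint differential expression across conditions.

Each condition (a cell classification) yields a moderated t-statistic per gene
for the species contrast, computed from its own TMM-normalized, precision-
weighted pseudobulk fit with empirical-Bayes variance shrinkage.  Genes are
then modeled as a mixture over K motifs, each motif a vector q_k of per-
condition DE probabilities; under motif k the statistic in condition d is
drawn from a scaled t (DE, probability q_kd) or a central t (non-DE).  EM
estimates the motif matrix Q, mixture weights pi and per-gene
responsibilities; BIC selects K; the per-gene per-condition DE posterior is
thresholded at > 0.65 and cross-species conservation at |delta posterior|
<= 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, special
from sklearn.base import BaseEstimator

from .pseudobulk import (
    PseudobulkMatrix,
    WeightedExpression,
    tmm_factors,
    voom_weights,
)


@dataclass
class ModeratedStats:
    """Per gene x condition moderated t-statistics and their mixture densities.

    ``scale`` holds sqrt((v_g + v1) / v_g) per gene x condition: the factor by
    which the alternative (DE) t-density is stretched relative to the null.
    """

    t: np.ndarray  # G x D
    dof: np.ndarray  # D (total df: residual + prior)
    scale: np.ndarray  # G x D
    genes: pd.Index
    conditions: list
    d0: np.ndarray | None = None
    s0sq: np.ndarray | None = None
    v1: np.ndarray | None = None

    def log_densities(self):
        """(log f0, log f1) evaluated at the observed statistics."""
        logf0 = stats.t.logpdf(self.t, self.dof[None, :])
        logf1 = stats.t.logpdf(self.t / self.scale, self.dof[None, :]) - np.log(
            self.scale
        )
        return logf0, logf1


def _inv_trigamma(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton; monotone decreasing)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = max(y + dif, 1e-8)
        if abs(dif) < 1e-10 * y:
            break
    return y


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior
    on the log sample variances; returns (prior df d0, prior variance s0^2)."""
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 1e-10:
        d0 = 1e6
    else:
        d0 = min(2.0 * _inv_trigamma(evar), 1e6)
    s0sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0sq)


def _condition_stats(
    logcpm: np.ndarray,
    weights: np.ndarray,
    design: np.ndarray,
    coef: int,
    tail_prop: float,
    v1_floor_ratio: float,
):
    """Weighted LS + variance shrinkage for one condition; returns the
    moderated t, total df, per-gene f1 scale and the fitted prior."""
    G, n = logcpm.shape
    p = design.shape[1]
    d_resid = n - p
    if d_resid < 3:
        raise ValueError("need >= 3 residual df per condition")
    beta = np.zeros(G)
    s2 = np.zeros(G)
    vg = np.zeros(G)
    for g in range(G):
        w = weights[g]
        Xw = design * w[:, None]
        XtWX = design.T @ Xw
        C = np.linalg.inv(XtWX)
        b = C @ (Xw.T @ logcpm[g])
        r = logcpm[g] - design @ b
        s2[g] = float(r @ (w * r)) / d_resid
        beta[g] = b[coef]
        vg[g] = C[coef, coef]
    d0, s0sq = squeeze_var(s2, d_resid)
    s2_post = (d0 * s0sq + d_resid * s2) / (d0 + d_resid)
    tmod = beta / np.sqrt(s2_post * vg)
    dof = d0 + d_resid
    # effect-prior variance from the upper tail of |t|
    n_tail = max(int(np.ceil(tail_prop * G)), 3)
    top = np.sort(np.abs(tmod))[-n_tail:]
    var_corr = dof / (dof - 2.0) if dof > 2 else 1.0
    vmed = float(np.median(vg))
    v1 = vmed * (float(np.mean(top**2)) / var_corr - 1.0)
    v1 = max(v1, v1_floor_ratio * vmed)
    scale = np.sqrt((vg + v1) / vg)
    return tmod, float(dof), scale, d0, s0sq, v1


def moderated_stats(
    conditions: dict,
    design_fn,
    coef: int = 1,
    tail_prop: float = 0.01,
    v1_floor_ratio: float = 0.1,
) -> ModeratedStats:
    """Per-condition moderated statistics for a shared gene set.

    Parameters
    ----------
    conditions : mapping condition -> (PseudobulkMatrix, sample metadata); the
        pseudobulk of each condition is TMM-normalized and precision-weighted
        on its own.
    design_fn : callable(metadata) -> (n_samples x p) design matrix whose
        column ``coef`` is the contrast of interest (e.g. the species
        indicator).
    """
    names = list(conditions)
    genes = None
    tcols, dofs, scales, d0s, s0s, v1s = [], [], [], [], [], []
    for name in names:
        pb, meta = conditions[name]
        if genes is None:
            genes = pb.counts.index
        elif not genes.equals(pb.counts.index):
            raise ValueError("conditions must share an identical gene set")
        norm = tmm_factors(pb)
        design = np.asarray(design_fn(meta.loc[pb.counts.columns]), dtype=float)
        we = voom_weights(pb, norm, design)
        tmod, dof, scale, d0, s0sq, v1 = _condition_stats(
            we.logcpm.to_numpy(),
            we.weights.to_numpy(),
            design,
            coef,
            tail_prop,
            v1_floor_ratio,
        )
        tcols.append(tmod)
        dofs.append(dof)
        scales.append(scale)
        d0s.append(d0)
        s0s.append(s0sq)
        v1s.append(v1)
    return ModeratedStats(
        t=np.column_stack(tcols),
        dof=np.array(dofs),
        scale=np.column_stack(scales),
        genes=genes,
        conditions=names,
        d0=np.array(d0s),
        s0sq=np.array(s0s),
        v1=np.array(v1s),
    )


@dataclass
class CormotifFit:
    k: int
    Q: np.ndarray  # K x D motif DE probabilities
    pi: np.ndarray  # K mixture weights
    responsibilities: np.ndarray  # G x K
    posterior: np.ndarray  # G x D DE posteriors
    loglik: float
    loglik_trace: np.ndarray
    bic: float


def _em_run(logf0, logf1, K, rng, max_iter, tol):
    G, D = logf0.shape
    pi = rng.dirichlet(np.ones(K))
    Q = rng.uniform(0.05, 0.95, size=(K, D))
    trace = []
    prev = -np.inf
    eps = 1e-6
    for _ in range(max_iter):
        # mixture density per gene x condition x motif, in log space
        a_num = np.log(Q)[None, :, :] + logf1[:, None, :]  # G x K x D
        b_num = np.log1p(-Q)[None, :, :] + logf0[:, None, :]
        log_mix = np.logaddexp(a_num, b_num)
        log_gene_k = log_mix.sum(axis=2) + np.log(pi)[None, :]  # G x K
        norm = special.logsumexp(log_gene_k, axis=1)
        loglik = float(norm.sum())
        z = np.exp(log_gene_k - norm[:, None])  # G x K
        trace.append(loglik)
        if loglik - prev < tol and np.isfinite(prev):
            prev = loglik
            break
        prev = loglik
        a = np.exp(a_num - log_mix)  # G x K x D, P(DE | motif k, data)
        zk = z.sum(axis=0)
        pi = np.clip(zk / G, 1e-12, None)
        pi /= pi.sum()
        Q = np.einsum("gk,gkd->kd", z, a) / np.maximum(zk[:, None], 1e-300)
        Q = np.clip(Q, eps, 1.0 - eps)
    # final E-quantities at the converged parameters
    a_num = np.log(Q)[None, :, :] + logf1[:, None, :]
    b_num = np.log1p(-Q)[None, :, :] + logf0[:, None, :]
    log_mix = np.logaddexp(a_num, b_num)
    log_gene_k = log_mix.sum(axis=2) + np.log(pi)[None, :]
    norm = special.logsumexp(log_gene_k, axis=1)
    z = np.exp(log_gene_k - norm[:, None])
    a = np.exp(a_num - log_mix)
    posterior = np.einsum("gk,gkd->gd", z, a)
    return pi, Q, z, posterior, float(norm.sum()), np.array(trace)


class CormotifModel(BaseEstimator):
    """EM-fit motif mixture over per-condition DE densities, BIC-selected K.

    fit() accepts a :class:`ModeratedStats`; ``fit_`` is the selected
    :class:`CormotifFit`, ``fits_by_k_`` holds the best fit per candidate K.
    """

    def __init__(
        self,
        k_list: tuple[int, ...] = (1, 2, 3, 4),
        n_starts: int = 5,
        max_iter: int = 500,
        tol: float = 1e-4,
        seed: int = 0,
    ):
        self.k_list = k_list
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, mstats: ModeratedStats, y=None):
        logf0, logf1 = mstats.log_densities()
        if not (np.isfinite(logf0).all() and np.isfinite(logf1).all()):
            raise ValueError("non-finite densities; check the input statistics")
        G, D = logf0.shape
        fits = {}
        ss = np.random.SeedSequence(self.seed)
        for K in self.k_list:
            if K > G:
                raise ValueError(f"K={K} exceeds the number of genes")
            best = None
            for child in ss.spawn(self.n_starts):
                rng = np.random.default_rng(child)
                pi, Q, z, post, ll, trace = _em_run(
                    logf0, logf1, K, rng, self.max_iter, self.tol
                )
                if best is None or ll > best[4]:
                    best = (pi, Q, z, post, ll, trace)
            pi, Q, z, post, ll, trace = best
            n_params = (K - 1) + K * D
            bic = -2.0 * ll + n_params * np.log(G)
            fits[K] = CormotifFit(
                k=K,
                Q=Q,
                pi=pi,
                responsibilities=z,
                posterior=post,
                loglik=ll,
                loglik_trace=trace,
                bic=bic,
            )
        self.fits_by_k_ = fits
        self.k_ = min(fits, key=lambda K: fits[K].bic)
        self.fit_ = fits[self.k_]
        self.genes_ = mstats.genes
        self.conditions_ = mstats.conditions
        return self

    def posterior_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fit_.posterior, index=self.genes_, columns=self.conditions_
        )


def fit_cormotif(
    mstats: ModeratedStats,
    k_list=(1, 2, 3, 4),
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-4,
    seed: int = 0,
) -> CormotifModel:
    """Fit the motif mixture for each K and select by BIC."""
    return CormotifModel(
        k_list=k_list, n_starts=n_starts, max_iter=max_iter, tol=tol, seed=seed
    ).fit(mstats)


def posterior_de(fit: CormotifFit | CormotifModel, cutoff: float = 0.65):
    """Strict-threshold DE calls from the per-gene per-condition posterior."""
    if isinstance(fit, CormotifModel):
        post = fit.posterior_frame()
        return post > cutoff
    return fit.posterior > cutoff


def classify_conservation(
    posterior_a: pd.DataFrame, posterior_b: pd.DataFrame, tol: float = 0.3
) -> pd.DataFrame:
    """Conserved iff |posterior_a - posterior_b| <= tol (inclusive), per gene
    per contrast; the two species-wise posterior tables must align exactly.
    A tiny epsilon keeps the inclusive boundary robust to float rounding."""
    if not posterior_a.index.equals(posterior_b.index) or list(
        posterior_a.columns
    ) != list(posterior_b.columns):
        raise ValueError("posterior tables must share genes and contrasts")
    return (posterior_a - posterior_b).abs() <= tol + 1e-12


def sample_from_model(
    Q: np.ndarray,
    pi: np.ndarray,
    n_genes: int,
    dof: float = 20.0,
    scale: float = 3.0,
    seed: int = 0,
):
    """Draw moderated statistics from the motif mixture itself.

    Used for generate-and-refit calibration: each gene picks a motif from pi,
    each condition a DE indicator from q_kd; DE statistics are scale * t(dof),
    null statistics t(dof).  Returns (ModeratedStats, motif index, DE truth).
    """
    rng = np.random.default_rng(seed)
    Q = np.asarray(Q, dtype=float)
    pi = np.asarray(pi, dtype=float)
    K, D = Q.shape
    motif = rng.choice(K, size=n_genes, p=pi / pi.sum())
    de = rng.random((n_genes, D)) < Q[motif]
    t = rng.standard_t(dof, size=(n_genes, D))
    t[de] *= scale
    mstats = ModeratedStats(
        t=t,
        dof=np.full(D, float(dof)),
        scale=np.full((n_genes, D), float(scale)),
        genes=pd.Index([f"GENE{i + 1:05d}" for i in range(n_genes)], name="gene"),
        conditions=[f"cond{d + 1}" for d in range(D)],
    )
    return mstats, motif, de
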