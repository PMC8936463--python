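"""Marker-threshold cell staging and one-vs-rest marker discovery.

A cell "positively expresses" a gene when its (scaled) expression exceeds the
mean of that gene across all cells being classified.  Cells are then assigned
the first matching rule of an ordered marker scheme; the default osteogenic
scheme encodes the canonical RUNX2 -> BGLAP -> PHEX -> MEPE progression:

    maturing osteocyte       MEPE+
    mineralizing osteoblast  PHEX+
    embedding osteoblast     BGLAP+ and RUNX2-
    osteoblast               BGLAP+ and RUNX2+
    preosteoblast            RUNX2+

Marker genes per class are found by one-vs-rest Wilcoxon rank-sum tests on
log-normalized values, gated on detection fraction and average log fold
change, up-regulated only, BH-adjusted within class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse, stats
from sklearn.base import BaseEstimator, ClassifierMixin
from statsmodels.stats.multitest import multipletests

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class MarkerRule:
    label: str
    positive: tuple[str, ...] = ()
    negative: tuple[str, ...] = ()


@dataclass
class MarkerScheme:
    """Ordered first-match-wins rule list mapping marker positivity to labels."""

    rules: tuple[MarkerRule, ...]

    def __post_init__(self):
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise ValueError("scheme labels must be unique")

    @property
    def genes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.rules:
            for g in r.positive + r.negative:
                if g not in seen:
                    seen.append(g)
        return tuple(seen)


OSTEOGENIC_SCHEME = MarkerScheme(
    rules=(
        MarkerRule("maturing osteocyte", positive=("MEPE",)),
        MarkerRule("mineralizing osteoblast", positive=("PHEX",)),
        MarkerRule("embedding osteoblast", positive=("BGLAP",), negative=("RUNX2",)),
        MarkerRule("osteoblast", positive=("BGLAP", "RUNX2")),
        MarkerRule("preosteoblast", positive=("RUNX2",)),
    )
)

GENERAL_SCHEME = MarkerScheme(
    rules=(
        MarkerRule("pluripotent", positive=("POU5F1",)),
        MarkerRule("mesenchymal", positive=("CD44",), negative=("POU5F1",)),
        MarkerRule("osteogenic", positive=("COL1A1",), negative=("POU5F1",)),
    )
)


def _scaled_frame(data, genes) -> pd.DataFrame:
    """Extract a cells x genes DataFrame of scaled values for the given genes."""
    if isinstance(data, ad.AnnData):
        missing = [g for g in genes if g not in data.var_names]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        layer = "scaled" if "scaled" in data.layers else None
        sub = data[:, list(genes)]
        X = sub.layers[layer] if layer else sub.X
        if sparse.issparse(X):
            X = np.asarray(X.todense())
        return pd.DataFrame(np.asarray(X), index=data.obs_names, columns=list(genes))
    df = pd.DataFrame(data)
    missing = [g for g in genes if g not in df.columns]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    return df[list(genes)]


def positive_expression(data, gene: str) -> pd.Series:
    """Boolean per cell: expression strictly greater than the all-cell mean."""
    vals = _scaled_frame(data, [gene])[gene]
    return vals > vals.mean()


class MarkerStageClassifier(BaseEstimator, ClassifierMixin):
    """First-match-wins marker-rule classifier over an ordered scheme.

    fit() computes the per-gene positivity thresholds (the all-cell means);
    predict() applies the rules.  Cells matching no rule get "unclassified".
    """

    def __init__(self, scheme: MarkerScheme = OSTEOGENIC_SCHEME):
        self.scheme = scheme

    def fit(self, X, y=None):
        frame = _scaled_frame(X, self.scheme.genes)
        self.means_ = frame.mean(axis=0)
        self.classes_ = np.array([r.label for r in self.scheme.rules] + [UNCLASSIFIED])
        return self

    def predict(self, X) -> np.ndarray:
        frame = _scaled_frame(X, self.scheme.genes)
        pos = frame.gt(self.means_, axis=1)
        labels = np.full(len(frame), UNCLASSIFIED, dtype=object)
        unassigned = np.ones(len(frame), dtype=bool)
        for rule in self.scheme.rules:
            match = np.ones(len(frame), dtype=bool)
            for g in rule.positive:
                match &= pos[g].to_numpy()
            for g in rule.negative:
                match &= ~pos[g].to_numpy()
            take = match & unassigned
            labels[take] = rule.label
            unassigned &= ~match
        return labels


def assign_stage(data, scheme: MarkerScheme) -> pd.Series:
    """Assign each cell the first matching rule label of the scheme."""
    clf = MarkerStageClassifier(scheme=scheme).fit(data)
    frame = _scaled_frame(data, scheme.genes)
    return pd.Series(clf.predict(data), index=frame.index, name="label")


def _rank_sum_pvalue(x: np.ndarray, y: np.ndarray, exact_max_n: int = 50) -> float:
    """Two-sided Wilcoxon rank-sum p; exact enumeration for small tie-free
    samples, normal approximation with tie correction otherwise."""
    n = len(x) + len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n
    if n <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def find_markers(
    adata: ad.AnnData,
    labels,
    min_pct: float = 0.25,
    min_logfc: float = 0.25,
    top_n: int = 100,
) -> pd.DataFrame:
    """One-vs-rest marker table per class on the log-normalized layer.

    Genes are tested only when detected in at least ``min_pct`` of the class's
    cells and showing average log fold change of at least ``min_logfc`` in the
    class's favour (up-regulated only).  Average logFC is the difference of
    ln(mean(expm1(lognorm)) + 1) between class and rest.  BH adjustment is
    within class; ``rank`` orders genes by logFC for the top-``top_n`` selector.
    """
    labels = pd.Series(labels, index=adata.obs_names)
    classes = [c for c in labels.unique() if c != UNCLASSIFIED]
    if len(classes) < 2:
        raise ValueError("need at least two classes to find markers")
    if "lognorm" not in adata.layers:
        raise ValueError("run lognormalize first")
    X = adata.layers["lognorm"]
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    rows = []
    for cls in classes:
        in_cls = (labels == cls).to_numpy()
        if in_cls.sum() < 2 or (~in_cls).sum() < 2:
            raise ValueError(f"class {cls!r} needs >=2 cells on both sides")
        Xc, Xr = X[in_cls], X[~in_cls]
        pct_in = (Xc > 0).mean(axis=0)
        pct_out = (Xr > 0).mean(axis=0)
        logfc = np.log(np.expm1(Xc).mean(axis=0) + 1.0) - np.log(
            np.expm1(Xr).mean(axis=0) + 1.0
        )
        testable = (pct_in >= min_pct) & (logfc >= min_logfc)
        idx = np.where(testable)[0]
        pvals = np.array(
            [_rank_sum_pvalue(Xc[:, j], Xr[:, j]) for j in idx]
        )
        qvals = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
        for j, p, q in zip(idx, pvals, qvals):
            rows.append(
                {
                    "class": cls,
                    "gene": adata.var_names[j],
                    "pct_in": pct_in[j],
                    "pct_out": pct_out[j],
                    "avg_logfc": logfc[j],
                    "pvalue": p,
                    "qvalue": q,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["class", "gene", "pct_in", "pct_out", "avg_logfc", "pvalue", "qvalue"],
    )
    if len(table):
        table["rank"] = (
            table.groupby("class")["avg_logfc"].rank(ascending=False, method="first")
        ).astype(int)
        table = table[table["rank"] <= top_n].sort_values(["class", "rank"])
    return table.reset_index(drop=True)
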