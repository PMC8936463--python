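"""Species demultiplexing of pooled droplets from two-genome alignment counts.

Each droplet carries the number of UMIs uniquely aligned to the human genome
and to the chimpanzee genome (reads aligning to both genomes having been
discarded upstream).  Two rules are provided:

* a ratio rule — human if human-aligned / total >= ``high`` (default 0.9),
  chimpanzee if <= ``low`` (default 0.1), multiplet otherwise.  This is the
  appropriate rule for closely related genomes where bleed-through is mild.
* a percentile rule emulating the Cell Ranger "barnyard" heuristic —
  provisional species by majority genome, multiplet if both genome counts
  exceed the 10th percentile of the respective species' own-genome counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

LABEL_HUMAN = "human"
LABEL_CHIMP = "chimpanzee"
LABEL_MULTIPLET = "multiplet"
LABEL_UNASSIGNED = "unassigned"


def _as_count_array(droplets) -> np.ndarray:
    """Accept a DataFrame with human_umi/chimp_umi columns or an (n, 2) array."""
    if isinstance(droplets, pd.DataFrame):
        X = droplets[["human_umi", "chimp_umi"]].to_numpy()
    else:
        X = np.asarray(droplets)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected an (n_droplets, 2) count table")
    if (X < 0).any():
        raise ValueError("alignment counts must be non-negative")
    return X.astype(float)


class RatioDemultiplexer(BaseEstimator):
    """Assign droplets to species by the human-aligned UMI fraction.

    Parameters
    ----------
    high : droplets with ratio >= high are called human (inclusive).
    low : droplets with ratio <= low are called chimpanzee (inclusive).

    Droplets with ratio strictly between the thresholds are multiplets;
    droplets with zero aligned UMIs are labelled unassigned.
    """

    def __init__(self, high: float = 0.9, low: float = 0.1):
        self.high = high
        self.low = low

    def fit(self, X=None, y=None):
        if not (0.0 <= self.low < self.high <= 1.0):
            raise ValueError("thresholds must satisfy 0 <= low < high <= 1")
        self.is_fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        self.fit()
        counts = _as_count_array(X)
        total = counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            ratio = np.where(total > 0, counts[:, 0] / np.where(total > 0, total, 1), np.nan)
        labels = np.full(len(counts), LABEL_MULTIPLET, dtype=object)
        labels[total == 0] = LABEL_UNASSIGNED
        labels[(total > 0) & (ratio >= self.high)] = LABEL_HUMAN
        labels[(total > 0) & (ratio <= self.low)] = LABEL_CHIMP
        self.ratio_ = ratio
        return labels


class PercentileDemultiplexer(BaseEstimator):
    """Cell Ranger-style percentile multiplet rule.

    fit() assigns provisional species by the majority genome and records the
    ``pct``-th percentile of each species' own-genome UMI counts; predict()
    relabels as multiplet any droplet whose human count exceeds the human
    percentile AND whose chimpanzee count exceeds the chimpanzee percentile.
    """

    def __init__(self, pct: float = 10.0, interpolation: str = "linear"):
        self.pct = pct
        self.interpolation = interpolation

    def fit(self, X, y=None):
        counts = _as_count_array(X)
        if counts.sum() == 0:
            raise ValueError("all-zero alignment table cannot be demultiplexed")
        provisional = np.where(counts[:, 0] >= counts[:, 1], LABEL_HUMAN, LABEL_CHIMP)
        nonzero = counts.sum(axis=1) > 0
        hmask = (provisional == LABEL_HUMAN) & nonzero
        cmask = (provisional == LABEL_CHIMP) & nonzero
        if hmask.sum() < 2 or cmask.sum() < 2:
            raise ValueError("need at least 2 droplets per provisional species")
        self.human_threshold_ = float(
            np.percentile(counts[hmask, 0], self.pct, method=self.interpolation)
        )
        self.chimp_threshold_ = float(
            np.percentile(counts[cmask, 1], self.pct, method=self.interpolation)
        )
        return self

    def predict(self, X) -> np.ndarray:
        counts = _as_count_array(X)
        total = counts.sum(axis=1)
        labels = np.where(
            counts[:, 0] >= counts[:, 1], LABEL_HUMAN, LABEL_CHIMP
        ).astype(object)
        both_high = (counts[:, 0] > self.human_threshold_) & (
            counts[:, 1] > self.chimp_threshold_
        )
        labels[both_high] = LABEL_MULTIPLET
        labels[total == 0] = LABEL_UNASSIGNED
        return labels


def assign_by_ratio(droplets, high: float = 0.9, low: float = 0.1) -> pd.DataFrame:
    """Ratio-rule species assignment; returns barcode, label and ratio."""
    est = RatioDemultiplexer(high=high, low=low)
    labels = est.predict(droplets)
    return _assignment_frame(droplets, labels, est.ratio_)


def assign_by_percentile(droplets, pct: float = 10.0) -> pd.DataFrame:
    """Percentile-rule species assignment; returns barcode, label and ratio."""
    est = PercentileDemultiplexer(pct=pct).fit(droplets)
    labels = est.predict(droplets)
    counts = _as_count_array(droplets)
    total = counts.sum(axis=1)
    ratio = np.where(total > 0, counts[:, 0] / np.where(total > 0, total, 1), np.nan)
    return _assignment_frame(droplets, labels, ratio)


def _assignment_frame(droplets, labels, ratio) -> pd.DataFrame:
    if isinstance(droplets, pd.DataFrame) and "barcode" in droplets.columns:
        barcodes = droplets["barcode"].to_numpy()
    elif isinstance(droplets, pd.DataFrame):
        barcodes = droplets.index.to_numpy()
    else:
        barcodes = np.array([f"droplet{i}" for i in range(len(labels))])
    return pd.DataFrame({"barcode": barcodes, "label": labels, "ratio": ratio})


def demux_report(assignments: pd.DataFrame, truth: pd.Series | None = None):
    """Summary counts per label, plus a confusion matrix and accuracy if truth
    labels (indexed like the assignments) are supplied."""
    counts = assignments["label"].value_counts().rename_axis("label").to_frame("n")
    report = {"counts": counts}
    if truth is not None:
        truth = pd.Series(truth).reindex(assignments["barcode"]).to_numpy()
        pred = assignments["label"].to_numpy()
        confusion = pd.crosstab(
            pd.Series(truth, name="true"), pd.Series(pred, name="assigned")
        )
        report["confusion"] = confusion
        report["accuracy"] = float(np.mean(pred == truth))
    return report
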