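"""Expression mean/variance comparisons across classifications and gene-set
enrichment (hypergeometric and Fisher's exact) with BH q-values.

The variance analysis computes, separately per species, per-gene means and
variances of pseudobulk expression within each cell classification and
compares adjacent classifications along the differentiation ordering with
Welch two-sided t-tests (on the gene-wise distributions of means and of
variances; reported variances are log2-transformed).  Enrichment tests take
user-supplied GMT collections; the Fisher background is the set of genes
tested for DE.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def mean_variance_by_group(expression: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene sample mean and variance within each group of columns.

    ``expression`` is genes x observations; ``groups`` maps each column to a
    group (e.g. species|classification).  Singleton groups are dropped with a
    warning; zero variances are flagged since log2 is undefined for them.
    """
    groups = pd.Series(groups, index=expression.columns)
    rows = []
    for g, cols in groups.groupby(groups).groups.items():
        if len(cols) < 2:
            warnings.warn(f"group {g!r} has a single observation; dropped")
            continue
        sub = expression[list(cols)]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore"):
            log2var = np.where(var > 0, np.log2(np.maximum(var, 1e-300)), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "group": g,
                    "gene": expression.index,
                    "mean": mean.to_numpy(),
                    "variance": var.to_numpy(),
                    "log2_variance": log2var,
                    "zero_variance": var.to_numpy() == 0,
                }
            )
        )
    if not rows:
        raise ValueError("no group with >= 2 observations")
    return pd.concat(rows, ignore_index=True)


def adjacent_stage_tests(
    table: pd.DataFrame, ordering: list[str], value: str = "variance"
) -> pd.DataFrame:
    """Welch two-sided t-tests between adjacent classifications.

    ``table`` is the output of :func:`mean_variance_by_group` with group
    labels drawn from ``ordering``; the test compares the per-gene
    distribution of ``value`` ("mean" or "variance") between each adjacent
    pair.  Missing groups are skipped with a warning.
    """
    rows = []
    for a, b in zip(ordering[:-1], ordering[1:]):
        xa = table.loc[table["group"] == a, value].dropna().to_numpy()
        xb = table.loc[table["group"] == b, value].dropna().to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(f"pair ({a!r}, {b!r}) missing data; skipped")
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "value": value,
                "t": float(t),
                "pvalue": float(p),
                "mean_a": float(xa.mean()),
                "mean_b": float(xb.mean()),
            }
        )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "value", "t", "pvalue",
                                       "mean_a", "mean_b"])


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: tab-separated set name, description, member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def hypergeom_enrich(
    query,
    universe,
    collection: dict[str, list[str]],
    p_cut: float = 0.01,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each gene set in the query.

    Sets are intersected with the universe first; sets left empty are skipped.
    Significance requires both p < p_cut and BH q < q_cut.  GeneRatio is
    overlapping / non-overlapping genes in the query.
    """
    query = set(query)
    universe = set(universe)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, members in collection.items():
        members = set(members) & universe
        if not members:
            continue
        overlap = len(query & members)
        M, n, N = len(universe), len(members), len(query)
        p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
        ratio = overlap / max(N - overlap, 1)
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "query_size": N,
                "set_size": n,
                "universe_size": M,
                "pvalue": p,
                "gene_ratio": ratio,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["set", "overlap", "query_size", "set_size", "universe_size",
                 "pvalue", "gene_ratio"],
    )
    if len(out):
        out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out["significant"] = (out["pvalue"] < p_cut) & (out["qvalue"] < q_cut)
    else:
        out["qvalue"] = []
        out["significant"] = []
    return out


def fisher_external(de_genes, background, external: dict[str, list[str]] | list):
    """One-sided Fisher's exact enrichment of external sets in the DE genes.

    The 2x2 table is (DE & set, DE \\ set; set \\ DE, neither), all within the
    DE-tested background.  Reports the overlap (DE.Interest), GeneRatio and
    the odds ratio; degenerate margins give p = 1 with a flag.
    """
    de = set(de_genes)
    bg = set(background)
    if not de <= bg:
        raise ValueError("DE genes must be a subset of the background")
    if not isinstance(external, dict):
        external = {"external": list(external)}
    rows = []
    for name, members in external.items():
        members = set(members) & bg
        a = len(de & members)
        b = len(de - members)
        c = len(members - de)
        d = len(bg) - a - b - c
        degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
        if degenerate:
            odds, p = np.nan, 1.0
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "set": name,
                "de_interest": a,
                "de_size": len(de),
                "set_size": len(members),
                "background_size": len(bg),
                "odds_ratio": float(odds) if np.isfinite(odds) else np.nan,
                "pvalue": float(p),
                "gene_ratio": a / max(len(de) - a, 1),
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out
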