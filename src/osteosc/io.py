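"""Readers and writers for the on-disk formats: 10X-style MTX triplets,
droplet alignment tables, metadata TSVs and versioned result tables."""

from __future__ import annotations

import os
from importlib.metadata import version, PackageNotFoundError

import numpy as np
import pandas as pd
import anndata as ad
from scipy import io as spio
from scipy import sparse


def _pkg_version() -> str:
    try:
        return version("osteosc")
    except PackageNotFoundError:
        return "dev"


def read_10x_triplet(directory) -> ad.AnnData:
    """Read matrix.mtx + barcodes.tsv + features.tsv (genes x cells on disk)
    into an AnnData of cells x genes."""
    mtx = os.path.join(directory, "matrix.mtx")
    bpath = os.path.join(directory, "barcodes.tsv")
    fpath = os.path.join(directory, "features.tsv")
    for path in (mtx, bpath, fpath):
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing 10X triplet file: {path}")
    try:
        X = spio.mmread(mtx)
    except ValueError as err:
        raise ValueError(f"malformed Matrix Market file {mtx}: {err}") from err
    barcodes = pd.read_csv(bpath, sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(fpath, sep="\t", header=None)
    if barcodes.duplicated().any():
        dupes = barcodes[barcodes.duplicated()].tolist()[:5]
        raise ValueError(f"duplicate barcodes: {dupes}")
    X = sparse.csr_matrix(X.T)
    if X.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix is {X.shape} but {len(barcodes)} barcodes x "
            f"{len(features)} features were provided"
        )
    var = pd.DataFrame(index=pd.Index(features[0].astype(str), name="gene"))
    for j, name in enumerate(["name", "mito", "ribo", "marker_role"], start=1):
        if j < features.shape[1]:
            col = features[j]
            if name in ("mito", "ribo"):
                col = col.astype(str).str.lower().isin(["true", "1", "yes"])
            var[name] = col.to_numpy()
    return ad.AnnData(
        X=X, obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")), var=var
    )


def write_10x_triplet(adata: ad.AnnData, directory) -> None:
    """Write an AnnData (cells x genes) as a genes x cells MTX triplet."""
    os.makedirs(directory, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    spio.mmwrite(
        os.path.join(directory, "matrix.mtx"), sparse.coo_matrix(X.T), field="integer"
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    feats = pd.DataFrame({"gene": adata.var_names, "name": adata.var_names})
    for col in ("mito", "ribo", "marker_role"):
        if col in adata.var:
            feats[col] = adata.var[col].to_numpy()
    feats.to_csv(
        os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False
    )


def write_table(df: pd.DataFrame, path, params: dict | None = None, index=True) -> None:
    """Write a result TSV with a comment header naming the producing version
    and the parameters actually applied."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# osteosc {_pkg_version()}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
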