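"""End-to-end pipeline: demultiplex -> QC -> annotate -> pseudobulk -> mixed-
model DE -> correlation motifs -> topics -> variance/enrichment, writing
versioned TSV outputs.

All randomness fans out from a single seed via SeedSequence, so re-running a
config reproduces identical outputs for every deterministic stage.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import cormotif as cm
from . import demux as dx
from . import enrich as en
from . import preprocess as pp
from . import pseudobulk as pbk
from . import topics as tp
from .io import read_10x_triplet, write_table
from .simulate import SimulationConfig, generate_experiment

logger = logging.getLogger("osteosc.pipeline")

_STAGE_NAMES = (
    "simulate",
    "demux",
    "qc",
    "annotate",
    "pseudobulk",
    "de",
    "cormotif",
    "topics",
    "enrich",
)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the global seed for a pipeline run."""

    outdir: str = "osteosc_out"
    # either a simulation block or input paths
    simulation: dict | None = None
    counts_dir: str | None = None
    droplet_tsv: str | None = None
    metadata_tsv: str | None = None
    go_gmt: str | None = None
    external_gmt: str | None = None
    # thresholds
    demux_method: str = "ratio"
    demux_high: float = 0.9
    demux_low: float = 0.1
    demux_pct: float = 10.0
    min_umi: int = 1000
    min_genes: int = 700
    max_mito: float = 0.25
    fdr: float = 0.01
    posterior_cutoff: float = 0.65
    conservation_tol: float = 0.3
    subsample_to: int | None = None
    cormotif_k: tuple[int, ...] = (1, 2, 3, 4)
    cormotif_starts: int = 3
    topics_k: tuple[int, ...] = (3, 4, 5, 6, 7)
    topics_max_iter: int = 50
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.simulation is None and self.counts_dir is None:
            raise ValueError("config needs either a simulation block or counts_dir")
        for attr in ("counts_dir", "droplet_tsv", "metadata_tsv", "go_gmt",
                     "external_gmt"):
            path = getattr(self, attr)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{attr} does not exist: {path}")
        if not (0 <= self.demux_low < self.demux_high <= 1):
            raise ValueError("demux thresholds out of range")
        if not 0 < self.fdr < 1 or not 0 < self.posterior_cutoff < 1:
            raise ValueError("fdr and posterior_cutoff must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("cormotif_k", "topics_k"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGE_NAMES, children)
    }


def _species_design(meta: pd.DataFrame) -> np.ndarray:
    x = (meta["species"] == dx.LABEL_HUMAN).astype(float).to_numpy()
    return np.column_stack([np.ones(len(meta)), x])


def run_pipeline(config: PipelineConfig) -> str:
    """Execute every stage and return the artifact directory."""
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "pipeline.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    seeds = _stage_seeds(config.seed)
    try:
        return _run(config, out, seeds)
    except Exception as err:
        logger.error("pipeline halted: %s", err)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: str, seeds: dict[str, int]) -> str:
    logger.info("parameters: %s", asdict(config))
    logger.info("stage seeds: %s", seeds)

    # ---- inputs ----------------------------------------------------------
    if config.simulation is not None:
        sim_cfg = SimulationConfig(**{**config.simulation, "seed": seeds["simulate"]})
        adata, droplets, truth = generate_experiment(sim_cfg)
        write_table(truth.genes, os.path.join(out, "truth_genes.tsv"))
        write_table(truth.droplets, os.path.join(out, "truth_droplets.tsv"))
        stages = list(sim_cfg.stages)
    else:
        adata = read_10x_triplet(config.counts_dir)
        droplets = pd.read_csv(config.droplet_tsv, sep="\t")
        meta = pd.read_csv(config.metadata_tsv, sep="\t", index_col=0)
        missing = [c for c in ("line", "replicate", "stage_true") if c not in meta]
        if missing:
            raise ValueError(f"metadata is missing required columns: {missing}")
        adata.obs = adata.obs.join(meta)
        stages = list(pd.unique(meta["stage_true"]))
    logger.info("input: %d droplets x %d genes", *adata.shape)

    # ---- demux -----------------------------------------------------------
    if config.demux_method == "ratio":
        assignments = dx.assign_by_ratio(
            droplets, high=config.demux_high, low=config.demux_low
        )
    elif config.demux_method == "percentile":
        assignments = dx.assign_by_percentile(droplets, pct=config.demux_pct)
    else:
        raise ValueError("demux_method must be 'ratio' or 'percentile'")
    write_table(
        assignments,
        os.path.join(out, "demux.tsv"),
        {"method": config.demux_method, "high": config.demux_high,
         "low": config.demux_low},
        index=False,
    )
    labels = pd.Series(
        assignments["label"].to_numpy(), index=assignments["barcode"]
    ).reindex(adata.obs_names)
    keep = labels.isin([dx.LABEL_HUMAN, dx.LABEL_CHIMP]).to_numpy()
    adata = adata[keep].copy()
    adata.obs["species"] = labels[keep].to_numpy()
    logger.info("demux: kept %d singlets (high=%s low=%s)", keep.sum(),
                config.demux_high, config.demux_low)

    # ---- qc + normalization ---------------------------------------------
    adata = pp.filter_cells(
        adata, min_umi=config.min_umi, min_genes=config.min_genes,
        max_mito=config.max_mito,
    )
    logger.info("qc: kept %d cells (min_umi=%d min_genes=%d max_mito=%s)",
                adata.n_obs, config.min_umi, config.min_genes, config.max_mito)
    adata = pp.lognormalize(adata)
    adata = pp.scale_and_regress(adata)
    write_table(
        adata.obs[["total_umis", "n_genes", "mito_frac"]],
        os.path.join(out, "qc_metrics.tsv"),
        {"min_umi": config.min_umi, "min_genes": config.min_genes,
         "max_mito": config.max_mito},
    )

    # ---- annotate --------------------------------------------------------
    adata.obs["stage"] = adata.obs["stage_true"].astype(str)
    osteo_mask = (adata.obs["stage"] == stages[-1]).to_numpy()
    substage = pd.Series("", index=adata.obs_names, dtype=object)
    if osteo_mask.sum() >= 2:
        substage.loc[osteo_mask] = ann.assign_stage(
            adata[osteo_mask], ann.OSTEOGENIC_SCHEME
        ).to_numpy()
    adata.obs["substage"] = substage
    write_table(
        adata.obs[["species", "stage", "substage"]],
        os.path.join(out, "labels.tsv"),
    )
    markers = ann.find_markers(adata, adata.obs["stage"])
    write_table(markers, os.path.join(out, "markers.tsv"), index=False)
    logger.info("annotate: %d osteogenic cells substaged; %d marker rows",
                osteo_mask.sum(), len(markers))

    # ---- pseudobulk + standard DE per classification scheme --------------
    flags = adata.var[["mito", "ribo"]]
    de_outputs = {}
    scheme_cells = {
        "stage": (np.ones(adata.n_obs, dtype=bool), adata.obs["stage"]),
        "substage": (
            osteo_mask & (adata.obs["substage"] != ann.UNCLASSIFIED).to_numpy()
            & (adata.obs["substage"] != "").to_numpy(),
            adata.obs["substage"],
        ),
    }
    pb_by_scheme = {}
    for scheme, (mask, cls_labels) in scheme_cells.items():
        sub = adata[mask]
        pb = pbk.build_pseudobulk(
            sub, cls_labels[mask], group_keys=("line", "replicate"),
            subsample_to=config.subsample_to, seed=seeds["pseudobulk"],
        )
        pb = pbk.filter_genes(pb, flags)
        pb_by_scheme[scheme] = pb
        write_table(
            pb.counts, os.path.join(out, f"pseudobulk_{scheme}.tsv"),
            {"scheme": scheme, "subsample_to": config.subsample_to},
        )
        rows = []
        for cls in pb.samples["classification"].unique():
            cols = pb.samples.index[pb.samples["classification"] == cls]
            sub_pb = pbk.PseudobulkMatrix(
                counts=pb.counts[cols], samples=pb.samples.loc[cols]
            )
            norm = pbk.tmm_factors(sub_pb)
            design = _species_design(sub_pb.samples)
            we = pbk.voom_weights(sub_pb, norm, design)
            res = pbk.fit_lmm(we, sub_pb.samples, fdr=config.fdr)
            res.insert(0, "classification", cls)
            rows.append(res.reset_index(names="gene"))
        de = pd.concat(rows, ignore_index=True)
        de_outputs[scheme] = de
        write_table(
            de, os.path.join(out, f"de_{scheme}.tsv"),
            {"fdr": config.fdr, "scheme": scheme}, index=False,
        )
        logger.info("de[%s]: %d genes x %d classifications, %d DE at q<%s",
                    scheme, pb.counts.shape[0],
                    pb.samples["classification"].nunique(),
                    int(de["de"].sum()), config.fdr)

    # ---- cormotif: interspecific DE over stages --------------------------
    pb = pb_by_scheme["stage"]
    conditions = {}
    for stage in stages:
        cols = pb.samples.index[pb.samples["classification"] == stage]
        conditions[stage] = (
            pbk.PseudobulkMatrix(counts=pb.counts[cols],
                                 samples=pb.samples.loc[cols]),
            pb.samples.loc[cols],
        )
    mstats = cm.moderated_stats(conditions, _species_design)
    cmfit = cm.fit_cormotif(
        mstats, k_list=config.cormotif_k, n_starts=config.cormotif_starts,
        seed=seeds["cormotif"],
    )
    post = cmfit.posterior_frame()
    write_table(post, os.path.join(out, "cormotif_posterior.tsv"),
                {"cutoff": config.posterior_cutoff, "k_selected": cmfit.k_})
    summary = pd.concat(
        [
            pd.DataFrame(
                {"k": K, "motif": np.arange(f.k), "pi": f.pi, "bic": f.bic,
                 **{f"q_{c}": f.Q[:, j] for j, c in enumerate(stages)}}
            )
            for K, f in cmfit.fits_by_k_.items()
        ],
        ignore_index=True,
    )
    write_table(summary, os.path.join(out, "cormotif_motifs.tsv"), index=False)
    de_calls = cm.posterior_de(cmfit, cutoff=config.posterior_cutoff)
    logger.info("cormotif: selected K=%d; DE per stage: %s", cmfit.k_,
                de_calls.sum().to_dict())

    # ---- cormotif: species-wise stage transitions + conservation ---------
    posteriors = {}
    for species in (dx.LABEL_HUMAN, dx.LABEL_CHIMP):
        conds = {}
        for a, b in zip(stages[:-1], stages[1:]):
            cols = pb.samples.index[
                (pb.samples["species"] == species)
                & pb.samples["classification"].isin([a, b])
            ]
            meta = pb.samples.loc[cols]
            conds[f"{a}->{b}"] = (
                pbk.PseudobulkMatrix(counts=pb.counts[cols], samples=meta),
                meta,
            )

        def stage_design(meta, _pair_levels=stages):
            later = meta["classification"].to_numpy()
            ref = min(
                (s for s in set(later)), key=lambda s: _pair_levels.index(s)
            )
            return np.column_stack(
                [np.ones(len(meta)), (later != ref).astype(float)]
            )

        sp_stats = cm.moderated_stats(conds, stage_design)
        sp_fit = cm.fit_cormotif(
            sp_stats, k_list=tuple(k for k in config.cormotif_k if k <= 3),
            n_starts=config.cormotif_starts, seed=seeds["cormotif"] + 1,
        )
        posteriors[species] = sp_fit.posterior_frame()
    conserved = cm.classify_conservation(
        posteriors[dx.LABEL_HUMAN], posteriors[dx.LABEL_CHIMP],
        tol=config.conservation_tol,
    )
    cons_out = pd.concat(
        {
            "posterior_human": posteriors[dx.LABEL_HUMAN],
            "posterior_chimpanzee": posteriors[dx.LABEL_CHIMP],
            "conserved": conserved,
        },
        axis=1,
    )
    cons_out.columns = ["|".join(c) for c in cons_out.columns]
    write_table(cons_out, os.path.join(out, "conservation.tsv"),
                {"tol": config.conservation_tol})

    # ---- expression variance across stages -------------------------------
    l2 = pbk.log2cpm(pb.counts)
    var_rows, test_rows = [], []
    for species in (dx.LABEL_HUMAN, dx.LABEL_CHIMP):
        cols = pb.samples.index[pb.samples["species"] == species]
        table = en.mean_variance_by_group(
            l2[cols], pb.samples.loc[cols, "classification"]
        )
        table.insert(0, "species", species)
        var_rows.append(table)
        for value in ("mean", "variance"):
            tests = en.adjacent_stage_tests(table, stages, value=value)
            tests.insert(0, "species", species)
            test_rows.append(tests)
    write_table(pd.concat(var_rows, ignore_index=True),
                os.path.join(out, "expression_variance.tsv"), index=False)
    write_table(pd.concat(test_rows, ignore_index=True),
                os.path.join(out, "variance_tests.tsv"), index=False)

    # ---- topic modeling ---------------------------------------------------
    batches = (
        adata.obs["replicate"].astype(str)
        if "replicate" in adata.obs
        else pd.Series("1", index=adata.obs_names)
    )
    nonzero = np.asarray(adata.X.sum(axis=0)).ravel() > 0
    corrected = tp.batch_correct_counts(adata[:, nonzero], batches.to_numpy())
    topic_frames = []
    for k in config.topics_k:
        fit = tp.fit_poisson_nmf(
            corrected, k=k, max_iter=config.topics_max_iter,
            seed=seeds["topics"] + k,
        )
        topic, _ = tp.to_topic_model(fit)
        obs = adata.obs.loc[fit.kept_cells_]
        long = pd.DataFrame(
            {
                "cell": np.repeat(obs.index.to_numpy(), k),
                "k": k,
                "topic": np.tile(np.arange(k), len(obs)),
                "probability": topic.ravel(),
                "species": np.repeat(obs["species"].to_numpy(), k),
                "stage": np.repeat(obs["stage"].to_numpy(), k),
            }
        )
        topic_frames.append(long)
        logger.info("topics k=%d: %d iterations, objective %.3f", k,
                    fit.n_iter_, fit.objective_trace_[-1])
    write_table(pd.concat(topic_frames, ignore_index=True),
                os.path.join(out, "topics.tsv"), index=False)

    # ---- enrichment -------------------------------------------------------
    universe = list(pb.counts.index)
    if config.go_gmt is not None:
        collection = en.read_gmt(config.go_gmt)
        go_rows = []
        for cls in markers["class"].unique():
            query = [g for g in markers.loc[markers["class"] == cls, "gene"]
                     if g in set(universe)]
            if not query:
                continue
            res = en.hypergeom_enrich(query, universe, collection)
            res.insert(0, "class", cls)
            go_rows.append(res)
        if go_rows:
            write_table(pd.concat(go_rows, ignore_index=True),
                        os.path.join(out, "go_enrichment.tsv"), index=False)
    if config.external_gmt is not None:
        external = en.read_gmt(config.external_gmt)
        fisher_rows = []
        for stage in stages:
            de_genes = post.index[de_calls[stage]]
            res = en.fisher_external(de_genes, universe, external)
            res.insert(0, "condition", stage)
            fisher_rows.append(res)
        write_table(pd.concat(fisher_rows, ignore_index=True),
                    os.path.join(out, "external_enrichment.tsv"), index=False)

    logger.info("pipeline complete: %s", out)
    return out
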