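"""Synthetic pooled-droplet scRNA-seq experiments with full ground truth.

The generator emulates the design of a two-species (human/chimpanzee) iPSC
osteogenesis time course: six cell lines per species plus one technical
replicate per species, three collection stages (pluripotent, mesenchymal,
osteogenic), five osteogenic substages with marker programs, per-line random
effects, motif-structured interspecific differential expression, cross-species
doublets, and cross-genome alignment bleed-through.  Every droplet, cell and
gene carries a truth record so each downstream stage can be tested without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse

HUMAN = "human"
CHIMP = "chimpanzee"

DEFAULT_STAGES = ("pluripotent", "mesenchymal", "osteogenic")
DEFAULT_SUBSTAGES = (
    "preosteoblast",
    "osteoblast",
    "embedding osteoblast",
    "mineralizing osteoblast",
    "maturing osteocyte",
)

# Marker programs: gene -> (labels in which the gene is boosted, log-scale effect).
# Stage markers follow the canonical pluripotent/mesenchymal/osteogenic trio;
# substage markers follow the RUNX2 -> BGLAP -> PHEX -> MEPE progression.
DEFAULT_MARKER_MAP = {
    "POU5F1": (("pluripotent",), 3.0),
    "CD44": (("mesenchymal",), 3.0),
    "COL1A1": (("osteogenic",), 3.0),
    "RUNX2": (("preosteoblast", "osteoblast"), 4.0),
    "BGLAP": (("osteoblast", "embedding osteoblast"), 4.0),
    "PHEX": (("mineralizing osteoblast",), 4.0),
    "MEPE": (("maturing osteocyte",), 4.0),
}

# Two interspecific motifs: one with DE shared across all conditions, one with
# essentially no DE anywhere (the dominant patterns in this study design).
DEFAULT_MOTIF_SPEC = (
    ((0.9, 0.9, 0.9), 0.3),
    ((0.05, 0.05, 0.05), 0.7),
)


@dataclass
class SimulationConfig:
    """Parameters of a synthetic pooled-droplet experiment.

    Fractions are probabilities in [0, 1]; effects and standard deviations are
    on the natural-log scale of expression except ``lfc_sd`` which is the SD of
    planted log2 fold changes.
    """

    n_genes: int = 1000
    n_lines_per_species: int = 6
    replicate_lines: tuple[str, ...] | None = None  # default: first line of each species
    stages: tuple[str, ...] = DEFAULT_STAGES
    substages: tuple[str, ...] = DEFAULT_SUBSTAGES
    cells_per_sample: int = 360
    marker_map: dict | None = None
    frac_de: float = 0.3
    motif_spec: tuple | None = None
    lfc_sd: float = 1.0
    line_effect_sd: float = 0.15
    stage_effect_sd: float = 0.4
    frac_stage_var: float = 0.2
    libsize_log_mean: float = float(np.log(5000.0))
    libsize_log_sd: float = 0.35
    mito_frac_mean: float = 0.05
    mito_frac_conc: float = 60.0
    doublet_rate: float = 0.0
    bleed: float = 0.0
    overdispersion: float = 0.0
    n_mito_genes: int = 5
    n_ribo_genes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("stages must be a non-empty ordered list")
        for name, val in [
            ("frac_de", self.frac_de),
            ("mito_frac_mean", self.mito_frac_mean),
            ("doublet_rate", self.doublet_rate),
            ("bleed", self.bleed),
            ("frac_stage_var", self.frac_stage_var),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.marker_map is None:
            self.marker_map = dict(DEFAULT_MARKER_MAP)
        if self.motif_spec is None:
            q = [
                tuple(np.full(len(self.stages), v)) for v in (0.9, 0.05)
            ]
            self.motif_spec = ((q[0], 0.3), (q[1], 0.7))
        weights = [w for _, w in self.motif_spec]
        if not np.isclose(sum(weights), 1.0):
            raise ValueError("motif weights must sum to 1")
        for qvec, _ in self.motif_spec:
            if len(qvec) != len(self.stages):
                raise ValueError(
                    "each motif vector needs one entry per simulated condition"
                )
        if len(self.marker_map) + self.n_mito_genes + self.n_ribo_genes > self.n_genes:
            raise ValueError("marker + mito + ribo genes exceed n_genes")
        if self.replicate_lines is None:
            self.replicate_lines = ("H1", "C1")[: max(0, 2)]


@dataclass
class SimulationTruth:
    """Ground truth for a simulated experiment.

    droplets : per-droplet species, doublet flag, line, replicate, stage and
        substage (indexed by barcode).
    genes : per-gene motif index, per-condition DE indicators and the planted
        log2 fold change (human relative to chimpanzee).
    line_effects : genes x lines matrix of random line intercepts (log scale).
    """

    droplets: pd.DataFrame
    genes: pd.DataFrame
    line_effects: pd.DataFrame


def _gene_names(config: SimulationConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    markers = list(config.marker_map)
    mito = [f"MT-SIM{i + 1}" for i in range(config.n_mito_genes)]
    ribo = [f"RPL-SIM{i + 1}" for i in range(config.n_ribo_genes)]
    n_rest = config.n_genes - len(markers) - len(mito) - len(ribo)
    rest = [f"GENE{i + 1:05d}" for i in range(n_rest)]
    names = markers + mito + ribo + rest
    is_mito = np.zeros(config.n_genes, dtype=bool)
    is_mito[len(markers) : len(markers) + len(mito)] = True
    is_ribo = np.zeros(config.n_genes, dtype=bool)
    is_ribo[len(markers) + len(mito) : len(markers) + len(mito) + len(ribo)] = True
    return names, is_mito, is_ribo


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    """One row per (species, line, replicate, stage) sample, plus pool ids.

    Each pool pairs one human line with one chimpanzee line at the same stage,
    so species and collection batch are never confounded.
    """
    rows = []
    for i in range(config.n_lines_per_species):
        for species, prefix in ((HUMAN, "H"), (CHIMP, "C")):
            line = f"{prefix}{i + 1}"
            reps = [1]
            if line in config.replicate_lines:
                reps.append(2)
            for rep in reps:
                for stage in config.stages:
                    rows.append(
                        {
                            "species": species,
                            "line": line,
                            "replicate": rep,
                            "stage": stage,
                            "pool": f"pool-{i + 1}-r{rep}-{stage}",
                        }
                    )
    return pd.DataFrame(rows)


def _draw_gene_truth(config: SimulationConfig, rng: np.random.Generator):
    G, D = config.n_genes, len(config.stages)
    weights = np.array([w for _, w in config.motif_spec])
    qmat = np.array([q for q, _ in config.motif_spec])  # K x D
    motif = rng.choice(len(weights), size=G, p=weights)
    de = rng.random((G, D)) < qmat[motif]
    # frac_de caps the overall share of genes allowed to carry any effect
    has_any = de.any(axis=1)
    allowed = rng.random(G) < config.frac_de
    de[~allowed] = False
    motif = np.where(allowed, motif, -1)
    lfc = np.where(de.any(axis=1), rng.normal(0.0, config.lfc_sd, size=G), 0.0)
    del has_any
    return motif, de, lfc


def generate_experiment(config: SimulationConfig):
    """Simulate a pooled two-species experiment.

    Returns
    -------
    adata : AnnData (droplets x genes) of UMI counts with truth metadata in
        ``.obs`` and gene flags in ``.var``.
    droplets : DataFrame (barcode, human_umi, chimp_umi) — the two-genome
        alignment-count table used for species demultiplexing.
    truth : SimulationTruth
    """
    rng = np.random.default_rng(config.seed)
    gene_names, is_mito, is_ribo = _gene_names(config)
    G = config.n_genes
    stages = list(config.stages)
    samples = _sample_table(config)

    motif, de, lfc = _draw_gene_truth(config, rng)

    baseline = rng.normal(0.0, 1.0, size=G)
    # stage modulation for a random subset of genes (transcriptomes differ by stage)
    stage_eff = np.zeros((G, len(stages)))
    var_genes = rng.random(G) < config.frac_stage_var
    stage_eff[var_genes] = rng.normal(
        0.0, config.stage_effect_sd, size=(int(var_genes.sum()), len(stages))
    )

    lines = sorted(samples["line"].unique())
    line_eff = {
        line: rng.normal(0.0, config.line_effect_sd, size=G) for line in lines
    }

    marker_idx = {g: i for i, g in enumerate(gene_names)}
    ln2 = np.log(2.0)

    def profile(species: str, line: str, stage: str, substage: str | None):
        """Relative gene abundances for one (species, line, stage, substage)."""
        mu = baseline + stage_eff[:, stages.index(stage)] + line_eff[line]
        for gene, (labels, effect) in config.marker_map.items():
            if stage in labels or (substage is not None and substage in labels):
                mu[marker_idx[gene]] += effect
        if species == HUMAN:
            mu = mu + de[:, stages.index(stage)] * lfc * ln2
        p = np.exp(mu - mu.max())
        p[is_mito] = 0.0
        p = p / p.sum()
        return p

    obs_rows: list[dict] = []
    count_blocks: list[sparse.csr_matrix] = []
    hu_umi: list[np.ndarray] = []
    ch_umi: list[np.ndarray] = []

    def draw_cells(p: np.ndarray, n: int):
        """Counts for n cells sharing relative abundances p (mito scaled per cell)."""
        totals = np.maximum(
            rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n), 1.0
        ).astype(np.int64)
        a = config.mito_frac_mean * config.mito_frac_conc
        b = (1.0 - config.mito_frac_mean) * config.mito_frac_conc
        mito_f = rng.beta(a, b, size=n) if is_mito.any() else np.zeros(n)
        pm = np.tile(p, (n, 1))
        pm *= (1.0 - mito_f)[:, None]
        if is_mito.any():
            pm[:, is_mito] = (mito_f / is_mito.sum())[:, None]
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            pm = pm * rng.gamma(shape, 1.0 / shape, size=pm.shape)
            pm /= pm.sum(axis=1, keepdims=True)
        return rng.multinomial(totals, pm), totals

    def split_alignment(totals: np.ndarray, species: str):
        own = rng.binomial(totals, 1.0 - config.bleed)
        other = totals - own
        if species == HUMAN:
            return own, other
        return other, own

    barcode_counter = 0

    def next_barcode() -> str:
        nonlocal barcode_counter
        barcode_counter += 1
        return f"BC{barcode_counter:07d}"

    for _, s in samples.iterrows():
        n = config.cells_per_sample
        if s["stage"] == stages[-1] and config.substages:
            # osteogenic cells are spread across the five substages
            sub_assign = rng.choice(len(config.substages), size=n)
            groups = [
                (config.substages[j], np.sum(sub_assign == j))
                for j in range(len(config.substages))
            ]
        else:
            groups = [(None, n)]
        for substage, n_sub in groups:
            if n_sub == 0:
                continue
            p = profile(s["species"], s["line"], s["stage"], substage)
            counts, totals = draw_cells(p, int(n_sub))
            h, c = split_alignment(totals, s["species"])
            count_blocks.append(sparse.csr_matrix(counts))
            hu_umi.append(h)
            ch_umi.append(c)
            for _ in range(int(n_sub)):
                obs_rows.append(
                    {
                        "barcode": next_barcode(),
                        "species_true": s["species"],
                        "doublet": False,
                        "line": s["line"],
                        "replicate": int(s["replicate"]),
                        "stage_true": s["stage"],
                        "substage_true": substage if substage is not None else "",
                        "pool": s["pool"],
                    }
                )

    # Cross-species doublets: one human cell and one chimpanzee cell from the
    # same pool merged into a single droplet.
    if config.doublet_rate > 0:
        pools = samples.groupby("pool")
        for pool, grp in pools:
            if set(grp["species"]) != {HUMAN, CHIMP}:
                continue
            n_d = int(round(config.doublet_rate * config.cells_per_sample))
            if n_d == 0:
                continue
            hrow = grp[grp["species"] == HUMAN].iloc[0]
            crow = grp[grp["species"] == CHIMP].iloc[0]
            stage = hrow["stage"]
            sub_h = (
                rng.choice(config.substages, size=n_d)
                if stage == stages[-1] and config.substages
                else [None] * n_d
            )
            sub_c = (
                rng.choice(config.substages, size=n_d)
                if stage == stages[-1] and config.substages
                else [None] * n_d
            )
            for j in range(n_d):
                ph = profile(HUMAN, hrow["line"], stage, sub_h[j])
                pc = profile(CHIMP, crow["line"], stage, sub_c[j])
                ch_counts, th = draw_cells(ph, 1)
                cc_counts, tc = draw_cells(pc, 1)
                merged = ch_counts[0] + cc_counts[0]
                h_own = rng.binomial(int(th[0]), 1.0 - config.bleed)
                c_own = rng.binomial(int(tc[0]), 1.0 - config.bleed)
                hu = h_own + (int(tc[0]) - c_own)
                cu = c_own + (int(th[0]) - h_own)
                count_blocks.append(sparse.csr_matrix(merged[None, :]))
                hu_umi.append(np.array([hu]))
                ch_umi.append(np.array([cu]))
                obs_rows.append(
                    {
                        "barcode": next_barcode(),
                        "species_true": "doublet",
                        "doublet": True,
                        "line": f"{hrow['line']}+{crow['line']}",
                        "replicate": int(hrow["replicate"]),
                        "stage_true": stage,
                        "substage_true": "",
                        "pool": pool,
                    }
                )

    X = sparse.vstack(count_blocks).tocsr()
    obs = pd.DataFrame(obs_rows).set_index("barcode")
    var = pd.DataFrame(
        {
            "mito": is_mito,
            "ribo": is_ribo,
            "marker_role": [
                ";".join(config.marker_map[g][0]) if g in config.marker_map else ""
                for g in gene_names
            ],
        },
        index=pd.Index(gene_names, name="gene"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["simulation_config"] = {
        k: v for k, v in asdict(config).items() if k != "marker_map"
    }

    droplets = pd.DataFrame(
        {
            "barcode": obs.index.to_numpy(),
            "human_umi": np.concatenate(hu_umi),
            "chimp_umi": np.concatenate(ch_umi),
        }
    )

    gene_truth = pd.DataFrame(
        {
            "motif": motif,
            "lfc": lfc,
            **{f"de_{st}": de[:, j] for j, st in enumerate(stages)},
        },
        index=pd.Index(gene_names, name="gene"),
    )
    line_effects = pd.DataFrame(
        {line: line_eff[line] for line in lines},
        index=pd.Index(gene_names, name="gene"),
    )
    truth = SimulationTruth(
        droplets=obs.copy(), genes=gene_truth, line_effects=line_effects
    )
    return adata, droplets, truth


def generate_topic_data(
    n_cells: int,
    n_genes: int,
    k: int,
    seed: int = 0,
    libsize: float = 2000.0,
    topic_concentration: float = 0.3,
    grade_concentration: float = 0.5,
):
    """Simulate counts from a grade-of-membership (topic) model.

    Each cell's expected counts are ``libsize * (L @ F.T)`` where the rows of L
    (cells x k topic grades) lie on the simplex and the columns of F
    (genes x k) are gene-probability vectors; counts are Poisson.

    Returns (AnnData, true topic-probability matrix L).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_genes:
        raise ValueError("k may not exceed n_genes")
    rng = np.random.default_rng(seed)
    F = rng.dirichlet(np.full(n_genes, topic_concentration), size=k).T  # genes x k
    if k == 1:
        L = np.ones((n_cells, 1))
    else:
        L = rng.dirichlet(np.full(k, grade_concentration), size=n_cells)
    rates = libsize * (L @ F.T)
    X = rng.poisson(rates)
    adata = ad.AnnData(
        X=sparse.csr_matrix(X),
        obs=pd.DataFrame(index=[f"BC{i + 1:06d}" for i in range(n_cells)]),
        var=pd.DataFrame(index=[f"GENE{j + 1:05d}" for j in range(n_genes)]),
    )
    adata.varm["true_gene_probs"] = F
    return adata, L
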