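import numpy as np
import pytest

import osteosc


@pytest.fixture(scope="session")
def small_experiment():
    """A small pooled experiment with doublets and alignment bleed-through."""
    cfg = osteosc.SimulationConfig(
        n_genes=150,
        n_lines_per_species=2,
        cells_per_sample=60,
        doublet_rate=0.05,
        bleed=0.02,
        seed=42,
    )
    return cfg, *osteosc.generate_experiment(cfg)


@pytest.fixture(scope="session")
def staged_adata():
    """A clean (no doublets/bleed) experiment taken through demux + QC +
    normalization + scaling, ready for marker-based annotation."""
    cfg = osteosc.SimulationConfig(
        n_genes=150,
        n_lines_per_species=2,
        cells_per_sample=80,
        seed=7,
    )
    adata, droplets, truth = osteosc.generate_experiment(cfg)
    assignments = osteosc.assign_by_ratio(droplets)
    adata.obs["species"] = (
        assignments.set_index("barcode")["label"].reindex(adata.obs_names).to_numpy()
    )
    adata = osteosc.filter_cells(adata, min_umi=500, min_genes=60)
    adata = osteosc.lognormalize(adata)
    adata = osteosc.scale_and_regress(adata)
    return adata


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
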