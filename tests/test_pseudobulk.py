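"""Pseudobulk construction, gene filters, TMM against an independent
brute-force implementation, precision weights, BH, and the mixed model."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import osteosc
from osteosc import pseudobulk as pbk
from osteosc.pseudobulk import (
    PseudobulkMatrix,
    bh_adjust,
    build_pseudobulk,
    filter_genes,
    fit_lmm,
    log2cpm,
    tmm_factors,
    voom_weights,
)


def toy_pb(counts, species=None, lines=None):
    counts = pd.DataFrame(
        np.asarray(counts),
        index=[f"g{i}" for i in range(np.asarray(counts).shape[0])],
        columns=[f"s{j}" for j in range(np.asarray(counts).shape[1])],
    )
    n = counts.shape[1]
    samples = pd.DataFrame(
        {
            "species": species or ["human"] * (n // 2) + ["chimpanzee"] * (n - n // 2),
            "line": lines or [f"L{j}" for j in range(n)],
            "replicate": 1,
            "classification": "osteogenic",
            "libsize": counts.sum(axis=0),
        },
        index=counts.columns,
    )
    return PseudobulkMatrix(counts=counts, samples=samples)


class TestBuildPseudobulk:
    def test_group_sum_equals_brute_force(self, small_experiment):
        _, adata, _, _ = small_experiment
        singlets = adata[~adata.obs["doublet"].to_numpy()].copy()
        pb = build_pseudobulk(singlets, singlets.obs["stage_true"])
        X = np.asarray(singlets.X.todense())
        meta = singlets.obs
        for sid in pb.counts.columns:
            line, rep, cls = sid.split("|")
            mask = (
                (meta["line"] == line)
                & (meta["replicate"].astype(str) == rep)
                & (meta["stage_true"] == cls)
            ).to_numpy()
            assert np.array_equal(pb.counts[sid].to_numpy(), X[mask].sum(axis=0))
        # conservation of the total without subsampling
        assert pb.counts.to_numpy().sum() == X.sum()

    def test_two_cell_example(self):
        X = np.array([[1, 2], [3, 4]])
        adata = ad.AnnData(
            X=sparse.csr_matrix(X),
            obs=pd.DataFrame(
                {"line": ["L1", "L1"], "replicate": [1, 1]}, index=["c1", "c2"]
            ),
            var=pd.DataFrame(index=["g1", "g2"]),
        )
        pb = build_pseudobulk(adata, ["osteo", "osteo"])
        assert list(pb.counts.iloc[:, 0]) == [4, 6]

    def test_subsample_too_large_drops_group(self, small_experiment):
        _, adata, _, _ = small_experiment
        singlets = adata[~adata.obs["doublet"].to_numpy()].copy()
        labels = singlets.obs["stage_true"].astype(str).copy()
        labels.iloc[:2] = "tiny"  # a 2-cell group below the subsample size
        with pytest.warns(UserWarning, match="dropped"):
            pb = build_pseudobulk(singlets, labels, subsample_to=30, seed=1)
        assert "tiny" not in set(pb.samples["classification"])
        assert (pb.samples["n_cells"] == 30).all()


class TestFilterGenes:
    def test_flagged_and_low_expression_removed(self):
        # gene g2 sits exactly at mean log2-CPM == 0 and must be removed
        lib_target = int(1.5e6 - 1)
        g2 = 1
        filler = lib_target - g2 - 500 - 1000
        counts = np.array([[500, 500], [1000, 1000], [g2, g2],
                           [filler, filler]])
        pb = toy_pb(counts)
        flags = pd.DataFrame(
            {"mito": [True, False, False, False], "ribo": [False, False, False, False]},
            index=pb.counts.index,
        )
        val = np.log2((g2 + 0.5) / (pb.counts.sum(axis=0).iloc[0] + 1) * 1e6)
        assert val == pytest.approx(0.0, abs=1e-12)
        out = filter_genes(pb, flags)
        assert "g0" not in out.counts.index  # mito
        assert "g2" not in out.counts.index  # boundary: <= 0 removed
        assert {"g1", "g3"} <= set(out.counts.index)

    def test_survivors_equal_brute_force(self, rng):
        counts = rng.integers(0, 500, size=(30, 6))
        pb = toy_pb(counts)
        flags = pd.DataFrame(
            {"mito": rng.random(30) < 0.1, "ribo": rng.random(30) < 0.1},
            index=pb.counts.index,
        )
        out = filter_genes(pb, flags)
        lib = counts.sum(axis=0)
        keep = []
        for i in range(30):
            l2 = np.log2((counts[i] + 0.5) / (lib + 1) * 1e6).mean()
            if not flags.iloc[i, 0] and not flags.iloc[i, 1] and l2 > 0:
                keep.append(f"g{i}")
        assert list(out.counts.index) == keep


def brute_force_tmm(counts, i, r):
    """Independent trimmed-weighted-mean implementation via explicit sorting."""
    obs, ref = counts[:, i].astype(float), counts[:, r].astype(float)
    nO, nR = counts[:, i].sum(), counts[:, r].sum()
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask], ref[mask]
    M = np.log2((obs / nO) / (ref / nR))
    A = 0.5 * np.log2((obs / nO) * (ref / nR))
    w = 1.0 / ((nO - obs) / (nO * obs) + (nR - ref) / (nR * ref))
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    loM, hiM = int(np.floor(n * 0.3)), n - int(np.floor(n * 0.3))
    loA, hiA = int(np.floor(n * 0.05)), n - int(np.floor(n * 0.05))
    orderM = np.argsort(M, kind="stable")
    orderA = np.argsort(A, kind="stable")
    keepM = np.zeros(n, bool)
    keepM[orderM[loM:hiM]] = True
    keepA = np.zeros(n, bool)
    keepA[orderA[loA:hiA]] = True
    keep = keepM & keepA
    return 2 ** (np.sum(M[keep] * w[keep]) / np.sum(w[keep]))


class TestTMM:
    def test_identical_libraries_give_unit_factors(self, rng):
        col = rng.integers(1, 300, size=40)
        pb = toy_pb(np.column_stack([col, col]))
        norm = tmm_factors(pb)
        assert np.allclose(norm.factors, 1.0)

    def test_pure_depth_difference_gives_unit_factors(self, rng):
        col = rng.integers(1, 300, size=40)
        pb = toy_pb(np.column_stack([col, 2 * col]))
        norm = tmm_factors(pb)
        assert np.allclose(norm.factors, 1.0)

    def test_four_sample_toy_matches_brute_force(self, rng):
        counts = rng.integers(1, 2000, size=(200, 4))
        counts[:40, 2] *= 4  # composition bias in one sample
        pb = toy_pb(counts)
        norm = tmm_factors(pb)
        lib = counts.sum(axis=0)
        f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(4)])
        r = int(np.argmin(np.abs(f75 - f75.mean())))
        raw = np.array([brute_force_tmm(counts, j, r) for j in range(4)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(norm.factors.to_numpy(), expected, atol=1e-8)
        assert np.exp(np.mean(np.log(norm.factors))) == pytest.approx(1.0)

    def test_zero_libsize_rejected(self):
        pb = toy_pb(np.array([[0, 5], [0, 5]]))
        with pytest.raises(ValueError):
            tmm_factors(pb)


class TestVoom:
    def design(self, pb):
        return np.column_stack(
            [np.ones(pb.counts.shape[1]),
             (pb.samples["species"] == "human").astype(float)]
        )

    def test_homoscedastic_counts_give_flat_weights(self, rng):
        # equal-mean Poisson counts: the mean-variance trend is flat
        counts = rng.poisson(500, size=(300, 8))
        pb = toy_pb(counts)
        we = voom_weights(pb, tmm_factors(pb), self.design(pb))
        w = we.weights.to_numpy()
        assert w.std() / w.mean() < 0.2

    def test_doubling_counts_preserves_weight_order(self, rng):
        counts = rng.poisson(rng.uniform(5, 2000, size=(250, 1)), size=(250, 6))
        pb = toy_pb(counts)
        we1 = voom_weights(pb, tmm_factors(pb), self.design(pb))
        pb2 = toy_pb(counts * 2)
        we2 = voom_weights(pb2, tmm_factors(pb2), self.design(pb2))
        r1 = we1.weights.rank().to_numpy()
        r2 = we2.weights.rank().to_numpy()
        assert np.corrcoef(r1.ravel(), r2.ravel())[0, 1] > 0.99

    def test_weights_track_mean_variance_trend(self, rng):
        # low-count genes are noisier on the log scale -> smaller weights
        lam = np.concatenate([np.full(150, 5.0), np.full(150, 2000.0)])
        counts = rng.poisson(lam[:, None], size=(300, 8))
        pb = toy_pb(counts)
        we = voom_weights(pb, tmm_factors(pb), self.design(pb))
        w = we.weights.to_numpy().mean(axis=1)
        assert w[:150].mean() < w[150:].mean()

    def test_underdetermined_design_rejected(self):
        pb = toy_pb(np.ones((5, 2)))
        with pytest.raises(ValueError):
            voom_weights(pb, tmm_factors(pb), np.ones((2, 2)))


def test_bh_step_up_hand_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    p = np.array([0.001, 0.01, 0.2, 0.9])
    q = bh_adjust(p)
    assert (q >= p).all()
    assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()


def sim_pseudobulk(seed, frac_de=0.0, lfc_sd=1.0, line_sd=0.15, n_genes=300):
    cfg = osteosc.SimulationConfig(
        n_genes=n_genes, n_lines_per_species=6, cells_per_sample=40,
        stages=("osteogenic",), substages=(), marker_map={}, frac_de=frac_de,
        motif_spec=(((1.0,), 1.0),) if frac_de > 0 else None,
        lfc_sd=lfc_sd, line_effect_sd=line_sd, n_mito_genes=0, n_ribo_genes=0,
        seed=seed,
    )
    adata, _, truth = osteosc.generate_experiment(cfg)
    adata.obs["species"] = adata.obs["species_true"]
    pb = build_pseudobulk(adata, adata.obs["stage_true"])
    pb = filter_genes(pb, adata.var[["mito", "ribo"]])
    norm = tmm_factors(pb)
    design = np.column_stack(
        [np.ones(pb.counts.shape[1]),
         (pb.samples["species"] == "human").astype(float)]
    )
    we = voom_weights(pb, norm, design)
    return we, pb, truth


class TestMixedModel:
    def test_reduces_to_species_mean_difference_without_line_variance(self):
        rng = np.random.default_rng(1)
        n = 8
        logcpm = pd.DataFrame(
            rng.normal(size=(5, n)), columns=[f"s{j}" for j in range(n)]
        )
        weights = pd.DataFrame(np.ones((5, n)), columns=logcpm.columns)
        we = pbk.WeightedExpression(logcpm, weights, np.zeros(1), np.zeros(1))
        meta = pd.DataFrame(
            {
                "species": ["human"] * 4 + ["chimpanzee"] * 4,
                "line": [f"L{j}" for j in range(n)],
            },
            index=logcpm.columns,
        )
        res = fit_lmm(we, meta)
        expected = logcpm.iloc[:, :4].mean(axis=1) - logcpm.iloc[:, 4:].mean(axis=1)
        zero_var = res["var_line"] < 1e-8
        assert zero_var.any()
        assert np.allclose(
            res.loc[zero_var, "beta_species"], expected[zero_var], atol=1e-6
        )

    def test_invariant_to_line_relabeling(self):
        we, pb, _ = sim_pseudobulk(seed=3, n_genes=60)
        res1 = fit_lmm(we, pb.samples)
        relabeled = pb.samples.copy()
        mapping = {l: f"X{i}" for i, l in enumerate(relabeled["line"].unique())}
        relabeled["line"] = relabeled["line"].map(mapping)
        res2 = fit_lmm(we, relabeled)
        assert np.allclose(res1["beta_species"], res2["beta_species"], atol=1e-8)
        assert np.allclose(res1["pvalue"], res2["pvalue"], atol=1e-6)

    def test_line_variance_detected_when_present(self):
        we, pb, _ = sim_pseudobulk(seed=5, line_sd=0.4, n_genes=150)
        res = fit_lmm(we, pb.samples)
        assert (res["var_line"] > 1e-8).mean() > 0.5

    def test_planted_effects_recover_sign(self):
        we, pb, truth = sim_pseudobulk(seed=9, frac_de=0.3, lfc_sd=2.0, n_genes=250)
        res = fit_lmm(we, pb.samples)
        genes = res.index
        de = truth.genes.loc[genes, "de_osteogenic"].to_numpy()
        big = de & (np.abs(truth.genes.loc[genes, "lfc"]) > 1.0).to_numpy()
        signs = np.sign(res["beta_species"].to_numpy()[big])
        true_signs = np.sign(truth.genes.loc[genes, "lfc"].to_numpy()[big])
        assert (signs == true_signs).mean() >= 0.99

    def test_single_species_rejected(self):
        we, pb, _ = sim_pseudobulk(seed=3, n_genes=20)
        meta = pb.samples.copy()
        meta["species"] = "human"
        with pytest.raises(ValueError):
            fit_lmm(we, meta)
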