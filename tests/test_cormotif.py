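"""Empirical-Bayes moderated statistics, EM motif recovery, posterior DE
calls and the cross-species conservation rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats, special

import osteosc
from osteosc import cormotif as cm
from osteosc import pseudobulk as pbk
from osteosc.cormotif import (
    CormotifModel,
    ModeratedStats,
    classify_conservation,
    fit_cormotif,
    posterior_de,
    sample_from_model,
    squeeze_var,
)


class TestSqueezeVar:
    def test_recovers_generating_prior_within_20pct(self, rng):
        d0, s0sq, d = 8.0, 0.5, 10
        G = 4000
        true_var = d0 * s0sq / rng.chisquare(d0, size=G)
        s2 = true_var * rng.chisquare(d, size=G) / d
        d0_hat, s0_hat = squeeze_var(s2, d)
        assert abs(d0_hat - d0) / d0 < 0.2
        assert abs(s0_hat - s0sq) / s0sq < 0.2

    def test_shrinkage_vanishes_with_large_residual_df(self, rng):
        # with many residual df the posterior variance tracks the sample one
        d = 200
        s2 = 0.7 * rng.chisquare(d, size=500) / d
        d0, s0sq = squeeze_var(s2, d)
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        assert np.corrcoef(s2, s2_post)[0, 1] > 0.95
        assert np.abs(np.log(s2_post / s2)).mean() < 0.2


class TestModeratedStats:
    def make_conditions(self, seed=0):
        cfg = osteosc.SimulationConfig(
            n_genes=200, n_lines_per_species=4, cells_per_sample=30,
            stages=("pluripotent", "osteogenic"), substages=(), marker_map={},
            frac_de=0.2, lfc_sd=1.5, n_mito_genes=0, n_ribo_genes=0, seed=seed,
        )
        adata, _, truth = osteosc.generate_experiment(cfg)
        adata.obs["species"] = adata.obs["species_true"]
        pb = pbk.build_pseudobulk(adata, adata.obs["stage_true"])
        pb = pbk.filter_genes(pb, adata.var[["mito", "ribo"]])
        conds = {}
        for stage in cfg.stages:
            cols = pb.samples.index[pb.samples["classification"] == stage]
            sub = pbk.PseudobulkMatrix(pb.counts[cols], pb.samples.loc[cols])
            conds[stage] = (sub, sub.samples)
        return conds, truth

    @staticmethod
    def design(meta):
        return np.column_stack(
            [np.ones(len(meta)), (meta["species"] == "human").astype(float)]
        )

    def test_shapes_and_density_normalization(self):
        conds, _ = self.make_conditions()
        ms = cm.moderated_stats(conds, self.design)
        assert ms.t.shape == (len(ms.genes), 2)
        assert (ms.dof > 3).all() and (ms.scale > 1).all()
        logf0, logf1 = ms.log_densities()
        # f1 is a stretched version of f0: lower density at 0
        assert (logf1[np.abs(ms.t) < 0.1] < logf0[np.abs(ms.t) < 0.1]).all()
        # each f integrates to 1 (check one gene/condition numerically)
        c = ms.scale[0, 0]
        grid = np.linspace(-400 * c, 400 * c, 400001)
        f1 = stats.t.pdf(grid / c, ms.dof[0]) / c
        assert np.trapezoid(f1, grid) == pytest.approx(1.0, abs=1e-3)

    def test_de_genes_get_larger_statistics(self):
        conds, truth = self.make_conditions(seed=4)
        ms = cm.moderated_stats(conds, self.design)
        de = truth.genes.loc[ms.genes, "de_osteogenic"].to_numpy()
        t_osteo = np.abs(ms.t[:, list(ms.conditions).index("osteogenic")])
        assert t_osteo[de].mean() > 2 * t_osteo[~de].mean()

    def test_mismatched_gene_sets_rejected(self):
        conds, _ = self.make_conditions()
        (pb, meta) = conds["pluripotent"]
        conds["pluripotent"] = (
            pbk.PseudobulkMatrix(pb.counts.iloc[:-1], meta), meta
        )
        with pytest.raises(ValueError, match="identical gene set"):
            cm.moderated_stats(conds, self.design)


class TestEM:
    Q = np.array([[0.9, 0.9, 0.9], [0.05, 0.05, 0.05]])
    PI = np.array([0.3, 0.7])

    def test_two_motif_recovery(self):
        ms, motif, de = sample_from_model(self.Q, self.PI, 4000, scale=4.0, seed=2)
        model = fit_cormotif(ms, k_list=(2,), n_starts=3, seed=0)
        f = model.fits_by_k_[2]
        order = np.argsort(-f.Q[:, 0])
        assert np.max(np.abs(f.Q[order] - self.Q)) < 0.05
        assert np.max(np.abs(f.pi[order] - self.PI)) < 0.05

    def test_loglik_monotone_every_iteration(self):
        ms, _, _ = sample_from_model(self.Q, self.PI, 1000, seed=3)
        model = fit_cormotif(ms, k_list=(1, 2, 3), n_starts=2, seed=1)
        for f in model.fits_by_k_.values():
            assert np.all(np.diff(f.loglik_trace) >= -1e-7)

    def test_simplex_invariants(self):
        ms, _, _ = sample_from_model(self.Q, self.PI, 800, seed=5)
        f = fit_cormotif(ms, k_list=(3,), n_starts=2, seed=2).fits_by_k_[3]
        assert np.allclose(f.responsibilities.sum(axis=1), 1.0, atol=1e-10)
        assert f.pi.sum() == pytest.approx(1.0, abs=1e-10)
        assert ((f.Q >= 0) & (f.Q <= 1)).all()
        assert ((f.posterior >= 0) & (f.posterior <= 1)).all()

    def test_label_swap_invariance(self):
        """Permuting motif indices leaves the DE posterior unchanged."""
        ms, _, _ = sample_from_model(self.Q, self.PI, 600, seed=7)
        f = fit_cormotif(ms, k_list=(2,), n_starts=2, seed=3).fits_by_k_[2]
        logf0, logf1 = ms.log_densities()
        perm = [1, 0]
        pi_p, Q_p = f.pi[perm], f.Q[perm]
        a_num = np.log(Q_p)[None] + logf1[:, None, :]
        b_num = np.log1p(-Q_p)[None] + logf0[:, None, :]
        log_mix = np.logaddexp(a_num, b_num)
        log_gene_k = log_mix.sum(axis=2) + np.log(pi_p)[None]
        z = np.exp(log_gene_k - special.logsumexp(log_gene_k, axis=1)[:, None])
        post = np.einsum("gk,gkd->gd", z, np.exp(a_num - log_mix))
        assert np.allclose(post, f.posterior, atol=1e-10)

    def test_single_condition_single_motif_matches_1d_oracle(self):
        """With one condition and one motif, EM reduces to a 1-D two-component
        mixture; compare against an independent scalar EM."""
        Q = np.array([[0.4]])
        ms, _, _ = sample_from_model(Q, np.array([1.0]), 3000, scale=4.0, seed=11)
        f = fit_cormotif(ms, k_list=(1,), n_starts=1, max_iter=2000, tol=1e-10,
                         seed=4).fits_by_k_[1]
        logf0, logf1 = ms.log_densities()
        f0, f1 = np.exp(logf0[:, 0]), np.exp(logf1[:, 0])
        q = 0.5
        for _ in range(5000):
            r = q * f1 / (q * f1 + (1 - q) * f0)
            q_new = r.mean()
            if abs(q_new - q) < 1e-12:
                break
            q = q_new
        assert f.Q[0, 0] == pytest.approx(q, abs=1e-4)

    def test_bic_prefers_generating_k(self):
        hits = 0
        for seed in range(3):
            ms, _, _ = sample_from_model(self.Q, self.PI, 3000, scale=4.0, seed=seed)
            model = fit_cormotif(ms, k_list=(1, 2, 3), n_starts=2, seed=seed)
            hits += model.k_ == 2
        assert hits >= 2

    def test_k_larger_than_genes_rejected(self):
        ms, _, _ = sample_from_model(self.Q, self.PI, 5, seed=0)
        with pytest.raises(ValueError):
            fit_cormotif(ms, k_list=(10,))


class TestPosteriorCalls:
    def test_strict_cutoff(self):
        fit = cm.CormotifFit(
            k=1, Q=np.array([[0.5]]), pi=np.array([1.0]),
            responsibilities=np.ones((3, 1)),
            posterior=np.array([[0.65], [0.651], [0.0]]),
            loglik=0.0, loglik_trace=np.zeros(1), bic=0.0,
        )
        calls = posterior_de(fit, cutoff=0.65)
        assert calls.ravel().tolist() == [False, True, False]

    def test_zero_q_gives_zero_posterior(self):
        ms, _, _ = sample_from_model(
            np.array([[0.5, 0.5]]), np.array([1.0]), 200, seed=1
        )
        logf0, logf1 = ms.log_densities()
        # with q = 0 exactly the DE posterior is exactly zero
        Q = np.zeros((1, 2))
        with np.errstate(divide="ignore"):
            a_num = np.log(Q)[None] + logf1[:, None, :]
        b_num = np.log1p(-Q)[None] + logf0[:, None, :]
        log_mix = np.logaddexp(a_num, b_num)
        post = np.exp(a_num - log_mix)[:, 0, :]
        assert (post == 0.0).all()


class TestConservation:
    def test_inclusive_boundary(self):
        a = pd.DataFrame({"c1": [0.9, 0.9, 0.5]}, index=["g1", "g2", "g3"])
        b = pd.DataFrame({"c1": [0.6, 0.5, 0.5]}, index=["g1", "g2", "g3"])
        out = classify_conservation(a, b, tol=0.3)
        assert out["c1"].tolist() == [True, False, True]

    def test_identical_posteriors_all_conserved(self, rng):
        a = pd.DataFrame(rng.random((20, 3)), columns=list("xyz"))
        assert classify_conservation(a, a.copy()).all().all()

    def test_randomized_grid_matches_literal_rule(self, rng):
        a = pd.DataFrame(rng.random((50, 4)))
        b = pd.DataFrame(rng.random((50, 4)))
        out = classify_conservation(a, b, tol=0.3)
        assert (out.to_numpy() == (np.abs(a.to_numpy() - b.to_numpy()) <= 0.3)).all()

    def test_mismatched_genes_rejected(self):
        a = pd.DataFrame({"c": [0.1]}, index=["g1"])
        b = pd.DataFrame({"c": [0.1]}, index=["g2"])
        with pytest.raises(ValueError):
            classify_conservation(a, b)
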