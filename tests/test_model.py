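"""Gene partition, masking/wiring contracts, NB likelihood, ELBO."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from curvae import autodiff as ad
from curvae import manifolds as mf
from curvae import model as M
from curvae.training import initialize


class TestGenePartition:
    def test_direct_indexing(self):
        part = M.GenePartition([("m", [0, 1]), ("rest", None)], 4)
        x1, x2 = part.partition_counts(np.array([5, 0, 2, 1]))
        np.testing.assert_array_equal(x1, [5, 0])
        np.testing.assert_array_equal(x2, [2, 1])

    def test_shared_sets_collapse_to_one_block(self):
        part = M.GenePartition([("a", [0, 1]), ("b", [0, 1]), ("rest", None)], 5)
        assert len(part.blocks) == 2  # the shared block is modelled once
        x = np.arange(5)
        xa, xb, xr = part.partition_counts(x)
        np.testing.assert_array_equal(xa, xb)

    def test_overlapping_but_unequal_sets_rejected(self):
        with pytest.raises(ValueError, match="same or disjoint"):
            M.GenePartition([("a", [0, 1]), ("b", [1, 2]), ("rest", None)], 5)

    def test_empty_marker_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            M.GenePartition([("a", []), ("rest", None)], 4)

    def test_union_must_cover_all_genes(self):
        with pytest.raises(ValueError, match="cover"):
            M.GenePartition([("a", [0, 1])], 4)

    def test_length_mismatch(self):
        part = M.GenePartition([("a", [0]), ("rest", None)], 3)
        with pytest.raises(ValueError):
            part.partition_counts(np.zeros(5))


class TestEncode:
    def test_masking_contract(self, tiny_model):
        """Perturbing a non-marker gene leaves component-1 posterior bit-identical."""
        model, X, rows = tiny_model
        p0 = model.encode(X)
        X2 = X.copy()
        X2[:, 20] += 7  # a 'rest' gene
        p1 = model.encode(X2)
        np.testing.assert_array_equal(ad.value(p0[0]["mu"]), ad.value(p1[0]["mu"]))
        np.testing.assert_array_equal(ad.value(p0[0]["sigma"]),
                                      ad.value(p1[0]["sigma"]))
        assert not np.array_equal(ad.value(p0[1]["mu"]), ad.value(p1[1]["mu"]))

    def test_all_zero_cell_is_finite(self, tiny_model):
        model, X, rows = tiny_model
        posts = model.encode(np.zeros((1, 30)))
        for p in posts:
            assert np.all(np.isfinite(ad.value(p["mu"])))
            assert np.all(np.isfinite(ad.value(p["sigma"])))

    def test_curved_location_on_manifold(self, tiny_model):
        model, X, rows = tiny_model
        rng = np.random.default_rng(0)
        Xr = rng.poisson(2.0, size=(256, 30)).astype(float)
        posts = model.encode(Xr)
        mu = np.asarray(ad.value(posts[0]["mu"]))
        sp = model.specs[0].space
        assert np.max(np.abs(mf.lorentz_inner(mu, mu) - 1.0 / sp.K)) < 1e-5

    def test_nan_input_rejected(self, tiny_model):
        model, X, rows = tiny_model
        bad = X.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            model.encode(bad)


class TestDecode:
    def test_block_means_sum_to_library_size(self, tiny_model):
        model, X, rows = tiny_model
        posts = model.encode(X)
        zs, _ = model.sample_latents(posts, np.random.default_rng(0))
        lib = X.sum(axis=1)
        means = model.decode(zs, rows, lib)
        for m in means:
            np.testing.assert_allclose(np.asarray(ad.value(m)).sum(axis=1),
                                       lib, rtol=1e-10)

    def test_signal_block_ignores_other_latent(self, tiny_model):
        """Changing z2 must not change the marker block's means."""
        model, X, rows = tiny_model
        posts = model.encode(X)
        zs, _ = model.sample_latents(posts, np.random.default_rng(0))
        lib = X.sum(axis=1)
        m0 = model.decode(zs, rows, lib)
        zs2 = [zs[0], ad.Tensor(ad.value(zs[1]) + 1.0)]
        m1 = model.decode(zs2, rows, lib)
        np.testing.assert_array_equal(ad.value(m0[0]), ad.value(m1[0]))
        assert not np.array_equal(ad.value(m0[1]), ad.value(m1[1]))

    def test_inapplicable_covariate_leaves_block_unchanged(self):
        """A covariate excluded from a component's decoder has no effect."""
        rng = np.random.default_rng(1)
        part = M.GenePartition([("sig", np.arange(5)), ("rest", None)], 20)
        specs = [M.LatentSpec("sig", mf.euclidean(2), "normal"),
                 M.LatentSpec("rest", mf.euclidean(3), "normal")]
        bd = M.CellBatchDesign(
            pd.DataFrame({"t": ["0", "4"] * 4, "donor": ["a"] * 4 + ["b"] * 4}),
            applicability={"sig": ("t",), "rest": ("t", "donor")})
        model = M.DecomposedVAE(part, specs, bd)
        initialize(model, rng)
        X = rng.poisson(3.0, (8, 20)).astype(float)
        posts = model.encode(X)
        zs = [ad.value(p["mu"]) for p in posts]
        lib = X.sum(1)
        m0 = model.decode(zs, bd.covariates, lib)
        flipped = bd.covariates.copy()
        flipped["donor"] = ["b"] * 4 + ["a"] * 4
        m1 = model.decode(zs, flipped, lib)
        np.testing.assert_array_equal(ad.value(m0[0]), ad.value(m1[0]))
        assert not np.array_equal(ad.value(m0[1]), ad.value(m1[1]))

    def test_unseen_batch_level_rejected(self, tiny_model):
        model, X, rows = tiny_model
        posts = model.encode(X)
        zs = [ad.value(p["mu"]) for p in posts]
        bad = rows.copy()
        bad.iloc[0, 0] = "zz"
        with pytest.raises(ValueError, match="unseen level"):
            model.decode(zs, bad, X.sum(1))


class TestNBLikelihood:
    def test_closed_form_at_zero(self):
        mu, th = 2.0, 1.5
        ll = M.nb_log_likelihood(np.array([0.0]), np.array([mu]), np.array([th]))
        assert float(ll) == pytest.approx(th * np.log(th / (th + mu)))

    def test_matches_loggamma_oracle(self):
        from scipy.special import gammaln
        x, mu, th = 3.0, 2.0, 1.5
        expected = (gammaln(x + th) - gammaln(th) - gammaln(x + 1)
                    + th * np.log(th / (th + mu)) + x * np.log(mu / (th + mu)))
        ll = M.nb_log_likelihood(np.array([x]), np.array([mu]), np.array([th]))
        assert float(ll) == pytest.approx(float(expected), abs=1e-12)
        # and scipy's own NB pmf agrees (p = th/(th+mu))
        ref = stats.nbinom.logpmf(int(x), th, th / (th + mu))
        assert float(ll) == pytest.approx(float(ref), abs=1e-12)

    def test_poisson_limit(self):
        x, mu = 4.0, 2.5
        ll = M.nb_log_likelihood(np.array([x]), np.array([mu]), np.array([1e6]))
        assert float(ll) == pytest.approx(float(stats.poisson.logpmf(int(x), mu)),
                                          abs=1e-3)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            M.nb_log_likelihood(np.array([1.5]), np.array([1.0]), np.array([1.0]))


class TestELBO:
    def test_elbo_below_log_evidence_quadrature(self):
        """1 cell, 3 genes, 1-D Euclidean latent: quadrature log-evidence
        upper-bounds the (exact closed-form KL) ELBO for random draws."""
        rng = np.random.default_rng(2)
        for trial in range(20):
            part = M.GenePartition([("all", None)], 3)
            specs = [M.LatentSpec("all", mf.euclidean(1), "normal")]
            model = M.DecomposedVAE(part, specs)
            initialize(model, np.random.default_rng(trial))
            x = rng.poisson(3.0, (1, 3)).astype(float) + 1.0
            lib = x.sum()
            posts = model.encode(x)
            mu_q = float(ad.value(posts[0]["mu"])[0, 0])
            sig_q = float(ad.value(posts[0]["sigma"])[0, 0])
            disp = np.asarray(ad.value(model.block_dispersion(0, None, 1)))[0]

            def loglik(z):
                m = model.decode([np.array([[z]])], None, np.array([lib]))
                return float(M.nb_log_likelihood(x, ad.value(m[0]), disp)[0])

            # ELBO = E_q[log p(x|z)] - KL(q||N(0,1)), both by quadrature
            from curvae.distributions import gaussian_kl_closed_form
            eq_ll = integrate.quad(lambda z: stats.norm.pdf(z, mu_q, sig_q) * loglik(z),
                                   mu_q - 8 * sig_q, mu_q + 8 * sig_q)[0]
            kl = float(gaussian_kl_closed_form(np.array([mu_q]), np.array([sig_q])))
            elbo = eq_ll - kl
            ev = integrate.quad(
                lambda z: stats.norm.pdf(z, 0, 1) * np.exp(loglik(z)),
                -10, 10)[0]
            assert elbo <= np.log(ev) + 1e-6

    def test_stop_gradient_blocks_cross_component_flow(self, tiny_model):
        model, X, rows = tiny_model
        model.specs[1].stop_grad_epochs = 5  # block rest-block grads into z1
        for p in model.params.values():
            p.grad = None
        # isolate the rest block's reconstruction gradient
        posts = model.encode(X[:4])
        zs, _ = model.sample_latents(posts, np.random.default_rng(0))
        stop = {1}  # rest block index
        means = model.decode(zs, rows.iloc[:4], X[:4].sum(1), stop_grad=stop)
        genes = model.partition.blocks[1][0]
        disp = model.block_dispersion(1, rows.iloc[:4], 4)
        ll = ad.mean(M.nb_log_likelihood(X[:4][:, genes], means[1], disp))
        ll.backward()
        g1 = model.params["enc/cycle/l0/W"].grad
        assert g1 is None or np.allclose(g1, 0.0)
        assert np.any(model.params["enc/rest/l0/W"].grad != 0.0)
        model.specs[1].stop_grad_epochs = 0

    def test_without_stop_gradient_flow_reaches_first_encoder(self, tiny_model):
        model, X, rows = tiny_model
        posts = model.encode(X[:4])
        zs, _ = model.sample_latents(posts, np.random.default_rng(0))
        means = model.decode(zs, rows.iloc[:4], X[:4].sum(1), stop_grad=None)
        genes = model.partition.blocks[1][0]
        disp = model.block_dispersion(1, rows.iloc[:4], 4)
        ll = ad.mean(M.nb_log_likelihood(X[:4][:, genes], means[1], disp))
        ll.backward()
        assert np.any(np.abs(model.params["enc/cycle/l0/W"].grad) > 0)

    def test_duplicated_minibatch_keeps_mean_loss(self, tiny_model):
        """Mean reduction: a duplicated cell gives exactly the 1-cell loss
        (latent draws held fixed at the posterior mean)."""

        class ZeroRng:
            def standard_normal(self, shape):
                return np.zeros(shape)

        model, X, rows = tiny_model
        one, row1 = X[:1], rows.iloc[:1]
        l1, _ = model.elbo_loss(one, row1, ZeroRng())
        dup = np.repeat(one, 4, axis=0)
        rows4 = pd.concat([row1] * 4, ignore_index=True)
        l4, _ = model.elbo_loss(dup, rows4, ZeroRng())
        assert float(ad.value(l4)) == pytest.approx(float(ad.value(l1)), abs=1e-9)

    def test_loss_finite_for_extreme_cells(self, tiny_model):
        model, X, rows = tiny_model
        Xe = X.copy()
        Xe[0] = 0.0
        Xe[1] = 0.0
        Xe[1, 3] = 50_000.0
        loss, stats_ = model.elbo_loss(Xe, rows, np.random.default_rng(5))
        assert np.isfinite(float(ad.value(loss)))

    def test_gene_permutation_invariance(self):
        """Permuting gene order (with remapped partition) keeps the loss."""
        rng = np.random.default_rng(6)
        X = rng.poisson(3.0, (12, 20)).astype(float)
        perm = rng.permutation(20)
        markers = np.array([2, 5, 7])

        def build(marker_idx, n):
            part = M.GenePartition([("sig", marker_idx), ("rest", None)], n)
            specs = [M.LatentSpec("sig", mf.hyperbolic(2, -2.0), "wrapped-normal"),
                     M.LatentSpec("rest", mf.euclidean(3), "normal")]
            return M.DecomposedVAE(part, specs)

        inv = np.argsort(perm)  # original gene g sits at column inv[g] of X[:, perm]
        m0 = build(markers, 20)
        initialize(m0, np.random.default_rng(7))
        m1 = build(np.sort(inv[markers]), 20)
        initialize(m1, np.random.default_rng(7))
        for name, p in m0.params.items():
            m1.params[name].data[...] = p.data
        # remap gene-indexed weights: m1's position of original gene g is the
        # rank of inv[g] within its own (sorted) index set
        for comp in ("sig", "rest"):
            ci = m0.partition.names.index(comp)
            src = m0.partition.index_sets[ci]
            dst = m1.partition.index_sets[ci]
            pos = {g: i for i, g in enumerate(dst)}
            W0 = m0.params[f"enc/{comp}/l0/W"].data
            W1 = m1.params[f"enc/{comp}/l0/W"].data
            for i, g in enumerate(src):
                W1[pos[inv[g]]] = W0[i]
        for bi, (src, _) in enumerate(m0.partition.blocks):
            dst = m1.partition.blocks[bi][0]
            pos = {g: i for i, g in enumerate(dst)}
            cols = [pos[inv[g]] for g in src]
            m1.params[f"dec/block{bi}/out/W"].data[:, cols] = \
                m0.params[f"dec/block{bi}/out/W"].data
            m1.params[f"dec/block{bi}/out/b"].data[cols] = \
                m0.params[f"dec/block{bi}/out/b"].data
            m1.params[f"disp/block{bi}"].data[:, cols] = \
                m0.params[f"disp/block{bi}"].data
        l0, _ = m0.elbo_loss(X, None, np.random.default_rng(8))
        l1, _ = m1.elbo_loss(X[:, perm], None, np.random.default_rng(8))
        assert float(ad.value(l0)) == pytest.approx(float(ad.value(l1)), abs=1e-9)


class TestCheckpoint:
    def test_roundtrip_restores_forward_pass(self, tiny_model, tmp_path):
        model, X, rows = tiny_model
        path = tmp_path / "ckpt.zip"
        model.save(path)
        clone = M.DecomposedVAE.load(path)
        p0 = model.encode(X)
        p1 = clone.encode(X)
        for a, b in zip(p0, p1):
            np.testing.assert_array_equal(ad.value(a["mu"]), ad.value(b["mu"]))
        l0, _ = model.elbo_loss(X, rows, np.random.default_rng(0))
        l1, _ = clone.elbo_loss(X, rows, np.random.default_rng(0))
        assert float(ad.value(l0)) == float(ad.value(l1))
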