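"""Pseudotime, alignment, decoding procedures, k-NN identity, discovery."""

import numpy as np
import pandas as pd
import pytest

from curvae import analysis as an
from curvae import manifolds as mf


class TestPseudotime:
    def test_cardinal_directions(self, h2):
        east = mf.poincare_to_lorentz(np.array([[0.5, 0.0]]) / np.sqrt(2), h2)
        north = mf.poincare_to_lorentz(np.array([[0.0, 0.5]]) / np.sqrt(2), h2)
        assert an.pseudotime(east, h2)[0] == pytest.approx(0.0)
        assert an.pseudotime(north, h2)[0] == pytest.approx(np.pi / 2)

    def test_lorentz_input_projects_first(self):
        sp = mf.hyperbolic(2, -1.0)
        z = np.array([[np.cosh(1.0), 0.0, np.sinh(1.0)]])
        assert an.pseudotime(z, sp)[0] == pytest.approx(np.pi / 2)

    def test_origin_gets_zero_with_warning(self, h2):
        with pytest.warns(UserWarning):
            ang = an.pseudotime(h2.origin[None], h2)
        assert ang[0] == 0.0

    def test_rejects_wrong_geometry(self):
        with pytest.raises(ValueError):
            an.pseudotime(np.zeros((3, 2)), mf.euclidean(2))
        with pytest.raises(ValueError):
            an.pseudotime(np.zeros((3, 4)), mf.hyperbolic(3, -1.0))

    def test_recentering_preserves_phase_order(self, h2):
        """After an off-center embedding is recentered, angular order
        matches the generating phase order up to rotation/flip."""
        rng = np.random.default_rng(0)
        phase = np.sort(rng.uniform(0, 2 * np.pi, 300))
        circle = 0.55 * np.column_stack([np.cos(phase), np.sin(phase)])
        off = mf.mobius_add(np.broadcast_to([0.25, -0.2], circle.shape),
                            circle, h2.K)  # gyro-translate off center
        o = an.auto_recenter_origin(off, h2.K)
        pts = off if o is None else mf.recenter(off, o, h2.K)
        ang = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * np.pi)
        from scipy.stats import spearmanr
        # ranks agree up to a cyclic shift: check via alignment correlation
        _, _, r, _ = an.align_pseudotime(ang, phase)
        assert r > 0.95


class TestAlignPseudotime:
    def test_identity_alignment(self):
        t = np.random.default_rng(1).uniform(0, 2 * np.pi, 100)
        rot, flip, r, sin_r = an.align_pseudotime(t, t)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert rot == pytest.approx(0.0)
        assert not flip
        assert sin_r == pytest.approx(1.0, abs=1e-9)

    def test_rotation_invariance(self):
        t = np.random.default_rng(2).uniform(0, 2 * np.pi, 200)
        est = np.mod(t + 1.0, 2 * np.pi)
        _, _, r, _ = an.align_pseudotime(est, t)
        assert r > 1 - 1e-6

    def test_flip_invariance(self):
        t = np.random.default_rng(3).uniform(0, 2 * np.pi, 200)
        est = np.mod(-t, 2 * np.pi)
        _, flip, r, _ = an.align_pseudotime(est, t)
        assert flip and r > 1 - 1e-6

    def test_r_never_exceeds_one(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(0, 2 * np.pi, 50)
        e = rng.uniform(0, 2 * np.pi, 50)
        _, _, r, _ = an.align_pseudotime(e, t)
        assert r <= 1 + 1e-12

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            an.align_pseudotime(np.ones(10), np.linspace(0, 6, 10))


class TestRatioClassification:
    def test_balanced_expression_is_unclassified(self):
        rc = an.central_portal_classify(np.array([2.0]), np.array([2.0]))
        assert rc["ratio"][0] == 0.5 and rc["label"][0] == "unclassified"

    def test_threshold_rule_verbatim(self):
        c = np.array([0.0, 1.0, 0.5])
        p = np.array([1.0, 0.0, 0.5])
        rc = an.central_portal_classify(c, p)
        assert list(rc["label"]) == ["central", "portal", "unclassified"]
        np.testing.assert_allclose(rc["ratio"], [0.0, 1.0, 0.5])

    def test_zero_zero_is_unclassified_at_half(self):
        rc = an.central_portal_classify(np.array([0.0]), np.array([0.0]))
        assert rc["ratio"][0] == 0.5 and rc["label"][0] == "unclassified"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            an.central_portal_classify(np.array([-1.0]), np.array([1.0]))


class TestKnnIdentity:
    def test_single_label_reference(self):
        rng = np.random.default_rng(5)
        ref = rng.standard_normal((80, 3))
        out = an.knn_identity(ref, ["T"] * 80, rng.standard_normal((10, 3)))
        assert all(o == "T" for o in out)

    def test_boundary_query_is_uncertain(self):
        """A query between two pure clusters flips its vote with k."""
        a = np.array([[-1.0, 0.0]]) + 0.01 * np.random.default_rng(6).standard_normal((40, 2))
        b = np.array([[1.0, 0.0]]) + 0.01 * np.random.default_rng(7).standard_normal((40, 2))
        ref = np.vstack([a, b])
        labels = ["A"] * 40 + ["B"] * 40
        # nearest neighbour is a single A-outlier planted next to the query
        ref = np.vstack([ref, [[0.05, 0.0]]])
        labels.append("A")
        out = an.knn_identity(ref, labels, np.array([[0.05, 0.01]]),
                              k_list=(1, 41))
        assert out[0] == "uncertain"

    def test_k1_returns_exact_neighbour_label(self):
        ref = np.array([[0.0, 0.0], [5.0, 5.0]])
        out = an.knn_identity(ref, ["x", "y"], np.array([[0.0, 0.0]]), k_list=[1])
        assert out[0] == "x"

    def test_k_larger_than_reference_rejected(self):
        with pytest.raises(ValueError):
            an.knn_identity(np.zeros((3, 2)), ["a"] * 3, np.zeros((1, 2)),
                            k_list=[5])

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            an.knn_identity(np.zeros((0, 2)), [], np.zeros((1, 2)))


class TestPhaseCorrelation:
    def test_pure_harmonic_scores_one(self):
        phase = np.random.default_rng(8).uniform(0, 2 * np.pi, 500)
        expr = 3 + 2 * np.cos(phase - 1.2)
        assert an.phase_correlation(expr, phase)[0] > 0.999

    def test_phase_independent_scores_near_zero(self):
        rng = np.random.default_rng(9)
        phase = rng.uniform(0, 2 * np.pi, 2000)
        expr = rng.normal(5.0, 1.0, 2000)
        assert an.phase_correlation(expr, phase)[0] < 0.1


class TestSelectiveDecode:
    def test_keep_all_is_ordinary_reconstruction(self, trained_gradient):
        model, X, genes, truth = trained_gradient
        full = an.selective_decode(model, X[:30], keep=set(model.partition.names))
        # block means sum to each cell's library size
        np.testing.assert_allclose(full.sum(axis=1),
                                   2 * X[:30].sum(axis=1), rtol=1e-8)

    def test_unknown_component_rejected(self, trained_gradient):
        model, X, *_ = trained_gradient
        with pytest.raises(KeyError):
            an.selective_decode(model, X[:5], keep={"nope"})
        with pytest.raises(ValueError):
            an.selective_decode(model, X[:5], keep=set())

    def test_fill_override_changes_output(self, trained_gradient):
        model, X, *_ = trained_gradient
        d0 = an.selective_decode(model, X[:10], keep={"rest"})
        d1 = an.selective_decode(model, X[:10], keep={"rest"},
                                 fill={"signal": np.array([0.005, -2.5])})
        assert not np.allclose(d0, d1)

    def test_dropping_signal_component_removes_gradient_signal(self, trained_gradient):
        """Marker genes decoded without the signal latent lose their
        dependence on the true gradient position."""
        model, X, genes, truth = trained_gradient
        mk = np.flatnonzero(genes["is_marker"])
        pos = truth["position"]
        d_rest = an.selective_decode(model, X, keep={"rest"})
        d_sig = an.selective_decode(model, X, keep={"signal"})
        r_rest = [abs(np.corrcoef(pos, d_rest[:, g])[0, 1]) for g in mk]
        r_sig = [abs(np.corrcoef(pos, d_sig[:, g])[0, 1]) for g in mk]
        assert np.median(r_rest) < 0.15
        assert np.median(r_sig) > 0.6


class TestCounterfactualDecode:
    def test_own_coordinate_is_identity(self, trained_gradient):
        model, X, *_ = trained_gradient
        import curvae.autodiff as ad
        posts = model.encode(X[:5])
        loc = np.asarray(ad.value(posts[0]["loc"]))
        full = an.selective_decode(model, X[:5], keep=set(model.partition.names))
        cf = [an.counterfactual_decode(model, X[i:i + 1], "signal", 0,
                                       loc[i, 0]) for i in range(5)]
        np.testing.assert_allclose(np.vstack(cf), full, rtol=1e-8)

    def test_index_out_of_range(self, trained_gradient):
        model, X, *_ = trained_gradient
        with pytest.raises(IndexError):
            an.counterfactual_decode(model, X[:2], "signal", 7, 1.0)

    def test_gradient_gene_responds_to_override(self, trained_gradient):
        """A gene rising with the latent gradient decodes higher under the
        high override than the low one for >= 90% of cells."""
        model, X, genes, truth = trained_gradient
        import curvae.autodiff as ad
        posts = model.encode(X)
        loc = np.asarray(ad.value(posts[0]["loc"]))
        pos = truth["position"]
        axis = int(np.argmax([abs(np.corrcoef(pos, loc[:, i])[0, 1])
                              for i in range(loc.shape[1])]))
        sgn = np.sign(np.corrcoef(pos, loc[:, axis])[0, 1])
        hi_v, lo_v = np.quantile(loc[:, axis], [0.95, 0.05])
        if sgn < 0:
            hi_v, lo_v = lo_v, hi_v
        hi = an.counterfactual_decode(model, X, "signal", axis, hi_v)
        lo = an.counterfactual_decode(model, X, "signal", axis, lo_v)
        mk = np.flatnonzero(genes["is_marker"])
        # pick the marker genes that truly increase with position
        rising = [g for g in mk if np.corrcoef(pos, X[:, g] / X.sum(1))[0, 1] > 0.3]
        assert len(rising) > 5
        frac = np.mean([(hi[:, g] > lo[:, g]).mean() for g in rising])
        assert frac >= 0.9


class TestDiscoverUpregulated:
    def test_recovers_spiked_genes(self, trained_spiked):
        model, X, genes, truth = trained_spiked
        tally = an.discover_upregulated(
            model, X, "rest", truth["group"], "stim", "ctrl",
            exclude=np.flatnonzero(genes["is_marker"]))
        assert tally["frequency"].max() <= 100
        spiked = set(np.flatnonzero(genes["spiked"]))
        freq = dict(zip(tally["gene"], tally["frequency"]))
        assert all(freq[g] >= 90 for g in spiked)

    def test_swapping_groups_reverses_ranking(self, trained_spiked):
        model, X, genes, truth = trained_spiked
        rev = an.discover_upregulated(
            model, X, "rest", truth["group"], "ctrl", "stim",
            exclude=np.flatnonzero(genes["is_marker"]))
        spiked = set(np.flatnonzero(genes["spiked"]))
        freq = dict(zip(rev["gene"], rev["frequency"]))
        assert all(freq[g] <= 10 for g in spiked)

    def test_identical_groups_flagged_degenerate(self, trained_spiked):
        model, X, genes, truth = trained_spiked
        labels = np.array(["same"] * len(truth["group"]))
        with pytest.warns(UserWarning, match="degenerate"):
            tally = an.discover_upregulated(model, X, "rest", labels,
                                            "same", "same")
        assert tally["degenerate"].all()

    def test_small_group_rejected(self, trained_spiked):
        model, X, genes, truth = trained_spiked
        with pytest.raises(ValueError):
            an.discover_upregulated(model, X[:50], "rest",
                                    truth["group"][:50], "stim", "ctrl")
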