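import numpy as np
import pytest

from honeyspec.simca import (
    fit_simca,
    score_samples,
    sensitivity_specificity,
)
from honeyspec.preprocess import fit_pipeline
from honeyspec.config import default_pipeline, default_regions
from honeyspec.spectra_io import select_regions


def gaussian_class(n=60, p=10, seed=0):
    rng = np.random.default_rng(seed)
    loadings = rng.normal(size=(p, 3))
    scores = rng.normal(size=(n, 3)) * np.array([3.0, 2.0, 1.0])
    return 5.0 + scores @ loadings.T + rng.normal(0, 0.2, size=(n, p))


class TestFitSimca:
    def test_centroid_sample_accepted_with_zero_distance(self):
        X = gaussian_class()
        model = fit_simca(X, k=3, alpha=0.05)
        dec = score_samples(model, X.mean(axis=0)[None, :])
        assert dec.t2[0] == pytest.approx(0.0, abs=1e-16)
        assert dec.q[0] == pytest.approx(0.0, abs=1e-16)
        assert dec.distance[0] == pytest.approx(0.0, abs=1e-12)
        assert dec.accepted[0]

    def test_limits_grow_as_alpha_shrinks(self):
        X = gaussian_class(seed=1)
        strict = fit_simca(X, k=3, alpha=0.05)
        loose = fit_simca(X, k=3, alpha=0.01)
        assert loose.t2_lim > strict.t2_lim
        assert loose.q_lim > strict.q_lim

    def test_training_set_mostly_accepted(self):
        """Monte Carlo: the 95% combined rule accepts nearly all of its own
        training samples on a Gaussian class."""
        fractions = []
        for rep in range(200):
            X = gaussian_class(seed=1000 + rep)
            model = fit_simca(X, alpha=0.05)  # k from the 95% variance rule
            fractions.append(score_samples(model, X).accepted.mean())
        assert np.mean(fractions) >= 0.85

    def test_k_at_least_n_rejected(self):
        with pytest.raises(ValueError):
            fit_simca(gaussian_class(n=5), k=5)

    def test_zero_residual_data_rejected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 2)) @ rng.normal(size=(2, 6))  # rank 2 exactly
        with pytest.raises(ValueError, match="residual"):
            fit_simca(X, k=2)


class TestScoreSamples:
    @pytest.fixture
    def model_and_train(self):
        X = gaussian_class(seed=3)
        return fit_simca(X, k=3, alpha=0.05), X

    def test_in_plane_outlier_rejected_via_t2(self, model_and_train):
        model, X = model_and_train
        span = np.abs((X - model.pca.center) @ model.pca.loadings[:, 0]).max()
        probe = model.pca.center + 10.0 * span * model.pca.loadings[:, 0]
        dec = score_samples(model, probe[None, :])
        assert not dec.accepted[0]
        assert dec.t_reduced[0] > 1.0
        assert dec.q_reduced[0] < 1.0

    def test_orthogonal_outlier_rejected_via_q(self, model_and_train):
        model, X = model_and_train
        rng = np.random.default_rng(4)
        v = rng.normal(size=X.shape[1])
        v -= model.pca.loadings @ (model.pca.loadings.T @ v)
        v /= np.linalg.norm(v)
        probe = model.pca.center + 100.0 * np.sqrt(model.q_lim) * v
        dec = score_samples(model, probe[None, :])
        assert not dec.accepted[0]
        assert dec.q_reduced[0] > 1.0
        assert dec.t_reduced[0] < 1.0

    def test_acceptance_region_convex_and_contains_centroid(self, model_and_train):
        """Grid oracle in the reduced (t, q) plane: the accepted set is convex."""
        model, X = model_and_train
        rng = np.random.default_rng(5)
        v = rng.normal(size=X.shape[1])
        v -= model.pca.loadings @ (model.pca.loadings.T @ v)
        v /= np.linalg.norm(v)
        lam1 = model.pca.explained_variance[0]

        def probe(t_red, q_red):
            x = (model.pca.center
                 + np.sqrt(max(t_red, 0) * model.t2_lim * lam1) * model.pca.loadings[:, 0]
                 + np.sqrt(max(q_red, 0) * model.q_lim) * v)
            return score_samples(model, x[None, :])

        grid = np.linspace(0, 2.0, 9)
        accepted = {}
        for t in grid:
            for q in grid:
                dec = probe(t, q)
                np.testing.assert_allclose([dec.t_reduced[0], dec.q_reduced[0]], [t, q], atol=1e-8)
                accepted[(t, q)] = bool(dec.accepted[0])
        assert accepted[(0.0, 0.0)]
        points = [p for p, ok in accepted.items() if ok]
        for a in points:
            for b in points:
                mid = ((a[0] + b[0]) / 2, (a[1] + b[1]) / 2)
                assert np.hypot(*mid) <= np.sqrt(2) + 1e-12  # midpoint inside the rule

    def test_rotation_invariance(self, model_and_train):
        _, X = model_and_train
        rng = np.random.default_rng(6)
        test = gaussian_class(n=20, seed=7)
        qmat, _ = np.linalg.qr(rng.normal(size=(X.shape[1], X.shape[1])))
        plain = score_samples(fit_simca(X, k=3), test)
        rotated = score_samples(fit_simca(X @ qmat, k=3), test @ qmat)
        np.testing.assert_allclose(plain.t2, rotated.t2, rtol=1e-8)
        np.testing.assert_allclose(plain.q, rotated.q, rtol=1e-6, atol=1e-10)
        np.testing.assert_array_equal(plain.accepted, rotated.accepted)

    def test_acceptance_monotone_in_alpha(self):
        X = gaussian_class(seed=8)
        test = gaussian_class(n=40, seed=9) + 1.0
        counts = []
        for alpha in (0.01, 0.05, 0.20):
            model = fit_simca(X, k=3, alpha=alpha)
            counts.append(int(score_samples(model, test).accepted.sum()))
        assert counts[0] >= counts[1] >= counts[2]


class TestMetrics:
    def test_sensitivity_from_accepted_counts(self):
        accepted = np.r_[np.ones(39), np.zeros(6), np.zeros(45)].astype(bool)
        labels = np.r_[["BA"] * 45, ["alien"] * 45]
        m = sensitivity_specificity(accepted, labels, "BA")
        assert m.sensitivity == 86.7

    def test_specificity_from_rejected_counts(self):
        accepted = np.r_[np.ones(45), np.zeros(15), np.ones(2), np.zeros(26), np.ones(2)].astype(bool)
        labels = np.r_[["BA"] * 45, ["Cat"] * 17, ["Mis"] * 28]
        m = sensitivity_specificity(accepted, labels, "BA")
        assert m.specificity == 91.1

    def test_everything_accepted_gives_zero_specificity(self):
        m = sensitivity_specificity(np.ones(10, dtype=bool),
                                    np.r_[["BA"] * 5, ["Mis"] * 5], "BA")
        assert m.specificity == 0.0
        assert m.sensitivity == 100.0

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_specificity(np.ones(3, dtype=bool), ["BA"] * 3, "BA")


class TestAlienOrdering:
    def test_mis_like_rejected_more_than_cat_like(self, default_dataset):
        """The far class is rejected at a higher rate than the overlapping one,
        mirroring the class geometry of the provenance study."""
        _, blocks, table = default_dataset
        frame = table.per_sample()
        block = select_regions(blocks["ftmir"], default_regions("ftmir"))
        tr = np.nonzero(((frame.class_label == "BA") & (frame.harvest_year < 2017)).to_numpy())[0]
        te = np.nonzero((frame.harvest_year == 2017).to_numpy())[0]
        train, fitted = fit_pipeline(block.take(tr), default_pipeline("ftmir"))
        model = fit_simca(train.intensities, alpha=0.05, target="BA")
        dec = score_samples(model, fitted.apply(block.take(te)).intensities)
        labels = frame.iloc[te]["class_label"].to_numpy()
        reject_mis = np.mean(~dec.accepted[labels == "Mis"])
        reject_cat = np.mean(~dec.accepted[labels == "Cat"])
        assert reject_mis >= reject_cat
        assert reject_mis > 0.9
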