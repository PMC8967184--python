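"""EM mixture model: steps, convergence, determinism, and recovery."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ddmc import DDMC, PhosphoDataset, SynthSpec, generate, quantify_weight_influence
from ddmc.model import hungarian_cluster_map, load_model, save_model
from conftest import make_windows


def manual_model(means, variances, mixing, weight=0.0):
    """A DDMC shell with parameters set by hand (no fitting)."""
    m = DDMC(n_clusters=len(means), weight=weight)
    m.means_ = np.asarray(means, dtype=float)
    m.variances_ = np.asarray(variances, dtype=float)
    m.mixing_ = np.asarray(mixing, dtype=float)
    return m


class TestESteps:
    def test_identical_clusters_split_evenly(self):
        m = manual_model([[0.0], [0.0]], [[1.0], [1.0]], [0.5, 0.5])
        R, _ = m._e_step(np.array([[1.3]]), np.ones((1, 1), dtype=bool))
        np.testing.assert_allclose(R, [[0.5, 0.5]])

    def test_frozen_two_cluster_posterior(self):
        # 1-D, means 0 and 1, unit variances, uniform mixing, x = 0.25:
        # log-density difference is 0.25, softmax gives (0.5622, 0.4378)
        m = manual_model([[0.0], [1.0]], [[1.0], [1.0]], [0.5, 0.5])
        R, _ = m._e_step(np.array([[0.25]]), np.ones((1, 1), dtype=bool))
        np.testing.assert_allclose(R[0], [0.5622, 0.4378], atol=5e-5)

    def test_all_missing_row_follows_prior(self):
        m = manual_model([[0.0], [5.0]], [[1.0], [1.0]], [0.7, 0.3])
        R, _ = m._e_step(np.array([[0.0]]), np.zeros((1, 1), dtype=bool))
        np.testing.assert_allclose(R[0], [0.7, 0.3])

    def test_rows_sum_to_one(self, synth_default):
        ds, _ = synth_default
        m = DDMC(n_clusters=4, weight=5.0, random_state=0).fit(ds)
        np.testing.assert_allclose(m.responsibilities_.sum(axis=1), 1.0, atol=1e-9)


class TestMStep:
    def test_weighted_mean(self):
        m = DDMC(n_clusters=1)
        X = np.array([[0.0], [4.0]])
        mask = np.ones_like(X, dtype=bool)
        m._m_step(X, mask, np.array([[0.25], [0.75]]))
        assert m.means_[0, 0] == pytest.approx(3.0)

    def test_hard_single_cluster_is_arithmetic_mean_of_observed(self):
        m = DDMC(n_clusters=1)
        X = np.array([[1.0, 5.0], [3.0, 0.0]])
        mask = np.array([[True, True], [True, False]])
        m._m_step(X, mask, np.ones((2, 1)))
        np.testing.assert_allclose(m.means_[0], [2.0, 5.0])

    def test_constant_column_hits_variance_floor(self):
        m = DDMC(n_clusters=1)
        X = np.full((3, 2), 2.5)
        m._m_step(X, np.ones_like(X, dtype=bool), np.ones((3, 1)))
        np.testing.assert_allclose(m.variances_[0], 1e-6)


class TestUpdateMissing:
    def test_convex_combination_of_centers(self):
        m = manual_model([[2.0], [4.0]], [[1.0], [1.0]], [0.5, 0.5])
        out = m._update_missing(
            np.array([[0.0]]), np.zeros((1, 1), dtype=bool), np.array([[0.5, 0.5]])
        )
        assert out[0, 0] == pytest.approx(3.0)

    def test_observed_cells_untouched(self, synth_default):
        ds, _ = synth_default
        m = DDMC(n_clusters=3, random_state=0).fit(ds)
        np.testing.assert_array_equal(m.imputed_[ds.mask], ds.abundance[ds.mask])

    def test_hard_assignment_gives_cluster_center(self):
        m = manual_model([[2.0], [4.0]], [[1.0], [1.0]], [0.5, 0.5])
        out = m._update_missing(
            np.array([[0.0]]), np.zeros((1, 1), dtype=bool), np.array([[0.0, 1.0]])
        )
        assert out[0, 0] == pytest.approx(4.0)


class TestFit:
    def test_single_cluster(self, synth_complete):
        ds, _ = synth_complete
        m = DDMC(n_clusters=1, random_state=0).fit(ds)
        np.testing.assert_allclose(m.responsibilities_, 1.0)
        np.testing.assert_allclose(m.means_[0], ds.abundance.mean(axis=0))
        np.testing.assert_allclose(m.cluster_centers()[:, 0], ds.abundance.mean(axis=0))

    def test_same_seed_is_deterministic(self, synth_default):
        ds, _ = synth_default
        a = DDMC(n_clusters=3, weight=5.0, random_state=42).fit(ds)
        b = DDMC(n_clusters=3, weight=5.0, random_state=42).fit(ds)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        np.testing.assert_array_equal(a.means_, b.means_)
        np.testing.assert_array_equal(a.imputed_, b.imputed_)

    def test_recovers_generating_partition(self, synth_default):
        ds, truth = synth_default
        m = DDMC(n_clusters=3, weight=5.0, seq_method="binomial", random_state=1).fit(ds)
        assert adjusted_rand_score(truth.labels, m.labels_) >= 0.9

    def test_pam250_method_also_recovers(self, synth_default):
        ds, truth = synth_default
        m = DDMC(n_clusters=3, weight=0.1, seq_method="pam250", random_state=1).fit(ds)
        assert adjusted_rand_score(truth.labels, m.labels_) >= 0.9

    def test_loglik_trace_finite_and_converged(self, synth_default):
        ds, _ = synth_default
        m = DDMC(n_clusters=3, weight=5.0, random_state=0).fit(ds)
        assert np.all(np.isfinite(m.log_likelihood_trace_))
        assert m.converged_

    def test_peptide_order_equivariance(self, synth_complete):
        ds, _ = synth_complete
        rng = np.random.default_rng(5)
        perm = rng.permutation(ds.n_peptides)
        m1 = DDMC(n_clusters=3, weight=5.0, random_state=3).fit(ds)
        m2 = DDMC(n_clusters=3, weight=5.0, random_state=3).fit(ds.subset(perm))
        # the recovered partition is identical up to cluster relabeling
        assert adjusted_rand_score(m1.labels_[perm], m2.labels_) == pytest.approx(1.0)

    def test_n_clusters_validation(self, tiny_dataset):
        with pytest.raises(ValueError, match="exceeds"):
            DDMC(n_clusters=10).fit(tiny_dataset)


class TestRescueAndAlignment:
    def test_empty_cluster_gets_reseeded(self, synth_complete):
        ds, _ = synth_complete
        m = DDMC(n_clusters=3, random_state=0).fit(ds)
        R = m.responsibilities_.copy()
        R[:, 2] = 0.0
        R /= R.sum(axis=1, keepdims=True)
        with pytest.warns(UserWarning, match="reseeding"):
            fixed = m._rescue_empty(R, ds.abundance, ds.mask)
        assert fixed[:, 2].sum() > 0

    def test_hungarian_identity_for_self(self, synth_default):
        ds, _ = synth_default
        m = DDMC(n_clusters=3, random_state=0).fit(ds)
        p = hungarian_cluster_map(m.responsibilities_, m.responsibilities_)
        np.testing.assert_array_equal(p, np.arange(3))

    def test_hungarian_undoes_column_shuffle(self, synth_default):
        ds, _ = synth_default
        m = DDMC(n_clusters=3, random_state=0).fit(ds)
        shuffled = m.responsibilities_[:, [2, 0, 1]]
        p = hungarian_cluster_map(m.responsibilities_, shuffled)
        np.testing.assert_array_equal(p, [2, 0, 1])


class TestWeightInfluence:
    def test_self_distance_zero_at_weight_zero(self, synth_complete):
        ds, _ = synth_complete
        fitted = DDMC(n_clusters=3, weight=0.0, random_state=0).fit(ds)
        d0, dmax = quantify_weight_influence(ds, fitted, large_weight=1e6)
        assert d0 == pytest.approx(0.0, abs=1e-6)
        assert dmax >= 0


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, synth_default):
        ds, _ = synth_default
        m = DDMC(n_clusters=3, weight=5.0, random_state=0).fit(ds)
        save_model(m, tmp_path / "model")
        back = load_model(tmp_path / "model")
        np.testing.assert_allclose(back.means_, m.means_)
        np.testing.assert_allclose(back.responsibilities_, m.responsibilities_, atol=1e-12)
        np.testing.assert_array_equal(back.labels_, m.labels_)
        assert back.get_params() == m.get_params()
        assert [w.residues for w in back.sequences_] == [w.residues for w in m.sequences_]


class TestOutOfSample:
    def test_transform_and_impute_new_data(self, synth_default):
        ds, truth = synth_default
        m = DDMC(n_clusters=3, weight=5.0, random_state=0).fit(ds)
        ds2, truth2 = generate(SynthSpec(seed=7))  # same conditions, same draw
        R2 = m.transform(ds2)
        np.testing.assert_allclose(R2.sum(axis=1), 1.0, atol=1e-9)
        filled = m.impute(ds2)
        np.testing.assert_array_equal(filled[ds2.mask], ds2.abundance[ds2.mask])
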