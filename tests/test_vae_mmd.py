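"""The semi-supervised VAE-MMD model: encoders, losses, MMD, training."""

import numpy as np
import pytest

from fcadapt._autodiff import Tensor
from fcadapt import vae_mmd as vm


def tiny_config(**kw):
    defaults = dict(
        input_dim=12, enc1_dim=8, enc2_dim=6, z1_dim=4, z2_dim=3,
        alpha=2.0, beta=1.0, epochs=3, batches_per_epoch=2, seed=0,
    )
    defaults.update(kw)
    return vm.VaeMmdConfig(**defaults)


def tiny_params(config, n_domains=2, seed=0):
    return vm.init_params(config, n_domains, np.random.default_rng(seed))


def batch(config, n=5, n_domains=2, seed=1):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-0.9, 0.9, (n, config.input_dim))
    d = np.eye(n_domains)[rng.integers(n_domains, size=n)]
    return x, d


class TestEncoders:
    def test_zero_weight_encoder_gives_zero_posterior(self):
        config = tiny_config()
        params = tiny_params(config)
        for k in ("enc1_w", "enc1_b", "enc1_mu_w", "enc1_mu_b",
                  "enc1_lv_w", "enc1_lv_b"):
            params[k].data[:] = 0.0
        x, d = batch(config)
        mu, lv = vm.encode_z1(params, x, d)
        assert np.array_equal(mu.data, np.zeros((5, config.z1_dim)))
        assert np.array_equal(lv.data, np.zeros((5, config.z1_dim)))

    def test_identical_inputs_identical_posteriors(self):
        config = tiny_config()
        params = tiny_params(config)
        x, d = batch(config, n=1)
        x2 = np.vstack([x, x])
        d2 = np.vstack([d, d])
        mu, lv = vm.encode_z1(params, x2, d2)
        assert np.array_equal(mu.data[0], mu.data[1])
        assert np.array_equal(lv.data[0], lv.data[1])

    def test_batch_shape_contract(self):
        config = tiny_config()
        params = tiny_params(config)
        x, d = batch(config, n=5)
        mu, lv = vm.encode_z1(params, x, d)
        assert mu.shape == (5, config.z1_dim) == lv.shape


class TestClassifier:
    def test_probabilities_sum_to_one(self):
        config = tiny_config()
        params = tiny_params(config)
        z1 = Tensor(np.random.default_rng(2).standard_normal((7, config.z1_dim)))
        probs = np.exp(vm.classifier_log_probs(params, z1).data)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_permuting_batch_permutes_outputs(self):
        config = tiny_config()
        params = tiny_params(config)
        z = np.random.default_rng(3).standard_normal((6, config.z1_dim))
        perm = np.array([3, 1, 5, 0, 2, 4])
        out = np.exp(vm.classifier_log_probs(params, Tensor(z)).data)
        out_perm = np.exp(vm.classifier_log_probs(params, Tensor(z[perm])).data)
        assert np.allclose(out[perm], out_perm)


class TestMMD:
    def test_identical_multisets_give_zero(self):
        a = np.random.default_rng(4).standard_normal((8, 3))
        assert vm.mmd_squared(a, a.copy(), bandwidth=1.0) < 1e-12

    def test_two_point_value_from_kernel_sum(self):
        # k(u,v) = exp(-(u-v)^2/2): 1 + 1 - 2*exp(-50)
        val = vm.mmd_squared(np.array([0.0]), np.array([10.0]), bandwidth=1.0)
        assert val == pytest.approx(1 + 1 - 2 * np.exp(-50.0), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(1, 21, size=2)
        dim = rng.integers(1, 4)
        a = rng.standard_normal((na, dim))
        b = rng.standard_normal((nb, dim))
        sigma = float(rng.uniform(0.5, 2.0))

        def k(u, v):
            return np.exp(-np.sum((u - v) ** 2) / (2 * sigma**2))

        brute = (
            np.mean([[k(u, v) for v in a] for u in a])
            + np.mean([[k(u, v) for v in b] for u in b])
            - 2 * np.mean([[k(u, v) for v in b] for u in a])
        )
        assert vm.mmd_squared(a, b, bandwidth=sigma) == pytest.approx(brute, abs=1e-10)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal((5, 2)), rng.standard_normal((9, 2))
        ab = vm.mmd_squared(a, b)
        ba = vm.mmd_squared(b, a)
        assert ab == pytest.approx(ba, abs=1e-12)
        assert ab >= 0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            vm.mmd_squared(np.empty((0, 2)), np.ones((3, 2)))


class TestLabeledLoss:
    def make_eps(self, config, n, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "z1": rng.standard_normal((n, config.z1_dim)),
            "z2": rng.standard_normal((n, config.z2_dim)),
        }

    def test_alpha_zero_kills_classification_term(self):
        config = tiny_config(alpha=0.0)
        params = tiny_params(config)
        x, d = batch(config)
        _, ce, _ = vm.loss_labeled(params, x, d, [0, 1, 2, 0, 1], config,
                                   self.make_eps(config, 5))
        assert float(ce.data) == 0.0

    def test_classification_term_linear_in_alpha(self):
        x, d = batch(tiny_config())
        eps = self.make_eps(tiny_config(), 5)
        results = {}
        for alpha in (1.0, 2.0):
            config = tiny_config(alpha=alpha)
            params = tiny_params(config, seed=0)
            elbo, ce, _ = vm.loss_labeled(params, x, d, [0, 1, 2, 0, 1],
                                          config, eps)
            results[alpha] = (float(elbo.data), float(ce.data))
        assert results[2.0][1] == pytest.approx(2 * results[1.0][1], rel=1e-12)
        assert results[2.0][0] == results[1.0][0]  # other terms untouched

    def test_finite_and_differentiable_across_seeded_draws(self):
        config = tiny_config()
        params = tiny_params(config)
        x, d = batch(config)
        for seed in range(100):
            eps = self.make_eps(config, 5, seed=seed)
            elbo, ce, _ = vm.loss_labeled(params, x, d, [0, 1, 2, 0, 1],
                                          config, eps)
            total = elbo + ce
            assert np.isfinite(total.data)
        total.backward()
        assert all(
            p.grad is None or np.all(np.isfinite(p.grad)) for p in params.values()
        )


class TestUnlabeledLoss:
    def test_point_mass_classifier_reduces_to_single_class(self):
        config = tiny_config()
        params = tiny_params(config)
        c = 2
        params["cls_w"].data[:] = 0.0
        params["cls_b"].data[:] = -1000.0
        params["cls_b"].data[c] = 0.0
        x, d = batch(config, n=4)
        rng = np.random.default_rng(5)
        eps = {
            "z1": rng.standard_normal((4, config.z1_dim)),
            "z2": rng.standard_normal((config.n_classes, 4, config.z2_dim)),
        }
        lt, _ = vm.loss_unlabeled(params, x, d, config, eps)
        # oracle: L_s with the forced class and the class-c noise draw
        mu1, lv1 = vm.encode_z1(params, x, d)
        z1 = mu1 + vm.exp(0.5 * lv1) * Tensor(eps["z1"])
        onehot = np.zeros((4, 3))
        onehot[:, c] = 1.0
        ls = vm.negelbo_given_z1(params, x, d, z1, mu1, lv1, onehot,
                                 eps["z2"][c]).sum()
        assert float(lt.data) == pytest.approx(float(ls.data), rel=1e-10)

    def test_uniform_classifier_entropy_equals_log3(self):
        config = tiny_config()
        params = tiny_params(config)
        params["cls_w"].data[:] = 0.0
        params["cls_b"].data[:] = 0.0
        n = 6
        x, d = batch(config, n=n)
        rng = np.random.default_rng(7)
        eps = {
            "z1": rng.standard_normal((n, config.z1_dim)),
            "z2": rng.standard_normal((config.n_classes, n, config.z2_dim)),
        }
        lt, _ = vm.loss_unlabeled(params, x, d, config, eps)
        # oracle: sum_c (1/3) L_c  minus  n * log(3)
        mu1, lv1 = vm.encode_z1(params, x, d)
        z1 = mu1 + vm.exp(0.5 * lv1) * Tensor(eps["z1"])
        expected = -n * np.log(3.0)
        for c in range(3):
            onehot = np.zeros((n, 3))
            onehot[:, c] = 1.0
            ls = vm.negelbo_given_z1(params, x, d, z1, mu1, lv1, onehot,
                                     eps["z2"][c])
            expected += float(ls.data.sum()) / 3.0
        assert float(lt.data) == pytest.approx(expected, rel=1e-10)

    def test_matches_per_sample_enumeration_oracle(self):
        config = tiny_config()
        params = tiny_params(config, seed=3)
        n = 5
        x, d = batch(config, n=n, seed=9)
        rng = np.random.default_rng(11)
        eps = {
            "z1": rng.standard_normal((n, config.z1_dim)),
            "z2": rng.standard_normal((config.n_classes, n, config.z2_dim)),
        }
        lt, _ = vm.loss_unlabeled(params, x, d, config, eps)
        # oracle: explicit per-sample, per-class enumeration
        mu1, lv1 = vm.encode_z1(params, x, d)
        z1 = mu1 + vm.exp(0.5 * lv1) * Tensor(eps["z1"])
        logq = vm.classifier_log_probs(params, z1).data
        q = np.exp(logq)
        expected = 0.0
        for i in range(n):
            for c in range(3):
                onehot = np.zeros((n, 3))
                onehot[:, c] = 1.0
                ls_c = vm.negelbo_given_z1(params, x, d, z1, mu1, lv1,
                                           onehot, eps["z2"][c]).data
                expected += q[i, c] * (ls_c[i] + logq[i, c])
        assert float(lt.data) == pytest.approx(expected, rel=1e-9)


class TestTotalLoss:
    def make_batches(self, config, domains, seed=13):
        rng = np.random.default_rng(seed)
        batches = {}
        for k, (name, labeled) in enumerate(domains.items()):
            n = 6
            d = np.zeros((n, len(domains)))
            d[:, k] = 1.0
            batches[name] = {
                "x": rng.uniform(-0.9, 0.9, (n, config.input_dim)),
                "d": d,
                "y_idx": rng.integers(3, size=n),
                "labeled": np.full(n, labeled),
            }
        return batches

    def test_beta_zero_has_exactly_zero_mmd_and_identical_other_terms(self):
        domains = {"source": True, "target": False}
        for beta in (0.0, 5.0):
            config = tiny_config(beta=beta)
            params = tiny_params(config, seed=1)
            batches = self.make_batches(config, domains)
            loss, bd, n_pairs = vm.total_loss(
                params, batches, config, np.random.default_rng(0)
            )
            if beta == 0.0:
                ref = bd
                assert bd.mmd_term == 0.0 and n_pairs == 0
        # same noise draws: non-MMD terms bit-identical across beta
        assert bd.labeled_elbo_sum == ref.labeled_elbo_sum
        assert bd.unlabeled_elbo_sum == ref.unlabeled_elbo_sum
        assert bd.classification_term == ref.classification_term
        assert bd.mmd_term > 0.0 and n_pairs == 1

    def test_auxiliary_cohort_adds_exactly_one_mmd_pair(self):
        config = tiny_config()
        params = tiny_params(config, n_domains=3)
        two = self.make_batches(config, {"source": True, "target": False})
        # re-make with 3 domains so one-hots are consistent
        three = self.make_batches(
            config, {"source": True, "target": False, "aux1": True}
        )
        _, _, pairs2 = vm.total_loss(
            tiny_params(config, n_domains=2), two, config,
            np.random.default_rng(0),
        )
        _, _, pairs3 = vm.total_loss(params, three, config,
                                     np.random.default_rng(0))
        assert pairs2 == 1 and pairs3 == 2

    def test_mmd_term_nonnegative_for_random_params(self):
        config = tiny_config(beta=3.0)
        for seed in range(5):
            params = tiny_params(config, seed=seed)
            batches = self.make_batches(config, {"source": True, "target": False},
                                        seed=seed)
            _, bd, _ = vm.total_loss(params, batches, config,
                                     np.random.default_rng(seed))
            assert bd.mmd_term >= 0.0

    def test_breakdown_total_is_sum_of_parts(self):
        config = tiny_config()
        params = tiny_params(config)
        batches = self.make_batches(config, {"source": True, "target": False})
        _, bd, _ = vm.total_loss(params, batches, config,
                                 np.random.default_rng(2))
        assert bd.total == pytest.approx(
            bd.labeled_elbo_sum + bd.unlabeled_elbo_sum
            + bd.classification_term + bd.mmd_term
        )


class TestTraining:
    def toy_data(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-0.9, 0.9, (n, 12))
        y = np.array(
            [("control", "autism", "asperger")[i % 3] for i in range(n)],
            dtype=object,
        )
        domain = np.array(["source", "target"] * (n // 2), dtype=object)
        y[domain == "target"] = "unknown"
        return X, y, domain

    def fit_tiny(self, seed=0, **kw):
        X, y, domain = self.toy_data()
        defaults = dict(
            input_dim=12, enc1_dim=8, enc2_dim=6, z1_dim=4, z2_dim=3,
            alpha=2.0, beta=1.0, epochs=3, batches_per_epoch=2, seed=seed,
        )
        defaults.update(kw)
        clf = vm.VAEMMDClassifier(**defaults)
        return clf.fit(X, y, domain=domain), X, y, domain

    def test_same_seed_identical_parameters(self):
        a, *_ = self.fit_tiny(seed=5)
        b, *_ = self.fit_tiny(seed=5)
        for k in a.params_:
            assert np.array_equal(a.params_[k].data, b.params_[k].data), k

    def test_history_records_all_loss_fields_per_epoch(self):
        clf, *_ = self.fit_tiny()
        assert len(clf.history_) == 3
        for rec in clf.history_:
            for key in ("labeled_elbo_sum", "unlabeled_elbo_sum",
                        "classification_term", "mmd_term", "total",
                        "epoch", "train_accuracy"):
                assert key in rec

    def test_checkpoints_track_first_layer(self):
        clf, *_ = self.fit_tiny()
        assert len(clf.w1_checkpoints_) == 3
        assert clf.w1_checkpoints_[0].shape == (12 + 2, 8)

    def test_missing_target_domain_with_beta_rejected(self):
        X, y, domain = self.toy_data()
        domain = np.where(domain == "target", "other", domain)
        y = np.array(["control", "autism", "asperger"] * 13 + ["control"],
                     dtype=object)
        clf = vm.VAEMMDClassifier(input_dim=12, enc1_dim=8, enc2_dim=6,
                                  z1_dim=4, z2_dim=3, beta=1.0, epochs=1)
        with pytest.raises(ValueError, match="target"):
            clf.fit(X, y, domain=domain)

    def test_all_unlabeled_rejected(self):
        X, y, domain = self.toy_data()
        y[:] = "unknown"
        clf = vm.VAEMMDClassifier(input_dim=12, enc1_dim=8, enc2_dim=6,
                                  z1_dim=4, z2_dim=3, epochs=1)
        with pytest.raises(ValueError, match="labeled"):
            clf.fit(X, y, domain=domain)

    def test_checkpoint_save_load_round_trip(self, tmp_path):
        clf, X, y, domain = self.fit_tiny()
        vm.save_checkpoint(clf, tmp_path / "ckpt")
        back = vm.load_checkpoint(tmp_path / "ckpt.npz")
        assert np.array_equal(
            back.predict(X, domain=domain), clf.predict(X, domain=domain)
        )
        assert back.config_ == clf.config_


class TestPredict:
    class Stub(vm.VAEMMDClassifier):
        def __init__(self, rows):
            super().__init__()
            self.rows = np.asarray(rows)
            self.classes_ = np.array(vm.CLASS_ORDER, dtype=object)
            self.params_ = {"stub": Tensor(np.zeros(1))}

        def predict_proba(self, X, domain=None):
            return self.rows

    def test_argmax_selection(self):
        stub = self.Stub([[0.2, 0.5, 0.3]])
        assert stub.predict(np.zeros((1, 2)))[0] == vm.CLASS_ORDER[1]

    def test_exact_tie_resolves_to_lowest_class_index(self):
        stub = self.Stub([[0.5, 0.5, 0.0]])
        assert stub.predict(np.zeros((1, 2)))[0] == vm.CLASS_ORDER[0]

    def test_batch_predict_equals_rowwise(self):
        rng = np.random.default_rng(17)
        rows = rng.dirichlet(np.ones(3), size=6)
        stub = self.Stub(rows)
        batch_out = stub.predict(np.zeros((6, 2)))
        row_out = [self.Stub([r]).predict(np.zeros((1, 2)))[0] for r in rows]
        assert list(batch_out) == row_out


class TestEndToEnd:
    def test_strong_signal_target_accuracy(self, strong_signal_run):
        """No site shift, strong class effect: target test accuracy >= 0.9."""
        assert strong_signal_run["target_test_accuracy"] >= 0.90

    def test_domain_confusion_reduces_latent_kl(self, beta_kl_grid):
        """beta>0 lowers residual source-target KL at every matched seed pair
        on average; the grid mean is monotone non-increasing in beta
        (one small inversion tolerated)."""
        means = {b: float(np.mean(v)) for b, v in beta_kl_grid.items()}
        assert means[10.0] < means[0.0]
        inversions = 0
        grid = sorted(means)
        for lo, hi in zip(grid, grid[1:]):
            if means[hi] > means[lo]:
                inversions += 1
                assert means[hi] <= 1.05 * means[lo]
        assert inversions <= 1
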