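"""Steps A-C: screening thresholds, CSP+SVM ON detection, the 9-class net."""

import numpy as np
import pytest

from sfebci import decoder as dec
from sfebci import signal_core as sc


class TestStepA:
    def _windows(self, rng, n=20):
        return rng.normal(scale=3.0, size=(n, 30, 100))

    def test_threshold_is_margin_times_peak(self, rng):
        w = np.zeros((1, 30, 100))
        i_fp1 = list(sc.MONTAGE_30).index("Fp1")
        w[0, i_fp1, :] = np.sqrt(2.0)   # energy = 100 * 2 = 200
        bank = dec.fit_step_a(w, list(sc.MONTAGE_30))
        assert bank.thresholds["Fp1"] == pytest.approx(210.0)

    def test_training_windows_always_accepted(self, rng):
        w = self._windows(rng)
        bank = dec.fit_step_a(w, list(sc.MONTAGE_30))
        assert dec.step_a_screen_batch(w, bank).all()

    def test_thresholds_match_brute_force(self, rng):
        w = self._windows(rng)
        bank = dec.fit_step_a(w, list(sc.MONTAGE_30))
        for name in sc.REFERENCE_CHANNELS:
            i = list(sc.MONTAGE_30).index(name)
            brute = 1.05 * max(float(np.sum(win[i] ** 2)) for win in w)
            assert bank.thresholds[name] == pytest.approx(brute)

    def test_zero_window_accepted_and_loud_rejected(self, rng):
        w = self._windows(rng)
        bank = dec.fit_step_a(w, list(sc.MONTAGE_30))
        assert dec.step_a_screen(np.zeros((30, 100)), bank)
        assert not dec.step_a_screen(w[0] * 10.0, bank)

    def test_missing_reference_channel_rejected(self, rng):
        no_fp1 = [c for c in sc.MONTAGE_30 if c != "Fp1"]
        with pytest.raises(sc.MontageMismatchError):
            dec.fit_step_a(rng.normal(size=(5, 29, 100)), no_fp1)


class TestThresholdMethodScore:
    @pytest.mark.parametrize("ar,rr,ts,expected", [
        (0.9945, 0.6866, 0.0055, 40.53),   # temporal-energy method
        (0.9948, 0.6467, 0.0055, 39.11),   # maximum-amplitude method
        (1.0, 1.0, 0.0, 50.00),
    ])
    def test_published_scores(self, ar, rr, ts, expected):
        assert dec.threshold_method_score(ar, rr, ts) == pytest.approx(
            expected, abs=0.005)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            dec.threshold_method_score(0.0, 0.5, 0.1)
        with pytest.raises(ValueError):
            dec.threshold_method_score(0.5, 0.5, -1.0)


class TestCSP:
    def _two_class(self, rng, n=40):
        """Class A has extra variance on channel 0, class B on channel 3."""
        a = rng.normal(size=(n, 6, 100))
        b = rng.normal(size=(n, 6, 100))
        a[:, 0] *= 3.0
        b[:, 3] *= 3.0
        return a, b

    def test_equal_variances_give_quarter_features(self):
        model = dec.CSPModel(filters=np.eye(4))
        rng = np.random.default_rng(0)
        base = rng.normal(size=100)
        window = np.tile(base, (4, 1)) * 2.0    # identical nonunit variances
        f = dec.csp_features(model, window)
        assert np.allclose(f, 0.25)

    def test_features_sum_to_one(self, rng):
        a, b = self._two_class(rng)
        model = dec.fit_csp(a, b)
        for w in a[:5]:
            assert dec.csp_features(model, w).sum() == pytest.approx(1.0)

    def test_eigen_oracle_and_separation(self, rng):
        a, b = self._two_class(rng)
        model = dec.fit_csp(a, b)
        # oracle: same generalized eigenproblem solved independently
        from scipy.linalg import eigh
        ca = dec._mean_normalized_cov(a)
        cb = dec._mean_normalized_cov(b)
        evals, evecs = eigh(ca, ca + cb)
        order = np.argsort(evals)
        expected = evecs[:, np.concatenate([order[::-1][:2], order[:2]])].T
        for row_got, row_exp in zip(model.filters, expected):
            cosang = abs(row_got @ row_exp) / (
                np.linalg.norm(row_got) * np.linalg.norm(row_exp))
            assert cosang == pytest.approx(1.0, abs=1e-8)
        # leading feature separates the classes
        from sklearn.metrics import roc_auc_score
        fa = dec.csp_features_batch(model, a)[:, 0]
        fb = dec.csp_features_batch(model, b)[:, 0]
        auc = roc_auc_score([1] * len(fa) + [0] * len(fb),
                            np.concatenate([fa, fb]))
        assert max(auc, 1 - auc) > 0.9

    def test_kernel_scale_closed_form(self):
        x = np.zeros((10, 4))
        x[::2] = 1.0                      # pooled variance = 0.25
        assert dec.kernel_scale(x) == pytest.approx(1.0)


class TestSFENetArchitecture:
    def test_layer_shape_audit(self):
        shapes = dec.SFENetSpec().layer_shapes()
        assert shapes == [(100, 30), (98, 64), (32, 64), (30, 128),
                          (128,), (64,), (32,), (9,)]

    def test_untrained_output_is_distribution(self, rng):
        net = dec.SFENet(seed=0)
        probs = net.predict_proba(rng.normal(size=(3, 30, 100)))
        assert probs.shape == (3, 9)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_forward_intermediate_shapes(self, rng):
        net = dec.SFENet(seed=0)
        cache = net.forward(rng.normal(size=(2, 100, 30)))
        assert cache["z1"].shape == (2, 98, 64)
        assert cache["pool"].shape == (2, 32, 64)
        assert cache["z2"].shape == (2, 30, 128)
        assert cache["h"].shape == (2, 128)

    def test_gradients_match_finite_differences(self, rng):
        """Backprop through conv/pool/GRU/dense checked numerically."""
        spec = dec.SFENetSpec(n_steps=12, n_channels=3, conv1_filters=4,
                              conv2_filters=5, gru_units=6, dense1=5,
                              dense2=4, n_classes=3, dropout=0.0,
                              recurrent_dropout=0.0)
        net = dec.SFENet(spec, seed=1)
        x = rng.normal(size=(4, 12, 3))
        y = np.eye(3)[rng.integers(0, 3, size=4)]
        cache = net.forward(x, train=False)
        grads = net.backward(cache, y)
        eps = 1e-6
        for name in ("W1", "Wxz", "Whh", "W5", "b3", "br"):
            p = net.params[name]
            flat_idx = [(0,) * p.ndim, tuple(d - 1 for d in p.shape)]
            for idx in flat_idx:
                orig = p[idx]
                p[idx] = orig + eps
                lp = net.loss(net.forward(x)["probs"], y)
                p[idx] = orig - eps
                lm = net.loss(net.forward(x)["probs"], y)
                p[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(numeric, rel=1e-3,
                                                         abs=1e-7)

    def test_training_is_deterministic_given_seed(self, rng):
        spec = dec.SFENetSpec(n_steps=20, n_channels=4, conv1_filters=4,
                              conv2_filters=6, gru_units=8, dense1=8,
                              dense2=6)
        x = rng.normal(size=(60, 4, 20))
        labels = [sc.ALL_LABELS[i % 9] for i in range(60)]
        n1, _ = dec.train_sfe_net(x, labels, spec=spec, seed=3, epochs=2)
        n2, _ = dec.train_sfe_net(x, labels, spec=spec, seed=3, epochs=2)
        for k in n1.params:
            assert np.array_equal(n1.params[k], n2.params[k])

    def test_missing_class_rejected(self, rng):
        net = dec.SFENet(seed=0)
        x = rng.normal(size=(10, 30, 100))
        with pytest.raises(ValueError):
            net.fit(x, ["s-RB"] * 10, epochs=1)

    def test_bundle_round_trip(self, tmp_path, rng):
        a = rng.normal(size=(8, 30, 100))
        b = rng.normal(size=(8, 30, 100)) * 2
        detector = dec.train_on_detector(a, b)
        bank = dec.fit_step_a(a, list(sc.MONTAGE_30))
        net = dec.SFENet(seed=0)
        dec.save_bundle(tmp_path / "bundle", bank, detector, net)
        bank2, det2, net2, meta = dec.load_bundle(tmp_path / "bundle")
        assert bank2.thresholds == pytest.approx(bank.thresholds)
        assert det2.gamma == pytest.approx(detector.gamma)
        w = rng.normal(size=(30, 100))
        assert np.allclose(dec.step_c_decode(net, w)[1],
                           dec.step_c_decode(net2, w)[1])

    def test_missing_bundle_names_train_command(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="train"):
            dec.load_bundle(tmp_path / "nope")


class TestBalancing:
    def test_minority_class_oversliced_to_match(self, rng):
        segs = {
            "big": [rng.normal(size=(3, 1000))],
            "small": [rng.normal(size=(3, 400))],
        }
        out = dec.balance_by_overlap(segs, length=100)
        assert len(out["big"]) == len(out["small"]) == 10
        assert out["small"].shape == (10, 3, 100)


class _ConstantModel:
    def __init__(self, label):
        self.label = label

    def fit(self, x, y):
        return self

    def predict(self, x):
        return np.array([self.label] * len(x))


class TestEvaluation:
    def test_perfect_predictions_identity_confusion(self, rng):
        classes = ["s-RB", "s-FB", "NON", "s-OM"]

        class Oracle:
            # class index is written into the windows themselves
            def fit(self, x, y):
                return self

            def predict(self, x):
                return np.array([classes[int(w[0, 0])] for w in x])

        x = rng.normal(size=(40, 2, 10))
        y = classes * 10
        for i, lab in enumerate(y):
            x[i, 0, 0] = classes.index(lab)
        report = dec.evaluate(Oracle, x, y, k_folds=4)
        assert report.accuracy == 1.0
        assert np.allclose(report.confusion,
                           np.diag(report.confusion.sum(axis=1)))
        assert report.confusion.sum() == 40

    def test_hand_built_confusion_metrics(self):
        confusion = np.array([[5, 1, 0],
                              [2, 6, 2],
                              [0, 1, 3]])
        report = dec.confusion_metrics(confusion, ["a", "b", "c"])
        assert report.accuracy == pytest.approx(14 / 20)
        assert report.precision == pytest.approx([5 / 7, 6 / 8, 3 / 5])
        assert report.recall == pytest.approx([5 / 6, 6 / 10, 3 / 4])
        f1_b = 2 * (6 / 8) * (6 / 10) / ((6 / 8) + (6 / 10))
        assert report.f1[1] == pytest.approx(f1_b)

    def test_instruction_assignment_by_accuracy(self):
        labels = list(sc.ALL_LABELS)
        diag = [99, 80, 95, 70, 90, 60, 85, 75, 99]
        confusion = np.diag(diag).astype(float)
        confusion[:, -1] += 100 - np.array(diag)   # misses decoded as NON
        report = dec.confusion_metrics(confusion, labels)
        mapping = dec.assign_instructions(report, ["Open", "Up", "Down"])
        # most vital "Open" goes to best non-s-RB class (s-LS at 95)
        assert mapping["s-LS"] == "Open"
        assert mapping["s-OM"] == "Up"     # 90 second best
        assert mapping["s-PM"] == "Down"   # 85 third
        assert "s-RB" not in mapping
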