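"""Task heads, label transforms, metric oracles, and the fitting loops."""

import numpy as np
import pytest

from echovid.errors import ContractError, DataError, ParameterError
from echovid.mae_core import EncoderConfig, PretrainState, run_pretraining
from echovid.nn import AdamW, Linear, Tensor, log_softmax
from echovid.synthetic_echo import PhantomParams, generate_phantom
from echovid.tasks_eval import (FitOptions, TaskSpec, attach_head,
                                bootstrap_ci, classification_metrics,
                                clinical_metrics, ef_threshold_labels,
                                finetune, inverse_transform_labels,
                                linear_probe, regression_metrics,
                                transform_labels)
from echovid.tokenization import CubeGridSpec

# ---------------------------------------------------------------------
# brute-force metric oracles (independent of the package implementations)
# ---------------------------------------------------------------------


def brute_mae(p, t):
    return sum(abs(a - b) for a, b in zip(p, t)) / len(p)


def brute_r2(p, t):
    mean_t = sum(t) / len(t)
    ss_res = sum((a - b) ** 2 for a, b in zip(p, t))
    ss_tot = sum((b - mean_t) ** 2 for b in t)
    return 1 - ss_res / ss_tot


def brute_auc(scores, labels):
    """Rank-sum enumeration over all positive/negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((1.0 if p > n else 0.5 if p == n else 0.0)
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_f1(preds, labels, positive=1):
    tp = sum(1 for p, l in zip(preds, labels) if p == positive and l == positive)
    fp = sum(1 for p, l in zip(preds, labels) if p == positive and l != positive)
    fn = sum(1 for p, l in zip(preds, labels) if p != positive and l == positive)
    if tp == 0:
        return 0.0
    prec, rec = tp / (tp + fp), tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def brute_pearson(p, t):
    p = np.asarray(p, float)
    t = np.asarray(t, float)
    pc = p - p.mean()
    tc = t - t.mean()
    return float((pc * tc).sum() / np.sqrt((pc ** 2).sum() * (tc ** 2).sum()))


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert m["mae"] == 0 and m["mse"] == 0 and m["r2"] == pytest.approx(1.0)

    def test_constant_mean_prediction_r2_zero(self):
        truth = np.array([1.0, 2, 3, 4])
        pred = np.full(4, truth.mean())
        assert regression_metrics(pred, truth)["r2"] == pytest.approx(0.0)

    def test_hand_example(self):
        m = regression_metrics(np.array([2.0, 2, 2]), np.array([1.0, 2, 3]))
        assert m["mae"] == pytest.approx(2 / 3)
        assert m["r2"] == pytest.approx(0.0)
        assert m["rmse"] == pytest.approx(np.sqrt(m["mse"]))

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 50))
            t = rng.standard_normal(n)
            p = t + rng.standard_normal(n) * 0.5
            m = regression_metrics(p, t)
            assert m["mae"] == pytest.approx(brute_mae(p, t))
            assert m["r2"] == pytest.approx(brute_r2(p, t))

    def test_degenerate_truth_raises(self):
        with pytest.raises(DataError):
            regression_metrics(np.array([1.0, 2]), np.array([3.0, 3.0]))


class TestClassificationMetrics:
    def _two_col(self, pos_scores):
        pos = np.asarray(pos_scores, float)
        return np.stack([1 - pos, pos], axis=1)

    def test_spec_auc_example(self):
        labels = np.array([0, 0, 1, 1])
        scores = self._two_col([0.1, 0.4, 0.35, 0.8])
        m = classification_metrics(scores, labels, 2)
        assert m["auc"] == pytest.approx(0.75)
        assert m["auc"] == pytest.approx(brute_auc([0.1, 0.4, 0.35, 0.8], labels))

    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        m = classification_metrics(self._two_col([0.1, 0.2, 0.8, 0.9]), labels, 2)
        assert m["auc"] == 1.0 and m["accuracy"] == 1.0 and m["f1"] == 1.0

    def test_onehot_scores_perfect(self):
        labels = np.array([0, 1, 2, 1])
        scores = np.eye(3)[labels]
        m = classification_metrics(scores, labels, 3)
        assert m["accuracy"] == 1.0 and m["f1"] == 1.0

    def test_matches_brute_force_binary(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            pos = rng.random(n)
            m = classification_metrics(self._two_col(pos), labels, 2)
            assert m["auc"] == pytest.approx(brute_auc(list(pos), list(labels)))
            preds = (pos >= 0.5).astype(int)
            assert m["f1"] == pytest.approx(brute_f1(list(preds), list(labels)))

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            classification_metrics(np.array([[0.5, 0.9], [0.1, 0.9]]),
                                   np.array([0, 1]), 2)

    def test_single_class_raises(self):
        with pytest.raises(DataError):
            classification_metrics(self._two_col([0.2, 0.6]), np.array([1, 1]), 2)


class TestClinicalMetrics:
    def test_identity(self):
        t = np.array([40.0, 55.0, 62.0])
        m = clinical_metrics(t, t)
        assert m["cor"] == pytest.approx(100.0)
        assert m["bias"] == 0.0 and m["std"] == 0.0

    def test_constant_shift(self):
        t = np.array([40.0, 55.0, 62.0])
        m = clinical_metrics(t + 5, t)
        assert m["cor"] == pytest.approx(100.0)
        assert m["bias"] == pytest.approx(5.0)
        assert m["std"] == pytest.approx(0.0, abs=1e-9)

    def test_anticorrelated(self):
        t = np.array([40.0, 55.0, 62.0])
        assert clinical_metrics(-t, t)["cor"] == pytest.approx(-100.0)

    def test_matches_brute_force(self, rng):
        p = rng.standard_normal(30) * 10 + 50
        t = rng.standard_normal(30) * 10 + 50
        m = clinical_metrics(p, t)
        assert m["cor"] == pytest.approx(100 * brute_pearson(p, t))
        diff = p - t
        assert m["bias"] == pytest.approx(float(diff.mean()))
        assert m["std"] == pytest.approx(float(np.std(diff, ddof=1)))

    def test_zero_variance_raises(self):
        with pytest.raises(DataError):
            clinical_metrics(np.array([1.0, 1.0]), np.array([2.0, 3.0]))


class TestEfThresholdLabels:
    def test_above_threshold_positive(self):
        assert ef_threshold_labels(np.array([55.0]), 0.5)[0] == 1

    def test_below_threshold_negative(self):
        assert ef_threshold_labels(np.array([45.0]), 0.5)[0] == 0

    def test_boundary_uses_geq(self):
        assert ef_threshold_labels(np.array([45.0]), 0.45)[0] == 1

    def test_invalid_threshold(self):
        with pytest.raises(ParameterError):
            ef_threshold_labels(np.array([50.0]), 1.5)


class TestTransformLabels:
    def test_log_fixed_point(self):
        task = TaskSpec(target="LV_ESV", log_scale=True)
        y = np.array([1.0])
        t = transform_labels(y, task)
        assert t[0] == 0.0
        np.testing.assert_allclose(inverse_transform_labels(t, task), y)

    def test_roundtrip_random_positive(self, rng):
        task = TaskSpec(target="LV_EDV", log_scale=True)
        y = rng.random(20) * 200 + 1e-3
        back = inverse_transform_labels(transform_labels(y, task), task)
        np.testing.assert_allclose(back, y, rtol=1e-12)

    def test_identity_for_ef(self, rng):
        task = TaskSpec(target="LV_EF", log_scale=False)
        y = rng.random(5) * 100
        np.testing.assert_array_equal(transform_labels(y, task), y)

    def test_nonpositive_rejected(self):
        task = TaskSpec(target="LV_ESV", log_scale=True)
        with pytest.raises(DataError):
            transform_labels(np.array([0.0, 5.0]), task)


class TestAttachHead:
    def test_regression_single_output(self, rng):
        head = attach_head(48, TaskSpec(), 24, rng)
        out = head(Tensor(rng.random((3, 48))))
        assert out.shape == (3, 1)

    def test_five_class_head(self, rng):
        task = TaskSpec(kind="classification", target="as_severity", n_classes=5)
        head = attach_head(24, task, 24, rng)
        assert head(Tensor(rng.random((2, 24)))).shape == (2, 5)

    def test_zero_weights_constant_bias(self, rng):
        head = attach_head(24, TaskSpec(), 24, rng)
        for p in head.parameters():
            p.data = np.zeros_like(p.data)
        head.fc2.bias.data[:] = 0.7
        out = head(Tensor(rng.random((4, 24)))).data
        np.testing.assert_allclose(out, 0.7, atol=1e-6)

    def test_wrong_width_raises(self, rng):
        with pytest.raises(ContractError):
            attach_head(30, TaskSpec(), 24, rng)


class TestBootstrapCI:
    def test_contains_point_estimate(self, rng):
        t = rng.standard_normal(100)
        p = t + rng.standard_normal(100) * 0.3
        mae = regression_metrics(p, t)["mae"]
        lo, hi = bootstrap_ci(lambda a, b: regression_metrics(a, b)["mae"],
                              p, t, n_boot=300, seed=0)
        assert lo <= mae <= hi

    def test_width_shrinks_with_n(self, rng):
        widths = []
        for n in (50, 200, 800):
            t = rng.standard_normal(n)
            p = t + rng.standard_normal(n) * 0.5
            lo, hi = bootstrap_ci(lambda a, b: regression_metrics(a, b)["mae"],
                                  p, t, n_boot=300, seed=1)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


# ---------------------------------------------------------------------
# fit loops on a miniature phantom task
# ---------------------------------------------------------------------

MICRO_GRID = CubeGridSpec(T=4, tau=2, H=16, h=8, W=16, w=8, d_model=24)
MICRO_CFG = EncoderConfig(depth=1, d_model=24, heads=2, mlp_ratio=2.0,
                          decoder_depth=1, decoder_width=12, decoder_heads=2)


def micro_dataset(n=18, seed=0, classification=False):
    rng = np.random.default_rng(seed)
    clips, targets = [], []
    for i in range(n):
        c = float(rng.uniform(0.1, 0.6))
        lc = generate_phantom(PhantomParams(
            T_raw=MICRO_GRID.T, H=MICRO_GRID.H, W=MICRO_GRID.W, cycle_length=4,
            a_ED=5.0, b_ED=3.5, contraction=c, speckle_sigma=0.05,
            seed=int(rng.integers(1 << 30))))
        clips.append(lc.clip.pixels)
        targets.append(lc.ef)
    clips = np.stack(clips)
    targets = np.asarray(targets)
    if classification:
        targets = (targets >= np.median(targets)).astype(float)
    idx = np.tile(np.arange(MICRO_GRID.T), (n, 1))
    n_tr = n - 8
    splits = {"train": slice(0, n_tr), "val": slice(n_tr, n_tr + 4),
              "test": slice(n_tr + 4, n)}
    return {s: {"clips": clips[sl], "frame_indices": idx[sl],
                "targets": targets[sl]} for s, sl in splits.items()}


@pytest.fixture(scope="module")
def micro_pretrain_ckpt(tmp_path_factory):
    data = micro_dataset(n=10, seed=3)
    res = run_pretraining(
        data["train"]["clips"], MICRO_GRID, MICRO_CFG,
        PretrainState(peak_lr=1e-3, warmup_init_lr=1e-4, batch_size=4,
                      mask_ratio=0.75, seed=0),
        tmp_path_factory.mktemp("pre"), total_steps=20)
    return res.checkpoint_path


class TestFinetune:
    def test_best_epoch_is_argmin_of_val_loss(self, micro_pretrain_ckpt):
        opts = FitOptions(epochs=4, batch_size=8, peak_lr=1e-3, seed=0,
                          use_stf=False)
        result = finetune(micro_pretrain_ckpt, micro_dataset(), TaskSpec(), opts)
        assert result.val_losses[result.best_epoch] == min(result.val_losses)

    def test_seed_reproducible(self, micro_pretrain_ckpt):
        opts = FitOptions(epochs=3, batch_size=8, peak_lr=1e-3, seed=7,
                          use_stf=False)
        r1 = finetune(micro_pretrain_ckpt, micro_dataset(), TaskSpec(), opts)
        r2 = finetune(micro_pretrain_ckpt, micro_dataset(), TaskSpec(), opts)
        assert r1.best_epoch == r2.best_epoch
        assert r1.report.metrics == r2.report.metrics

    def test_random_init_requires_configs(self):
        with pytest.raises(ParameterError):
            finetune(None, micro_dataset(), TaskSpec(), FitOptions())

    def test_classification_path(self, micro_pretrain_ckpt):
        task = TaskSpec(kind="classification", target="LV_EF", n_classes=2)
        opts = FitOptions(epochs=2, batch_size=8, peak_lr=1e-3, seed=0,
                          use_stf=False)
        result = finetune(micro_pretrain_ckpt, micro_dataset(classification=True),
                          task, opts)
        assert set(result.report.metrics) == {"accuracy", "auc", "f1"}

    def test_missing_split_raises(self, micro_pretrain_ckpt):
        data = micro_dataset()
        data["val"] = {"clips": data["val"]["clips"][:0],
                       "frame_indices": data["val"]["frame_indices"][:0],
                       "targets": data["val"]["targets"][:0]}
        with pytest.raises(DataError):
            finetune(micro_pretrain_ckpt, data, TaskSpec(),
                     FitOptions(epochs=1, use_stf=False))


class TestLinearProbe:
    def test_encoder_frozen(self, micro_pretrain_ckpt):
        opts = FitOptions(epochs=2, batch_size=8, peak_lr=1e-2, seed=0)
        # linear_probe raises internally if any encoder weight moved
        result = linear_probe(micro_pretrain_ckpt, micro_dataset(), TaskSpec(), opts)
        assert result.report.n == 4

    def test_probe_on_separable_features_reaches_perfect_accuracy(self, rng):
        """One linear map trained on linearly separable features -> accuracy 1."""
        n = 40
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        feats = rng.standard_normal((n, 8)).astype(np.float32)
        feats[:, 0] = labels * 4.0 - 2.0 + rng.standard_normal(n) * 0.1
        probe = Linear(8, 2, rng)
        opt = AdamW([probe.weight, probe.bias], lr=0.05)
        onehot = np.eye(2, dtype=np.float32)[labels]
        for _ in range(120):
            logits = probe(Tensor(feats))
            loss = -(Tensor(onehot) * log_softmax(logits)).sum() * (1.0 / n)
            opt.zero_grad()
            loss.backward()
            opt.step()
        acc = (probe(Tensor(feats)).data.argmax(axis=1) == labels).mean()
        assert acc == 1.0
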