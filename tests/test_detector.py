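"""Detection dataset generation, training and evaluation metrics."""

from __future__ import annotations

import numpy as np
import pytest

from oxisense.detector import (
    DetectionDataset,
    DetectionSimulator,
    NoiseSpec,
    add_frame_noise,
    build_detection_dataset,
    evaluate,
    train_detector,
    DetectorModel,
)
from oxisense.forward import ForwardSolver
from oxisense.nn import MLP
from oxisense.thrombus_sampler import Target, make_target_grid


def test_frame_noise_snr_exact():
    """The noise normalisation enforces the requested power ratio exactly,
    so the mean ratio over many frames matches 10^(-SNR/10)."""
    rng = np.random.default_rng(0)
    ratios = []
    for _ in range(200):
        signal = rng.standard_normal(50)
        noisy = add_frame_noise(signal, 15.0, rng)
        ratios.append(
            np.linalg.norm(noisy - signal) ** 2 / np.linalg.norm(signal) ** 2
        )
    assert np.mean(ratios) == pytest.approx(10 ** (-1.5), rel=0.05)
    zero = np.zeros(10)
    assert np.array_equal(add_frame_noise(zero, 15.0, rng), zero)


@pytest.fixture(scope="module")
def quiet_simulator(tiny_bundle):
    """Simulator with vanishing jitter and effectively disabled frame noise."""
    solver = ForwardSolver(tiny_bundle.mesh, tiny_bundle.array,
                           tiny_bundle.geom)
    noise = NoiseSpec(target_jitter_sd=1e-12, background_jitter_sd=1e-12,
                      snr_db=300.0)
    return DetectionSimulator(solver, tiny_bundle.pattern, noise)


def test_negative_without_jitter_is_exactly_zero(quiet_simulator):
    rng = np.random.default_rng(1)
    sample = quiet_simulator.negative(rng)
    assert np.abs(sample).max() < 1e-9


def test_positive_has_contrast(quiet_simulator):
    rng = np.random.default_rng(2)
    clot = Target(center=np.array([0.03, 0.03, 0.018]), diameter=0.016)
    sample = quiet_simulator.positive(clot, rng)
    assert np.linalg.norm(sample) > 1e-4


def test_generation_reproducible(tiny_bundle):
    solver = ForwardSolver(tiny_bundle.mesh, tiny_bundle.array,
                           tiny_bundle.geom)
    sim = DetectionSimulator(solver, tiny_bundle.pattern)
    grid = make_target_grid(diameter=0.016, spacing=0.02)
    a = build_detection_dataset(sim, grid, 4, 4, seed=9)
    b = build_detection_dataset(sim, grid, 4, 4, seed=9)
    assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)


def test_negatives_much_weaker_than_positives(tiny_bundle):
    """Median response of background-jitter negatives stays well below the
    median response to a 1.6 cm clot."""
    pos = np.linalg.norm(tiny_bundle.dataset.X[tiny_bundle.dataset.y == 1],
                         axis=1)
    neg = np.linalg.norm(tiny_bundle.dataset.X[tiny_bundle.dataset.y == 0],
                         axis=1)
    assert np.median(neg) / np.median(pos) < 0.5


def test_class_balance_and_split_disjoint(tiny_bundle):
    ds = tiny_bundle.dataset
    assert (ds.y == 1).sum() == (ds.y == 0).sum()
    tr, va, te = ds.split(seed=0)
    all_idx = np.concatenate([tr, va, te])
    assert len(np.unique(all_idx)) == len(ds)
    for part in (tr, va, te):
        assert len(np.unique(ds.y[part])) == 2


def test_detector_fits_linearly_separable_toy():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-2, 0.3, (60, 8)), rng.normal(2, 0.3, (60, 8))])
    y = np.repeat([0, 1], 60)
    ds = DetectionDataset(X=X, y=y)
    model, (tr, _, _) = train_detector(ds, widths=(16, 8), epochs=80, lr0=1e-2,
                                       seed=0)
    assert (model.predict(X[tr]) == y[tr]).mean() == 1.0


def test_label_shuffle_gives_chance_accuracy():
    """With permuted labels the classifier cannot beat the permutation
    null: held-out accuracy stays near 50%."""
    rng = np.random.default_rng(1)
    X = np.vstack(
        [rng.normal(-1, 0.5, (500, 10)), rng.normal(1, 0.5, (500, 10))]
    )
    y = rng.permutation(np.repeat([0, 1], 500))
    ds = DetectionDataset(X=X, y=y)
    model, (_, _, te) = train_detector(ds, widths=(16, 8), epochs=40, lr0=1e-2,
                                       seed=1)
    acc = (model.predict(X[te]) == y[te]).mean()
    assert abs(acc - 0.5) <= 0.15


def test_training_seeded_reproducible(tiny_bundle):
    m1, _ = train_detector(tiny_bundle.dataset, widths=(16, 8), epochs=15,
                           seed=4)
    m2, _ = train_detector(tiny_bundle.dataset, widths=(16, 8), epochs=15,
                           seed=4)
    assert m1.history.train_loss == m2.history.train_loss


def _report_from_predictions(y_true, y_pred):
    class _Fixed:
        def __init__(self, pred):
            self.pred = np.asarray(pred)

        def predict(self, X):
            return self.pred

    model = _Fixed(y_pred)
    return evaluate(model, np.zeros((len(y_true), 1)), y_true)


def test_evaluate_hand_computed_fixture():
    """Metrics agree with manual arithmetic on a 20-sample fixture:
    TP=8, FN=2, FP=1, TN=9."""
    y_true = np.array([1] * 10 + [0] * 10)
    y_pred = np.array([1] * 8 + [0] * 2 + [1] * 1 + [0] * 9)
    rep = _report_from_predictions(y_true, y_pred)
    assert rep.sensitivity == pytest.approx(0.8)
    assert rep.precision == pytest.approx(8 / 9)
    assert rep.f1 == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))
    assert rep.fp_fraction == pytest.approx(1 / 20)
    assert rep.accuracy == pytest.approx(17 / 20)
    assert rep.confusion.sum() == 20
    # F1 identity holds to near machine precision
    assert rep.f1 == pytest.approx(
        2 * rep.precision * rep.sensitivity / (rep.precision + rep.sensitivity),
        abs=1e-12,
    )


def test_evaluate_degenerate_predictors():
    y_true = np.repeat([1, 0], 10)
    perfect = _report_from_predictions(y_true, y_true)
    assert perfect.sensitivity == perfect.precision == perfect.f1 == 1.0
    assert perfect.fp_fraction == 0.0

    all_present = _report_from_predictions(y_true, np.ones(20, dtype=int))
    assert all_present.sensitivity == 1.0
    assert all_present.precision == pytest.approx(0.5)

    with pytest.raises(ValueError, match="both classes"):
        _report_from_predictions(np.ones(4, dtype=int), np.ones(4, dtype=int))


def test_detection_degrades_with_snr(tiny_bundle):
    """Average separability does not improve when the frame SNR drops from
    30 dB to 0 dB on a fixed coarse dataset."""
    solver = ForwardSolver(tiny_bundle.mesh, tiny_bundle.array,
                           tiny_bundle.geom)
    grid = make_target_grid(diameter=0.016, spacing=0.014)
    accs = []
    for snr in (30.0, 0.0):
        sim = DetectionSimulator(solver, tiny_bundle.pattern,
                                 NoiseSpec(snr_db=snr))
        ds = build_detection_dataset(sim, grid, 40, 40, seed=2)
        model, (_, _, te) = train_detector(ds, widths=(32, 16), epochs=60,
                                           lr0=1e-2, seed=2)
        accs.append((model.predict(ds.X[te]) == ds.y[te]).mean())
    assert accs[0] + 0.02 >= accs[1]
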