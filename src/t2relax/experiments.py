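"""Desk-scale comparison experiments.

The full-scale study (128x128 maps, 10,000 training series, GPU-scale
training) is summarised in the documentation; the functions here run the
same experimental design at a size a single CPU handles in minutes:
32x32 maps, encoder widths (16, 16, 32, 64), 300 training series.  The
*mechanisms* under test — Rician bias of Gaussian-loss estimators, the
accuracy gain of supervised CNNs, the spatial-prior dependence revealed
by pixel-random test data, and noise robustness — are size-independent
orderings, which is what these experiments measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .evaluation import ErrorMaps, slice_summary
from .fitting import fit_image_series
from .networks import (
    NetworkConfig,
    TrainingConfig,
    build_network,
    predict_parameter_map,
    train_model,
)
from .series import ImageSeries
from .signal_model import decay_signal, default_grid, rician_corrupt, snr_db
from .synthetic import DatasetManifest, SyntheticDataset, generate_dataset

__all__ = [
    "DeskProfile",
    "make_desk_corpora",
    "train_desk_network",
    "fit_predictor",
    "network_predictor",
    "median_slice_accuracy",
    "low_snr_bias",
    "noise_degradation",
]


@dataclass(frozen=True)
class DeskProfile:
    """Scaled-down study conditions for single-CPU experiments."""

    shape: tuple[int, int] = (32, 32)
    encoder_widths: tuple[int, ...] = (16, 16, 32, 64)
    n_train: int = 300
    n_test: int = 20
    cnn_epochs: int = 40
    cnn_batch: int = 10
    nn1d_epochs: int = 40
    nn1d_batch: int = 2048


def make_desk_corpora(seed: int, profile: DeskProfile = DeskProfile()):
    """Naturalistic train + test corpora and a pixel-random test corpus.

    Seeds for the three corpora are derived disjointly from ``seed``.
    """
    grid = default_grid()

    def make(style, n, sub_seed):
        return generate_dataset(
            DatasetManifest(
                n_series=n,
                shape=profile.shape,
                style=style,
                master_seed=sub_seed,
                grid=grid,
            )
        )

    train_nat = make("naturalistic", profile.n_train, seed * 3 + 0)
    test_nat = make("naturalistic", profile.n_test, seed * 3 + 1)
    test_urand = make("urand", profile.n_test, seed * 3 + 2)
    return train_nat, test_nat, test_urand


def train_desk_network(
    arch: str,
    strategy: str,
    train_ds: SyntheticDataset,
    seed: int,
    profile: DeskProfile = DeskProfile(),
):
    """Build and train one desk-profile network; returns (model, history)."""
    model = build_network(
        NetworkConfig(
            arch=arch, n_inputs=train_ds.grid.n, encoder_widths=profile.encoder_widths
        ),
        seed=seed,
    )
    config = TrainingConfig(
        strategy=strategy,
        epochs=profile.cnn_epochs if arch == "cnn" else profile.nn1d_epochs,
        batch_size=profile.cnn_batch if arch == "cnn" else profile.nn1d_batch,
        seed=seed,
    )
    history = train_model(model, train_ds, config)
    return model, history


def fit_predictor(method: str) -> Callable[[ImageSeries], "object"]:
    return lambda series: fit_image_series(series, method=method)


def network_predictor(model) -> Callable[[ImageSeries], "object"]:
    return lambda series: predict_parameter_map(model, series)


def median_slice_accuracy(predict, dataset: SyntheticDataset) -> float:
    """Median over series of the per-slice median absolute T error."""
    accuracies = []
    for i in range(len(dataset)):
        sample = dataset.sample(i)
        pmap = predict(sample.series)
        m = slice_summary(ErrorMaps(pmap.t, sample.truth.t_map), with_ssim=False)
        accuracies.append(m.accuracy)
    return float(np.median(accuracies))


def low_snr_bias(predict, dataset: SyntheticDataset, snr_threshold_db: float = 15.0) -> float:
    """Median signed T error over test pixels whose true SNR is below a cut."""
    errors = []
    for i in range(len(dataset)):
        sample = dataset.sample(i)
        truth = sample.truth
        clean = decay_signal(truth.s0_map, truth.t_map, dataset.grid)
        snr = snr_db(clean, sample.sigma)
        sel = snr < snr_threshold_db
        if not sel.any():
            continue
        pmap = predict(sample.series)
        errors.append((pmap.t - truth.t_map)[sel])
    if not errors:
        raise ValueError("no pixels below the SNR threshold")
    return float(np.median(np.concatenate(errors)))


def noise_degradation(
    predict, dataset: SyntheticDataset, sigma_add: float, seed: int
) -> float:
    """Accuracy degradation from added Rician noise, vs the method's own
    zero-added-noise reference: median over series of the per-slice median
    |T_noisy - T_reference|."""
    rng = np.random.default_rng(seed)
    degradations = []
    for i in range(len(dataset)):
        series = dataset.sample(i).series
        reference = predict(series)
        noisy = ImageSeries(
            data=rician_corrupt(series.data, sigma_add, rng),
            grid=series.grid,
            provenance=series.provenance + "+noise",
        )
        pmap = predict(noisy)
        m = slice_summary(ErrorMaps(pmap.t, reference.t), with_ssim=False)
        degradations.append(m.accuracy)
    return float(np.median(degradations))
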