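"""Scaled-down study presets: an end-to-end pipeline sized for one CPU.

The reference study trains the U-Net on 10,000 synthetic 128 x 128 series for
1000 epochs; these presets shrink every axis (map size, network width, corpus
size, epochs) so that synthesis -> training -> evaluation runs in minutes on
a single CPU while preserving the phenomena under study: the Rician-noise
bias of least squares, the accuracy advantage of a convolutional estimator on
spatially correlated data, and the shrinking of that advantage on
uncorrelated (pixelwise-random) data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn import CNNSpec, TrainConfig, build_cnn, build_nn1d, train_model
from .synth import SynthConfig, build_synthetic_dataset, procedural_corpus

__all__ = ["ScaledDownStudy", "train_scaled_down_models"]


@dataclass(frozen=True)
class ScaledDownStudy:
    """Problem sizes for the CPU-scale study."""

    size: int = 32              # map side (reference: 128)
    n_train: int = 240          # corpus-mode training series (reference: 10,000)
    n_test: int = 50            # held-out test series per dataset (reference: 1000)
    cnn_epochs: int = 60        # reference: 1000
    cnn_batch: int = 8          # reference: 100
    nn1d_train_series: int = 100
    nn1d_epochs: int = 40       # reference: 5 epochs over 13.1e6 curves
    nn1d_batch: int = 4096      # reference: 10,000
    lr: float = 0.002


def train_scaled_down_models(seed: int = 11, study: ScaledDownStudy = ScaledDownStudy()):
    """Build corpora, train both estimators, and return models plus test data.

    Training and test datasets use disjoint corpus partitions and disjoint
    seeds, so no ground-truth image pair is shared.  Returns a dict with the
    trained ``cnn`` (corpus-trained) and ``nn1d`` (urand-trained), their
    training histories, and the held-out ``corpus_test`` / ``urand_test``
    record lists.
    """
    n_imgs = 2 * study.n_train + 2 * study.n_test
    corpus = procedural_corpus(n_imgs, size=study.size, seed=seed)
    train_part = corpus[: 2 * study.n_train]
    test_part = corpus[2 * study.n_train :]

    train_recs = build_synthetic_dataset(
        SynthConfig(n_series=study.n_train, size=study.size, mode="corpus", seed=seed + 1),
        corpus=train_part,
    )
    corpus_test = build_synthetic_dataset(
        SynthConfig(n_series=study.n_test, size=study.size, mode="corpus", seed=seed + 2),
        corpus=test_part,
    )
    urand_test = build_synthetic_dataset(
        SynthConfig(n_series=study.n_test, size=study.size, mode="urand", seed=seed + 3)
    )
    nn1d_train = build_synthetic_dataset(
        SynthConfig(
            n_series=study.nn1d_train_series, size=study.size, mode="urand", seed=seed + 5
        )
    )

    cnn = build_cnn(CNNSpec.scaled_down(), seed=seed)
    cnn_history = train_model(
        cnn,
        train_recs,
        TrainConfig(epochs=study.cnn_epochs, batch_size=study.cnn_batch,
                    lr=study.lr, seed=seed),
    )
    nn1d = build_nn1d(seed=seed)
    nn1d_history = train_model(
        nn1d,
        nn1d_train,
        TrainConfig(epochs=study.nn1d_epochs, batch_size=study.nn1d_batch,
                    lr=study.lr, seed=seed),
    )
    return {
        "cnn": cnn,
        "cnn_history": cnn_history,
        "nn1d": nn1d,
        "nn1d_history": nn1d_history,
        "train_records": train_recs,
        "corpus_test": corpus_test,
        "urand_test": urand_test,
        "study": study,
        "seed": seed,
    }
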