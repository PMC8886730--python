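"""Shared fixtures. Heavy training artifacts are session-scoped so the
pretraining and alternating-training runs happen once and are reused by the
trainer, visualization and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from xrattn import (
    AlternatingSchedule,
    EncoderDecoder,
    EncoderDecoderConfig,
    PhantomSpec,
    RunConfig,
    build_model,
    phantom_dataset,
    pretrain_encoder_decoder,
    train_alternating,
)

# phantom-scale study conditions used across the suite
TRAIN_SIZE = 64
ENCDEC = dict(depth=3, base_channels=8)
PRETRAIN = dict(n_train=64, n_holdout=32, epochs=30, learning_rate=3e-3, batch_size=8)
ALTERNATE = dict(
    n_total=200, epochs=28, learning_rate=3e-3, attention_learning_rate=3e-4, batch_size=8
)


@pytest.fixture(scope="session")
def spec64() -> PhantomSpec:
    return PhantomSpec().scaled(TRAIN_SIZE)


@pytest.fixture(scope="session")
def spec128() -> PhantomSpec:
    return PhantomSpec()


def small_config(seed: int = 0) -> RunConfig:
    return RunConfig(image_size=TRAIN_SIZE, attachment_stages=[0, 1, 2], seed=seed)


def small_encdec_config() -> EncoderDecoderConfig:
    return EncoderDecoderConfig(**ENCDEC)


@pytest.fixture(scope="session")
def pretrain_result(spec64):
    """Encoder-decoder pretrained as a lung segmenter on 64 phantoms.

    Returns (encdec, history, holdout dataset of 32 fresh phantoms).
    """
    train = phantom_dataset(PRETRAIN["n_train"], spec64, seed=11)
    holdout = phantom_dataset(PRETRAIN["n_holdout"], spec64, seed=977)
    encdec = EncoderDecoder(small_encdec_config(), seed=0)
    history = pretrain_encoder_decoder(
        encdec,
        train,
        epochs=PRETRAIN["epochs"],
        batch_size=PRETRAIN["batch_size"],
        learning_rate=PRETRAIN["learning_rate"],
        seed=0,
    )
    return encdec, history, holdout


@pytest.fixture(scope="session")
def trained_pipeline(spec64, pretrain_result):
    """Full phantom pipeline: pretrained attention + alternating training.

    A 200-phantom set is split 140/30/30; the classifier's encoder-decoder is
    initialized from the pretraining fixture and trained with the alternating
    schedule. Returns dict with model, datasets and history.
    """
    encdec, _, _ = pretrain_result
    full = phantom_dataset(ALTERNATE["n_total"], spec64, seed=42)
    train = full.subset(np.arange(0, 140))
    val = full.subset(np.arange(140, 170))
    test = full.subset(np.arange(170, 200))
    model = build_model(small_config(seed=0), "small_cnn", small_encdec_config())
    model.encdec.load_state_dict(encdec.state_dict())
    schedule = AlternatingSchedule(
        period_epochs=1, first_component="main", total_epochs=ALTERNATE["epochs"]
    )
    history, best_state = train_alternating(
        model,
        train,
        val,
        schedule,
        learning_rate=ALTERNATE["learning_rate"],
        attention_learning_rate=ALTERNATE["attention_learning_rate"],
        batch_size=ALTERNATE["batch_size"],
        seed=0,
    )
    model.load_state_dict(best_state)
    return {
        "model": model,
        "train": train,
        "val": val,
        "test": test,
        "history": history,
    }
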