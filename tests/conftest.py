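"""Shared fixtures: the seeded synthetic benchmark cohort.

The benchmark emulates the study conditions at desk scale: 40 patients
with 20 slices each (800 slices), an even good/medium/bad mix, volumes
generated at 512x512 and downsampled to 96x96 for the QA network.
Generation and channel preparation are session-scoped because several
test modules share them.
"""

import numpy as np
import pytest

from segqa import model, phantom

BENCHMARK_SEED = 11
BENCHMARK_N_PATIENTS = 40
BENCHMARK_SLICES = 20
BENCHMARK_INPUT_SIZE = 96
BENCHMARK_TAU = 3.0

TRAIN_KW = dict(base_lr=0.05, random_crop=False, max_iterations=600,
                eval_interval=150, input_size=BENCHMARK_INPUT_SIZE)


@pytest.fixture(scope="session")
def benchmark_dataset():
    return phantom.generate_dataset(
        n_patients=BENCHMARK_N_PATIENTS,
        slices_per_patient=BENCHMARK_SLICES,
        seed=BENCHMARK_SEED,
        tau=BENCHMARK_TAU,
    )


@pytest.fixture(scope="session")
def benchmark_inputs(benchmark_dataset):
    """All three channels prepared once at the QA input size."""
    return model.prepare_inputs(
        benchmark_dataset, ("ct", "prob", "unc"), BENCHMARK_INPUT_SIZE)


def subset_channels(data: dict, channels: tuple[str, ...]) -> dict:
    """Select a channel subset from prepared (ct, prob, unc) tensors."""
    order = ("ct", "prob", "unc")
    idx = [order.index(c) for c in channels]
    return {s: dict(d, x=d["x"][:, idx]) for s, d in data.items()}


def train_levels3(data, channels, seed=1):
    cfg = model.ClassifierConfig(channel_set=channels, head="levels3",
                                 seed=seed, **TRAIN_KW)
    return model.train(model.build_model(cfg), subset_channels(data, cfg.channel_set))
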