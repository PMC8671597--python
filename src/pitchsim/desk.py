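"""Desk-scale study conditions: the package's reduced end-to-end setup.

One canonical configuration, chosen once, for running the whole pipeline on
a single CPU: a 50-bin synthetic dataset (20 exemplars per bin), a
50-fiber x 250-timestep periphery (5 kHz output rate), and a 2-conv-layer
classifier.  The full-scale settings remain available through the regular
configs; this module only bundles the reduced ones so tests, the CLI and
the reproduction script share identical conditions.
"""

from __future__ import annotations

import numpy as np

from .classifier import F0Classifier, F0ClassifierResults, TrainConfig
from .dataset import DatasetConfig, build_dataset
from .nnet import ArchitectureSpec
from .periphery import PeripheryConfig, PeripheryModel

__all__ = ["desk_periphery", "desk_architecture", "desk_dataset",
           "train_desk_classifier"]

DESK_N_BINS = 50
DESK_EXEMPLARS = 20


def desk_periphery() -> PeripheryModel:
    return PeripheryModel(PeripheryConfig(n_fibers=50, output_rate=5000.0))


def desk_architecture(n_classes: int = DESK_N_BINS) -> ArchitectureSpec:
    return ArchitectureSpec(
        input_shape=(50, 250),
        kernel_counts=[16, 16],
        kernel_sizes=[(2, 13), (2, 6)],
        pool_strides=[(2, 8), (2, 4)],
        fc_width=64,
        n_classes=n_classes,
    )


def desk_dataset(seed: int, periphery: PeripheryModel | None = None):
    cfg = DatasetConfig(n_bins=DESK_N_BINS, exemplars_per_bin=DESK_EXEMPLARS)
    return build_dataset(cfg, np.random.default_rng(seed),
                         periphery=periphery or desk_periphery())


def train_desk_classifier(seed: int = 0,
                          max_steps: int = 800) -> F0ClassifierResults:
    """Build the desk dataset, train the desk classifier, return results."""
    ds = desk_dataset(seed)
    model = F0Classifier.from_dataset(ds, spec=desk_architecture(), seed=seed)
    return model.fit(TrainConfig.desk_scale(max_steps=max_steps),
                     seed=seed + 1)
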