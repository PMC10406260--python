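"""Dataset assembly: cohorts of simulated subjects over a protocol grid.

Training and validation examples each draw their protocol uniformly at
manifest-build time (multi-center configuration, fixed thereafter);
test subjects are simulated under *every* protocol so that per-protocol
Dice can be averaged over a balanced design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .phantom import (
    DatasetSplit,
    LabelMap,
    Protocol,
    SimulatedImage,
    TissueNMR,
    DEFAULT_NMR,
    make_anatomy,
    simulate_image,
    split_cohort,
)


@dataclass
class StudyData:
    """In-memory train/val/test simulated images plus the split."""

    train: list[SimulatedImage]
    val: list[SimulatedImage]
    test: list[SimulatedImage]
    split: DatasetSplit
    protocols: list[Protocol]

    def manifest(self) -> pd.DataFrame:
        rows = []
        for split_name, images in (
            ("train", self.train), ("val", self.val), ("test", self.test)
        ):
            for im in images:
                rows.append({
                    "subject_id": im.label_map.subject_id,
                    "split": split_name,
                    "tr_ms": im.protocol.tr_ms,
                    "te_ms": im.protocol.te_ms,
                    "noise_sigma": im.noise_sigma,
                    "seed": im.seed,
                })
        return pd.DataFrame(rows)


def build_study_data(
    protocols: Sequence[Protocol],
    n_subjects: int = 25,
    size: tuple[int, int] = (96, 96),
    noise_sigma: float = 0.03,
    variability: float = 0.5,
    ratio: tuple[int, int, int] = (16, 4, 5),
    nmr: TissueNMR = DEFAULT_NMR,
    seed: int = 0,
) -> StudyData:
    """Simulate a full cohort: anatomies, split, protocol assignment.

    Deterministic in ``seed``; every per-subject anatomy and noise seed
    is drawn from one master generator in a fixed order.
    """
    protocols = list(protocols)
    master = np.random.default_rng(seed)
    ids = [f"sub-{i:04d}" for i in range(n_subjects)]
    anat_seeds = {s: int(master.integers(2 ** 31)) for s in ids}
    split = split_cohort(ids, ratio=ratio, seed=int(master.integers(2 ** 31)))

    def _anatomy(sid: str) -> LabelMap:
        return make_anatomy(
            seed=anat_seeds[sid], size=size, variability=variability,
            subject_id=sid,
        )

    train, val, test = [], [], []
    for sid in split.train_ids + split.val_ids:
        proto = protocols[int(master.integers(len(protocols)))]
        img = simulate_image(
            _anatomy(sid), proto, nmr=nmr, noise_sigma=noise_sigma,
            seed=int(master.integers(2 ** 31)),
        )
        (train if sid in split.train_ids else val).append(img)
    for sid in split.test_ids:
        anatomy = _anatomy(sid)
        for proto in protocols:
            test.append(simulate_image(
                anatomy, proto, nmr=nmr, noise_sigma=noise_sigma,
                seed=int(master.integers(2 ** 31)),
            ))
    return StudyData(train=train, val=val, test=test, split=split,
                     protocols=protocols)
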