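"""Train one U-Net under a train-time modification and evaluate it.

Builds a small cohort, trains with a contrast setting applied to train
and validation images, and reports per-tissue Dice under several
test-time settings (~1 minute on one CPU).
"""

import numpy as np

from contexseg import (
    ModelConfig,
    ModificationSetting,
    TrainConfig,
    enumerate_protocols,
    evaluate_setting_pair,
    train_model,
)
from contexseg.dataset import build_study_data
from contexseg.pipeline import subsample_protocols

protocols = subsample_protocols(enumerate_protocols(), 6)
data = build_study_data(protocols, n_subjects=25, size=(48, 48),
                        noise_sigma=0.03, seed=1)
print(f"cohort: {len(data.train)} train / {len(data.val)} val / "
      f"{len(data.test)} test images over {len(protocols)} protocols")

train_setting = ModificationSetting("contrast", -4)
model = train_model(
    data.train, data.val, train_setting,
    ModelConfig(input_size=(48, 48), depth=2, base_channels=8,
                dropout_rate=0.1),
    TrainConfig(epochs=60, learning_rate=5e-3, batch_size=8, seed=0),
)
print(f"trained with {train_setting}; best epoch {model.best_epoch} "
      f"(val loss {model.best_val_loss:.4f})")

print("\nmean Dice (CSF, GM, WM) by test-time setting:")
for test_setting in (ModificationSetting.none(),
                     ModificationSetting("contrast", 4),
                     ModificationSetting("contrast", -21),
                     ModificationSetting("contrast", 21)):
    scores = evaluate_setting_pair(model, test_setting, data.test,
                                   protocols)
    per_tissue = scores.mean(axis=1)
    print(f"  test={test_setting.label:>4}: "
          + "  ".join(f"{v:.3f}" for v in per_tissue)
          + f"   mean={per_tissue.mean():.3f}")
print("\nmatched mild settings keep Dice high; strongly opposed "
      "test-time contrast degrades it — the grid maps this exhaustively.")
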