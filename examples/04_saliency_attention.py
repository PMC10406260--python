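"""Integrated-Gradients saliency for a segmentation model.

Overfits a small net on one phantom, computes per-tissue IG maps,
verifies completeness, and rescales/differences the maps (~20 s).
"""

import numpy as np

from contexseg import (
    ModelConfig,
    ModificationSetting,
    Protocol,
    TrainConfig,
    make_anatomy,
    rescale_saliency,
    saliency_difference,
    segmentation_ig,
    simulate_image,
    train_model,
)
from contexseg.model import prepare_input
from contexseg.saliency import completeness_residual

anatomy = make_anatomy(seed=7, size=(32, 32), variability=0.3)
image = simulate_image(anatomy, Protocol(500, 25), noise_sigma=0.0)
model = train_model(
    [image], [image], ModificationSetting.none(),
    ModelConfig(input_size=(32, 32), depth=2, base_channels=8,
                dropout_rate=0.0),
    TrainConfig(epochs=150, learning_rate=5e-3, batch_size=1, seed=0),
)
x = prepare_input(image, ModificationSetting.none())

print("completeness |sum IG - (F(x) - F(x'))| vs path steps "
      "(trapezoid error shrinks):")
for n in (4, 8, 16, 32):
    smap = segmentation_ig(model, x, label=2, n_steps=n)
    print(f"  n_steps={n:2d}: residual {completeness_residual(model, smap, x):10.3f}")

maps = {}
for label, name in ((1, "CSF"), (2, "GM"), (3, "WM")):
    raw = segmentation_ig(model, x, label=label, n_steps=16)
    maps[name] = rescale_saliency(raw)
    att = maps[name].attributions
    fg = anatomy.foreground
    print(f"{name}: rescaled attribution mean fg {att[fg].mean():+.3f}, "
          f"bg {att[~fg].mean():+.3f}")

# attention shift: same label, same image, different test-time setting
x_mod = prepare_input(image, ModificationSetting("contrast", 11))
gm_mod = rescale_saliency(segmentation_ig(model, x_mod, label=2, n_steps=16))
diff = saliency_difference(gm_mod, maps["GM"])
print(f"\nGM saliency shift under test-time contrast +11: max |diff| "
      f"{np.abs(diff.attributions).max():.3f}, mean |diff| "
      f"{np.abs(diff.attributions).mean():.3f} "
      "(where the model's attention moved)")
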