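"""Simulate multi-protocol brain phantoms.

Builds one subject's anatomy, images it under the full 42-protocol
spin-echo grid, and prints how the tissue contrasts move with (TR, TE).
"""

import numpy as np

from contexseg import (
    DEFAULT_NMR,
    enumerate_protocols,
    make_anatomy,
    simulate_image,
    spin_echo_signal,
)

protocols = enumerate_protocols((300, 800, 100), (10, 40, 5))
print(f"{len(protocols)} protocols, TR {protocols[0].tr_ms:g}-"
      f"{protocols[-1].tr_ms:g} ms, TE {protocols[0].te_ms:g}-"
      f"{protocols[-1].te_ms:g} ms")

anatomy = make_anatomy(seed=7, size=(96, 96), variability=0.5)
counts = {t: int((anatomy.labels == i).sum())
          for i, t in enumerate(["bg", "CSF", "GM", "WM"])}
print("anatomy pixel counts:", counts)

print("\nper-protocol noiseless tissue signals (GM-WM gap drives task "
      "difficulty):")
for proto in (protocols[0], protocols[17], protocols[-1]):
    sig = {name: spin_echo_signal(params, proto)
           for name, params in DEFAULT_NMR.items()}
    img = simulate_image(anatomy, proto, noise_sigma=0.03, seed=0)
    print(f"  TR={proto.tr_ms:3g} TE={proto.te_ms:2g}: "
          + "  ".join(f"{k}={v:.3f}" for k, v in sig.items())
          + f"  |GM-WM|={abs(sig['GM'] - sig['WM']):.3f}"
          + f"  noisy max={img.intensities.max():.3f}")

# the same anatomy, different protocols -> same labels, new contrasts;
# different seeds -> different anatomies
other = make_anatomy(seed=8, size=(96, 96), variability=0.5)
print(f"\npixels differing between subjects 7 and 8: "
      f"{int((anatomy.labels != other.labels).sum())}")
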