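"""Run a small train x test modification grid end to end.

A reduced 3x3 contrast grid (one run, 2 protocols) so the example
finishes in about a minute; the full scaled-down study is
`replicate_small(PipelineConfig(seed=1), out)` or
`contexseg replicate-small --seed 1 --out out/` (~8 minutes).
"""

from pathlib import Path

from contexseg import PipelineConfig, replicate_small
from contexseg.config import (
    DataConfig, GridSpec, SaliencyConfig,
)
from contexseg.model import ModelConfig, TrainConfig

cfg = PipelineConfig(
    seed=1,
    data=DataConfig(n_subjects=10, size=(32, 32), n_protocols=2,
                    ratio=(6, 2, 2)),
    grid=GridSpec(kind="contrast", strengths=(-11, 11), n_runs=1),
    model=ModelConfig(input_size=(32, 32), depth=2, base_channels=8,
                      dropout_rate=0.1),
    train=TrainConfig(epochs=40, learning_rate=5e-3, batch_size=8),
    saliency=SaliencyConfig(n_steps=8),
)
out = Path("scratch/example_grid")
result = replicate_small(cfg, out, progress=True)

print("\nmean-over-tissues DSC heatmap (rows: train setting, cols: test):")
print(result.grid_result.mean_matrix().round(3).to_string())
for name, (train, test, value) in result.extremes.items():
    print(f"{name:>12}: train={train:>4} test={test:>4} DSC={value:.3f}")
print(f"\noutputs in {out}/ (heatmap CSV/PNG per tissue, extremes.json, "
      "attention_report.png, manifest.json)")
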