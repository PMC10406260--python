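"""Integrated-Gradients saliency for segmentation models.

For a class ``l`` the attribution of input pixel ``i`` sums the IG of
every output pixel, which collapses to a single path integral of the
gradient of the *summed* class-probability map:

    IG_i = (x_i - x'_i) * integral_0^1 d[ sum_mn F^l(x' + b (x - x'))_mn ] / dx_i db

evaluated with trapezoidal quadrature (default step 1/16).  Attribution
maps are rescaled by mapping their 5th/95th percentiles to -1/+1 (so
attribution is not dominated by tissue intensity), averaged across the
models of one grid cell, and differenced between cells to visualize
attention shift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Protocol as TypingProtocol, Sequence

import numpy as np

from .grid import GridResult, TISSUES
from .model import TrainedModel, class_sum_and_input_grad, prepare_input
from .phantom import SimulatedImage, TISSUE_LABELS, TISSUE_NAMES


class SupportsInputGrad(TypingProtocol):
    """Anything exposing the summed class probability and its input
    gradient (duck-typed so surrogate models can be attributed too)."""

    def class_sum_and_input_grad(
        self, image: np.ndarray, label: int
    ) -> tuple[float, np.ndarray]: ...


@dataclass(frozen=True)
class SaliencyMap:
    """Per-pixel attribution of one class for one image and model."""

    attributions: np.ndarray
    label: int
    n_steps: int
    baseline_kind: str = "zeros"
    rescaled: bool = False

    def __post_init__(self) -> None:
        att = np.asarray(self.attributions)
        if att.ndim != 2:
            raise ValueError("attributions must be 2D")
        if self.rescaled and (np.abs(att) > 1 + 1e-9).any():
            raise ValueError("rescaled attributions must lie in [-1, 1]")


@dataclass(frozen=True)
class SaliencyDiff:
    """Pixelwise difference of two rescaled saliency maps (a - b)."""

    attributions: np.ndarray
    label: int


def _grad_fn(model) -> "callable":
    if hasattr(model, "class_sum_and_input_grad"):
        return model.class_sum_and_input_grad
    if isinstance(model, TrainedModel):
        return lambda image, label: class_sum_and_input_grad(
            model, image, label
        )
    raise TypeError(
        "model must expose class_sum_and_input_grad(image, label)"
    )


def segmentation_ig(
    model,
    image: np.ndarray,
    label: int,
    baseline: np.ndarray | None = None,
    n_steps: int = 16,
) -> SaliencyMap:
    """Integrated Gradients of the summed class-``label`` probability.

    Walks the straight path from ``baseline`` (all-zeros in network
    input space by default) to ``image`` in ``n_steps`` segments,
    accumulating input gradients with trapezoidal weights
    (1/2, 1, ..., 1, 1/2) / n_steps, then multiplies elementwise by
    ``image - baseline``.  Exact for models linear in the input with
    any ``n_steps >= 1``; satisfies completeness up to quadrature error.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    x = np.asarray(image, dtype=float)
    if baseline is None:
        x0 = np.zeros_like(x)
        baseline_kind = "zeros"
    else:
        x0 = np.asarray(baseline, dtype=float)
        baseline_kind = "custom"
        if x0.shape != x.shape:
            raise ValueError("baseline shape must match the image")
    delta = x - x0
    if not delta.any():
        return SaliencyMap(
            attributions=np.zeros_like(x), label=label, n_steps=n_steps,
            baseline_kind=baseline_kind,
        )
    grad_fn = _grad_fn(model)
    acc = np.zeros_like(x)
    for k in range(n_steps + 1):
        beta = k / n_steps
        weight = (0.5 if k in (0, n_steps) else 1.0) / n_steps
        _, grad = grad_fn(x0 + beta * delta, label)
        if not np.isfinite(grad).all():
            raise FloatingPointError(
                f"non-finite input gradient at beta={beta:g}"
            )
        acc += weight * grad
    return SaliencyMap(
        attributions=delta * acc, label=label, n_steps=n_steps,
        baseline_kind=baseline_kind,
    )


def completeness_residual(
    model, saliency: SaliencyMap, image: np.ndarray,
    baseline: np.ndarray | None = None,
) -> float:
    """|sum_i IG_i - (sum_mn F(x) - sum_mn F(x'))| for one map."""
    x = np.asarray(image, dtype=float)
    x0 = np.zeros_like(x) if baseline is None else np.asarray(baseline)
    grad_fn = _grad_fn(model)
    fx, _ = grad_fn(x, saliency.label)
    f0, _ = grad_fn(x0, saliency.label)
    return abs(float(saliency.attributions.sum()) - (fx - f0))


def rescale_saliency(smap: SaliencyMap) -> SaliencyMap:
    """Affine map sending the 5th percentile to -1 and the 95th to +1,
    then clipping to [-1, 1].

    Percentiles use numpy's linear interpolation over all pixels of the
    one map.  Raises on a constant map (degenerate percentiles).
    """
    att = smap.attributions
    p5, p95 = np.percentile(att, [5, 95])
    if p95 == p5:
        raise ValueError("degenerate percentiles: constant attributions")
    scaled = -1.0 + 2.0 * (att - p5) / (p95 - p5)
    return replace(smap, attributions=np.clip(scaled, -1.0, 1.0),
                   rescaled=True)


def average_saliency(maps: Sequence[SaliencyMap]) -> SaliencyMap:
    """Pixelwise arithmetic mean of maps sharing label/shape/rescaling."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if (m.label != first.label
                or m.attributions.shape != first.attributions.shape
                or m.rescaled != first.rescaled):
            raise ValueError("maps must share label, shape and rescaling")
    mean = np.mean([m.attributions for m in maps], axis=0)
    return replace(first, attributions=mean)


def saliency_difference(a: SaliencyMap, b: SaliencyMap) -> SaliencyDiff:
    """a - b pixelwise; both operands must be rescaled and congruent."""
    if not (a.rescaled and b.rescaled):
        raise ValueError("difference maps require rescaled operands")
    if a.label != b.label or a.attributions.shape != b.attributions.shape:
        raise ValueError("operands must share label and geometry")
    return SaliencyDiff(attributions=a.attributions - b.attributions,
                        label=a.label)


def attention_report(
    grid_result: GridResult,
    image: SimulatedImage,
    cases: dict[str, tuple[str, str]],
    n_steps: int = 16,
) -> dict:
    """Saliency panels for named grid cells on one representative image.

    ``cases`` maps a case name (e.g. ``best``, ``original``, ``worst``,
    ``opposite_bad``) to a (train label, test label) cell.  For each
    case and tissue the report holds the rescaled saliency averaged over
    that cell's trained models, the difference versus the ``original``
    case, the predicted label map of the first model, and the cell's
    mean DSC from the heatmaps.
    """
    test_by_label = {s.label: s for s in grid_result.config.test_settings}
    report: dict = {"cases": {}, "image": image}
    for name, (train_label, test_label) in cases.items():
        models = [m for (lbl, _run), m in sorted(grid_result.models.items())
                  if lbl == train_label]
        if not models:
            raise ValueError(f"no cached models for train setting "
                             f"{train_label!r}")
        test_setting = test_by_label[test_label]
        x = prepare_input(image, test_setting)
        per_tissue = {}
        for t in TISSUE_LABELS:
            maps = [
                rescale_saliency(segmentation_ig(m, x, t, n_steps=n_steps))
                for m in models
            ]
            per_tissue[TISSUE_NAMES[t]] = average_saliency(maps)
        from .model import predict_labels
        dsc = {
            tissue: float(
                grid_result.heatmaps[tissue].values.loc[train_label,
                                                        test_label]
            )
            for tissue in TISSUES
        }
        report["cases"][name] = {
            "cell": (train_label, test_label),
            "saliency": per_tissue,
            "prediction": predict_labels(models[0], x),
            "dsc": dsc,
        }
    if "original" in report["cases"]:
        ref = report["cases"]["original"]["saliency"]
        for name, entry in report["cases"].items():
            entry["diff_vs_original"] = {
                tissue: saliency_difference(entry["saliency"][tissue],
                                            ref[tissue])
                for tissue in ref
            }
    return report


def plot_attention_report(report: dict, out_path) -> None:
    """Render the report as a Fig-style panel grid PNG
    (rows: prediction / GM saliency / GM difference; columns: cases)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cases = report["cases"]
    names = list(cases)
    n = len(names)
    fig, axes = plt.subplots(3, n, figsize=(3 * n, 9), squeeze=False)
    for j, name in enumerate(names):
        entry = cases[name]
        axes[0][j].imshow(entry["prediction"], cmap="viridis",
                          vmin=0, vmax=3)
        gm_dsc = entry["dsc"]["GM"]
        axes[0][j].set_title(f"{name} {entry['cell']}\nGM DSC {gm_dsc:.3f}",
                             fontsize=9)
        axes[1][j].imshow(entry["saliency"]["GM"].attributions,
                          cmap="coolwarm", vmin=-1, vmax=1)
        diff = entry.get("diff_vs_original")
        if diff is not None:
            axes[2][j].imshow(diff["GM"].attributions, cmap="coolwarm",
                              vmin=-2, vmax=2)
        for ax in (axes[0][j], axes[1][j], axes[2][j]):
            ax.set_xticks([])
            ax.set_yticks([])
    axes[0][0].set_ylabel("prediction")
    axes[1][0].set_ylabel("GM saliency")
    axes[2][0].set_ylabel("diff vs original")
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
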