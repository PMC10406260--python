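"""The train-setting x test-setting modification grid.

For every train-time modification setting a model is trained (the
setting also applied to validation images), then evaluated under every
test-time setting; per-tissue Dice is averaged within protocols, over
test subjects, and across repeated runs, yielding one heatmap per
tissue whose center cell ("Ori", "Ori") is the unmodified reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import StudyData
from .model import (
    ModelConfig,
    TrainConfig,
    TrainedModel,
    prepare_input,
    train_model,
)
from .modifications import ModificationSetting
from .phantom import Protocol, TISSUE_LABELS, TISSUE_NAMES

TISSUES = tuple(TISSUE_NAMES[t] for t in TISSUE_LABELS)  # CSF, GM, WM


def dice(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); both empty -> 1, one empty -> 0."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(gt_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


@dataclass(frozen=True)
class GridConfig:
    """Axes and repetition plan of one modification grid."""

    train_settings: tuple[ModificationSetting, ...]
    test_settings: tuple[ModificationSetting, ...]
    protocols: tuple[Protocol, ...]
    n_runs: int = 3
    base_seed: int = 0
    model_cfg: ModelConfig = field(default_factory=ModelConfig)
    train_cfg: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        for name, settings in (("train", self.train_settings),
                               ("test", self.test_settings)):
            kinds = {s.kind for s in settings} - {"none"}
            if len(kinds) > 1:
                raise ValueError(
                    f"{name}_settings mix kinds {sorted(kinds)}"
                )
            if not settings:
                raise ValueError(f"{name}_settings is empty")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def settings_axis(
    kind: str, strengths: Sequence[int]
) -> tuple[ModificationSetting, ...]:
    """Build one grid axis: given strengths in ascending order with the
    unmodified "Ori" setting inserted between the negative and positive
    halves (heatmap layout convention)."""
    neg = sorted(s for s in strengths if s < 0)
    pos = sorted(s for s in strengths if s > 0)
    axis = [ModificationSetting(kind, s) for s in neg]
    axis.append(ModificationSetting.none())
    axis += [ModificationSetting(kind, s) for s in pos]
    return tuple(axis)


@dataclass
class HeatmapGrid:
    """Per-tissue mean-DSC heatmap over (train setting, test setting)."""

    tissue: str
    values: pd.DataFrame  # rows: train settings, cols: test settings
    per_protocol: np.ndarray  # (n_train, n_test, n_protocols), run-averaged
    protocols: tuple[Protocol, ...]
    n_runs: int

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        finite = vals[np.isfinite(vals)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("DSC values must lie in [0, 1]")
        recon = np.nanmean(self.per_protocol, axis=2)
        if not np.allclose(np.where(np.isfinite(vals), vals, 0),
                           np.where(np.isfinite(recon), recon, 0)):
            raise ValueError(
                "heatmap values must equal the per-protocol tensor mean"
            )


@dataclass
class GridResult:
    """Everything a finished grid run produced."""

    config: GridConfig
    heatmaps: dict[str, HeatmapGrid]  # keyed by tissue name
    models: dict[tuple[str, int], TrainedModel]  # (train label, run)
    failures: list[tuple[str, int, str]]  # (train label, run, error)

    def mean_matrix(self) -> pd.DataFrame:
        """Unweighted mean of the CSF/GM/WM heatmaps."""
        stacked = np.stack(
            [self.heatmaps[t].values.to_numpy() for t in TISSUES]
        )
        first = self.heatmaps[TISSUES[0]].values
        return pd.DataFrame(stacked.mean(axis=0), index=first.index,
                            columns=first.columns)


def evaluate_setting_pair(
    model: TrainedModel,
    test_setting: ModificationSetting,
    test_set: Sequence,
    protocols: Sequence[Protocol],
    prepared: Sequence[np.ndarray] | None = None,
    batch_size: int = 16,
) -> np.ndarray:
    """Per-tissue, per-protocol mean DSC of one model under one
    test-time setting.

    Applies the test setting then z-score to each test image, predicts,
    computes Dice per tissue, and averages within each protocol over
    images.  ``prepared`` may carry the already modified+normalized
    inputs (same order as ``test_set``) so the filter work is shared
    across models.  Returns an array (3 tissues, n_protocols).
    """
    if prepared is None:
        prepared = [prepare_input(im, test_setting) for im in test_set]
    sums = np.zeros((len(TISSUE_LABELS), len(protocols)))
    counts = np.zeros(len(protocols))
    proto_index = {p: k for k, p in enumerate(protocols)}
    from .nn import softmax

    for start in range(0, len(test_set), batch_size):
        chunk = list(range(start, min(start + batch_size, len(test_set))))
        x = np.stack([prepared[i] for i in chunk])[:, None]
        preds = softmax(model.net.forward(x)).argmax(axis=1)
        for pred, i in zip(preds, chunk):
            image = test_set[i]
            k = proto_index[image.protocol]
            gt = image.label_map.labels
            for ti, t in enumerate(TISSUE_LABELS):
                sums[ti, k] += dice(pred == t, gt == t)
            counts[k] += 1
    if (counts == 0).any():
        raise ValueError("a protocol has no test images")
    return sums / counts[None, :]


def run_grid(
    config: GridConfig,
    data: StudyData,
    cache_dir: str | Path | None = None,
    progress: bool = False,
) -> GridResult:
    """Train and evaluate the full train x test modification grid.

    Trains ``len(train_settings) * n_runs`` models (run ``r`` uses seed
    ``base_seed + r``), evaluates each against every test setting, and
    averages DSC over runs and protocols.  Completed (train setting,
    run) evaluations are cached on disk when ``cache_dir`` is given, so
    an interrupted grid resumes.  A failed training is recorded and its
    cells are left missing (NaN); the run continues.
    """
    n_train = len(config.train_settings)
    n_test = len(config.test_settings)
    n_proto = len(config.protocols)
    # (runs, tissue, train, test, protocol)
    tensor = np.full(
        (config.n_runs, len(TISSUE_LABELS), n_train, n_test, n_proto),
        np.nan,
    )
    models: dict[tuple[str, int], TrainedModel] = {}
    failures: list[tuple[str, int, str]] = []
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    # modified+normalized test inputs are model-independent: compute once
    prepared_by_setting = [
        [prepare_input(im, ts) for im in data.test]
        for ts in config.test_settings
    ]
    for i, train_setting in enumerate(config.train_settings):
        for run in range(config.n_runs):
            key = f"train_{train_setting.label}_run{run}"
            cfile = cache / f"{key}.npy" if cache is not None else None
            if cfile is not None and cfile.exists():
                tensor[run, :, i] = np.load(cfile)
                mfile = cache / f"{key}_model.npz"
                if mfile.exists():
                    from .model import load_model

                    models[(train_setting.label, run)] = load_model(
                        str(mfile)[: -len(".npz")]
                    )
                continue
            if progress:  # pragma: no cover - cosmetic
                print(f"[grid] training {key}", flush=True)
            try:
                model = train_model(
                    data.train, data.val, train_setting,
                    config.model_cfg,
                    TrainConfig(
                        epochs=config.train_cfg.epochs,
                        learning_rate=config.train_cfg.learning_rate,
                        batch_size=config.train_cfg.batch_size,
                        seed=config.base_seed + run,
                        deterministic=config.train_cfg.deterministic,
                    ),
                )
            except Exception as exc:  # noqa: BLE001 - cell bookkeeping
                failures.append((train_setting.label, run, repr(exc)))
                continue
            models[(train_setting.label, run)] = model
            for j, test_setting in enumerate(config.test_settings):
                tensor[run, :, i, j] = evaluate_setting_pair(
                    model, test_setting, data.test, config.protocols,
                    prepared=prepared_by_setting[j],
                )
            if cfile is not None:
                from .model import save_model

                save_model(model, str(cache / f"{key}_model"))
                np.save(cfile, tensor[run, :, i])
    run_avg = np.nanmean(tensor, axis=0) if config.n_runs > 1 else tensor[0]
    labels_train = [s.label for s in config.train_settings]
    labels_test = [s.label for s in config.test_settings]
    heatmaps = {}
    for ti, tissue in enumerate(TISSUES):
        per_protocol = run_avg[ti]
        values = pd.DataFrame(
            np.nanmean(per_protocol, axis=2),
            index=labels_train, columns=labels_test,
        )
        heatmaps[tissue] = HeatmapGrid(
            tissue=tissue, values=values, per_protocol=per_protocol,
            protocols=config.protocols, n_runs=config.n_runs,
        )
    return GridResult(config=config, heatmaps=heatmaps, models=models,
                      failures=failures)


def _center_index(labels: Sequence[str]) -> int:
    try:
        return list(labels).index("Ori")
    except ValueError as exc:
        raise ValueError("grid axis has no 'Ori' setting") from exc


def locate_extremes(matrix: pd.DataFrame) -> dict[str, tuple[str, str, float]]:
    """Best / worst cells and the point reflection of worst through
    the ("Ori", "Ori") center.

    ``matrix`` is a mean-DSC heatmap (typically the unweighted mean over
    tissues).  Ties are broken in row-major order.  Returns a dict with
    keys ``best``, ``worst``, ``opposite_bad``, each a
    ``(train label, test label, value)`` triple.
    """
    vals = matrix.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("heatmap has missing cells")
    best_flat = int(vals.argmax())
    worst_flat = int(vals.argmin())
    bi, bj = np.unravel_index(best_flat, vals.shape)
    wi, wj = np.unravel_index(worst_flat, vals.shape)
    ci = _center_index(matrix.index)
    cj = _center_index(matrix.columns)
    oi, oj = 2 * ci - wi, 2 * cj - wj
    if not (0 <= oi < vals.shape[0] and 0 <= oj < vals.shape[1]):
        raise ValueError("reflection of worst cell falls outside the grid")

    def _cell(i: int, j: int) -> tuple[str, str, float]:
        return (str(matrix.index[i]), str(matrix.columns[j]),
                float(vals[i, j]))

    return {
        "best": _cell(bi, bj),
        "worst": _cell(wi, wj),
        "opposite_bad": _cell(oi, oj),
    }


def relative_improvement(matrix: pd.DataFrame, train_label: str,
                         test_label: str) -> float:
    """(value - original) / original versus the ("Ori","Ori") cell."""
    original = float(matrix.loc["Ori", "Ori"])
    value = float(matrix.loc[train_label, test_label])
    return (value - original) / original


def save_heatmaps(result: GridResult, out_dir: str | Path) -> list[Path]:
    """Write one CSV per tissue (rows=train, cols=test settings)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for tissue, hm in result.heatmaps.items():
        path = out / f"heatmap_{tissue}.csv"
        hm.values.to_csv(path, float_format="%.6f")
        paths.append(path)
    return paths


def plot_heatmaps(result: GridResult, out_dir: str | Path) -> list[Path]:
    """Render per-tissue heatmap PNGs with the 'Ori' center marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for tissue, hm in result.heatmaps.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        vals = hm.values.to_numpy()
        im = ax.imshow(vals, cmap="RdYlBu_r", origin="upper")
        ax.set_xticks(range(len(hm.values.columns)),
                      hm.values.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(hm.values.index)),
                      hm.values.index, fontsize=7)
        ax.set_xlabel("test-time setting")
        ax.set_ylabel("train-time setting")
        ci = _center_index(hm.values.index)
        cj = _center_index(hm.values.columns)
        ax.plot(cj, ci, marker="s", mfc="none", mec="black", ms=10)
        ax.set_title(f"Mean DSC over protocols: {tissue}")
        fig.colorbar(im, ax=ax)
        path = out / f"heatmap_{tissue}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
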