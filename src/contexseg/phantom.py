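"""Synthetic multi-protocol brain phantoms.

2D label maps with a nested head geometry (background -> CSF rim -> GM
ribbon -> WM core, plus a ventricle-like CSF interior) are warped by a
smooth random deformation field to emulate per-subject anatomical
variability.  Tissue intensities follow the spin-echo signal equation

    S = PD * (1 - exp(-TR/T1)) * exp(-TE/T2)

so that a (TR, TE) protocol grid produces the distinct tissue contrasts
of a multi-center acquisition, with additive Gaussian noise and an
optional smooth multiplicative bias field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
TISSUE_LABELS = (CSF, GM, WM)
TISSUE_NAMES = {CSF: "CSF", GM: "GM", WM: "WM"}


@dataclass(frozen=True)
class Protocol:
    """A spin-echo (TR, TE) pair in milliseconds."""

    tr_ms: float
    te_ms: float

    def __post_init__(self) -> None:
        if not (self.tr_ms > 0 and self.te_ms > 0):
            raise ValueError("TR and TE must be positive")
        if not self.te_ms < self.tr_ms:
            raise ValueError("TE must be smaller than TR")

    def label(self) -> str:
        return f"TR{self.tr_ms:g}_TE{self.te_ms:g}"


class TissueParams(NamedTuple):
    """NMR properties of one tissue: relaxation times (ms), proton density."""

    t1_ms: float
    t2_ms: float
    pd: float


@dataclass(frozen=True)
class TissueNMR:
    """Per-tissue T1/T2/PD triplets for CSF, GM and WM."""

    csf: TissueParams
    gm: TissueParams
    wm: TissueParams

    def __post_init__(self) -> None:
        for name, p in self.items():
            if not (p.t1_ms > 0 and p.t2_ms > 0 and p.pd > 0):
                raise ValueError(f"{name}: T1, T2 and PD must be positive")
            if not p.t2_ms < p.t1_ms:
                raise ValueError(f"{name}: T2 must be smaller than T1")

    def items(self):
        return (("CSF", self.csf), ("GM", self.gm), ("WM", self.wm))

    def by_label(self, label: int) -> TissueParams:
        return {CSF: self.csf, GM: self.gm, WM: self.wm}[label]


#: 1.5T-like literature values; plumbing defaults, configurable.
DEFAULT_NMR = TissueNMR(
    csf=TissueParams(t1_ms=2400.0, t2_ms=160.0, pd=1.0),
    gm=TissueParams(t1_ms=900.0, t2_ms=90.0, pd=0.85),
    wm=TissueParams(t1_ms=600.0, t2_ms=75.0, pd=0.75),
)


@dataclass(frozen=True)
class LabelMap:
    """Integer tissue map: 0 background, 1 CSF, 2 GM, 3 WM."""

    labels: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be a 2D array")
        if not np.isin(lab, (BACKGROUND, CSF, GM, WM)).all():
            raise ValueError("labels must take values in {0,1,2,3}")
        for t in TISSUE_LABELS:
            if not (lab == t).any():
                raise ValueError(
                    f"tissue {TISSUE_NAMES[t]} is absent from the label map"
                )
        border = np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
        if (border != BACKGROUND).any():
            raise ValueError("edge pixels must be background")

    @property
    def size(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def foreground(self) -> np.ndarray:
        return self.labels != BACKGROUND


@dataclass(frozen=True)
class SimulatedImage:
    """A simulated 2D acquisition tied to its anatomy and protocol."""

    intensities: np.ndarray
    label_map: LabelMap
    protocol: Protocol
    noise_sigma: float
    seed: int

    def __post_init__(self) -> None:
        img = np.asarray(self.intensities)
        if img.shape != self.label_map.labels.shape:
            raise ValueError("intensities and label map shapes differ")
        if not np.isfinite(img).all() or (img < 0).any():
            raise ValueError("intensities must be finite and non-negative")


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validation/test subject-id partition."""

    train_ids: tuple
    val_ids: tuple
    test_ids: tuple
    split_ratio: tuple[int, int, int] = (16, 4, 5)

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = len(self.train_ids) + len(self.val_ids) + len(self.test_ids)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split lists must be disjoint")


def spin_echo_signal(tissue: TissueParams, protocol: Protocol) -> float:
    """Spin-echo signal S = PD * (1 - exp(-TR/T1)) * exp(-TE/T2).

    Strictly increasing in TR, strictly decreasing in TE, bounded by
    (0, PD).
    """
    vals = (*tissue, protocol.tr_ms, protocol.te_ms)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite tissue or protocol parameters")
    t1, t2, pd = tissue
    return pd * (1.0 - math.exp(-protocol.tr_ms / t1)) * math.exp(
        -protocol.te_ms / t2
    )


def _template(size: tuple[int, int]) -> np.ndarray:
    """Undeformed nested-ring head template with a ventricle."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # head fits with a ~8% margin so edges stay background after warping
    ry, rx = 0.42 * h, 0.40 * w
    r = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    labels = np.full(size, BACKGROUND, dtype=np.int64)
    labels[r <= 1.0] = CSF
    labels[r <= 0.90] = GM
    labels[r <= 0.64] = WM
    # ventricle-like CSF interior, slightly off-center vertically
    rv = np.sqrt(((yy - cy + 0.08 * h) / (0.16 * h)) ** 2
                 + ((xx - cx) / (0.10 * w)) ** 2)
    labels[rv <= 1.0] = CSF
    return labels


def make_anatomy(
    seed: int,
    size: tuple[int, int] = (96, 96),
    variability: float = 0.5,
    subject_id: str | None = None,
) -> LabelMap:
    """Generate a deformed nested-ring phantom label map.

    Parameters
    ----------
    seed:
        Seeds the random deformation field; identical arguments give
        bit-identical maps.
    size:
        (H, W), at least 32x32.
    variability:
        Non-negative amplitude of the smooth random displacement field,
        in units of ~4% of the image height per unit of variability.
        0 returns the undeformed template.

    Raises
    ------
    ValueError
        If any tissue class vanishes after deformation.
    """
    h, w = size
    if h < 32 or w < 32:
        raise ValueError("size must be at least 32x32")
    if variability < 0:
        raise ValueError("variability must be >= 0")
    labels = _template(size)
    if variability > 0:
        rng = np.random.default_rng(seed)
        amp = 0.04 * h * variability
        disp = rng.standard_normal((2, h, w))
        disp = ndimage.gaussian_filter(disp, sigma=(0, h / 8.0, w / 8.0))
        # normalize so the peak displacement magnitude equals amp
        mag = np.sqrt((disp ** 2).sum(axis=0)).max()
        if mag > 0:
            disp *= amp / mag
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        coords = np.stack([yy + disp[0], xx + disp[1]])
        labels = ndimage.map_coordinates(
            labels, coords, order=0, mode="nearest"
        )
    labels[0, :] = labels[-1, :] = BACKGROUND
    labels[:, 0] = labels[:, -1] = BACKGROUND
    sid = subject_id if subject_id is not None else f"sub-{seed:04d}"
    return LabelMap(labels=labels, subject_id=sid)  # validates tissues


def bias_field(
    size: tuple[int, int], seed: int, strength: float = 0.2
) -> np.ndarray:
    """Smooth multiplicative low-order polynomial bias field around 1.

    ``strength`` is the approximate peak relative deviation from unity.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    y = np.linspace(-1, 1, h)[:, None]
    x = np.linspace(-1, 1, w)[None, :]
    c = rng.uniform(-1, 1, size=6)
    poly = (c[0] * y + c[1] * x + c[2] * y * x
            + c[3] * y ** 2 + c[4] * x ** 2 + c[5])
    peak = np.abs(poly).max()
    if peak > 0:
        poly *= strength / peak
    return 1.0 + poly


def simulate_image(
    anatomy: LabelMap,
    protocol: Protocol,
    nmr: TissueNMR = DEFAULT_NMR,
    noise_sigma: float = 0.03,
    bias: np.ndarray | None = None,
    seed: int = 0,
) -> SimulatedImage:
    """Simulate a 2D spin-echo acquisition of ``anatomy`` under ``protocol``.

    Foreground intensity is the closed-form spin-echo signal of the
    tissue at each pixel, times the optional bias field, plus additive
    Gaussian noise of standard deviation ``noise_sigma`` (applied to the
    whole image, then clipped at zero).  Background is exactly zero
    before noise.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    lab = anatomy.labels
    if bias is not None:
        bias = np.asarray(bias, dtype=float)
        if bias.shape != lab.shape:
            raise ValueError("bias field shape must match the anatomy")
    img = np.zeros(lab.shape, dtype=float)
    for t in TISSUE_LABELS:
        img[lab == t] = spin_echo_signal(nmr.by_label(t), protocol)
    if bias is not None:
        img *= bias
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        img = np.clip(img, 0.0, None)
    return SimulatedImage(
        intensities=img, label_map=anatomy, protocol=protocol,
        noise_sigma=noise_sigma, seed=seed,
    )


def enumerate_protocols(
    tr_range: tuple[float, float, float] = (300.0, 800.0, 100.0),
    te_range: tuple[float, float, float] = (10.0, 40.0, 5.0),
) -> list[Protocol]:
    """Cartesian (TR, TE) grid, inclusive of both endpoints, TR-major.

    Defaults give the 6 x 7 = 42 protocol grid (TR 300..800 ms step
    100, TE 10..40 ms step 5).
    """
    def _steps(start: float, stop: float, step: float) -> list[float]:
        if step <= 0 or stop < start:
            raise ValueError("range must satisfy start <= stop, step > 0")
        n = int(round((stop - start) / step))
        if not math.isclose(start + n * step, stop, rel_tol=0, abs_tol=1e-9):
            raise ValueError("stop must be reachable from start by step")
        return [start + i * step for i in range(n + 1)]

    return [
        Protocol(tr_ms=tr, te_ms=te)
        for tr in _steps(*tr_range)
        for te in _steps(*te_range)
    ]


def split_cohort(
    subject_ids: Sequence,
    ratio: tuple[int, int, int] = (16, 4, 5),
    seed: int = 0,
) -> DatasetSplit:
    """Random disjoint train/val/test partition with sizes ~ ``ratio``.

    Sizes are floor(n * r / sum(ratio)) per part; the remainder goes to
    the training set.  Deterministic in ``seed``.
    """
    ids = list(subject_ids)
    n = len(ids)
    if n < sum(ratio):
        raise ValueError(f"cohort must have at least {sum(ratio)} subjects")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    total = sum(ratio)
    n_val = n * ratio[1] // total
    n_test = n * ratio[2] // total
    n_train = n - n_val - n_test
    return DatasetSplit(
        train_ids=tuple(perm[:n_train]),
        val_ids=tuple(perm[n_train:n_train + n_val]),
        test_ids=tuple(perm[n_train + n_val:]),
        split_ratio=ratio,
    )


def select_slices(
    volume: np.ndarray,
    percentiles: Sequence[float] = (10, 30, 50, 70, 90),
    axis: int = 0,
) -> list[int]:
    """Nearest-rank percentile slice indices over non-empty slices.

    A slice is non-empty if it contains any non-zero voxel.  Returned
    indices therefore never point at empty slices.
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    vol = np.moveaxis(vol, axis, 0)
    nonempty = [i for i in range(vol.shape[0]) if np.any(vol[i] != 0)]
    if not nonempty:
        raise ValueError("volume has no non-empty slice")
    n = len(nonempty)
    out = []
    for p in percentiles:
        if not 0 <= p <= 100:
            raise ValueError("percentiles must lie in [0, 100]")
        rank = max(1, math.ceil(p / 100.0 * n))
        out.append(nonempty[rank - 1])
    return out


def dataset_plan(subject_ids: Sequence, protocols: Sequence[Protocol]):
    """Full (subject, protocol) image plan as a DataFrame.

    At the reference scale (500 subjects x 42 protocols) this enumerates
    21,000 simulated images.
    """
    import pandas as pd

    rows = [
        {"subject_id": s, "tr_ms": p.tr_ms, "te_ms": p.te_ms}
        for s in subject_ids
        for p in protocols
    ]
    return pd.DataFrame(rows, columns=["subject_id", "tr_ms", "te_ms"])
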