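"""Contrast and texture image modification filters.

Two families of intensity modifications, each parameterized by a signed
integer strength and applied identically at train and/or test time:

* **Contrast** — a sigmoid-logistic remapping of foreground intensities
  with gain ``G``.  For ``G > 0`` contrast increases; the ``G < 0``
  branch is the analytic inverse of the positive branch, so contrast
  decreases and ``apply(G)`` then ``apply(-G)`` is the identity.  The
  filter is a strictly increasing bijection of ``[0, max(f)]``.

* **Texture** — total-variation (TV) smoothing with fidelity weight
  ``alpha`` (``alpha > 0``, smaller alpha = stronger smoothing), and a
  sharpening variant ``2 f - u(-alpha)`` for ``alpha < 0`` that reflects
  the smoothed image about the original.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft

STRENGTH_MIN, STRENGTH_MAX = 2, 21


@dataclass(frozen=True)
class ModificationSetting:
    """One train- or test-time modification: kind plus integer strength.

    ``kind`` is ``"contrast"`` (strength is the gain G), ``"texture"``
    (strength is the TV weight alpha) or ``"none"`` (the unmodified
    "Ori" setting, no strength).  Valid strengths are the integers with
    2 <= |s| <= 21.
    """

    kind: str
    strength: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("contrast", "texture", "none"):
            raise ValueError(f"unknown modification kind {self.kind!r}")
        if self.kind == "none":
            if self.strength is not None:
                raise ValueError("'none' takes no strength")
        else:
            s = self.strength
            if s is None or int(s) != s:
                raise ValueError("strength must be an integer")
            if not STRENGTH_MIN <= abs(int(s)) <= STRENGTH_MAX:
                raise ValueError(
                    "strength must satisfy "
                    f"{STRENGTH_MIN} <= |s| <= {STRENGTH_MAX}, got {s}"
                )

    @classmethod
    def none(cls) -> "ModificationSetting":
        return cls(kind="none")

    @property
    def label(self) -> str:
        return "Ori" if self.kind == "none" else str(self.strength)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label if self.kind == "none" else f"{self.kind}{self.strength:+d}"


def h_gain(G: float) -> float:
    """Sigmoid-logistic gain h(G) = (1 - e^{-G/2}) / (1 + e^{-G/2}).

    Equals tanh(G/4); odd, strictly increasing, bounded in (-1, 1).
    """
    if G == 0:
        raise ValueError("G must be nonzero")
    return float(np.tanh(G / 4.0))


def _foreground(image: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != image.shape:
            raise ValueError("mask shape must match the image")
        return m
    return image > 0


def apply_contrast(
    image: np.ndarray,
    G: float,
    mask: np.ndarray | None = None,
    max_fg: float | None = None,
) -> np.ndarray:
    """Sigmoid-logistic contrast modification of the image foreground.

    For gain ``G > 0``::

        f_c = max(f) * h(f / max(f) * G) / h(G)

    and for ``G < 0`` the analytic inverse::

        f_c = (2 max(f) / G) * ln[(max(f) + f h(G)) / (max(f) - f h(G))]

    where ``max(f)`` is the maximum foreground intensity (or ``max_fg``
    if given).  Both branches fix 0 and ``max(f)`` and are strictly
    increasing, so the filter is a bijection of ``[0, max(f)]``.
    Pixels outside the foreground mask are returned bit-identical.
    """
    if G == 0:
        raise ValueError("G must be nonzero")
    img = np.asarray(image, dtype=float)
    if (img < 0).any():
        raise ValueError("input intensities must be non-negative")
    fg = _foreground(img, mask)
    m = float(np.max(img[fg])) if max_fg is None else float(max_fg)
    if not m > 0:
        raise ValueError("maximum foreground intensity must be positive")
    f = img[fg]
    h = h_gain(G)
    if G > 0:
        fc = m * np.tanh((f / m) * G / 4.0) / h
    else:
        # guard: f*|h| may round to m exactly at f = max(f)
        fh = np.clip(f * h, -(1 - 1e-12) * m, (1 - 1e-12) * m)
        fc = (2.0 * m / G) * np.log((m + fh) / (m - fh))
    out = img.copy()
    out[fg] = np.clip(fc, 0.0, m)
    return out


def _grad(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences with Neumann boundary (zero at last row/col)."""
    gy = np.zeros_like(u)
    gx = np.zeros_like(u)
    gy[:-1, :] = u[1:, :] - u[:-1, :]
    gx[:, :-1] = u[:, 1:] - u[:, :-1]
    return gy, gx


def _div(py: np.ndarray, px: np.ndarray) -> np.ndarray:
    """Negative adjoint of ``_grad`` (backward-difference divergence)."""
    d = np.zeros_like(py)
    d[0, :] += py[0, :]
    d[1:-1, :] += py[1:-1, :] - py[:-2, :]
    d[-1, :] += -py[-2, :]
    d[:, 0] += px[:, 0]
    d[:, 1:-1] += px[:, 1:-1] - px[:, :-2]
    d[:, -1] += -px[:, -2]
    return d


def tv_objective(u: np.ndarray, f: np.ndarray, alpha: float) -> float:
    """Isotropic ROF objective TV(u) + alpha * sum((f - u)^2)."""
    gy, gx = _grad(u)
    return float(np.sqrt(gy ** 2 + gx ** 2).sum()
                 + alpha * ((f - u) ** 2).sum())


def total_variation(u: np.ndarray) -> float:
    """Isotropic discrete total variation with Neumann boundary."""
    gy, gx = _grad(u)
    return float(np.sqrt(gy ** 2 + gx ** 2).sum())


def tv_denoise(
    image: np.ndarray,
    alpha: float,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> np.ndarray:
    """Split-Bregman minimizer of ``TV(u) + alpha * sum((f - u)^2)``.

    Isotropic TV, forward differences with Neumann boundaries; the
    linear u-subproblem is solved exactly per iteration with a DCT.
    Iterations stop when the relative change of ``u`` drops below
    ``tol``; hitting ``max_iter`` first raises a warning that reports
    the achieved residual.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    f = np.asarray(image, dtype=float)
    if f.ndim != 2:
        raise ValueError("image must be 2D")
    h, w = f.shape
    lam = 2.0 * alpha
    # DCT eigenvalues of the Neumann Laplacian
    ky = (2.0 * np.cos(np.pi * np.arange(h) / h) - 2.0)[:, None]
    kx = (2.0 * np.cos(np.pi * np.arange(w) / w) - 2.0)[None, :]
    denom = 2.0 * alpha - lam * (ky + kx)
    u = f.copy()
    dy = np.zeros_like(f)
    dx = np.zeros_like(f)
    by = np.zeros_like(f)
    bx = np.zeros_like(f)
    residual = np.inf
    for _ in range(max_iter):
        rhs = 2.0 * alpha * f - lam * _div(dy - by, dx - bx)
        u_new = spfft.idctn(spfft.dctn(rhs, norm="ortho") / denom,
                            norm="ortho")
        gy, gx = _grad(u_new)
        sy, sx = gy + by, gx + bx
        mag = np.sqrt(sy ** 2 + sx ** 2)
        shrink = np.maximum(mag - 1.0 / lam, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(mag > 0, shrink / mag, 0.0)
        dy, dx = scale * sy, scale * sx
        by, bx = sy - dy, sx - dx
        denom_u = np.linalg.norm(u)
        residual = (np.linalg.norm(u_new - u) / denom_u
                    if denom_u > 0 else np.linalg.norm(u_new))
        u = u_new
        if residual < tol:
            break
    else:
        warnings.warn(
            f"tv_denoise did not converge in {max_iter} iterations "
            f"(relative change {residual:.2e})",
            RuntimeWarning,
        )
    return u


def apply_texture(
    image: np.ndarray,
    alpha: float,
    mask: np.ndarray | None = None,
    max_fg: float | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> np.ndarray:
    """TV texture modification: smoothing for alpha > 0, sharpening below.

    ``alpha > 0`` returns the TV-smoothed image ``u(alpha)``;
    ``alpha < 0`` returns the sharpened ``2 f - u(-alpha)``.  Intensities
    are normalized to [0, 1] by the maximum foreground value before the
    TV solve and rescaled after, so alpha is scale-free.  With a mask,
    non-foreground pixels are returned bit-identical.
    """
    if alpha == 0:
        raise ValueError("alpha must be nonzero")
    f = np.asarray(image, dtype=float)
    m = float(np.max(np.abs(f))) if max_fg is None else float(max_fg)
    if m == 0:
        return f.copy()
    fn = f / m
    u = tv_denoise(fn, abs(alpha), tol=tol, max_iter=max_iter) * m
    out = u if alpha > 0 else 2.0 * f - u
    if mask is not None:
        fg = _foreground(f, mask)
        out = np.where(fg, out, f)
    return out


def apply_setting(
    image: np.ndarray,
    setting: ModificationSetting,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Apply one ModificationSetting to an image (identity for 'none')."""
    if setting.kind == "none":
        return np.asarray(image, dtype=float).copy()
    if setting.kind == "contrast":
        return apply_contrast(image, float(setting.strength), mask=mask)
    out = apply_texture(image, float(setting.strength), mask=mask)
    # clip: sharpening can overshoot below zero on noisy images
    return np.clip(out, 0.0, None)
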