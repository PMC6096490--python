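"""Resolution-dependent amplitude scaling.

The sharpening model multiplies each Fourier amplitude by an overall scale

    A(d) = w_sharpen(d) * A_sharpen(d) + w_blur(d) * A_blur(d)

where

    A_sharpen(d) = exp(+B_sharpen / (4 d^2))     low-resolution sharpening
    A_blur(d)    = exp(-B_blur   / (4 d^2))      high-resolution soft limit
    w_sharpen(d) = 1 / (1 + exp(-k (d - d_cut))) logistic crossover
    w_blur(d)    = 1 - w_sharpen(d)

A positive ``B_sharpen`` sharpens, negative blurs.  When the map is blurred
overall (``B_sharpen <= 0``) no additional high-resolution blur is applied:
the scale is ``A_sharpen(d)`` everywhere.  Defaults: ``B_blur = 200`` A^2
(attenuation by roughly 250-fold at 3 A), ``k = 10`` per A (the weight
crossover is ~90% complete within about +/-0.2 A of ``d_cut``), and ``d_cut``
equal to the nominal map resolution.

The overall sharpness of a map is summarized Wilson-style by the isotropic B
of its amplitude falloff, F(d) = F0 exp(-B_iso/(4 d^2)); anisotropy is
removed by fitting a symmetric B tensor to log amplitudes and rescaling so
the residual falloff is isotropic with B_iso = trace/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateMapError, SharpmaxError
from .map_io import (FourierCoefficients, ShellTable, VolumeGrid,
                     resolution_shells)

__all__ = [
    "SharpenParams",
    "ScaleProfile",
    "AnisoTensor",
    "scale_profile",
    "apply_sharpening",
    "fit_isotropic_b",
    "remove_anisotropy",
    "kurtosis",
    "empirical_overall_b",
    "transition_completion",
]

_EXP_CLIP = 60.0  # |exponent| cap to keep exp() finite


@dataclass(frozen=True)
class SharpenParams:
    """Four-parameter sharpen/blur model.

    b_sharpen : A^2, positive sharpens, negative blurs.
    b_blur    : A^2, high-resolution soft limit (default 200).
    d_cut     : A, sharpen-to-blur transition resolution (nominal map
                resolution by convention).
    k         : 1/A, transition steepness (default 10).
    """

    b_sharpen: float
    d_cut: float
    b_blur: float = 200.0
    k: float = 10.0

    def __post_init__(self):
        if self.b_blur < 0:
            raise SharpmaxError("b_blur must be >= 0")
        if self.k <= 0:
            raise SharpmaxError("k must be > 0")
        if self.d_cut <= 0:
            raise SharpmaxError("d_cut must be > 0")

    def replace(self, **kw) -> "SharpenParams":
        return replace(self, **kw)


@dataclass
class ScaleProfile:
    """Per-term factors of the four-parameter scale function."""

    a_sharpen: np.ndarray
    a_blur: np.ndarray
    w_sharpen: np.ndarray
    w_blur: np.ndarray
    a_total: np.ndarray

    def to_frame(self, d: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({
            "d": np.ravel(d),
            "a_sharpen": np.ravel(self.a_sharpen),
            "a_blur": np.ravel(self.a_blur),
            "w_sharpen": np.ravel(self.w_sharpen),
            "w_blur": np.ravel(self.w_blur),
            "a_total": np.ravel(self.a_total),
        })


@dataclass
class AnisoTensor:
    """Symmetric anisotropic B tensor (A^2)."""

    tensor: np.ndarray

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.shape != (3, 3) or not np.allclose(self.tensor, self.tensor.T):
            raise SharpmaxError("aniso tensor must be symmetric 3x3")

    @property
    def b_iso(self) -> float:
        return float(np.trace(self.tensor) / 3.0)


def _exp(x):
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


def scale_profile(d, params: SharpenParams) -> ScaleProfile:
    """Evaluate the scale function on an array of resolutions (A).

    ``d`` may contain +inf (the zero-frequency term), where every factor
    is exactly 1.
    """
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        inv4d2 = np.where(np.isfinite(d), 1.0 / (4.0 * d**2), 0.0)
    a_sharpen = _exp(params.b_sharpen * inv4d2)
    a_blur = _exp(-params.b_blur * inv4d2)
    if params.b_sharpen <= 0:
        # blurring overall: no extra high-resolution blur
        w_sharpen = np.ones_like(a_sharpen)
        w_blur = np.zeros_like(a_sharpen)
        a_total = a_sharpen
    else:
        arg = np.where(np.isfinite(d), params.k * (d - params.d_cut), _EXP_CLIP)
        w_sharpen = 1.0 / (1.0 + _exp(-arg))
        w_blur = 1.0 - w_sharpen
        a_total = w_sharpen * a_sharpen + w_blur * a_blur
    return ScaleProfile(a_sharpen, a_blur, w_sharpen, w_blur, a_total)


def transition_completion(k: float = 10.0, half_width: float = 0.2) -> float:
    """Completion level of the sharpen-to-blur weight crossover reached at
    ``d_cut +/- half_width``, as a fraction of the full 0-to-1 swing.

    The logistic is symmetric, so the sharpening weight at
    ``d_cut + half_width`` equals the blurring weight at
    ``d_cut - half_width``; with the default k = 10 per A the transition is
    ~90% complete within about 0.2 A of the crossover.
    """
    return float(1.0 / (1.0 + np.exp(-k * half_width)))


def apply_sharpening(coeffs: FourierCoefficients,
                     params: SharpenParams) -> FourierCoefficients:
    """Multiply amplitudes by A(d); phases untouched."""
    prof = scale_profile(coeffs.d_grid(), params)
    out = coeffs.copy()
    out.data *= prof.a_total
    return out


def empirical_overall_b(resolution: float) -> float:
    """Crystallographic fallback target: overall B of ten times the
    resolution in A (e.g. 40 A^2 at 4 A)."""
    return 10.0 * float(resolution)


# ---------------------------------------------------------------------------
# Wilson-style B estimation
# ---------------------------------------------------------------------------

def _term_arrays(coeffs: FourierCoefficients):
    d = coeffs.d_grid()
    sel = coeffs.retained_mask() & np.isfinite(d)
    amp = np.abs(coeffs.data[sel])
    return d[sel], amp


def fit_isotropic_b(coeffs: FourierCoefficients,
                    shells: ShellTable | None = None) -> float:
    """Fit the overall isotropic B of the amplitude falloff.

    Amplitude-weighted least squares of ln F against 1/(4 d^2) over the
    retained terms (slope = -B_iso).  When a shell table with at least three
    shells is supplied, terms in the lowest-resolution shell are excluded:
    the strongest low-order terms do not follow the Wilson-style falloff and
    would otherwise distort the fit.
    """
    d, amp = _term_arrays(coeffs)
    if shells is not None and len(shells) >= 3:
        keep = d <= shells.d_edges[1]
        d, amp = d[keep], amp[keep]
    pos = amp > 0
    d, amp = d[pos], amp[pos]
    if d.size < 2:
        raise DegenerateMapError("not enough non-zero amplitudes to fit B")
    x = 1.0 / (4.0 * d**2)
    y = np.log(amp)
    w = amp
    slope = _weighted_slope(x, y, w)
    return -slope


def _weighted_slope(x, y, w):
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    denom = (w * (x - xm) ** 2).sum()
    if denom == 0:
        raise DegenerateMapError("degenerate resolution distribution")
    return float((w * (x - xm) * (y - ym)).sum() / denom)


def remove_anisotropy(coeffs: FourierCoefficients):
    """Fit and remove an anisotropic B tensor from the amplitudes.

    ln F(h) = c - (1/4) s^T B s is fitted by linear least squares in the six
    tensor entries plus scale; amplitudes are rescaled so the residual
    falloff is isotropic with B_iso = trace(B)/3.  Phases are unchanged.

    Returns ``(corrected, AnisoTensor)``.  On a singular fit a warning is
    issued and the identity correction applied.
    """
    n = coeffs.data.shape
    comps = [np.fft.fftfreq(n[i], d=1.0) * n[i] / coeffs.cell[i] for i in range(3)]
    hx, ky, lz = np.meshgrid(*comps, indexing="ij")
    s1, s2, s3 = hx.ravel(), ky.ravel(), lz.ravel()
    amp = np.abs(coeffs.data).ravel()
    d = coeffs.d_grid().ravel()
    sel = (amp > 0) & np.isfinite(d) & coeffs.retained_mask().ravel()
    if sel.sum() < 20:
        warnings.warn("too few terms for anisotropy fit; identity applied")
        return coeffs.copy(), AnisoTensor(np.zeros((3, 3)))
    s1, s2, s3 = s1[sel], s2[sel], s3[sel]
    X = np.column_stack([
        np.ones(sel.sum()),
        -0.25 * s1**2, -0.25 * s2**2, -0.25 * s3**2,
        -0.5 * s1 * s2, -0.5 * s1 * s3, -0.5 * s2 * s3,
    ])
    y = np.log(amp[sel])
    sol, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 7:
        warnings.warn("singular anisotropy fit; identity correction applied")
        return coeffs.copy(), AnisoTensor(np.zeros((3, 3)))
    B = np.array([[sol[1], sol[4], sol[5]],
                  [sol[4], sol[2], sol[6]],
                  [sol[5], sol[6], sol[3]]])
    tensor = AnisoTensor(B)
    b_iso = tensor.b_iso
    # correction: divide out exp(-s^T B s / 4), restore exp(-b_iso s^2 / 4)
    svec = np.stack([hx, ky, lz])
    quad = np.einsum("i...,ij,j...->...", svec, B, svec)
    s2_grid = hx**2 + ky**2 + lz**2
    factor = _exp(0.25 * quad - 0.25 * b_iso * s2_grid)
    out = coeffs.copy()
    out.data *= factor
    return out, tensor


# ---------------------------------------------------------------------------
# kurtosis
# ---------------------------------------------------------------------------

def kurtosis(grid: VolumeGrid) -> float:
    """Raw (Pearson) kurtosis of map values: m4 / m2^2, Gaussian -> 3.

    Invariant under affine rescaling of the density.  Peaky, well-sharpened
    maps score high; only the location of the maximum over candidate B
    values matters for sharpening.
    """
    v = grid.values - grid.values.mean()
    m2 = np.mean(v**2)
    if m2 == 0:
        raise DegenerateMapError("kurtosis undefined for a constant map")
    return float(np.mean(v**4) / m2**2)
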