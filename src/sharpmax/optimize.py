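"""Sharpening strategies and the zero-B map-model correlation metric.

Four ways to choose the overall sharpening of a map are provided:

* ``auto_sharpen_sa`` -- scan candidate overall B values, score each by the
  adjusted surface area and take the interior maximum (the core method);
* ``auto_sharpen_kurtosis`` -- same scan, maximize map kurtosis instead;
* ``halfmap_sharpen`` -- per-shell scaling by R * CC*, with CC* estimated
  from the half-map Fourier shell correlation and R the ratio of zero-B
  model amplitudes to map amplitudes;
* ``model_sharpen`` -- per-shell R * CC* with CC* estimated from the
  map-model FSC corrected by an exponential model-error factor.

Quality of any sharpened map is measured by ``map_model_cc_zero_b``: the
real-space correlation, near atoms, to a map computed from the model with
all atomic B values set to zero and truncated at the same resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateMapError, NotApplicableError, SharpmaxError
from .map_io import (AtomicModel, FourierCoefficients, ShellTable, VolumeGrid,
                     atom_distance_mask, coeffs_to_map, map_to_coeffs,
                     resolution_shells)
from .scaling import (SharpenParams, apply_sharpening, fit_isotropic_b,
                      kurtosis, remove_anisotropy, scale_profile)
from .segmentation import (MoleculeMask, adjusted_surface_area,
                           applicability_check, calibrate_c_scale,
                           contour_stats, find_molecule_mask,
                           threshold_for_volume)

__all__ = [
    "OptimizationTrace",
    "ModelErrorParams",
    "default_b_targets",
    "scan_sharpening",
    "auto_sharpen_sa",
    "auto_sharpen_kurtosis",
    "auto_sharpen_model",
    "cc_star_from_halfmap_fsc",
    "fourier_shell_correlation",
    "halfmap_sharpen",
    "model_sharpen",
    "map_model_cc_zero_b",
    "model_map_coeffs",
]


def default_b_targets() -> np.ndarray:
    """Candidate overall B grid: -100 to +300 A^2 in 20 A^2 steps."""
    return np.arange(-100.0, 300.0 + 1e-9, 20.0)


@dataclass
class OptimizationTrace:
    """Per-candidate record of a sharpening scan plus its diagnostics."""

    b_candidate: np.ndarray
    b_fitted: np.ndarray
    surface_area: np.ndarray
    n_regions: np.ndarray
    kurtosis: np.ndarray
    sa_adjusted: np.ndarray | None = None
    cc: np.ndarray | None = None
    c_scale: float = float("nan")
    signal: float = float("nan")
    noise: float = float("nan")
    applicable: bool = False
    chosen_b: float = float("nan")
    b_initial: float = float("nan")
    threshold: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "b_candidate": self.b_candidate,
            "b_fitted": self.b_fitted,
            "surface_area": self.surface_area,
            "n_regions": self.n_regions,
            "sa_adjusted": (self.sa_adjusted if self.sa_adjusted is not None
                            else np.full_like(self.b_candidate, np.nan)),
            "kurtosis": self.kurtosis,
        }
        if self.cc is not None:
            cols["cc"] = self.cc
        if self.threshold is not None:
            cols["threshold"] = self.threshold
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ModelErrorParams:
    """Assumed model coordinate error and the equivalent error B factor.

    The exponential error model damps the true correlation as
    exp(-B_eff/(4 d^2)) with B_eff = 8 pi^2 rmse^2 / 3, the standard
    equivalence between an isotropic B and a total positional r.m.s.
    displacement.  Default rmse: a quarter of the map resolution.
    """

    rmse: float
    b_eff: float = field(init=False)

    def __post_init__(self):
        if self.rmse < 0:
            raise SharpmaxError("rmse must be >= 0")
        self.b_eff = 8.0 * np.pi**2 * self.rmse**2 / 3.0

    @classmethod
    def from_resolution(cls, resolution: float) -> "ModelErrorParams":
        return cls(rmse=resolution / 4.0)


# ---------------------------------------------------------------------------
# scan machinery
# ---------------------------------------------------------------------------

def _argmax_prefer_last(values: np.ndarray) -> int:
    """Index of the maximum; ties broken toward the end (higher B, less
    sharpening, less fragmentation risk)."""
    v = np.asarray(values)
    return int(len(v) - 1 - np.argmax(v[::-1]))


def scan_sharpening(grid: VolumeGrid, resolution: float,
                    b_targets=None, params_base: SharpenParams | None = None,
                    mask: MoleculeMask | None = None, fraction: float = 0.2,
                    n_shells: int = 20, b_probe: float = 50.0,
                    min_snr: float = 3.0) -> OptimizationTrace:
    """Score sharpened versions of a map over a grid of target overall B.

    The map is assumed already corrected for anisotropy.  For each target
    overall B the sharpening B is ``b_initial - target``; the sharpened map
    is re-thresholded to enclose ``fraction`` of the molecular volume and
    its contour statistics and kurtosis recorded.  C_scale is then
    calibrated from the scan extremes, SA_adjusted filled in, the
    applicability test evaluated, and ``chosen_b`` set to the argmax of
    SA_adjusted (ties toward higher B).
    """
    b_targets = np.asarray(default_b_targets() if b_targets is None else b_targets,
                           dtype=float)
    if b_targets.size < 3:
        raise SharpmaxError("need at least 3 candidate B values")
    b_targets = np.sort(b_targets)
    coeffs = map_to_coeffs(grid, d_min=resolution)
    shells = resolution_shells(coeffs, min(n_shells, coeffs.n_terms // 10))
    b0 = fit_isotropic_b(coeffs, shells)
    if mask is None:
        mask = find_molecule_mask(coeffs_to_map(coeffs), resolution)
    base = params_base or SharpenParams(b_sharpen=0.0, d_cut=resolution)
    d = coeffs.d_grid()

    n = b_targets.size
    sa = np.zeros(n)
    nr = np.zeros(n, dtype=int)
    kur = np.zeros(n)
    b_fit = np.zeros(n)
    thr = np.zeros(n)
    for i, target in enumerate(b_targets):
        params = base.replace(b_sharpen=b0 - target, d_cut=base.d_cut or resolution)
        prof = scale_profile(d, params)
        sharp = coeffs.copy()
        sharp.data *= prof.a_total
        m = coeffs_to_map(sharp)
        thr[i] = threshold_for_volume(m, mask, fraction)
        stats = contour_stats(m, thr[i], mask)
        sa[i] = stats.surface_area
        nr[i] = stats.n_regions
        kur[i] = kurtosis(m)
        b_fit[i] = fit_isotropic_b(sharp, shells)

    trace = OptimizationTrace(b_targets, b_fit, sa, nr, kur,
                              threshold=thr, b_initial=b0)
    try:
        trace.c_scale = calibrate_c_scale(sa, nr)
    except NotApplicableError:
        trace.sa_adjusted = sa.astype(float)
        trace.applicable = False
        return trace
    trace.sa_adjusted = sa - trace.c_scale * nr
    trace.applicable, trace.signal, trace.noise = applicability_check(
        b_targets, trace.sa_adjusted, b_probe=b_probe, min_snr=min_snr)
    idx = _argmax_prefer_last(trace.sa_adjusted)
    if idx in (0, n - 1):
        trace.applicable = False
    if trace.applicable:
        trace.chosen_b = float(b_targets[idx])
    return trace


def _sharpen_at(grid: VolumeGrid, resolution: float, b_target: float,
                b0: float, params_base: SharpenParams | None = None) -> VolumeGrid:
    coeffs = map_to_coeffs(grid, d_min=resolution)
    base = params_base or SharpenParams(b_sharpen=0.0, d_cut=resolution)
    params = base.replace(b_sharpen=b0 - b_target)
    return coeffs_to_map(apply_sharpening(coeffs, params), grid.origin_shift)


def _prepare(grid: VolumeGrid, resolution: float, correct_aniso: bool):
    """Optionally remove anisotropy; returns the working map."""
    coeffs = map_to_coeffs(grid, d_min=resolution)
    if correct_aniso:
        coeffs, _ = remove_anisotropy(coeffs)
    return coeffs_to_map(coeffs, grid.origin_shift)


def auto_sharpen_sa(grid: VolumeGrid, resolution: float, b_targets=None,
                    fraction: float = 0.2, correct_aniso: bool = True,
                    mask: MoleculeMask | None = None,
                    params_base: SharpenParams | None = None,
                    **scan_kw):
    """Sharpen a map by maximizing the adjusted surface area.

    Returns ``(sharpened_map, trace)``.  When the applicability test fails
    the input map is returned unchanged and ``trace.applicable`` is False
    (the method declines rather than guessing).
    """
    work = _prepare(grid, resolution, correct_aniso)
    trace = scan_sharpening(work, resolution, b_targets=b_targets, mask=mask,
                            fraction=fraction, params_base=params_base, **scan_kw)
    if not trace.applicable:
        return grid, trace
    out = _sharpen_at(work, resolution, trace.chosen_b, trace.b_initial,
                      params_base)
    return out, trace


def auto_sharpen_kurtosis(grid: VolumeGrid, resolution: float, b_targets=None,
                          correct_aniso: bool = True,
                          mask: MoleculeMask | None = None,
                          params_base: SharpenParams | None = None,
                          **scan_kw):
    """Sharpen by maximizing map kurtosis over the same candidate scan."""
    work = _prepare(grid, resolution, correct_aniso)
    trace = scan_sharpening(work, resolution, b_targets=b_targets, mask=mask,
                            params_base=params_base, **scan_kw)
    idx = _argmax_prefer_last(trace.kurtosis)
    if idx in (0, len(trace.b_candidate) - 1):
        warnings.warn("kurtosis is monotone over the scan; boundary optimum")
    trace.chosen_b = float(trace.b_candidate[idx])
    trace.applicable = True
    out = _sharpen_at(work, resolution, trace.chosen_b, trace.b_initial,
                      params_base)
    return out, trace


# ---------------------------------------------------------------------------
# shell correlations
# ---------------------------------------------------------------------------

def fourier_shell_correlation(c1: FourierCoefficients, c2: FourierCoefficients,
                              shells: ShellTable) -> np.ndarray:
    """FSC of two coefficient sets in the given resolution shells."""
    if c1.grid_shape != c2.grid_shape:
        raise SharpmaxError("coefficient grids differ")
    d = c1.d_grid()
    idx = shells.shell_index(d)
    fsc = np.zeros(len(shells))
    for i in range(len(shells)):
        sel = idx == i
        a, b = c1.data[sel], c2.data[sel]
        denom = np.sqrt((np.abs(a)**2).sum() * (np.abs(b)**2).sum())
        fsc[i] = float(np.real(np.vdot(a, b)) / denom) if denom > 0 else 0.0
    return fsc


def cc_star_from_halfmap_fsc(cc):
    """True-map correlation estimate CC* = sqrt(2 CC / (1 + CC)).

    Derived from the half-map FSC assuming independent half-set noise.
    Negative FSC carries no usable signal and maps to 0; output is clipped
    to [0, 1].
    """
    cc = np.asarray(cc, dtype=float)
    if np.any(cc <= -1):
        raise SharpmaxError("FSC must be > -1")
    pos = np.clip(cc, 0.0, 1.0)
    out = np.sqrt(2.0 * pos / (1.0 + pos))
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def model_map_coeffs(model: AtomicModel, cell, grid_shape, d_min: float,
                     b_values=0.0) -> FourierCoefficients:
    """Analytic structure factors of a Gaussian-atom model on an FFT grid.

    Atoms are single Gaussians with electron-count weights; ``b_values``
    (scalar or per-atom) replaces the model B values, so 0 gives point
    scatterers whose map is the resolution-limited point response after
    truncation at ``d_min``.  This is an approximation to tabulated
    electron scattering factors, adequate for ranking sharpening levels.
    """
    cell = np.asarray(cell, dtype=float)
    shape = tuple(int(s) for s in grid_shape)
    ref = FourierCoefficients(np.zeros(shape, dtype=complex), cell, d_min)
    d = ref.d_grid()
    keep = d >= d_min
    hkl = np.argwhere(keep)
    # integer frequencies (wrapped)
    freqs = [np.fft.fftfreq(shape[i], d=1.0) * shape[i] for i in range(3)]
    h = np.stack([freqs[i][hkl[:, i]] for i in range(3)], axis=1)
    s2 = ((h / cell) ** 2).sum(axis=1)
    frac = model.xyz / cell
    b = np.broadcast_to(np.asarray(b_values, dtype=float), (len(model),))
    w = model.scattering_weights()
    vals = np.zeros(len(hkl), dtype=complex)
    chunk = max(1, int(2e6 // max(len(hkl), 1)))
    for a0 in range(0, len(model), chunk):
        a1 = min(a0 + chunk, len(model))
        phase = np.exp(-2j * np.pi * (h @ frac[a0:a1].T))
        damp = w[a0:a1] * np.exp(-b[a0:a1] * s2[:, None] / 4.0)
        vals += (phase * damp).sum(axis=1)
    data = np.zeros(shape, dtype=complex)
    data[tuple(hkl.T)] = vals
    return FourierCoefficients(data, cell, d_min)


def _shell_scale_apply(coeffs: FourierCoefficients, shells: ShellTable,
                       scale: np.ndarray) -> FourierCoefficients:
    """Multiply every term by its shell's scale factor (origin term kept)."""
    d = coeffs.d_grid()
    idx = shells.shell_index(d)
    factors = np.ones(coeffs.grid_shape)
    for i in range(len(shells)):
        factors[idx == i] = scale[i]
    out = coeffs.copy()
    out.data *= factors
    return out


def _amplitude_ratio(model_coeffs: FourierCoefficients,
                     map_coeffs: FourierCoefficients,
                     shells: ShellTable) -> np.ndarray:
    """Per-shell R: mean zero-B model amplitude / mean map amplitude."""
    d = map_coeffs.d_grid()
    idx = shells.shell_index(d)
    r = np.zeros(len(shells))
    for i in range(len(shells)):
        sel = idx == i
        map_mean = np.abs(map_coeffs.data[sel]).mean()
        mod_mean = np.abs(model_coeffs.data[sel]).mean()
        if map_mean == 0:
            warnings.warn(f"shell {i} has zero map amplitude; scale set to 0")
            r[i] = 0.0
        else:
            r[i] = mod_mean / map_mean
    return r


def halfmap_sharpen(full: FourierCoefficients, half1: VolumeGrid,
                    half2: VolumeGrid, model: AtomicModel, resolution: float,
                    n_shells: int = 20) -> FourierCoefficients:
    """Per-shell scaling of the full map by R * CC*.

    CC* comes from the half-map FSC; R normalizes each shell to the
    amplitude of a zero-B model map, so shells where the map is weaker than
    the ideal model map are boosted and noisy shells are damped.  A model is
    required for the normalization.
    """
    if half1.grid_shape != half2.grid_shape:
        raise SharpmaxError("half-maps must share a grid")
    full = full.truncate(resolution)
    shells = resolution_shells(full, n_shells)
    c1 = map_to_coeffs(half1, d_min=resolution)
    c2 = map_to_coeffs(half2, d_min=resolution)
    fsc = fourier_shell_correlation(c1, c2, shells)
    cc_star = cc_star_from_halfmap_fsc(fsc)
    mod = model_map_coeffs(model, full.cell, full.grid_shape, resolution, 0.0)
    r = _amplitude_ratio(mod, full, shells)
    out = _shell_scale_apply(full, shells, r * cc_star)
    out_shells = shells.replace(fsc=fsc, cc_star=cc_star, ratio=r)
    out._shells = out_shells  # diagnostic attachment
    return out


def model_sharpen(full: FourierCoefficients, model: AtomicModel,
                  resolution: float, err: ModelErrorParams | None = None,
                  n_shells: int = 20) -> FourierCoefficients:
    """Per-shell scaling by R * CC* with CC* from the map-model FSC.

    The observed map-model correlation is corrected for assumed coordinate
    error by the exponential factor exp(-B_eff/(4 d^2)) (sigma_A-style), so
    CC* = CC * exp(+B_eff/(4 d^2)) clipped to [0, 1].
    """
    if len(model) == 0:
        raise SharpmaxError("empty model")
    err = err or ModelErrorParams.from_resolution(resolution)
    full = full.truncate(resolution)
    shells = resolution_shells(full, n_shells)
    mod = model_map_coeffs(model, full.cell, full.grid_shape, resolution, 0.0)
    cc = fourier_shell_correlation(full, mod, shells)
    correction = np.exp(np.clip(err.b_eff / (4.0 * shells.d_mid**2), 0, 60))
    cc_star = np.clip(np.clip(cc, 0.0, None) * correction, 0.0, 1.0)
    r = _amplitude_ratio(mod, full, shells)
    out = _shell_scale_apply(full, shells, r * cc_star)
    out._shells = shells.replace(fsc=cc, cc_star=cc_star, ratio=r)
    return out


# ---------------------------------------------------------------------------
# zero-B map-model correlation
# ---------------------------------------------------------------------------

def map_model_cc_zero_b(grid: VolumeGrid, model: AtomicModel,
                        resolution: float, mask_radius: float = 3.0,
                        _model_map: np.ndarray | None = None,
                        _mask: np.ndarray | None = None) -> float:
    """Correlation of a map to the zero-B model map, near atoms.

    Both maps are truncated to ``resolution``; the Pearson correlation is
    taken over grid points within ``mask_radius`` A of any atom.  The
    private arguments let scan loops reuse the model map and mask.
    """
    if _model_map is None:
        mod = model_map_coeffs(model, grid.cell, grid.grid_shape, resolution, 0.0)
        _model_map = coeffs_to_map(mod).values
    if _mask is None:
        _mask = atom_distance_mask(grid, model, mask_radius)
    if not _mask.any():
        raise SharpmaxError("no grid points near model atoms")
    m = coeffs_to_map(map_to_coeffs(grid, d_min=resolution)).values
    a = m[_mask] - m[_mask].mean()
    b = _model_map[_mask] - _model_map[_mask].mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise DegenerateMapError("constant density inside the correlation mask")
    return float((a * b).sum() / denom)


def cc_scan(grid: VolumeGrid, model: AtomicModel, resolution: float,
            b_targets=None, mask_radius: float = 3.0,
            params_base: SharpenParams | None = None):
    """Zero-B map-model CC for each candidate overall B.

    Returns ``(b_targets, cc_values, b_initial)``; the model map and atom
    mask are computed once and reused across candidates.
    """
    b_targets = np.asarray(default_b_targets() if b_targets is None else b_targets,
                           dtype=float)
    b_targets = np.sort(b_targets)
    coeffs = map_to_coeffs(grid, d_min=resolution)
    shells = resolution_shells(coeffs, min(20, coeffs.n_terms // 10))
    b0 = fit_isotropic_b(coeffs, shells)
    mod = model_map_coeffs(model, grid.cell, grid.grid_shape, resolution, 0.0)
    model_map = coeffs_to_map(mod).values
    mask = atom_distance_mask(grid, model, mask_radius)
    base = params_base or SharpenParams(b_sharpen=0.0, d_cut=resolution)
    d = coeffs.d_grid()
    cc = np.zeros(b_targets.size)
    for i, target in enumerate(b_targets):
        prof = scale_profile(d, base.replace(b_sharpen=b0 - target))
        sharp = coeffs.copy()
        sharp.data *= prof.a_total
        m = coeffs_to_map(sharp)
        cc[i] = map_model_cc_zero_b(m, model, resolution,
                                    _model_map=model_map, _mask=mask)
    return b_targets, cc, b0


def auto_sharpen_model(grid: VolumeGrid, model: AtomicModel, resolution: float,
                       b_targets=None, correct_aniso: bool = True,
                       mask_radius: float = 3.0,
                       params_base: SharpenParams | None = None):
    """Sharpen by maximizing the zero-B map-model correlation over the scan."""
    work = _prepare(grid, resolution, correct_aniso)
    b, cc, b0 = cc_scan(work, model, resolution, b_targets=b_targets,
                        mask_radius=mask_radius, params_base=params_base)
    idx = _argmax_prefer_last(cc)
    chosen = float(b[idx])
    out = _sharpen_at(work, resolution, chosen, b0, params_base)
    trace = OptimizationTrace(
        b_candidate=b, b_fitted=np.full_like(b, np.nan),
        surface_area=np.full_like(b, np.nan), n_regions=np.zeros(b.size, int),
        kurtosis=np.full_like(b, np.nan), cc=cc, chosen_b=chosen,
        applicable=True, b_initial=b0)
    return out, trace
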