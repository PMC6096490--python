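"""Molecule masking, iso-contour statistics and the adjusted surface area.

The sharpening objective scores a candidate map by contouring it at a
threshold enclosing a fixed fraction (default 20%) of the molecular volume
and computing

    SA_adjusted = SA - C_scale * N_regions

where SA is the number of grid points just outside the iso-contour surface
(face-adjacent to an inside point) and N_regions the number of contiguous
above-threshold regions (6-connectivity).  C_scale is calibrated per map so
that the most- and least-sharpened candidates score equally; the interior
maximum of SA_adjusted then identifies the optimal overall B.

Conventions (the field does not prescribe them; each is isolated so it can
be toggled): regions use face connectivity, points exactly at the threshold
count as inside, and points beyond the map edge count as below threshold
(cryo-EM maps are boxed with solvent margins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateMapError, NotApplicableError, SharpmaxError
from .map_io import VolumeGrid, write_map

__all__ = [
    "MoleculeMask",
    "ContourStats",
    "find_molecule_mask",
    "threshold_for_volume",
    "contour_stats",
    "adjusted_surface_area",
    "calibrate_c_scale",
    "applicability_check",
]

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass
class MoleculeMask:
    """Boolean grid marking the region occupied by the macromolecule."""

    mask: np.ndarray
    volume_fraction: float
    smoothing_radius: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 0 < self.volume_fraction < 1:
            raise SharpmaxError("volume_fraction must be in (0, 1)")

    def write(self, path, cell) -> None:
        write_map(VolumeGrid(self.mask.astype(float), cell), path)


@dataclass
class ContourStats:
    """Surface area and connectivity of one iso-contour level."""

    threshold: float
    n_regions: int
    surface_area: int
    enclosed_fraction: float | None = None

    def __post_init__(self):
        # an empty contour has no surface; a contour filling the whole grid
        # has regions but no outside points, hence zero surface
        if self.n_regions == 0 and self.surface_area != 0:
            raise SharpmaxError("surface_area must vanish with n_regions")


# ---------------------------------------------------------------------------
# molecule mask
# ---------------------------------------------------------------------------

def smoothed_squared_density(grid: VolumeGrid, radius: float) -> np.ndarray:
    """Gaussian-smoothed squared deviation from the map mean.

    The kernel sigma is ``radius / sqrt(3)`` so its radius of gyration
    matches ``radius`` (in A); the kernel is truncated at 3 sigma.
    """
    v = grid.values - grid.values.mean()
    sigma_vox = (radius / np.sqrt(3.0)) / grid.spacing
    return ndimage.gaussian_filter(v * v, sigma=sigma_vox, truncate=3.0,
                                   mode="wrap")


def _null_split_gap(fraction: float) -> float:
    """Between-class mean gap (in units of the global standard deviation)
    produced by splitting a featureless Gaussian field at the top-``fraction``
    quantile: phi(z_f)/f + phi(z_f)/(1-f)."""
    from scipy import stats
    z = stats.norm.ppf(1.0 - fraction)
    phi = stats.norm.pdf(z)
    return float(phi / fraction + phi / (1.0 - fraction))


def _split_gap_ratio(flat: np.ndarray, fraction: float) -> float:
    """Observed between-class gap of a top-``fraction`` quantile split,
    relative to the gap a featureless Gaussian field would produce."""
    scale = flat.std()
    if scale == 0:
        return 1.0
    t = np.quantile(flat, 1.0 - fraction)
    inside = flat >= t
    if inside.all() or not inside.any():
        return 1.0
    gap = flat[inside].mean() - flat[~inside].mean()
    return float(gap / (_null_split_gap(fraction) * scale))


def has_molecular_contrast(sm: np.ndarray,
                           probes=(0.05, 0.1, 0.2, 0.3, 0.5),
                           factor: float = 1.3) -> bool:
    """Whether the local variance field carries real molecule/solvent
    contrast.

    Any quantile split of a featureless field produces a between-class gap
    by selection alone, with a known analytic size; a field with a genuine
    molecular region exceeds it when probed below the true volume fraction.
    The detector takes the maximum gap ratio over a handful of probe
    fractions (featureless fields stay near 1.0, structured ones reach
    1.5 or more) and compares with ``factor``.
    """
    flat = sm.ravel()
    return max(_split_gap_ratio(flat, f) for f in probes) > factor


def _fraction_update(sm: np.ndarray, fraction: float) -> float:
    """One update of the molecular volume fraction (isodata step).

    The local r.m.s. density (square root of the smoothed squared density,
    which de-skews the molecule class) is split at the top-``fraction``
    quantile and the new fraction is the volume above the midpoint of the
    two class means: an underestimated molecular region grows, an
    overestimated one shrinks.  Callers gate this on
    :func:`has_molecular_contrast`; without contrast the guess is a fixed
    point by construction.
    """
    flat = np.sqrt(np.maximum(sm.ravel(), 0.0))
    if flat.std() == 0:
        return fraction
    t = np.quantile(flat, 1.0 - fraction)
    inside = flat >= t
    if inside.all() or not inside.any():
        return fraction
    new_f = float(np.mean(flat > 0.5 * (flat[inside].mean()
                                        + flat[~inside].mean())))
    return float(np.clip(new_f, 0.01, 0.99))


def find_molecule_mask(grid: VolumeGrid, resolution: float,
                       initial_fraction_guesses=(0.05, 0.1, 0.2, 0.3, 0.5),
                       smoothing_radius: float | None = None,
                       max_cycles: int = 40, tol: float = 0.005,
                       stability_tol: float = 0.1) -> MoleculeMask:
    """Locate the region of high local density variance.

    The local smoothed squared density is computed with a Gaussian of radius
    1.5x the map resolution (a compromise between detail and robustness);
    each starting guess of the molecular volume fraction is refined by the
    probabilistic update above for at most ``max_cycles`` cycles or until it
    moves by less than ``tol`` (the update is weakly contracting, so a few
    dozen cycles are allowed by default).  If the guesses do not converge to a common
    fraction (spread > ``stability_tol``) a warning is issued and the median
    fraction used.
    """
    if grid.values.std() == 0:
        raise DegenerateMapError("cannot mask a constant map")
    radius = smoothing_radius if smoothing_radius is not None else 1.5 * resolution
    sm = smoothed_squared_density(grid, radius)
    contrast = has_molecular_contrast(sm)
    converged = []
    for guess in initial_fraction_guesses:
        f = float(guess)
        if contrast:
            for _ in range(max_cycles):
                f_new = _fraction_update(sm, f)
                if abs(f_new - f) < tol:
                    f = f_new
                    break
                f = f_new
        converged.append(f)
    converged = np.asarray(converged)
    if converged.max() - converged.min() > stability_tol:
        warnings.warn("molecule-volume fraction did not stabilize across "
                      "starting guesses; using the median")
    fraction = float(np.median(converged))
    t = np.quantile(sm, 1.0 - fraction)
    mask = sm >= t
    return MoleculeMask(mask, float(mask.mean()), radius)


# ---------------------------------------------------------------------------
# thresholding and contour statistics
# ---------------------------------------------------------------------------

def threshold_for_volume(grid: VolumeGrid, mask: MoleculeMask,
                         fraction: float = 0.2) -> float:
    """Smallest threshold putting at most ``fraction`` of the masked volume
    inside the contour (points at the threshold count as inside)."""
    if not 0 < fraction < 1:
        raise SharpmaxError("fraction must be in (0, 1)")
    vals = grid.values[mask.mask]
    if vals.size == 0:
        raise DegenerateMapError("empty molecule mask")
    if vals.max() == vals.min():
        raise DegenerateMapError("constant density inside the mask")
    target = max(1, int(round(fraction * vals.size)))
    uniq, counts = np.unique(vals, return_counts=True)
    # count of values >= uniq[i]
    above = np.cumsum(counts[::-1])[::-1]
    ok = above <= target
    if not ok.any():
        return float(uniq[-1])
    return float(uniq[np.argmax(ok)])


def contour_stats(grid: VolumeGrid, threshold: float,
                  mask: MoleculeMask | None = None,
                  connectivity: int = 6) -> ContourStats:
    """Region count and surface area of the iso-contour at ``threshold``.

    Surface area is the number of outside grid points face-adjacent to at
    least one inside point; regions are contiguous inside components.
    ``connectivity`` may be 6 (faces, default) or 26 (faces+edges+corners)
    for the region labeling.
    """
    inside = grid.values >= threshold
    if not inside.any():
        return ContourStats(threshold, 0, 0,
                            0.0 if mask is not None else None)
    if connectivity == 6:
        structure = _FACE_STRUCTURE
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise SharpmaxError("connectivity must be 6 or 26")
    _, n_regions = ndimage.label(inside, structure=structure)
    dilated = ndimage.binary_dilation(inside, structure=_FACE_STRUCTURE)
    surface_area = int((dilated & ~inside).sum())
    enclosed = None
    if mask is not None:
        enclosed = float((inside & mask.mask).sum() / max(mask.mask.sum(), 1))
    return ContourStats(threshold, int(n_regions), surface_area, enclosed)


def adjusted_surface_area(stats: ContourStats, c_scale: float) -> float:
    """SA_adjusted = surface_area - c_scale * n_regions."""
    return float(stats.surface_area - c_scale * stats.n_regions)


# ---------------------------------------------------------------------------
# C_scale calibration and applicability
# ---------------------------------------------------------------------------

def calibrate_c_scale(surface_area, n_regions) -> float:
    """Region-count weight that equalizes the end points of a sharpening scan.

    Inputs are per-candidate surface areas and region counts sorted by
    candidate overall B ascending; the first row is the most sharpened map,
    the last the least.  Solving SA_first - c N_first = SA_last - c N_last
    gives c = (SA_first - SA_last) / (N_first - N_last).
    """
    sa = np.asarray(surface_area, dtype=float)
    nr = np.asarray(n_regions, dtype=float)
    if sa.size < 3:
        raise SharpmaxError("need at least 3 scan points to calibrate")
    if nr[0] == nr[-1]:
        raise NotApplicableError(
            "region counts identical at scan extremes; C_scale undefined")
    return float((sa[0] - sa[-1]) / (nr[0] - nr[-1]))


def applicability_check(b_values, sa_adjusted, b_probe: float = 50.0,
                        min_snr: float = 3.0):
    """Decide whether the adjusted-surface-area criterion is usable.

    The trace is rejected outright if SA_adjusted at the scanned point
    nearest ``b_probe`` falls below the (calibrated, equal) end-point value.
    Otherwise signal = max(SA_adjusted) - end-point value, and noise is the
    r.m.s. deviation of each interior point from the linear interpolation of
    its two neighbours; the criterion applies iff signal/noise >= min_snr.

    Returns ``(applicable, signal, noise)``.
    """
    b = np.asarray(b_values, dtype=float)
    sa = np.asarray(sa_adjusted, dtype=float)
    if b.size < 4:
        raise SharpmaxError("need at least 4 scan points for the applicability test")
    endpoint = 0.5 * (sa[0] + sa[-1])
    signal = float(sa.max() - endpoint)
    resid = sa[1:-1] - 0.5 * (sa[:-2] + sa[2:])
    noise = float(np.sqrt(np.mean(resid**2)))
    probe = int(np.argmin(np.abs(b - b_probe)))
    if sa[probe] < endpoint:
        return False, signal, noise
    if noise == 0:
        return signal > 0, signal, noise
    return bool(signal / noise >= min_snr), signal, noise
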