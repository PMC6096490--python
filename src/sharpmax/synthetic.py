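"""Synthetic maps, models and half-maps with known ground truth.

Every algorithm in the package is exercised on fixtures generated here: a
pseudo-peptide chain of Gaussian atoms in an orthogonal cell, rendered to a
grid through analytic structure factors, optionally blurred by a known
overall B, degraded with resolution-dependent phase noise, split into noisy
half-maps, or paired with a coordinate-jittered copy of the model.

Atoms are single Gaussians with electron-count weights -- not multi-Gaussian
scattering factors.  That is sufficient for testing sharpening logic, whose
inputs are amplitude falloffs and connectivity, but the absolute density
scale does not emulate any particular microscope.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SharpmaxError
from .map_io import (AtomicModel, FourierCoefficients, VolumeGrid,
                     coeffs_to_map)
from .optimize import model_map_coeffs

__all__ = [
    "SyntheticSpec",
    "make_model",
    "model_to_map",
    "make_map",
    "degrade_map",
    "make_half_maps",
    "jitter_model",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a reproducible synthetic fixture.

    The default -- a 500-atom bonded chain packed into the central 20 A
    cube of a 44 A cell at 1 A spacing, 3 A resolution cutoff -- matches
    the atom density of real protein interiors (~0.06 atoms/A^3) so that
    iso-contours connect the way they do in deposited maps, while keeping
    every full-pipeline test fast.  ``noise_sigma`` is in map units; the
    zero-B noise-free default map has a standard deviation of roughly
    0.15 map units, so ``noise_sigma = 0.008`` emulates a mid-quality
    reconstruction (zero-B map-model correlation around 0.8).
    """

    n_atoms: int = 500
    cell: tuple[float, float, float] = (44.0, 44.0, 44.0)
    grid_shape: tuple[int, int, int] = (44, 44, 44)
    true_b: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    layout: str = "chain"  # chain | blob | two-domain
    d_min: float = 3.0
    margin: float = 12.0
    domain_b: tuple[float, float] = (60.0, 160.0)


def _chain_positions(rng, n_atoms, cell, margin, start=None):
    """Pseudo-polymer: a persistent random walk with ~1.5 A bonded steps.

    Successive atoms are 1.5 A apart (bonded); the direction persistence
    makes atoms two to three steps apart sit near the 3.8 A Calpha-Calpha
    distance of real chains.  Non-bonded atoms keep >= 1.0 A clearance, so
    the rendered density forms continuous tubes at typical map resolutions.
    """
    cell = np.asarray(cell, dtype=float)
    lo = np.full(3, margin)
    hi = cell - margin
    if np.any(hi <= lo):
        raise SharpmaxError("cell too small for the solvent margin")
    x = start if start is not None else lo + (hi - lo) * rng.random(3)
    x = np.clip(x, lo, hi)
    direction = _unit(rng.standard_normal(3))
    atoms = [x]
    for _ in range(n_atoms - 1):
        for _attempt in range(200):
            step = _unit(direction + 0.55 * rng.standard_normal(3))
            cand = atoms[-1] + 1.5 * step
            if np.any(cand < lo) or np.any(cand > hi):
                direction = _unit(0.5 * (lo + hi) - atoms[-1])
                continue
            prev = np.asarray(atoms)
            if len(prev) < 2 or np.min(
                    np.linalg.norm(prev[:-1] - cand, axis=1)) >= 1.0:
                direction = _unit(cand - atoms[-1])
                atoms.append(cand)
                break
        else:
            atoms.append(np.clip(atoms[-1] + 1.5 * _unit(
                rng.standard_normal(3)), lo, hi))
    return np.asarray(atoms)


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def make_model(spec: SyntheticSpec) -> AtomicModel:
    """Generate the fixture model for a spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    cell = np.asarray(spec.cell, dtype=float)
    if spec.layout == "chain":
        xyz = _chain_positions(rng, spec.n_atoms, cell, spec.margin)
    elif spec.layout == "blob":
        # uniform-density globule at protein interior packing (~0.06 / A^3)
        center = cell / 2.0
        r_pack = (3.0 * spec.n_atoms / (4.0 * np.pi * 0.06)) ** (1.0 / 3.0)
        radius = min(r_pack, float(min(cell) / 2.0 - spec.margin))
        u = rng.standard_normal((spec.n_atoms, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        xyz = center + u * radius * rng.random(spec.n_atoms)[:, None] ** (1 / 3)
    elif spec.layout == "two-domain":
        half = spec.n_atoms // 2
        c1 = cell * np.array([0.3, 0.5, 0.5])
        c2 = cell * np.array([0.7, 0.5, 0.5])
        xyz1 = _chain_positions(rng, half, cell, spec.margin, start=c1)
        xyz2 = _chain_positions(rng, spec.n_atoms - half, cell, spec.margin,
                                start=c2)
        xyz = np.vstack([xyz1, xyz2])
    else:
        raise SharpmaxError(f"unknown layout {spec.layout!r}")
    if np.any(xyz < 0) or np.any(xyz > cell):
        raise SharpmaxError("atoms fall outside the cell")
    elements = np.array(["C", "N", "C", "O"] * (len(xyz) // 4 + 1),
                        dtype=object)[:len(xyz)]
    return AtomicModel(elements, xyz, np.zeros(len(xyz)), np.ones(len(xyz)))


def model_to_map(model: AtomicModel, cell, grid_shape, d_min: float,
                 b_values=None) -> VolumeGrid:
    """Render a model to a grid through analytic Gaussian-atom structure
    factors truncated at ``d_min``.  ``b_values`` overrides the model B
    values (scalar or per-atom); with B = 0 each atom is the
    resolution-limited point response."""
    b = model.b_values if b_values is None else b_values
    coeffs = model_map_coeffs(model, cell, grid_shape, d_min, b)
    return coeffs_to_map(coeffs)


def make_map(spec: SyntheticSpec, model: AtomicModel | None = None):
    """Build the full fixture.

    Returns a dict with the model, the zero-B noise-free reference map
    (``truth``), the observed map (overall B = ``true_b`` applied in
    reciprocal space, plus white Gaussian noise of ``noise_sigma``) and its
    coefficients.  For the ``two-domain`` layout each half of the model is
    blurred by its own ``domain_b`` value instead of ``true_b``.
    """
    model = make_model(spec) if model is None else model
    cell = np.asarray(spec.cell, dtype=float)
    if spec.layout == "two-domain":
        half = len(model) // 2
        b = np.empty(len(model))
        b[:half] = spec.domain_b[0]
        b[half:] = spec.domain_b[1]
        coeffs = model_map_coeffs(model, cell, spec.grid_shape, spec.d_min, b)
    else:
        coeffs = model_map_coeffs(model, cell, spec.grid_shape, spec.d_min,
                                  spec.true_b)
    observed = coeffs_to_map(coeffs)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng((spec.seed, 1))
        observed = VolumeGrid(
            observed.values + rng.normal(scale=spec.noise_sigma,
                                         size=observed.grid_shape),
            cell)
    truth = model_to_map(model, cell, spec.grid_shape, spec.d_min, 0.0)
    return {"model": model, "truth": truth, "map": observed, "coeffs": coeffs}


def _negate_layout(a: np.ndarray) -> np.ndarray:
    return np.roll(a[::-1, ::-1, ::-1], shift=(1, 1, 1), axis=(0, 1, 2))


def degrade_map(coeffs: FourierCoefficients, rms_phase_error_fn,
                seed: int) -> FourierCoefficients:
    """Randomize phases with resolution-dependent zero-mean noise.

    ``rms_phase_error_fn(d)`` gives the target r.m.s. phase error in
    radians at resolution ``d``.  The perturbation field is antisymmetric
    under Friedel inversion, so Hermitian symmetry -- and hence the realness
    of the map -- is preserved; amplitudes are exactly unchanged.
    """
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(coeffs.grid_shape)
    eps = (eps - _negate_layout(eps)) / np.sqrt(2.0)  # antisymmetric, unit rms
    d = coeffs.d_grid()
    sigma = np.where(np.isfinite(d), rms_phase_error_fn(np.where(
        np.isfinite(d), d, 1.0)), 0.0)
    out = coeffs.copy()
    out.data *= np.exp(1j * eps * sigma)
    return out


def make_half_maps(true_map: VolumeGrid, noise_sigma: float, seed: int):
    """Two independent noisy copies of a map; their mean approximates the
    full reconstruction."""
    rngs = [np.random.default_rng((seed, i)) for i in (1, 2)]
    return tuple(
        VolumeGrid(true_map.values + r.normal(scale=noise_sigma,
                                              size=true_map.grid_shape),
                   true_map.cell.copy(), true_map.origin_shift)
        for r in rngs)


def jitter_model(model: AtomicModel, rmse: float, seed: int) -> AtomicModel:
    """Displace atoms isotropically with total r.m.s. displacement ``rmse``
    (normal with per-axis sigma rmse/sqrt(3)); B values untouched."""
    if rmse < 0:
        raise SharpmaxError("rmse must be >= 0")
    out = model.copy()
    if rmse > 0:
        rng = np.random.default_rng(seed)
        out.xyz = out.xyz + rng.normal(scale=rmse / np.sqrt(3.0),
                                       size=out.xyz.shape)
    return out
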