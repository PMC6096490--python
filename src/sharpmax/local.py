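"""Local sharpening: overlapping boxes, sharpened independently, blended.

The occupied region of the map is tiled with overlapping cubic boxes
(default 40 grid units on a side, 50% overlap).  Each box is sharpened with
one of the global strategies at the global resolution cutoff, and the
sharpened boxes are recombined with exponential distance weights

    w_i(x) = exp(-|x - c_i| / d_o)

where c_i is the center of box i and d_o defaults to the average
nearest-neighbour distance between box centers.  The weighted average is
exact for constant fields, so recombination introduces no seams by itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SharpmaxError
from .map_io import AtomicModel, VolumeGrid, map_to_coeffs, coeffs_to_map
from .optimize import (auto_sharpen_kurtosis, auto_sharpen_model,
                       auto_sharpen_sa, halfmap_sharpen)
from .segmentation import MoleculeMask, find_molecule_mask

__all__ = ["LocalBox", "LocalCombineParams", "plan_boxes", "combine_boxes",
           "local_sharpen"]


@dataclass
class LocalBox:
    """Axis-aligned sub-box of a grid (clipped at map edges)."""

    origin: tuple[int, int, int]
    size: tuple[int, int, int]
    center: np.ndarray  # Cartesian A

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.size))


@dataclass
class LocalCombineParams:
    """Characteristic distance (A) of the exponential blending weight."""

    d_o: float

    def __post_init__(self):
        if self.d_o <= 0:
            raise SharpmaxError("d_o must be > 0")


def _box_center(origin, size, spacing) -> np.ndarray:
    return (np.asarray(origin) + 0.5 * np.asarray(size)) * spacing


def plan_boxes(grid: VolumeGrid, mask: MoleculeMask, size: int = 40,
               stride: int | None = None) -> list[LocalBox]:
    """Tile the masked region with overlapping boxes.

    Boxes of edge ``size`` grid units are laid out from the mask bounding
    box with stride ``size // 2`` (50% overlap) and clipped at the map
    edges; boxes containing no masked points are dropped.  A mask that fits
    inside a single box yields one box centered on it.
    """
    if size < 8:
        raise SharpmaxError("box size must be >= 8 grid units")
    m = mask.mask
    if not m.any():
        raise SharpmaxError("empty molecule mask")
    stride = stride or max(1, size // 2)
    shape = np.asarray(grid.grid_shape)
    spacing = grid.spacing
    lo, hi = [], []
    for ax in range(3):
        proj = m.any(axis=tuple(i for i in range(3) if i != ax))
        nz = np.nonzero(proj)[0]
        lo.append(int(nz[0]))
        hi.append(int(nz[-1]) + 1)
    lo, hi = np.asarray(lo), np.asarray(hi)
    if np.all(hi - lo <= size):
        # single box centered on the blob
        center = (lo + hi) / 2.0
        origin = np.clip((center - size / 2.0).round().astype(int), 0,
                         np.maximum(shape - size, 0))
        bsize = np.minimum(size, shape - origin)
        return [LocalBox(tuple(origin), tuple(bsize),
                         _box_center(origin, bsize, spacing))]
    # edge boxes are clipped, but never below half the nominal size: a
    # sliver box has too little density to sharpen on its own, so its
    # origin is shifted inward instead
    min_size = max(8, size // 2)
    starts = [
        sorted({min(s, max(0, shape[ax] - min_size))
                for s in range(lo[ax], hi[ax], stride)})
        for ax in range(3)
    ]
    boxes = []
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                origin = np.array([i, j, k])
                bsize = np.minimum(size, shape - origin)
                box = LocalBox(tuple(origin), tuple(bsize),
                               _box_center(origin, bsize, spacing))
                if m[box.slices()].any():
                    boxes.append(box)
    covered = np.zeros(grid.grid_shape, dtype=bool)
    for box in boxes:
        covered[box.slices()] = True
    coverage = (covered & m).sum() / m.sum()
    if coverage < 0.95:
        raise SharpmaxError(f"box tiling covers only {coverage:.0%} of the mask")
    return boxes


def default_d_o(boxes: list[LocalBox]) -> float:
    """Average nearest-neighbour distance between box centers (A)."""
    if len(boxes) == 1:
        return float(np.linalg.norm(np.asarray(boxes[0].size)) / 2.0)
    centers = np.stack([b.center for b in boxes])
    dist = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    return float(dist.min(axis=1).mean())


def combine_boxes(sharpened: list[tuple[LocalBox, VolumeGrid]],
                  params: LocalCombineParams, out_shape, cell,
                  fill: VolumeGrid | None = None) -> VolumeGrid:
    """Blend sharpened boxes with exponential distance weights.

    Points covered by no box raise an error unless ``fill`` is given, in
    which case they pass through the fill map unchanged (used for solvent
    corners outside every density box).
    """
    out_shape = tuple(int(s) for s in out_shape)
    cell = np.asarray(cell, dtype=float)
    spacing = cell / np.asarray(out_shape)
    num = np.zeros(out_shape)
    den = np.zeros(out_shape)
    for box, sub in sharpened:
        sl = box.slices()
        ax = [(np.arange(box.origin[i], box.origin[i] + box.size[i])
               * spacing[i] - box.center[i]) ** 2 for i in range(3)]
        d = np.sqrt(ax[0][:, None, None] + ax[1][None, :, None]
                    + ax[2][None, None, :])
        w = np.exp(-d / params.d_o)
        num[sl] += w * sub.values
        den[sl] += w
    uncovered = den == 0
    if uncovered.any():
        if fill is None:
            raise SharpmaxError("some output grid points are covered by no box")
        num[uncovered] = fill.values[uncovered]
        den[uncovered] = 1.0
    return VolumeGrid(num / den, cell)


def local_sharpen(grid: VolumeGrid, resolution: float, method: str = "sa",
                  model: AtomicModel | None = None,
                  half_maps: tuple[VolumeGrid, VolumeGrid] | None = None,
                  box_size: int = 40, d_o: float | None = None,
                  mask: MoleculeMask | None = None,
                  b_targets=None, fraction: float = 0.2):
    """Sharpen overlapping local boxes and recombine.

    ``method`` is one of ``sa``, ``kurtosis``, ``half_map`` or ``model``;
    the same resolution cutoff is used in every box.  Boxes where the
    adjusted-surface-area test declines (or any strategy fails) fall back
    to the unsharpened box contents with a warning.

    Returns ``(map, per_box)`` where ``per_box`` is a list of
    ``(LocalBox, chosen_b_or_None)``.
    """
    if method not in ("sa", "kurtosis", "half_map", "model"):
        raise SharpmaxError(f"unknown method {method!r}")
    if method == "model" and model is None:
        raise SharpmaxError("model-based local sharpening needs a model")
    if method == "half_map" and (half_maps is None or model is None):
        raise SharpmaxError("half-map local sharpening needs half-maps and a model")
    if mask is None:
        mask = find_molecule_mask(grid, resolution)
    boxes = plan_boxes(grid, mask, size=box_size)
    spacing = grid.spacing
    shape = np.asarray(grid.grid_shape)
    margin = max(4, box_size // 4)
    results, per_box = [], []
    for box in boxes:
        sl = box.slices()
        # analyze the box with a margin of surrounding context (clipped at
        # the map edge) so the cut through density does not distort the
        # spectrum; only the central nominal region is blended
        lo = np.maximum(np.asarray(box.origin) - margin, 0)
        hi = np.minimum(np.asarray(box.origin) + np.asarray(box.size)
                        + margin, shape)
        ctx_sl = tuple(slice(lo[i], hi[i]) for i in range(3))
        inner = tuple(slice(box.origin[i] - lo[i],
                            box.origin[i] - lo[i] + box.size[i])
                      for i in range(3))
        sub = VolumeGrid(grid.values[ctx_sl], spacing * (hi - lo))
        chosen = None
        try:
            if method == "sa":
                out, trace = auto_sharpen_sa(sub, resolution,
                                             b_targets=b_targets,
                                             fraction=fraction,
                                             correct_aniso=False)
                if not trace.applicable:
                    warnings.warn("box declined by applicability test; "
                                  "left unsharpened")
                    out = sub
                else:
                    chosen = trace.chosen_b
            elif method == "kurtosis":
                out, trace = auto_sharpen_kurtosis(sub, resolution,
                                                   b_targets=b_targets,
                                                   correct_aniso=False)
                chosen = trace.chosen_b
            elif method == "model":
                sub_model = _atoms_in_ctx(model, lo, hi, spacing)
                out, trace = auto_sharpen_model(sub, sub_model, resolution,
                                                b_targets=b_targets,
                                                correct_aniso=False)
                chosen = trace.chosen_b
            else:  # half_map
                sub_model = _atoms_in_ctx(model, lo, hi, spacing)
                h1 = VolumeGrid(half_maps[0].values[ctx_sl], sub.cell)
                h2 = VolumeGrid(half_maps[1].values[ctx_sl], sub.cell)
                coeffs = halfmap_sharpen(map_to_coeffs(sub, d_min=resolution),
                                         h1, h2, sub_model, resolution)
                out = coeffs_to_map(coeffs)
        except SharpmaxError as exc:
            warnings.warn(f"box at {box.origin} not sharpened: {exc}")
            out = sub
        inner_grid = VolumeGrid(out.values[inner],
                                spacing * np.asarray(box.size))
        results.append((box, inner_grid))
        per_box.append((box, chosen))
    params = LocalCombineParams(d_o if d_o is not None else default_d_o(boxes))
    combined = combine_boxes(results, params, grid.grid_shape, grid.cell,
                             fill=grid)
    combined.origin_shift = grid.origin_shift
    return combined, per_box


def _atoms_in_ctx(model: AtomicModel, lo, hi, spacing,
                  pad: float = 3.0) -> AtomicModel:
    """Atoms inside a context box (grid-index bounds), re-expressed in its
    frame; ``pad`` (A) admits atoms just outside whose density leaks in."""
    lo_cart = np.asarray(lo) * spacing - pad
    hi_cart = np.asarray(hi) * spacing + pad
    sel = np.all((model.xyz >= lo_cart) & (model.xyz <= hi_cart), axis=1)
    if not sel.any():
        raise SharpmaxError("no atoms inside the box")
    return AtomicModel(model.elements[sel],
                       model.xyz[sel] - np.asarray(lo) * spacing,
                       model.b_values[sel], model.occupancy[sel])
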