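"""High-level modelling interface: build an :class:`AutoSharpener` from a map
(and optional model / half-maps), call :meth:`~AutoSharpener.fit`, inspect the
returned :class:`SharpenResult`.

This mirrors the fit/results split of statistical modelling packages: the
sharpener holds the data and configuration, the result holds the chosen
parameters, the optimization trace, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SharpmaxError
from .local import local_sharpen
from .map_io import (AtomicModel, VolumeGrid, coeffs_to_map, map_to_coeffs,
                     read_map, read_model, write_map)
from .optimize import (OptimizationTrace, auto_sharpen_kurtosis,
                       auto_sharpen_model, auto_sharpen_sa, halfmap_sharpen,
                       map_model_cc_zero_b)
from .scaling import fit_isotropic_b

__all__ = ["AutoSharpener", "SharpenResult"]


@dataclass
class SharpenResult:
    """Outcome of one sharpening run."""

    map: VolumeGrid
    method: str
    resolution: float
    applicable: bool
    trace: OptimizationTrace | None = None
    chosen_b: float = float("nan")
    b_initial: float = float("nan")
    per_box: list | None = None
    model_cc: float | None = None

    @property
    def declined(self) -> bool:
        return not self.applicable

    def fitted_b(self) -> float:
        """Overall B of the output map (Wilson-style fit)."""
        from .map_io import resolution_shells
        c = map_to_coeffs(self.map, d_min=self.resolution)
        return fit_isotropic_b(c, resolution_shells(c, 20))

    def summary(self) -> str:
        rows = [
            ("method", self.method),
            ("resolution (A)", f"{self.resolution:.2f}"),
            ("status", "sharpened" if self.applicable else "declined"),
            ("initial overall B (A^2)", _fmt(self.b_initial)),
            ("chosen overall B (A^2)", _fmt(self.chosen_b)),
        ]
        if self.trace is not None:
            rows += [
                ("C_scale", _fmt(self.trace.c_scale)),
                ("signal", _fmt(self.trace.signal)),
                ("noise", _fmt(self.trace.noise)),
            ]
        if self.model_cc is not None:
            rows.append(("map-model CC (zero-B)", f"{self.model_cc:.4f}"))
        if self.per_box is not None:
            chosen = [b for _, b in self.per_box if b is not None]
            rows.append(("boxes sharpened",
                         f"{len(chosen)}/{len(self.per_box)}"))
        width = max(len(k) for k, _ in rows)
        lines = ["Auto-sharpening summary", "=" * 32]
        lines += [f"{k.ljust(width)} : {v}" for k, v in rows]
        return "\n".join(lines)

    def save_map(self, path) -> None:
        write_map(self.map, path)

    def save_trace(self, path) -> None:
        if self.trace is None:
            raise SharpmaxError("this method records no scan trace")
        self.trace.to_csv(path)

    def plot_trace(self, ax=None):
        """Plot SA_adjusted (or CC) against candidate overall B."""
        if self.trace is None:
            raise SharpmaxError("this method records no scan trace")
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        t = self.trace
        if t.sa_adjusted is not None and np.isfinite(t.sa_adjusted).any():
            ax.plot(t.b_candidate, t.sa_adjusted, "o-", label="SA_adjusted")
        if t.cc is not None:
            ax2 = ax.twinx()
            ax2.plot(t.b_candidate, t.cc, "s--", color="tab:red", label="CC")
            ax2.set_ylabel("map-model CC (zero B)")
        if np.isfinite(self.chosen_b):
            ax.axvline(self.chosen_b, color="k", ls=":")
        ax.set_xlabel("overall B (A$^2$)")
        ax.set_ylabel("adjusted surface area")
        return ax


def _fmt(x) -> str:
    return "-" if x is None or (isinstance(x, float) and not np.isfinite(x)) \
        else f"{x:.2f}"


class AutoSharpener:
    """Automatic sharpening of a density map.

    Parameters
    ----------
    map : VolumeGrid
        The map to sharpen.
    resolution : float
        Nominal resolution in A; also the Fourier truncation limit and the
        sharpen-to-blur transition resolution.
    method : str
        ``sa`` (adjusted surface area, default), ``kurtosis``, ``half_map``
        or ``model``.
    model : AtomicModel, optional
        Required for ``model`` and ``half_map`` methods.
    half_maps : (VolumeGrid, VolumeGrid), optional
        Required for ``half_map``.
    local : bool
        Sharpen overlapping local boxes instead of the whole map.
    b_targets : array, optional
        Candidate overall B grid (default -100..300 in steps of 20 A^2).
    fraction : float
        Fraction of the molecular volume enclosed by the scoring contour.
    """

    def __init__(self, map: VolumeGrid, resolution: float, method: str = "sa",
                 model: AtomicModel | None = None,
                 half_maps: tuple[VolumeGrid, VolumeGrid] | None = None,
                 local: bool = False, b_targets=None, fraction: float = 0.2,
                 box_size: int = 40, correct_aniso: bool = True):
        if method not in ("sa", "kurtosis", "half_map", "model"):
            raise SharpmaxError(f"unknown method {method!r}")
        if method in ("model", "half_map") and model is None:
            raise SharpmaxError(f"method {method!r} requires an atomic model")
        if method == "half_map" and half_maps is None:
            raise SharpmaxError("half_map method requires two half-maps")
        self.map = map
        self.resolution = float(resolution)
        self.method = method
        self.model = model
        self.half_maps = half_maps
        self.local = local
        self.b_targets = b_targets
        self.fraction = fraction
        self.box_size = box_size
        self.correct_aniso = correct_aniso

    @classmethod
    def from_files(cls, map_path, resolution, model_path=None,
                   half1_path=None, half2_path=None, **kw) -> "AutoSharpener":
        model = read_model(model_path) if model_path else None
        half_maps = None
        if half1_path and half2_path:
            half_maps = (read_map(half1_path), read_map(half2_path))
        return cls(read_map(map_path), resolution, model=model,
                   half_maps=half_maps, **kw)

    def fit(self) -> SharpenResult:
        if self.local:
            out, per_box = local_sharpen(
                self.map, self.resolution, method=self.method,
                model=self.model, half_maps=self.half_maps,
                box_size=self.box_size, b_targets=self.b_targets,
                fraction=self.fraction)
            res = SharpenResult(out, self.method + " (local)",
                                self.resolution, applicable=True,
                                per_box=per_box)
        elif self.method == "sa":
            out, trace = auto_sharpen_sa(self.map, self.resolution,
                                         b_targets=self.b_targets,
                                         fraction=self.fraction,
                                         correct_aniso=self.correct_aniso)
            res = SharpenResult(out, "sa", self.resolution, trace.applicable,
                                trace, trace.chosen_b, trace.b_initial)
        elif self.method == "kurtosis":
            out, trace = auto_sharpen_kurtosis(self.map, self.resolution,
                                               b_targets=self.b_targets,
                                               correct_aniso=self.correct_aniso)
            res = SharpenResult(out, "kurtosis", self.resolution, True,
                                trace, trace.chosen_b, trace.b_initial)
        elif self.method == "model":
            out, trace = auto_sharpen_model(self.map, self.model,
                                            self.resolution,
                                            b_targets=self.b_targets,
                                            correct_aniso=self.correct_aniso)
            res = SharpenResult(out, "model", self.resolution, True,
                                trace, trace.chosen_b, trace.b_initial)
        else:  # half_map
            coeffs = halfmap_sharpen(
                map_to_coeffs(self.map, d_min=self.resolution),
                self.half_maps[0], self.half_maps[1], self.model,
                self.resolution)
            out = coeffs_to_map(coeffs, self.map.origin_shift)
            res = SharpenResult(out, "half_map", self.resolution, True)
        if self.model is not None:
            res.model_cc = map_model_cc_zero_b(res.map, self.model,
                                               self.resolution)
        return res
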