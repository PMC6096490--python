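"""Maps, Fourier coefficients, resolution shells and atomic models.

Real-space density lives in :class:`VolumeGrid`; its frequency-domain twin is
:class:`FourierCoefficients`, which stores the full complex FFT of the grid
together with the unit cell so that every term has a well-defined resolution
``d = 1/|s|`` with ``s = (h/a, k/b, l/c)``.  v1 supports orthogonal cells and
P1 symmetry, which covers single-particle cryo-EM maps.

File formats go through :mod:`gemmi`: CCP4/MRC for maps (written as mode-2,
32-bit float), PDB/mmCIF for models.  All coordinates are Cartesian angstroms
and grid indexing is 0-based with a fixed X,Y,Z axis order fixed at read time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .errors import DegenerateMapError, MapFormatError, ResolutionError

__all__ = [
    "VolumeGrid",
    "FourierCoefficients",
    "ShellTable",
    "AtomicModel",
    "read_map",
    "write_map",
    "read_model",
    "write_model",
    "map_to_coeffs",
    "coeffs_to_map",
    "resolution_shells",
    "extract_region_near_model",
]

# electron counts used as single-Gaussian scattering weights
_ELEMENT_WEIGHTS = {
    "H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "P": 15.0, "S": 16.0,
    "MG": 12.0, "CA": 20.0, "FE": 26.0, "ZN": 30.0,
}
_DEFAULT_WEIGHT = 6.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VolumeGrid:
    """Real density values on a 3D grid in an orthogonal unit cell.

    Parameters
    ----------
    values : (nx, ny, nz) float array
        Density in arbitrary map units.
    cell : (3,) float array
        Cell edge lengths a, b, c in angstrom (angles fixed at 90 degrees).
    origin_shift : (3,) int tuple
        Grid-index offset of the first point relative to the cell origin.
    """

    values: np.ndarray
    cell: np.ndarray
    origin_shift: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        self.cell = np.asarray(self.cell, dtype=np.float64)
        self.origin_shift = tuple(int(i) for i in self.origin_shift)
        if self.values.ndim != 3 or min(self.values.shape) < 4:
            raise MapFormatError(
                f"grid must be 3D with every edge >= 4 points, got {self.values.shape}")
        if self.cell.shape != (3,) or np.any(self.cell <= 0):
            raise MapFormatError(f"cell edges must be positive, got {self.cell}")
        if not np.all(np.isfinite(self.values)):
            raise MapFormatError("map contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spacing(self) -> np.ndarray:
        """Grid spacing along each axis in angstrom."""
        return self.cell / np.asarray(self.values.shape, dtype=float)

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.values.copy(), self.cell.copy(), self.origin_shift)

    def standardized(self) -> np.ndarray:
        v = self.values - self.values.mean()
        s = v.std()
        if s == 0:
            raise DegenerateMapError("map is constant")
        return v / s


@dataclass
class FourierCoefficients:
    """Complex Fourier terms of a map, in numpy ``fftn`` index layout.

    ``data[h, k, l]`` holds the term with integer frequency indices
    ``(h, k, l)`` (negative indices wrap, as in :func:`numpy.fft.fftn`).
    Hermitian symmetry is an invariant: the inverse transform is real.
    ``d_min`` records the high-resolution truncation applied; truncated
    terms are zeroed and stay zeroed (idempotent).
    """

    data: np.ndarray
    cell: np.ndarray
    d_min: float | None = None

    def __post_init__(self):
        self.data = np.ascontiguousarray(self.data, dtype=np.complex128)
        self.cell = np.asarray(self.cell, dtype=np.float64)
        if self.data.ndim != 3:
            raise MapFormatError("coefficient block must be 3D")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "FourierCoefficients":
        return FourierCoefficients(self.data.copy(), self.cell.copy(), self.d_min)

    def s2_grid(self) -> np.ndarray:
        """|s|^2 for every term, s = (h/a, k/b, l/c)."""
        n = self.data.shape
        comps = [np.fft.fftfreq(n[i], d=1.0) * n[i] / self.cell[i] for i in range(3)]
        hx, ky, lz = np.meshgrid(*comps, indexing="ij", sparse=True)
        return hx**2 + ky**2 + lz**2

    def d_grid(self) -> np.ndarray:
        """Resolution d = 1/|s| per term; the (0,0,0) term gets +inf."""
        s2 = self.s2_grid()
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(s2)

    def retained_mask(self) -> np.ndarray:
        """Boolean grid of terms kept after truncation (origin included)."""
        if self.d_min is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.d_grid() >= self.d_min

    @property
    def n_terms(self) -> int:
        return int(self.retained_mask().sum())

    def is_hermitian(self, rtol: float = 1e-8) -> bool:
        conj_flip = np.conj(_negate_indices(self.data))
        scale = np.abs(self.data).max()
        if scale == 0:
            return True
        return bool(np.allclose(self.data, conj_flip, atol=rtol * scale, rtol=0))

    def truncate(self, d_min: float) -> "FourierCoefficients":
        """Zero all terms with d < d_min.  Idempotent; d_min only tightens."""
        if d_min <= 0:
            raise ResolutionError("d_min must be positive")
        out = self.copy()
        out.data[out.d_grid() < d_min] = 0.0
        out.d_min = d_min if self.d_min is None else max(self.d_min, d_min)
        return out


def _negate_indices(a: np.ndarray) -> np.ndarray:
    """a[-h, -k, -l] with wrap-around, i.e. the Friedel mate layout."""
    return np.roll(a[::-1, ::-1, ::-1], shift=(1, 1, 1), axis=(0, 1, 2))


@dataclass
class ShellTable:
    """Per-resolution-shell statistics of a coefficient set.

    Shells are equal-count in Fourier terms (approximately equal volume in
    1/d^3); ``d_edges`` are the shell boundaries in d, descending, with
    ``d_edges[0] = inf``.  A term with d exactly on a boundary belongs to the
    lower-resolution (larger-d) shell.
    """

    d_mid: np.ndarray
    n_terms: np.ndarray
    mean_amplitude: np.ndarray
    d_edges: np.ndarray
    fsc: np.ndarray | None = None
    cc_star: np.ndarray | None = None
    ratio: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.d_mid)

    def shell_index(self, d: np.ndarray) -> np.ndarray:
        """Map resolutions to shell numbers; -1 for d outside all shells."""
        # d_edges descending: shell i covers (d_edges[i+1], d_edges[i]]
        idx = np.searchsorted(-self.d_edges, -np.asarray(d), side="left") - 1
        idx = np.where((idx < 0) | (idx >= len(self)), -1, idx)
        return idx

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "d_mid": self.d_mid,
            "n_terms": self.n_terms,
            "mean_amplitude": self.mean_amplitude,
        }
        for name in ("fsc", "cc_star", "ratio"):
            val = getattr(self, name)
            if val is not None:
                cols[name] = val
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def replace(self, **kw) -> "ShellTable":
        return dataclasses.replace(self, **kw)


@dataclass
class AtomicModel:
    """Point-atom model: element symbols, Cartesian positions (A), isotropic
    B values (A^2) and occupancies."""

    elements: np.ndarray
    xyz: np.ndarray
    b_values: np.ndarray
    occupancy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.b_values = np.asarray(self.b_values, dtype=np.float64)
        if self.occupancy is None:
            self.occupancy = np.ones(len(self.xyz))
        self.occupancy = np.asarray(self.occupancy, dtype=np.float64)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise MapFormatError("xyz must be (n, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise MapFormatError("model has non-finite coordinates")
        if np.any(self.b_values < 0):
            raise MapFormatError("negative B value")
        if np.any((self.occupancy < 0) | (self.occupancy > 1)):
            raise MapFormatError("occupancy outside [0, 1]")

    def __len__(self) -> int:
        return len(self.xyz)

    def copy(self) -> "AtomicModel":
        return AtomicModel(self.elements.copy(), self.xyz.copy(),
                           self.b_values.copy(), self.occupancy.copy())

    def shifted(self, offset) -> "AtomicModel":
        out = self.copy()
        out.xyz = out.xyz + np.asarray(offset, dtype=float)
        return out

    def scattering_weights(self) -> np.ndarray:
        return np.array([
            _ELEMENT_WEIGHTS.get(str(e).upper(), _DEFAULT_WEIGHT) for e in self.elements
        ]) * self.occupancy


# ---------------------------------------------------------------------------
# file i/o
# ---------------------------------------------------------------------------

def read_map(path) -> VolumeGrid:
    """Read a CCP4/MRC map (modes 0/1/2), normalizing axis order to X,Y,Z."""
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError, ValueError) as exc:
        raise MapFormatError(f"cannot read map {path}: {exc}") from exc
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    cell = ccp4.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise MapFormatError("v1 supports orthogonal cells only")
    values = np.array(ccp4.grid, dtype=np.float64)
    if np.isnan(values).any():
        raise MapFormatError("map has unset grid points")
    origin = tuple(ccp4.header_i32(i) for i in (5, 6, 7))
    return VolumeGrid(values, np.array([cell.a, cell.b, cell.c]), origin)


def write_map(grid: VolumeGrid, path) -> None:
    """Write a map as CCP4/MRC mode 2 (32-bit float)."""
    g = gemmi.FloatGrid(*grid.grid_shape)
    g.set_unit_cell(gemmi.UnitCell(*grid.cell, 90, 90, 90))
    g.spacegroup = gemmi.find_spacegroup_by_name("P1")
    np.asarray(g)[...] = grid.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    for word, val in zip((5, 6, 7), grid.origin_shift):
        ccp4.set_header_i32(word, int(val))
    ccp4.write_ccp4_map(str(path))


def read_model(path) -> AtomicModel:
    """Read a PDB or mmCIF model into a flat atom table."""
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, OSError, ValueError) as exc:
        raise MapFormatError(f"cannot read model {path}: {exc}") from exc
    elements, xyz, bvals, occ = [], [], [], []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    elements.append(atom.element.name)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    bvals.append(max(atom.b_iso, 0.0))
                    occ.append(min(max(atom.occ, 0.0), 1.0))
        break  # first model only
    if not xyz:
        raise MapFormatError(f"no atoms found in {path}")
    return AtomicModel(np.array(elements, dtype=object), np.array(xyz),
                       np.array(bvals), np.array(occ))


def write_model(model: AtomicModel, path, cell=None) -> None:
    """Write a model as PDB (one chain of pseudo-residues)."""
    st = gemmi.Structure()
    st.name = "sharpmax"
    if cell is not None:
        st.cell = gemmi.UnitCell(*np.asarray(cell, dtype=float), 90, 90, 90)
    st.spacegroup_hm = "P 1"
    md = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i in range(len(model)):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        elem = str(model.elements[i])
        atom.name = elem
        atom.element = gemmi.Element(elem)
        atom.pos = gemmi.Position(*model.xyz[i])
        atom.b_iso = float(model.b_values[i])
        atom.occ = float(model.occupancy[i])
        res.add_atom(atom)
        chain.add_residue(res)
    md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def nyquist_limit(grid: VolumeGrid) -> float:
    """Smallest usable d_min: twice the coarsest grid spacing."""
    return 2.0 * float(grid.spacing.max())


def map_to_coeffs(grid: VolumeGrid, d_min: float | None = None) -> FourierCoefficients:
    """Forward FFT of a map, optionally truncated at resolution ``d_min``."""
    if d_min is not None and d_min < nyquist_limit(grid) - 1e-9:
        raise ResolutionError(
            f"d_min = {d_min} below Nyquist limit {nyquist_limit(grid):.3f} A")
    coeffs = FourierCoefficients(np.fft.fftn(grid.values), grid.cell.copy())
    if d_min is not None:
        coeffs = coeffs.truncate(d_min)
    return coeffs


def coeffs_to_map(coeffs: FourierCoefficients,
                  origin_shift=(0, 0, 0)) -> VolumeGrid:
    """Inverse FFT to a real grid; requires Hermitian symmetry."""
    if not coeffs.is_hermitian():
        raise MapFormatError("coefficients are not Hermitian; map would be complex")
    values = np.fft.ifftn(coeffs.data).real
    return VolumeGrid(values, coeffs.cell.copy(), origin_shift)


def resolution_shells(coeffs: FourierCoefficients, n_shells: int = 20) -> ShellTable:
    """Bin retained non-origin terms into ``n_shells`` equal-count shells.

    The shell midpoint is the amplitude-fit-consistent ``1/sqrt(<1/d^2>)``.
    """
    if n_shells < 2:
        raise ResolutionError("need at least 2 shells")
    d = coeffs.d_grid()
    sel = coeffs.retained_mask() & np.isfinite(d)
    d_sel = d[sel]
    amp_sel = np.abs(coeffs.data[sel])
    if d_sel.size < n_shells:
        raise ResolutionError(
            f"only {d_sel.size} terms for {n_shells} shells")
    order = np.argsort(-d_sel, kind="stable")  # descending d
    d_sorted = d_sel[order]
    amp_sorted = amp_sel[order]
    # equal-count boundaries, moved forward so ties stay in the earlier
    # (lower-resolution) shell
    bounds = [0]
    for i in range(1, n_shells):
        j = (i * d_sel.size) // n_shells
        while j < d_sel.size and j > bounds[-1] and d_sorted[j] == d_sorted[j - 1]:
            j += 1
        if j <= bounds[-1] or j >= d_sel.size:
            continue
        bounds.append(j)
    bounds.append(d_sel.size)
    d_mid, n_terms, f_mean, edges = [], [], [], [np.inf]
    for a, b in zip(bounds[:-1], bounds[1:]):
        dseg = d_sorted[a:b]
        d_mid.append(1.0 / np.sqrt(np.mean(1.0 / dseg**2)))
        n_terms.append(b - a)
        f_mean.append(float(np.mean(amp_sorted[a:b])))
        edges.append(float(dseg[-1]))
    edges[-1] = edges[-1] * (1 - 1e-12)  # include the last term
    return ShellTable(np.array(d_mid), np.array(n_terms, dtype=int),
                      np.array(f_mean), np.array(edges))


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------

def atom_distance_mask(grid: VolumeGrid, model: AtomicModel, radius: float) -> np.ndarray:
    """Boolean grid marking points within ``radius`` (A) of any atom."""
    shape = np.asarray(grid.grid_shape)
    spacing = grid.spacing
    mask = np.zeros(grid.grid_shape, dtype=bool)
    half = np.ceil(radius / spacing).astype(int)
    for pos in model.xyz:
        idx = pos / spacing
        lo = np.maximum(np.floor(idx - half).astype(int), 0)
        hi = np.minimum(np.ceil(idx + half).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ax = [(np.arange(lo[i], hi[i]) * spacing[i] - pos[i]) ** 2 for i in range(3)]
        d2 = ax[0][:, None, None] + ax[1][None, :, None] + ax[2][None, None, :]
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub |= d2 <= radius * radius
    return mask


def extract_region_near_model(grid: VolumeGrid, model: AtomicModel,
                              radius: float = 5.0):
    """Cut out the density within ``radius`` of any atom.

    Returns ``(region, shifted_model)``: a minimal enclosing box with the same
    grid spacing (origin_shift updated to the box corner), density outside the
    radius zeroed, and the model translated into the new frame.
    """
    near = atom_distance_mask(grid, model, radius)
    if not near.any():
        raise MapFormatError("model does not overlap the map extent")
    lo, hi = [], []
    for ax in range(3):
        proj = near.any(axis=tuple(i for i in range(3) if i != ax))
        nz = np.nonzero(proj)[0]
        lo.append(int(nz[0]))
        hi.append(int(nz[-1]) + 1)
    # keep every edge >= 4 points
    for ax in range(3):
        while hi[ax] - lo[ax] < 4:
            if lo[ax] > 0:
                lo[ax] -= 1
            elif hi[ax] < grid.grid_shape[ax]:
                hi[ax] += 1
            else:
                break
    sl = tuple(slice(lo[i], hi[i]) for i in range(3))
    values = np.where(near[sl], grid.values[sl], 0.0)
    spacing = grid.spacing
    new_cell = spacing * (np.asarray(hi) - np.asarray(lo))
    origin = tuple(grid.origin_shift[i] + lo[i] for i in range(3))
    region = VolumeGrid(values, new_cell, origin)
    shifted = model.shifted(-np.asarray(lo) * spacing)
    return region, shifted
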