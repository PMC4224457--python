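"""Electron-density maps on periodic orthogonal grids.

The map model is deliberately simple: a real-space scalar field sampled on a
regular grid that tiles an orthogonal P1 cell.  Maps are either read from
CCP4/MRC files (via gemmi) or synthesised from an atomic model by placing one
isotropic Gaussian per atom, with width set by the atomic B value plus a
resolution blur.  Two lookup modes are provided: nearest-grid-node (the fast
search path) and trilinear interpolation (the sensitive re-scoring path).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "DensityGrid",
    "density_from_atoms",
    "interpolate",
    "value_at_grid",
    "ensemble_minmax_maps",
    "read_ccp4",
    "write_ccp4",
    "ELECTRON_COUNTS",
]

#: electrons per neutral atom, for the elements that occur in nucleic-acid
#: backbones (plus a few commonly present in ligands/solvent).
ELECTRON_COUNTS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "ZN": 30,
}

#: Gaussian contributions are cut off beyond this many angstroms.
ATOM_TRUNCATION = 4.5

#: default resolution blur (sigma, A) added in quadrature to the B-factor
#: width.  Follows the common sigma = 0.225 * d map-synthesis convention at
#: d = 2.2 A, the resolution of the reference maps the fingerprint targets
#: are modelled on.
DEFAULT_SIGMA_RES = 0.5


@dataclass
class AtomRecord:
    """A point atom: name, element, position (A), B value (A^2), occupancy."""

    name: str
    element: str
    pos: np.ndarray
    b_iso: float = 20.0
    occupancy: float = 1.0

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,):
            raise ValueError("pos must be a 3-vector")
        if not self.b_iso > 0:
            raise ValueError(f"b_iso must be positive, got {self.b_iso}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")


@dataclass
class DensityGrid:
    """Scalar density on a regular 3D grid tiling an orthogonal cell.

    ``values[i, j, k]`` is the density at Cartesian position
    ``origin + (i, j, k) * spacing``; indexing wraps periodically, i.e. the
    grid tiles the cell.  ``mean`` and ``sigma`` are whole-grid statistics and
    are recomputed on construction.
    """

    values: np.ndarray
    cell: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mean: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        self.cell = np.asarray(self.cell, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.cell.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("cell and origin must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive on all axes")
        self.mean = float(self.values.mean())
        self.sigma = float(self.values.std())

    @property
    def shape(self) -> np.ndarray:
        return np.array(self.values.shape)

    @property
    def spacing(self) -> np.ndarray:
        """Grid step in A per axis."""
        return self.cell / self.shape

    def copy_with(self, values: np.ndarray) -> "DensityGrid":
        return DensityGrid(values=values, cell=self.cell.copy(), origin=self.origin.copy())

    def same_geometry(self, other: "DensityGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.cell, other.cell)
            and np.allclose(self.origin, other.origin)
        )


def _element_of(atom: AtomRecord) -> int:
    z = ELECTRON_COUNTS.get(atom.element.upper().strip())
    if z is None:
        raise ValueError(f"unknown element {atom.element!r}")
    return z


def density_from_atoms(
    atoms: list[AtomRecord],
    cell,
    spacing: float = 0.5,
    origin=(0.0, 0.0, 0.0),
    sigma_res: float = DEFAULT_SIGMA_RES,
) -> DensityGrid:
    """Synthesise a periodic density map from an atomic model.

    Each atom contributes ``occ * Z * (2*pi*s2)**-1.5 * exp(-r^2 / (2*s2))``
    with ``s2 = B/(8*pi^2) + sigma_res**2``, truncated at 4.5 A.  Atoms
    outside the cell wrap around (P1 periodicity).
    """
    if not atoms:
        raise ValueError("at least one atom is required")
    if spacing > 1.0:
        raise ValueError("spacing must be <= 1.0 A")
    cell = np.asarray(cell, dtype=float)
    origin = np.asarray(origin, dtype=float)
    shape = np.maximum(1, np.rint(cell / spacing).astype(int))
    step = cell / shape
    values = np.zeros(tuple(shape))
    # per-axis index reach of the truncation sphere
    reach = np.ceil(ATOM_TRUNCATION / step).astype(int)
    ax_ranges = [np.arange(-reach[d], reach[d] + 1) for d in range(3)]
    for atom in atoms:
        z = _element_of(atom)
        s2 = atom.b_iso / (8.0 * np.pi**2) + sigma_res**2
        amp = atom.occupancy * z * (2.0 * np.pi * s2) ** -1.5
        f = (atom.pos - origin) / step  # fractional grid coords
        i0 = np.rint(f).astype(int)
        # local box around the atom, in unwrapped index space
        dx = [(i0[d] + ax_ranges[d]) * step[d] - (atom.pos[d] - origin[d]) for d in range(3)]
        r2 = (
            dx[0][:, None, None] ** 2
            + dx[1][None, :, None] ** 2
            + dx[2][None, None, :] ** 2
        )
        mask = r2 <= ATOM_TRUNCATION**2
        contrib = np.zeros_like(r2)
        contrib[mask] = amp * np.exp(-r2[mask] / (2.0 * s2))
        ii = (i0[0] + ax_ranges[0]) % shape[0]
        jj = (i0[1] + ax_ranges[1]) % shape[1]
        kk = (i0[2] + ax_ranges[2]) % shape[2]
        I, J, K = np.meshgrid(ii, jj, kk, indexing="ij")
        np.add.at(values, (I.ravel(), J.ravel(), K.ravel()), contrib.ravel())
    return DensityGrid(values=values, cell=cell, origin=origin)


def interpolate(grid: DensityGrid, pos) -> np.ndarray | float:
    """Trilinear interpolation with periodic wrapping; exact at grid nodes.

    ``pos`` may be a single 3-vector or an array of shape (..., 3).
    """
    pos = np.asarray(pos, dtype=float)
    scalar = pos.ndim == 1
    f = (pos - grid.origin) / grid.spacing
    i0 = np.floor(f).astype(int)
    w = f - i0
    shape = grid.shape
    v = grid.values
    out = np.zeros(f.shape[:-1])
    for corner in range(8):
        d = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = (i0 + d) % shape
        wt = np.prod(np.where(d == 1, w, 1.0 - w), axis=-1)
        out = out + wt * v[idx[..., 0], idx[..., 1], idx[..., 2]]
    return float(out) if scalar else out


def value_at_grid(grid: DensityGrid, pos) -> np.ndarray | float:
    """Density at the grid node nearest to ``pos`` (no interpolation)."""
    pos = np.asarray(pos, dtype=float)
    scalar = pos.ndim == 1
    idx = np.rint((pos - grid.origin) / grid.spacing).astype(int) % grid.shape
    out = grid.values[idx[..., 0], idx[..., 1], idx[..., 2]]
    return float(out) if scalar else out


def ensemble_minmax_maps(fragment_maps: list[DensityGrid]) -> tuple[DensityGrid, DensityGrid]:
    """Pointwise minimum and maximum over an ensemble of co-gridded maps.

    A high value in the minimum map marks density conserved across every
    ensemble member; a low value in the maximum map marks a conserved hole.
    """
    if not fragment_maps:
        raise ValueError("need at least one map")
    first = fragment_maps[0]
    for g in fragment_maps[1:]:
        if not first.same_geometry(g):
            raise ValueError("ensemble maps must share grid geometry")
    stack = np.stack([g.values for g in fragment_maps])
    return first.copy_with(stack.min(axis=0)), first.copy_with(stack.max(axis=0))


def read_ccp4(path: str) -> DensityGrid:
    """Read a CCP4/MRC map, expanded to the full (P1) cell."""
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"), gemmi.MapSetup.Full)
    arr = np.array(m.grid, copy=True, dtype=float)
    cell = np.array([m.grid.unit_cell.a, m.grid.unit_cell.b, m.grid.unit_cell.c])
    return DensityGrid(values=arr, cell=cell)


def write_ccp4(grid: DensityGrid, path: str) -> None:
    """Write a mode-2 (float32) CCP4 map covering the full cell."""
    if not np.allclose(grid.origin, 0.0):
        raise ValueError("only full-cell maps with origin (0,0,0) can be written")
    g = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    g.unit_cell = gemmi.UnitCell(*grid.cell, 90.0, 90.0, 90.0)
    g.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
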