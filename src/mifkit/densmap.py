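"""Contact-density maps from fragment scatter clouds.

Crystal-structure surveys of weak hydrogen bonds produce scatter clouds:
positions of contact-group atoms (donor carbons or hydrogens) around a
central ring substructure, expressed in the substructure's molecular
frame. This module bins such clouds onto regular grids, expands them
under the substructure's point symmetry, smooths with a 27-point box
average (each node averaged with its up-to-26 neighbors), and rescales
to percent-of-maximum with iso-level mask extraction.

Grid conventions: voxels are origin-anchored and half-open
[edge, edge + spacing), so a point exactly on a boundary lands in the
higher-index voxel. Boundary smoothing averages over the neighbors that
exist (zero-padding available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import scipy.ndimage

__all__ = [
    "FragmentScatter",
    "VolumetricGrid",
    "DensityGrid",
    "mirror_ops",
    "select_contact_atoms",
    "expand_symmetry",
    "bin_density",
    "smooth27",
    "percent_of_max",
    "iso_mask",
    "subsample_structures",
    "read_scatter_mol2",
    "write_scatter_mol2",
    "write_dx",
    "read_dx",
    "write_cube",
]

#: angstrom per Bohr, for CUBE output
BOHR = 0.529177210903


@dataclass(frozen=True)
class FragmentScatter:
    """Contact-atom positions in the reference molecular frame.

    ``role`` records which probe-side atom the positions refer to
    (densities based on donor carbons differ from those based on donor
    hydrogens); ``sources`` tags each point with its structure id.
    """

    positions: np.ndarray
    role: str = "donor_carbon"
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(p)):
            raise ValueError("scatter positions must be finite")
        object.__setattr__(self, "positions", p)
        if self.sources and len(self.sources) != len(p):
            raise ValueError("sources must match positions")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class VolumetricGrid:
    """A regular scalar grid: origin (node 0 position), cubic spacing,
    and a 3-D value array."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be a 3-D array")
        object.__setattr__(self, "values", v)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def node_positions(self) -> np.ndarray:
        """(n, 3) positions of all nodes in grid order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.origin + self.spacing * idx


@dataclass(frozen=True)
class DensityGrid(VolumetricGrid):
    """A volumetric grid with a recorded normalization state:
    ``counts`` (raw histogram), ``smoothed`` or ``percent`` (max = 100)."""

    state: str = "counts"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.state not in ("counts", "smoothed", "percent"):
            raise ValueError(f"unknown state {self.state!r}")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")


def mirror_ops(axes: Iterable[int] = (1,)) -> list[np.ndarray]:
    """Identity plus single-axis mirror matrices (0=u, 1=v, 2=w).

    ``mirror_ops((1,))`` is the point symmetry of a C2v ring like
    pyridine in its own frame (v -> -v); add axis 2 for the w mirror.
    """
    ops = [np.eye(3)]
    for ax in axes:
        m = np.eye(3)
        m[ax, ax] = -1.0
        ops.append(m)
    return ops


def select_contact_atoms(structure, central_positions: np.ndarray,
                         residue_names: Sequence[str] = ("ALA", "ILE", "LEU", "PRO", "VAL"),
                         element: str = "C", role: str = "donor_carbon",
                         atom_names: Sequence[str] | None = None,
                         range_cutoff: float = 7.0,
                         source_id: str = "") -> FragmentScatter:
    """Pick contact-group atoms near a central substructure.

    ``structure`` is a biotite AtomArray already aligned into the
    reference frame; ``central_positions`` are the substructure atom
    positions in the same frame. Atoms whose residue name, element and
    (optionally) atom name match, and which lie within ``range_cutoff``
    of any central atom, are returned as a scatter.
    """
    central = np.asarray(central_positions, dtype=float).reshape(-1, 3)
    if central.shape[0] == 0:
        raise ValueError("central substructure is empty")
    mask = np.isin(structure.res_name, list(residue_names))
    if element:
        mask &= structure.element == element
    if atom_names is not None:
        mask &= np.isin(structure.atom_name, list(atom_names))
    coords = structure.coord[mask]
    if coords.shape[0] == 0:
        return FragmentScatter(np.empty((0, 3)), role=role)
    d = np.linalg.norm(coords[:, None, :] - central[None, :, :], axis=2)
    keep = d.min(axis=1) <= range_cutoff
    pos = coords[keep]
    return FragmentScatter(pos, role=role,
                           sources=(source_id,) * len(pos) if source_id else ())


def expand_symmetry(scatter: FragmentScatter, ops: Sequence[np.ndarray]) -> FragmentScatter:
    """Replicate scatter positions under frame-space symmetry operations.

    Output size is |ops| * |points|; each op must be orthogonal
    (rotation or mirror) within 1e-10.
    """
    out = []
    for op in ops:
        op = np.asarray(op, dtype=float)
        if np.max(np.abs(op @ op.T - np.eye(3))) > 1e-10:
            raise ValueError("symmetry operation is not orthogonal")
        out.append(scatter.positions @ op.T)
    pos = np.vstack(out) if out else scatter.positions[:0]
    return FragmentScatter(pos, role=scatter.role,
                           sources=scatter.sources * len(ops) if scatter.sources else ())


def bin_density(scatter: FragmentScatter, spacing: float = 0.5,
                extent: float = 8.0, origin: np.ndarray | None = None,
                shape: tuple[int, int, int] | None = None) -> DensityGrid:
    """Histogram scatter positions onto a regular grid (counts state).

    Default geometry is a cube of half-width ``extent`` about the frame
    origin. Voxels are half-open [edge, edge + spacing); points on a
    boundary go to the higher-index voxel; points outside the box are
    dropped with a warning. Total in-box count is conserved.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if origin is None:
        n = 2 * int(np.ceil(extent / spacing))
        origin = np.array([-spacing * n / 2.0] * 3)
        shape = (n, n, n)
    else:
        origin = np.asarray(origin, dtype=float)
        if shape is None:
            raise ValueError("shape required with explicit origin")
    values = np.zeros(shape)
    if len(scatter):
        idx = np.floor((scatter.positions - origin) / spacing + 1e-12).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        if not inside.all():
            warnings.warn(f"{int((~inside).sum())} scatter points outside the grid box",
                          stacklevel=2)
        np.add.at(values, tuple(idx[inside].T), 1.0)
    return DensityGrid(origin=origin, spacing=spacing, values=values, state="counts")


def smooth27(grid: DensityGrid, zero_pad: bool = False) -> DensityGrid:
    """27-point box smoothing: each node becomes the mean of itself and
    its up-to-26 adjacent nodes.

    Boundary nodes average over the neighbors that exist; with
    ``zero_pad`` missing neighbors count as zeros instead (divisor 27
    everywhere).
    """
    kernel = np.ones((3, 3, 3))
    summed = scipy.ndimage.convolve(grid.values, kernel, mode="constant", cval=0.0)
    if zero_pad:
        out = summed / 27.0
    else:
        counts = scipy.ndimage.convolve(np.ones_like(grid.values), kernel,
                                        mode="constant", cval=0.0)
        out = summed / counts
    return DensityGrid(origin=grid.origin, spacing=grid.spacing,
                       values=out, state="smoothed")


def percent_of_max(grid: DensityGrid) -> DensityGrid:
    """Rescale so the maximum node is 100 (all-zero grids stay zero)."""
    mx = grid.values.max() if grid.values.size else 0.0
    vals = grid.values * (100.0 / mx) if mx > 0 else np.zeros_like(grid.values)
    return DensityGrid(origin=grid.origin, spacing=grid.spacing,
                       values=vals, state="percent")


def iso_mask(grid: DensityGrid, thresholds: Sequence[float] = (75.0, 50.0, 25.0)
             ) -> dict[float, np.ndarray]:
    """Boolean node masks at the given iso levels (value >= level).

    Conventional level sets: 75/50/25 percent for survey-style maps,
    80/50 for comparison overlays.
    """
    return {float(t): grid.values >= t for t in thresholds}


def subsample_structures(ids: Sequence[str], n: int, seed: int = 0) -> list[str]:
    """Seeded uniform subsample of structure ids (without replacement)."""
    rng = np.random.default_rng(seed)
    ids = list(ids)
    if n >= len(ids):
        return ids
    pick = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(pick)]


# ---------------------------------------------------------------------------
# MOL2 scatter I/O (TRIPOS ATOM records, coordinates + names only)


def read_scatter_mol2(path: str | Path, role: str = "donor_carbon") -> FragmentScatter:
    """Read scatter positions from a TRIPOS MOL2 file's ATOM records.

    Only atom names and coordinates are consumed. Malformed ATOM records
    raise with the offending line number; an empty file yields an empty
    scatter with a warning.
    """
    positions: list[list[float]] = []
    in_atoms = False
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = ln.strip()
        if stripped.startswith("@<TRIPOS>"):
            in_atoms = stripped == "@<TRIPOS>ATOM"
            continue
        if not in_atoms or not stripped:
            continue
        parts = stripped.split()
        if len(parts) < 5:
            raise ValueError(f"{path}:{lineno}: malformed MOL2 ATOM record: {ln!r}")
        try:
            positions.append([float(parts[2]), float(parts[3]), float(parts[4])])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinate: {ln!r}") from exc
    if not positions:
        warnings.warn(f"{path}: no ATOM records found; empty scatter", stacklevel=2)
        return FragmentScatter(np.empty((0, 3)), role=role)
    return FragmentScatter(np.array(positions), role=role)


def write_scatter_mol2(scatter: FragmentScatter, path: str | Path,
                       atom_name: str = "C") -> None:
    """Write a scatter as a minimal TRIPOS MOL2 (one atom per point)."""
    n = len(scatter)
    lines = [
        "@<TRIPOS>MOLECULE", "scatter", f"{n} 0 0 0 0", "SMALL", "NO_CHARGES", "",
        "@<TRIPOS>ATOM",
    ]
    for i, (x, y, z) in enumerate(scatter.positions, start=1):
        lines.append(f"{i:>7d} {atom_name:<4s} {x:12.4f} {y:12.4f} {z:12.4f} {atom_name}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Volumetric writers: OpenDX (VMD-readable) and Gaussian CUBE


def write_dx(grid: VolumetricGrid, path: str | Path) -> None:
    """Write an OpenDX regular-grid scalar file.

    Header: origin = node (0,0,0) position in angstroms, delta = cubic
    spacing on each axis; data in x-fastest-last (C) order, three values
    per line, as molecular viewers expect.
    """
    nx, ny, nz = grid.shape
    s = grid.spacing
    o = grid.origin
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.values.ravel(order="C")
    for lo in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[lo:lo + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path) -> VolumetricGrid:
    """Read back an OpenDX regular grid written by :func:`write_dx`."""
    counts = None
    origin = None
    deltas: list[float] = []
    data: list[float] = []
    n_items = None
    for ln in Path(path).read_text().splitlines():
        t = ln.split()
        if not t:
            continue
        if ln.startswith("object 1"):
            counts = tuple(int(x) for x in t[-3:])
        elif t[0] == "origin":
            origin = np.array([float(x) for x in t[1:4]])
        elif t[0] == "delta":
            deltas.append(max(float(x) for x in t[1:4]))
        elif "data follows" in ln:
            n_items = int(t[-3])
        elif n_items is not None and len(data) < n_items:
            try:
                data.extend(float(x) for x in t)
            except ValueError:
                break
    if counts is None or origin is None or n_items is None:
        raise ValueError(f"{path}: not a recognizable OpenDX grid")
    values = np.array(data[:n_items]).reshape(counts, order="C")
    return VolumetricGrid(origin=origin, spacing=deltas[0], values=values)


def write_cube(grid: VolumetricGrid, path: str | Path,
               elements: Sequence[str] = (), coords: np.ndarray | None = None) -> None:
    """Write a Gaussian CUBE file (lengths converted to Bohr per the
    format's convention); optional atom records in angstrom input."""
    numbers = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "F": 9, "Cl": 17}
    nx, ny, nz = grid.shape
    s = grid.spacing / BOHR
    o = grid.origin / BOHR
    natom = len(elements)
    lines = [
        "mifkit volumetric grid",
        "scalar field (lengths in Bohr)",
        f"{natom:5d} {o[0]:11.6f} {o[1]:11.6f} {o[2]:11.6f}",
        f"{nx:5d} {s:11.6f} {0.0:11.6f} {0.0:11.6f}",
        f"{ny:5d} {0.0:11.6f} {s:11.6f} {0.0:11.6f}",
        f"{nz:5d} {0.0:11.6f} {0.0:11.6f} {s:11.6f}",
    ]
    if natom:
        for el, (x, y, z) in zip(elements, np.asarray(coords) / BOHR):
            z_num = numbers.get(el, 0)
            lines.append(f"{z_num:5d} {0.0:11.6f} {x:11.6f} {y:11.6f} {z:11.6f}")
    flat = grid.values.ravel(order="C")
    for lo in range(0, flat.size, 6):
        lines.append(" ".join(f"{v:12.5e}" for v in flat[lo:lo + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def splat_field_to_grid(positions: np.ndarray, values: np.ndarray,
                        spacing: float, extent: float) -> VolumetricGrid:
    """Nearest-node splatting of scattered field samples onto a lattice.

    Each sample value is written to its nearest grid node (last writer
    wins on collisions); untouched nodes stay zero. Intended for
    exporting spherical-scan fields to DX/CUBE viewers.
    """
    n = 2 * int(np.ceil(extent / spacing)) + 1
    origin = np.array([-spacing * (n - 1) / 2.0] * 3)
    grid = np.zeros((n, n, n))
    idx = np.rint((np.asarray(positions) - origin) / spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < n), axis=1)
    for (i, j, k), v in zip(idx[inside], np.asarray(values)[inside]):
        grid[i, j, k] = v
    return VolumetricGrid(origin=origin, spacing=spacing, values=grid)
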