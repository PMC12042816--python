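"""Molecular coordinate frames and spherical scan grids.

A ring-containing target molecule defines an *o-uvw* coordinate system:
the origin sits at the centroid of the ring atoms, the w axis is the
(least-squares) normal of the ring plane, the u axis points from the
origin toward a designated heavy atom (projected into the ring plane),
and v = w x u completes a right-handed orthonormal triad.

Interaction-field scans place probes on a spherical grid around this
frame: radii sampled on a closed interval, polar angle measured from +w
over [0, 180] degrees, azimuth from +u toward +v over [0, 360) degrees.
Poles and the azimuth wrap-around are deduplicated so every grid point
is geometrically unique.

All coordinates are in angstroms. Atom indices are 0-based in memory and
1-based in file formats.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "Molecule",
    "MolecularFrame",
    "SphericalGridSpec",
    "GridPoint",
    "DegeneratePlaneError",
    "UndefinedAxisError",
    "build_frame",
    "make_spherical_grid",
    "grid_point_count",
    "to_frame",
    "from_frame",
    "read_xyz",
    "write_xyz",
    "read_sdf_coordinates",
]

# distance below which two grid points are considered coincident (angstrom)
_DEDUP_TOL = 1e-8


class DegeneratePlaneError(ValueError):
    """Ring atoms do not define a plane (collinear or fewer than 3)."""


class UndefinedAxisError(ValueError):
    """The u-axis reference atom coincides with the ring centroid."""


@dataclass(frozen=True)
class Molecule:
    """A molecule as element symbols plus Cartesian coordinates.

    Parameters
    ----------
    elements : sequence of str
        Element symbols, one per atom.
    coords : (n_atoms, 3) array
        Positions in angstroms.
    ring_sets : sequence of index tuples, optional
        Known ring-atom index sets (0-based).
    aromatic_flags : sequence of bool, optional
        One flag per entry of ``ring_sets``; flagged rings receive a
        dummy interaction site at their centroid during probe scans.
    """

    elements: tuple[str, ...]
    coords: np.ndarray
    ring_sets: tuple[tuple[int, ...], ...] = ()
    aromatic_flags: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if coords.shape[0] != len(self.elements):
            raise ValueError("elements and coords length mismatch")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        if self.aromatic_flags and len(self.aromatic_flags) != len(self.ring_sets):
            raise ValueError("aromatic_flags must match ring_sets")
        n = coords.shape[0]
        for ring in self.ring_sets:
            if any(i < 0 or i >= n for i in ring):
                raise IndexError("ring index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def ring_centroids(self, aromatic_only: bool = True) -> np.ndarray:
        """Centroids of the stored rings, optionally aromatic-flagged only."""
        flags = self.aromatic_flags or (True,) * len(self.ring_sets)
        cents = [
            self.coords[list(ring)].mean(axis=0)
            for ring, ok in zip(self.ring_sets, flags)
            if ok or not aromatic_only
        ]
        return np.array(cents).reshape(-1, 3)


@dataclass(frozen=True)
class MolecularFrame:
    """Right-handed orthonormal o-uvw frame of a ring system.

    ``rotation`` maps lab-frame *displacements* to (u, v, w) components:
    its rows are the u, v and w axes expressed in lab coordinates.
    """

    origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    w_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "u_axis", "v_axis", "w_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        u, v, w = self.u_axis, self.v_axis, self.w_axis
        for a in (u, v, w):
            if abs(np.linalg.norm(a) - 1.0) > 1e-12:
                raise ValueError("frame axes must be unit vectors")
        if max(abs(u @ v), abs(u @ w), abs(v @ w)) > 1e-10:
            raise ValueError("frame axes must be mutually orthogonal")
        if np.linalg.norm(np.cross(u, v) - w) > 1e-9:
            raise ValueError("frame must be right-handed (u x v = w)")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with rows (u, v, w): lab displacement -> frame components."""
        return np.vstack([self.u_axis, self.v_axis, self.w_axis])

    def to_json(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "rotation": self.rotation.tolist(),
        }

    @classmethod
    def from_json(cls, data: dict) -> "MolecularFrame":
        rot = np.asarray(data["rotation"], dtype=float)
        return cls(np.asarray(data["origin"], dtype=float), rot[0], rot[1], rot[2])


@dataclass(frozen=True)
class SphericalGridSpec:
    """Spherical sampling scheme around a molecular frame.

    Radii run from ``r_min`` to ``r_max_radius`` inclusive in steps of
    ``r_step``; angles are in degrees, polar over [0, 180], azimuth over
    [0, 360). Steps must divide their ranges evenly. The defaults are
    the canonical weak-hydrogen-bond scan: 2-7 A at 0.2 A with 10-degree
    angular steps, i.e. 15,964 unique points.
    """

    r_min: float = 2.0
    r_max_radius: float = 7.0
    r_step: float = 0.2
    polar_step: float = 10.0
    azimuth_step: float = 10.0

    def __post_init__(self) -> None:
        if self.r_step <= 0:
            raise ValueError("r_step must be positive")
        if self.polar_step <= 0 or self.azimuth_step <= 0:
            raise ValueError("angular steps must be positive")
        for rng, step, what in ((180.0, self.polar_step, "polar"), (360.0, self.azimuth_step, "azimuth")):
            k = rng / step
            if abs(k - round(k)) > 1e-9:
                raise ValueError(f"{what}_step must divide {rng} evenly")
        if self.r_max_radius >= self.r_min:
            k = (self.r_max_radius - self.r_min) / self.r_step
            if abs(k - round(k)) > 1e-9:
                raise ValueError("r_step must divide the radius range evenly")

    @property
    def radii(self) -> np.ndarray:
        if self.r_max_radius < self.r_min:
            return np.empty(0)
        n = int(round((self.r_max_radius - self.r_min) / self.r_step)) + 1
        return self.r_min + self.r_step * np.arange(n)

    @property
    def polar_values(self) -> np.ndarray:
        n = int(round(180.0 / self.polar_step)) + 1
        return self.polar_step * np.arange(n)

    @property
    def azimuth_values(self) -> np.ndarray:
        n = int(round(360.0 / self.azimuth_step))
        return self.azimuth_step * np.arange(n)


@dataclass(frozen=True)
class GridPoint:
    """One scan-grid point, indexed, in frame coordinates (u, v, w)."""

    index: int
    radius: float
    polar: float
    azimuth: float
    position: np.ndarray  # (u, v, w) components, angstrom

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


def _spherical_to_cartesian(radius: float, polar_deg: float, azimuth_deg: float) -> np.ndarray:
    th = math.radians(polar_deg)
    ph = math.radians(azimuth_deg)
    s = math.sin(th)
    return np.array([radius * s * math.cos(ph), radius * s * math.sin(ph), radius * math.cos(th)])


def make_spherical_grid(spec: SphericalGridSpec) -> list[GridPoint]:
    """Enumerate the deduplicated spherical grid of ``spec``.

    Ordering is radius-major, then polar, then azimuth. The two poles
    contribute exactly one point per radius (the azimuth=0 instance is
    kept); azimuth 360 is identified with 0 by construction.
    """
    points: list[GridPoint] = []
    idx = 0
    for r in spec.radii:
        for th in spec.polar_values:
            at_pole = th < 1e-12 or abs(th - 180.0) < 1e-12
            azimuths = spec.azimuth_values[:1] if at_pole else spec.azimuth_values
            for ph in azimuths:
                points.append(GridPoint(idx, float(r), float(th), float(ph),
                                        _spherical_to_cartesian(r, th, ph)))
                idx += 1
    return points


def grid_point_count(spec: SphericalGridSpec) -> int:
    """Closed-form point count: r * ((p - 2) * a + 2) for p polar rings
    (both poles included) and a azimuth values per non-pole ring."""
    n_r = len(spec.radii)
    if n_r == 0:
        return 0
    p = len(spec.polar_values)
    a = len(spec.azimuth_values)
    return n_r * ((p - 2) * a + 2)


def build_frame(mol: Molecule, ring_atoms: Iterable[int], u_atom: int) -> MolecularFrame:
    """Construct the o-uvw frame of ``mol`` from a ring and a u-axis atom.

    The origin is the ring-atom centroid; w is the least-squares plane
    normal of the ring atoms (sign fixed so the largest-magnitude
    component is positive, for determinism); u points from the origin
    toward ``u_atom`` after projection into the ring plane; v = w x u.

    Raises
    ------
    DegeneratePlaneError
        If the ring atoms are collinear (no unique plane).
    UndefinedAxisError
        If ``u_atom`` projects onto the origin.
    """
    ring = sorted(set(int(i) for i in ring_atoms))
    if len(ring) < 3:
        raise DegeneratePlaneError("need at least 3 ring atoms")
    pts = mol.coords[ring]
    origin = pts.mean(axis=0)
    centered = pts - origin
    # plane normal = left-singular vector of the smallest singular value
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegeneratePlaneError("ring atoms are collinear")
    w = vt[2]
    # deterministic sign: largest-|component| positive
    k = int(np.argmax(np.abs(w)))
    if w[k] < 0:
        w = -w
    w = w / np.linalg.norm(w)

    ref = mol.coords[u_atom] - origin
    u = ref - (ref @ w) * w  # project into the ring plane
    nu = np.linalg.norm(u)
    if nu < 1e-8:
        raise UndefinedAxisError("u_atom projects onto the ring centroid")
    u = u / nu
    v = np.cross(w, u)
    return MolecularFrame(origin, u, v, w)


def to_frame(frame: MolecularFrame, lab_points: np.ndarray) -> np.ndarray:
    """Lab coordinates -> (u, v, w) frame coordinates. Accepts (3,) or (n, 3)."""
    p = np.asarray(lab_points, dtype=float)
    return (p - frame.origin) @ frame.rotation.T


def from_frame(frame: MolecularFrame, frame_points: np.ndarray) -> np.ndarray:
    """(u, v, w) frame coordinates -> lab coordinates. Inverse of to_frame."""
    q = np.asarray(frame_points, dtype=float)
    return q @ frame.rotation + frame.origin


# ---------------------------------------------------------------------------
# File I/O: XYZ (2-line header), SDF V2000 coordinate block, frame JSON


def read_xyz(path: str | Path) -> Molecule:
    """Read a standard XYZ file (atom count, comment, then element x y z)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed XYZ header") from exc
    elements, coords = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed XYZ atom line: {ln!r}")
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    if len(elements) != n:
        raise ValueError(f"{path}: expected {n} atoms, found {len(elements)}")
    return Molecule(tuple(elements), np.array(coords))


def write_xyz(mol: Molecule, path: str | Path, comment: str = "") -> None:
    lines = [str(mol.n_atoms), comment]
    for el, (x, y, z) in zip(mol.elements, mol.coords):
        lines.append(f"{el:<3s} {x:14.8f} {y:14.8f} {z:14.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sdf_coordinates(path: str | Path) -> Molecule:
    """Read elements + coordinates from the first record of an SDF/MOL file.

    Only the V2000 coordinate block is used; bonds, charges and
    properties are ignored.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    rdmol = next((m for m in supplier if m is not None), None)
    if rdmol is None:
        raise ValueError(f"{path}: no parseable SDF record")
    conf = rdmol.GetConformer()
    elements = tuple(a.GetSymbol() for a in rdmol.GetAtoms())
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(rdmol.GetNumAtoms())])
    return Molecule(elements, coords)


def save_frame(frame: MolecularFrame, path: str | Path) -> None:
    Path(path).write_text(json.dumps(frame.to_json(), indent=1))


def load_frame(path: str | Path) -> MolecularFrame:
    return MolecularFrame.from_json(json.loads(Path(path).read_text()))
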