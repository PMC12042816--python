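"""Projection of fitted interaction fields onto protein/ligand complexes.

A ligand containing the reference ring substructure is superposed onto
the reference molecule by least-squares rigid-body fitting (Kabsch; no
reflections). The recovered transform carries lab coordinates of the
complex into the reference molecular frame, where a fitted Gaussian
expansion E(r) can be evaluated: on a lab-frame lattice around the
ligand for visualization, or directly at protein atom positions for
interaction reports. Reports list atoms inside "interaction formable
areas" — regions where the normalized field meets a threshold
(conventionally 0.8, 0.6 and 0.4).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cgfit import ApproxFunction, evaluate
from .densmap import VolumetricGrid
from .molframe import Molecule

__all__ = [
    "RigidTransform",
    "ComplexScene",
    "superpose",
    "build_scene",
    "map_function",
    "contact_report",
    "read_pdb_complex",
]


@dataclass(frozen=True)
class RigidTransform:
    """x_frame = rotation @ x_lab + translation (proper rotation only)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-10:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("transform contains a reflection")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Returns the transform taking ``mobile`` onto ``reference`` and the
    post-fit RMSD. The rotation determinant is forced to +1, so mirror
    images are fit as well as a proper rotation allows, never reflected.

    Raises
    ------
    ValueError
        For fewer than 3 pairs or collinear/degenerate point sets.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.shape[0] < 3:
        raise ValueError("need >= 3 corresponding point pairs")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise ValueError("point sets are collinear; rotation not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    rmsd = float(np.sqrt(np.mean(np.sum((X0 @ R.T - Y0) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


@dataclass
class ComplexScene:
    """A protein/ligand complex mapped onto a reference molecular frame.

    ``correspondence`` maps ligand atom indices to reference-molecule
    atom indices (>= 3 non-collinear pairs); ``transform`` carries lab
    coordinates into the reference frame.
    """

    protein_elements: tuple[str, ...]
    protein_coords: np.ndarray
    protein_res_names: tuple[str, ...]
    protein_res_ids: tuple[int, ...]
    protein_atom_names: tuple[str, ...]
    protein_chains: tuple[str, ...]
    ligand_elements: tuple[str, ...]
    ligand_coords: np.ndarray
    correspondence: dict[int, int]
    transform: RigidTransform | None = None
    rmsd: float | None = None

    @property
    def substructure_coords(self) -> np.ndarray:
        return self.ligand_coords[sorted(self.correspondence)]

    @property
    def substructure_centroid(self) -> np.ndarray:
        return self.substructure_coords.mean(axis=0)


def build_scene(protein, ligand_elements: Sequence[str], ligand_coords: np.ndarray,
                reference: Molecule,
                correspondence: Mapping[int, int] | None = None) -> ComplexScene:
    """Assemble a ComplexScene and recover its frame transform.

    ``protein`` is a biotite AtomArray (or any object with ``element``,
    ``coord``, ``res_name``, ``res_id``, ``atom_name``, ``chain_id``
    arrays). When ``correspondence`` is omitted, it is found
    automatically by matching elements between the ligand and the
    reference and choosing the assignment with the lowest superposition
    RMSD (reported in the scene).
    """
    ligand_coords = np.asarray(ligand_coords, dtype=float)
    if correspondence is None:
        correspondence, transform, rmsd = _auto_correspondence(
            tuple(ligand_elements), ligand_coords, reference)
    else:
        correspondence = {int(k): int(v) for k, v in correspondence.items()}
        lig_idx = sorted(correspondence)
        ref_idx = [correspondence[i] for i in lig_idx]
        transform, rmsd = superpose(ligand_coords[lig_idx], reference.coords[ref_idx])
    return ComplexScene(
        protein_elements=tuple(protein.element),
        protein_coords=np.asarray(protein.coord, dtype=float),
        protein_res_names=tuple(protein.res_name),
        protein_res_ids=tuple(int(i) for i in protein.res_id),
        protein_atom_names=tuple(protein.atom_name),
        protein_chains=tuple(protein.chain_id),
        ligand_elements=tuple(ligand_elements),
        ligand_coords=ligand_coords,
        correspondence=correspondence,
        transform=transform,
        rmsd=rmsd,
    )


def _auto_correspondence(elements: tuple[str, ...], coords: np.ndarray,
                         reference: Molecule, max_perm: int = 40320
                         ) -> tuple[dict[int, int], RigidTransform, float]:
    """Element-matched correspondence search minimizing RMSD.

    Tries permutations of same-element ligand atoms against the
    reference atom list (symmetric ligands are ambiguous); practical
    for reference substructures up to ~8 atoms per element.
    """
    ref_by_el: dict[str, list[int]] = {}
    for i, el in enumerate(reference.elements):
        ref_by_el.setdefault(el, []).append(i)
    lig_by_el: dict[str, list[int]] = {}
    for i, el in enumerate(elements):
        lig_by_el.setdefault(el, []).append(i)

    choices: list[list[tuple[tuple[int, ...], tuple[int, ...]]]] = []
    for el, ref_idx in ref_by_el.items():
        lig_idx = lig_by_el.get(el, [])
        if len(lig_idx) < len(ref_idx):
            raise ValueError(f"ligand lacks enough {el} atoms to match the reference")
        per_el = []
        for combo in itertools.permutations(lig_idx, len(ref_idx)):
            per_el.append((combo, tuple(ref_idx)))
            if len(per_el) > max_perm:
                raise ValueError("correspondence search too large; provide a mapping")
        choices.append(per_el)

    best: tuple[float, dict[int, int], RigidTransform] | None = None
    for assignment in itertools.product(*choices):
        mapping = {}
        for lig_combo, ref_idx in assignment:
            mapping.update(dict(zip(lig_combo, ref_idx)))
        lig_idx = sorted(mapping)
        ref_idx = [mapping[i] for i in lig_idx]
        try:
            tr, rmsd = superpose(coords[lig_idx], reference.coords[ref_idx])
        except ValueError:
            continue
        if best is None or rmsd < best[0]:
            best = (rmsd, mapping, tr)
    if best is None:
        raise ValueError("no valid correspondence found")
    return best[1], best[2], best[0]


def map_function(fn: ApproxFunction, scene: ComplexScene, spacing: float = 0.1,
                 nodes_per_axis: int = 200, clamp: bool = False) -> VolumetricGrid:
    """Evaluate a fitted field on a lab-frame lattice around the ligand.

    The cubic lattice (``nodes_per_axis`` per axis; the canonical 200 at
    0.1 A gives 8,000,000 nodes) is centered on the ligand-substructure
    centroid; with an even node count the centroid sits half a spacing
    off the central edge, by convention toward lower indices. Each node
    is transformed into the molecular frame and evaluated.
    """
    if scene.transform is None:
        raise ValueError("scene has no frame transform")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n = int(nodes_per_axis)
    center = scene.substructure_centroid
    axis = spacing * (np.arange(n) - (n - 1) / 2.0)
    origin = center + axis[0]
    X, Y, Z = np.meshgrid(*(center[i] + axis for i in range(3)), indexing="ij")
    lab = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    frame_pts = scene.transform.apply(lab)
    vals = evaluate(fn, frame_pts, clamp=clamp).reshape(n, n, n)
    return VolumetricGrid(origin=origin, spacing=spacing, values=vals)


def contact_report(scene: ComplexScene, fn: ApproxFunction,
                   thresholds: Sequence[float] = (0.8, 0.6, 0.4),
                   role: str = "donor_carbon",
                   annotate_spacing: float = 0.2,
                   annotate_extent: float = 8.0) -> pd.DataFrame:
    """Protein atoms inside interaction-formable areas of ``fn``.

    Field values are evaluated exactly at (frame-transformed) heavy-atom
    positions — never interpolated from a lattice. The report lists one
    row per protein atom reaching the lowest threshold, with boolean
    columns per threshold and, for atoms below the top threshold, the
    distance to the nearest frame-lattice node at or above it.
    """
    if scene.transform is None:
        raise ValueError("scene has no frame transform")
    thresholds = sorted(float(t) for t in thresholds)
    top = max(thresholds)
    frame_pos = scene.transform.apply(scene.protein_coords)
    values = np.asarray(evaluate(fn, frame_pos))

    # frame-space lattice of the top-threshold region, for the distance
    # annotation only (values above come from exact atom positions)
    half_n = int(round(annotate_extent / annotate_spacing))
    ax = annotate_spacing * (np.arange(2 * half_n + 1) - half_n)
    U, V, W = np.meshgrid(ax, ax, ax, indexing="ij")
    lattice = np.column_stack([U.ravel(), V.ravel(), W.ravel()])
    lat_vals = np.asarray(evaluate(fn, lattice))
    hot = lattice[lat_vals >= top]

    rows = []
    lowest = min(thresholds)
    for i in np.flatnonzero(values >= lowest):
        row = {
            "atom_index": int(i),
            "atom_name": scene.protein_atom_names[i],
            "element": scene.protein_elements[i],
            "residue": scene.protein_res_names[i],
            "res_id": scene.protein_res_ids[i],
            "chain": scene.protein_chains[i],
            "value": float(values[i]),
            "role": role,
        }
        for t in thresholds:
            row[f"ge_{t:g}"] = bool(values[i] >= t)
        if values[i] < top and len(hot):
            row["dist_to_top_area"] = float(
                np.min(np.linalg.norm(hot - frame_pos[i], axis=1)))
        else:
            row["dist_to_top_area"] = 0.0 if values[i] >= top else np.nan
        rows.append(row)
    cols = ["atom_index", "atom_name", "element", "residue", "res_id", "chain",
            "value", "role"] + [f"ge_{t:g}" for t in thresholds] + ["dist_to_top_area"]
    return pd.DataFrame(rows, columns=cols)


def read_pdb_complex(path: str | Path, ligand_res_name: str
                     ) -> tuple[object, tuple[str, ...], np.ndarray]:
    """Read a PDB file and split it into protein and one ligand.

    Uses standard PDB columns via biotite with the first-conformer
    altloc rule; the ligand is every HETATM whose residue name matches
    ``ligand_res_name``. Returns (protein AtomArray, ligand elements,
    ligand coordinates).
    """
    import biotite.structure.io.pdb as pdb

    pf = pdb.PDBFile.read(str(path))
    arr = pf.get_structure(model=1, altloc="first")
    is_lig = (arr.res_name == ligand_res_name) & arr.hetero
    if not np.any(is_lig):
        raise ValueError(f"{path}: no HETATM residue named {ligand_res_name!r}")
    protein = arr[~is_lig & (arr.element != "")]
    lig = arr[is_lig]
    return protein, tuple(lig.element), np.asarray(lig.coord, dtype=float)
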