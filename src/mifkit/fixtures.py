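"""Seeded synthetic inputs mirroring the structures the pipeline consumes.

Everything here is generated, not measured: ring molecules with ideal
geometry, interaction fields built from known Gaussian coefficients
(for fit-recovery experiments), scatter clouds drawn from Gaussian
lobes above and below a ring plane (the shape real CH/π contact
surveys produce, with lobe centers at |w| = 3.6 A, a typical optimum
ring-center-to-donor-carbon distance), and toy protein/ligand scenes
with a known rigid pose. All generators are deterministic for a fixed
seed and carry their ground truth alongside the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cgfit import ApproxFunction, CGFBasis, CGFTerm, alpha_from_rmax, evaluate
from .complexmap import ComplexScene, RigidTransform, build_scene
from .densmap import FragmentScatter
from .molframe import GridPoint, MolecularFrame, Molecule, build_frame
from .probescan import MIFField

__all__ = [
    "SyntheticFieldSpec",
    "synthetic_field",
    "toy_ring_molecule",
    "toy_complex",
    "synthetic_scatter",
    "random_rotation",
]


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Ground truth for a synthetic normalized field."""

    terms: tuple[CGFTerm, ...]
    coefficients: tuple[float, ...]
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.coefficients):
            raise ValueError("terms/coefficients length mismatch")

    def function(self) -> ApproxFunction:
        return ApproxFunction(CGFBasis(self.terms), np.array(self.coefficients))


def default_field_spec(noise: float = 0.0, seed: int = 0) -> SyntheticFieldSpec:
    """A two-lobe ground truth: an s-type bump at 3.6 A decay scale plus
    a w^2 (d-type) term concentrating weight above/below the ring plane.

    Coefficients are chosen so the field peaks at ~0.98 on the w axis at
    |w| ~ 3.6 A — the shape of a normalized field whose most stable
    points sit at the typical ring-center-to-donor-carbon optimum.
    """
    terms = (
        CGFTerm(0, 0, 0, alpha_from_rmax(0, 3.6), 3.6),
        CGFTerm(0, 0, 2, alpha_from_rmax(2, 3.6), 3.6),
    )
    return SyntheticFieldSpec(terms, (0.04, 0.20), noise=noise, seed=seed)


def synthetic_field(spec: SyntheticFieldSpec, grid: Sequence[GridPoint],
                    frame: MolecularFrame | None = None) -> MIFField:
    """Build an MIFField whose normalized values follow known coefficients.

    normalized_n = clip(sum_i c_i g_i(r_n) + noise_n, 0, 1). The raw
    channel is filled with -normalized (a consistent attractive field
    with Δe_max = -1) so downstream code sees a well-formed field. The
    generating spec is attached as ``ground_truth``.
    """
    rng = np.random.default_rng(spec.seed)
    if frame is None:
        frame = MolecularFrame(np.zeros(3), np.array([1.0, 0, 0]),
                               np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))
    pts = np.array([gp.position for gp in grid])
    fn = spec.function()
    vals = np.asarray(evaluate(fn, pts))
    if spec.noise:
        vals = vals + rng.normal(0.0, spec.noise, size=vals.shape)
    vals = np.clip(vals, 0.0, 1.0)
    field = MIFField(frame, list(grid), raw=-vals, normalized=vals,
                     delta_e_max=-1.0 if vals.max() > 0 else None,
                     probe_name="synthetic")
    field.ground_truth = spec  # type: ignore[attr-defined]
    return field


def toy_ring_molecule(n_ring: int = 6, radius: float = 1.39,
                      hetero: dict[int, str] | None = None,
                      ch_length: float = 1.08) -> Molecule:
    """A regular planar ring in the lab xy-plane with radial H substituents.

    Ring atom 0 sits on +x; ``hetero`` substitutes elements at given
    ring positions (e.g. {0: "N"} for a pyridine-like ring, which then
    carries no H at that position). The ring is flagged aromatic, so a
    dummy interaction site appears at its centroid.
    """
    hetero = hetero or {}
    ang = 2.0 * np.pi * np.arange(n_ring) / n_ring
    ring = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n_ring)])
    elements = [hetero.get(i, "C") for i in range(n_ring)]
    coords = [ring]
    for i in range(n_ring):
        if elements[i] == "C":
            coords.append(ring[i] * (1.0 + ch_length / radius))
            elements.append("H")
    return Molecule(tuple(elements), np.vstack(coords),
                    ring_sets=(tuple(range(n_ring)),), aromatic_flags=(True,))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR with sign fix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


class _ArrayLikeProtein:
    """Minimal stand-in for a biotite AtomArray (synthetic scenes only)."""

    def __init__(self, elements, coords, res_names, res_ids, atom_names, chains):
        self.element = np.array(elements)
        self.coord = np.asarray(coords, dtype=float)
        self.res_name = np.array(res_names)
        self.res_id = np.array(res_ids)
        self.atom_name = np.array(atom_names)
        self.chain_id = np.array(chains)


def toy_complex(seed: int = 0, n_shell: int = 40, shell_radius: float = 6.0,
                planted: Sequence[np.ndarray] = ()) -> tuple[ComplexScene, RigidTransform]:
    """A synthetic protein/ligand scene with a known rigid pose.

    A pyridine-like ring ligand is placed at a random rotation +
    translation; ``n_shell`` carbon "protein" atoms are scattered on a
    shell around it, and any ``planted`` frame-coordinate positions are
    added as extra atoms (useful for placing atoms at known field
    values). Returns the scene and the true lab->frame transform.
    """
    rng = np.random.default_rng(seed)
    ref = toy_ring_molecule(6, 1.39, hetero={0: "N"})
    ref_frame = build_frame(ref, range(6), u_atom=0)

    R = random_rotation(rng)
    t = rng.uniform(-10.0, 10.0, size=3)
    lig_coords = ref.coords @ R.T + t
    # true lab->frame map: undo the pose, then apply the reference frame:
    # frame(p) = F_rot (R^T (p - t) - F_origin)
    rot = ref_frame.rotation @ R.T
    trans = ref_frame.rotation @ (-R.T @ t - ref_frame.origin)
    true = RigidTransform(rot, trans)

    shell_dirs = rng.normal(size=(n_shell, 3))
    shell_dirs /= np.linalg.norm(shell_dirs, axis=1, keepdims=True)
    shell_frame = shell_dirs * shell_radius
    frame_positions = list(shell_frame) + [np.asarray(p, dtype=float) for p in planted]
    # place protein atoms by mapping frame coords through the inverse pose
    inv = true.inverse()
    prot_coords = inv.apply(np.array(frame_positions))
    n_prot = len(frame_positions)
    protein = _ArrayLikeProtein(
        ["C"] * n_prot, prot_coords,
        ["ALA"] * n_prot, list(range(1, n_prot + 1)),
        ["CB"] * n_prot, ["A"] * n_prot,
    )
    correspondence = {i: i for i in range(6)}  # ring atoms only
    scene = build_scene(protein, ref.elements, lig_coords, ref,
                        correspondence=correspondence)
    return scene, true


def synthetic_scatter(ops: Sequence[np.ndarray] = (), n: int = 500, seed: int = 0,
                      lobe_height: float = 3.6, lobe_sigma: float = 0.5,
                      role: str = "donor_carbon") -> FragmentScatter:
    """Draw a CH/π-style scatter: two Gaussian lobes above and below the
    ring plane at |w| = ``lobe_height``, optionally symmetry-expanded.

    With n = 0 the scatter is empty. When ``ops`` are given the raw draw
    is replicated under them (so the binned density is symmetric under
    the generating operations up to grid tolerance).
    """
    from .densmap import expand_symmetry

    rng = np.random.default_rng(seed)
    if n == 0:
        return FragmentScatter(np.empty((0, 3)), role=role)
    signs = rng.choice([-1.0, 1.0], size=n)
    centers = np.column_stack([np.zeros(n), np.zeros(n), signs * lobe_height])
    pos = centers + rng.normal(0.0, lobe_sigma, size=(n, 3))
    scatter = FragmentScatter(pos, role=role)
    if len(ops):
        scatter = expand_symmetry(scatter, list(ops))
    return scatter
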