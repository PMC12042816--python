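"""Probe placement, orientation and interaction-field assembly.

A probe molecule (methane, ethylene, benzene or acetylene) carries a
donor vector **M** along a chosen C-H bond, anchored at the donor
carbon. At every grid point the probe is translated so the donor carbon
sits on the point and rigidly rotated so **M** aligns with **G**_n, the
unit vector from the grid point to the nearest site of the target
(real atoms plus one dummy site at the centroid of each flagged
aromatic ring). An energy backend evaluates the dimer; raw energies are
normalized to [0, 1] against the most stable (most negative) value
Δe_max, with repulsive (>= 0) and failed evaluations clamped to zero.

The residual rotation about the aligned M axis is fixed by turning the
probe's secondary reference vector as close as possible to a supplied
"up" direction (the target frame's w axis during scans); this degree of
freedom is a package convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .molframe import GridPoint, MolecularFrame, Molecule, from_frame

__all__ = [
    "ProbeGeometry",
    "ProbePose",
    "MIFField",
    "PROBES",
    "get_probe",
    "nearest_site",
    "orient_probe",
    "scan",
    "normalize_field",
    "classical_backend",
    "LJ_PARAMS",
    "write_cp_inputs",
    "parse_cp_coordinates",
    "cp_interaction_energy",
]

#: Coulomb constant in kcal*angstrom/(mol*e^2)
COULOMB_KCAL = 332.0637

#: raw-energy failure marker (normalizes to 0)
FAILURE = float("nan")


@dataclass(frozen=True)
class ProbeGeometry:
    """Rigid probe monomer with its donor C-H axis.

    ``m_origin`` indexes the donor carbon; ``m_vector`` is the unit
    vector from that carbon toward the designated hydrogen.
    ``secondary`` is the reference direction used to fix the residual
    torsion about M (chosen perpendicular-ish to M per probe).
    """

    name: str
    elements: tuple[str, ...]
    coords: np.ndarray
    m_origin: int
    m_hydrogen: int
    secondary: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "secondary", np.asarray(self.secondary, dtype=float))
        if self.elements[self.m_origin] != "C":
            raise ValueError("M origin must be a carbon atom")
        m = self.m_vector
        h = coords[self.m_hydrogen] - coords[self.m_origin]
        if np.linalg.norm(np.cross(m, h)) > 1e-6:
            raise ValueError("designated H does not lie on the M ray")

    @property
    def m_vector(self) -> np.ndarray:
        v = self.coords[self.m_hydrogen] - self.coords[self.m_origin]
        return v / np.linalg.norm(v)


def _tetrahedral(r_ch: float) -> np.ndarray:
    d = r_ch / math.sqrt(3.0)
    return np.array([[d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]])


def _build_probes() -> dict[str, ProbeGeometry]:
    probes: dict[str, ProbeGeometry] = {}

    # methane: experimental r(CH) = 1.087 A, tetrahedral
    h = _tetrahedral(1.087)
    probes["methane"] = ProbeGeometry(
        "methane",
        ("C", "H", "H", "H", "H"),
        np.vstack([[0.0, 0.0, 0.0], h]),
        m_origin=0,
        m_hydrogen=1,
        secondary=(h[2] - h[1]),  # roughly perpendicular to the first C-H
    )

    # ethylene: r(CC) = 1.339, r(CH) = 1.086, HCC angle 121.3 deg, planar
    rcc, rch, a = 1.339, 1.086, math.radians(121.3)
    c0 = np.array([0.0, 0.0, 0.0])
    c1 = np.array([rcc, 0.0, 0.0])
    # hydrogens on c0 point away from c1 (HCC angle a measured from the C=C axis)
    h0a = c0 + rch * np.array([math.cos(a), math.sin(a), 0.0])
    h0b = c0 + rch * np.array([math.cos(a), -math.sin(a), 0.0])
    h1a = c1 + rch * np.array([-math.cos(a), math.sin(a), 0.0])
    h1b = c1 + rch * np.array([-math.cos(a), -math.sin(a), 0.0])
    probes["ethylene"] = ProbeGeometry(
        "ethylene",
        ("C", "C", "H", "H", "H", "H"),
        np.vstack([c0, c1, h0a, h0b, h1a, h1b]),
        m_origin=0,
        m_hydrogen=2,
        secondary=(c1 - c0) / rcc,  # the C=C axis
    )

    # benzene: r(CC) = 1.391, r(CH) = 1.080, planar hexagon
    rcc, rch = 1.391, 1.080
    ring_r = rcc  # hexagon circumradius equals the bond length
    ang = np.radians(60.0 * np.arange(6))
    carbons = np.column_stack([ring_r * np.cos(ang), ring_r * np.sin(ang), np.zeros(6)])
    hydros = np.column_stack([(ring_r + rch) * np.cos(ang), (ring_r + rch) * np.sin(ang), np.zeros(6)])
    probes["benzene"] = ProbeGeometry(
        "benzene",
        ("C",) * 6 + ("H",) * 6,
        np.vstack([carbons, hydros]),
        m_origin=0,
        m_hydrogen=6,
        secondary=np.array([0.0, 0.0, 1.0]),  # ring normal
    )

    # acetylene: r(CC) = 1.203, r(CH) = 1.063, linear
    rcc, rch = 1.203, 1.063
    probes["acetylene"] = ProbeGeometry(
        "acetylene",
        ("C", "C", "H", "H"),
        np.array([
            [0.0, 0.0, 0.0],
            [-rcc, 0.0, 0.0],
            [rch, 0.0, 0.0],
            [-rcc - rch, 0.0, 0.0],
        ]),
        m_origin=0,
        m_hydrogen=2,
        secondary=np.array([0.0, 1.0, 0.0]),  # any axis perpendicular to the rod
    )
    return probes


#: packaged standard-geometry probes, keyed by name
PROBES: dict[str, ProbeGeometry] = _build_probes()


def get_probe(name: str) -> ProbeGeometry:
    try:
        return PROBES[name]
    except KeyError:
        raise KeyError(f"unknown probe {name!r}; available: {sorted(PROBES)}") from None


@dataclass(frozen=True)
class ProbePose:
    """A rigidly posed probe at one grid point."""

    grid_index: int
    coords: np.ndarray  # posed atom positions, lab frame
    elements: tuple[str, ...]
    g_vector: np.ndarray
    rotation: np.ndarray  # applied 3x3 rotation


@dataclass
class MIFField:
    """A molecular interaction field on a spherical scan grid.

    ``raw`` holds backend energies in kcal/mol with NaN marking failed
    evaluations; ``normalized`` holds the [0, 1] field; ``delta_e_max``
    is the most negative raw energy (None when no point is attractive).
    """

    frame: MolecularFrame
    grid: list[GridPoint]
    raw: np.ndarray
    normalized: np.ndarray
    delta_e_max: float | None
    probe_name: str = ""

    @property
    def positions(self) -> np.ndarray:
        """Grid-point positions in frame coordinates, shape (n, 3)."""
        return np.array([gp.position for gp in self.grid])

    def to_json(self) -> dict:
        raw = [None if not np.isfinite(x) else float(x) for x in self.raw]
        return {
            "frame": self.frame.to_json(),
            "probe": self.probe_name,
            "grid": [
                {"index": g.index, "radius": g.radius, "polar": g.polar,
                 "azimuth": g.azimuth, "position": g.position.tolist()}
                for g in self.grid
            ],
            "raw": raw,
            "normalized": self.normalized.tolist(),
            "delta_e_max": self.delta_e_max,
        }

    @classmethod
    def from_json(cls, data: dict) -> "MIFField":
        frame = MolecularFrame.from_json(data["frame"])
        grid = [
            GridPoint(g["index"], g["radius"], g["polar"], g["azimuth"], np.array(g["position"]))
            for g in data["grid"]
        ]
        raw = np.array([FAILURE if x is None else x for x in data["raw"]], dtype=float)
        return cls(frame, grid, raw, np.asarray(data["normalized"], dtype=float),
                   data["delta_e_max"], data.get("probe", ""))


def interaction_sites(target: Molecule) -> tuple[np.ndarray, int]:
    """Stack real-atom positions with aromatic-ring dummy centroids.

    Returns (sites, n_real); dummies are ordered after real atoms so
    the lowest-index tie-break prefers real atoms.
    """
    dummies = target.ring_centroids(aromatic_only=True)
    sites = np.vstack([target.coords, dummies]) if len(dummies) else target.coords
    return sites, target.n_atoms


def nearest_site(target: Molecule, point: np.ndarray,
                 sites: np.ndarray | None = None) -> tuple[int, np.ndarray]:
    """Nearest interaction site of ``target`` to ``point`` and the unit
    direction G_n from the point toward it.

    Ties are broken by lowest site index (real atoms precede dummies).
    """
    if sites is None:
        sites, _ = interaction_sites(target)
    point = np.asarray(point, dtype=float)
    d = np.linalg.norm(sites - point, axis=1)
    i = int(np.argmin(d))  # argmin returns the first (lowest-index) minimum
    if d[i] < 1e-8:
        raise ValueError("grid point coincides with an interaction site")
    g = (sites[i] - point) / d[i]
    return i, g


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b.

    The antiparallel case rotates 180 degrees about normalize(a x e),
    where e is the lab axis least aligned with a.
    """
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(a @ b)
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        e = np.zeros(3)
        e[int(np.argmin(np.abs(a)))] = 1.0
        axis = np.cross(a, e)
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, math.pi)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    axis = axis / s
    return _axis_angle(axis, math.atan2(s, c))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def orient_probe(probe: ProbeGeometry, point: np.ndarray, g_vector: np.ndarray,
                 up: np.ndarray | None = None, grid_index: int = -1) -> ProbePose:
    """Pose ``probe`` at ``point`` with its M vector along ``g_vector``.

    The donor carbon is translated onto the grid point, then the probe
    is rigidly rotated about that carbon by the minimal rotation mapping
    M onto G_n. When ``up`` is given, the residual torsion about the
    aligned axis is fixed by rotating the probe's secondary reference
    vector as close as possible to ``up``.
    """
    point = np.asarray(point, dtype=float)
    g = np.asarray(g_vector, dtype=float)
    g = g / np.linalg.norm(g)
    rot = _rotation_aligning(probe.m_vector, g)

    if up is not None:
        s = rot @ probe.secondary
        # components of s and up perpendicular to the aligned axis g
        s_perp = s - (s @ g) * g
        u_perp = np.asarray(up, dtype=float) - (np.asarray(up, dtype=float) @ g) * g
        ns, nu = np.linalg.norm(s_perp), np.linalg.norm(u_perp)
        if ns > 1e-10 and nu > 1e-10:
            sp, upn = s_perp / ns, u_perp / nu
            cosang = float(np.clip(sp @ upn, -1.0, 1.0))
            sinang = float(np.cross(sp, upn) @ g)
            rot = _axis_angle(g, math.atan2(sinang, cosang)) @ rot

    local = probe.coords - probe.coords[probe.m_origin]
    coords = (rot @ local.T).T + point
    return ProbePose(grid_index, coords, probe.elements, g, rot)


# ---------------------------------------------------------------------------
# Energy backends

#: Lennard-Jones well depths (kcal/mol) and diameters (angstrom) per element,
#: plus default partial charges (e). Generic nonbonded parameters for the
#: small set of elements the probes and ring targets contain.
LJ_PARAMS: dict[str, tuple[float, float, float]] = {
    "H": (0.0300, 2.50, 0.0),
    "C": (0.0860, 3.40, 0.0),
    "N": (0.1700, 3.25, 0.0),
    "O": (0.2100, 2.96, 0.0),
    "S": (0.2500, 3.50, 0.0),
    "F": (0.0610, 2.90, 0.0),
    "Cl": (0.2650, 3.40, 0.0),
}

EnergyBackend = Callable[[Molecule, ProbePose], float]


def classical_backend(params: Mapping[str, tuple[float, float, float]] | None = None,
                      target_charges: Sequence[float] | None = None,
                      probe_charges: Sequence[float] | None = None,
                      clash_distance: float = 0.1) -> EnergyBackend:
    """Lennard-Jones + Coulomb pairwise backend (desk-scale test engine).

    E = sum over intermolecular pairs 4*eps_ij*((sig/d)^12 - (sig/d)^6)
        + k_e q_i q_j / d, kcal/mol, with Lorentz-Berthelot combining.
    Pairs closer than ``clash_distance`` produce the failure marker.
    """
    table = dict(LJ_PARAMS)
    if params:
        table.update(params)

    def lookup(el: str) -> tuple[float, float, float]:
        try:
            return table[el]
        except KeyError:
            raise KeyError(f"no nonbonded parameters for element {el!r}") from None

    def backend(target: Molecule, pose: ProbePose) -> float:
        tp = [lookup(e) for e in target.elements]
        pp = [lookup(e) for e in pose.elements]
        qt = np.array([p[2] for p in tp]) if target_charges is None else np.asarray(target_charges, float)
        qp = np.array([p[2] for p in pp]) if probe_charges is None else np.asarray(probe_charges, float)
        eps_t = np.array([p[0] for p in tp])
        sig_t = np.array([p[1] for p in tp])
        eps_p = np.array([p[0] for p in pp])
        sig_p = np.array([p[1] for p in pp])

        d = np.linalg.norm(target.coords[:, None, :] - pose.coords[None, :, :], axis=2)
        if np.any(d < clash_distance):
            return FAILURE
        eps = np.sqrt(eps_t[:, None] * eps_p[None, :])
        sig = 0.5 * (sig_t[:, None] + sig_p[None, :])
        sr6 = (sig / d) ** 6
        lj = 4.0 * eps * (sr6 * sr6 - sr6)
        coul = COULOMB_KCAL * qt[:, None] * qp[None, :] / d
        return float(np.sum(lj + coul))

    return backend


def normalize_field(raw: np.ndarray) -> tuple[np.ndarray, float | None]:
    """Normalize raw energies to [0, 1] against the most stable value.

    E_n = raw_n / min(raw) for attractive (negative) points; repulsive
    (>= 0) and failed (NaN) points map to 0. Returns the normalized
    array and Δe_max = min(raw) (None when nothing is attractive).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("need at least one raw energy")
    finite = raw[np.isfinite(raw)]
    if finite.size == 0 or finite.min() >= 0:
        return np.zeros_like(raw), None
    emin = float(finite.min())
    norm = np.where(np.isfinite(raw) & (raw < 0), raw / emin, 0.0)
    return norm, emin


def scan(target: Molecule, frame: MolecularFrame, grid: Sequence[GridPoint],
         probe: ProbeGeometry, backend: EnergyBackend,
         probe_name: str | None = None) -> MIFField:
    """Scan ``probe`` over ``grid`` (frame coordinates) around ``target``.

    Each grid point is mapped to the lab frame, the probe posed with M
    along G_n (torsion fixed against the frame's w axis), and the
    backend evaluated. A backend exception or failure marker records
    NaN for that point and never aborts the scan.
    """
    sites, _ = interaction_sites(target)
    raw = np.empty(len(grid))
    for j, gp in enumerate(grid):
        lab_point = from_frame(frame, gp.position)
        try:
            _, g = nearest_site(target, lab_point, sites)
            pose = orient_probe(probe, lab_point, g, up=frame.w_axis, grid_index=gp.index)
            raw[j] = backend(target, pose)
        except Exception:
            raw[j] = FAILURE
    norm, emin = normalize_field(raw)
    return MIFField(frame, list(grid), raw, norm, emin,
                    probe_name or probe.name)


# ---------------------------------------------------------------------------
# Counterpoise job generation (input text only; no engine is run)

CP_TEMPLATE = """%chk={name}.chk
# {method}/{basis} counterpoise=2

{name}: target + {probe} counterpoise single point

{charge} {mult} {charge} {mult} {charge} {mult}
{atoms}

"""


def write_cp_inputs(target: Molecule, pose: ProbePose, method: str, basis: str,
                    name: str = "mif_point", charge: int = 0, mult: int = 1) -> str:
    """Emit a two-fragment counterpoise single-point job description.

    Fragment 1 is the target, fragment 2 the posed probe; coordinates
    are printed to 6 decimals. The method/basis strings pass through
    verbatim.
    """
    if target.n_atoms == 0 or len(pose.elements) == 0:
        raise ValueError("both fragments must be non-empty")
    lines = []
    for el, (x, y, z) in zip(target.elements, target.coords):
        lines.append(f"{el}(Fragment=1) {x:12.6f} {y:12.6f} {z:12.6f}")
    for el, (x, y, z) in zip(pose.elements, pose.coords):
        lines.append(f"{el}(Fragment=2) {x:12.6f} {y:12.6f} {z:12.6f}")
    return CP_TEMPLATE.format(name=name, method=method, basis=basis,
                              probe="probe", charge=charge, mult=mult,
                              atoms="\n".join(lines))


def parse_cp_coordinates(text: str) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Parse back the atom lines of a counterpoise job (round-trip check).

    Returns [(element, fragment), ...] and the coordinate array.
    """
    atoms: list[tuple[str, int]] = []
    coords: list[list[float]] = []
    for ln in text.splitlines():
        ln = ln.strip()
        if "(Fragment=" not in ln:
            continue
        head, rest = ln.split(")", 1)
        el, frag = head.split("(Fragment=")
        atoms.append((el.strip(), int(frag)))
        coords.append([float(x) for x in rest.split()[:3]])
    return atoms, np.array(coords)


def cp_interaction_energy(e_dimer: float, e_frag1: float, e_frag2: float) -> float:
    """Counterpoise interaction energy from three user-supplied energies:
    E_int = E(dimer) - E(fragment 1) - E(fragment 2), same units in/out."""
    return e_dimer - e_frag1 - e_frag2
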