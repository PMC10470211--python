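"""Intramolecular and inter-carotenoid geometric descriptors.

Implements the quantities used to characterize protein-bound carotenoids:

* **BLA** (bond length alternation): mean single-bond length minus mean
  double-bond length along the conjugated polyene path.  Bond classes come
  from the template's formal bond orders, never from the observed lengths
  (the crystal lengths are the measurement); a triple bond is excluded from
  both means.
* **Signed torsions** (IUPAC convention) and the s-cis/s-trans classification
  of the end-ring single bonds (|angle| > 90 deg is s-trans; the boundary
  belongs to s-cis).
* **Polyene plane fits** (total least squares) and the plane-pair geometry of
  two carotenoids bound side by side: interplanar angle, minimum inter-chain
  atom distance, and the crossing dihedral over a named atom quadruple
  spanning the two ligands.
* **Pseudo-twofold axis relations**: the angle between the approximate C2
  axis relating the two protein subunits and the one relating the two
  carotenoid polyenes, classified as coincident / perpendicular / oblique.

All descriptors are pure functions of heavy-atom coordinates and are
invariant under rigid-body motion; signed torsions flip under mirror images.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    MissingAtomError,
    ScopeError,
)
from .structure_io import Atom, LigandInstance, normalize_atom_name

__all__ = [
    "CarotenoidTemplate", "builtin_templates",
    "BLAResult", "TorsionResult", "RingConformation", "PlanePairGeometry",
    "AxisRelation",
    "extract_polyene", "bla", "dihedral", "ring_conformation", "fit_plane",
    "pair_geometry", "pseudo_twofold_axes",
]

COINCIDENT_MAX_DEG = 30.0   # axis_klass thresholds; the source literature is
PERPENDICULAR_MIN_DEG = 60.0  # qualitative, these make the call reproducible


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CarotenoidTemplate:
    """Named ligand chemotype: atoms, formal bonds, polyene path, end rings.

    ``polyene_path`` is the ordered conjugated chain (all carbons); bond
    orders along it must alternate single/multiple (a triple bond may stand
    in a "double" slot, as in mytiloxanthin's C7-C8).  ``end_rings`` name the
    ring fragments used for B-factor statistics, and ``torsions`` the named
    atom quadruples (e.g. the 6/6' ring torsion ``C5-C6-C7-C8``).
    """

    code: str
    atoms: tuple[str, ...]
    bonds: tuple[tuple[str, str, int], ...]
    polyene_path: tuple[str, ...]
    end_rings: Mapping[str, frozenset[str]]
    torsions: Mapping[str, tuple[str, str, str, str]]
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError(f"{self.code}: duplicate atom names")
        if any(not a.upper().startswith("C") for a in self.polyene_path):
            raise ValueError(f"{self.code}: polyene path must be all carbon")
        orders = self.path_bond_orders()
        singles = [o == 1 for o in orders]
        if any(singles[i] == singles[i + 1] for i in range(len(singles) - 1)):
            raise ValueError(f"{self.code}: polyene bond orders do not alternate")
        rings = list(self.end_rings.values())
        for i in range(len(rings)):
            for j in range(i + 1, len(rings)):
                if set(rings[i]) & set(rings[j]):
                    raise ValueError(f"{self.code}: end-ring sets overlap")

    def bond_order(self, a: str, b: str) -> int:
        key = frozenset((normalize_atom_name(a), normalize_atom_name(b)))
        for x, y, o in self.bonds:
            if frozenset((normalize_atom_name(x), normalize_atom_name(y))) == key:
                return o
        raise KeyError(f"{self.code}: no bond {a}-{b}")

    def path_bond_orders(self) -> list[int]:
        return [self.bond_order(self.polyene_path[i], self.polyene_path[i + 1])
                for i in range(len(self.polyene_path) - 1)]


def _template_from_dict(code: str, d: dict) -> CarotenoidTemplate:
    return CarotenoidTemplate(
        code=code,
        atoms=tuple(d["atoms"]),
        bonds=tuple((a, b, int(o)) for a, b, o in d["bonds"]),
        polyene_path=tuple(d["polyene_path"]),
        end_rings={k: frozenset(v) for k, v in d["end_rings"].items()},
        torsions={k: tuple(v) for k, v in d["torsions"].items()},
        description=d.get("description", ""),
    )


def builtin_templates() -> dict[str, CarotenoidTemplate]:
    """Load the shipped astaxanthin (AXT) and mytiloxanthin (MXT) templates."""
    text = resources.files("carotenostruct").joinpath(
        "data/carotenoid_templates.json").read_text()
    raw = json.loads(text)
    return {code: _template_from_dict(code, d) for code, d in raw.items()}


def load_templates(path) -> dict[str, CarotenoidTemplate]:
    """Load user templates from a JSON dictionary (same schema as the shipped file)."""
    with open(path) as fh:
        raw = json.load(fh)
    return {code: _template_from_dict(code, d) for code, d in raw.items()}


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass
class BLAResult:
    ligand: str
    mean_single: float
    mean_double: float
    bla: float
    n_single: int
    n_double: int
    scope: str = "chain_only"


@dataclass
class TorsionResult:
    name: str
    atoms: tuple[str, str, str, str]
    angle: float  # signed degrees in (-180, 180]


@dataclass
class RingConformation:
    ring: str
    torsion: TorsionResult
    klass: str  # "s-cis" | "s-trans"


@dataclass
class PlanePairGeometry:
    interplanar_angle: float        # deg, [0, 90]
    min_distance: float             # A, over inter-ligand polyene atoms
    crossing_dihedral: float | None  # deg, signed
    axis_angle: float | None = None  # deg, carotenoid-pair vs dimer C2 axis
    axis_klass: str | None = None   # coincident | perpendicular | oblique


@dataclass
class AxisRelation:
    axis_angle: float               # deg, acute
    axis_klass: str
    dimer_axis: np.ndarray = field(repr=False, default=None)
    pair_axis: np.ndarray = field(repr=False, default=None)
    dimer_rotation_angle: float = float("nan")   # deg, ~180 for a true twofold
    pair_rotation_angle: float = float("nan")
    pair_mapping: str = "forward"   # which path orientation superposed best


# ---------------------------------------------------------------------------
# polyene extraction
# ---------------------------------------------------------------------------

def _ligand_atom(ligand: LigandInstance, name: str) -> Atom:
    want = normalize_atom_name(name)
    for a in ligand.residue.atoms:
        if normalize_atom_name(a.name) == want:
            return a
    raise MissingAtomError(f"{ligand.label}: atom {name} not found")


def extract_polyene(ligand: LigandInstance) -> tuple[list[Atom], list[int]]:
    """Realize the template's polyene path on the coordinates.

    Returns the atoms in path order and the formal bond order of each
    consecutive pair.
    """
    t = ligand.template
    atoms = [_ligand_atom(ligand, n) for n in t.polyene_path]
    return atoms, list(t.path_bond_orders())


def polyene_coords(ligand: LigandInstance) -> np.ndarray:
    atoms, _ = extract_polyene(ligand)
    return np.array([a.pos for a in atoms])


# ---------------------------------------------------------------------------
# BLA
# ---------------------------------------------------------------------------

def bla(path_atoms: Sequence[Atom], bond_orders: Sequence[int],
        scope: str = "chain_only", ligand: str = "") -> BLAResult:
    """Bond length alternation over (a scope of) the polyene path.

    ``scope`` is ``chain_only`` (every path bond), ``beta_side`` or
    ``beta_prime_side`` (the half toward the start/end of the path).  Halves
    split at the central bond; with an odd bond count the central bond
    belongs to neither half.  Triple bonds never enter either mean.
    """
    if len(path_atoms) != len(bond_orders) + 1:
        raise ValueError("need one bond order per consecutive atom pair")
    coords = np.array([a.pos for a in path_atoms])
    lengths = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    m = len(bond_orders)
    if scope == "chain_only":
        sel = range(m)
    elif scope in ("beta_side", "beta_prime_side"):
        if m % 2:  # odd: drop the central bond
            half = (range(0, m // 2) if scope == "beta_side"
                    else range(m // 2 + 1, m))
        else:
            half = (range(0, m // 2) if scope == "beta_side"
                    else range(m // 2, m))
        sel = half
    else:
        raise ValueError(f"unknown scope {scope!r}")
    singles = [lengths[i] for i in sel if bond_orders[i] == 1]
    doubles = [lengths[i] for i in sel if bond_orders[i] == 2]
    if not singles or not doubles:
        raise ScopeError(
            f"scope {scope!r} has {len(singles)} single / {len(doubles)} double bonds")
    ms, md = float(np.mean(singles)), float(np.mean(doubles))
    return BLAResult(ligand=ligand, mean_single=ms, mean_double=md,
                     bla=ms - md, n_single=len(singles), n_double=len(doubles),
                     scope=scope)


def bla_for_ligand(ligand: LigandInstance, scope: str = "chain_only") -> BLAResult:
    atoms, orders = extract_polyene(ligand)
    return bla(atoms, orders, scope=scope, ligand=ligand.code)


# ---------------------------------------------------------------------------
# torsions and planes
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, IUPAC convention, range (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("collinear points: torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:  # atan2 may return exactly -pi; the range is (-180, 180]
        ang += 360.0
    return ang


def torsion_for_ligand(ligand: LigandInstance, name: str) -> TorsionResult:
    quad = ligand.template.torsions.get(name)
    if quad is None:
        raise KeyError(f"{ligand.code}: no torsion named {name!r}")
    pts = [_ligand_atom(ligand, n).pos for n in quad]
    return TorsionResult(name=name, atoms=tuple(quad), angle=dihedral(*pts))


def ring_conformation(ligand: LigandInstance, ring_torsion_name: str) -> RingConformation:
    """Classify an end-ring single-bond conformation by the 90 deg rule."""
    tors = torsion_for_ligand(ligand, ring_torsion_name)
    klass = "s-trans" if abs(tors.angle) > 90.0 else "s-cis"
    return RingConformation(ring=ring_torsion_name, torsion=tors, klass=klass)


def fit_plane(points) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares plane through >=3 points.

    Returns (unit normal, centroid, rms out-of-plane distance).  The normal's
    sign is fixed toward a positive z-component (ties: positive x, then y).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need >= 3 points in 3D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; plane undefined")
    normal = vt[2]
    tol = 1e-12
    if normal[2] < -tol or (abs(normal[2]) <= tol and
                            (normal[0] < -tol or (abs(normal[0]) <= tol and normal[1] < 0))):
        normal = -normal
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return normal, centroid, rms


# ---------------------------------------------------------------------------
# carotenoid pairs
# ---------------------------------------------------------------------------

def _resolve_quadruple(carA: LigandInstance, carB: LigandInstance,
                       quadruple: Sequence[tuple[str, str]]) -> list[np.ndarray]:
    ligs = {"A": carA, "B": carB}
    pts = []
    for which, name in quadruple:
        lig = ligs.get(which)
        if lig is None:
            raise ValueError(f"quadruple selector must be 'A' or 'B', got {which!r}")
        pts.append(_ligand_atom(lig, name).pos)
    return pts


def pair_geometry(carA: LigandInstance, carB: LigandInstance,
                  crossing_quadruple: Sequence[tuple[str, str]] | None = None,
                  ) -> PlanePairGeometry:
    """Plane-pair geometry for two carotenoids bound side by side.

    The interplanar angle is the acute angle between the least-squares planes
    of the two polyene chains; ``min_distance`` is the minimum over all
    inter-ligand polyene heavy-atom pairs (end rings excluded); the crossing
    dihedral is evaluated on a quadruple of ``("A"|"B", atom_name)`` refs
    spanning the two ligands, e.g. ``[("B","C9"),("B","C15"),("A","C15"),
    ("A","C9")]``.
    """
    coordsA = polyene_coords(carA)
    coordsB = polyene_coords(carB)
    nA, _, _ = fit_plane(coordsA)
    nB, _, _ = fit_plane(coordsB)
    cosang = abs(float(np.dot(nA, nB)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    d = np.linalg.norm(coordsA[:, None, :] - coordsB[None, :, :], axis=-1)
    cross = None
    if crossing_quadruple is not None:
        cross = dihedral(*_resolve_quadruple(carA, carB, crossing_quadruple))
    return PlanePairGeometry(interplanar_angle=angle,
                             min_distance=float(d.min()),
                             crossing_dihedral=cross)


def _rotation_axis_angle(rot: np.ndarray) -> tuple[np.ndarray, float]:
    from scipy.spatial.transform import Rotation

    rv = Rotation.from_matrix(rot).as_rotvec()
    ang = float(np.linalg.norm(rv))
    axis = rv / ang if ang > 1e-12 else np.array([0.0, 0.0, 1.0])
    return axis, float(np.degrees(ang))


def pseudo_twofold_axes(dimer, carA: LigandInstance, carB: LigandInstance,
                        ) -> AxisRelation:
    """Relation between the dimer's and the carotenoid pair's pseudo-C2 axes.

    The dimer axis is the rotation axis of the best superposition of one
    protein subunit onto the other (a near-180 deg rotation for a true
    pseudo-twofold).  The carotenoid-pair axis is the rotation axis of the
    best rigid map of carA's polyene onto carB's, trying both the forward and
    the reversed path orientation and keeping the lower-RMSD one.
    """
    from .superposition import kabsch, superpose_chains

    chains = dimer.protein_chains()
    if len(chains) < 2:
        raise ValueError("dimer must contain two protein chains")
    sup = superpose_chains(chains[0], chains[1])
    if sup.rotation_angle < 120.0:
        warnings.warn(
            f"subunit superposition rotation is {sup.rotation_angle:.0f} deg; "
            "no meaningful twofold", stacklevel=2)
    dimer_axis, dimer_ang = sup.rotation_axis, sup.rotation_angle

    A = polyene_coords(carA)
    B = polyene_coords(carB)
    n = min(len(A), len(B))
    offA, offB = (len(A) - n) // 2, (len(B) - n) // 2  # centered common subpath
    A = A[offA:offA + n]
    B = B[offB:offB + n]
    fwd = kabsch(A, B)
    rev = kabsch(A, B[::-1])
    best, mapping = (fwd, "forward") if fwd.rmsd <= rev.rmsd else (rev, "reversed")
    pair_axis, pair_ang = best.rotation_axis, best.rotation_angle

    cosang = abs(float(np.dot(dimer_axis, pair_axis)))
    axis_angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if axis_angle < COINCIDENT_MAX_DEG:
        klass = "coincident"
    elif axis_angle > PERPENDICULAR_MIN_DEG:
        klass = "perpendicular"
    else:
        klass = "oblique"
    return AxisRelation(axis_angle=axis_angle, axis_klass=klass,
                        dimer_axis=dimer_axis, pair_axis=pair_axis,
                        dimer_rotation_angle=dimer_ang,
                        pair_rotation_angle=pair_ang,
                        pair_mapping=mapping)
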