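"""Protein-carotenoid interaction descriptors.

Four views of how a bound carotenoid sits in its protein shell:

* ``contact_residues`` -- the residues with any heavy atom within a cutoff
  (default 4 A) of any ligand heavy atom, the way binding-site tables are
  reported in crystallographic papers.
* ``hydrogen_bonds`` -- heavy-atom N/O...N/O pairs within ``d_max`` whose
  typing admits a donor->acceptor assignment; hydrogens are absent from the
  model, so the optional geometric filter uses the donor's bonded heavy-atom
  antecedent as a proxy (antecedent-donor-acceptor angle >= 90 deg).
* ``sasa`` / ``sasa_partition`` -- Shrake-Rupley solvent-accessible surface
  area on a deterministic Fibonacci sphere lattice (no RNG), and the
  partition of a ligand's isolated SASA into per-chain buried fractions:
  fraction_by_chain[X] = (SASA(ligand alone) - SASA(ligand with chain X
  alone)) / SASA(ligand alone).  Pairwise burial may double-count triple
  overlaps; the residual is reported as ``overlap``.
* ``fragment_bfactor`` -- mean/SD of crystallographic B over a template-
  defined ligand fragment (e.g. an end ring), a proxy for local disorder.

The van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 A) follow Bondi's
compilation; burial fractions are mildly radii-sensitive, so the table is
part of the module contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import CarotenostructError, UnknownElementError
from .structure_io import (
    Atom,
    LigandInstance,
    Residue,
    Structure,
    normalize_atom_name,
)

VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

#: protein heavy-atom donor/acceptor typing (hydrogens absent); backbone N is
#: a donor and backbone O an acceptor for every residue type.
_SIDECHAIN_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("ASN", "ND2"), ("GLN", "NE2"),
    ("TRP", "NE1"),
}
_SIDECHAIN_ACCEPTORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("MET", "SD"),
}


@dataclass
class ContactShell:
    ligand: str
    cutoff: float
    residues: list[tuple[str, int, str, float]]  # (chain, seq_id, name, min dist)

    def labels(self) -> list[str]:
        return [f"{name.capitalize()}{seq}({chain})"
                for chain, seq, name, _ in self.residues]


@dataclass
class AtomRef:
    chain_id: str
    seq_id: int
    res_name: str
    atom_name: str

    @property
    def label(self) -> str:
        return f"{self.res_name.capitalize()}{self.seq_id}({self.chain_id}):{self.atom_name}"


@dataclass
class HydrogenBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float
    klass: str  # "protein-ligand" | "ligand-internal"


@dataclass
class SASAPartition:
    ligand: str
    total_isolated: float                    # A^2, ligand alone
    fraction_by_chain: dict[str, float]      # chain id (or partner-group label) -> buried
    fraction_exposed: float                  # SASA in full complex / isolated
    overlap: float                           # sum(buried) + exposed - 1


@dataclass
class FragmentBStats:
    fragment: str
    atom_count: int
    mean_b: float
    sd_b: float


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _ligand_residue(ligand) -> Residue:
    return ligand.residue if isinstance(ligand, LigandInstance) else ligand


def contact_residues(structure: Structure, ligand, cutoff: float = 4.0,
                     include_waters: bool = False) -> ContactShell:
    """Protein residues with a heavy atom within ``cutoff`` of the ligand.

    Waters, glycans and partner carotenoids are excluded; only polymer
    residues are listed, sorted by chain then residue number.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lres = _ligand_residue(ligand)
    lig_pts = np.array([a.pos for a in lres.heavy_atoms()])
    if not len(lig_pts):
        raise CarotenostructError(f"ligand {lres.label} has no heavy atoms")
    tree = cKDTree(lig_pts)
    hits = []
    for chain in structure.protein_chains():
        for res in chain.residues:
            if res is lres:
                continue
            if res.is_water and not include_waters:
                continue
            if not res.is_polymer and not (res.is_water and include_waters):
                continue
            pts = np.array([a.pos for a in res.heavy_atoms()])
            if not len(pts):
                continue
            d = float(np.min(tree.query(pts, k=1)[0]))
            if d <= cutoff:
                hits.append((res.chain_id, res.seq_id, res.name, d))
    hits.sort(key=lambda h: (h[0], h[1]))
    name = ligand.code if isinstance(ligand, LigandInstance) else lres.name
    return ContactShell(ligand=name, cutoff=cutoff, residues=hits)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _protein_atom_roles(res: Residue, atom: Atom) -> tuple[bool, bool]:
    """(donor?, acceptor?) for a protein heavy atom; N/O only."""
    if atom.element not in ("N", "O"):
        return False, False
    if atom.name == "N":
        return True, False
    if atom.name in ("O", "OXT"):
        return False, True
    key = (res.name, atom.name)
    donor = key in _SIDECHAIN_DONORS
    acceptor = key in _SIDECHAIN_ACCEPTORS
    if not donor and not acceptor:  # unknown residue/atom types: permissive
        donor = True
        acceptor = atom.element == "O"
    return donor, acceptor


def _ligand_atom_roles(ligand, atom: Atom) -> tuple[bool, bool]:
    if atom.element not in ("N", "O"):
        return False, False
    if isinstance(ligand, LigandInstance):
        # hydroxyl (single-bonded O) donates and accepts; keto O only accepts
        for a, b, order in ligand.bond_graph:
            names = {normalize_atom_name(a), normalize_atom_name(b)}
            if normalize_atom_name(atom.name) in names:
                if order >= 2 and atom.element == "O":
                    return False, True
        return True, True
    return True, atom.element == "O"


def _antecedent(res: Residue, atom: Atom) -> Atom | None:
    """Nearest bonded heavy atom in the same residue (<= 1.8 A)."""
    best, best_d = None, 1.8
    for other in res.heavy_atoms():
        if other is atom:
            continue
        d = float(np.linalg.norm(other.pos - atom.pos))
        if d < best_d:
            best, best_d = other, d
    return best


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hydrogen_bonds(structure: Structure, ligand, d_max: float = 3.5,
                   require_geometry: bool = False,
                   include_internal: bool = True) -> list[HydrogenBond]:
    """Heavy-atom hydrogen bonds involving the ligand.

    Each N/O...N/O pair within ``d_max`` is reported once, oriented
    donor -> acceptor where the typing allows it (hydroxyl-hydroxyl pairs are
    reported in a single orientation).  With ``require_geometry`` the
    antecedent-donor-acceptor angle must be >= 90 deg.
    """
    lres = _ligand_residue(ligand)
    lig_polar = [(a, *_ligand_atom_roles(ligand, a))
                 for a in lres.heavy_atoms() if a.element in ("N", "O")]
    bonds: list[HydrogenBond] = []

    def try_bond(atom1, res1, roles1, atom2, res2, roles2, klass):
        d = float(np.linalg.norm(atom1.pos - atom2.pos))
        if d > d_max or d < 0.5:
            return
        for (da, ra, rda), (db, rb, rdb) in (((atom1, res1, roles1), (atom2, res2, roles2)),
                                             ((atom2, res2, roles2), (atom1, res1, roles1))):
            if not (rda[0] and rdb[1]):  # donor on one side, acceptor on the other
                continue
            if require_geometry:
                ante = _antecedent(ra, da)
                if ante is not None and _angle_deg(ante.pos, da.pos, db.pos) < 90.0:
                    continue
            bonds.append(HydrogenBond(
                donor=AtomRef(ra.chain_id, ra.seq_id, ra.name, da.name),
                acceptor=AtomRef(rb.chain_id, rb.seq_id, rb.name, db.name),
                distance=d, klass=klass))
            return  # report each pair once

    for chain in structure.protein_chains():
        for res in chain.polymer_residues():
            for patom in res.heavy_atoms():
                roles = _protein_atom_roles(res, patom)
                if not any(roles):
                    continue
                for latom, ld, la in lig_polar:
                    try_bond(latom, lres, (ld, la), patom, res, roles,
                             "protein-ligand")
    if include_internal:
        bonded = set()
        if isinstance(ligand, LigandInstance):
            bonded = {frozenset((normalize_atom_name(a), normalize_atom_name(b)))
                      for a, b, _ in ligand.bond_graph}
        for i in range(len(lig_polar)):
            for j in range(i + 1, len(lig_polar)):
                a1, d1, r1 = lig_polar[i]
                a2, d2, r2 = lig_polar[j]
                if frozenset((normalize_atom_name(a1.name),
                              normalize_atom_name(a2.name))) in bonded:
                    continue
                try_bond(a1, lres, (d1, r1), a2, lres, (d2, r2), "ligand-internal")
    return bonds


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley, deterministic Fibonacci lattice)
# ---------------------------------------------------------------------------

_POINT_CACHE: dict[int, np.ndarray] = {}


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere lattice (Fibonacci spiral)."""
    pts = _POINT_CACHE.get(n)
    if pts is None:
        i = np.arange(n) + 0.5
        z = 1.0 - 2.0 * i / n
        phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
        r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        _POINT_CACHE[n] = pts
    return pts


def sasa(atoms: Sequence[Atom], probe: float = 1.4, n_points: int = 960,
         radii: dict[str, float] | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area, A^2.

    Each atom's expanded sphere (r_vdw + probe) is sampled on a fixed spiral
    lattice; the accessible area is the exposed point fraction times the full
    sphere area.  Fully deterministic for a given ``n_points``.
    """
    table = VDW_RADII if radii is None else radii
    rads = []
    for a in atoms:
        r = table.get(a.element.upper())
        if r is None:
            raise UnknownElementError(f"no van der Waals radius for {a.element!r}")
        rads.append(r + probe)
    if not atoms:
        return np.zeros(0)
    coords = np.array([a.pos for a in atoms])
    rads = np.array(rads)
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = rads.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        neigh = [j for j in tree.query_ball_point(coords[i], rads[i] + rmax)
                 if j != i and np.linalg.norm(coords[j] - coords[i]) < rads[i] + rads[j]]
        pts = coords[i] + rads[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            exposed &= np.linalg.norm(pts - coords[j], axis=1) >= rads[j]
            if not exposed.any():
                break
        areas[i] = exposed.mean() * 4.0 * np.pi * rads[i] ** 2
    return areas


def sasa_partition(structure: Structure, ligand, probe: float = 1.4,
                   n_points: int = 960) -> SASAPartition:
    """Partition a ligand's isolated SASA into per-chain buried fractions.

    Protein chains are keyed by chain id; glycans and partner carotenoids
    (any other non-water het group) get their own entries keyed by residue
    label.  ``fraction_exposed`` is the ligand's SASA in the full complex
    relative to its isolated SASA.
    """
    lres = _ligand_residue(ligand)
    lig_atoms = lres.heavy_atoms()
    iso = sasa(lig_atoms, probe, n_points)
    total = float(iso.sum())
    if total <= 0:
        raise CarotenostructError(f"ligand {lres.label} has zero isolated SASA")

    groups: list[tuple[str, list[Atom]]] = []
    for chain in structure.protein_chains():
        atoms = [a for r in chain.polymer_residues() for a in r.heavy_atoms()]
        if atoms:
            groups.append((chain.chain_id, atoms))
    for res in structure.ligand_residues():
        if res is lres:
            continue
        atoms = res.heavy_atoms()
        if atoms:
            groups.append((res.label, atoms))

    nlig = len(lig_atoms)
    fractions: dict[str, float] = {}
    for key, atoms in groups:
        areas = sasa(list(lig_atoms) + atoms, probe, n_points)[:nlig]
        fractions[key] = (total - float(areas.sum())) / total
    all_atoms = list(lig_atoms) + [a for _, atoms in groups for a in atoms]
    exposed = float(sasa(all_atoms, probe, n_points)[:nlig].sum()) / total
    name = ligand.code if isinstance(ligand, LigandInstance) else lres.name
    return SASAPartition(ligand=name, total_isolated=total,
                         fraction_by_chain=fractions, fraction_exposed=exposed,
                         overlap=sum(fractions.values()) + exposed - 1.0)


# ---------------------------------------------------------------------------
# fragment B-factors
# ---------------------------------------------------------------------------

def fragment_bfactor(ligand: LigandInstance, fragment_name: str) -> FragmentBStats:
    """Unweighted mean/SD of B-factors over a template-defined fragment."""
    frags = ligand.template.end_rings
    if fragment_name not in frags:
        raise KeyError(f"{ligand.code}: no fragment {fragment_name!r}; "
                       f"have {sorted(frags)}")
    want = {normalize_atom_name(n) for n in frags[fragment_name]}
    bs = [a.b_factor for a in ligand.residue.heavy_atoms()
          if normalize_atom_name(a.name) in want]
    if not bs:
        raise CarotenostructError(f"fragment {fragment_name!r} has no atoms in model")
    arr = np.array(bs)
    return FragmentBStats(fragment=fragment_name, atom_count=len(arr),
                          mean_b=float(arr.mean()), sd_b=float(arr.std(ddof=0)))
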