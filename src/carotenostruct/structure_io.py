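"""Structure reading/writing and the atomic data model.

The in-memory model is a thin chain/residue/atom hierarchy carrying exactly
what the geometric analyses need: coordinates, elements, B-factors and
occupancies under *author* chain/residue numbering (interaction reports cite
residues the way crystallographers do, e.g. ``Ser133(A)``).  Parsing and
serialization of mmCIF/PDB are delegated to :mod:`gemmi`.

Alternate locations are resolved on input by keeping, per atom name, the
conformer with the highest occupancy (ties broken by file order), so all
downstream geometry sees a single-conformer model.  Waters are retained but
flagged and excluded from contact/H-bond analyses by default.  Hydrogens are
not expected; every geometric criterion in this package is defined on heavy
atoms.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    DimerSelectionError,
    FormatError,
    LigandMatchError,
)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: residues treated as carbohydrate (kept, but never counted as protein)
GLYCAN_NAMES = {"NAG", "NDG", "BMA", "MAN", "GAL", "FUC", "GLC", "SIA", "XYS"}


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """A single (alt-loc resolved) atom."""

    name: str
    element: str
    pos: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise FormatError(f"atom {self.name}: non-finite or non-3D position")
        if self.b_factor < 0:
            raise FormatError(f"atom {self.name}: negative B-factor")
        if not 0.0 <= self.occupancy <= 1.0:
            raise FormatError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class Residue:
    name: str
    seq_id: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    is_polymer: bool = True
    is_water: bool = False

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    @property
    def label(self) -> str:
        """Human-readable tag, e.g. ``Ser133(A)``."""
        return f"{self.name.capitalize()}{self.seq_id}({self.chain_id})"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    @property
    def is_protein(self) -> bool:
        return any(r.is_polymer for r in self.residues)


@dataclass
class Structure:
    """An ordered collection of chains plus the selected-assembly tag."""

    chains: list[Chain] = field(default_factory=list)
    assembly_id: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise FormatError("structure has no chains")

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.is_protein]

    def iter_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def ligand_residues(self, include_waters: bool = False) -> list[Residue]:
        out = []
        for r in self.iter_residues():
            if r.is_polymer:
                continue
            if r.is_water and not include_waters:
                continue
            out.append(r)
        return out

    def protein_atoms(self) -> list[Atom]:
        return [a for c in self.protein_chains() for r in c.polymer_residues()
                for a in r.atoms if a.is_heavy]


@dataclass
class LigandInstance:
    """A het residue resolved against a carotenoid template."""

    residue: Residue
    template: "object"  # CarotenoidTemplate; kept loose to avoid an import cycle
    bond_graph: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def code(self) -> str:
        return self.template.code

    @property
    def label(self) -> str:
        return self.residue.label


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _resolve_altlocs(raw: list[tuple[str, str, np.ndarray, float, float, str]]) -> list[Atom]:
    """Keep, per atom name, the conformer with highest occupancy (ties: first)."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for name, element, pos, b, occ, alt in raw:
        atom = Atom(name=name, element=element, pos=pos, b_factor=b,
                    occupancy=occ, alt_loc=alt)
        if name not in best:
            best[name] = atom
            order.append(name)
        elif occ > best[name].occupancy:
            best[name] = atom
    return [best[n] for n in order]


def _residue_is_polymer(gres: gemmi.Residue) -> bool:
    if gres.het_flag == "A":
        return True
    if gres.het_flag == "H":
        return False
    info = gemmi.find_tabulated_residue(gres.name)
    return bool(info and info.is_amino_acid())


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read an mmCIF or PDB file into the package's atomic model.

    All ATOM/HETATM records of the first model are represented; alternate
    locations collapse to the highest-occupancy conformer and waters are
    retained but flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "pdb": gemmi.CoorFormat.Pdb}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0 or len(st[0]) == 0:
        raise FormatError(f"{path}: empty model")
    st.setup_entities()

    chains: list[Chain] = []
    for gchain in st[0]:
        residues: list[Residue] = []
        for gres in gchain:
            raw = []
            for ga in gres:
                alt = ga.altloc if ga.altloc not in ("\x00", "") else ""
                raw.append((ga.name, ga.element.name,
                            np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                            float(ga.b_iso), float(min(ga.occ, 1.0)), alt))
            residues.append(Residue(
                name=gres.name,
                seq_id=gres.seqid.num,
                chain_id=gchain.name,
                atoms=_resolve_altlocs(raw),
                is_polymer=_residue_is_polymer(gres),
                is_water=gres.is_water() or gres.name in _WATER_NAMES,
            ))
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if not chains:
        raise FormatError(f"{path}: no chains with atoms")
    return Structure(chains=chains, name=path.stem)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_structure(structure: Structure, path: str | Path) -> None:
    """Write the model as mmCIF (``.cif``) or PDB (``.pdb``), by extension."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = structure.name or "model"
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            gres.het_flag = "A" if res.is_polymer else "H"
            if res.is_water:
                gres.het_flag = "H"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.b_iso = a.b_factor
                ga.occ = a.occupancy
                if a.alt_loc:
                    ga.altloc = a.alt_loc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    if path.suffix.lower() == ".pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# dimer selection
# ---------------------------------------------------------------------------

def _chain_coords(chain: Chain) -> np.ndarray:
    pts = [a.pos for r in chain.polymer_residues() for a in r.atoms if a.is_heavy]
    return np.array(pts) if pts else np.empty((0, 3))

def _ligand_sharing_pairs(structure: Structure, cutoff: float = 5.0
                          ) -> dict[tuple[str, str], int]:
    """Count, per protein-chain pair, the ligands contacting both chains."""
    from scipy.spatial import cKDTree

    trees = {}
    for chain in structure.protein_chains():
        coords = _chain_coords(chain)
        if len(coords):
            trees[chain.chain_id] = cKDTree(coords)
    pairs: dict[tuple[str, str], int] = {}
    for lig in structure.ligand_residues():
        if lig.name in GLYCAN_NAMES:
            continue
        lig_coords = np.array([a.pos for a in lig.heavy_atoms()])
        if not len(lig_coords):
            continue
        near = sorted(
            cid for cid, tree in trees.items()
            if np.any(np.asarray(tree.query(lig_coords, k=1)[0]) <= cutoff)
        )
        for i in range(len(near)):
            for j in range(i + 1, len(near)):
                key = (near[i], near[j])
                pairs[key] = pairs.get(key, 0) + 1
    return pairs


def _mean_b(chains: Iterable[Chain]) -> float:
    bs = [a.b_factor for c in chains for r in c.polymer_residues()
          for a in r.atoms if a.is_heavy]
    return float(np.mean(bs)) if bs else math.inf


def _restrict_to_dimer(structure: Structure, pair: tuple[str, str],
                       cutoff: float = 5.0) -> Structure:
    from scipy.spatial import cKDTree

    keep = [structure.get_chain(pair[0]), structure.get_chain(pair[1])]
    keep_ids = set(pair)
    coords = np.vstack([_chain_coords(c) for c in keep])
    tree = cKDTree(coords)
    chains: list[Chain] = []
    for chain in structure.chains:
        if chain.chain_id in keep_ids:
            chains.append(chain)
            continue
        # carry over non-polymer residues (ligands, glycans) near this dimer
        extra = []
        for res in chain.residues:
            if res.is_polymer:
                continue
            pts = np.array([a.pos for a in res.heavy_atoms()])
            if len(pts) and np.any(np.asarray(tree.query(pts, k=1)[0]) <= cutoff):
                extra.append(res)
        if extra:
            chains.append(Chain(chain_id=chain.chain_id, residues=extra))
    return Structure(chains=chains, assembly_id="+".join(sorted(pair)),
                     name=structure.name)


def select_dimer(structure: Structure, mode: str = "lowest_mean_b",
                 chain_ids: Sequence[str] | None = None) -> Structure:
    """Restrict a multi-copy assembly to a single heterodimer plus its ligands.

    ``lowest_mean_b`` pairs protein chains through shared ligand contacts and
    keeps the pair whose protein atoms have the lowest mean B-factor, the
    criterion crystallographers use to pick the best-ordered copy in an
    asymmetric unit.  ``by_chain_ids`` takes the two ids in *chain_ids*.
    """
    protein_ids = [c.chain_id for c in structure.protein_chains()]
    if mode == "by_chain_ids":
        if not chain_ids or len(chain_ids) != 2:
            raise DimerSelectionError("by_chain_ids requires exactly two chain ids")
        missing = [cid for cid in chain_ids if cid not in protein_ids]
        if missing:
            raise DimerSelectionError(f"chains not found: {missing}; have {protein_ids}")
        return _restrict_to_dimer(structure, (chain_ids[0], chain_ids[1]))
    if mode != "lowest_mean_b":
        raise ValueError(f"unknown mode {mode!r}")

    pairs = _ligand_sharing_pairs(structure)
    if not pairs:
        if len(protein_ids) == 2:  # single dimer, nothing to choose
            return _restrict_to_dimer(structure, (protein_ids[0], protein_ids[1]))
        raise DimerSelectionError(
            f"no ligand-sharing chain pairs found among chains {protein_ids}")
    # deterministic: sort candidates by (mean B, chain ids) so the choice is
    # independent of chain order in the file
    scored = sorted(
        (( _mean_b([structure.get_chain(a), structure.get_chain(b)]), (a, b))
         for (a, b) in pairs),
    )
    return _restrict_to_dimer(structure, scored[0][1])


# ---------------------------------------------------------------------------
# ligand matching
# ---------------------------------------------------------------------------

def normalize_atom_name(name: str) -> str:
    """Map atom-name dialects onto one spelling (``C1*``/``C1′`` -> ``C1'``)."""
    return name.strip().upper().replace("*", "'").replace("′", "'")


def match_ligands(structure: Structure, templates: Sequence["object"],
                  min_fraction: float = 0.9, return_unmatched: bool = False):
    """Resolve het residues against carotenoid templates.

    A residue matches a template when at least ``min_fraction`` of the
    template's heavy-atom names are present (after name normalization).  When
    the residue name equals a template code only that template is considered;
    otherwise all templates compete and a multi-template match is an error.
    """
    instances: list[LigandInstance] = []
    unmatched: list[Residue] = []
    by_code = {t.code: t for t in templates}
    for res in structure.ligand_residues():
        if res.name in GLYCAN_NAMES:
            continue
        present = {normalize_atom_name(a.name) for a in res.heavy_atoms()}
        candidates = [by_code[res.name]] if res.name in by_code else list(templates)
        hits = []
        for t in candidates:
            tnames = {normalize_atom_name(n) for n in t.atoms}
            if len(tnames & present) / len(tnames) >= min_fraction:
                hits.append(t)
        if len(hits) > 1:
            raise LigandMatchError(
                f"{res.label} matches several templates: {[t.code for t in hits]}")
        if not hits:
            unmatched.append(res)
            continue
        t = hits[0]
        norm_present = present
        bond_graph = [(a, b, o) for (a, b, o) in t.bonds
                      if normalize_atom_name(a) in norm_present
                      and normalize_atom_name(b) in norm_present]
        instances.append(LigandInstance(residue=res, template=t, bond_graph=bond_graph))
    if return_unmatched:
        return instances, unmatched
    return instances


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

def _round_floats(obj, ndigits: int = 4):
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, np.floating):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_round_floats(x, ndigits) for x in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _round_floats(getattr(obj, f.name), ndigits)
                for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(x, ndigits) for x in obj]
    if isinstance(obj, (Atom, Residue)):
        return _round_floats(dataclasses.asdict(obj), ndigits)
    return obj


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize an analysis result deterministically (fields in declaration
    order, floats at 4 decimals)."""
    path = Path(path)
    plain = _round_floats(report)
    try:
        if format == "json":
            path.write_text(json.dumps(plain, indent=2) + "\n")
        elif format == "tsv":
            rows = plain if isinstance(plain, list) else [plain]
            if rows and not isinstance(rows[0], dict):
                rows = [{"value": r} for r in rows]
            cols = list(rows[0].keys()) if rows else []
            lines = ["\t".join(cols)]
            for row in rows:
                lines.append("\t".join(_fmt_cell(row.get(c)) for c in cols))
            path.write_text("\n".join(lines) + "\n")
        else:
            raise ValueError(f"unknown report format {format!r}")
    except OSError as exc:
        raise IOError(f"cannot write report to {path}: {exc}") from exc


def _fmt_cell(v) -> str:
    if isinstance(v, float):
        return f"{v:.4f}"
    if isinstance(v, (dict, list)):
        return json.dumps(v)
    return "" if v is None else str(v)
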