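"""End-to-end analyses of deposited reference structures.

Drives the whole pipeline against real depositions when the coordinate
files are available locally (they are not shipped with the package; see
``scripts/fetch_reference_data.py``):

* the blue carotenoprotein heterodimer (PDB 8I34) -- dimer selection by
  lowest mean B, AXT/MXT ligand matching, subunit superposition, carotenoid
  pair geometry, SASA partition, contact shells, hydrogen bonds and
  end-ring B-factors;
* beta-crustacyanin (PDB 1GKA) -- the AXT1/AXT2 crossing dihedral and axis
  relation used as the comparative benchmark;
* the human ependymin-related protein dimer (PDB 6E8N) -- dimer-level
  superposition against the carotenoprotein dimer.

Each function returns a flat dict of named quantities so callers (tests,
scripts) can compare against published values.
"""

from __future__ import annotations

from pathlib import Path

from . import interaction_analysis as ia
from . import superposition as sp
from .carotenoid_geometry import (
    bla_for_ligand,
    builtin_templates,
    pair_geometry,
    pseudo_twofold_axes,
    ring_conformation,
)
from .structure_io import Structure, match_ligands, read_structure, select_dimer

DEFAULT_DATA_DIR = Path("data") / "reference"


def load_reference_structure(pdb_id: str, data_dir: str | Path | None = None
                             ) -> Structure:
    """Load a locally cached deposition (``<data_dir>/<pdb_id>.cif|.pdb``)."""
    base = Path(data_dir) if data_dir else DEFAULT_DATA_DIR
    for ext in (".cif", ".pdb"):
        path = base / f"{pdb_id.upper()}{ext}"
        if path.exists():
            return read_structure(path)
    raise FileNotFoundError(
        f"reference structure {pdb_id} not found under {base}/ -- deposited "
        "coordinates are not distributed with this package; run "
        "scripts/fetch_reference_data.py (requires network access) first")


def _ligand_by_code(ligands, code: str):
    for lig in ligands:
        if lig.code == code:
            return lig
    raise KeyError(f"no ligand matched template {code}; have "
                   f"{[l.code for l in ligands]}")


def analyze_carotenoprotein(structure: Structure) -> dict:
    """Full analysis of the AXT/MXT-binding heterodimer deposition."""
    dimer = select_dimer(structure, mode="lowest_mean_b")
    templates = list(builtin_templates().values())
    ligands = match_ligands(dimer, templates, min_fraction=0.8)
    axt = _ligand_by_code(ligands, "AXT")
    mxt = _ligand_by_code(ligands, "MXT")
    chains = dimer.protein_chains()
    sup = sp.superpose_chains(chains[0], chains[1])
    crossing = [("B", "C9"), ("B", "C15"), ("A", "C15"), ("A", "C9")]
    geom = pair_geometry(axt, mxt, crossing_quadruple=crossing)
    axes = pseudo_twofold_axes(dimer, axt, mxt)
    part_axt = ia.sasa_partition(dimer, axt)
    part_mxt = ia.sasa_partition(dimer, mxt)
    shell_axt = ia.contact_residues(dimer, axt, cutoff=4.0)
    hbonds_mxt = ia.hydrogen_bonds(dimer, mxt)
    ring_b = ia.fragment_bfactor(axt, "beta")
    ring_bp = ia.fragment_bfactor(axt, "beta_prime")
    out = {
        "selected_dimer": dimer.assembly_id,
        "subunit_rmsd_angstrom": sup.rmsd,
        "subunit_n_matched": sup.n_matched,
        "crossing_dihedral_deg": geom.crossing_dihedral,
        "polyene_min_distance_angstrom": geom.min_distance,
        "interplanar_angle_deg": geom.interplanar_angle,
        "axis_angle_deg": axes.axis_angle,
        "axis_klass": axes.axis_klass,
        "axt_ring_conformation_6": ring_conformation(axt, "C5-C6-C7-C8").klass,
        "axt_ring_conformation_6p": ring_conformation(axt, "C5'-C6'-C7'-C8'").klass,
        "axt_bla_angstrom": bla_for_ligand(axt).bla,
        "mxt_bla_angstrom": bla_for_ligand(mxt).bla,
        "axt_beta_ring_mean_b": ring_b.mean_b,
        "axt_beta_prime_ring_mean_b": ring_bp.mean_b,
        "axt_contact_shell": shell_axt.labels(),
        "mxt_hbond_partners": sorted({hb.donor.label.split(":")[0]
                                      for hb in hbonds_mxt}
                                     | {hb.acceptor.label.split(":")[0]
                                        for hb in hbonds_mxt}),
    }
    out["axt_sasa_fraction_by_chain"] = {
        k: round(v, 4) for k, v in part_axt.fraction_by_chain.items()}
    out["mxt_sasa_fraction_by_chain"] = {
        k: round(v, 4) for k, v in part_mxt.fraction_by_chain.items()}
    return out


def analyze_crustacyanin(structure: Structure) -> dict:
    """Crossing dihedral and axis relation for the two AXTs of crustacyanin."""
    dimer = select_dimer(structure, mode="lowest_mean_b")
    templates = [builtin_templates()["AXT"]]
    ligands = match_ligands(dimer, templates, min_fraction=0.8)
    if len(ligands) < 2:
        raise RuntimeError(f"expected two AXT copies, matched {len(ligands)}")
    axt1, axt2 = ligands[0], ligands[1]
    crossing = [("A", "C6'"), ("A", "C12'"), ("B", "C12'"), ("B", "C6'")]
    geom = pair_geometry(axt1, axt2, crossing_quadruple=crossing)
    axes = pseudo_twofold_axes(dimer, axt1, axt2)
    return {
        "crossing_dihedral_deg": geom.crossing_dihedral,
        "polyene_min_distance_angstrom": geom.min_distance,
        "axis_angle_deg": axes.axis_angle,
        "axis_klass": axes.axis_klass,
    }


def compare_dimers(carotenoprotein: Structure, epdr1: Structure) -> dict:
    """Dimer-level C-alpha superposition of the two folds."""
    dA = select_dimer(carotenoprotein, mode="lowest_mean_b")
    dB = select_dimer(epdr1, mode="lowest_mean_b")
    sup = sp.superpose_dimers(dA, dB)
    return {"dimer_rmsd_angstrom": sup.rmsd, "dimer_n_matched": sup.n_matched}
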