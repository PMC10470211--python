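"""Sequence-level annotations for secreted carotenoprotein subunits.

Covers the bookkeeping around a secreted glycoprotein's primary structure:
N-glycosylation sequons (Asn-x-Thr, x != Pro; optionally Asn-x-Ser/Thr),
signal-peptide cleavage (the cleavage position is a user-supplied fact, e.g.
from Edman sequencing of the mature N terminus -- no prediction is done
here), conserved-cysteine profiling, and monoisotopic exact masses for
carotenoid molecular formulas and their ESI adducts.

Masses use pinned IUPAC/CODATA monoisotopic values; charged adducts are
electron-corrected ([M+H]+ adds a proton and removes an electron).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from .errors import FormulaError, SequenceError, UnknownElementError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: monoisotopic masses, Da (IUPAC 2021 atomic-mass evaluation values)
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "NA": 22.98976928,
    "K": 38.9637064864,
    "CL": 34.968852682,
}
ELECTRON_MASS = 0.00054858

ADDUCTS = {
    "M": (0.0, 0),
    "[M+H]+": (MONOISOTOPIC_MASS["H"], 1),
    "[M+Na]+": (MONOISOTOPIC_MASS["NA"], 1),
}


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    signal_cleavage: int | None = None  # mature chain starts at cleavage+1 (1-based)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - AMINO_ACIDS - {"X"}
        if bad:
            raise SequenceError(f"{self.id}: invalid residue letters {sorted(bad)}")
        if self.signal_cleavage is not None and not (
                0 < self.signal_cleavage < len(self.sequence)):
            raise SequenceError(f"{self.id}: cleavage position out of range")


@dataclass
class SequonHit:
    position: int            # 1-based on the scanned sequence
    triplet: str
    mature_position: int | None = None  # 1-based on the mature chain, if known


@dataclass
class CysteineProfile:
    positions: list[int]     # 1-based, mature numbering
    count: int
    profile_label: str       # pattern-table match or "unclassified"


@dataclass
class MassResult:
    formula: dict[str, int]
    adduct: str
    mz: float


# ---------------------------------------------------------------------------
# sequons
# ---------------------------------------------------------------------------

def scan_sequons(record: ProteinRecord, pattern: str = "NxT") -> list[SequonHit]:
    """All N-x-[T|S/T] motifs with x != P, on precursor numbering.

    When the signal cleavage is known each hit also carries its mature-chain
    position (negative/None for hits inside the signal peptide).
    """
    if pattern == "NxT":
        third = {"T"}
    elif pattern in ("NxS/T", "NxST"):
        third = {"S", "T"}
    else:
        raise ValueError(f"unknown sequon pattern {pattern!r}")
    seq = record.sequence
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in third:
            mature = None
            if record.signal_cleavage is not None:
                m = i + 1 - record.signal_cleavage
                mature = m if m >= 1 else None
            hits.append(SequonHit(position=i + 1, triplet=seq[i:i + 3],
                                  mature_position=mature))
    return hits


def mature_sequence(record: ProteinRecord) -> str:
    """Suffix after the signal-peptide cleavage position."""
    if record.signal_cleavage is None:
        raise SequenceError(f"{record.id}: signal cleavage position not set")
    return record.sequence[record.signal_cleavage:]


def edman_prefix_match(sequence: str, edman: str, wildcard: str = "X") -> bool:
    """Does an N-terminal Edman read (with wildcards) prefix-match a chain?"""
    seq = sequence.upper()
    read = edman.upper()
    if len(read) > len(seq):
        return False
    return all(e == wildcard or e == s for e, s in zip(read, seq))


# ---------------------------------------------------------------------------
# cysteine profiles
# ---------------------------------------------------------------------------

def _load_profile_table() -> dict:
    text = resources.files("carotenostruct").joinpath(
        "data/cysteine_profiles.json").read_text()
    return json.loads(text)


def cysteine_profile(record: ProteinRecord | str,
                     pattern_table: dict | None = None) -> CysteineProfile:
    """Cysteine positions/count on the mature chain, with an advisory label.

    The label is assigned only when exactly one pattern-table row matches the
    observed count and coarse gap classes; otherwise ``unclassified``.  The
    shipped table is a reconstruction (see its ``_comment``) and the label is
    advisory -- positions and count are always exact.
    """
    if isinstance(record, ProteinRecord):
        seq = (mature_sequence(record) if record.signal_cleavage is not None
               else record.sequence)
    else:
        seq = record.upper()
    positions = [i + 1 for i, c in enumerate(seq) if c == "C"]
    table = pattern_table if pattern_table is not None else _load_profile_table()
    short_max = table.get("short_gap_max", 40)
    gaps = [positions[i + 1] - positions[i] for i in range(len(positions) - 1)]
    gap_classes = ["short" if g <= short_max else "long" for g in gaps]
    matches = []
    for row in table.get("profiles", []):
        if row["count"] != len(positions):
            continue
        want = row.get("gap_classes")
        if want is not None and list(want) != gap_classes:
            continue
        matches.append(row["name"])
    label = matches[0] if len(set(matches)) == 1 and matches else "unclassified"
    return CysteineProfile(positions=positions, count=len(positions),
                           profile_label=label)


# ---------------------------------------------------------------------------
# exact mass
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula.replace(" ", "")):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at {pos}")
        pos = m.end()
        if not m.group(1):
            continue
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula.replace(" ", "")) or not counts:
        raise FormulaError(f"cannot parse formula {formula!r}")
    return counts


def exact_mass(formula: str | dict[str, int], adduct: str = "M") -> MassResult:
    """Monoisotopic m/z of a molecular formula under an ESI adduct."""
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    mass = 0.0
    for el, n in counts.items():
        m = MONOISOTOPIC_MASS.get(el.upper())
        if m is None:
            raise UnknownElementError(f"no monoisotopic mass for element {el!r}")
        mass += m * n
    if adduct not in ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; have {sorted(ADDUCTS)}")
    extra, charge = ADDUCTS[adduct]
    mz = mass + extra - charge * ELECTRON_MASS
    if charge:
        mz /= charge
    return MassResult(formula=counts, adduct=adduct, mz=mz)
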