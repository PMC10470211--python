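"""Sequence-guided rigid-body superposition with Kabsch RMSD.

Chains are matched through a global pairwise sequence alignment (BLOSUM62,
affine gaps) and superposed over the matched C-alpha atoms by the Kabsch
least-squares rotation (proper rotations only; a reflection is never
chosen).  Optional iterative trimming removes C-alpha pairs deviating by
more than ``trim_sigma`` times the current RMSD and refits, emulating the
outlier rejection structure-comparison servers apply before quoting an RMSD
over "n matched atoms".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DegenerateGeometryError, SequenceError
from .structure_io import Chain, Structure

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U", "PYL": "O",
}
_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class AlignmentResult:
    pairs: list[tuple[int, int]]     # matched (iA, iB) residue indices, 0-based
    identity: float                  # identical / aligned columns, end gaps excluded
    score: float
    alignedA: str
    alignedB: str


@dataclass
class SuperpositionResult:
    n_matched: int
    rmsd: float
    rotation: np.ndarray = field(repr=False)      # 3x3, det +1; maps A onto B
    translation: np.ndarray = field(repr=False)   # b ~ R @ a + t
    rotation_angle: float                         # degrees
    rotation_axis: np.ndarray = field(repr=False)
    trimmed: list = field(default_factory=list)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# sequence alignment
# ---------------------------------------------------------------------------

def align_sequences(seqA: str, seqB: str, substitution_table: str = "BLOSUM62",
                    gap_open: float = 10.0, gap_extend: float = 0.5,
                    ) -> AlignmentResult:
    """Global alignment with affine gaps; identity excludes terminal gaps."""
    for seq in (seqA, seqB):
        if not seq:
            raise SequenceError("empty sequence")
        bad = set(seq.upper()) - _ALPHABET
        if bad:
            raise SequenceError(f"invalid residue letters: {sorted(bad)}")
    matrix = substitution_matrices.load(substitution_table)
    aligner = Align.PairwiseAligner(
        mode="global", substitution_matrix=matrix,
        open_gap_score=-abs(gap_open), extend_gap_score=-abs(gap_extend))
    aln = aligner.align(seqA.upper(), seqB.upper())[0]
    gA, gB = str(aln[0]), str(aln[1])

    def span(g: str) -> tuple[int, int]:
        first = len(g) - len(g.lstrip("-"))
        last = len(g.rstrip("-")) - 1
        return first, last

    a0, a1 = span(gA)
    b0, b1 = span(gB)
    start, end = max(a0, b0), min(a1, b1)
    ncols = max(end - start + 1, 0)
    ident = sum(1 for k in range(start, end + 1)
                if gA[k] == gB[k] and gA[k] != "-")
    pairs: list[tuple[int, int]] = []
    iA = iB = 0
    for ca, cb in zip(gA, gB):
        if ca != "-" and cb != "-":
            pairs.append((iA, iB))
        iA += ca != "-"
        iB += cb != "-"
    return AlignmentResult(pairs=pairs,
                           identity=ident / ncols if ncols else 0.0,
                           score=float(aln.score), alignedA=gA, alignedB=gB)


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------

def kabsch(coordsA, coordsB) -> SuperpositionResult:
    """Least-squares proper rotation superposing A onto B (SVD form)."""
    A = np.asarray(coordsA, dtype=float)
    B = np.asarray(coordsB, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matched n x 3 arrays")
    if len(A) < 3:
        raise ValueError("need at least 3 matched points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    for M in (A0, B0):
        s = np.linalg.svd(M, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError("collinear point set; rotation ill-defined")
    H = A0.T @ B0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = A0 @ R.T - B0
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    from scipy.spatial.transform import Rotation
    rv = Rotation.from_matrix(R).as_rotvec()
    ang = float(np.linalg.norm(rv))
    axis = rv / ang if ang > 1e-12 else np.array([0.0, 0.0, 1.0])
    return SuperpositionResult(n_matched=len(A), rmsd=rmsd, rotation=R,
                               translation=t, rotation_angle=float(np.degrees(ang)),
                               rotation_axis=axis)


# ---------------------------------------------------------------------------
# chain / dimer superposition
# ---------------------------------------------------------------------------

def chain_sequence_and_calphas(chain: Chain) -> tuple[str, np.ndarray, list]:
    seq, coords, residues = [], [], []
    for res in chain.polymer_residues():
        ca = res.get_atom("CA")
        if ca is None:
            continue
        seq.append(_AA3TO1.get(res.name, "X"))
        coords.append(ca.pos)
        residues.append(res)
    if not seq:
        raise SequenceError(f"chain {chain.chain_id} has no C-alpha atoms")
    return "".join(seq), np.array(coords), residues


TRIM_FLOOR = 1e-4  # A; below this an already-exact fit is never "trimmed"


def _iterative_fit(A: np.ndarray, B: np.ndarray, labels: list,
                   trim_sigma: float | None, max_iter: int) -> SuperpositionResult:
    keep = np.ones(len(A), dtype=bool)
    trimmed: list = []
    result = kabsch(A, B)
    if trim_sigma is not None:
        for _ in range(max_iter):
            dev = np.linalg.norm(A[keep] @ result.rotation.T
                                 + result.translation - B[keep], axis=1)
            bad = dev > max(trim_sigma * result.rmsd, TRIM_FLOOR)
            if not bad.any() or keep.sum() - bad.sum() < 3:
                break
            idx = np.where(keep)[0][bad]
            keep[idx] = False
            trimmed.extend(labels[i] for i in idx)
            result = kabsch(A[keep], B[keep])
    result.trimmed = trimmed
    return result


def superpose_chains(chainA: Chain, chainB: Chain, trim_sigma: float | None = 2.0,
                     max_iter: int = 10) -> SuperpositionResult:
    """Superpose two chains over sequence-aligned C-alpha pairs."""
    seqA, cA, resA = chain_sequence_and_calphas(chainA)
    seqB, cB, resB = chain_sequence_and_calphas(chainB)
    aln = align_sequences(seqA, seqB)
    if len(aln.pairs) < 3:
        raise DegenerateGeometryError(
            f"only {len(aln.pairs)} matched residue pairs; need >= 3")
    A = np.array([cA[i] for i, _ in aln.pairs])
    B = np.array([cB[j] for _, j in aln.pairs])
    labels = [(resA[i].label, resB[j].label) for i, j in aln.pairs]
    return _iterative_fit(A, B, labels, trim_sigma, max_iter)


def superpose_dimers(dimerA: Structure, dimerB: Structure,
                     trim_sigma: float | None = 2.0, max_iter: int = 10,
                     ) -> SuperpositionResult:
    """Superpose two two-chain assemblies with a single rigid transform.

    Both chain pairings are tried (first-to-first and crossed) and the one
    giving the lower RMSD is kept.
    """
    chA = dimerA.protein_chains()
    chB = dimerB.protein_chains()
    if len(chA) < 2 or len(chB) < 2:
        raise ValueError("each assembly must contain two protein chains")
    best: SuperpositionResult | None = None
    for pairing in ((0, 1), (1, 0)):
        A_all, B_all, labels = [], [], []
        for ia, ib in zip((0, 1), pairing):
            seqA, cA, resA = chain_sequence_and_calphas(chA[ia])
            seqB, cB, resB = chain_sequence_and_calphas(chB[ib])
            aln = align_sequences(seqA, seqB)
            A_all.extend(cA[i] for i, _ in aln.pairs)
            B_all.extend(cB[j] for _, j in aln.pairs)
            labels.extend((resA[i].label, resB[j].label) for i, j in aln.pairs)
        if len(A_all) < 3:
            continue
        res = _iterative_fit(np.array(A_all), np.array(B_all), labels,
                             trim_sigma, max_iter)
        if best is None or res.rmsd < best.rmsd:
            best = res
    if best is None:
        raise DegenerateGeometryError("no chain pairing yielded >= 3 matched pairs")
    return best
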