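"""Residue correspondence between two chains and superposed Cα RMSD.

For conformer pairs of the same protein (point mutants, alternative crystal
forms) a global sequence alignment recovers the topologically equivalent
residue pairs; an optional refinement stage iteratively superposes the mapped
Cα atoms and discards pairs that deviate by more than a distance cap,
approximating the aligned-core RMSD of structure-alignment tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure_io import ChainModel

logger = logging.getLogger(__name__)

GAP_OPEN = -10.0
GAP_EXTEND = -0.5
REFINE_DISTANCE_CAP = 5.0   # Å, pair rejection during sequence+refine
REFINE_MAX_ROUNDS = 10


class AlignmentError(ValueError):
    """Raised when no usable residue correspondence can be established."""


@dataclass
class ResidueMapping:
    """Ordered one-to-one pairs of (wildtype, mutant) sequence indices."""

    pairs: list[tuple[int, int]]
    coverage_wt: float
    coverage_mut: float

    def __post_init__(self):
        wt = [a for a, _ in self.pairs]
        mut = [b for _, b in self.pairs]
        if len(set(wt)) != len(wt) or len(set(mut)) != len(mut):
            raise ValueError("mapping must be one-to-one")
        if wt != sorted(wt) or mut != sorted(mut):
            raise ValueError("mapping must be order-preserving on both chains")

    @property
    def n(self) -> int:
        return len(self.pairs)

    def to_table(self, wt: ChainModel, mut: ChainModel):
        import pandas as pd

        rows = []
        for a, b in self.pairs:
            ra, rb = wt.residues[a], mut.residues[b]
            rows.append(
                {
                    "wt_chain": ra.chain_id, "wt_resnum": ra.seq_number,
                    "wt_icode": ra.insertion_code, "wt_name3": ra.name3,
                    "mut_chain": rb.chain_id, "mut_resnum": rb.seq_number,
                    "mut_icode": rb.insertion_code, "mut_name3": rb.name3,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SuperpositionResult:
    """Least-squares rigid-body fit of one coordinate set onto another."""

    rotation: np.ndarray      # 3×3 proper rotation
    translation: np.ndarray   # 3-vector, Å
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Kabsch fit of ``coords_b`` onto ``coords_a`` (rows correspond by index).

    Reflections are disallowed: the rotation determinant is +1.  Degenerate
    (collinear or coincident) point sets do not raise; the returned rotation is
    then one of the equally optimal fits selected by the SVD.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matching n×3 arrays")
    if a.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    if np.array_equal(a, b):
        # identical sets superpose exactly; skip the eigensolver noise
        return SuperpositionResult(rotation=np.eye(3), translation=np.zeros(3), rmsd=0.0)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    p, q = b - cb, a - ca
    cov = p.T @ q
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = p @ rot.T + ca
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=ca - cb @ rot.T, rmsd=rmsd)


def _global_alignment_pairs(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Aligned non-gap columns of a global BLOSUM62 alignment."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def align_chains(wt: ChainModel, mut: ChainModel, mode: str = "sequence") -> ResidueMapping:
    """Topologically equivalent residue pairs between two chains.

    mode="sequence": global Needleman–Wunsch (BLOSUM62, affine gaps) of the
    one-letter sequences; aligned non-gap columns become pairs.
    mode="sequence+refine": additionally superpose on the current pairs'
    Cα atoms and drop pairs deviating by more than 5 Å, iterating to
    convergence — a proxy for a structure-based common core.
    """
    if len(wt) == 0 or len(mut) == 0:
        raise AlignmentError("cannot align an empty chain")
    if mode not in {"sequence", "sequence+refine"}:
        raise ValueError(f"unknown alignment mode {mode!r}")
    pairs = _global_alignment_pairs(wt.sequence, mut.sequence)
    if not pairs:
        raise AlignmentError("alignment produced zero residue pairs")
    if mode == "sequence+refine":
        ca_wt, ca_mut = wt.ca_coords(), mut.ca_coords()
        for _ in range(REFINE_MAX_ROUNDS):
            usable = [
                (a, b) for a, b in pairs
                if not (np.isnan(ca_wt[a]).any() or np.isnan(ca_mut[b]).any())
            ]
            if len(usable) < 3:
                raise AlignmentError("fewer than 3 Cα pairs; superposition underdetermined")
            idx_a = [a for a, _ in usable]
            idx_b = [b for _, b in usable]
            fit = superpose(ca_wt[idx_a], ca_mut[idx_b])
            moved = fit.transform(ca_mut[idx_b])
            dev = np.linalg.norm(moved - ca_wt[idx_a], axis=1)
            kept = [p for p, d in zip(usable, dev) if d <= REFINE_DISTANCE_CAP]
            if len(kept) == len(pairs):
                pairs = kept
                break
            pairs = kept
        if not pairs:
            raise AlignmentError("refinement discarded all residue pairs")
    if len(pairs) < 3:
        raise AlignmentError("fewer than 3 aligned pairs; superposition underdetermined")
    return ResidueMapping(
        pairs=pairs,
        coverage_wt=len(pairs) / len(wt),
        coverage_mut=len(pairs) / len(mut),
    )


def ca_rmsd(wt: ChainModel, mut: ChainModel, mapping: ResidueMapping) -> float:
    """Cα RMSD over the mapped residue pairs after Kabsch superposition.

    Pairs where either residue lacks a Cα are dropped with a warning.
    """
    ca_wt, ca_mut = wt.ca_coords(), mut.ca_coords()
    usable = [
        (a, b) for a, b in mapping.pairs
        if not (np.isnan(ca_wt[a]).any() or np.isnan(ca_mut[b]).any())
    ]
    if len(usable) < len(mapping.pairs):
        logger.warning("dropped %d mapped pairs lacking Cα", len(mapping.pairs) - len(usable))
    if len(usable) < 3:
        raise AlignmentError("fewer than 3 Cα pairs for RMSD")
    idx_a = [a for a, _ in usable]
    idx_b = [b for _, b in usable]
    return superpose(ca_wt[idx_a], ca_mut[idx_b]).rmsd
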