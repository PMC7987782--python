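"""Synthetic structure pairs with controlled perturbation regimes.

Real wildtype/mutant conformer pairs fall on a spectrum between two regimes:
side-chain repacking with a preserved backbone (low Cα RMSD yet substantial
network change) and rigid backbone motion, e.g. a hinge bend, with locally
preserved contact networks (high Cα RMSD yet a similar network).  This module
generates idealized α-helical chains with pseudo-side-chains and applies
either perturbation deterministically per seed, so every pipeline stage can
be exercised — and those two regimes distinguished — without any downloaded
structure.

Pseudo-side-chains carry the correct heavy-atom count for each residue type
but simplified geometry (atoms stacked along the Cα outward normal with a
small seeded jitter): the contact network depends only on atom positions and
counts, so this exercises every code path without a rotamer library.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import (
    AtomRecord,
    ChainModel,
    ResidueUnit,
    ONE_TO_THREE,
    THREE_TO_ONE,
)

# idealized α-helix geometry
HELIX_RISE = 1.5        # Å per residue along the axis
HELIX_TURN_DEG = 100.0  # rotation per residue
HELIX_RADIUS = 2.3      # Å, Cα distance from the axis

SIDECHAIN_JITTER = 0.3   # Å, max displacement of pseudo-side-chain atoms
SIDECHAIN_SPACING = 1.5  # Å between stacked pseudo-atoms

#: heavy side-chain atom counts of the 20 standard residue types
SIDECHAIN_ATOM_COUNTS = {
    "GLY": 0, "ALA": 1, "SER": 2, "CYS": 2, "THR": 3, "VAL": 3, "PRO": 3,
    "ASP": 4, "ASN": 4, "ILE": 4, "LEU": 4, "MET": 4, "GLU": 5, "GLN": 5,
    "LYS": 5, "HIS": 6, "ARG": 7, "PHE": 7, "TYR": 8, "TRP": 10,
}

_SIDECHAIN_NAMES = ["CB", "CG", "CD", "CE", "CZ", "CH1", "CH2", "CH3", "CH4", "CH5"]

BACKBONE_NAMES = ("N", "CA", "C", "O")

SCENARIO_NAMES = ("identity", "sidechain_repack", "hinge_bend", "point_mutation")


@dataclass
class SyntheticScenario:
    """A named perturbation regime with its parameters; the seed fixes everything."""

    name: str
    n_res: int = 60
    seed: int = 0
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIO_NAMES}")
        if self.n_res < 10:
            raise ValueError("n_res must be ≥ 10 for a non-trivial network")


def _helix_ca(i: float) -> np.ndarray:
    theta = np.deg2rad(HELIX_TURN_DEG) * i
    return np.array(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )


def _helix_frame(i: float) -> tuple[np.ndarray, np.ndarray]:
    """(tangent, outward normal) of the helix curve at residue index i."""
    tangent = _helix_ca(i + 0.5) - _helix_ca(i - 0.5)
    tangent /= np.linalg.norm(tangent)
    theta = np.deg2rad(HELIX_TURN_DEG) * i
    outward = np.array([np.cos(theta), np.sin(theta), 0.0])
    return tangent, outward


def _backbone_atoms(i: int) -> list[AtomRecord]:
    """Idealized N, CA, C, O for residue i; the carbonyl O points along the
    helix axis toward the amide N of residue i+4, as in a hydrogen-bonded
    α-helix, so i/i±3/i±4 backbone contacts all form."""
    ca = _helix_ca(i)
    tangent, outward = _helix_frame(i)
    up = np.cross(tangent, outward)
    n_pos = ca - 1.2 * tangent + 0.4 * up
    c_pos = ca + 1.2 * tangent + 0.2 * up
    t4, u4 = _helix_frame(i + 4)
    up4 = np.cross(t4, u4)
    n4_pos = _helix_ca(i + 4) - 1.2 * t4 + 0.4 * up4
    o_dir = n4_pos - c_pos
    o_dir /= np.linalg.norm(o_dir)
    return [
        AtomRecord("N", "N", n_pos),
        AtomRecord("CA", "C", ca),
        AtomRecord("C", "C", c_pos),
        AtomRecord("O", "O", c_pos + 1.23 * o_dir),
    ]


def random_sequence(n_res: int, seed: int) -> str:
    """Deterministic sequence covering all 20 types as evenly as length allows."""
    rng = np.random.default_rng(seed)
    letters = sorted(ONE_TO_THREE)
    base = (letters * (n_res // 20 + 1))[:n_res]
    return "".join(rng.permutation(base))


def make_chain(
    n_res: int, sequence: str | None = None, seed: int = 0, pdb_id: str = "SYNT"
) -> ChainModel:
    """Idealized α-helical chain with pseudo-side-chains, deterministic per seed.

    ``sequence`` is a one-letter string of length ``n_res`` (poly-alanine when
    omitted).  Backbone N, CA, C, O atoms follow the helix; each residue's
    side-chain pseudo-atoms are stacked outward from the Cα with seeded
    jitter ≤ 0.3 Å.
    """
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    bad = [c for c in sequence if c not in ONE_TO_THREE]
    if bad:
        raise ValueError(f"non-standard residue letter {bad[0]!r}")
    rng = np.random.default_rng(seed)
    residues = []
    for i, letter in enumerate(sequence):
        name3 = ONE_TO_THREE[letter]
        ca = _helix_ca(i)
        _, outward = _helix_frame(i)
        atoms = _backbone_atoms(i)
        atoms.extend(_sidechain_atoms(name3, ca, outward, rng))
        residues.append(
            ResidueUnit(
                chain_id="A",
                seq_number=i + 1,
                insertion_code="",
                name3=name3,
                atoms=atoms,
            )
        )
    return ChainModel(pdb_id=pdb_id, chain_id="A", residues=residues,
                      resolution=1.5, r_free=0.22, r_work=0.19)


def _sidechain_atoms(
    name3: str, ca: np.ndarray, outward: np.ndarray, rng: np.random.Generator
) -> list[AtomRecord]:
    atoms = []
    for k in range(SIDECHAIN_ATOM_COUNTS[name3]):
        jitter_dir = rng.normal(size=3)
        jitter_dir /= np.linalg.norm(jitter_dir)
        jitter = jitter_dir * (SIDECHAIN_JITTER * rng.random())
        pos = ca + (1.0 + SIDECHAIN_SPACING * k) * outward + jitter
        atoms.append(AtomRecord(_SIDECHAIN_NAMES[k], "C", pos))
    return atoms


def perturb_sidechains(
    chain: ChainModel, fraction: float, magnitude: float, seed: int = 0
) -> ChainModel:
    """Displace the side chains of a seeded random residue subset; backbone untouched.

    Each selected residue's pseudo-side-chain atoms move by independent random
    vectors of norm ≤ ``magnitude``; N, CA, C, O coordinates are bitwise
    unchanged.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be ≥ 0")
    out = copy.deepcopy(chain)
    rng = np.random.default_rng(seed)
    n = len(out.residues)
    n_pick = int(round(fraction * n))
    picked = set(rng.choice(n, size=n_pick, replace=False).tolist()) if n_pick else set()
    for i in sorted(picked):
        for atom in out.residues[i].atoms:
            if atom.name in BACKBONE_NAMES:
                continue
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            atom.position = atom.position + direction * (magnitude * rng.uniform(0.5, 1.0))
    return out


def hinge_bend(chain: ChainModel, pivot: int, angle: float, seed: int = 0) -> ChainModel:
    """Rigidly rotate all residues after ``pivot`` about an axis through its Cα.

    The axis is perpendicular to the helix axis (the construction's z axis),
    so a nonzero ``angle`` (degrees) bends the chain at the pivot while
    preserving all pairwise distances within each segment.
    """
    n = len(chain.residues)
    if not (0 < pivot < n - 1):
        raise ValueError(f"pivot must lie strictly inside the chain (got {pivot} for n={n})")
    out = copy.deepcopy(chain)
    if angle == 0.0:
        return out  # rotation by zero is the exact identity
    pivot_ca = out.residues[pivot].ca
    if pivot_ca is None:
        raise ValueError("pivot residue has no Cα")
    center = pivot_ca.position.copy()
    rot = Rotation.from_rotvec(np.deg2rad(angle) * np.array([1.0, 0.0, 0.0]))
    for res in out.residues[pivot + 1:]:
        for atom in res.atoms:
            atom.position = rot.apply(atom.position - center) + center
    return out


def mutate_residue(chain: ChainModel, position: int, new_type: str, seed: int = 0) -> ChainModel:
    """Point substitution: swap residue type and regenerate its pseudo-side-chain."""
    name3 = ONE_TO_THREE.get(new_type, new_type)
    if name3 not in THREE_TO_ONE:
        raise ValueError(f"unknown residue type {new_type!r}")
    out = copy.deepcopy(chain)
    res = out.residues[position]
    ca = res.ca
    if ca is None:
        raise ValueError("mutated residue has no Cα")
    _, outward = _helix_frame(position)
    rng = np.random.default_rng(seed)
    res.name3 = name3
    res.atoms = [a for a in res.atoms if a.name in BACKBONE_NAMES]
    res.atoms.extend(_sidechain_atoms(name3, ca.position, outward, rng))
    return out


def make_pair(scenario: SyntheticScenario) -> tuple[ChainModel, ChainModel, dict]:
    """Wildtype-like and perturbed chain for a scenario, plus qualitative expectations.

    The expectation record states what downstream comparison of the pair must
    show: whether the Cα RMSD is exactly zero, whether the NDS is zero or
    positive, and whether lost/gained edge classes may be populated.
    """
    p = scenario.parameters
    seq = p.get("sequence") or random_sequence(scenario.n_res, scenario.seed)
    wt = make_chain(scenario.n_res, seq, seed=scenario.seed)

    if scenario.name == "identity":
        mut = copy.deepcopy(wt)
        expect = {"rmsd_zero": True, "nds_zero": True, "network_change": False}
    elif scenario.name == "sidechain_repack":
        # two independently repacked conformers of one backbone: each has
        # side-chain contacts the other lacks, so edges are both lost and
        # gained while the Cα trace stays identical
        fraction = p.get("fraction", 0.5)
        magnitude = p.get("magnitude", 3.0)
        wt = perturb_sidechains(wt, fraction, magnitude, seed=scenario.seed + 1)
        mut = perturb_sidechains(
            make_chain(scenario.n_res, seq, seed=scenario.seed),
            fraction, magnitude, seed=scenario.seed + 2,
        )
        expect = {"rmsd_zero": True, "nds_zero": False, "network_change": True}
    elif scenario.name == "hinge_bend":
        pivot = p.get("pivot", (3 * scenario.n_res) // 4)
        mut = hinge_bend(wt, pivot=pivot, angle=p.get("angle", 60.0))
        expect = {
            "rmsd_zero": False, "nds_zero": False,
            "network_change": True, "rmsd_above": 1.0, "pivot": pivot,
        }
    elif scenario.name == "point_mutation":
        position = p.get("position", scenario.n_res // 2)
        target = p.get("target", "TRP")
        mut = mutate_residue(wt, position, target, seed=scenario.seed + 1)
        expect = {
            "rmsd_zero": True, "nds_zero": False,
            "network_change": True, "mutated_position": position,
        }
    else:  # unreachable: SyntheticScenario validates the name
        raise ValueError(scenario.name)
    return wt, mut, expect


# ---------------------------------------------------------------------------
# default fixture set and normalization table


@lru_cache(maxsize=1)
def default_fixture_chains() -> tuple[ChainModel, ...]:
    """Ten deterministic 60-residue chains with varied sequences (seeds 1001–1010)."""
    return tuple(
        make_chain(60, random_sequence(60, seed), seed=seed, pdb_id=f"SYN{seed}")
        for seed in range(1001, 1011)
    )


@lru_cache(maxsize=1)
def default_normalization_table():
    """Default amino-acid-pair contact maxima, derived from synthetic helices.

    The reference set holds 60 deterministic helices (the ten fixture chains
    plus fifty more seeds) together with side-chain-perturbed, hinge-bent
    and point-mutated variants of the fixture chains, so that every one of
    the 210 unordered residue-type pairs is observed at least once and the
    maxima reflect the same perturbation regimes the generator produces.
    Reproducing published per-case NDS magnitudes on real structures depends
    on the reference set behind this table; edge counts, degrees and hub
    partitions do not, since they only use edge presence.
    """
    from .psn_builder import derive_normalization

    chains = list(default_fixture_chains()) + [
        make_chain(60, random_sequence(60, seed), seed=seed, pdb_id=f"SYN{seed}")
        for seed in range(2001, 2051)
    ]
    mutation_targets = ["TRP", "PHE", "ARG", "GLU", "LYS", "TYR", "HIS", "MET", "GLN", "LEU"]
    for k, base in enumerate(default_fixture_chains()):
        chains.append(perturb_sidechains(base, fraction=0.5, magnitude=3.0, seed=3001 + k))
        chains.append(hinge_bend(base, pivot=45, angle=60.0))
        chains.append(mutate_residue(base, 30, mutation_targets[k], seed=3101 + k))
    table = derive_normalization(
        chains,
        provenance=(
            "synthetic helix reference set: 60 base chains (seeds 1001-1010, 2001-2050) "
            "plus perturbed/bent/mutated fixture variants"
        ),
    )
    return table
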