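"""Nucleotide conformer database and rigid-body superposition.

The database stores one entry per nucleotide of a reference structure (the
ordered main-chain atoms) together with 5'/3' chain adjacency, and answers
one question: given an oriented sugar ring (or phosphate group) in the map,
what do plausible neighbouring nucleotides look like?  Every database sugar
is superposed on the query ring and its neighbour is emitted in map
coordinates; the density decides which candidate survives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .density import DensityGrid
from .fingerprint import FingerprintTarget, Placement, score_mean

__all__ = [
    "NucleotideFragment",
    "FragmentDatabase",
    "build_database",
    "prune_ensemble",
    "superpose_rigid",
    "seed_from_sugar",
    "seed_from_phosphate",
    "query_extensions",
    "RING_ATOMS",
    "PHOSPHATE_ATOMS",
]

logger = logging.getLogger(__name__)

RING_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")
_RING_BONDS = (("C1'", "C2'"), ("C2'", "C3'"), ("C3'", "C4'"), ("C4'", "O4'"), ("O4'", "C1'"))
#: atom set defining the phosphate-group frame; O3' belongs to the 5'-side
#: residue, the others to the residue owning the phosphorus.
PHOSPHATE_ATOMS = ("O3'", "P", "OP1", "OP2", "O5'")
MAIN_CHAIN = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'", "O2'")
NUCLEOTIDE_RESNAMES = {"A", "C", "G", "U", "I", "N", "DA", "DC", "DG", "DT", "DU", "DI"}
#: legacy PDB atom-name aliases
_NAME_ALIASES = {"O1P": "OP1", "O2P": "OP2"}

O3P_BOND_MAX = 2.0  # A; covalent-plausibility cutoff for chain adjacency


def _normalize_name(name: str) -> str:
    name = name.strip().replace("*", "'")
    return _NAME_ALIASES.get(name, name)


@dataclass
class NucleotideFragment:
    """Ordered main-chain atom coordinates of one nucleotide."""

    atoms: dict[str, np.ndarray]
    source_id: str = ""

    def __post_init__(self):
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}
        missing = [a for a in RING_ATOMS if a not in self.atoms]
        if missing:
            raise ValueError(f"sugar-ring atoms missing: {missing}")
        for a, b in _RING_BONDS:
            d = np.linalg.norm(self.atoms[a] - self.atoms[b])
            if not 1.3 <= d <= 1.7:
                raise ValueError(f"ring bond {a}-{b} = {d:.2f} A outside [1.3, 1.7]")

    def coords(self, names) -> np.ndarray:
        return np.array([self.atoms[n] for n in names])

    @property
    def ring(self) -> np.ndarray:
        return self.coords(RING_ATOMS)

    @property
    def anchor(self) -> np.ndarray | None:
        """Base attachment atom (N9 for purines, N1 for pyrimidines)."""
        for n in ("N9", "N1"):
            if n in self.atoms:
                return self.atoms[n]
        return None

    def transformed(self, placement: Placement) -> "NucleotideFragment":
        return NucleotideFragment(
            atoms={k: placement.transform(v) for k, v in self.atoms.items()},
            source_id=self.source_id,
        )

    def has(self, *names) -> bool:
        return all(n in self.atoms for n in names)


@dataclass
class FragmentDatabase:
    """Ordered nucleotide fragments with 5'/3' chain adjacency."""

    nucleotides: list[NucleotideFragment]
    next_idx: list[int | None] = field(default_factory=list)
    prev_idx: list[int | None] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.nucleotides)
        if not self.next_idx:
            self.next_idx = [None] * n
            self.prev_idx = [None] * n
            for i in range(n - 1):
                a, b = self.nucleotides[i], self.nucleotides[i + 1]
                if b.has("P") and np.linalg.norm(a.atoms["O3'"] - b.atoms["P"]) < O3P_BOND_MAX:
                    self.next_idx[i] = i + 1
                    self.prev_idx[i + 1] = i
        for i, j in enumerate(self.next_idx):
            if j is not None and self.prev_idx[j] != i:
                raise ValueError("inconsistent chain adjacency")

    @property
    def size(self) -> int:
        return len(self.nucleotides)

    def adjacent_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in enumerate(self.next_idx) if j is not None]


def build_database(reference) -> FragmentDatabase:
    """Build a conformer database from a reference structure.

    ``reference`` is a PDB path, a ``gemmi.Structure``, or a list of
    ``NucleotideFragment``.  Residues missing sugar-ring atoms are skipped
    with a logged warning; adjacency is recorded where consecutive residues
    are covalently plausible (O3'-P < 2 A).
    """
    if isinstance(reference, list):
        return FragmentDatabase(nucleotides=list(reference))
    if isinstance(reference, gemmi.Structure):
        st = reference
    else:
        st = gemmi.read_structure(str(reference))
    frags: list[NucleotideFragment] = []
    next_idx: list[int | None] = []
    prev_idx: list[int | None] = []
    for chain in st[0]:
        prev_in_chain = None
        for res in chain:
            if res.name.strip() not in NUCLEOTIDE_RESNAMES:
                continue
            atoms: dict[str, np.ndarray] = {}
            for at in res:
                nm = _normalize_name(at.name)
                if nm in MAIN_CHAIN or nm in ("N1", "N9"):
                    if nm not in atoms:  # first altloc wins
                        atoms[nm] = np.array([at.pos.x, at.pos.y, at.pos.z])
            try:
                frag = NucleotideFragment(atoms=atoms, source_id=f"{chain.name}/{res.seqid.num}")
            except ValueError as exc:
                logger.warning("skipping %s/%s %s: %s", chain.name, res.seqid.num, res.name, exc)
                prev_in_chain = None
                continue
            frags.append(frag)
            next_idx.append(None)
            prev_idx.append(None)
            i = len(frags) - 1
            if prev_in_chain is not None and frag.has("P"):
                d = np.linalg.norm(frags[prev_in_chain].atoms["O3'"] - frag.atoms["P"])
                if d < O3P_BOND_MAX:
                    next_idx[prev_in_chain] = i
                    prev_idx[i] = prev_in_chain
            prev_in_chain = i
    if not frags:
        raise ValueError("no nucleotides found in reference")
    return FragmentDatabase(nucleotides=frags, next_idx=next_idx, prev_idx=prev_idx)


def prune_ensemble(
    fragments: list[NucleotideFragment],
    probe_atoms=("O2'",),
    cutoff: float = 1.0,
) -> list[NucleotideFragment]:
    """Drop rare conformers from a superposed ensemble.

    Iteratively removes the single fragment whose probe atom lies farthest
    from the current ensemble mean, while that distance exceeds ``cutoff``;
    the mean is recomputed after every removal.  Fragments are assumed
    already superposed on the conserved atoms of the search fragment.
    """
    if not fragments:
        raise ValueError("empty ensemble")
    if isinstance(probe_atoms, str):
        probe_atoms = (probe_atoms,)
    kept = list(fragments)
    while len(kept) > 1:
        devs = np.zeros(len(kept))
        for atom in probe_atoms:
            pos = np.array([f.atoms[atom] for f in kept])
            devs = np.maximum(devs, np.linalg.norm(pos - pos.mean(axis=0), axis=1))
        worst = int(np.argmax(devs))
        if devs[worst] <= cutoff:
            break
        kept.pop(worst)
    return kept


def superpose_rigid(moving, fixed) -> Placement:
    """Least-squares rigid superposition (proper rotation only).

    Returns the placement P with ``P.transform(moving) ~= fixed`` minimising
    the RMSD; reflections are never returned, so mirrored point sets keep a
    positive residual.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("moving and fixed must be matched (n, 3) arrays")
    if len(moving) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    mc, fc = moving - cm, fixed - cf
    if min(np.linalg.matrix_rank(mc, tol=1e-8), np.linalg.matrix_rank(fc, tol=1e-8)) < 2:
        warnings.warn("degenerate (collinear) point set in superposition", stacklevel=2)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*optimal rotation is not uniquely.*")
        rot, _ = Rotation.align_vectors(fc, mc)
    R = rot.as_matrix()
    return Placement(rotation=R, translation=cf - R @ cm)


def rmsd(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def seed_from_sugar(
    db: FragmentDatabase,
    hit: Placement,
    sugar_target: FingerprintTarget,
) -> NucleotideFragment:
    """Convert a sugar-fingerprint hit directly into a nucleoside-level seed.

    The target's template nucleotide is carried rigidly by the hit; the
    terminal phosphate keeps the template's (arbitrary) conformation.
    """
    if sugar_target.frame_atoms is None:
        raise ValueError("sugar target carries no template atoms")
    return NucleotideFragment(
        atoms={k: hit.transform(v) for k, v in sugar_target.frame_atoms.items()},
        source_id="seed/sugar",
    )


def _sugar_placement(sugar_target: FingerprintTarget, frag: NucleotideFragment) -> Placement:
    """Placement of the sugar fingerprint frame onto a placed nucleotide."""
    tmpl_ring = np.array([sugar_target.frame_atoms[n] for n in RING_ATOMS])
    return superpose_rigid(tmpl_ring, frag.ring)


def sugar_score(
    grid: DensityGrid, frag: NucleotideFragment, sugar_target: FingerprintTarget
) -> float:
    """Interpolated s_mean of the sugar fingerprint at a placed nucleotide."""
    return score_mean(sugar_target, grid, _sugar_placement(sugar_target, frag), interpolated=True)


def phosphate_score(
    grid: DensityGrid, phos_atoms: dict[str, np.ndarray], target: FingerprintTarget
) -> float:
    """Interpolated s_mean of the phosphate fingerprint at a placed group."""
    tmpl = np.array([target.frame_atoms[n] for n in PHOSPHATE_ATOMS])
    world = np.array([phos_atoms[n] for n in PHOSPHATE_ATOMS])
    return score_mean(target, grid, superpose_rigid(tmpl, world), interpolated=True)


def seed_from_phosphate(
    db: FragmentDatabase,
    hit: Placement,
    grid: DensityGrid,
    phosphate_target: FingerprintTarget,
    sugar_target: FingerprintTarget,
) -> tuple[NucleotideFragment, NucleotideFragment]:
    """Convert a phosphate-fingerprint hit into the best binucleotide seed.

    Every adjacent database pair is superposed, via its linking phosphate
    group, onto the hit; the pair whose two flanking sugars score highest by
    summed interpolated s_mean wins (ties: lowest database index).
    """
    pairs = db.adjacent_pairs()
    if not pairs:
        raise ValueError("database has no adjacent nucleotide pairs")
    if phosphate_target.frame_atoms is None:
        raise ValueError("phosphate target carries no template atoms")
    world = np.array([hit.transform(phosphate_target.frame_atoms[n]) for n in PHOSPHATE_ATOMS])
    best = None
    for i, j in pairs:
        a, b = db.nucleotides[i], db.nucleotides[j]
        if not b.has("P", "OP1", "OP2", "O5'"):
            continue
        group = np.array(
            [a.atoms["O3'"], b.atoms["P"], b.atoms["OP1"], b.atoms["OP2"], b.atoms["O5'"]]
        )
        pl = superpose_rigid(group, world)
        ta, tb = a.transformed(pl), b.transformed(pl)
        s = sugar_score(grid, ta, sugar_target) + sugar_score(grid, tb, sugar_target)
        if best is None or s > best[0]:
            best = (s, ta, tb)
    if best is None:
        raise ValueError("no complete phosphate-linked pair in database")
    return best[1], best[2]


def query_extensions(
    db: FragmentDatabase,
    terminal_sugar: np.ndarray,
    direction: str,
) -> list[tuple[NucleotideFragment, dict[str, np.ndarray]]]:
    """Candidate one-nucleotide extensions of a chain terminus.

    ``terminal_sugar`` holds the five ring-atom coordinates (C1', C2', C3',
    C4', O4') of the chain's terminal sugar; ``direction`` is "3" or "5".
    Each database nucleotide with a neighbour in that direction is superposed
    (by its sugar ring) on the terminal sugar, and the transformed neighbour
    is emitted together with the intervening phosphate-group atoms.
    """
    if direction not in ("3", "5"):
        raise ValueError("direction must be '3' or '5'")
    if db.size == 0:
        raise ValueError("empty database")
    terminal_sugar = np.asarray(terminal_sugar, dtype=float)
    out = []
    for i in range(db.size):
        j = db.next_idx[i] if direction == "3" else db.prev_idx[i]
        if j is None:
            continue
        nb = db.nucleotides[j]
        cur = db.nucleotides[i]
        # the linking phosphate is owned by the 3'-side residue of the pair
        owner = nb if direction == "3" else cur
        o3_owner = cur if direction == "3" else nb
        if not owner.has("P", "OP1", "OP2", "O5'"):
            continue
        pl = superpose_rigid(cur.ring, terminal_sugar)
        new_frag = nb.transformed(pl)
        phos = {n: pl.transform(owner.atoms[n]) for n in ("P", "OP1", "OP2", "O5'")}
        phos["O3'"] = pl.transform(o3_owner.atoms["O3'"])
        out.append((new_frag, phos))
    return out
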