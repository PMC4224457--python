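"""Grow fingerprint hits into nucleotide chains, with calibrated stopping,
short-trace filtering and trace merging.

Growth alternates between the 3' and 5' ends of a seed.  Each candidate
extension (every database conformer superposed on the terminal sugar) is
scored by interpolated s_mean of the sugar fingerprint at the new sugar plus
s_mean of the phosphate fingerprint at the intervening phosphate; the best
candidate is accepted while its *sugar* score exceeds a threshold calibrated
so that random placements beat it with probability ``tail_prob`` (default
0.1%).  A clash rule (new C1' at least 3 A from every C1' already in the
trace) stops the grower from retracing its own path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .density import DensityGrid, interpolate
from .fingerprint import FingerprintTarget, Placement, search_local
from .fragdb import (
    FragmentDatabase,
    NucleotideFragment,
    phosphate_score,
    query_extensions,
    seed_from_phosphate,
    seed_from_sugar,
    sugar_score,
)

__all__ = [
    "ChainTrace",
    "ScoreThreshold",
    "calibrate_threshold",
    "grow_chain",
    "filter_short",
    "merge_traces",
    "trace_all",
    "write_traces_pdb",
]

CLASH_RADIUS = 3.0  # A; anti-backtrack exclusion between C1' atoms
O3P_MAX = 2.5  # A; post-growth backbone continuity bound


@dataclass
class ChainTrace:
    """An ordered 5'->3' chain of nucleotide fragments with per-nucleotide
    sugar s_mean scores."""

    nucleotides: list[NucleotideFragment]
    scores: list[float]
    seed_index: int = 0

    def __post_init__(self):
        if len(self.nucleotides) < 1:
            raise ValueError("a trace holds at least one nucleotide")
        if len(self.scores) != len(self.nucleotides):
            raise ValueError("one score per nucleotide")

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def total_score(self) -> float:
        return float(sum(self.scores))

    def c1_positions(self) -> np.ndarray:
        return np.array([f.atoms["C1'"] for f in self.nucleotides])


@dataclass
class ScoreThreshold:
    """Score cutoff calibrated from random placements."""

    value: float
    n_samples: int
    tail_prob: float
    degenerate: bool = False

    def __post_init__(self):
        if not 0.0 < self.tail_prob < 1.0:
            raise ValueError("tail_prob must be in (0, 1)")
        if self.n_samples < 1000:
            raise ValueError("n_samples must be >= 1000")


def calibrate_threshold(
    grid: DensityGrid,
    target: FingerprintTarget,
    n_samples: int = 100_000,
    tail_prob: float = 0.001,
    seed: int = 0,
) -> ScoreThreshold:
    """Empirical (1 - tail_prob) quantile of s_mean over random placements.

    Translations are uniform over the cell, rotations uniform over SO(3);
    scores use interpolated density.  On a constant map every score is zero
    and the threshold is returned flagged as degenerate.
    """
    rng = np.random.default_rng(seed)
    t = grid.origin + rng.uniform(0.0, 1.0, size=(n_samples, 3)) * grid.cell
    R = Rotation.random(n_samples, random_state=rng).as_matrix()
    pos = np.einsum("nij,pj->npi", R, target.probes) + t[:, None, :]
    vals = interpolate(grid, pos)
    n = target.n
    scores = vals[:, :n].mean(axis=1) - vals[:, n:].mean(axis=1)
    value = float(np.quantile(scores, 1.0 - tail_prob))
    return ScoreThreshold(
        value=value, n_samples=n_samples, tail_prob=tail_prob, degenerate=grid.sigma == 0.0
    )


def _min_c1_distance(frag: NucleotideFragment, trace: ChainTrace) -> float:
    d = np.linalg.norm(trace.c1_positions() - frag.atoms["C1'"], axis=1)
    return float(d.min())


def grow_chain(
    grid: DensityGrid,
    db: FragmentDatabase,
    seed: ChainTrace,
    threshold: ScoreThreshold,
    sugar_target: FingerprintTarget,
    phosphate_target: FingerprintTarget,
) -> ChainTrace:
    """Extend a seed trace in both directions until the density gives out.

    Ends alternate; an end closes when the best candidate's sugar score fails
    the threshold or its C1' clashes with the existing trace.
    """
    nts = list(seed.nucleotides)
    scores = list(seed.scores)
    seed_index = seed.seed_index
    open_ends = {"3": True, "5": True}
    trace = ChainTrace(nucleotides=nts, scores=scores, seed_index=seed_index)
    while any(open_ends.values()):
        for direction in ("3", "5"):
            if not open_ends[direction]:
                continue
            terminal = nts[-1] if direction == "3" else nts[0]
            best = None
            for new_frag, phos in query_extensions(db, terminal.ring, direction):
                s_sugar = sugar_score(grid, new_frag, sugar_target)
                s_phos = phosphate_score(grid, phos, phosphate_target)
                total = s_sugar + s_phos
                if best is None or total > best[0]:
                    best = (total, s_sugar, new_frag, phos)
            if best is None:
                open_ends[direction] = False
                continue
            _, s_sugar, new_frag, phos = best
            if s_sugar <= threshold.value or _min_c1_distance(new_frag, trace) < CLASH_RADIUS:
                open_ends[direction] = False
                continue
            if direction == "3":
                nts.append(new_frag)
                scores.append(s_sugar)
            else:
                # the intervening phosphate replaces the old terminal's
                # (arbitrary-conformation) phosphate to keep O3'-P continuity
                old = nts[0]
                patched = dict(old.atoms)
                patched.update({k: phos[k] for k in ("P", "OP1", "OP2", "O5'")})
                nts[0] = NucleotideFragment(atoms=patched, source_id=old.source_id)
                nts.insert(0, new_frag)
                scores.insert(0, s_sugar)
                seed_index += 1
            trace = ChainTrace(nucleotides=nts, scores=scores, seed_index=seed_index)
    return trace


def filter_short(traces: list[ChainTrace], min_len: int = 3) -> list[ChainTrace]:
    """Reject candidate chains that failed to grow to ``min_len`` nucleotides."""
    return [t for t in traces if len(t) >= min_len]


def _alignment(a: ChainTrace, b: ChainTrace, radius: float):
    """Best index offset aligning b onto a (same 5'->3' direction).

    Returns (offset d with b[j] ~ a[j + d], number of consecutive matches) or
    None if no run of >= 2 consecutive C1' matches exists.
    """
    ca, cb = a.c1_positions(), b.c1_positions()
    best = None
    for d in range(-len(b) + 1, len(a)):
        run = total = 0
        longest = 0
        for j in range(len(b)):
            i = j + d
            if 0 <= i < len(a) and np.linalg.norm(ca[i] - cb[j]) < radius:
                run += 1
                longest = max(longest, run)
                total += 1
            else:
                run = 0
        if longest >= 2 and (best is None or total > best[1]):
            best = (d, total)
    return best


def _merge_pair(a: ChainTrace, b: ChainTrace, d: int) -> ChainTrace:
    """Union of two aligned traces; at branch points the continuation with the
    higher remaining summed score wins."""
    lo = min(0, d)
    hi = max(len(a), d + len(b))
    nts, scores = [], []
    for i in range(lo, hi):
        fa = a.nucleotides[i] if 0 <= i < len(a) else None
        fb = b.nucleotides[i - d] if 0 <= i - d < len(b) else None
        if fa is not None and fb is not None:
            if np.linalg.norm(fa.atoms["C1'"] - fb.atoms["C1'"]) < 2.0:
                nts.append(fa)
                scores.append(a.scores[i])
            else:
                # branch: keep the tail with the higher remaining score
                ra = sum(a.scores[i:])
                rb = sum(b.scores[i - d :])
                if ra >= rb:
                    nts.extend(a.nucleotides[i:])
                    scores.extend(a.scores[i:])
                else:
                    nts.extend(b.nucleotides[i - d :])
                    scores.extend(b.scores[i - d :])
                break
        elif fa is not None:
            nts.append(fa)
            scores.append(a.scores[i])
        elif fb is not None:
            nts.append(fb)
            scores.append(b.scores[i - d])
    return ChainTrace(nucleotides=nts, scores=scores, seed_index=max(0, -lo))


def merge_traces(traces: list[ChainTrace], match_radius: float = 1.0) -> list[ChainTrace]:
    """Merge traces sharing >= 2 consecutive nucleotides (C1' within
    ``match_radius``, same direction) into single chains.

    Output traces are pairwise non-overlapping by the same criterion and are
    ordered by total score descending; merging never increases the number of
    distinct nucleotide positions.
    """
    pool = sorted(traces, key=lambda t: -t.total_score)
    out: list[ChainTrace] = []
    for t in pool:
        cur = t
        merged = True
        while merged:
            merged = False
            for i, u in enumerate(out):
                al = _alignment(u, cur, match_radius)
                if al is not None:
                    out.pop(i)
                    cur = _merge_pair(u, cur, al[0])
                    merged = True
                    break
        out.append(cur)
    out.sort(key=lambda t: -t.total_score)
    return out


def trace_all(
    grid: DensityGrid,
    db: FragmentDatabase,
    sugar_target: FingerprintTarget,
    phosphate_target: FingerprintTarget,
    center=None,
    radius: float = 6.0,
    step_deg: float = 18.0,
    n_best: int = 50,
    min_len: int = 3,
    threshold_samples: int = 100_000,
    tail_prob: float = 0.001,
    seed: int = 0,
    use_phosphate: bool = True,
) -> list[ChainTrace]:
    """Find fragments near ``center`` (or over the whole cell) and grow them
    into merged, filtered chain traces.  Deterministic for a fixed seed."""
    sugar_hits = search_local(grid, sugar_target, center, radius, step_deg, n_best)
    phos_hits = (
        search_local(grid, phosphate_target, center, radius, step_deg, n_best)
        if use_phosphate
        else []
    )
    threshold = calibrate_threshold(grid, sugar_target, threshold_samples, tail_prob, seed)

    seeds: list[ChainTrace] = []
    for hit in sugar_hits:
        frag = seed_from_sugar(db, hit, sugar_target)
        seeds.append(ChainTrace(nucleotides=[frag], scores=[hit.score_mean], seed_index=0))
    for hit in phos_hits:
        try:
            fa, fb = seed_from_phosphate(db, hit, grid, phosphate_target, sugar_target)
        except ValueError:
            continue
        seeds.append(
            ChainTrace(
                nucleotides=[fa, fb],
                scores=[sugar_score(grid, fa, sugar_target), sugar_score(grid, fb, sugar_target)],
                seed_index=0,
            )
        )

    traces: list[ChainTrace] = []
    built_c1: list[np.ndarray] = []
    for s in seeds:
        # skip seeds already covered by a grown trace
        if built_c1:
            existing = np.vstack(built_c1)
            d = np.linalg.norm(existing - s.nucleotides[0].atoms["C1'"], axis=1)
            if d.min() < 1.5:
                continue
        grown = grow_chain(grid, db, s, threshold, sugar_target, phosphate_target)
        traces.append(grown)
        if len(grown) >= min_len:
            built_c1.append(grown.c1_positions())
    return merge_traces(filter_short(traces, min_len))


def write_traces_pdb(traces: list[ChainTrace], path: str) -> None:
    """Write traces as a PDB model: one chain per trace, residues numbered
    5'->3', base type unassigned (written as U, noted in a REMARK)."""
    st = gemmi.Structure()
    st.name = "natrace model"
    model = gemmi.Model("1")
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for ti, trace in enumerate(traces):
        chain = gemmi.Chain(chain_ids[ti % len(chain_ids)])
        for ri, frag in enumerate(trace.nucleotides, start=1):
            res = gemmi.Residue()
            res.name = "U"
            res.seqid = gemmi.SeqId(ri, " ")
            for name, pos in frag.atoms.items():
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element("P" if name == "P" else name[0])
                at.pos = gemmi.Position(*pos)
                at.occ = 1.0
                at.b_iso = 20.0
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.raw_remarks = ["REMARK 999 BASE TYPES UNASSIGNED; ALL RESIDUES WRITTEN AS U"]
    st.write_pdb(str(path))
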