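"""Model-vs-reference metrics: C1' coverage and phosphorus coordinate error.

A reference C1' counts as built when any model C1' lies within the cutoff
(1.5 A by default); the phosphorus error is the mean distance from each
matched reference P to its nearest model P, with matches limited to pairs
within 3 A (so unbuilt regions do not inflate the error).
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["CoverageReport", "c1_coverage", "phosphorus_error", "write_report"]

P_MATCH_RADIUS = 3.0


@dataclass
class CoverageReport:
    """Counts of reference C1' atoms recovered by a built model."""

    n_built: int
    n_total: int
    fraction: float
    p_error: float | None

    def row(self, label: str = "") -> dict:
        return {
            "structure": label,
            "built": self.n_built,
            "total": self.n_total,
            "fraction_pct": round(100.0 * self.fraction, 1),
            "phosphorus_error_A": None if self.p_error is None else round(self.p_error, 2),
        }


def _atom_coords(model, name: str) -> np.ndarray:
    """Coordinates of all atoms called ``name`` in a model.

    Accepts a gemmi.Structure, a PDB path, an (n, 3) array, or any iterable
    of objects exposing ``atoms`` dicts (NucleotideFragment) or
    ``nucleotides`` lists (ChainTrace).
    """
    if isinstance(model, (str,)):
        model = gemmi.read_structure(model)
    if isinstance(model, gemmi.Structure):
        out = []
        for chain in model[0]:
            for res in chain:
                for at in res:
                    if at.name.strip().replace("*", "'") == name:
                        out.append([at.pos.x, at.pos.y, at.pos.z])
        return np.array(out).reshape(-1, 3)
    arr = np.asarray(model, dtype=object)
    if getattr(arr, "dtype", None) is not None and arr.dtype != object:
        a = np.asarray(model, dtype=float)
        return a.reshape(-1, 3)
    out = []
    for item in model:
        if hasattr(item, "nucleotides"):
            for f in item.nucleotides:
                if name in f.atoms:
                    out.append(f.atoms[name])
        elif hasattr(item, "atoms"):
            if name in item.atoms:
                out.append(item.atoms[name])
        else:
            out.append(np.asarray(item, dtype=float))
    return np.array(out).reshape(-1, 3)


def c1_coverage(built, reference, cutoff: float = 1.5) -> CoverageReport:
    """Fraction of reference C1' atoms matched by a built C1' within cutoff.

    Matching is counted per reference atom; one built atom may satisfy
    several reference atoms.  The phosphorus error of the matched model is
    attached to the report.
    """
    ref = _atom_coords(reference, "C1'")
    if len(ref) == 0:
        raise ValueError("reference contains no C1' atoms")
    mod = _atom_coords(built, "C1'")
    if len(mod) == 0:
        return CoverageReport(n_built=0, n_total=len(ref), fraction=0.0, p_error=None)
    d, _ = cKDTree(mod).query(ref)
    n_built = int((d <= cutoff).sum())
    return CoverageReport(
        n_built=n_built,
        n_total=len(ref),
        fraction=n_built / len(ref),
        p_error=phosphorus_error(built, reference),
    )


def phosphorus_error(built, reference, cutoff: float = P_MATCH_RADIUS) -> float | None:
    """Mean nearest-neighbour distance between matched P atoms (pairs within
    ``cutoff``); None when nothing matches."""
    ref = _atom_coords(reference, "P")
    mod = _atom_coords(built, "P")
    if len(ref) == 0 or len(mod) == 0:
        return None
    d, _ = cKDTree(mod).query(ref)
    d = d[d <= cutoff]
    if len(d) == 0:
        return None
    return float(d.mean())


def write_report(reports: list[tuple[str, CoverageReport]], path: str) -> None:
    """Emit a TSV of coverage reports (structure, built, total, fraction %,
    phosphorus error A)."""
    df = pd.DataFrame([r.row(label) for label, r in reports])
    df.to_csv(path, sep="\t", index=False)
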