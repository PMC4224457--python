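"""Fingerprint search targets and the pruned six-dimensional fragment search.

A search target describes a rigid fragment (ribose sugar or phosphate group)
as paired sets of probe points: *high* probes where density must be high if
the fragment is present, and *low* probes where it must be low.  Two scores
are defined over a placed target:

*   ``s_mean``   = mean(density at high probes) - mean(density at low probes)
*   ``s_minmax`` = min(density at high probes)  - max(density at low probes)

``s_minmax`` can only get worse as probe pairs accumulate (the minimum can
only decrease, the maximum only increase), which permits aggressive early
termination during the translational search.  Survivors of the fast min/max
pass are re-scored with the more sensitive ``s_mean`` on interpolated
density.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

from .density import DensityGrid, interpolate, value_at_grid

__all__ = [
    "FingerprintTarget",
    "Placement",
    "score_mean",
    "score_minmax",
    "score_minmax_pruned",
    "sample_rotations",
    "derive_probes",
    "search_local",
    "load_default_targets",
]

MAX_PROBE_RADIUS = 6.0


@dataclass
class FingerprintTarget:
    """Paired high/low probe offsets for one rigid fragment type.

    Offsets are in the fragment-local frame, relative to the fragment centre
    (the centroid of the conserved atoms).  The first high probe marks the
    fragment's most conserved strong density feature and drives the
    first-probe pruning optimisation.  ``frame_atoms`` optionally carries the
    template atom coordinates (same local frame) used to convert hits into
    atomic fragments and to re-derive placements by superposition.
    """

    name: str
    high_probes: np.ndarray
    low_probes: np.ndarray
    high_names: list[str] | None = None
    frame_atoms: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        self.high_probes = np.atleast_2d(np.asarray(self.high_probes, dtype=float))
        self.low_probes = np.atleast_2d(np.asarray(self.low_probes, dtype=float))
        if self.high_probes.shape != self.low_probes.shape or self.high_probes.shape[1] != 3:
            raise ValueError("high and low probe counts must be equal (n x 3 each)")
        for arr in (self.high_probes, self.low_probes):
            if np.any(np.linalg.norm(arr, axis=1) > MAX_PROBE_RADIUS + 1e-9):
                raise ValueError(f"probe offsets must lie within {MAX_PROBE_RADIUS} A of the centre")
        if self.frame_atoms is not None:
            self.frame_atoms = {k: np.asarray(v, dtype=float) for k, v in self.frame_atoms.items()}

    @property
    def n(self) -> int:
        return len(self.high_probes)

    @property
    def probes(self) -> np.ndarray:
        """High probes stacked over low probes, shape (2n, 3)."""
        return np.vstack([self.high_probes, self.low_probes])

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "high_probes": self.high_probes.tolist(),
            "low_probes": self.low_probes.tolist(),
        }
        if self.high_names is not None:
            d["high_names"] = list(self.high_names)
        if self.frame_atoms is not None:
            d["frame_atoms"] = {k: v.tolist() for k, v in self.frame_atoms.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FingerprintTarget":
        return cls(
            name=d["name"],
            high_probes=np.array(d["high_probes"]),
            low_probes=np.array(d["low_probes"]),
            high_names=d.get("high_names"),
            frame_atoms={k: np.array(v) for k, v in d["frame_atoms"].items()}
            if "frame_atoms" in d
            else None,
        )


@dataclass
class Placement:
    """A rigid placement (proper rotation + translation) with attached scores."""

    rotation: np.ndarray
    translation: np.ndarray
    score_minmax: float | None = None
    score_mean: float | None = None

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det=+1)")

    def transform(self, points) -> np.ndarray:
        """Map fragment-local points into the map frame."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Placement":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


def _probe_positions(target: FingerprintTarget, placement: Placement) -> np.ndarray:
    return placement.transform(target.probes)


def score_mean(
    target: FingerprintTarget,
    grid: DensityGrid,
    placement: Placement,
    interpolated: bool = True,
) -> float:
    """mean(high-probe density) - mean(low-probe density)."""
    pos = _probe_positions(target, placement)
    vals = interpolate(grid, pos) if interpolated else value_at_grid(grid, pos)
    n = target.n
    return float(vals[:n].mean() - vals[n:].mean())


def score_minmax(target: FingerprintTarget, grid: DensityGrid, placement: Placement) -> float:
    """min(high-probe density) - max(low-probe density), nearest-node lookup."""
    pos = _probe_positions(target, placement)
    vals = value_at_grid(grid, pos)
    n = target.n
    return float(vals[:n].min() - vals[n:].max())


def score_minmax_pruned(
    target: FingerprintTarget,
    grid: DensityGrid,
    placement: Placement,
    threshold: float,
) -> float | None:
    """``score_minmax`` with early termination.

    Probe pairs are evaluated in stored order; the partial min-max difference
    is an upper bound on the final score, so as soon as it drops below
    ``threshold`` the placement is rejected (returns None).  When a score is
    returned it equals ``score_minmax`` exactly.
    """
    hi = placement.transform(target.high_probes)
    lo = placement.transform(target.low_probes)
    min_h = np.inf
    max_l = -np.inf
    for j in range(target.n):
        min_h = min(min_h, value_at_grid(grid, hi[j]))
        max_l = max(max_l, value_at_grid(grid, lo[j]))
        if min_h - max_l < threshold:
            return None
    return float(min_h - max_l)


def sample_rotations(step_deg: float = 18.0) -> np.ndarray:
    """Quasi-uniform covering of SO(3) by a zyz Euler grid.

    beta is sampled uniformly in ``step_deg``; the gamma count at each beta
    ring scales with sin(beta) (near the poles alpha and gamma act on the same
    degree of freedom), which keeps neighbouring samples within ``step_deg``
    in the rotation-angle metric without the full alpha x beta x gamma product.
    Returns an array of rotation matrices, shape (N, 3, 3).
    """
    if not 0 < step_deg <= 90:
        raise ValueError("step must be in (0, 90] degrees")
    n_beta = int(np.ceil(180.0 / step_deg))
    n_alpha = int(np.ceil(360.0 / step_deg))
    eulers = []
    for k in range(n_beta + 1):
        beta = 180.0 * k / n_beta
        if k == 0 or k == n_beta:
            n_gamma = 1
        else:
            n_gamma = max(1, int(np.ceil(360.0 * np.sin(np.deg2rad(beta)) / step_deg)))
        for a in range(n_alpha):
            alpha = 360.0 * a / n_alpha
            for g in range(n_gamma):
                gamma = 360.0 * g / n_gamma
                eulers.append((alpha, beta, gamma))
    return Rotation.from_euler("zyz", eulers, degrees=True).as_matrix()


_NEIGHBOURS_26 = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
)


def derive_probes(
    min_map: DensityGrid,
    max_map: DensityGrid,
    fragment_atoms,
    extra_high=(),
    radius: float = 6.0,
    min_sep: float = 2.5,
    name: str = "fragment",
) -> FingerprintTarget:
    """Derive a fingerprint target from ensemble minimum/maximum maps.

    High probes sit on the named fragment atoms (in the fragment-local frame
    of the maps, centre at the origin) plus any ``extra_high`` offsets.  Low
    probes are placed by a rising-contour sweep of the maximum map: grid
    points within ``radius`` of the centre are visited in ascending max-map
    order and a probe is placed wherever a new low-density feature is born
    (a visited point with no previously visited neighbour), subject to
    pairwise separation >= ``min_sep``.  Probe counts are then equalised by
    truncating the longer list.
    """
    if not min_map.same_geometry(max_map):
        raise ValueError("min and max maps must share geometry")
    high_names = [a.name for a in fragment_atoms]
    high = [np.asarray(a.pos, dtype=float) for a in fragment_atoms]
    high += [np.asarray(p, dtype=float) for p in extra_high]
    high_names += [f"extra{i}" for i in range(len(extra_high))]

    # candidate grid points within `radius` of the fragment centre (origin)
    g = max_map
    shape = g.shape
    step = g.spacing
    axes = [g.origin[d] + step[d] * np.arange(shape[d]) for d in range(3)]
    # local maps are small and non-wrapping around the fragment: use the
    # unwrapped node positions directly
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    r2 = X**2 + Y**2 + Z**2
    inside = r2 <= radius**2
    idx = np.argwhere(inside)
    if len(idx) == 0:
        raise ValueError("no grid points within radius of the fragment centre")
    vals = g.values[inside]
    dists = r2[inside]
    order = np.lexsort((np.arange(len(idx)), dists, vals))

    visited = np.zeros(tuple(shape), dtype=bool)
    lows: list[np.ndarray] = []
    low_vals: list[float] = []
    for oi in order:
        i, j, k = idx[oi]
        nb = _NEIGHBOURS_26 + (i, j, k)
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb = nb[ok]
        born = not visited[nb[:, 0], nb[:, 1], nb[:, 2]].any()
        visited[i, j, k] = True
        if born:
            pos = g.origin + step * (i, j, k)
            if all(np.linalg.norm(pos - p) >= min_sep for p in lows):
                lows.append(pos)
                low_vals.append(g.values[i, j, k])
    if not lows:
        raise ValueError("no low-probe candidates found")

    n = min(len(high), len(lows))
    keep = np.argsort(low_vals, kind="stable")[:n]
    keep.sort()
    # low probes are born on map lattice nodes; pull them off the exact
    # lattice by a negligible radial contraction so that rotated offsets
    # never fall exactly midway between grid nodes (keeps nearest-node
    # rounding well defined for any map sharing the derivation spacing)
    low = np.array([lows[i] for i in keep]) * (1.0 - 1e-4)
    return FingerprintTarget(
        name=name,
        high_probes=np.array(high[:n]),
        low_probes=low,
        high_names=high_names[:n],
    )


def _candidate_nodes(grid: DensityGrid, center, radius):
    """Grid nodes searched as candidate translations.

    Returns (wrapped index array (M,3), unwrapped Cartesian positions (M,3),
    distance to center (M,)).  ``center=None`` means the whole grid.
    """
    shape = grid.shape
    step = grid.spacing
    if center is None:
        idx = np.argwhere(np.ones(tuple(shape), dtype=bool))
        pos = grid.origin + idx * step
        return idx, pos, np.zeros(len(idx))
    center = np.asarray(center, dtype=float)
    ic = np.rint((center - grid.origin) / step).astype(int)
    reach = np.floor(radius / step).astype(int)
    if np.all(reach == 0):
        raise ValueError("radius smaller than one grid step: no candidate translations")
    rngs = [np.arange(ic[d] - reach[d], ic[d] + reach[d] + 1) for d in range(3)]
    I, J, K = np.meshgrid(*rngs, indexing="ij")
    idx_un = np.column_stack([I.ravel(), J.ravel(), K.ravel()])
    pos = grid.origin + idx_un * step
    d = np.linalg.norm(pos - center, axis=1)
    sel = d <= radius
    if not sel.any():
        raise ValueError("radius smaller than one grid step: no candidate translations")
    return idx_un[sel] % shape, pos[sel], d[sel]


def search_local(
    grid: DensityGrid,
    target: FingerprintTarget,
    center,
    radius: float = 6.0,
    step_deg: float = 18.0,
    n_best: int = 50,
    rotations: np.ndarray | None = None,
) -> list[Placement]:
    """Pruned rotation/translation search for a fingerprint target.

    For each sampled orientation the probe offsets are rotated and rounded to
    the nearest grid vector once, then scored against every candidate grid
    node within ``radius`` of ``center`` (or the whole grid if ``center`` is
    None).  Three prunes keep the cost low: (i) nearest-node lookups on
    pre-rounded offsets, (ii) a running best-list of size ``n_best`` whose
    worst retained s_minmax (floored at 0) is the live rejection threshold,
    and (iii) immediate elimination of translations whose first-high-probe
    density is below mean + 1 sigma.  Survivors are re-scored with ``s_mean``
    on interpolated density, placements with non-positive s_mean are dropped,
    and the rest are returned sorted by s_mean descending (ties: distance to
    center, then rotation index).
    """
    idx, pos, dist = _candidate_nodes(grid, center, radius)
    if rotations is None:
        rotations = sample_rotations(step_deg)
    shape = grid.shape
    step = grid.spacing
    v = grid.values
    stat_cut = grid.mean + grid.sigma
    n = target.n
    probes = target.probes

    heap: list[tuple] = []  # (score, -dist, -rot_idx, -cand_idx); heap[0] = worst retained

    def live_threshold() -> float:
        if len(heap) < n_best:
            return 0.0
        return max(0.0, heap[0][0])

    for ri, R in enumerate(rotations):
        off = np.rint((probes @ R.T) / step).astype(int)  # probe offsets in grid units
        thr = live_threshold()
        # optimisation (iii): first-high-probe density must exceed mean + sigma
        p0 = (idx + off[0]) % shape
        v0 = v[p0[:, 0], p0[:, 1], p0[:, 2]]
        alive = np.where(v0 >= stat_cut)[0]
        if alive.size == 0:
            continue
        min_h = v0[alive]
        max_l = None
        for j in range(n):
            if j > 0:
                pj = (idx[alive] + off[j]) % shape
                min_h = np.minimum(min_h, v[pj[:, 0], pj[:, 1], pj[:, 2]])
            pl = (idx[alive] + off[n + j]) % shape
            lv = v[pl[:, 0], pl[:, 1], pl[:, 2]]
            max_l = lv if max_l is None else np.maximum(max_l, lv)
            keep = (min_h - max_l) >= thr  # early termination of the pair loop
            if not keep.all():
                alive = alive[keep]
                min_h = min_h[keep]
                max_l = max_l[keep]
            if alive.size == 0:
                break
        if alive.size == 0:
            continue
        scores = min_h - max_l
        for ci, s in zip(alive, scores):
            entry = (float(s), -float(dist[ci]), -ri, -int(ci))
            if len(heap) < n_best:
                heapq.heappush(heap, entry)
            elif entry > heap[0]:
                heapq.heapreplace(heap, entry)

    results = []
    for s, nd, nri, nci in heap:
        if s < 0:
            continue
        ri, ci = -nri, -nci
        pl = Placement(rotation=rotations[ri], translation=pos[ci], score_minmax=s)
        pl.score_mean = score_mean(target, grid, pl, interpolated=True)
        if pl.score_mean > 0:
            results.append((pl, -nd, ri))
    results.sort(key=lambda t: (-t[0].score_mean, t[1], t[2]))
    return [r[0] for r in results]


def load_default_targets() -> dict[str, FingerprintTarget]:
    """Load the packaged sugar and phosphate fingerprint targets."""
    text = resources.files("natrace.data").joinpath("targets.json").read_text()
    raw = json.loads(text)
    return {k: FingerprintTarget.from_dict(d) for k, d in raw.items()}
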