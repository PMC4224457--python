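"""Download-free synthetic fixtures: idealized helices, perturbed conformer
ensembles, Gaussian-atom maps, and FOM-driven phase-error map degradation.

The template nucleotide was solved once by least squares over standard
ribonucleotide bond/angle restraints together with a helix-closure
constraint, so that repeated application of the helix operator (32.7 deg
twist about z, 2.81 A rise) yields a covalently continuous single-strand
backbone (O3'(i)-P(i+1) = 1.59 A).  The radial scale is compact (C1' at
~5.8 A from the axis) so that a 6 A search sphere centred on the helix axis
contains sugar centroids; the database, targets and maps all derive from the
same template, which is what the tracing contracts require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0e, i1e
from scipy.spatial.transform import Rotation

from .density import AtomRecord, DensityGrid, density_from_atoms, ensemble_minmax_maps
from .fingerprint import FingerprintTarget, derive_probes
from .fragdb import (
    FragmentDatabase,
    NucleotideFragment,
    PHOSPHATE_ATOMS,
    RING_ATOMS,
    build_database,
    superpose_rigid,
)

__all__ = [
    "HelixSpec",
    "make_template",
    "helix_operator",
    "make_helix",
    "perturb_ensemble",
    "degrade_map",
    "fragments_to_atoms",
    "helix_map",
    "default_database",
    "build_default_targets",
]

A_FORM_TWIST = 32.7  # deg per step
A_FORM_RISE = 2.81  # A per step

# idealized ribonucleotide template (frozen output of the dev-time solve)
TEMPLATE_COORDS = {
    "P": (4.4673, -1.6461, -1.3043),
    "OP1": (5.4341, -1.5618, -0.1917),
    "OP2": (3.9021, -2.9724, -1.6226),
    "O5'": (3.2718, -0.6341, -1.0221),
    "C5'": (3.3976, 0.7065, -1.4912),
    "C4'": (4.8046, 0.9261, -2.0153),
    "O4'": (4.8056, -0.5213, -1.9701),
    "C3'": (5.6913, 1.3487, -0.8466),
    "O3'": (4.8893, 1.8961, 0.1950),
    "C2'": (6.2615, 0.0398, -0.2978),
    "C1'": (5.1747, -0.9573, -0.6716),
    "O2'": (7.4678, -0.2688, -0.9684),
    "N9": (3.9660, -1.0097, 0.1496),
}

BASE_RING_RADIUS = 1.17  # A; circumradius of the idealized 5-membered base ring


def _base_ring_atoms() -> dict[str, np.ndarray]:
    """A planar five-membered base ring attached at N9, pointing inward.

    The glycosidic direction continues from C1' through N9; the ring plane
    contains that direction and is roughly perpendicular to the sugar ring,
    emulating how a base extends from the sugar toward the helix axis.
    """
    c1 = np.array(TEMPLATE_COORDS["C1'"])
    n9 = np.array(TEMPLATE_COORDS["N9"])
    ring = np.array([TEMPLATE_COORDS[a] for a in ("C1'", "C2'", "C3'", "C4'", "O4'")])
    d = n9 - c1
    d /= np.linalg.norm(d)
    nrm = np.cross(ring[1] - ring[0], ring[3] - ring[0])
    nrm /= np.linalg.norm(nrm)
    e2 = np.cross(nrm, d)
    e2 /= np.linalg.norm(e2)
    centre = n9 + BASE_RING_RADIUS * d
    names = ("N9", "C4", "C5", "N7", "C8")  # N9 is vertex 0
    out = {}
    for k, name in enumerate(names):
        theta = np.pi + np.deg2rad(72.0 * k)  # vertex 0 back at N9
        out[name] = centre + BASE_RING_RADIUS * (np.cos(theta) * d + np.sin(theta) * e2)
    return out


def base_far_point() -> np.ndarray:
    """The point on the base-ring circle diametrically opposite N9 (a
    conserved density feature not centred on any atom)."""
    c1 = np.array(TEMPLATE_COORDS["C1'"])
    n9 = np.array(TEMPLATE_COORDS["N9"])
    d = n9 - c1
    d /= np.linalg.norm(d)
    return n9 + 2.0 * BASE_RING_RADIUS * d


@dataclass
class HelixSpec:
    """Parameters of an idealized single-strand helix fixture."""

    n_nt: int = 12
    twist: float = A_FORM_TWIST  # deg per step
    rise: float = A_FORM_RISE  # A per step
    seed: int = 0
    b_iso: float = 20.0

    def __post_init__(self):
        if self.n_nt < 1:
            raise ValueError("n_nt must be >= 1")
        if not 0 < self.twist < 360:
            raise ValueError("twist must be in (0, 360) degrees")
        if self.rise <= 0:
            raise ValueError("rise must be positive")


def make_template(with_base: bool = True) -> NucleotideFragment:
    """The idealized template nucleotide in the helix frame (axis = z)."""
    atoms = {k: np.array(v) for k, v in TEMPLATE_COORDS.items()}
    if with_base:
        atoms.update(_base_ring_atoms())
    return NucleotideFragment(atoms=atoms, source_id="template")


def helix_operator(twist: float = A_FORM_TWIST, rise: float = A_FORM_RISE):
    """(R, t) advancing one nucleotide step along the helix axis (z)."""
    R = Rotation.from_euler("z", twist, degrees=True).as_matrix()
    return R, np.array([0.0, 0.0, rise])


def make_helix(spec: HelixSpec) -> list[NucleotideFragment]:
    """Place the template ``n_nt`` times by the helical symmetry operator."""
    R, t = helix_operator(spec.twist, spec.rise)
    frags = []
    tmpl = make_template()
    Ri, ti = np.eye(3), np.zeros(3)
    for i in range(spec.n_nt):
        frags.append(
            NucleotideFragment(
                atoms={k: Ri @ v + ti for k, v in tmpl.atoms.items()}, source_id=f"SYN/{i + 1}"
            )
        )
        Ri, ti = R @ Ri, R @ ti + t
    return frags


_BASE_UNIT = ("N9", "C4", "C5", "N7", "C8")


def _perturbed_atoms(fragment: NucleotideFragment, amplitude: float, rng) -> dict:
    """Zero-mean Gaussian displacements; backbone atoms get independent
    per-atom noise of RMS ``amplitude``, while the two rigid units move as
    wholes — the sugar ring at half amplitude (so ring bond lengths are
    preserved exactly) and the base ring at full amplitude."""
    ring_shift = rng.normal(0.0, amplitude / (2.0 * np.sqrt(3.0)), size=3)
    base_shift = rng.normal(0.0, amplitude / np.sqrt(3.0), size=3)
    atoms = {}
    for name, pos in fragment.atoms.items():
        if name in RING_ATOMS:
            atoms[name] = pos + ring_shift
        elif name in _BASE_UNIT:
            atoms[name] = pos + base_shift
        else:
            atoms[name] = pos + rng.normal(0.0, amplitude / np.sqrt(3.0), size=3)
    return atoms


def perturb_ensemble(
    fragment: NucleotideFragment, n: int, amplitude: float, seed: int = 0
) -> list[NucleotideFragment]:
    """``n`` copies of a fragment with zero-mean random displacements.

    Per-atom displacement vectors have RMS length ``amplitude``; the rigid
    sugar ring is displaced as a unit at half amplitude.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    return [
        NucleotideFragment(
            atoms=_perturbed_atoms(fragment, amplitude, rng),
            source_id=f"{fragment.source_id}/pert{m}",
        )
        for m in range(n)
    ]


def _perturb_chain(frags, amplitude, rng) -> list[NucleotideFragment]:
    return [
        NucleotideFragment(atoms=_perturbed_atoms(f, amplitude, rng), source_id=f.source_id)
        for f in frags
    ]


def fragments_to_atoms(frags, b_iso: float = 20.0) -> list[AtomRecord]:
    """Flatten nucleotide fragments into atom records for map synthesis."""
    atoms = []
    for f in frags:
        for name, pos in f.atoms.items():
            element = "P" if name == "P" else name[0]
            atoms.append(AtomRecord(name=name, element=element, pos=pos, b_iso=b_iso))
    return atoms


def helix_map(
    spec: HelixSpec, spacing: float = 0.5, margin: float = 7.0
) -> tuple[DensityGrid, list[NucleotideFragment], np.ndarray]:
    """Synthesise a helix and its density map.

    Returns (grid, fragments, center): the helix axis runs along z through
    the cell centre, and ``center`` is the mid-height axis point (a natural
    view centre for local searches).
    """
    frags = make_helix(spec)
    coords = np.vstack([f.coords(list(f.atoms)) for f in frags])
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    cell = hi - lo + 2 * margin
    shift = margin - lo
    frags = [
        NucleotideFragment(atoms={k: v + shift for k, v in f.atoms.items()}, source_id=f.source_id)
        for f in frags
    ]
    grid = density_from_atoms(fragments_to_atoms(frags, spec.b_iso), cell=cell, spacing=spacing)
    center = shift + (lo + hi) / 2.0
    center[:2] = shift[:2]  # helix axis is x=y=0 before shifting
    return grid, frags, center


def default_database(seed: int = 0) -> FragmentDatabase:
    """Curated synthetic conformer database: one clean helix plus several
    perturbed ones (independent chains, no cross-links).

    The perturbed chains give the grower a spread of linkage conformations to
    choose from, so density scoring can pull a drifting chain back onto the
    true backbone — the role the diversity of a real reference structure
    plays in the full method.
    """
    rng = np.random.default_rng(seed)
    frags = list(make_helix(HelixSpec(n_nt=16)))
    for amp in (0.15, 0.25, 0.25, 0.35, 0.45):
        chain = _perturb_chain(make_helix(HelixSpec(n_nt=8)), amp, rng)
        # displace so the chains cannot be mistaken for one another
        off = rng.uniform(40.0, 60.0, size=3)
        frags.extend(
            NucleotideFragment(atoms={k: v + off for k, v in f.atoms.items()}, source_id=f.source_id)
            for f in chain
        )
    return build_database(frags)


def _kappa_from_fom(m: np.ndarray) -> np.ndarray:
    """Invert the von Mises mean-resultant identity E[cos dphi] = I1/I0(kappa)."""
    kgrid = np.geomspace(1e-4, 2e4, 6000)
    agrid = i1e(kgrid) / i0e(kgrid)
    return np.interp(m, agrid, kgrid)


def degrade_map(grid: DensityGrid, mean_fom: float, seed: int = 0, fom_jitter: float = 0.1) -> DensityGrid:
    """Add FOM-consistent random phase error to a map.

    The map is Fourier transformed; each coefficient's phase is perturbed by
    an angle drawn from a von Mises distribution whose concentration solves
    E[cos dphi] = m, with per-coefficient m drawn as mean_fom plus Gaussian
    jitter (sigma ``fom_jitter``), clipped to [0, 1].  Hermitian symmetry is
    preserved (mirror coefficients get opposite phase shifts; self-conjugate
    coefficients are untouched), so the output is real and the amplitude
    spectrum is exactly unchanged.
    """
    if not 0.0 <= mean_fom <= 1.0:
        raise ValueError("mean_fom must be in [0, 1]")
    rng = np.random.default_rng(seed)
    F = np.fft.fftn(grid.values)
    shape = np.array(F.shape)
    n = F.size
    # flat indices of each coefficient and of its Hermitian mirror -k mod N
    ix, iy, iz = np.meshgrid(*[np.arange(s) for s in F.shape], indexing="ij")
    fid = (ix * shape[1] + iy) * shape[2] + iz
    mx, my, mz = (-ix) % shape[0], (-iy) % shape[1], (-iz) % shape[2]
    mid = (mx * shape[1] + my) * shape[2] + mz
    fid, mid = fid.ravel(), mid.ravel()

    if mean_fom >= 1.0:
        return grid.copy_with(grid.values.copy())
    else:
        m = np.clip(rng.normal(mean_fom, fom_jitter, size=n), 0.0, 1.0)
        kappa = _kappa_from_fom(m)
        dphi = rng.vonmises(0.0, kappa)
        dphi[m >= 0.999999] = 0.0
    # antisymmetrise: dphi(-k) = -dphi(k); self-conjugate coefficients fixed
    canon = fid < mid
    out_phi = np.zeros(n)
    out_phi[fid[canon]] = dphi[fid[canon]]
    out_phi[mid[canon]] = -dphi[fid[canon]]
    out_phi = out_phi.reshape(F.shape)
    Fd = np.abs(F) * np.exp(1j * (np.angle(F) + out_phi))
    values = np.fft.ifftn(Fd).real
    return grid.copy_with(values)


# ---------------------------------------------------------------------------
# fingerprint-target derivation from synthetic ensembles


def _local_ensemble_maps(
    frame_atoms: tuple[str, ...],
    centre_index: int,
    n_members: int,
    amplitude: float,
    seed: int,
    spacing: float,
    box: float,
    b_iso: float,
) -> tuple[list[DensityGrid], dict[str, np.ndarray]]:
    """Density maps of perturbed helix members in a fragment-local frame.

    Each member is a perturbed 5-nt helix; its middle fragment's conserved
    atoms are superposed onto the template's (centred at the origin) and the
    density of the *whole* member (context included) is rendered on a local
    grid, so conserved neighbour density shows up in the maximum map and low
    probes avoid it.
    """
    rng = np.random.default_rng(seed)
    context = make_helix(HelixSpec(n_nt=5))
    mid = 2
    tmpl = context[mid]
    if all(a in tmpl.atoms for a in frame_atoms):
        anchor = tmpl.coords(frame_atoms)
    else:  # phosphate frame borrows O3' from the 5'-side neighbour
        anchor = np.array(
            [
                context[mid - 1].atoms[a] if a == "O3'" else tmpl.atoms[a]
                for a in frame_atoms
            ]
        )
    centre = anchor.mean(axis=0)
    # template atoms of the fragment (plus the borrowed O3') in the local frame
    local_atoms = {k: v - centre for k, v in tmpl.atoms.items()}
    if "O3'" in frame_atoms and "O3'" not in tmpl.atoms:
        local_atoms["O3'"] = context[mid - 1].atoms["O3'"] - centre
    if frame_atoms == PHOSPHATE_ATOMS:
        local_atoms = {
            "O3'": context[mid - 1].atoms["O3'"] - centre,
            **{k: tmpl.atoms[k] - centre for k in ("P", "OP1", "OP2", "O5'")},
        }

    origin = np.full(3, -box / 2.0)
    cell = np.full(3, box)
    maps = []
    for _ in range(n_members):
        member = _perturb_chain(context, amplitude, rng)
        if frame_atoms == PHOSPHATE_ATOMS:
            moving = np.array(
                [
                    member[mid - 1].atoms["O3'"] if a == "O3'" else member[mid].atoms[a]
                    for a in frame_atoms
                ]
            )
        else:
            moving = member[mid].coords(frame_atoms)
        pl = superpose_rigid(moving, anchor - centre)
        world = []
        for f in member:
            for name, pos in f.atoms.items():
                world.append(
                    AtomRecord(
                        name=name,
                        element="P" if name == "P" else name[0],
                        pos=pl.transform(pos),
                        b_iso=b_iso,
                    )
                )
        maps.append(density_from_atoms(world, cell=cell, spacing=spacing, origin=origin))
    return maps, local_atoms


SUGAR_HIGH_ORDER = ("C1'", "C2'", "C3'", "C4'", "O4'", "C5'", "O3'", "N9")
PHOSPHATE_HIGH_ORDER = ("P", "OP1", "OP2", "O5'", "O3'")


def _far_base_offset(local_atoms: dict[str, np.ndarray]) -> np.ndarray:
    """Far side of the base ring in the local frame (not an atomic centre)."""
    c1, n9 = local_atoms["C1'"], local_atoms["N9"]
    d = n9 - c1
    d /= np.linalg.norm(d)
    return n9 + 2.0 * BASE_RING_RADIUS * d


def build_default_targets(
    seed: int = 0,
    n_members: int = 50,
    amplitude: float = 0.25,
    spacing: float = 0.5,
    min_sep: float = 2.5,
) -> dict[str, FingerprintTarget]:
    """Derive sugar and phosphate fingerprint targets from synthetic ensembles.

    The first high probe is C1' (sugar) / P (phosphate) — the most conserved
    strong density feature of each fragment, as required by the first-probe
    pruning rule.
    """
    out = {}
    for name, frame, order in (
        ("sugar", RING_ATOMS, SUGAR_HIGH_ORDER),
        ("phosphate", PHOSPHATE_ATOMS, PHOSPHATE_HIGH_ORDER),
    ):
        maps, local_atoms = _local_ensemble_maps(
            frame_atoms=frame,
            centre_index=2,
            n_members=n_members,
            amplitude=amplitude,
            seed=seed,
            spacing=spacing,
            box=24.0,
            b_iso=20.0,
        )
        min_map, max_map = ensemble_minmax_maps(maps)
        frag_atoms = [
            AtomRecord(name=a, element="P" if a == "P" else a[0], pos=local_atoms[a])
            for a in order
            if a in local_atoms
        ]
        extra_high = [_far_base_offset(local_atoms)] if name == "sugar" else []
        target = derive_probes(
            min_map, max_map, frag_atoms, extra_high=extra_high,
            radius=6.0, min_sep=min_sep, name=name,
        )
        target.frame_atoms = {k: np.asarray(v) for k, v in local_atoms.items()}
        out[name] = target
    return out
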