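# Methods notes

This note records the models, parameter choices and known limitations behind
`natrace`, in the spirit of a software methods section.

## Density model

Maps are real-space scalar fields on regular grids tiling an orthogonal P1
cell, with periodic (wrap-around) indexing.  Synthetic maps place one
isotropic Gaussian per atom with variance

    s² = B/(8π²) + σ_res²,

integrated weight `occupancy × Z` (Z = electron count), truncated at 4.5 Å.
`σ_res` models resolution blur on top of thermal motion; the default 0.5 Å
follows the common map-synthesis convention σ ≈ 0.225·d at d = 2.2 Å, the
resolution regime the packaged fingerprint targets are modelled on.  Real
maps read from CCP4/MRC files are expanded to the full cell by the I/O
layer; space-group symmetry beyond P1 is out of scope and must be expanded
upstream.

Two lookup modes exist by design: nearest-grid-node for the fast search
path (probe offsets are rounded to grid vectors once per orientation and
reused for every translation) and trilinear interpolation for re-scoring
and growth.  Grid statistics (mean, σ) are whole-grid quantities and feed
the "first probe above mean + 1σ" pruning rule.

## Fingerprint targets

A target holds equal counts of high and low probe offsets in a
fragment-local frame (centre = centroid of the conserved atoms: the five
sugar-ring atoms, or O3′/P/OP1/OP2/O5′ for the phosphate).  The packaged
targets are derived from a synthetic ensemble: 50 five-nucleotide helices
with random atomic displacements (RMS 0.25 Å; rigid units displaced as
wholes), each member superposed by its middle fragment onto the template
frame and rendered as density *with its helical context*, so that conserved
neighbour density appears in the ensemble maximum map and low probes avoid
it.  High probes sit on conserved atoms — C1′ first for sugars, P first for
phosphates (the most conserved strong feature, used for first-probe
pruning) — plus one probe beyond the base ring's far edge (a conserved
feature not centred on an atom; it is what breaks the near-flip symmetry of
an isolated ribose blob).  O2′ is deliberately not a high probe.

Low probes are placed by a rising-contour sweep of the maximum map within
6 Å of the centre: grid points are visited in ascending max-map value and a
probe is placed wherever a new low-density feature is born (a visited point
with no previously visited 26-neighbour), subject to pairwise separation
≥ 2.5 Å; counts are equalised by truncating the longer list.  A constant
maximum map therefore yields exactly one low probe.  Derived low probes are
contracted radially by 1 part in 10⁴ to take them off the exact map
lattice; otherwise a rotated offset can land exactly midway between grid
nodes and nearest-node rounding becomes representation-dependent.

## Search

Orientations: a zyz Euler grid with β uniform in the step and the γ count
scaled by sin β (near the poles α and γ act on the same degree of freedom).
At the default 18° step this yields 2680 orientations whose empirical
covering radius is ~14°.  Translations: grid nodes within 6 Å of the view
centre (or the whole grid in whole-cell mode).

Scoring uses s_minmax with three optimisations: per-orientation offset
rounding; immediate elimination of translations whose first-high-probe
density is below mean + 1σ (this filter is lossy by design and is treated
as part of the method, not an approximation to be undone); and early
termination against a live threshold equal to the worst member of a best-50
list, floored at the initial threshold 0.  The threshold is re-read once
per orientation batch; this is provably equivalent in output to continuous
per-candidate updating, since a threshold at or below the 50th-best score
never discards a final member.  Survivors are re-scored with interpolated
s_mean, placements with non-positive s_mean are dropped (this is what keeps
flat or featureless regions empty-handed), and results are ordered by
s_mean with deterministic tie-breaks (distance to centre, then orientation
index).  An exhaustive-enumeration oracle in the test suite confirms the
pruned search is exact, not approximate, over the same candidate set.

## Conformer database and growing

The database stores one entry per nucleotide (main-chain atoms, base
anchor) with 5′/3′ adjacency where O3′–P < 2 Å.  Superpositions are
least-squares rigid fits (proper rotations only) on the sugar ring
(C1′, C2′, C3′, C4′, O4′) or the phosphate group.  Rare conformers can be
removed by iteratively discarding the fragment whose probe atom (O2′ for
sugars; C5′ and C3′ for phosphates) lies farthest (> 1 Å) from the ensemble
mean, recomputing after each removal.

Growth alternates 3′ and 5′ extensions.  Candidates are scored by
s_mean(new sugar) + s_mean(intervening phosphate); the best is accepted if
its *sugar* score exceeds the calibrated threshold (the phosphate score
ranks candidates but does not gate acceptance) and its C1′ is ≥ 3 Å from
every C1′ already in the trace.  The clash rule is what stops the grower
from retracing its own path; without it the extension step oscillates.  On
5′ acceptance the old terminal's placeholder phosphate is replaced by the
intervening group so O3′–P continuity holds along the chain.  The
acceptance threshold is the empirical 99.9% quantile of s_mean over 100 000
uniformly random placements in the current map, calibrated once per map.

The packaged synthetic database (one ideal 16-nt helix plus five 8-nt
helices perturbed at RMS 0.15–0.45 Å) is intentionally *diverse*: the
spread of linkage conformations is what lets density scoring pull a
drifting chain back onto the true backbone, the role played by the
conformational variety of a real reference structure when the database is
built from a deposited model (`natrace trace --db reference.pdb`).

Merging unions traces that share at least two consecutive nucleotides (C1′
within 1 Å, same 5′→3′ direction); at branch points the continuation with
the higher remaining summed score survives.  This is a score-greedy
simplification of full graph-based branch resolution; it never increases
the number of distinct nucleotide positions.  Traces shorter than three
nucleotides are rejected.

## Synthetic fixtures and what they do (not) show

The template ribonucleotide was solved once by least squares over standard
bond/angle restraints plus a helix-closure constraint, so that the helical
operator (twist 32.7°, rise 2.81 Å) generates a covalently continuous
single strand (O3′–P = 1.59 Å).  Its radial scale is compact (C1′ at
~5.3 Å, ring centroids at ~5.4 Å from the axis) so that a 6 Å search sphere
centred on the helix axis — the canonical interactive use — contains sugar
centroids; a duplex-accurate A-form radius (~9.4 Å) would place every sugar
outside that sphere.  A planar five-membered base ring is attached at N9,
pointing inward, because base density is what real maps provide as the
orientation anchor.  Consequences: C1′–C1′ steps are ~4.1 Å (real A-RNA:
~5.9 Å), and the fixtures exercise single strands, not duplexes.

Phase-error degradation Fourier-transforms the map, perturbs each
coefficient's phase by a von Mises deviate whose concentration solves
E[cos Δφ] = m (the standard acentric FOM relation), with per-coefficient m
drawn as mean FOM + Gaussian jitter (σ 0.1, clipped to [0, 1]), and
inverts.  Hermitian symmetry is preserved exactly (mirror coefficients get
opposite shifts; self-conjugate ones are untouched), so amplitudes are
unchanged and the output is real.  The FOM profile is flat in resolution;
experimentally phased data have better low-resolution phases, so a given
mean FOM here is *harsher* than the same mean FOM in a real map.  Passing
recovery tests on these fixtures demonstrates the search/grow/merge
machinery under controlled degradation; it does not demonstrate performance
on real crystallographic maps with solvent, model bias, or non-P1 symmetry.

Parameter recovery is evaluated as C1′ coverage at 1.5 Å.  Because a single
phase-error realisation makes a short helix succeed or fail almost
atomically, degradation behaviour is measured as the mean over three noise
realisations per FOM level; on 12-nt fixtures this mean is monotone in FOM
(12.0 / 6.7 / 6.3 built at FOM 1.0 / 0.8 / 0.6 under the default seeds of
the acceptance suite, i.e. ~53% at FOM 0.6).

## Numerical choices and degenerate inputs

- Initial search threshold 0; score ties at the best-list boundary resolve
  by (distance, orientation index, candidate index).
- Constant maps: both scores are 0 everywhere; calibration returns a
  threshold of 0 flagged `degenerate`; searches return nothing because the
  s_mean > 0 filter fails.
- `seed_from_phosphate` ties resolve to the lowest database index.
- Superposition refuses reflections (det = +1 enforced); collinear point
  sets are flagged with a warning.
- Ensemble pruning removes the single worst fragment per iteration
  (recompute-after-each-removal reading of successive removal).
- Problem sizes in the test and acceptance runs: 12-nt helices on ~57×58×97
  grids at 0.5 Å, 32³ grids for search-oracle equivalence, 100 000-placement
  threshold calibrations, three noise realisations per FOM level.

## Known limitations

- No sugar-pucker assignment, base typing, or torsion regularisation; built
  residues are written as "U" with a REMARK noting unassigned bases.
  Downstream rebuilding/refinement tools are expected to consume the trace.
- No structure-factor engine: maps come from real-space Gaussians, not from
  reflections; centric reflections are not special-cased in degradation.
- Non-orthogonal cells and space-group symmetry are not handled internally;
  supply full-cell P1 maps.
- Merging is pairwise score-greedy; pathological many-way branch topologies
  may merge sub-optimally.
- The whole-cell search mode scales linearly with grid size and is meant
  for small cells; it is not an FFT translational search by design.
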