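"""Fingerprint scoring, rotation sampling, probe derivation and the pruned
local search."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from natrace import (
    AtomRecord,
    DensityGrid,
    FingerprintTarget,
    Placement,
    density_from_atoms,
    derive_probes,
    sample_rotations,
    score_mean,
    score_minmax,
    score_minmax_pruned,
    search_local,
)


def constant_grid(value=0.0, n=12, cell=12.0):
    return DensityGrid(values=np.full((n, n, n), value), cell=np.array([cell] * 3))


def toy_target(high, low):
    return FingerprintTarget(name="toy", high_probes=np.array(high), low_probes=np.array(low))


def random_placements(rng, n, box=12.0):
    rots = Rotation.random(n, random_state=rng).as_matrix()
    trans = rng.uniform(0.0, box, size=(n, 3))
    return [Placement(rotation=R, translation=t) for R, t in zip(rots, trans)]


@pytest.fixture(scope="module")
def bumpy_grid():
    rng = np.random.default_rng(7)
    atoms = [
        AtomRecord(name="C", element="C", pos=rng.uniform(2.0, 10.0, 3), b_iso=rng.uniform(15, 40))
        for _ in range(25)
    ]
    return density_from_atoms(atoms, cell=(12.0, 12.0, 12.0), spacing=0.5)


class TestScores:
    def test_constant_map_scores_zero(self, sugar_target):
        grid = constant_grid(3.7)
        pl = Placement(rotation=np.eye(3), translation=np.array([6.0, 6.0, 6.0]))
        assert score_mean(sugar_target, grid, pl) == pytest.approx(0.0, abs=1e-12)
        assert score_minmax(sugar_target, grid, pl) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_values(self):
        """High densities {2,3,4}, low {1,0,-1}: s_mean = 3 - 0 = 3 and
        s_minmax = 2 - 1 = 1."""
        grid = constant_grid(0.0, n=16, cell=16.0)
        hi_off = np.array([[1.0, 0, 0], [0, 2.0, 0], [0, 0, 3.0]])
        lo_off = np.array([[-1.0, 0, 0], [0, -2.0, 0], [0, 0, -3.0]])
        t = np.array([8.0, 8.0, 8.0])
        for off, val in zip(hi_off, (2.0, 3.0, 4.0)):
            idx = tuple(np.rint(t + off).astype(int))
            grid.values[idx] = val
        for off, val in zip(lo_off, (1.0, 0.0, -1.0)):
            idx = tuple(np.rint(t + off).astype(int))
            grid.values[idx] = val
        grid = DensityGrid(values=grid.values, cell=grid.cell)  # refresh stats
        target = toy_target(hi_off, lo_off)
        pl = Placement(rotation=np.eye(3), translation=t)
        assert score_mean(target, grid, pl, interpolated=False) == pytest.approx(3.0)
        assert score_minmax(target, grid, pl) == pytest.approx(1.0)

    def test_score_mean_matches_per_probe_oracle(self, sugar_target, bumpy_grid):
        from natrace.density import interpolate

        rng = np.random.default_rng(11)
        for pl in random_placements(rng, 20):
            vals = [interpolate(bumpy_grid, pl.transform(p)) for p in sugar_target.high_probes]
            low = [interpolate(bumpy_grid, pl.transform(p)) for p in sugar_target.low_probes]
            oracle = np.mean(vals) - np.mean(low)
            assert score_mean(sugar_target, bumpy_grid, pl) == pytest.approx(oracle, abs=1e-12)

    def test_minmax_le_mean(self, sugar_target, bumpy_grid):
        rng = np.random.default_rng(13)
        for pl in random_placements(rng, 1000):
            s_mm = score_minmax(sugar_target, bumpy_grid, pl)
            s_me = score_mean(sugar_target, bumpy_grid, pl, interpolated=False)
            assert s_mm <= s_me + 1e-12

    def test_shift_invariance_and_scaling(self, sugar_target, bumpy_grid):
        """Both scores are differences (constant-shift invariant) and are
        homogeneous of degree one in the map values."""
        rng = np.random.default_rng(17)
        shifted = bumpy_grid.copy_with(bumpy_grid.values + 5.0)
        scaled = bumpy_grid.copy_with(bumpy_grid.values * 2.5)
        for pl in random_placements(rng, 50):
            s_me = score_mean(sugar_target, bumpy_grid, pl)
            s_mm = score_minmax(sugar_target, bumpy_grid, pl)
            assert score_mean(sugar_target, shifted, pl) == pytest.approx(s_me, abs=1e-9)
            assert score_minmax(sugar_target, shifted, pl) == pytest.approx(s_mm, abs=1e-9)
            assert score_mean(sugar_target, scaled, pl) == pytest.approx(2.5 * s_me, abs=1e-9)
            assert score_minmax(sugar_target, scaled, pl) == pytest.approx(2.5 * s_mm, abs=1e-9)


class TestPrunedScore:
    def test_no_pruning_at_minus_infinity(self, sugar_target, bumpy_grid):
        rng = np.random.default_rng(19)
        for pl in random_placements(rng, 200):
            s = score_minmax_pruned(sugar_target, bumpy_grid, pl, -np.inf)
            assert s == pytest.approx(score_minmax(sugar_target, bumpy_grid, pl), abs=1e-12)

    def test_first_pair_rejection(self):
        grid = constant_grid(0.0, n=16, cell=16.0)
        grid.values[9, 8, 8] = 1.0  # high probe density 1
        grid.values[7, 8, 8] = 2.0  # low probe density 2
        grid = DensityGrid(values=grid.values, cell=grid.cell)
        target = toy_target([[1.0, 0, 0], [0, 1.0, 0]], [[-1.0, 0, 0], [0, -1.0, 0]])
        pl = Placement(rotation=np.eye(3), translation=np.array([8.0, 8.0, 8.0]))
        assert score_minmax_pruned(target, grid, pl, threshold=0.0) is None

    def test_accepted_set_matches_brute_force(self, sugar_target, bumpy_grid):
        rng = np.random.default_rng(23)
        threshold = 0.05
        placements = random_placements(rng, 10_000)
        full = np.array([score_minmax(sugar_target, bumpy_grid, p) for p in placements])
        pruned = [
            score_minmax_pruned(sugar_target, bumpy_grid, p, threshold) for p in placements
        ]
        accepted = np.array([s is not None for s in pruned])
        np.testing.assert_array_equal(accepted, full >= threshold)
        for s, f, a in zip(pruned, full, accepted):
            if a:
                assert s == pytest.approx(f, abs=1e-12)


def rotation_angle_deg(R1, R2):
    return np.degrees(np.linalg.norm(Rotation.from_matrix(R1.T @ R2).as_rotvec()))


class TestRotationSampling:
    def test_coarse_step_includes_identity(self):
        rots = sample_rotations(90.0)
        assert any(np.allclose(R, np.eye(3), atol=1e-9) for R in rots)
        assert len(rots) < 200

    def test_count_at_18_degrees(self):
        assert 2000 <= len(sample_rotations(18.0)) <= 4200

    def test_covering_at_18_degrees(self):
        rots = sample_rotations(18.0)
        quats = Rotation.from_matrix(rots).as_quat()
        rng = np.random.default_rng(29)
        sample = Rotation.random(300, random_state=rng).as_quat()
        dots = np.abs(sample @ quats.T).clip(max=1.0)
        worst = np.degrees(2 * np.arccos(dots.max(axis=1))).max()
        assert worst <= 18.0

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            sample_rotations(0.0)
        with pytest.raises(ValueError):
            sample_rotations(-5.0)


class TestDeriveProbes:
    def _frag_atoms(self):
        return [AtomRecord(name="C1'", element="C", pos=np.zeros(3))]

    def _flat_maps(self, value=1.0):
        n = 25
        cell = np.array([12.5] * 3)
        origin = np.full(3, -6.0)  # node 12 sits exactly at the origin
        vals = np.full((n, n, n), value)
        lo = DensityGrid(values=vals.copy(), cell=cell, origin=origin)
        hi = DensityGrid(values=vals.copy(), cell=cell, origin=origin)
        return lo, hi

    def test_constant_max_map_places_single_low_probe(self):
        lo, hi = self._flat_maps()
        target = derive_probes(lo, hi, self._frag_atoms(), radius=5.0, min_sep=2.0)
        assert target.n == 1

    def test_two_isolated_minima_both_probed(self):
        lo, hi = self._flat_maps(value=2.0)
        # carve two separated wells in the maximum map
        hi.values[12 + 8, 12, 12] = 0.0
        hi.values[12 - 8, 12, 12] = 0.5
        hi = DensityGrid(values=hi.values, cell=hi.cell, origin=hi.origin)
        frag = [
            AtomRecord(name="C1'", element="C", pos=np.zeros(3)),
            AtomRecord(name="C2'", element="C", pos=np.array([1.5, 0, 0])),
        ]
        target = derive_probes(lo, hi, frag, radius=5.0, min_sep=2.0)
        assert target.n == 2
        lows = target.low_probes
        assert np.linalg.norm(lows[0] - lows[1]) >= 2.0
        found = {tuple(np.sign(p).astype(int)) for p in lows}
        assert (1, 0, 0) in found and (-1, 0, 0) in found

    def test_derived_sugar_target_separates_high_from_low(self):
        """High probes must sit on conserved density (high minimum-map value)
        and low probes on conserved holes, for an ensemble of synthetic
        nucleotide maps."""
        from natrace.density import interpolate
        from natrace.synthetic import build_default_targets, _local_ensemble_maps
        from natrace.density import ensemble_minmax_maps
        from natrace.fragdb import RING_ATOMS

        maps, _ = _local_ensemble_maps(
            frame_atoms=RING_ATOMS, centre_index=2, n_members=16, amplitude=0.25,
            seed=5, spacing=0.5, box=24.0, b_iso=20.0,
        )
        lo, hi = ensemble_minmax_maps(maps)
        target = build_default_targets(seed=5, n_members=16)["sugar"]
        high_min = interpolate(lo, target.high_probes)
        low_max = interpolate(hi, target.low_probes)
        assert high_min.min() > low_max.max()


class TestSearchLocal:
    def test_flat_map_returns_nothing(self, sugar_target):
        grid = constant_grid(0.0, n=24, cell=12.0)
        hits = search_local(grid, sugar_target, center=np.array([6.0, 6.0, 6.0]), radius=5.0)
        assert hits == []

    def test_recovers_known_placement(self, sugar_target, single_sugar_case):
        grid, truth = single_sugar_case
        hits = search_local(grid, sugar_target, center=truth.translation + 0.3, radius=6.0)
        assert hits
        top = hits[0]
        diag = np.linalg.norm(grid.spacing)
        assert np.linalg.norm(top.translation - truth.translation) <= diag
        assert rotation_angle_deg(top.rotation, truth.rotation) <= 18.0
        assert top.score_mean > 0 and top.score_minmax >= 0

    def test_recovery_robust_at_coarser_grid(self, sugar_target):
        rot = Rotation.from_euler("zyz", [40, 55, 10], degrees=True).as_matrix()
        trans = np.array([10.2, 9.7, 10.4])
        pl = Placement(rotation=rot, translation=trans)
        atoms = [
            AtomRecord(name=k, element="P" if k == "P" else k[0], pos=pl.transform(v))
            for k, v in sugar_target.frame_atoms.items()
        ]
        grid = density_from_atoms(atoms, cell=(20.0, 20.0, 20.0), spacing=0.7)
        hits = search_local(grid, sugar_target, center=trans + 0.3, radius=6.0)
        assert hits
        assert np.linalg.norm(hits[0].translation - trans) <= np.linalg.norm(grid.spacing)
        assert rotation_angle_deg(hits[0].rotation, rot) <= 18.0

    def test_radius_below_grid_step_rejected(self, sugar_target):
        grid = constant_grid(1.0, n=12, cell=12.0)
        with pytest.raises(ValueError):
            search_local(grid, sugar_target, center=np.array([6.1, 6.1, 6.1]), radius=0.2)

    def test_whole_grid_search_agrees_with_local(self, sugar_target):
        """On a cell small enough that everything lies within the local
        sphere, whole-grid search finds the same best placement."""
        from natrace.synthetic import HelixSpec, helix_map

        grid, frags, center = helix_map(HelixSpec(n_nt=2), spacing=0.7, margin=5.0)
        local = search_local(grid, sugar_target, center, radius=6.0, step_deg=36.0, n_best=10)
        whole = search_local(grid, sugar_target, None, step_deg=36.0, n_best=10)
        assert local and whole
        np.testing.assert_allclose(whole[0].translation, local[0].translation, atol=1e-9)
        np.testing.assert_allclose(whole[0].rotation, local[0].rotation, atol=1e-9)
        assert whole[0].score_mean == pytest.approx(local[0].score_mean, abs=1e-12)
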