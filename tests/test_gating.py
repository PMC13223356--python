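"""χ2 gating, velocity/gliding, tail-plane angles and salt bridges."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from cetpdyn import synthetic
from cetpdyn.gating import (
    DihedralSeries,
    chi2_series,
    detect_gate_events,
    detect_glide_events,
    dihedral_angle,
    instantaneous_velocity,
    normalize_chi2,
    salt_bridges,
    tail_plane_angle,
)
from cetpdyn.lipidpath import LipidTrace
from cetpdyn.trajectory import Frame, TrajectoryEnsemble

from conftest import toy_structure


def _brute_dihedral(p0, p1, p2, p3):
    """Independent atan2 dihedral for the oracle-equivalence check."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return np.degrees(np.arctan2(y, x))


class TestDihedral:
    def test_planar_cis_zero(self):
        p = [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]]
        assert dihedral_angle(*p) == pytest.approx(0.0, abs=1e-5)

    def test_trans_180(self):
        p = [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]]
        assert abs(dihedral_angle(*p)) == pytest.approx(180.0, abs=1e-5)

    def test_oracle_equivalence_random_quadruples(self):
        """Implementation agrees with the brute-force atan2 formula."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            pts = rng.normal(size=(4, 3))
            got = dihedral_angle(*pts)
            ref = _brute_dihedral(*pts)
            d = (got - ref + 180.0) % 360.0 - 180.0
            assert abs(d) < 1e-3  # float32 path inside the library call


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [(-170.0, 10.0), (170.0, -10.0), (0.0, 0.0), (90.0, 90.0), (-90.0, 90.0),
         (135.0, -45.0)],
    )
    def test_ring_symmetry(self, raw, expected):
        assert normalize_chi2(np.array([raw]))[0] == pytest.approx(expected)

    def test_constant_series_smoothing_identity(self):
        s = DihedralSeries(times=np.arange(50.0), raw=np.full(50, 33.0), window_ps=20)
        assert np.allclose(s.smoothed, 33.0)


class TestChi2Series:
    def _phe_ensemble(self, chi2_per_frame):
        """Four-atom residue posed to a prescribed χ2 per frame."""
        frames = []
        for chi in chi2_per_frame:
            rad = np.radians(chi)
            # CA-CB along z, CG at the dihedral hinge, CD1 rotated by chi
            ca = [0.0, 1.0, -1.0]
            cb = [0.0, 0.0, -1.0]
            cg = [0.0, 0.0, 0.0]
            cd1 = [np.sin(rad), np.cos(rad), 0.3]
            frames.append(np.array([ca, cb, cg, cd1]))
        s = toy_structure(frames[0], names=["CA", "CB", "CG", "CD1"],
                          resids=[263] * 4, resnames=["PHE"] * 4)
        return TrajectoryEnsemble(s, [Frame(i * 2.0, c) for i, c in enumerate(frames)])

    def test_recovers_posed_angles(self):
        target = [0.0, 30.0, 60.0, -45.0]
        ens = self._phe_ensemble(target)
        series = chi2_series(ens, 263)
        for got, want in zip(series.raw, target):
            d = (got - want + 180.0) % 360.0 - 180.0
            assert abs(d) < 0.01

    def test_missing_atom_named(self):
        s = toy_structure(np.zeros((3, 3)), names=["CA", "CB", "CG"],
                          resids=[263] * 3, resnames=["PHE"] * 3)
        ens = TrajectoryEnsemble(s, [Frame(0.0, np.zeros((3, 3)))])
        with pytest.raises(ValueError, match="CD1"):
            chi2_series(ens, 263)


class TestGateDetector:
    def test_injected_excursion_with_lipid(self):
        series, truth = synthetic.gen_rotamer_series(
            baseline_deg=0.0, flip_intervals_ps=[(400.0, 800.0)], delta_deg=50.0,
            noise_sd_deg=2.0, dt_ps=2.0, n_frames=1000, seed=1,
        )
        # lipid passes the residue during the excursion
        n = len(series)
        com = np.full((n, 3), 10.0)
        inside = truth["flipped"]
        com[inside] = [0.0, 0.0, 0.5]
        trace = LipidTrace(times=series.times, com=com, s=com[:, 2],
                           r=np.zeros(n))
        events = detect_gate_events(series, trace, residue_position=np.zeros(3))
        assert len(events) == 1
        ev = events[0]
        flip_frames = np.flatnonzero(truth["flipped"])
        assert ev.open_frame < flip_frames[-1] and ev.close_frame > flip_frames[0]
        assert ev.lipid_coincident

    def test_noise_only_no_events(self):
        for seed in range(5):
            series, _ = synthetic.gen_rotamer_series(
                baseline_deg=0.0, flip_intervals_ps=[], delta_deg=0.0,
                noise_sd_deg=5.0, dt_ps=2.0, n_frames=1000, seed=seed,
            )
            assert detect_gate_events(series) == []

    def test_below_threshold_delta_ignored(self):
        series, _ = synthetic.gen_rotamer_series(
            baseline_deg=0.0, flip_intervals_ps=[(400.0, 800.0)], delta_deg=10.0,
            noise_sd_deg=0.0, dt_ps=2.0, n_frames=1000, seed=0,
        )
        assert detect_gate_events(series, rotation_threshold_deg=40.0) == []

    def test_excursion_without_lipid_flag_false(self):
        series, _ = synthetic.gen_rotamer_series(
            baseline_deg=0.0, flip_intervals_ps=[(400.0, 800.0)], delta_deg=50.0,
            noise_sd_deg=0.0, dt_ps=2.0, n_frames=1000, seed=0,
        )
        n = len(series)
        trace = LipidTrace(times=series.times, com=np.full((n, 3), 10.0),
                           s=np.zeros(n), r=np.zeros(n))
        events = detect_gate_events(series, trace, residue_position=np.zeros(3))
        assert len(events) == 1
        assert not events[0].lipid_coincident

    def test_recall_precision_sweep(self):
        """Noise-free telegraph signals: every excursion >= threshold is
        found (recall 1) and nothing else (precision 1)."""
        for delta in (40.0, 50.0, 70.0, 85.0):
            series, truth = synthetic.gen_rotamer_series(
                baseline_deg=-20.0,
                flip_intervals_ps=[(200.0, 400.0), (1200.0, 1500.0)],
                delta_deg=delta, noise_sd_deg=0.0, dt_ps=2.0, n_frames=1000, seed=0,
            )
            events = detect_gate_events(series, rotation_threshold_deg=40.0)
            assert len(events) == 2
            flips = truth["flipped"]
            for ev in events:
                assert flips[(ev.open_frame + ev.close_frame) // 2]


class TestVelocity:
    def _trace(self, s, dt=10.0):
        s = np.asarray(s, dtype=float)
        return LipidTrace(times=np.arange(len(s)) * dt,
                          com=np.column_stack([np.zeros_like(s), np.zeros_like(s), s]),
                          s=s, r=np.zeros_like(s))

    @pytest.mark.parametrize("window", [1, 3, 5, 9])
    def test_affine_exact_any_window(self, window):
        """v(t)=1 nm/ns recovered exactly for linear s(t), any smoothing."""
        t = np.arange(50) * 10.0
        v = instantaneous_velocity(self._trace(1.0e-3 * t + 0.2), window_frames=window)
        assert np.allclose(v, 1.0, atol=1e-12)

    def test_constant_zero(self):
        v = instantaneous_velocity(self._trace(np.full(30, 2.0)))
        assert np.allclose(v, 0.0)

    def test_quadratic_linear_velocity(self):
        """s = ½at² gives v = a·t within finite-difference error."""
        a = 2.0e-6  # nm/ps²
        t = np.arange(200) * 10.0
        v = instantaneous_velocity(self._trace(0.5 * a * t**2), window_frames=1)
        expect = a * t * 1000.0
        assert np.abs(v[1:-1] - expect[1:-1]).max() < 1e-9

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            instantaneous_velocity(self._trace(np.arange(4.0)), window_frames=5)


class TestGlideDetector:
    def test_injected_spike_with_contact(self):
        trace, truth = synthetic.gen_transit_trace(
            n_frames=400, dt_ps=10.0, mean_velocity_nm_ns=1.0,
            spike_times_ps=[2000.0], spike_magnitudes_nm_ns=[5.0],
            noise_sd_nm=0.005, seed=0,
        )
        v = instantaneous_velocity(trace)
        pl = np.zeros(len(v), dtype=bool)
        fr = truth["spike_frames"][0]
        pl[fr - 10: fr + 10] = True
        events = detect_glide_events(v, pl)
        assert len(events) == 1
        assert events[0].pl_contact
        assert events[0].start_frame <= fr <= events[0].end_frame

    def test_no_spikes_empty(self):
        trace, _ = synthetic.gen_transit_trace(
            n_frames=300, dt_ps=10.0, mean_velocity_nm_ns=1.0,
            noise_sd_nm=0.005, seed=1,
        )
        assert detect_glide_events(instantaneous_velocity(trace)) == []

    def test_spike_without_contact_flag_false(self):
        trace, truth = synthetic.gen_transit_trace(
            n_frames=400, dt_ps=10.0, mean_velocity_nm_ns=1.0,
            spike_times_ps=[2000.0], spike_magnitudes_nm_ns=[5.0],
            noise_sd_nm=0.005, seed=2,
        )
        events = detect_glide_events(instantaneous_velocity(trace),
                                     np.zeros(400, dtype=bool))
        assert len(events) == 1
        assert not events[0].pl_contact

    def test_zero_variance_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            events = detect_glide_events(np.full(100, 1.0))
        assert events == []
        assert any("zero-variance" in r.message for r in caplog.records)


class TestTailPlane:
    def _pl_ensemble(self, vec_b, n_frames=3):
        """Two 3-atom tails: tail A along +z, tail B along vec_b."""
        vec_b = np.asarray(vec_b, dtype=float)
        coords = np.zeros((6, 3))
        for i in range(3):
            coords[i] = [0, 0, 0.14 * i]
            coords[3 + i] = np.array([1.0, 0, 0]) + vec_b * 0.14 * i
        s = toy_structure(coords, names=["C1A", "C2A", "C3A", "C1B", "C2B", "C3B"],
                          resids=[1] * 6, resnames=["POPC"] * 6)
        return TrajectoryEnsemble(s, [Frame(i * 10.0, coords) for i in range(n_frames)])

    def test_parallel(self):
        ens = self._pl_ensemble([0, 0, 1.0])
        tps = tail_plane_angle(ens, "name C1A C2A C3A", "name C1B C2B C3B")
        assert np.allclose(tps.angles, 0.0)
        assert tps.parallel.all()

    def test_antiparallel(self):
        ens = self._pl_ensemble([0, 0, -1.0])
        tps = tail_plane_angle(ens, "name C1A C2A C3A", "name C1B C2B C3B")
        assert np.allclose(tps.angles, 180.0)
        assert not tps.parallel.any()

    def test_orthogonal(self):
        ens = self._pl_ensemble([0, 1.0, 0])
        tps = tail_plane_angle(ens, "name C1A C2A C3A", "name C1B C2B C3B")
        assert np.allclose(tps.angles, 90.0)
        assert not tps.parallel.any()

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_rigid_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        ens = self._pl_ensemble(rng.normal(size=3))
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3)
        moved = TrajectoryEnsemble(
            ens.structure, [Frame(f.time, f.coords @ rot.T + shift) for f in ens.frames]
        )
        a = tail_plane_angle(ens, "name C1A C2A C3A", "name C1B C2B C3B")
        b = tail_plane_angle(moved, "name C1A C2A C3A", "name C1B C2B C3B")
        assert np.allclose(a.angles, b.angles, atol=1e-8)


class TestSaltBridges:
    def _ensemble(self, nh1_distance_per_frame):
        """Arg NH1 at a controlled distance from a phosphate oxygen."""
        frames = []
        for d in nh1_distance_per_frame:
            coords = np.array([
                [d, 0.0, 0.0],   # NH1
                [d, 0.3, 0.0],   # NH2
                [0.0, 0.0, 0.0],  # phosphate O
            ])
            frames.append(coords)
        s = toy_structure(frames[0], names=["NH1", "NH2", "O13"],
                          resids=[201, 201, 900], resnames=["ARG", "ARG", "POPC"],
                          elements=["N", "N", "O"])
        return TrajectoryEnsemble(s, [Frame(i * 10.0, c) for i, c in enumerate(frames)])

    def test_always_formed(self):
        recs = salt_bridges(self._ensemble([0.35] * 10), "resid 900")
        assert len(recs) == 1
        assert recs[0].occupancy == 1.0
        assert recs[0].mean_distance_nm == pytest.approx(0.35)

    def test_never_formed(self):
        recs = salt_bridges(self._ensemble([0.45] * 10), "resid 900")
        assert recs[0].occupancy == 0.0
        assert np.isnan(recs[0].mean_distance_nm)

    def test_half_formed(self):
        recs = salt_bridges(self._ensemble([0.35] * 5 + [0.45] * 5), "resid 900")
        assert recs[0].occupancy == pytest.approx(0.5)

    def test_unmapped_residue_skipped(self, caplog):
        ens = self._ensemble([0.35] * 4)
        with caplog.at_level("WARNING"):
            recs = salt_bridges(ens, "resid 900", charged_residues=[201, 900])
        assert [r.resid for r in recs] == [201]
        assert any("no charged-atom map" in r.message for r in caplog.records)
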