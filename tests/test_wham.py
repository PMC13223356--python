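"""WHAM: binning, solver oracles, bootstrap errors, convergence blocks."""

import numpy as np
import pytest

from cetpdyn import synthetic, wham
from cetpdyn.constants import KB_KCAL
from cetpdyn.synthetic import AnalyticPMFSpec
from cetpdyn.wham import (
    UmbrellaWindow,
    bin_windows,
    bootstrap_pmf,
    convergence_blocks,
    read_manifest,
    read_pullx,
    wham_solve,
    write_pullx,
)

KT = KB_KCAL * 300.0


def _window(center, k=500.0, rc=None, times=None, **kw):
    rc = np.asarray(rc if rc is not None else [center], dtype=float)
    times = np.asarray(times if times is not None else np.arange(1, len(rc) + 1),
                       dtype=float)
    return UmbrellaWindow(center_nm=center, k_kj_mol_nm2=k, times_ps=times,
                          rc_nm=rc, **kw)


class TestPullxIO:
    def test_roundtrip(self, tmp_path):
        w = _window(0.3, rc=np.linspace(0.2, 0.4, 50))
        p = write_pullx(w, tmp_path / "w.pullx")
        back = read_pullx(p, 0.3, 500.0)
        assert np.allclose(back.rc_nm, w.rc_nm)
        assert np.allclose(back.times_ps, w.times_ps)

    def test_comment_dialects(self, tmp_path):
        p = tmp_path / "g.xvg"
        p.write_text("# gromacs\n@ title\n0.0 0.10\n1.0 0.11\n")
        w = read_pullx(p, 0.1, 500.0)
        assert len(w.rc_nm) == 2

    def test_malformed_line_numbered(self, tmp_path):
        p = tmp_path / "bad.pullx"
        p.write_text("0.0 0.1\nonlyonecolumn\n")
        with pytest.raises(ValueError, match=":2:"):
            read_pullx(p, 0.1, 500.0)

    def test_manifest(self, tmp_path):
        for i, c in enumerate((0.0, 0.1)):
            write_pullx(_window(c, rc=np.full(20, c)), tmp_path / f"w{i}.pullx")
        man = tmp_path / "windows.tsv"
        man.write_text(
            "file\tcenter_nm\tk_kJ_mol_nm2\nw0.pullx\t0.0\t500\nw1.pullx\t0.1\t500\n"
        )
        windows = read_manifest(man)
        assert [w.center_nm for w in windows] == [0.0, 0.1]


class TestBinWindows:
    def test_single_window_one_bin_mass(self):
        w = _window(0.1, rc=np.full(100, 0.105))
        binned = bin_windows([w], 0.0, 0.2, n_bins=10)
        assert binned.counts.sum() == 100
        assert (binned.counts[0] > 0).sum() == 1

    def test_periodic_min_image_bias(self):
        """Near the seam the bias distance wraps: center L-0.05 vs bin at 0
        is 0.05 away, not L-0.05."""
        L = 2.0
        w = _window(L - 0.05, rc=np.array([0.01]))
        binned = bin_windows([w], 0.0, L, n_bins=100, periodic=True)
        k_kcal = w.k_kcal
        b0 = binned.bias_kcal[0, 0]
        center0 = binned.bin_centers[0]
        expect = 0.5 * k_kcal * (center0 + 0.05) ** 2  # wrapped distance
        assert b0 == pytest.approx(expect, rel=1e-9)
        assert b0 < 0.5 * k_kcal * (L - 0.06) ** 2

    def test_gap_diagnostic(self, caplog):
        a = _window(0.0, rc=np.full(50, 0.0))
        b = _window(1.0, rc=np.full(50, 1.0))
        with caplog.at_level("WARNING"):
            binned = bin_windows([a, b], -0.1, 1.1, n_bins=60)
        assert binned.overlap_fraction == 0.0
        assert len(binned.gaps) == 1

    def test_empty_window_named(self):
        w = _window(0.5, rc=np.array([0.5]), times=np.array([1.0]),
                    equilibration_cutoff_ps=10.0, name="w5")
        with pytest.raises(ValueError, match="w5"):
            bin_windows([w], 0.0, 1.0, n_bins=10)


class TestWhamSolve:
    def test_unbiased_uniform_flat(self):
        rng = np.random.default_rng(0)
        w = _window(0.5, k=1e-9, rc=rng.uniform(0, 1, 200_000))
        binned = bin_windows([w], 0.0, 1.0, n_bins=20)
        prof = wham_solve(binned)
        assert np.nanmax(np.abs(prof.free_energy)) < 0.05

    def test_boltzmann_inversion_oracle(self):
        """Single unbiased window: WHAM equals -kT ln(histogram) up to the
        common shift (<= 1e-6 kcal/mol)."""
        rng = np.random.default_rng(1)
        w = _window(0.5, k=1e-9, rc=rng.beta(2.0, 3.0, 50_000))
        binned = bin_windows([w], 0.0, 1.0, n_bins=25)
        prof = wham_solve(binned, tol=1e-12)
        counts = binned.counts[0]
        with np.errstate(divide="ignore"):
            direct = np.where(counts > 0, -KT * np.log(counts / counts.sum()), np.nan)
        direct -= np.nanmin(direct)
        mask = counts > 0
        assert np.nanmax(np.abs(prof.free_energy[mask] - direct[mask])) < 1e-6

    def test_gauge_invariance_bias_offset(self):
        """Adding a constant to every bias leaves F unchanged to 1e-10."""
        pmf = AnalyticPMFSpec(form="double-well", barrier_kcal=1.5, well_nm=0.3)
        windows = synthetic.gen_umbrella_samples(
            pmf, np.arange(-0.5, 0.51, 0.1), 500.0, 500, seed=5
        )
        binned = bin_windows(windows, -0.6, 0.6, n_bins=40)
        p1 = wham_solve(binned, tol=1e-12)
        binned.bias_kcal = binned.bias_kcal + 7.3
        p2 = wham_solve(binned, tol=1e-12)
        m = ~np.isnan(p1.free_energy)
        assert np.abs(p1.free_energy[m] - p2.free_energy[m]).max() < 1e-10

    def test_flat_pmf_recovery(self):
        pmf = AnalyticPMFSpec(form="flat")
        windows = synthetic.gen_umbrella_samples(
            pmf, np.round(np.arange(-0.5, 0.51, 0.1), 10), 500.0, 20_000, seed=6
        )
        binned = bin_windows(windows, -0.55, 0.55, bin_width_nm=0.02)
        prof = wham_solve(binned)
        fe = prof.free_energy[~np.isnan(prof.free_energy)]
        assert np.sqrt(np.mean(fe**2)) < 0.1

    def test_periodic_cosine_recovery(self):
        pmf = AnalyticPMFSpec(form="periodic-cosine", amplitude_kcal=2.0, period_nm=2.0)
        centers = np.round(np.arange(-1.0, 1.0, 0.1), 10)
        windows = synthetic.gen_umbrella_samples(pmf, centers, 500.0, 4000, seed=7)
        binned = bin_windows(windows, -1.0, 1.0, bin_width_nm=0.02, periodic=True)
        prof = wham_solve(binned)
        truth = pmf.f(prof.bin_centers)
        truth -= truth.min()
        assert np.nanmax(np.abs(prof.free_energy - truth)) < 0.2

    def test_periodic_flat_no_seam_artifact(self):
        pmf = AnalyticPMFSpec(form="flat")
        centers = np.round(np.arange(-1.0, 1.0, 0.1), 10)
        windows = synthetic.gen_umbrella_samples(pmf, centers, 500.0, 3000, seed=8)
        binned = bin_windows(windows, -1.0, 1.0, bin_width_nm=0.02, periodic=True)
        prof = wham_solve(binned)
        fe = prof.free_energy
        seam = abs(fe[0] - fe[-1])
        neighbor = np.abs(np.diff(fe))
        assert seam < 2.0 * np.median(neighbor) + 0.05

    def test_accuracy_improves_with_samples(self):
        """RMS error on the double-well shrinks monotonically (over seeds)
        as samples per window grow."""
        pmf = AnalyticPMFSpec(form="double-well", barrier_kcal=2.0, well_nm=0.3)
        centers = np.round(np.arange(-0.5, 0.51, 0.1), 10)

        def rms(n, seed):
            windows = synthetic.gen_umbrella_samples(pmf, centers, 500.0, n, seed=seed)
            binned = bin_windows(windows, -0.55, 0.55, bin_width_nm=0.02)
            prof = wham_solve(binned)
            truth = pmf.f(prof.bin_centers)
            truth -= truth.min()
            m = ~np.isnan(prof.free_energy)
            return np.sqrt(np.mean((prof.free_energy[m] - truth[m]) ** 2))

        errs = {n: np.median([rms(n, s) for s in (1, 2, 3)]) for n in (200, 2000, 20000)}
        assert errs[20000] < errs[2000] < errs[200]

    def test_empty_coverage_rejected(self):
        w = _window(0.5, rc=np.full(10, 5.0))  # all samples out of range
        with pytest.raises(ValueError):
            binned = bin_windows([w], 0.0, 1.0, n_bins=10)
            wham_solve(binned)


class TestBootstrap:
    def test_duplicated_data_zero_sd(self):
        """Zero within-window variability: every resampled block is
        identical, so the bootstrap sd vanishes."""
        windows = [
            _window(c, rc=np.full(200, c), times=np.arange(1.0, 201.0))
            for c in (0.0, 0.1, 0.2)
        ]
        sd = bootstrap_pmf(windows, -0.05, 0.25, n_bins=15, n_boot=5, seed=0)
        assert np.nanmax(sd) == 0.0

    def test_sd_shrinks_with_samples(self):
        pmf = AnalyticPMFSpec(form="flat")
        centers = np.round(np.arange(-0.2, 0.21, 0.1), 10)

        def med_sd(n, seed):
            windows = synthetic.gen_umbrella_samples(pmf, centers, 500.0, n, seed=seed)
            sd = bootstrap_pmf(windows, -0.25, 0.25, bin_width_nm=0.02,
                               n_boot=20, seed=seed)
            return np.nanmedian(sd)

        small = np.median([med_sd(500, s) for s in (1, 2, 3)])
        large = np.median([med_sd(4000, s) for s in (1, 2, 3)])
        assert large < small

    def test_two_replicates_warns(self, caplog):
        windows = [_window(0.0, rc=np.random.default_rng(0).normal(0, 0.05, 100),
                           times=np.arange(1.0, 101.0))]
        with caplog.at_level("WARNING"):
            bootstrap_pmf(windows, -0.2, 0.2, n_bins=10, n_boot=2, seed=0)
        assert any("unstable" in r.message for r in caplog.records)

    def test_block_length_beyond_span_rejected(self):
        windows = [_window(0.0, rc=np.zeros(50), times=np.arange(1.0, 51.0))]
        with pytest.raises(ValueError, match="block length"):
            bootstrap_pmf(windows, -0.1, 0.1, n_bins=5, n_boot=5, seed=0,
                          block_length_ps=500.0)


class TestConvergence:
    def test_stationary_converged(self):
        pmf = AnalyticPMFSpec(form="flat")
        centers = np.round(np.arange(-0.2, 0.21, 0.1), 10)
        windows = synthetic.gen_umbrella_samples(pmf, centers, 500.0, 6000, seed=9)
        span = windows[0].times_ps[-1]
        report = convergence_blocks(
            windows, [(0, span / 3), (0, 2 * span / 3), (0, span)],
            -0.25, 0.25, bin_width_nm=0.02,
        )
        assert report.converged

    def test_shifted_second_half_flagged(self):
        """Windows whose second half samples a shifted PMF fail the check."""
        rng = np.random.default_rng(3)
        windows = []
        for c in (0.0, 0.1, 0.2):
            n = 4000
            first = rng.normal(c, 0.05, n // 2)
            second = rng.normal(c + 0.06, 0.05, n // 2)  # drifted ensemble
            windows.append(_window(c, rc=np.concatenate([first, second]),
                                   times=np.arange(1.0, n + 1.0)))
        report = convergence_blocks(
            windows, [(0, 2000), (0, 4000)], -0.2, 0.4, bin_width_nm=0.02,
            threshold_kcal=0.2,
        )
        assert not report.converged

    def test_single_block_zero_deviation(self):
        windows = [_window(0.0, rc=np.random.default_rng(0).normal(0, 0.05, 500),
                           times=np.arange(1.0, 501.0))]
        report = convergence_blocks(windows, [(0, 500)], -0.2, 0.2, n_bins=10)
        assert np.all(report.max_pairwise_deviation == 0.0)
        assert report.converged

    def test_empty_range_rejected(self):
        windows = [_window(0.0, rc=np.zeros(10), times=np.arange(1.0, 11.0))]
        with pytest.raises(ValueError, match="block"):
            convergence_blocks(windows, [(5.0, 5.0)], -0.1, 0.1, n_bins=5)
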