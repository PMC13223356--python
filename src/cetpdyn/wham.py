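"""Umbrella-sampling PMF estimation by the weighted histogram analysis method.

Biased reaction-coordinate samples from harmonically restrained windows are
histogrammed, unbiased and combined by self-consistent WHAM iteration into
a potential of mean force F(ξ), optionally on a periodic reaction
coordinate (first and last bins treated as neighbours through minimum-image
bias distances).  Errors come from a moving-block bootstrap; convergence is
assessed by re-solving on progressively longer time blocks.

Units: reaction coordinate nm, time ps, energies kcal/mol internally
(window force constants are stated in kJ/mol/nm² as in pull codes and
converted on use).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import KB_KCAL, KJ_PER_KCAL

logger = logging.getLogger(__name__)

__all__ = [
    "UmbrellaWindow",
    "BinnedWindows",
    "PMFProfile",
    "ConvergenceReport",
    "read_pullx",
    "write_pullx",
    "read_manifest",
    "bin_windows",
    "wham_solve",
    "bootstrap_pmf",
    "convergence_blocks",
    "estimate_pmf",
]


@dataclass
class UmbrellaWindow:
    """Biased samples of one umbrella window.

    ``k_kj_mol_nm2`` is the harmonic force constant about ``center_nm``;
    samples before ``equilibration_cutoff_ps`` are discarded by the
    binning stage.
    """

    center_nm: float
    k_kj_mol_nm2: float
    times_ps: np.ndarray
    rc_nm: np.ndarray
    equilibration_cutoff_ps: float = 0.0
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.rc_nm = np.asarray(self.rc_nm, dtype=float)
        if self.times_ps.shape != self.rc_nm.shape:
            raise ValueError("times and RC samples must align")
        if self.k_kj_mol_nm2 <= 0:
            raise ValueError("force constant must be positive")
        if not self.name:
            self.name = f"win_{self.center_nm:+.3f}"

    @property
    def k_kcal(self) -> float:
        return self.k_kj_mol_nm2 / KJ_PER_KCAL

    def production(self, t_lo: float | None = None, t_hi: float | None = None) -> np.ndarray:
        """Post-equilibration RC samples, optionally restricted to [t_lo, t_hi]."""
        lo = self.equilibration_cutoff_ps if t_lo is None else t_lo
        mask = self.times_ps >= lo
        if t_hi is not None:
            mask &= self.times_ps <= t_hi
        return self.rc_nm[mask]


def read_pullx(
    path: str | Path,
    center_nm: float,
    k_kj_mol_nm2: float,
    equilibration_cutoff_ps: float = 0.0,
) -> UmbrellaWindow:
    """Read a two-column (time_ps, rc_nm) pull-output text file.

    Lines starting with '#' or '@' are comments (GROMACS pullx dialect).
    """
    path = Path(path)
    times, rcs = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "@")):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
        times.append(float(parts[0]))
        rcs.append(float(parts[1]))
    return UmbrellaWindow(
        center_nm=center_nm,
        k_kj_mol_nm2=k_kj_mol_nm2,
        times_ps=np.array(times),
        rc_nm=np.array(rcs),
        equilibration_cutoff_ps=equilibration_cutoff_ps,
        name=path.stem,
    )


def write_pullx(window: UmbrellaWindow, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"# umbrella window {window.name}",
        f"# center_nm {window.center_nm:.6g}  k_kJ_mol_nm2 {window.k_kj_mol_nm2:.6g}",
        "# time_ps  rc_nm",
    ]
    for t, x in zip(window.times_ps, window.rc_nm):
        lines.append(f"{t:.4f} {x:.8f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_manifest(path: str | Path, equilibration_cutoff_ps: float = 0.0) -> list[UmbrellaWindow]:
    """Read a TSV manifest (file, center_nm, k_kJ_mol_nm2) of pullx files."""
    path = Path(path)
    windows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.lower().startswith("file"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected file, center_nm, k columns")
        fname = (path.parent / parts[0]).resolve()
        windows.append(
            read_pullx(fname, float(parts[1]), float(parts[2]), equilibration_cutoff_ps)
        )
    if not windows:
        raise ValueError(f"no windows listed in manifest {path}")
    return windows


# ---------------------------------------------------------------------------
# binning


@dataclass
class BinnedWindows:
    """Per-window histograms and bias energies on a common RC grid."""

    bin_centers: np.ndarray      # (n_bins,), nm
    bin_width: float
    counts: np.ndarray           # (n_windows, n_bins)
    bias_kcal: np.ndarray        # (n_windows, n_bins)
    periodic: bool
    period_nm: float | None
    window_names: list[str]
    overlap_fraction: float      # adjacent-window pairs sharing >=1 occupied bin
    gaps: list[tuple[str, str]]  # adjacent pairs with no shared occupied bin


def _min_image(delta: np.ndarray, period: float) -> np.ndarray:
    return delta - period * np.round(delta / period)


def bin_windows(
    windows: list[UmbrellaWindow],
    rc_min: float,
    rc_max: float,
    n_bins: int = 0,
    bin_width_nm: float = 0.02,
    equilibration_cutoff_ps: float | None = None,
    periodic: bool = False,
) -> BinnedWindows:
    """Histogram each window's production samples on a common RC grid.

    Bias energy at bin b for window i is ½ k_i Δ², with Δ the
    minimum-image difference to the window center when the RC is periodic
    (period = rc_max - rc_min).  Samples outside the range are wrapped into
    it when periodic, dropped otherwise.  The overlap diagnostic reports
    the fraction of adjacent-window pairs sharing at least one occupied
    bin, with the offending pairs listed.
    """
    if rc_min >= rc_max:
        raise ValueError("rc_min must be below rc_max")
    if n_bins == 0:
        n_bins = max(2, int(round((rc_max - rc_min) / bin_width_nm)))
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    edges = np.linspace(rc_min, rc_max, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    period = rc_max - rc_min if periodic else None

    counts = np.zeros((len(windows), n_bins))
    bias = np.zeros((len(windows), n_bins))
    for i, w in enumerate(windows):
        x = w.production(equilibration_cutoff_ps)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"window {w.name}: non-finite RC samples")
        if periodic:
            x = rc_min + np.mod(x - rc_min, period)
        else:
            x = x[(x >= rc_min) & (x <= rc_max)]
        if x.size == 0:
            raise ValueError(
                f"window {w.name}: no post-cutoff samples inside [{rc_min}, {rc_max}]"
            )
        c, _ = np.histogram(x, bins=edges)
        counts[i] = c
        delta = centers - w.center_nm
        if periodic:
            delta = _min_image(delta, period)
        bias[i] = 0.5 * w.k_kcal * delta**2

    order = np.argsort([w.center_nm for w in windows])
    gaps = []
    n_pairs = 0
    for a, b in zip(order[:-1], order[1:]):
        n_pairs += 1
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            gaps.append((windows[a].name, windows[b].name))
    overlap = 1.0 - len(gaps) / n_pairs if n_pairs else 1.0
    if gaps:
        logger.warning("non-overlapping adjacent windows: %s", gaps)
    return BinnedWindows(
        bin_centers=centers,
        bin_width=float(edges[1] - edges[0]),
        counts=counts,
        bias_kcal=bias,
        periodic=periodic,
        period_nm=period,
        window_names=[w.name for w in windows],
        overlap_fraction=overlap,
        gaps=gaps,
    )


# ---------------------------------------------------------------------------
# solver


@dataclass
class PMFProfile:
    """Free-energy profile F(ξ), kcal/mol, minimum shifted to zero."""

    bin_centers: np.ndarray
    free_energy: np.ndarray          # NaN where the RC was never sampled
    sd: np.ndarray | None
    temperature_k: float
    periodic: bool
    n_iterations: int
    residual: float
    window_free_energies: np.ndarray | None = None

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["rc_nm\tF_kcal_mol\tsd_kcal_mol"]
        sd = self.sd if self.sd is not None else np.full_like(self.free_energy, np.nan)
        for x, f, s in zip(self.bin_centers, self.free_energy, sd):
            fs = "nan" if np.isnan(f) else f"{f:.6f}"
            ss = "nan" if np.isnan(s) else f"{s:.6f}"
            lines.append(f"{x:.5f}\t{fs}\t{ss}")
        path.write_text("\n".join(lines) + "\n")
        return path

    def metadata_json(self, path: str | Path, **extra) -> Path:
        payload = {
            "temperature_k": self.temperature_k,
            "periodic": self.periodic,
            "n_iterations": self.n_iterations,
            "residual": self.residual,
            **extra,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def wham_solve(
    binned: BinnedWindows,
    temperature_k: float = 300.0,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> PMFProfile:
    """Self-consistent WHAM iteration.

    Window free energies f_i (gauge f_1 = 0) and unbiased bin
    probabilities p_b are iterated until max |Δf_i| < tol;
    F = -kB·T·ln p, shifted so its minimum is zero.  Bins never sampled by
    any window are NaN in the output; a histogram with no counts at all is
    an error.
    """
    counts = binned.counts
    if counts.sum() == 0:
        raise ValueError("empty coverage: no counts in any window")
    kt = KB_KCAL * temperature_k
    n_i = counts.sum(axis=1)                       # samples per window
    m_b = counts.sum(axis=0)                       # samples per bin
    u = binned.bias_kcal
    f = np.zeros(len(n_i))
    occupied = m_b > 0

    for it in range(1, max_iter + 1):
        # p_b ∝ M_b / Σ_i N_i exp((f_i - u_ib)/kT)
        with np.errstate(over="ignore", under="ignore"):
            denom = np.einsum("i,ib->b", n_i, np.exp((f[:, None] - u) / kt))
        p = np.where(occupied & (denom > 0), m_b / np.where(denom > 0, denom, 1.0), 0.0)
        total = p.sum()
        if total <= 0:
            raise ValueError("WHAM iteration collapsed: zero total probability")
        p /= total
        # f_i = -kT ln Σ_b p_b exp(-u_ib/kT)   (log-sum-exp for stability)
        a = np.log(np.where(p > 0, p, 1.0))[None, :] - u / kt
        a = np.where(p[None, :] > 0, a, -np.inf)
        amax = a.max(axis=1)
        f_new = -kt * (amax + np.log(np.sum(np.exp(a - amax[:, None]), axis=1)))
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM failed to converge in {max_iter} iterations (residual {residual:.3g})"
        )

    with np.errstate(divide="ignore"):
        fe = np.where(p > 0, -kt * np.log(np.where(p > 0, p, 1.0)), np.nan)
    fe -= np.nanmin(fe)
    return PMFProfile(
        bin_centers=binned.bin_centers,
        free_energy=fe,
        sd=None,
        temperature_k=temperature_k,
        periodic=binned.periodic,
        n_iterations=it,
        residual=residual,
        window_free_energies=f,
    )


# ---------------------------------------------------------------------------
# bootstrap and convergence


def bootstrap_pmf(
    windows: list[UmbrellaWindow],
    rc_min: float,
    rc_max: float,
    n_bins: int = 0,
    bin_width_nm: float = 0.02,
    temperature_k: float = 300.0,
    periodic: bool = False,
    n_boot: int = 100,
    seed: int = 0,
    block_length_ps: float | None = None,
    tol: float = 1e-8,
) -> np.ndarray:
    """Per-bin standard deviation of F from a moving-block bootstrap.

    Each replicate resamples contiguous blocks of ``block_length_ps``
    within every window (preserving autocorrelation), re-solves WHAM and
    re-shifts its minimum to zero; the per-bin sd is taken over replicates.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if n_boot < 10:
        logger.warning("n_boot=%d gives unstable error estimates", n_boot)
    rng = np.random.default_rng(seed)

    base = bin_windows(
        windows, rc_min, rc_max, n_bins=n_bins, bin_width_nm=bin_width_nm,
        periodic=periodic,
    )
    edges = np.linspace(rc_min, rc_max, len(base.bin_centers) + 1)
    period = rc_max - rc_min

    # per-window production series and block length in samples
    series = []
    blocks = []
    for w in windows:
        x = w.production()
        if periodic:
            x = rc_min + np.mod(x - rc_min, period)
        else:
            x = x[(x >= rc_min) & (x <= rc_max)]
        t = w.times_ps[w.times_ps >= w.equilibration_cutoff_ps]
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        if block_length_ps is None:
            blk = max(1, len(x) // 20)
        else:
            if block_length_ps > (t[-1] - t[0] if len(t) > 1 else 0):
                raise ValueError(
                    f"block length {block_length_ps} ps exceeds the production span "
                    f"of window {w.name}"
                )
            blk = max(1, int(round(block_length_ps / dt)))
        series.append(x)
        blocks.append(min(blk, len(x)))

    profiles = np.empty((n_boot, len(base.bin_centers)))
    for rep in range(n_boot):
        counts = np.zeros_like(base.counts)
        for i, x in enumerate(series):
            n = len(x)
            blk = blocks[i]
            n_blocks = int(np.ceil(n / blk))
            starts = rng.integers(0, max(1, n - blk + 1), size=n_blocks)
            idx = (starts[:, None] + np.arange(blk)[None, :]).ravel()[:n]
            c, _ = np.histogram(x[idx], bins=edges)
            counts[i] = c
        resampled = BinnedWindows(
            bin_centers=base.bin_centers,
            bin_width=base.bin_width,
            counts=counts,
            bias_kcal=base.bias_kcal,
            periodic=base.periodic,
            period_nm=base.period_nm,
            window_names=base.window_names,
            overlap_fraction=base.overlap_fraction,
            gaps=base.gaps,
        )
        prof = wham_solve(resampled, temperature_k=temperature_k, tol=tol)
        profiles[rep] = prof.free_energy
    return np.nanstd(profiles, axis=0, ddof=1)


@dataclass
class ConvergenceReport:
    """PMFs over progressively longer time blocks and their spread."""

    block_ranges_ps: list[tuple[float, float]]
    profiles: list[PMFProfile]
    max_pairwise_deviation: np.ndarray   # per bin, kcal/mol
    converged: bool
    threshold_kcal: float


def convergence_blocks(
    windows: list[UmbrellaWindow],
    block_ranges_ps: list[tuple[float, float]],
    rc_min: float,
    rc_max: float,
    n_bins: int = 0,
    bin_width_nm: float = 0.02,
    temperature_k: float = 300.0,
    periodic: bool = False,
    threshold_kcal: float = 0.2,
    tol: float = 1e-8,
) -> ConvergenceReport:
    """Re-solve the PMF on each time block and compare profiles bin-wise.

    Converged when the maximum pairwise deviation over commonly sampled
    bins stays below ``threshold_kcal``.
    """
    if not block_ranges_ps:
        raise ValueError("no block ranges given")
    profiles = []
    for lo, hi in block_ranges_ps:
        if hi <= lo:
            raise ValueError(f"empty block range ({lo}, {hi})")
        sub = []
        for w in windows:
            mask = (w.times_ps >= lo) & (w.times_ps <= hi)
            if not mask.any():
                raise ValueError(f"window {w.name}: no samples in block ({lo}, {hi})")
            sub.append(
                UmbrellaWindow(
                    center_nm=w.center_nm,
                    k_kj_mol_nm2=w.k_kj_mol_nm2,
                    times_ps=w.times_ps[mask],
                    rc_nm=w.rc_nm[mask],
                    equilibration_cutoff_ps=0.0,
                    name=w.name,
                )
            )
        binned = bin_windows(
            sub, rc_min, rc_max, n_bins=n_bins, bin_width_nm=bin_width_nm,
            periodic=periodic,
        )
        profiles.append(wham_solve(binned, temperature_k=temperature_k, tol=tol))

    stack = np.array([p.free_energy for p in profiles])
    n_bins_out = stack.shape[1]
    max_dev = np.zeros(n_bins_out)
    for b in range(n_bins_out):
        col = stack[:, b]
        col = col[~np.isnan(col)]
        max_dev[b] = np.ptp(col) if col.size > 1 else 0.0
    converged = bool(np.nanmax(max_dev) < threshold_kcal) if len(profiles) > 1 else True
    return ConvergenceReport(
        block_ranges_ps=list(block_ranges_ps),
        profiles=profiles,
        max_pairwise_deviation=max_dev,
        converged=converged,
        threshold_kcal=threshold_kcal,
    )


def estimate_pmf(
    windows: list[UmbrellaWindow],
    rc_min: float,
    rc_max: float,
    n_bins: int = 0,
    bin_width_nm: float = 0.02,
    temperature_k: float = 300.0,
    periodic: bool = False,
    n_boot: int = 100,
    seed: int = 0,
    block_length_ps: float | None = None,
    tol: float = 1e-8,
) -> PMFProfile:
    """Bin, solve and bootstrap in one call; returns the profile with errors."""
    binned = bin_windows(
        windows, rc_min, rc_max, n_bins=n_bins, bin_width_nm=bin_width_nm,
        periodic=periodic,
    )
    profile = wham_solve(binned, temperature_k=temperature_k, tol=tol)
    profile.sd = bootstrap_pmf(
        windows, rc_min, rc_max, n_bins=n_bins, bin_width_nm=bin_width_nm,
        temperature_k=temperature_k, periodic=periodic, n_boot=n_boot, seed=seed,
        block_length_ps=block_length_ps, tol=tol,
    )
    return profile
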