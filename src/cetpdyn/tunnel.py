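"""Tunnel geometry profiling.

The lipid-conducting tunnel is described by a polyline axis through the
centers of the C-barrel, neck and N-barrel.  Along that axis the module
computes per-axial-bin cavity volume (probe-excluded voxel counting) and
lining hydrophobicity, and compares two profile ensembles bin-by-bin with a
rank-sum test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.stats
from scipy.spatial import cKDTree

from .constants import DEFAULT_PROBE_RADIUS_NM, atom_radius_nm
from .trajectory import DomainDefinition, Structure, TrajectoryEnsemble, select

__all__ = [
    "TunnelAxis",
    "TunnelProfile",
    "ProfileComparison",
    "MannWhitneyResult",
    "tunnel_axis",
    "volume_profile",
    "hydrophobicity_profile",
    "mann_whitney_u",
    "compare_profiles",
]


@dataclass
class TunnelAxis:
    """Polyline tunnel axis with arc-length parameterization.

    Arc length is measured from the C-barrel end (first control point).
    """

    control_points: np.ndarray  # (m, 3), nm

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise ValueError("control points must be (m, 3)")
        if len(self.control_points) < 2:
            raise ValueError("axis needs at least 2 control points")
        seg = np.diff(self.control_points, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        if np.any(seglen <= 1e-12):
            raise ValueError("coincident consecutive control points on axis")
        self.arc = np.concatenate([[0.0], np.cumsum(seglen)])

    @property
    def length(self) -> float:
        return float(self.arc[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Interpolate the axis position at arc length(s) s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty((len(s), 3))
        for k in range(3):
            out[:, k] = np.interp(s, self.arc, self.control_points[:, k])
        return out if out.shape[0] > 1 else out[0]

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Arc-length coordinate s and lateral distance r of arbitrary points.

        Each point maps to its nearest point on the polyline.
        """
        s, r, _ = self.project_full(points)
        return s, r

    def project_full(
        self, points: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Like :meth:`project`, also returning an ``interior`` mask.

        ``interior`` is False for points whose nearest polyline point is a
        clamped global endpoint (the point lies axially beyond the axis);
        the volume grid uses this to avoid counting space past the open
        tunnel ends.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        p0 = self.control_points[:-1]
        seg = np.diff(self.control_points, axis=0)
        seglen2 = np.einsum("ij,ij->i", seg, seg)
        n_seg = len(p0)
        best_d2 = np.full(len(pts), np.inf)
        best_s = np.zeros(len(pts))
        interior = np.ones(len(pts), dtype=bool)
        for i in range(n_seg):
            t_raw = (pts - p0[i]) @ seg[i] / seglen2[i]
            t = np.clip(t_raw, 0.0, 1.0)
            proj = p0[i] + t[:, None] * seg[i]
            d2 = np.einsum("ij,ij->i", pts - proj, pts - proj)
            better = d2 < best_d2
            best_d2[better] = d2[better]
            best_s[better] = self.arc[i] + t[better] * math.sqrt(seglen2[i])
            clamped = np.zeros(len(pts), dtype=bool)
            if i == 0:
                clamped |= t_raw < 0.0
            if i == n_seg - 1:
                clamped |= t_raw > 1.0
            interior[better] = ~clamped[better]
        return best_s, np.sqrt(best_d2), interior

    def tangent_at(self, s: float) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.arc, s, side="right") - 1, 0,
                        len(self.arc) - 2))
        d = self.control_points[i + 1] - self.control_points[i]
        return d / np.linalg.norm(d)


def tunnel_axis(
    structure: Structure,
    domains: DomainDefinition,
    refine_step_nm: float = 0.2,
    slab_nm: float = 0.8,
) -> TunnelAxis:
    """Axis through the Cα centers of mass of C-barrel, neck and N-barrel.

    The coarse three-point polyline is resampled every ``refine_step_nm``
    and each sample is re-centered laterally on the centroid of the Cα
    atoms inside a slab of thickness ``slab_nm`` perpendicular to the local
    tangent; the axial position of each sample is preserved.
    """
    coms = []
    for name in ("c_barrel", "neck", "n_barrel"):
        idx = select(structure, domains.expression(name))
        coms.append(structure.coords0[idx].mean(axis=0))
    coms = np.asarray(coms)
    if (np.linalg.norm(np.diff(coms, axis=0), axis=1) <= 1e-9).any():
        raise ValueError("degenerate axis: coincident domain centers")
    coarse = TunnelAxis(coms)

    ca = np.flatnonzero(np.char.upper(structure.names.astype(str)) == "CA")
    if ca.size == 0:
        ca = np.arange(structure.n_atoms)
    pts = structure.coords0[ca]
    s_atoms, _ = coarse.project(pts)

    n_samples = max(2, int(round(coarse.length / refine_step_nm)) + 1)
    s_grid = np.linspace(0.0, coarse.length, n_samples)
    refined = np.empty((n_samples, 3))
    half = slab_nm / 2.0
    for i, s in enumerate(s_grid):
        p = np.atleast_2d(coarse.point_at(s))[0]
        u = coarse.tangent_at(s)
        in_slab = np.abs(s_atoms - s) <= half
        if in_slab.sum() >= 3:
            c = pts[in_slab].mean(axis=0)
            lateral = (c - p) - np.dot(c - p, u) * u
            refined[i] = p + lateral
        else:
            refined[i] = p
    # drop accidental duplicates produced by identical lateral corrections
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(refined, axis=0), axis=1) > 1e-9]
    )
    return TunnelAxis(refined[keep])


# ---------------------------------------------------------------------------
# profiles


@dataclass
class TunnelProfile:
    """Per-axial-bin profile with the per-frame stack retained.

    ``values`` is the across-frame mean; bins never touched by any lining
    residue (hydrophobicity) are NaN and carry ``occupied=False``.
    """

    bin_edges: np.ndarray          # (n_bins + 1,), nm along the axis
    stack: np.ndarray              # (n_frames, n_bins)
    kind: str                      # "volume" (nm^3) or "hydrophobicity"
    occupied: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.stack = np.atleast_2d(np.asarray(self.stack, dtype=float))
        if self.stack.shape[1] != len(self.bin_edges) - 1:
            raise ValueError("stack width must equal number of bins")
        if self.occupied is None:
            self.occupied = ~np.all(np.isnan(self.stack), axis=0)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def values(self) -> np.ndarray:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.stack, axis=0)

    @property
    def total(self) -> float:
        """Sum over bins of the across-frame mean (volume profiles)."""
        return float(np.nansum(self.values))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["bin_start_nm\tbin_end_nm\tvalue\tn_frames"]
        vals = self.values
        for b in range(self.n_bins):
            v = vals[b]
            sval = "nan" if np.isnan(v) else f"{v:.6g}"
            lines.append(
                f"{self.bin_edges[b]:.4f}\t{self.bin_edges[b + 1]:.4f}\t{sval}\t{self.n_frames}"
            )
        path.write_text("\n".join(lines) + "\n")
        return path


def _bin_edges(length: float, bin_width: float) -> np.ndarray:
    n_bins = max(1, int(math.ceil(length / bin_width - 1e-9)))
    return np.linspace(0.0, length, n_bins + 1)


def volume_profile(
    ensemble: TrajectoryEnsemble,
    axis: TunnelAxis,
    bin_width_nm: float = 0.2,
    grid_spacing_nm: float = 0.05,
    probe_radius_nm: float = DEFAULT_PROBE_RADIUS_NM,
    max_radius_nm: float = 1.2,
) -> TunnelProfile:
    """Probe-excluded cavity volume per axial bin, per frame.

    A Cartesian voxel grid covers the axis neighbourhood; a voxel belongs to
    the tunnel interior when (a) its lateral distance to the axis is at most
    ``max_radius_nm`` (the radial envelope bounding the tunnel rather than
    all protein voids), and (b) its center lies farther than
    (element vdW radius + probe radius) from every atom center.  Per-bin
    volume is the interior-voxel count times the voxel volume.
    """
    if grid_spacing_nm <= 0:
        raise ValueError("grid_spacing must be positive")
    edges = _bin_edges(axis.length, bin_width_nm)

    lo = axis.control_points.min(axis=0) - max_radius_nm
    hi = axis.control_points.max(axis=0) + max_radius_nm
    axes_1d = [np.arange(lo[k], hi[k] + grid_spacing_nm / 2, grid_spacing_nm) for k in range(3)]
    if any(len(a) == 0 for a in axes_1d):
        raise ValueError("empty voxel grid")
    gx, gy, gz = np.meshgrid(*axes_1d, indexing="ij")
    voxels = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    s_vox, r_vox, inside = axis.project_full(voxels)
    keep = inside & (r_vox <= max_radius_nm) & (s_vox >= 0.0) & (s_vox <= axis.length)
    voxels = voxels[keep]
    bin_of = np.clip(np.searchsorted(edges, s_vox[keep], side="right") - 1, 0, len(edges) - 2)

    elements = np.char.upper(ensemble.structure.elements.astype(str))
    radii = np.array([atom_radius_nm(e) for e in elements])
    voxel_tree = cKDTree(voxels)
    vvol = grid_spacing_nm ** 3

    stack = np.zeros((ensemble.n_frames, len(edges) - 1))
    for fi, frame in enumerate(ensemble.frames):
        blocked = np.zeros(len(voxels), dtype=bool)
        for rad in np.unique(radii):
            atoms = frame.coords[radii == rad]
            hits = voxel_tree.query_ball_point(atoms, rad + probe_radius_nm)
            for h in hits:
                blocked[h] = True
        free_bins = bin_of[~blocked]
        stack[fi] = np.bincount(free_bins, minlength=len(edges) - 1) * vvol
    return TunnelProfile(bin_edges=edges, stack=stack, kind="volume")


def hydrophobicity_profile(
    ensemble: TrajectoryEnsemble,
    axis: TunnelAxis,
    bin_width_nm: float = 0.2,
    lining_cutoff_nm: float = 0.6,
    scale: dict[str, float] | None = None,
    default: float | None = None,
) -> TunnelProfile:
    """Mean lining-residue hydrophobicity per axial bin, per frame.

    A residue lines a bin in a frame when at least one of its heavy atoms
    projects into that bin with lateral distance <= ``lining_cutoff_nm``.
    Residue names absent from ``scale`` raise unless ``default`` is given.
    Bins with no lining residues are NaN (excluded from comparisons).
    """
    from .constants import load_hydrophobicity_scale

    if scale is None:
        scale = load_hydrophobicity_scale()
    s = ensemble.structure
    edges = _bin_edges(axis.length, bin_width_nm)
    n_bins = len(edges) - 1

    heavy = s.heavy_atoms()
    res_of_atom = s.residue_index[heavy]
    n_res = s.n_residues
    res_values = np.empty(n_res)
    for r in range(n_res):
        name = s.residue_name(r).upper()
        if name in scale:
            res_values[r] = scale[name]
        elif default is not None:
            res_values[r] = default
        else:
            raise ValueError(
                f"residue {name} {s.residue_resid(r)} missing from hydrophobicity "
                "scale and no default supplied"
            )

    stack = np.full((ensemble.n_frames, n_bins), np.nan)
    for fi, frame in enumerate(ensemble.frames):
        s_at, r_at = axis.project(frame.coords[heavy])
        near = (r_at <= lining_cutoff_nm) & (s_at >= 0.0) & (s_at <= axis.length)
        if not near.any():
            continue
        bins = np.clip(np.searchsorted(edges, s_at[near], side="right") - 1, 0, n_bins - 1)
        for b in range(n_bins):
            res_here = np.unique(res_of_atom[near][bins == b])
            if res_here.size:
                stack[fi, b] = res_values[res_here].mean()
    return TunnelProfile(bin_edges=edges, stack=stack, kind="hydrophobicity")


# ---------------------------------------------------------------------------
# rank-sum comparison


@dataclass
class MannWhitneyResult:
    U: float
    p: float
    method: str

    def __iter__(self):
        return iter((self.U, self.p))


def _exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U (counts) for tie-free samples.

    Classic counting recursion c(u; a, b) = c(u-b; a-1, b) + c(u; a, b-1),
    i.e. the coefficients of the Gaussian binomial [a+b choose a]_q.
    """
    size = n1 * n2 + 1
    prev_row = [np.zeros(size) for _ in range(n2 + 1)]  # a = 0
    for b in range(n2 + 1):
        prev_row[b][0] = 1.0
    for _a in range(1, n1 + 1):
        row = [np.zeros(size) for _ in range(n2 + 1)]
        row[0][0] = 1.0
        for b in range(1, n2 + 1):
            row[b] = row[b - 1].copy()
            row[b][b:] += prev_row[b][: size - b]
        prev_row = row
    return prev_row[n2]


def _u_from_split(gt: np.ndarray, x_idx: tuple[int, ...], all_idx: np.ndarray) -> float:
    mask = np.zeros(len(all_idx), dtype=bool)
    mask[list(x_idx)] = True
    return float(gt[np.ix_(mask, ~mask)].sum())


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, enumeration_limit: int = 20000
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test (midrank ties).

    U counts pairs where x exceeds y (ties count 1/2).  The two-sided p is
    exact — from the tie-free rank-sum counting recursion when
    n1·n2 <= 400, or full permutation enumeration for small tied samples —
    and otherwise a normal approximation with tie and continuity
    correction.  The method used is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])

    # U via pairwise comparison (midrank ties), equivalent to rank sums
    gt = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    u = float(gt.sum())

    has_ties = len(np.unique(pooled)) < n1 + n2
    if not has_ties and n1 * n2 <= 400:
        dist = _exact_u_distribution(n1, n2)
        total = dist.sum()
        lo = dist[: int(round(u)) + 1].sum() / total
        hi = dist[int(round(u)):].sum() / total
        p = min(1.0, 2.0 * min(lo, hi))
        return MannWhitneyResult(U=u, p=p, method="exact-recursion")
    if has_ties and math.comb(n1 + n2, n1) <= enumeration_limit:
        gtt = (pooled[:, None] > pooled[None, :]).astype(float) + 0.5 * (
            pooled[:, None] == pooled[None, :]
        )
        np.fill_diagonal(gtt, 0.0)
        all_idx = np.arange(n1 + n2)
        us = np.array(
            [
                _u_from_split(gtt, comb, all_idx)
                for comb in itertools.combinations(range(n1 + n2), n1)
            ]
        )
        lo = np.mean(us <= u + 1e-12)
        hi = np.mean(us >= u - 1e-12)
        p = min(1.0, 2.0 * min(lo, hi))
        return MannWhitneyResult(U=u, p=p, method="exact-enumeration")

    # normal approximation with tie and continuity correction
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return MannWhitneyResult(U=u, p=1.0, method="normal-degenerate")
    cc = 0.5 if u != mu else 0.0
    z = (u - mu - math.copysign(cc, u - mu)) / math.sqrt(var)
    p = min(1.0, 2.0 * scipy.stats.norm.sf(abs(z)))
    return MannWhitneyResult(U=u, p=p, method="normal-approx")


@dataclass
class ProfileComparison:
    """Per-bin rank-sum comparison between two profile ensembles."""

    bin_edges: np.ndarray
    U: np.ndarray
    p: np.ndarray
    median_a: np.ndarray
    median_b: np.ndarray
    significant: np.ndarray
    alpha: float
    bh_corrected: bool = False

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["bin_start_nm\tbin_end_nm\tU\tp\tmedian_a\tmedian_b\tsignificant"]
        for b in range(len(self.U)):
            lines.append(
                f"{self.bin_edges[b]:.4f}\t{self.bin_edges[b + 1]:.4f}\t"
                f"{self.U[b]:.6g}\t{self.p[b]:.6g}\t{self.median_a[b]:.6g}\t"
                f"{self.median_b[b]:.6g}\t{int(self.significant[b])}"
            )
        path.write_text("\n".join(lines) + "\n")
        return path


def compare_profiles(
    stack_a: TunnelProfile,
    stack_b: TunnelProfile,
    alpha: float = 0.05,
    bh: bool = False,
) -> ProfileComparison:
    """Bin-by-bin Mann-Whitney comparison of per-frame profile distributions.

    Significance flags p < alpha per bin; no multiplicity correction by
    default (Benjamini-Hochberg with ``bh=True``).  Bins empty in either
    ensemble are excluded (p = NaN, never significant).
    """
    if not np.allclose(stack_a.bin_edges, stack_b.bin_edges):
        raise ValueError("profile bin grids differ")
    n_bins = stack_a.n_bins
    U = np.full(n_bins, np.nan)
    p = np.full(n_bins, np.nan)
    med_a = np.full(n_bins, np.nan)
    med_b = np.full(n_bins, np.nan)
    for b in range(n_bins):
        a = stack_a.stack[:, b]
        bb = stack_b.stack[:, b]
        a = a[~np.isnan(a)]
        bb = bb[~np.isnan(bb)]
        if a.size == 0 or bb.size == 0:
            continue
        res = mann_whitney_u(a, bb)
        U[b], p[b] = res.U, res.p
        med_a[b] = np.median(a)
        med_b[b] = np.median(bb)
    testable = ~np.isnan(p)
    sig = np.zeros(n_bins, dtype=bool)
    if bh and testable.any():
        adj = scipy.stats.false_discovery_control(p[testable])
        sig[testable] = adj < alpha
    else:
        sig[testable] = p[testable] < alpha
    return ProfileComparison(
        bin_edges=stack_a.bin_edges,
        U=U,
        p=p,
        median_a=med_a,
        median_b=med_b,
        significant=sig,
        alpha=alpha,
        bh_corrected=bh,
    )
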