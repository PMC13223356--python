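"""Lipid path tracing, contact bookkeeping and fate classification.

Follows the transiting lipid's reference-group center of mass through the
tunnel: the axial coordinate s(t) and lateral offset r(t) against the
tunnel axis, the residues it stays in contact with (the 0.6 nm / >1 ns
filter), the across-replicate average path, traversal-vs-fallout
classification, and hydrophobic contact patches.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import Structure, TrajectoryEnsemble, center_of_mass, select
from .tunnel import TunnelAxis

logger = logging.getLogger(__name__)

__all__ = [
    "LipidTrace",
    "ContactRecord",
    "PathEnsembleSummary",
    "FateCall",
    "trace_lipid",
    "contact_residues",
    "average_path",
    "classify_fate",
    "hydrophobic_patches",
]


@dataclass
class LipidTrace:
    """Center-of-mass path of the lipid reference group.

    ``s`` is the arc-length coordinate of the nearest axis point (nm) and
    ``r`` the lateral distance to it; s need not be monotone (backsliding
    is allowed and does occur).
    """

    times: np.ndarray       # ps
    com: np.ndarray         # (n_frames, 3), nm
    s: np.ndarray           # nm
    r: np.ndarray           # nm
    replicate: str = "rep0"
    axis_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.com = np.asarray(self.com, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.times)
        if not (len(self.com) == len(self.s) == len(self.r) == n):
            raise ValueError("trace arrays must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class ContactRecord:
    """Cumulative contact bookkeeping for one residue against the lipid."""

    resid: int
    resname: str
    cumulative_ns: float
    min_distance_nm: float
    first_frame: int
    last_frame: int
    tight: bool = False   # ever within the 0.3 nm tight-contact subset


@dataclass
class PathEnsembleSummary:
    """Across-replicate mean path with per-grid-point standard deviation."""

    grid_fractions: np.ndarray   # (n_grid,), arc-length fractions in [0, 1]
    mean: np.ndarray             # (n_grid, 3), nm
    sd: np.ndarray               # (n_grid, 3), nm
    n_replicates: int

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["fraction\tmean_x\tmean_y\tmean_z\tsd_x\tsd_y\tsd_z"]
        for i, f in enumerate(self.grid_fractions):
            m = self.mean[i]
            s = self.sd[i]
            lines.append(
                f"{f:.4f}\t{m[0]:.6g}\t{m[1]:.6g}\t{m[2]:.6g}\t"
                f"{s[0]:.6g}\t{s[1]:.6g}\t{s[2]:.6g}"
            )
        path.write_text("\n".join(lines) + "\n")
        return path


@dataclass
class FateCall:
    """Outcome of one pull replicate: traversal, fallout or incomplete."""

    label: str                       # traversal | fallout | incomplete
    event_frame: int | None
    exit_s_nm: float | None
    exit_r_nm: float | None
    replicate: str = "rep0"

    def to_json_dict(self) -> dict:
        return {
            "replicate": self.replicate,
            "label": self.label,
            "event_frame": self.event_frame,
            "exit_s_nm": self.exit_s_nm,
            "exit_r_nm": self.exit_r_nm,
        }


# ---------------------------------------------------------------------------


def trace_lipid(
    ensemble: TrajectoryEnsemble,
    lipid_selection: str | np.ndarray,
    axis: TunnelAxis,
    masses: np.ndarray | None = None,
) -> LipidTrace:
    """Per-frame COM of the lipid reference group projected onto the axis."""
    if isinstance(lipid_selection, str):
        idx = select(ensemble.structure, lipid_selection)
    else:
        idx = np.asarray(lipid_selection, dtype=int)
        if idx.size == 0:
            raise ValueError("empty lipid selection")
    com = np.array([center_of_mass(f, idx, masses) for f in ensemble.frames])
    s, r = axis.project(com)
    return LipidTrace(
        times=ensemble.times, com=com, s=s, r=r, replicate=ensemble.replicate
    )


def contact_residues(
    ensemble: TrajectoryEnsemble,
    lipid_selection: str | np.ndarray,
    protein_selection: str | np.ndarray | None = None,
    r_contact_nm: float = 0.6,
    tight_nm: float = 0.3,
    min_duration_ns: float = 1.0,
) -> list[ContactRecord]:
    """Residues in sustained contact with the lipid.

    Contact in a frame: minimum heavy-atom distance between the residue and
    any lipid heavy atom <= ``r_contact_nm`` (inclusive).  Cumulative
    contact time is summed over all (possibly non-consecutive) frames, each
    weighted by its local frame spacing; only residues with cumulative time
    strictly greater than ``min_duration_ns`` are reported, sorted by
    cumulative time descending (residue number ascending on ties).
    Residues ever within ``tight_nm`` are additionally marked tight.
    """
    if r_contact_nm <= 0:
        raise ValueError("r_contact must be positive")
    s = ensemble.structure
    if isinstance(lipid_selection, str):
        lip = select(s, lipid_selection)
    else:
        lip = np.asarray(lipid_selection, dtype=int)
    heavy = set(s.heavy_atoms().tolist())
    lip = np.array([i for i in lip if i in heavy], dtype=int)
    if lip.size == 0:
        raise ValueError("lipid selection has no heavy atoms")
    if protein_selection is None:
        prot = np.array(sorted(heavy - set(lip.tolist())), dtype=int)
    elif isinstance(protein_selection, str):
        prot = select(s, protein_selection)
        prot = np.array([i for i in prot if i in heavy], dtype=int)
    else:
        prot = np.asarray(protein_selection, dtype=int)

    times = ensemble.times
    span_ns = (times[-1] - times[0]) / 1000.0 if len(times) > 1 else 0.0
    if min_duration_ns >= span_ns:
        logger.warning(
            "min_duration %.3g ns is not shorter than the trajectory span %.3g ns; "
            "no residue can qualify",
            min_duration_ns,
            span_ns,
        )

    # per-frame duration: local spacing (half-intervals at the ends)
    if len(times) > 1:
        w = np.empty(len(times))
        mid = (times[1:] + times[:-1]) / 2.0
        w[0] = mid[0] - times[0] + (times[1] - times[0]) / 2.0
        w[-1] = times[-1] - mid[-1] + (times[-1] - times[-2]) / 2.0
        w[1:-1] = mid[1:] - mid[:-1]
    else:
        w = np.array([0.0])

    res_idx_of = s.residue_index[prot]
    n_res = s.n_residues
    cum_ps = np.zeros(n_res)
    min_d = np.full(n_res, np.inf)
    first = np.full(n_res, -1, dtype=int)
    last = np.full(n_res, -1, dtype=int)
    tight = np.zeros(n_res, dtype=bool)

    for fi, frame in enumerate(ensemble.frames):
        tree = cKDTree(frame.coords[lip])
        d, _ = tree.query(frame.coords[prot])
        per_res = np.full(n_res, np.inf)
        np.minimum.at(per_res, res_idx_of, d)
        hit = per_res <= r_contact_nm
        cum_ps[hit] += w[fi]
        tight |= per_res <= tight_nm
        newly = hit & (first == -1)
        first[newly] = fi
        last[hit] = fi
        min_d = np.minimum(min_d, per_res)

    records = []
    for ri in range(n_res):
        cum_ns = cum_ps[ri] / 1000.0
        if cum_ns > min_duration_ns:
            records.append(
                ContactRecord(
                    resid=s.residue_resid(ri),
                    resname=s.residue_name(ri),
                    cumulative_ns=float(cum_ns),
                    min_distance_nm=float(min_d[ri]),
                    first_frame=int(first[ri]),
                    last_frame=int(last[ri]),
                    tight=bool(tight[ri]),
                )
            )
    records.sort(key=lambda rec: (-rec.cumulative_ns, rec.resid))
    return records


def write_contacts_tsv(records: list[ContactRecord], path: str | Path) -> Path:
    path = Path(path)
    lines = ["resid\tresname\tcum_time_ns\tmin_dist_nm\tfirst_frame\tlast_frame\ttight"]
    for r in records:
        lines.append(
            f"{r.resid}\t{r.resname}\t{r.cumulative_ns:.6g}\t{r.min_distance_nm:.6g}"
            f"\t{r.first_frame}\t{r.last_frame}\t{int(r.tight)}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def average_path(traces: list[LipidTrace], n_grid: int = 50) -> PathEnsembleSummary:
    """Mean and sd of positions across replicates at matched arc fractions.

    Each trace is resampled at ``n_grid`` equal arc-length fractions of its
    own axial span; because backsliding makes s(t) non-monotone, the
    resampled position at a level is taken at the first (interpolated)
    crossing of that level.
    """
    if not traces:
        raise ValueError("need at least one trace")
    axis_ids = {t.axis_id for t in traces}
    if len(axis_ids) > 1:
        raise ValueError(f"traces computed on different axes: {sorted(axis_ids)}")
    fractions = np.linspace(0.0, 1.0, n_grid)
    resampled = np.empty((len(traces), n_grid, 3))
    for ti, tr in enumerate(traces):
        s0, s1 = tr.s[0], tr.s.max()
        levels = s0 + fractions * (s1 - s0)
        for gi, lev in enumerate(levels):
            resampled[ti, gi] = _position_at_first_crossing(tr, lev)
    mean = resampled.mean(axis=0)
    sd = resampled.std(axis=0, ddof=0)
    return PathEnsembleSummary(
        grid_fractions=fractions, mean=mean, sd=sd, n_replicates=len(traces)
    )


def _position_at_first_crossing(trace: LipidTrace, level: float) -> np.ndarray:
    s = trace.s
    if level <= s[0]:
        return trace.com[0]
    above = np.flatnonzero(s >= level)
    if above.size == 0:
        return trace.com[-1]
    i = above[0]
    if i == 0 or s[i] == s[i - 1]:
        return trace.com[i]
    f = (level - s[i - 1]) / (s[i] - s[i - 1])
    return trace.com[i - 1] + f * (trace.com[i] - trace.com[i - 1])


def classify_fate(
    trace: LipidTrace,
    axis: TunnelAxis,
    exit_s_nm: float,
    lateral_max_nm: float = 0.8,
    interface_window: tuple[float, float] | None = None,
) -> FateCall:
    """Traversal / fallout / incomplete call for one replicate.

    Traversal: s(t) reaches ``exit_s_nm`` before any fallout.  Fallout:
    r(t) exceeds ``lateral_max_nm`` while s(t) lies inside the interface
    window (default: middle third of the axis, the barrel–neck interface
    where the first plug sits).  The first qualifying event wins; a trace
    that does neither is incomplete.
    """
    if not (0.0 <= exit_s_nm <= axis.length):
        raise ValueError("exit_s outside the axis span")
    if interface_window is None:
        interface_window = (axis.length / 3.0, 2.0 * axis.length / 3.0)
    s_lo, s_hi = interface_window
    if s_lo >= s_hi:
        raise ValueError("impossible interface window: s_lo >= s_hi")

    traversal_frames = np.flatnonzero(trace.s >= exit_s_nm)
    fallout_frames = np.flatnonzero(
        (trace.r > lateral_max_nm) & (trace.s >= s_lo) & (trace.s <= s_hi)
    )
    t_frame = int(traversal_frames[0]) if traversal_frames.size else None
    f_frame = int(fallout_frames[0]) if fallout_frames.size else None
    if t_frame is not None and (f_frame is None or t_frame <= f_frame):
        return FateCall(
            label="traversal",
            event_frame=t_frame,
            exit_s_nm=float(trace.s[t_frame]),
            exit_r_nm=float(trace.r[t_frame]),
            replicate=trace.replicate,
        )
    if f_frame is not None:
        return FateCall(
            label="fallout",
            event_frame=f_frame,
            exit_s_nm=float(trace.s[f_frame]),
            exit_r_nm=float(trace.r[f_frame]),
            replicate=trace.replicate,
        )
    return FateCall(
        label="incomplete",
        event_frame=None,
        exit_s_nm=None,
        exit_r_nm=None,
        replicate=trace.replicate,
    )


def hydrophobic_patches(
    contacts: list[ContactRecord],
    structure: Structure,
    link_cutoff_nm: float = 0.8,
    min_size: int = 3,
) -> list[list[int]]:
    """Single-linkage clusters of contact residues (author resids).

    Residues whose minimum heavy-atom distance in the reference frame is
    <= ``link_cutoff_nm`` are linked; connected components of size >=
    ``min_size`` are reported largest first.
    """
    if not contacts:
        raise ValueError("no contact records to cluster")
    import scipy.sparse
    import scipy.sparse.csgraph

    resids = [c.resid for c in contacts]
    heavy = structure.heavy_atoms()
    groups = []
    for rid in resids:
        atoms = heavy[structure.resids[heavy] == rid]
        groups.append(structure.coords0[atoms])
    n = len(groups)
    rows, cols = [], []
    for i in range(n):
        tree = cKDTree(groups[i])
        for j in range(i + 1, n):
            d, _ = tree.query(groups[j], k=1)
            if d.min() <= link_cutoff_nm:
                rows.append(i)
                cols.append(j)
    adj = scipy.sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    _, labels = scipy.sparse.csgraph.connected_components(adj, directed=False)
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(resids[i])
    out = [sorted(c) for c in clusters.values() if len(c) >= min_size]
    out.sort(key=lambda c: (-len(c), c[0]))
    return out


def write_fates_json(fates: list[FateCall], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps([f.to_json_dict() for f in fates], indent=2, sort_keys=True) + "\n"
    )
    return path
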