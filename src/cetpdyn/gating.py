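"""Phenylalanine-gate and gliding-event detection.

The tunnel neck is guarded by aromatic side chains whose χ2 rotations open
and close a flap, and by the phospholipid plugs whose acyl tails form a
hydrophobic plane the transiting lipid glides over.  This module extracts
χ2 dihedral series (with ring-symmetry normalization and a moving
average), detects gate-opening excursions and their lipid coincidence,
computes the lipid's instantaneous velocity and its spike ("gliding")
events, the acyl-tail plane angle, and salt-bridge occupancies around the
plug headgroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lipidpath import LipidTrace
from .trajectory import TrajectoryEnsemble, select

logger = logging.getLogger(__name__)

__all__ = [
    "DihedralSeries",
    "GateEvent",
    "GlideEvent",
    "TailPlaneSeries",
    "SaltBridgeRecord",
    "dihedral_angle",
    "normalize_chi2",
    "chi2_series",
    "detect_gate_events",
    "instantaneous_velocity",
    "detect_glide_events",
    "tail_plane_angle",
    "salt_bridges",
]

#: Formal-charge heavy atoms per charged residue type.
CHARGED_SIDECHAIN_ATOMS = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees, (-180, 180]) of four points."""
    from MDAnalysis.lib.distances import calc_dihedrals

    rad = calc_dihedrals(
        np.asarray(p0, dtype=np.float32)[None, :],
        np.asarray(p1, dtype=np.float32)[None, :],
        np.asarray(p2, dtype=np.float32)[None, :],
        np.asarray(p3, dtype=np.float32)[None, :],
    )[0]
    # sign flipped to the common atan2 (IUPAC) convention
    deg = float(-np.degrees(rad))
    if deg <= -180.0:
        deg += 360.0
    return deg


def normalize_chi2(raw: np.ndarray) -> np.ndarray:
    """Reduce χ2 by the two-fold ring symmetry to (-90, 90]."""
    r = np.mod(np.asarray(raw, dtype=float), 180.0)
    r = np.where(r > 90.0, r - 180.0, r)
    return r


def moving_average(x: np.ndarray, window_frames: int) -> np.ndarray:
    """Centered moving average; edges use the available partial window."""
    w = int(window_frames)
    if w <= 1:
        return np.asarray(x, dtype=float).copy()
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


@dataclass
class DihedralSeries:
    """χ2 torsion series of one residue.

    ``raw`` is in (-180, 180]; ``normalized`` applies the aromatic-ring
    two-fold symmetry, mapping to (-90, 90]; ``smoothed`` is the centered
    moving average of the normalized series over ``window_ps``.
    """

    times: np.ndarray
    raw: np.ndarray
    residue: str = ""
    window_ps: float = 20.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.times.shape != self.raw.shape:
            raise ValueError("times and raw values must align")
        self.normalized = normalize_chi2(self.raw)
        dt = float(np.median(np.diff(self.times))) if len(self.times) > 1 else 1.0
        self.window_frames = max(1, int(round(self.window_ps / dt)))
        self.smoothed = moving_average(self.normalized, self.window_frames)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times))) if len(self.times) > 1 else 1.0

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["time_ps\traw_deg\tnormalized_deg\tsmoothed_deg"]
        for t, r, n, s in zip(self.times, self.raw, self.normalized, self.smoothed):
            lines.append(f"{t:.4f}\t{r:.4f}\t{n:.4f}\t{s:.4f}")
        path.write_text("\n".join(lines) + "\n")
        return path


def chi2_series(
    ensemble: TrajectoryEnsemble, resid: int, window_ps: float = 20.0
) -> DihedralSeries:
    """χ2 = dihedral(CA, CB, CG, CD1) of one residue, per frame."""
    s = ensemble.structure
    atoms = {}
    res_atoms = np.flatnonzero(s.resids == resid)
    if res_atoms.size == 0:
        raise ValueError(f"no residue {resid} in structure")
    for name in ("CA", "CB", "CG", "CD1"):
        hits = res_atoms[np.char.upper(s.names[res_atoms].astype(str)) == name]
        if hits.size == 0:
            raise ValueError(f"residue {resid} is missing atom {name}")
        atoms[name] = int(hits[0])
    raw = np.array(
        [
            dihedral_angle(
                f.coords[atoms["CA"]],
                f.coords[atoms["CB"]],
                f.coords[atoms["CG"]],
                f.coords[atoms["CD1"]],
            )
            for f in ensemble.frames
        ]
    )
    resname = s.resnames[res_atoms[0]]
    return DihedralSeries(
        times=ensemble.times, raw=raw, residue=f"{resname}{resid}", window_ps=window_ps
    )


# ---------------------------------------------------------------------------
# gate events


@dataclass
class GateEvent:
    residue: str
    open_frame: int
    close_frame: int          # exclusive-end convention; == n_frames if open-ended
    magnitude_deg: float
    lipid_coincident: bool = False
    open_ended: bool = False


def _wrapped_diff_180(a: np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Difference on the 180°-periodic circle, in (-90, 90]."""
    d = np.mod(a - b, 180.0)
    return np.where(d > 90.0, d - 180.0, d)


def circular_median_180(values: np.ndarray, max_candidates: int = 1440) -> float:
    """Median on the 180°-periodic circle: the data value minimizing the sum
    of wrapped absolute deviations (subsampled candidates for long series)."""
    v = np.asarray(values, dtype=float)
    cand = np.sort(v)
    if len(cand) > max_candidates:
        cand = cand[:: int(np.ceil(len(cand) / max_candidates))]
    costs = np.abs(_wrapped_diff_180(v[None, :], cand[:, None])).sum(axis=1)
    return float(cand[np.argmin(costs)])


def detect_gate_events(
    series: DihedralSeries,
    lipid_trace: LipidTrace | None = None,
    residue_position: np.ndarray | None = None,
    rotation_threshold_deg: float = 40.0,
    min_dwell_ps: float = 10.0,
    proximity_nm: float = 1.0,
) -> list[GateEvent]:
    """Gate-opening excursions of a χ2 series.

    Baseline is the circular median of the normalized series; an event is a
    contiguous span where the smoothed series deviates from baseline by at
    least ``rotation_threshold_deg`` (on the 180°-periodic circle) for at
    least ``min_dwell_ps``.  If a lipid trace and the residue position are
    given, events during which the lipid COM comes within ``proximity_nm``
    of the residue are flagged lipid-coincident.
    """
    baseline = circular_median_180(series.normalized)
    dev = np.abs(_wrapped_diff_180(series.smoothed, baseline))
    mask = dev >= rotation_threshold_deg
    min_frames = max(1, int(round(min_dwell_ps / series.dt)))

    if lipid_trace is not None:
        if len(lipid_trace) != len(series):
            raise ValueError("lipid trace and dihedral series time bases differ")
        if residue_position is None:
            raise ValueError("residue_position required to flag lipid coincidence")
        pos = np.asarray(residue_position, dtype=float)
        if pos.ndim == 1:
            near = np.linalg.norm(lipid_trace.com - pos[None, :], axis=1) <= proximity_nm
        else:
            near = np.linalg.norm(lipid_trace.com - pos, axis=1) <= proximity_nm
    else:
        near = np.zeros(len(series), dtype=bool)

    events = []
    for start, stop in _runs(mask):
        if stop - start < min_frames:
            continue
        events.append(
            GateEvent(
                residue=series.residue,
                open_frame=int(start),
                close_frame=int(stop),
                magnitude_deg=float(dev[start:stop].max()),
                lipid_coincident=bool(near[start:stop].any()),
                open_ended=bool(stop == len(series) and mask[-1]),
            )
        )
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as [start, stop) pairs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    padded = np.concatenate([[False], m, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


# ---------------------------------------------------------------------------
# velocity and gliding


def instantaneous_velocity(trace: LipidTrace, window_frames: int = 5) -> np.ndarray:
    """Axial velocity of the lipid, nm/ns, aligned with ``trace.times``.

    Central finite difference of s(t) (one-sided at the ends) followed by a
    centered moving average; exact for affine s(t) at every frame.
    """
    if len(trace) < window_frames + 1:
        raise ValueError("trace too short for the requested smoothing window")
    s = trace.s
    t = trace.times
    v = np.empty_like(s)
    v[1:-1] = (s[2:] - s[:-2]) / (t[2:] - t[:-2])
    v[0] = (s[1] - s[0]) / (t[1] - t[0])
    v[-1] = (s[-1] - s[-2]) / (t[-1] - t[-2])
    v *= 1000.0  # nm/ps -> nm/ns
    return moving_average(v, window_frames)


@dataclass
class GlideEvent:
    start_frame: int
    end_frame: int            # exclusive
    peak_velocity: float      # nm/ns
    baseline_mean: float      # nm/ns
    pl_contact: bool = False


def detect_glide_events(
    velocity: np.ndarray,
    pl_contact: np.ndarray | None = None,
    k_sigma: float = 2.0,
    min_dwell_frames: int = 3,
) -> list[GlideEvent]:
    """Velocity-spike (gliding) events.

    A two-pass baseline (spikes found with the first-pass mean/sd are
    excluded before the second pass) avoids spike contamination; an event
    is a contiguous span with velocity above mean + k_sigma·sd for at
    least ``min_dwell_frames``.  Events touching any frame with PL contact
    are flagged.
    """
    v = np.asarray(velocity, dtype=float)
    if pl_contact is None:
        pl = np.zeros(len(v), dtype=bool)
    else:
        pl = np.asarray(pl_contact, dtype=bool)
        if len(pl) != len(v):
            raise ValueError("velocity and PL-contact series lengths differ")
    sd0 = v.std()
    if sd0 == 0:
        logger.warning("zero-variance velocity series: no gliding events detectable")
        return []
    candidates = v > v.mean() + k_sigma * sd0
    base = v[~candidates] if (~candidates).any() else v
    mean, sd = float(base.mean()), float(base.std())
    if sd == 0:
        sd = sd0
    thr = mean + k_sigma * sd
    mask = v > thr
    events = []
    for start, stop in _runs(mask):
        if stop - start < min_dwell_frames:
            continue
        events.append(
            GlideEvent(
                start_frame=int(start),
                end_frame=int(stop),
                peak_velocity=float(v[start:stop].max()),
                baseline_mean=mean,
                pl_contact=bool(pl[start:stop].any()),
            )
        )
    return events


# ---------------------------------------------------------------------------
# acyl-tail plane angle


@dataclass
class TailPlaneSeries:
    """Angle between the two acyl-tail end-to-end vectors of one PL."""

    times: np.ndarray
    angles: np.ndarray             # degrees in [0, 180]
    parallel_threshold_deg: float = 50.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any((self.angles < 0) | (self.angles > 180)):
            raise ValueError("angles must lie in [0, 180]")
        self.parallel = self.angles <= self.parallel_threshold_deg


def tail_plane_angle(
    ensemble: TrajectoryEnsemble,
    tail_a_selection: str | np.ndarray,
    tail_b_selection: str | np.ndarray,
    parallel_threshold_deg: float = 50.0,
) -> TailPlaneSeries:
    """Per-frame angle between the two tails' terminal-segment vectors.

    Each tail's vector runs from the first to the last atom of its terminal
    segment selection (default usage: the terminal 3 carbons per tail);
    the parallel-plane flag marks angles at or below the threshold.
    """
    s = ensemble.structure
    sel_a = select(s, tail_a_selection) if isinstance(tail_a_selection, str) else np.asarray(tail_a_selection, dtype=int)
    sel_b = select(s, tail_b_selection) if isinstance(tail_b_selection, str) else np.asarray(tail_b_selection, dtype=int)
    if len(sel_a) < 2 or len(sel_b) < 2:
        raise ValueError("each tail terminal segment needs at least 2 atoms")
    angles = np.empty(ensemble.n_frames)
    for fi, frame in enumerate(ensemble.frames):
        va = frame.coords[sel_a[-1]] - frame.coords[sel_a[0]]
        vb = frame.coords[sel_b[-1]] - frame.coords[sel_b[0]]
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            raise ValueError(f"zero-length tail vector in frame {fi}")
        c = float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))
        angles[fi] = np.degrees(np.arccos(c))
    return TailPlaneSeries(
        times=ensemble.times, angles=angles, parallel_threshold_deg=parallel_threshold_deg
    )


# ---------------------------------------------------------------------------
# salt bridges


@dataclass
class SaltBridgeRecord:
    resid: int
    resname: str
    occupancy: float          # fraction of frames with the bridge formed
    mean_distance_nm: float   # mean min distance over formed frames (NaN if never)


def salt_bridges(
    ensemble: TrajectoryEnsemble,
    pl_headgroup_selection: str | np.ndarray,
    charged_residues: list[int] | None = None,
    cutoff_nm: float = 0.4,
) -> list[SaltBridgeRecord]:
    """Salt-bridge occupancy of charged side chains against PL headgroups.

    A bridge is formed in a frame when the minimum distance between the
    residue's formal-charge heavy atoms (Arg NH1/NH2/NE, Lys NZ, Asp
    OD1/OD2, Glu OE1/OE2) and the headgroup charged atoms (the supplied
    selection: phosphate oxygens, choline nitrogen) is <= ``cutoff_nm``.
    Residues of types outside the map are skipped with a warning.
    """
    s = ensemble.structure
    head = (
        select(s, pl_headgroup_selection)
        if isinstance(pl_headgroup_selection, str)
        else np.asarray(pl_headgroup_selection, dtype=int)
    )
    if head.size == 0:
        raise ValueError("empty headgroup selection")

    if charged_residues is None:
        charged_residues = sorted(
            {
                int(s.resids[i])
                for i in range(s.n_atoms)
                if str(s.resnames[i]).upper() in CHARGED_SIDECHAIN_ATOMS
            }
        )
    records = []
    for rid in charged_residues:
        atoms_of_res = np.flatnonzero(s.resids == rid)
        if atoms_of_res.size == 0:
            logger.warning("charged residue %d not found; skipped", rid)
            continue
        resname = str(s.resnames[atoms_of_res[0]]).upper()
        if resname not in CHARGED_SIDECHAIN_ATOMS:
            logger.warning("residue %s%d has no charged-atom map; skipped", resname, rid)
            continue
        wanted = CHARGED_SIDECHAIN_ATOMS[resname]
        charged = atoms_of_res[
            np.isin(np.char.upper(s.names[atoms_of_res].astype(str)), wanted)
        ]
        if charged.size == 0:
            logger.warning("residue %s%d lacks its charged atoms; skipped", resname, rid)
            continue
        formed = np.zeros(ensemble.n_frames, dtype=bool)
        dists = np.empty(ensemble.n_frames)
        for fi, frame in enumerate(ensemble.frames):
            d = np.linalg.norm(
                frame.coords[charged][:, None, :] - frame.coords[head][None, :, :],
                axis=2,
            ).min()
            dists[fi] = d
            formed[fi] = d <= cutoff_nm
        occ = float(formed.mean())
        mean_d = float(dists[formed].mean()) if formed.any() else float("nan")
        records.append(
            SaltBridgeRecord(
                resid=rid, resname=resname, occupancy=occ, mean_distance_nm=mean_d
            )
        )
    return records
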