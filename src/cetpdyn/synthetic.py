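"""Ground-truth-labelled synthetic inputs for every analysis stage.

Each generator emulates one statistical structure the analyses assume:

* three rigid Cα domains (two barrels hinged on a neck) oscillating with
  controllable phase coupling and angular noise,
* a lipid center of mass transiting a straight tunnel with injected
  velocity spikes and optional lateral fallout,
* two-state telegraph χ2 rotamer series,
* Boltzmann-distributed umbrella-window samples from a known analytic PMF
  (Metropolis sampling, burn-in discarded, parameters recorded),
* a hollow-cylinder pseudo-protein point cloud with per-residue
  hydrophobicity labels (the analytic oracle for tunnel profiling).

All generators are deterministic given (spec, seed): one seeded
``numpy.random.Generator`` per call.  Ground-truth labels always align
one-to-one with the generated frames/bins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import KB_KCAL, KJ_PER_KCAL, atom_radius_nm
from .gating import DihedralSeries
from .lipidpath import LipidTrace
from .trajectory import (
    DomainDefinition,
    Frame,
    Structure,
    TrajectoryEnsemble,
    write_structure_pdb,
    write_trajectory,
)
from .wham import UmbrellaWindow

__all__ = [
    "OscillatorSpec",
    "AnalyticPMFSpec",
    "GroundTruth",
    "PSEUDO_DOMAINS",
    "gen_domain_trajectory",
    "gen_transit_trace",
    "gen_rotamer_series",
    "gen_umbrella_samples",
    "gen_tunnel_cloud",
    "write_fixture",
]

#: Cα spacing of the pseudo-protein, nm.
CA_SPACING_NM = 0.38

#: Atoms per pseudo-domain.
DOMAIN_LENGTH = 20

#: Residue-range partition of the 60-residue pseudo-protein.  Arc order
#: follows the tunnel axis: C-barrel (1-20) -> neck (21-40) -> N-barrel
#: (41-60).
PSEUDO_DOMAINS = DomainDefinition(
    c_barrel=[(1, 20)], neck=[(21, 40)], n_barrel=[(41, 60)]
)


class GroundTruth(dict):
    """Per-generator truth labels (a dict with JSON serialization)."""

    def to_json(self, path: str | Path) -> Path:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            return v

        path = Path(path)
        path.write_text(json.dumps(_clean(dict(self)), indent=2, sort_keys=True) + "\n")
        return path


# ---------------------------------------------------------------------------
# oscillating three-domain pseudo-protein


@dataclass
class OscillatorSpec:
    """Parameters of the hinged-barrel oscillator.

    Per-domain entries are keyed ``"n_barrel"`` / ``"c_barrel"``.  Defaults
    reproduce the barrel-motion regimes seen in the plug-bound protein:
    the N-barrel swinging between 35° and 40° and the C-barrel between 47°
    and 57° about the neck.
    """

    n_frames: int = 4096
    dt_ps: float = 10.0
    mean_angle_deg: dict = field(
        default_factory=lambda: {"n_barrel": 37.5, "c_barrel": 52.0}
    )
    amplitude_deg: dict = field(
        default_factory=lambda: {"n_barrel": 2.5, "c_barrel": 5.0}
    )
    frequency_per_ps: float = 0.002
    phase_offset_rad: dict = field(
        default_factory=lambda: {"n_barrel": 0.0, "c_barrel": 0.0}
    )
    noise_sd_deg: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.dt_ps <= 0:
            raise ValueError("dt must be positive")
        vals = [
            self.dt_ps, self.frequency_per_ps, self.noise_sd_deg,
            *self.mean_angle_deg.values(), *self.amplitude_deg.values(),
            *self.phase_offset_rad.values(),
        ]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite oscillator parameters")
        if any(a < 0 for a in self.amplitude_deg.values()) or self.noise_sd_deg < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")


def _pseudo_structure() -> tuple[Structure, dict]:
    """Static reference geometry (all domain angles 0): returns the
    structure and the hinge bookkeeping used to pose frames."""
    n_atoms = 3 * DOMAIN_LENGTH
    neck_len = (DOMAIN_LENGTH - 1) * CA_SPACING_NM
    coords = np.zeros((n_atoms, 3))
    geom = {
        "neck_len": neck_len,
        "c_hinge": np.array([0.0, 0.5, 0.0]),
        "n_hinge": np.array([0.0, -0.5, neck_len]),
    }
    coords = _pose(0.0, 0.0, geom)
    names = np.array(["CA"] * n_atoms, dtype=object)
    elements = np.array(["C"] * n_atoms, dtype=object)
    resids = np.arange(1, n_atoms + 1)
    resnames = np.array(["GLY"] * n_atoms, dtype=object)
    chains = np.array(["A"] * n_atoms, dtype=object)
    structure = Structure(
        names=names,
        elements=elements,
        resids=resids,
        resnames=resnames,
        chains=chains,
        residue_index=np.arange(n_atoms),
        coords0=coords,
    )
    return structure, geom


def _pose(theta_n_deg: float, theta_c_deg: float, geom: dict) -> np.ndarray:
    """Atom coordinates for given barrel-vs-neck angles (degrees).

    The neck runs along +z; each barrel hangs from its hinge with its axis
    tilted by θ from the neck axis (oriented away from that barrel), so the
    principal-axis angle recovered downstream equals θ exactly.
    """
    i = np.arange(1, DOMAIN_LENGTH + 1)[:, None] * CA_SPACING_NM
    th_c = math.radians(theta_c_deg)
    th_n = math.radians(theta_n_deg)
    d_c = np.array([math.sin(th_c), 0.0, math.cos(th_c)])
    d_n = np.array([math.sin(th_n), 0.0, -math.cos(th_n)])
    c_barrel = geom["c_hinge"] + i * d_c
    neck = np.column_stack(
        [np.zeros(DOMAIN_LENGTH), np.zeros(DOMAIN_LENGTH),
         np.arange(DOMAIN_LENGTH) * CA_SPACING_NM]
    )
    n_barrel = geom["n_hinge"] + i * d_n
    return np.vstack([c_barrel, neck, n_barrel])


def gen_domain_trajectory(
    spec: OscillatorSpec,
    coupling: str = "in_phase",
    walk_step_rad: float = 0.4,
) -> tuple[TrajectoryEnsemble, GroundTruth]:
    """Three-domain pseudo-protein with controlled barrel-phase coupling.

    θ_i(t) = mean_i + A_i sin(2πft + φ_i) + noise.  ``coupling`` sets
    φ_C − φ_N to 0 (``in_phase``), π (``anti_phase``), or replaces the
    fixed offsets by independent random-walk phases (``uncoupled``,
    Gaussian steps of ``walk_step_rad`` per frame).  Truth stores the exact
    realized angle series (and their noise-free versions).
    """
    if coupling not in ("in_phase", "anti_phase", "uncoupled"):
        raise ValueError(f"unknown coupling {coupling!r}")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) * spec.dt_ps
    omega = 2.0 * math.pi * spec.frequency_per_ps

    phi_n = spec.phase_offset_rad["n_barrel"]
    if coupling == "in_phase":
        phases = {"n_barrel": phi_n + omega * t, "c_barrel": phi_n + omega * t}
    elif coupling == "anti_phase":
        phases = {
            "n_barrel": phi_n + omega * t,
            "c_barrel": phi_n + math.pi + omega * t,
        }
    else:
        walk_n = np.cumsum(rng.normal(0.0, walk_step_rad, spec.n_frames))
        walk_c = np.cumsum(rng.normal(0.0, walk_step_rad, spec.n_frames))
        phases = {
            "n_barrel": phi_n + omega * t + walk_n,
            "c_barrel": spec.phase_offset_rad["c_barrel"] + omega * t + walk_c,
        }

    clean = {}
    realized = {}
    for dom in ("n_barrel", "c_barrel"):
        clean[dom] = (
            spec.mean_angle_deg[dom]
            + spec.amplitude_deg[dom] * np.sin(phases[dom])
        )
        noise = rng.normal(0.0, spec.noise_sd_deg, spec.n_frames) if spec.noise_sd_deg else 0.0
        realized[dom] = clean[dom] + noise

    structure, geom = _pseudo_structure()
    frames = [
        Frame(
            time=t[k],
            coords=_pose(realized["n_barrel"][k], realized["c_barrel"][k], geom),
        )
        for k in range(spec.n_frames)
    ]
    ensemble = TrajectoryEnsemble(structure=structure, frames=frames,
                                  replicate=f"osc_{coupling}_{spec.seed}")
    truth = GroundTruth(
        times_ps=t,
        theta_n=realized["n_barrel"],
        theta_c=realized["c_barrel"],
        theta_n_clean=clean["n_barrel"],
        theta_c_clean=clean["c_barrel"],
        coupling=coupling,
        seed=spec.seed,
    )
    return ensemble, truth


# ---------------------------------------------------------------------------
# lipid transit trace


def gen_transit_trace(
    n_frames: int,
    dt_ps: float,
    mean_velocity_nm_ns: float,
    spike_times_ps: tuple | list = (),
    spike_magnitudes_nm_ns: tuple | list = (),
    spike_width_ps: float = 20.0,
    fallout_frame: int | None = None,
    noise_sd_nm: float = 0.0,
    seed: int = 0,
    s0_nm: float = 0.0,
    exit_s_nm: float | None = None,
    lateral_magnitude_nm: float = 1.2,
    replicate: str = "transit",
) -> tuple[LipidTrace, GroundTruth]:
    """Axial transit at ``mean_velocity`` with Gaussian velocity spikes.

    The axial coordinate advances as the integral of
    v(t) = mean + Σ_j m_j exp(−(t−t_j)²/(2w²)); position noise of
    ``noise_sd_nm`` is added on top.  If ``fallout_frame`` is set, the
    lateral displacement ramps past the tunnel radius from that frame
    onward.  Truth records spike times/frames and the fate label.
    """
    if dt_ps <= 0:
        raise ValueError("dt must be positive")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    t = np.arange(n_frames) * dt_ps
    span = n_frames * dt_ps
    spike_times_ps = list(spike_times_ps)
    spike_magnitudes_nm_ns = list(spike_magnitudes_nm_ns)
    if len(spike_times_ps) != len(spike_magnitudes_nm_ns):
        raise ValueError("spike times and magnitudes must align")
    for ts in spike_times_ps:
        if not (0.0 <= ts < span):
            raise ValueError(f"spike time {ts} ps outside [0, {span}) ps")

    rng = np.random.default_rng(seed)
    v = np.full(n_frames, float(mean_velocity_nm_ns))
    for ts, mag in zip(spike_times_ps, spike_magnitudes_nm_ns):
        v += mag * np.exp(-0.5 * ((t - ts) / spike_width_ps) ** 2)
    # integrate v (nm/ns) over dt (ps)
    s_clean = s0_nm + np.concatenate(
        [[0.0], np.cumsum((v[1:] + v[:-1]) / 2.0 * dt_ps / 1000.0)]
    )
    s = s_clean + (rng.normal(0.0, noise_sd_nm, n_frames) if noise_sd_nm else 0.0)

    lat = np.zeros(n_frames)
    if fallout_frame is not None:
        if not (0 <= fallout_frame < n_frames):
            raise ValueError("fallout_frame outside the trajectory")
        ramp = np.minimum(1.0, (np.arange(n_frames) - fallout_frame + 1) / 3.0)
        lat[fallout_frame:] = lateral_magnitude_nm * ramp[fallout_frame:]

    com = np.column_stack([lat, np.zeros(n_frames), s])
    trace = LipidTrace(times=t, com=com, s=s, r=np.abs(lat), replicate=replicate)

    if fallout_frame is not None:
        fate = "fallout"
    elif exit_s_nm is not None and s_clean.max() >= exit_s_nm:
        fate = "traversal"
    else:
        fate = "incomplete"
    truth = GroundTruth(
        times_ps=t,
        s_clean=s_clean,
        velocity_clean=v,
        spike_times_ps=spike_times_ps,
        spike_frames=[int(round(ts / dt_ps)) for ts in spike_times_ps],
        fallout_frame=fallout_frame,
        fate=fate,
        seed=seed,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# rotamer telegraph series


def gen_rotamer_series(
    baseline_deg: float,
    flip_intervals_ps: list[tuple[float, float]],
    delta_deg: float,
    noise_sd_deg: float,
    dt_ps: float,
    n_frames: int,
    seed: int = 0,
    window_ps: float = 20.0,
    residue: str = "PHE0",
) -> tuple[DihedralSeries, GroundTruth]:
    """Two-state telegraph χ2 series: baseline ↔ baseline + delta.

    ``flip_intervals_ps`` are disjoint [t0, t1) spans within the series
    during which the rotamer sits in the flipped state; Gaussian noise of
    ``noise_sd_deg`` is added throughout.
    """
    if dt_ps <= 0:
        raise ValueError("dt must be positive")
    span = n_frames * dt_ps
    ivs = sorted(flip_intervals_ps)
    for k, (a, b) in enumerate(ivs):
        if b <= a:
            raise ValueError(f"empty interval ({a}, {b})")
        if a < 0 or b > span:
            raise ValueError(f"interval ({a}, {b}) outside the series span [0, {span}]")
        if k and a < ivs[k - 1][1]:
            raise ValueError(f"overlapping intervals {ivs[k - 1]} and {(a, b)}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * dt_ps
    flipped = np.zeros(n_frames, dtype=bool)
    for a, b in ivs:
        flipped |= (t >= a) & (t < b)
    raw = baseline_deg + delta_deg * flipped
    if noise_sd_deg:
        raw = raw + rng.normal(0.0, noise_sd_deg, n_frames)
    # keep raw in the conventional (-180, 180] branch
    raw = np.mod(raw + 180.0, 360.0) - 180.0
    raw = np.where(raw == -180.0, 180.0, raw)
    series = DihedralSeries(times=t, raw=raw, residue=residue, window_ps=window_ps)
    truth = GroundTruth(
        flip_intervals_ps=ivs,
        flipped=flipped,
        baseline_deg=baseline_deg,
        delta_deg=delta_deg,
        seed=seed,
    )
    return series, truth


# ---------------------------------------------------------------------------
# umbrella windows from an analytic PMF


@dataclass
class AnalyticPMFSpec:
    """A known free-energy curve to sample umbrella windows from.

    Forms: ``flat``; ``harmonic`` (½·a·ξ², curvature kcal/mol/nm²);
    ``periodic-cosine`` (A/2·(1−cos 2πξ/L), peak-to-trough amplitude A
    kcal/mol over period L nm); ``double-well`` (h·((ξ/w)²−1)², barrier h
    kcal/mol between minima at ±w nm).
    """

    form: str = "flat"
    amplitude_kcal: float = 2.0     # periodic-cosine
    curvature_kcal_nm2: float = 10.0  # harmonic
    barrier_kcal: float = 2.0       # double-well
    well_nm: float = 0.5            # double-well
    period_nm: float = 2.0          # periodic forms
    temperature_k: float = 300.0

    def __post_init__(self) -> None:
        if self.form not in ("flat", "harmonic", "periodic-cosine", "double-well"):
            raise ValueError(f"unknown PMF form {self.form!r}")
        if self.form == "periodic-cosine" and self.period_nm <= 0:
            raise ValueError("period must be positive for a periodic PMF")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive")

    @property
    def periodic(self) -> bool:
        return self.form == "periodic-cosine"

    def f(self, xi: np.ndarray) -> np.ndarray:
        """F(ξ) in kcal/mol."""
        xi = np.asarray(xi, dtype=float)
        if self.form == "flat":
            return np.zeros_like(xi)
        if self.form == "harmonic":
            return 0.5 * self.curvature_kcal_nm2 * xi**2
        if self.form == "periodic-cosine":
            return 0.5 * self.amplitude_kcal * (
                1.0 - np.cos(2.0 * math.pi * xi / self.period_nm)
            )
        return self.barrier_kcal * ((xi / self.well_nm) ** 2 - 1.0) ** 2


def gen_umbrella_samples(
    pmf: AnalyticPMFSpec,
    window_centers_nm: np.ndarray | list,
    force_constant_kj_mol_nm2: float = 500.0,
    n_samples_per_window: int = 2000,
    seed: int = 0,
    dt_sample_ps: float = 1.0,
    step_nm: float = 0.02,
    burn_in: int = 1000,
    thin: int = 10,
    n_walkers: int = 32,
) -> list[UmbrellaWindow]:
    """Draw biased samples per window from exp(−[F(ξ)+½k(ξ−ξc)²]/kBT).

    Metropolis sampling (Gaussian proposals of ``step_nm``) with the
    burn-in discarded and chains thinned; samples are pooled from
    ``n_walkers`` independent walkers per window.  Sampling parameters are
    recorded in each window's metadata.  Windows with ``n_samples = 0``
    are returned empty (flagged invalid downstream by the binning stage).
    """
    centers = np.asarray(window_centers_nm, dtype=float)
    if centers.size == 0:
        raise ValueError("no window centers")
    if np.any(np.diff(centers) < 0):
        raise ValueError("window centers must be sorted ascending")
    if force_constant_kj_mol_nm2 <= 0:
        raise ValueError("force constant must be positive")
    k_kcal = force_constant_kj_mol_nm2 / KJ_PER_KCAL
    kt = KB_KCAL * pmf.temperature_k
    rng = np.random.default_rng(seed)
    meta = {
        "sampler": "metropolis",
        "step_nm": step_nm,
        "burn_in": burn_in,
        "thin": thin,
        "n_walkers": n_walkers,
        "seed": seed,
    }

    def energy(x: np.ndarray, center: float) -> np.ndarray:
        delta = x - center
        if pmf.periodic:
            delta = delta - pmf.period_nm * np.round(delta / pmf.period_nm)
        e = pmf.f(x) + 0.5 * k_kcal * delta**2
        if not np.all(np.isfinite(e)):
            raise ValueError("non-finite energy: unnormalizable biased density")
        return e

    windows = []
    for center in centers:
        if n_samples_per_window == 0:
            windows.append(
                UmbrellaWindow(
                    center_nm=float(center),
                    k_kj_mol_nm2=force_constant_kj_mol_nm2,
                    times_ps=np.array([]),
                    rc_nm=np.array([]),
                    metadata=dict(meta),
                )
            )
            continue
        per_walker = int(math.ceil(n_samples_per_window / n_walkers))
        n_steps = burn_in + per_walker * thin
        x = center + 0.05 * rng.standard_normal(n_walkers)
        e = energy(x, center)
        kept = []
        for step in range(1, n_steps + 1):
            prop = x + rng.normal(0.0, step_nm, n_walkers)
            e_prop = energy(prop, center)
            accept = rng.random(n_walkers) < np.exp(np.minimum(0.0, -(e_prop - e) / kt))
            x = np.where(accept, prop, x)
            e = np.where(accept, e_prop, e)
            if step > burn_in and (step - burn_in) % thin == 0:
                kept.append(x.copy())
        samples = np.concatenate(kept)[:n_samples_per_window]
        if pmf.periodic:
            samples = samples - pmf.period_nm * np.round(
                (samples - center) / pmf.period_nm
            )
        times = np.arange(1, len(samples) + 1) * dt_sample_ps
        windows.append(
            UmbrellaWindow(
                center_nm=float(center),
                k_kj_mol_nm2=force_constant_kj_mol_nm2,
                times_ps=times,
                rc_nm=samples,
                metadata=dict(meta),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# hollow-cylinder pseudo-protein


def gen_tunnel_cloud(
    radius_nm: float,
    length_nm: float,
    atom_spacing_nm: float,
    hydrophobicity: float | list | np.ndarray = 1.0,
    probe_radius_nm: float = 0.14,
    element: str = "C",
) -> tuple[Structure, dict[str, float], GroundTruth]:
    """Hollow cylinder of pseudo-atoms lining a tunnel of known geometry.

    Wall-atom centers sit at ``radius + (atom vdW radius + probe radius)``
    so that the probe-accessible cavity has exactly the nominal radius —
    this makes the analytic volume πr²L the oracle for the voxel counter.
    ``hydrophobicity`` is a single value for all rings or one value per
    ring; each ring is one residue.  Returns the structure, the
    residue-name→value scale, and truth with the analytic volumes.
    """
    if radius_nm <= 0 or length_nm < 0 or atom_spacing_nm <= 0:
        raise ValueError("radius, length and spacing must be positive")
    if atom_spacing_nm > radius_nm:
        raise ValueError("degenerate wall: atom spacing exceeds the tunnel radius")
    wall_r = radius_nm + atom_radius_nm(element) + probe_radius_nm
    n_rings = int(round(length_nm / atom_spacing_nm)) + 1
    zs = np.linspace(0.0, length_nm, n_rings) if n_rings > 1 else np.array([0.0])
    n_per_ring = max(3, int(math.ceil(2.0 * math.pi * wall_r / atom_spacing_nm)))
    phis = np.arange(n_per_ring) * 2.0 * math.pi / n_per_ring

    if np.isscalar(hydrophobicity):
        ring_values = np.full(n_rings, float(hydrophobicity))
    else:
        ring_values = np.asarray(hydrophobicity, dtype=float)
        if len(ring_values) != n_rings:
            raise ValueError(
                f"need one hydrophobicity per ring ({n_rings}), got {len(ring_values)}"
            )
    unique_vals = {}
    scale: dict[str, float] = {}
    resnames_per_ring = []
    for v in ring_values:
        if v not in unique_vals:
            name = f"H{len(unique_vals):02d}"
            unique_vals[v] = name
            scale[name] = float(v)
        resnames_per_ring.append(unique_vals[v])

    coords, names, elements, resids, resnames, residx = [], [], [], [], [], []
    for ring, z in enumerate(zs):
        for phi in phis:
            coords.append([wall_r * math.cos(phi), wall_r * math.sin(phi), z])
            names.append("CA")
            elements.append(element)
            resids.append(ring + 1)
            resnames.append(resnames_per_ring[ring])
            residx.append(ring)
    structure = Structure(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        chains=np.array(["A"] * len(names), dtype=object),
        residue_index=np.array(residx, dtype=int),
        coords0=np.array(coords, dtype=float),
    )
    truth = GroundTruth(
        radius_nm=radius_nm,
        length_nm=length_nm,
        wall_radius_nm=wall_r,
        total_volume_nm3=math.pi * radius_nm**2 * length_nm,
        volume_per_unit_length_nm2=math.pi * radius_nm**2,
        ring_values=ring_values,
    )
    return structure, scale, truth


# ---------------------------------------------------------------------------
# fixture writing


def write_fixture(
    ensemble: TrajectoryEnsemble, out_dir: str | Path, fmt: str = "PDB+XTC"
) -> dict[str, Path]:
    """Write an ensemble as a PDB topology plus XTC or DCD trajectory."""
    if ensemble.n_frames == 0:
        raise ValueError("cannot write an empty ensemble")
    if fmt not in ("PDB+XTC", "PDB+DCD"):
        raise ValueError(f"unsupported fixture format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = ensemble.replicate or "fixture"
    top = write_structure_pdb(ensemble.structure, out_dir / f"{stem}.pdb")
    ext = "xtc" if fmt.endswith("XTC") else "dcd"
    traj = write_trajectory(ensemble, out_dir / f"{stem}.{ext}", fmt=ext)
    return {"topology": top, "trajectory": traj}
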