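"""Uniform in-memory trajectory model.

Reads PDB/GRO topologies and XTC/DCD coordinate trajectories (via
MDAnalysis) into a small, explicit data model used by every analysis stage:
a :class:`Structure` (atoms + residues), time-ordered :class:`Frame` objects
holding nm coordinates, and a :class:`TrajectoryEnsemble` per replicate.

Coordinates are stored in nm internally regardless of the source format;
times are ps.  No periodic-boundary unwrapping is performed: inputs are
assumed whole-molecule (true for the synthetic fixtures and for
post-processed trajectories).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import A_PER_NM

logger = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "Frame",
    "TrajectoryEnsemble",
    "DomainDefinition",
    "load_structure",
    "load_trajectory",
    "select",
    "center_of_mass",
    "write_structure_pdb",
    "write_trajectory",
]


@dataclass
class Structure:
    """Atoms and residues of one molecular system.

    Per-atom arrays are aligned; ``residue_index`` maps every atom to one
    residue (0-based internal index).  ``resids`` keeps the as-authored
    residue sequence numbers, which is what all user-facing selections use.
    """

    names: np.ndarray          # atom names, str
    elements: np.ndarray       # element symbols, str
    resids: np.ndarray         # author residue numbers, int, per atom
    resnames: np.ndarray       # residue names, str, per atom
    chains: np.ndarray         # chain identifiers, str, per atom
    residue_index: np.ndarray  # 0-based residue index per atom
    coords0: np.ndarray        # first-model coordinates, nm, (n_atoms, 3)
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr_name in ("elements", "resids", "resnames", "chains", "residue_index"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"per-atom array {arr_name!r} length mismatch")
        if self.coords0.shape != (n, 3):
            raise ValueError("coords0 must be (n_atoms, 3)")
        if self.masses is not None and len(self.masses) != n:
            raise ValueError("masses length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max()) + 1 if self.n_atoms else 0

    def residue_resid(self, residue_index: int) -> int:
        """Author residue number of an internal residue index."""
        mask = self.residue_index == residue_index
        return int(self.resids[mask][0])

    def residue_name(self, residue_index: int) -> str:
        mask = self.residue_index == residue_index
        return str(self.resnames[mask][0])

    def atoms_of_residue(self, residue_index: int) -> np.ndarray:
        return np.flatnonzero(self.residue_index == residue_index)

    def heavy_atoms(self) -> np.ndarray:
        """Indices of non-hydrogen atoms."""
        return np.flatnonzero(np.char.upper(self.elements.astype(str)) != "H")


@dataclass
class Frame:
    """One trajectory frame: time (ps) and per-atom coordinates (nm)."""

    time: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in frame")


@dataclass
class TrajectoryEnsemble:
    """Topology plus time-ordered frames for one simulation replicate."""

    structure: Structure
    frames: list[Frame]
    replicate: str = "rep0"

    def __post_init__(self) -> None:
        for i, f in enumerate(self.frames):
            if f.coords.shape[0] != self.structure.n_atoms:
                raise ValueError(
                    f"frame {i}: {f.coords.shape[0]} atoms, structure has "
                    f"{self.structure.n_atoms}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    @property
    def coords(self) -> np.ndarray:
        """All coordinates as one (n_frames, n_atoms, 3) array, nm."""
        return np.stack([f.coords for f in self.frames])

    @property
    def dt(self) -> float:
        """Median frame spacing, ps."""
        t = self.times
        if len(t) < 2:
            raise ValueError("need >= 2 frames for a time step")
        return float(np.median(np.diff(t)))


@dataclass
class DomainDefinition:
    """Named residue-range partition of the protein into its three domains.

    Ranges are inclusive author residue numbers.  Domains must be pairwise
    disjoint and non-empty; optional ``lipid`` and ``pl`` selections name the
    transiting lipid and the phospholipid plugs.
    """

    n_barrel: list[tuple[int, int]]
    neck: list[tuple[int, int]]
    c_barrel: list[tuple[int, int]]
    lipid: str | None = None
    pl: str | None = None

    def __post_init__(self) -> None:
        sets = {}
        for name in ("n_barrel", "neck", "c_barrel"):
            ranges = getattr(self, name)
            if not ranges:
                raise ValueError(f"domain {name!r} has no residue ranges")
            s: set[int] = set()
            for lo, hi in ranges:
                if hi < lo:
                    raise ValueError(f"domain {name!r}: bad range {lo}-{hi}")
                s.update(range(lo, hi + 1))
            sets[name] = s
        for a in sets:
            for b in sets:
                if a < b and sets[a] & sets[b]:
                    raise ValueError(f"domains {a!r} and {b!r} overlap")

    def expression(self, domain: str) -> str:
        """Selection expression for one domain (Cα atoms)."""
        ranges = getattr(self, domain)
        spans = ",".join(f"{lo}-{hi}" for lo, hi in ranges)
        return f"resid {spans} and name CA"


# ---------------------------------------------------------------------------
# loading


def _structure_from_universe(u) -> Structure:
    atoms = u.atoms
    try:
        elements = np.array([e if e else "C" for e in atoms.elements], dtype=object)
    except Exception:
        # fall back to first letter of the atom name, stripping digits
        elements = np.array(
            [re.sub(r"[^A-Za-z]", "", n)[:1].upper() or "C" for n in atoms.names],
            dtype=object,
        )
    try:
        chains = np.array([s if s else "A" for s in atoms.chainIDs], dtype=object)
    except Exception:
        chains = np.array(["A"] * len(atoms), dtype=object)
    resids_per_atom = atoms.resids
    # internal residue index: order of first appearance
    _, inv = np.unique(atoms.resindices, return_inverse=True)
    return Structure(
        names=np.array(atoms.names, dtype=object),
        elements=elements,
        resids=np.asarray(resids_per_atom, dtype=int),
        resnames=np.array(atoms.resnames, dtype=object),
        chains=chains,
        residue_index=inv.astype(int),
        coords0=np.asarray(atoms.positions, dtype=float) / A_PER_NM,
    )


def _validate_pdb_text(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) < 54:
            raise ValueError(
                f"{path}: malformed coordinate record at line {lineno} "
                f"(shorter than the fixed-width coordinate fields)"
            )


def load_structure(path: str | Path) -> Structure:
    """Read a PDB or GRO file into a :class:`Structure`.

    Coordinates of the file's first model are retained, converted to nm.
    Raises ``ValueError`` for malformed records (naming the line) and for
    unknown extensions.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext not in (".pdb", ".gro"):
        raise ValueError(f"unsupported structure format {ext!r} (expected .pdb or .gro)")
    if ext == ".pdb":
        _validate_pdb_text(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # mda raises many types for bad input
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise ValueError(f"{path}: no atoms parsed")
    return _structure_from_universe(u)


def load_trajectory(
    structure: Structure,
    path: str | Path,
    dt_ps: float | None = None,
    replicate: str = "rep0",
) -> TrajectoryEnsemble:
    """Read an XTC or DCD trajectory against an already-loaded structure.

    The trajectory atom count must equal the structure atom count.  Times are
    ps; if the file carries no usable time metadata (common for DCD), times
    are synthesized as ``index * dt_ps`` and a warning is logged.
    """
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XTC import XTCReader

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext == ".xtc":
        reader = XTCReader(str(path))
    elif ext == ".dcd":
        reader = DCDReader(str(path))
    else:
        raise ValueError(f"unsupported trajectory format {ext!r} (expected .xtc or .dcd)")

    with reader:
        if reader.n_atoms != structure.n_atoms:
            raise ValueError(
                f"atom-count mismatch: trajectory {path} has {reader.n_atoms} atoms, "
                f"structure has {structure.n_atoms}"
            )
        frames = []
        for i, ts in enumerate(reader):
            try:
                coords = np.asarray(ts.positions, dtype=float) / A_PER_NM
                t = float(ts.time)
            except Exception as exc:
                raise ValueError(f"unreadable frame {i} in {path}: {exc}") from exc
            frames.append(Frame(time=t, coords=coords))

    times = np.array([f.time for f in frames])
    needs_synthesis = len(times) > 1 and not np.all(np.diff(times) > 0)
    # DCD stores only a nominal step, not wall-clock times: trust the caller's dt
    if ext == ".dcd" and dt_ps is not None:
        needs_synthesis = True
    if needs_synthesis:
        dt = dt_ps if dt_ps is not None else 1.0
        logger.warning(
            "%s carries no usable frame times; synthesizing index * %.3g ps", path, dt
        )
        for i, f in enumerate(frames):
            f.time = i * dt
    return TrajectoryEnsemble(structure=structure, frames=frames, replicate=replicate)


# ---------------------------------------------------------------------------
# selections

_SEL_RE = re.compile(
    r"^\s*resid\s+(?P<ranges>[\d,\-\s]+?)(?:\s+and\s+name\s+(?P<names>[\w'\s]+))?\s*$",
    re.IGNORECASE,
)
_NAME_RE = re.compile(r"^\s*name\s+(?P<names>[\w'\s]+?)\s*$", re.IGNORECASE)


def select(structure: Structure, expression: str) -> np.ndarray:
    """Resolve a selection expression to an ordered array of atom indices.

    Mini-language: ``resid A-B[,C-D] [and name N1 N2 ...]`` or
    ``name N1 N2 ...`` alone.  Residue numbers are author numbering.  An
    empty result raises (a silently empty selection is never returned).
    """
    m = _SEL_RE.match(expression)
    mask = np.ones(structure.n_atoms, dtype=bool)
    if m:
        resid_mask = np.zeros(structure.n_atoms, dtype=bool)
        for token in m.group("ranges").replace(" ", "").split(","):
            if not token:
                continue
            if "-" in token:
                lo_s, hi_s = token.split("-", 1)
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(token)
            hit = (structure.resids >= lo) & (structure.resids <= hi)
            if not hit.any():
                raise ValueError(f"selection {expression!r}: no residues in range {token}")
            resid_mask |= hit
        mask &= resid_mask
        names = m.group("names")
    else:
        m2 = _NAME_RE.match(expression)
        if not m2:
            raise ValueError(
                f"cannot parse selection {expression!r}; expected "
                "'resid A-B[,C-D] [and name N1 N2 ...]' or 'name N1 ...'"
            )
        names = m2.group("names")
    if names:
        wanted = {n.upper() for n in names.split()}
        name_mask = np.isin(np.char.upper(structure.names.astype(str)), sorted(wanted))
        mask &= name_mask
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"selection {expression!r} matched no atoms")
    return idx


def center_of_mass(
    frame: Frame | np.ndarray,
    selection: Sequence[int] | np.ndarray,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Mass-weighted mean position (nm) of the selected atoms in one frame.

    Unit masses are assumed when none are supplied.
    """
    coords = frame.coords if isinstance(frame, Frame) else np.asarray(frame)
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    pts = coords[sel]
    if masses is None:
        return pts.mean(axis=0)
    w = np.asarray(masses, dtype=float)
    if w.shape[0] != sel.shape[0]:
        raise ValueError("masses must align with the selection")
    return (pts * w[:, None]).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# fixture writing (used by the synthetic generators)


def _universe_from_structure(structure: Structure):
    import MDAnalysis as mda

    n_res = structure.n_residues
    u = mda.Universe.empty(
        structure.n_atoms,
        n_residues=n_res,
        atom_resindex=structure.residue_index,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", structure.names.astype(str))
    u.add_TopologyAttr("elements", structure.elements.astype(str))
    res_resids = np.empty(n_res, dtype=int)
    res_resnames = np.empty(n_res, dtype=object)
    for r in range(n_res):
        res_resids[r] = structure.residue_resid(r)
        res_resnames[r] = structure.residue_name(r)
    u.add_TopologyAttr("resids", res_resids)
    u.add_TopologyAttr("resnames", res_resnames.astype(str))
    u.add_TopologyAttr("segids", ["A"])
    u.atoms.positions = structure.coords0 * A_PER_NM
    return u


def write_structure_pdb(structure: Structure, path: str | Path) -> Path:
    """Write the structure (first-frame coordinates) as a PDB file."""
    path = Path(path)
    u = _universe_from_structure(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    return path


def write_trajectory(
    ensemble: TrajectoryEnsemble, path: str | Path, fmt: str = "xtc"
) -> Path:
    """Write the ensemble's frames as XTC or DCD."""
    import MDAnalysis as mda

    if ensemble.n_frames == 0:
        raise ValueError("cannot write an empty ensemble")
    path = Path(path)
    if fmt.lower() not in ("xtc", "dcd"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    u = _universe_from_structure(ensemble.structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=ensemble.structure.n_atoms) as w:
            for i, f in enumerate(ensemble.frames):
                u.atoms.positions = f.coords * A_PER_NM
                u.trajectory.ts.frame = i
                u.trajectory.ts.time = f.time
                w.write(u.atoms)
    return path
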