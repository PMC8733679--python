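"""Core structural data model shared by all analyses.

Conventions used throughout the package:

* lengths in nm, times in ns, masses in amu, charges in elementary charges,
  energies in kJ/mol;
* atom indices are 0-based inside arrays (the 1-based serial of the source
  file is ``index + 1``);
* residues are identified by ``(chain_id, resid)`` with the numbering of the
  source file preserved verbatim;
* periodic cells are stored as a 3x3 matrix whose *rows* are the lattice
  vectors in nm; ``box=None`` means no periodicity.

File parsing and writing (PDB, GRO, XTC, DCD, multi-model PDB) is delegated
to MDAnalysis; everything is converted to the unit conventions above on the
way in and out.
"""

from __future__ import annotations

import pathlib
import urllib.request
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Structure",
    "Trajectory",
    "AtomGroup",
    "AnalysisWindows",
    "load_structure",
    "load_trajectory",
    "write_structure",
    "write_trajectory",
    "minimum_image_distance",
    "distance_array",
    "center_of_mass",
    "make_windows",
    "recenter_membrane",
    "fetch_pdb",
    "element_from_name",
    "mass_of_element",
]

# Standard atomic masses (amu).  Deliberately small: unknown elements are an
# error, not a guess.
ELEMENT_MASSES = {
    "H": 1.008, "D": 2.014, "B": 10.811, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974,
    "S": 32.06, "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938,
    "FE": 55.845, "ZN": 65.38, "SE": 78.971, "BR": 79.904, "I": 126.904,
}

# Atom names that unambiguously denote a two-letter element in biomolecular
# files (ions, cofactor metals).  "CA" stays carbon: in protein records it is
# the alpha carbon.
_TWO_LETTER_NAMES = {"CL", "NA", "MG", "FE", "ZN", "BR", "SE", "MN"}


def element_from_name(name: str) -> str:
    """Infer the element symbol from an atom name (PDB/GRO convention)."""
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if stripped in _TWO_LETTER_NAMES:
        return stripped
    return stripped[0]


def mass_of_element(element: str, atom_label: str = "") -> float:
    try:
        return ELEMENT_MASSES[element.upper()]
    except KeyError:
        raise ValueError(
            f"unknown element {element!r} for atom {atom_label or '<unnamed>'}; "
            "supply a mass override"
        ) from None


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class Structure:
    """An atom table with one coordinate set and an optional periodic box."""

    chain_ids: np.ndarray      # (n,) str
    resids: np.ndarray         # (n,) int, source-file numbering
    resnames: np.ndarray       # (n,) str
    names: np.ndarray          # (n,) str
    elements: np.ndarray       # (n,) str
    masses: np.ndarray         # (n,) float, amu
    coords: np.ndarray         # (n, 3) float, nm
    box: np.ndarray | None = None   # (3, 3) lattice vectors, nm
    charges: np.ndarray | None = None  # (n,) float, e
    label: str = ""

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("chain_ids", "resids", "resnames", "elements", "masses"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length != atom count {n}")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coordinate count {self.coords.shape} != atom count {n}"
            )
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            bad = int(np.argmax(self.masses <= 0))
            raise ValueError(f"non-positive mass for atom {self.atom_label(bad)}")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3, 3)
        # residue ids must be non-decreasing within a chain; formats without
        # chain identifiers (GRO) concatenate molecules and are exempt
        for cid in np.unique(self.chain_ids):
            if str(cid) == "":
                continue
            r = self.resids[self.chain_ids == cid]
            if np.any(np.diff(r) < 0):
                raise ValueError(f"residue ids decrease within chain {cid!r}")

    # -- basic introspection ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom_label(self, i: int) -> str:
        return (
            f"{self.chain_ids[i]}/{self.resnames[i]}{self.resids[i]}/"
            f"{self.names[i]} (serial {i + 1})"
        )

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique ``(chain, resid)`` keys in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.resids):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    # -- selections ---------------------------------------------------------

    def select(self, expr: str, allow_empty: bool = False,
               label: str | None = None) -> "AtomGroup":
        from .selection import select as _select
        return _select(self, expr, allow_empty=allow_empty, label=label)

    def atom_group(self, indices: Iterable[int], label: str = "") -> "AtomGroup":
        return AtomGroup(self, np.asarray(sorted(set(int(i) for i in indices)),
                                          dtype=int), label)

    def with_coords(self, coords: np.ndarray,
                    box: np.ndarray | None = None) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float),
                       box=self.box if box is None else box)

    # -- MDAnalysis bridge --------------------------------------------------

    def to_universe(self):
        """Build an MDAnalysis Universe (Angstrom units) from this structure."""
        import MDAnalysis as mda

        # contiguous (chain, resid, resname) runs define residues
        resindex = np.zeros(self.n_atoms, dtype=int)
        res_keys: list[tuple[str, int, str]] = []
        for i in range(self.n_atoms):
            key = (str(self.chain_ids[i]), int(self.resids[i]),
                   str(self.resnames[i]))
            if not res_keys or key != res_keys[-1]:
                res_keys.append(key)
            resindex[i] = len(res_keys) - 1
        seg_names: list[str] = []
        res_segindex = np.zeros(len(res_keys), dtype=int)
        for j, (cid, _, _) in enumerate(res_keys):
            if not seg_names or cid != seg_names[-1]:
                seg_names.append(cid)
            res_segindex[j] = len(seg_names) - 1

        u = mda.Universe.empty(
            self.n_atoms, n_residues=len(res_keys), n_segments=len(seg_names),
            atom_resindex=resindex, residue_segindex=res_segindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", list(self.names))
        u.add_TopologyAttr("elements", list(self.elements))
        u.add_TopologyAttr("masses", self.masses)
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("segids", [s if s else "X" for s in seg_names])
        u.add_TopologyAttr("chainIDs",
                           [str(c) if str(c) else "X" for c in self.chain_ids])
        if self.charges is not None:
            u.add_TopologyAttr("charges", self.charges)
        u.atoms.positions = self.coords * 10.0
        if self.box is not None:
            from MDAnalysis.lib.mdamath import triclinic_box
            b = self.box * 10.0
            u.dimensions = triclinic_box(b[0], b[1], b[2])
        return u


@dataclass
class AtomGroup:
    """A sorted, de-duplicated set of atom indices on a structure."""

    structure: Structure
    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        idx = np.unique(idx)
        if idx.size and (idx[0] < 0 or idx[-1] >= self.structure.n_atoms):
            raise IndexError(
                f"atom indices out of range for structure with "
                f"{self.structure.n_atoms} atoms"
            )
        self.indices = idx

    def __len__(self) -> int:
        return int(self.indices.size)

    def coords(self, frame_coords: np.ndarray | None = None) -> np.ndarray:
        xyz = (self.structure.coords if frame_coords is None else frame_coords)
        return xyz[self.indices]

    @property
    def masses(self) -> np.ndarray:
        return self.structure.masses[self.indices]

    def residue_keys(self) -> list[tuple[str, int]]:
        seen: dict[tuple[str, int], None] = {}
        s = self.structure
        for i in self.indices:
            seen.setdefault((str(s.chain_ids[i]), int(s.resids[i])), None)
        return list(seen)

    def split_by_residue(self) -> list["AtomGroup"]:
        s = self.structure
        buckets: dict[tuple[str, int], list[int]] = {}
        for i in self.indices:
            buckets.setdefault((str(s.chain_ids[i]), int(s.resids[i])),
                               []).append(int(i))
        return [
            AtomGroup(s, np.asarray(v), label=f"{k[0]}:{k[1]}")
            for k, v in buckets.items()
        ]

    def union(self, other: "AtomGroup", label: str = "") -> "AtomGroup":
        return AtomGroup(self.structure,
                         np.union1d(self.indices, other.indices), label)


@dataclass
class Trajectory:
    """In-memory frame sequence over a fixed topology."""

    topology: Structure
    times: np.ndarray            # (F,) ns
    coords: np.ndarray           # (F, n, 3) nm
    boxes: np.ndarray | None = None   # (F, 3, 3) nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1:]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if len(self.times) != len(self.coords):
            raise ValueError("times and frames differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def box_at(self, f: int) -> np.ndarray | None:
        if self.boxes is not None:
            return self.boxes[f]
        return self.topology.box


@dataclass
class AnalysisWindows:
    """Half-open ``[start, end)`` time intervals (ns) used for averaging."""

    windows: list[tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        ws = [(float(a), float(b)) for a, b in self.windows]
        for a, b in ws:
            if not b > a:
                raise ValueError(f"window ({a}, {b}) has non-positive length")
        ws_sorted = sorted(ws)
        for (a1, b1), (a2, b2) in zip(ws_sorted, ws_sorted[1:]):
            if a2 < b1:
                raise ValueError(
                    f"windows ({a1}, {b1}) and ({a2}, {b2}) overlap"
                )
        self.windows = ws

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def frame_indices(self, times: np.ndarray) -> list[np.ndarray]:
        times = np.asarray(times, dtype=float)
        out = []
        for a, b in self.windows:
            out.append(np.nonzero((times >= a) & (times < b))[0])
        return out


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------


def _min_image_sq(deltas: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Squared minimum-image norms of displacement vectors.

    Wraps into the central cell by fractional rounding, then searches the 27
    nearest images -- exact for every cell whose inter-face distance exceeds
    twice the largest distance of interest, and for all toy boxes used here.
    """
    box = np.asarray(box, dtype=float).reshape(3, 3)
    if not np.any(box[~np.eye(3, dtype=bool)]):
        # orthorhombic: fractional rounding alone is the exact minimum image
        L = np.diag(box)
        base = deltas - np.round(deltas / L) * L
        return np.square(base).sum(axis=-1)
    frac = deltas @ np.linalg.inv(box)
    frac -= np.round(frac)
    base = frac @ box
    best = None
    for i in (-1.0, 0.0, 1.0):
        for j in (-1.0, 0.0, 1.0):
            for k in (-1.0, 0.0, 1.0):
                shift = i * box[0] + j * box[1] + k * box[2]
                d2 = np.square(base + shift).sum(axis=-1)
                best = d2 if best is None else np.minimum(best, d2)
    return best


def minimum_image_distance(p, q, box: np.ndarray | None = None) -> float:
    """Shortest distance between two points over periodic images (nm)."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    if box is None:
        return float(np.linalg.norm(d))
    return float(np.sqrt(_min_image_sq(d[None, :], box)[0]))


def distance_array(P: np.ndarray, Q: np.ndarray,
                   box: np.ndarray | None = None) -> np.ndarray:
    """All pairwise (minimum-image) distances between two coordinate sets."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    deltas = Q[None, :, :] - P[:, None, :]
    if box is None:
        return np.sqrt(np.square(deltas).sum(axis=-1))
    return np.sqrt(_min_image_sq(deltas, box))


def center_of_mass(group: AtomGroup,
                   frame_coords: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted mean position of a group (no periodic unwrapping)."""
    if len(group) == 0:
        raise ValueError("center of mass of an empty group")
    m = group.masses
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    return (group.coords(frame_coords) * m[:, None]).sum(axis=0) / total


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def make_windows(trajectory: Trajectory, length: float | None = None,
                 burn_in: float = 0.0,
                 intervals: Sequence[tuple[float, float]] | None = None,
                 label: str = "") -> AnalysisWindows:
    """Build analysis windows over a trajectory.

    Either pass ``intervals`` explicitly (e.g. the enhanced-sampling
    convention of analysing only the 100-150 and 150-200 ns stretches of a
    replica), or a fixed window ``length`` with an equilibration ``burn_in``;
    only complete windows after the burn-in are kept.
    """
    if intervals is not None:
        w = AnalysisWindows(list(intervals), label or "explicit")
        span = (trajectory.times[0], trajectory.times[-1])
        for a, b in w.windows:
            if b <= span[0] or a > span[1]:
                warnings.warn(
                    f"window ({a}, {b}) ns lies outside the trajectory span "
                    f"{span}", stacklevel=2)
        return w
    if length is None or length <= 0:
        raise ValueError("window length must be positive")
    if burn_in < 0:
        raise ValueError("burn-in must be non-negative")
    end = float(trajectory.times[-1])
    windows = []
    start = burn_in
    while start + length <= end + 1e-9:
        windows.append((start, start + length))
        start += length
    if not windows:
        warnings.warn(
            f"trajectory of {end:g} ns is too short for burn-in {burn_in:g} ns"
            f" + window {length:g} ns; no analysis windows", stacklevel=2)
    return AnalysisWindows(windows, label or f"{length:g}ns-windows")


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

_STRUCTURE_FORMATS = {".pdb": "PDB", ".gro": "GRO"}
_TRAJ_FORMATS = {".xtc": "XTC", ".dcd": "DCD", ".pdb": "PDB"}


def _infer_format(path, table, format=None) -> str:
    if format:
        return format.upper()
    suffix = pathlib.Path(path).suffix.lower()
    if suffix in table:
        return table[suffix]
    raise ValueError(f"cannot infer file format from {path!r}")


def _box_from_dimensions(dimensions) -> np.ndarray | None:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if np.all(dims[:3] == 0):
        return None
    from MDAnalysis.lib.mdamath import triclinic_vectors
    return np.asarray(triclinic_vectors(dims), dtype=float) / 10.0


def load_structure(path, format: str | None = None,
                   mass_overrides: dict[str, float] | None = None) -> Structure:
    """Read a PDB or GRO file into a Structure (coordinates in nm)."""
    import MDAnalysis as mda

    fmt = _infer_format(path, _STRUCTURE_FORMATS, format)
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=fmt, to_guess=())
    n = len(u.atoms)
    names = np.asarray([a.name for a in u.atoms], dtype=object)
    resnames = np.asarray([a.resname for a in u.atoms], dtype=object)
    resids = np.asarray([a.resid for a in u.atoms], dtype=int)
    if hasattr(u.atoms, "chainIDs"):
        chains = np.asarray([c if c.strip() else "" for c in u.atoms.chainIDs],
                            dtype=object)
    else:
        chains = np.asarray(["" for _ in range(n)], dtype=object)
    file_elements = (
        [e.strip() for e in u.atoms.elements]
        if hasattr(u.atoms, "elements") else [""] * n
    )
    overrides = {k.upper(): v for k, v in (mass_overrides or {}).items()}
    elements, masses = [], []
    for i in range(n):
        el = file_elements[i].upper() or element_from_name(str(names[i]))
        elements.append(el)
        label = f"{chains[i]}/{resnames[i]}{resids[i]}/{names[i]}"
        if str(names[i]).upper() in overrides:
            masses.append(overrides[str(names[i]).upper()])
        elif el in overrides:
            masses.append(overrides[el])
        else:
            masses.append(mass_of_element(el, label))
    return Structure(
        chain_ids=chains, resids=resids,
        resnames=resnames, names=names,
        elements=np.asarray(elements, dtype=object),
        masses=np.asarray(masses, dtype=float),
        coords=u.atoms.positions / 10.0,
        box=_box_from_dimensions(u.dimensions),
        label=path.stem,
    )


def load_trajectory(path, topology: Structure, format: str | None = None,
                    dt: float | None = None) -> Trajectory:
    """Read an XTC/DCD/multi-model-PDB trajectory over a known topology.

    ``dt`` (ns) is required for containers without time stamps (PDB).
    """
    import MDAnalysis as mda

    fmt = _infer_format(path, _TRAJ_FORMATS, format)
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path), format=fmt)
    except (ValueError, IOError) as exc:
        raise ValueError(
            f"trajectory {path} does not match topology with "
            f"{topology.n_atoms} atoms: {exc}"
        ) from exc
    times, coords, boxes = [], [], []
    has_boxes = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if ts.n_atoms != topology.n_atoms:
                raise ValueError(
                    f"frame has {ts.n_atoms} atoms, topology has "
                    f"{topology.n_atoms}")
            coords.append(ts.positions / 10.0)
            times.append(ts.time / 1000.0)   # ps -> ns
            b = _box_from_dimensions(ts.dimensions)
            if b is None:
                has_boxes = False
            boxes.append(b)
    n = len(coords)
    if fmt == "PDB":
        if dt is None:
            raise ValueError("dt (ns) is required for time-less PDB trajectories")
        times = [dt * i for i in range(n)]
    return Trajectory(
        topology=topology,
        times=np.asarray(times),
        coords=np.asarray(coords),
        boxes=np.asarray(boxes) if has_boxes and n else None,
    )


def write_structure(structure: Structure, path) -> None:
    """Write a Structure to PDB or GRO (units converted back on the way out)."""
    u = structure.to_universe()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory to XTC, DCD or multi-model PDB."""
    import MDAnalysis as mda
    from MDAnalysis.lib.mdamath import triclinic_box

    fmt = _infer_format(path, _TRAJ_FORMATS, format)
    u = traj.topology.to_universe()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms,
                        multiframe=True, format=fmt) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f] * 10.0
                b = traj.box_at(f)
                if b is not None:
                    bb = b * 10.0
                    u.dimensions = triclinic_box(bb[0], bb[1], bb[2])
                u.trajectory.ts.time = traj.times[f] * 1000.0  # ns -> ps
                u.trajectory.ts.frame = f
                w.write(u.atoms)


def recenter_membrane(traj: Trajectory, membrane: AtomGroup,
                      head_name: str = "P") -> Trajectory:
    """Shift each frame along z so the membrane midplane sits at z = 0.

    The midplane is the mean z of the membrane's phosphate-like atoms
    (``head_name``), falling back to all membrane atoms.  Coordinates are
    translated only (no re-wrapping): callers measuring centers of mass across
    the membrane should apply this before analysis.
    """
    s = traj.topology
    head_idx = [i for i in membrane.indices if str(s.names[i]) == head_name]
    idx = np.asarray(head_idx if head_idx else membrane.indices, dtype=int)
    coords = traj.coords.copy()
    for f in range(traj.n_frames):
        coords[f, :, 2] -= coords[f, idx, 2].mean()
    return Trajectory(topology=s, times=traj.times.copy(), coords=coords,
                      boxes=None if traj.boxes is None else traj.boxes.copy())


def fetch_pdb(accession: str, cache_dir=None, timeout: float = 30.0):
    """Download a deposited PDB entry by 4-character accession, with caching.

    Returns the path of the cached file.  Requires network access on first
    use for a given accession.
    """
    accession = accession.strip().upper()
    if len(accession) != 4:
        raise ValueError(f"not a 4-character PDB accession: {accession!r}")
    cache = pathlib.Path(cache_dir or pathlib.Path.home() / ".cache" / "arrbind")
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{accession}.pdb"
    if target.exists():
        return target
    url = f"https://files.rcsb.org/download/{accession}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    target.write_bytes(data)
    return target
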