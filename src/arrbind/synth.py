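"""Seeded toy receptor-membrane-arrestin systems with known ground truth.

The generator emulates, at bead resolution, the ingredients of a
GPCR/arrestin simulation system so that every observable of this package can
be verified by parameter recovery without any MD engine:

* a two-leaflet lipid slab in the xy-plane centred at z = 0, mixing PC-like
  (``PCX``), anionic PG-like (``PGX``, head charge -1 e) and
  cholesterol-like (``CHX``) pseudo-molecules of 3-4 beads on a grid;
* a seven-helix receptor bundle (chain R) spanning the slab, with
  bead-chain ICL3 and C-terminus loops below the membrane and a
  full-backbone ICL2 segment whose helicity can toggle;
* a two-lobe arrestin body (chain A) below the lower leaflet with four
  marked N-lobe strands, C-edge loop beads and a basic patch of
  lysines/arginines near the anionic heads;
* rigid-body arrestin motion with exactly discretised Ornstein-Uhlenbeck
  insertion depth d(t) and rotation alpha(t);
* two-state Markov membrane-contact processes for scripted loop residues
  (contact pose: 0.35 nm below a "home" lipid head; detached pose: 1.2 nm);
* per-atom isotropic Gaussian jitter with per-residue amplitudes.

Every stochastic element's exact parameters are exported as GroundTruth, and
one seeded NumPy generator drives the whole pipeline, so fixtures are
bit-reproducible.  No physical realism is attempted beyond what the
observables measure: distances, charges and labels.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import secondary
from .core import Structure, Trajectory
from .geometry import rotate_about_normal

__all__ = [
    "ToySystemSpec",
    "OUSpec",
    "ContactProcess",
    "DynamicsSpec",
    "GroundTruth",
    "ToyComplex",
    "ToyBundle",
    "build_toy_complex",
    "simulate_trajectory",
    "write_fixture",
    "default_dynamics",
    "default_params",
    "markov_effective_sample_size",
    "TM_RANGES",
    "SELECTIONS",
]

# beta2AR-like transmembrane helix residue ranges (chain R)
TM_RANGES = ((29, 60), (67, 96), (103, 136), (147, 171), (197, 229),
             (267, 298), (305, 328))
ICL2_RESIDS = tuple(range(137, 147))          # full backbone, F139 inside
ICL3_RESIDS = tuple(range(230, 267))          # bead chain, S246/S261/S262
CTERM_RESIDS = tuple(range(343, 363))         # bead chain, G351/G361
NLOBE_STRANDS = ((8, 15), (20, 27), (33, 40), (46, 53))
CLOBE_RESIDS = (255, 286)
CEDGE_RESIDS = tuple(range(190, 196)) + (226, 227) + tuple(range(331, 335))
BASIC_PATCH_RESIDS = (230, 231, 233, 237, 251, 325, 327)
PHOSPHO_RESIDS = (246, 261, 262)

_TM_SEL = " ".join(f"{a}:{b}" for a, b in TM_RANGES)
_NLOBE_SEL = " ".join(f"{a}:{b}" for a, b in NLOBE_STRANDS)

#: Default named selections that resolve on every toy complex.
SELECTIONS = {
    "tm_bundle": f"chain R and name CA and resid {_TM_SEL}",
    "receptor_fit": f"chain R and name CA and resid {_TM_SEL}",
    "icl2": "chain R and resid 137:146",
    "icl3": "chain R and resid 230:266",
    "cterm": "chain R and resid 343:362",
    "nlobe": f"chain A and resid {_NLOBE_SEL}",
    "clobe": f"chain A and resid {CLOBE_RESIDS[0]}:{CLOBE_RESIDS[1]}",
    "cedge": "chain A and resid 190:195 226:227 331:334",
    "basic_patch": "chain A and resid " + " ".join(map(str, BASIC_PATCH_RESIDS)),
    "membrane": "resname PCX PGX CHX",
    "pg_lipids": "resname PGX",
}

_SPECIAL_RESNAMES = {
    131: "ARG", 139: "PHE", 147: "LYS", 232: "LYS", 268: "GLU",
    246: "SER", 261: "SER", 262: "SER", 351: "GLY", 361: "GLY",
}
_ARRESTIN_RESNAMES = {135: "GLU", 314: "GLU"}
for _r in BASIC_PATCH_RESIDS:
    _ARRESTIN_RESNAMES[_r] = "ARG" if _r == 237 else "LYS"


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class ToySystemSpec:
    """Geometry and composition of the toy complex.

    Lipid counts default to the 54:36:10 PC:PG:cholesterol molar ratio of
    the study membrane, on an ``nx x ny`` grid per leaflet.
    """

    nx: int = 8
    ny: int = 8
    spacing: float = 1.4            # nm, lipid grid spacing
    pc_per_leaflet: int = 32
    pg_per_leaflet: int = 22
    chol_per_leaflet: int = 6
    pore_radius: float = 1.9        # nm, lipid-free zone around the bundle
    leaflet_z: float = 2.0          # nm, head-bead planes at +-leaflet_z
    box_height: float = 18.0        # nm
    d0: float = 4.48                # nm, built insertion depth
    phosphorylated: bool = True

    def __post_init__(self) -> None:
        n = self.pc_per_leaflet + self.pg_per_leaflet + self.chol_per_leaflet
        if min(self.pc_per_leaflet, self.pg_per_leaflet,
               self.chol_per_leaflet) < 0 or n == 0:
            raise ValueError("lipid counts must be non-negative, total > 0")
        if n > self.nx * self.ny:
            raise ValueError("membrane does not fit the leaflet grid")
        if self.d0 <= self.leaflet_z:
            raise ValueError("arrestin would overlap the membrane")

    @property
    def box_lengths(self) -> tuple[float, float, float]:
        return (self.nx * self.spacing, self.ny * self.spacing,
                self.box_height)


@dataclass
class OUSpec:
    """Ornstein-Uhlenbeck process: stationary mean/SD and relaxation time."""

    mean: float
    sd: float
    tau_ns: float

    def __post_init__(self) -> None:
        if self.sd < 0 or self.tau_ns <= 0:
            raise ValueError("OU needs sd >= 0 and tau > 0")


@dataclass
class ContactProcess:
    """Two-state Markov membrane contact: stationary p and contact dwell."""

    p: float
    dwell_contact_ns: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("stationary probability must be in (0, 1)")
        if self.dwell_contact_ns <= 0:
            raise ValueError("dwell time must be positive")

    @property
    def dwell_detached_ns(self) -> float:
        return self.dwell_contact_ns * (1.0 - self.p) / self.p

    def decay(self, dt: float) -> float:
        """Per-frame autocorrelation factor exp(-(kon+koff) dt)."""
        rate = 1.0 / self.dwell_contact_ns + 1.0 / self.dwell_detached_ns
        return float(np.exp(-rate * dt))


def markov_effective_sample_size(process: ContactProcess, n_frames: int,
                                 dt: float) -> float:
    """Effective sample size of the contact indicator after autocorrelation."""
    lam = process.decay(dt)
    return n_frames * (1.0 - lam) / (1.0 + lam)


@dataclass
class DynamicsSpec:
    """Stochastic dynamics of the toy trajectory."""

    ou_d: OUSpec = field(default_factory=lambda: OUSpec(4.48, 0.065, 1.0))
    ou_alpha: OUSpec = field(default_factory=lambda: OUSpec(0.0, 3.5, 1.0))
    contacts: dict = field(default_factory=dict)   # (chain, resid) -> ContactProcess
    jitter: dict = field(default_factory=dict)     # (chain, resid) -> sigma nm
    default_jitter: float = 0.01                   # nm per axis
    icl2_p_helical: float | None = 0.625           # None = static helix
    dt: float = 0.1                                # ns
    n_frames: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.default_jitter < 0:
            raise ValueError("jitter amplitudes must be non-negative")


def default_dynamics(n_frames: int = 5000, seed: int = 0) -> DynamicsSpec:
    """The study-condition defaults: tight phosphorylated-receptor complex in
    a charged membrane, TM6-proximal ICL3 half membrane-bound, C-terminus
    contact probability decaying away from helix 8, C-edge loops anchored."""
    contacts = {}
    for r in ICL3_RESIDS:
        p = 0.8 if r >= 250 else 0.15
        contacts[("R", r)] = ContactProcess(p=p, dwell_contact_ns=5.0)
    knots = [(343, 0.7), (351, 0.4), (361, 0.1), (362, 0.1)]
    for r in CTERM_RESIDS:
        p = float(np.interp(r, [k for k, _ in knots], [v for _, v in knots]))
        contacts[("R", r)] = ContactProcess(p=p, dwell_contact_ns=5.0)
    for r in CEDGE_RESIDS:
        contacts[("A", r)] = ContactProcess(p=0.95, dwell_contact_ns=20.0)
    jitter = {("R", r): 0.005 for r in ICL2_RESIDS}
    return DynamicsSpec(contacts=contacts, jitter=jitter, n_frames=n_frames,
                        seed=seed)


@dataclass
class GroundTruth:
    """Exact generator parameters, exported next to every fixture."""

    build: dict
    dynamics: dict
    derived: dict

    def to_json(self, path) -> None:
        pathlib.Path(path).write_text(json.dumps(self._plain(), indent=2,
                                                 sort_keys=True))

    def _plain(self) -> dict:
        def conv(obj):
            if isinstance(obj, dict):
                return {_key(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        def _key(k):
            return "|".join(map(str, k)) if isinstance(k, tuple) else str(k)

        return {"build": conv(self.build), "dynamics": conv(self.dynamics),
                "derived": conv(self.derived)}


@dataclass
class ToyComplex:
    structure: Structure
    spec: ToySystemSpec
    truth: dict                      # build-level ground truth + layout
    _layout: dict = field(repr=False, default_factory=dict)


@dataclass
class ToyBundle:
    structure: Structure
    trajectory: Trajectory
    spec: ToySystemSpec
    dynamics: DynamicsSpec
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------


def _align_template(coords: np.ndarray) -> np.ndarray:
    """Rotate a backbone template so its long axis is x and plane is xy."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    rot = vt  # rows: principal axes
    if np.linalg.det(rot) < 0:
        rot[2] = -rot[2]
    return centered @ rot.T


def build_toy_complex(spec: ToySystemSpec, seed: int = 0) -> ToyComplex:
    """Deterministically build the toy membrane-receptor-arrestin complex.

    The membrane slab is centred at z = 0, the receptor bundle runs along z,
    and the arrestin sits below the lower leaflet at insertion depth
    ``spec.d0`` in the alpha = 0 reference orientation.
    """
    rng = np.random.default_rng(seed)
    Lx, Ly, Lz = spec.box_lengths
    cx, cy = Lx / 2.0, Ly / 2.0

    chain, resid, resname, name, elem, charge, xyz = [], [], [], [], [], [], []

    def add(c, r, rn, n, e, q, pos):
        chain.append(c); resid.append(r); resname.append(rn)
        name.append(n); elem.append(e); charge.append(q)
        xyz.append(np.asarray(pos, dtype=float))

    # ----- membrane (the receptor bundle occupies a lipid-free pore) -----
    grid = np.asarray([
        (i, j) for i in range(spec.nx) for j in range(spec.ny)
        if np.hypot((i + 0.5) * spec.spacing - cx,
                    (j + 0.5) * spec.spacing - cy) > spec.pore_radius
    ])
    n_types = (spec.pc_per_leaflet + spec.pg_per_leaflet
               + spec.chol_per_leaflet)
    if n_types > len(grid):
        raise ValueError(
            f"{n_types} lipids per leaflet do not fit the "
            f"{len(grid)} grid cells outside the receptor pore")
    types = (["PCX"] * spec.pc_per_leaflet + ["PGX"] * spec.pg_per_leaflet
             + ["CHX"] * spec.chol_per_leaflet)
    n_lipids_leaflet = len(types)
    lipid_resid = 0
    head_xy: list[tuple[float, float]] = []
    lower_pg_heads: list[np.ndarray] = []
    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        order = rng.permutation(len(grid))[:n_lipids_leaflet]
        assigned = list(zip(order, types))
        for cell, lip in assigned:
            lipid_resid += 1
            gx = (grid[cell, 0] + 0.5) * spec.spacing
            gy = (grid[cell, 1] + 0.5) * spec.spacing
            if lip == "CHX":
                for k, z in enumerate((1.6, 1.1, 0.6)):
                    add("M", lipid_resid, lip, f"C{k + 1}", "C", 0.0,
                        (gx, gy, sign * z))
            else:
                q = -1.0 if lip == "PGX" else 0.0
                add("M", lipid_resid, lip, "P", "P", q,
                    (gx, gy, sign * spec.leaflet_z))
                for k, z in enumerate((1.5, 1.0, 0.5)):
                    add("M", lipid_resid, lip, f"C{k + 1}", "C", 0.0,
                        (gx, gy, sign * z))
                if leaflet == "lower":
                    head_xy.append((gx, gy))
                    if lip == "PGX":
                        lower_pg_heads.append(np.array([gx, gy]))
    if not head_xy:
        raise ValueError("membrane has no phospholipid heads")
    head_xy = np.asarray(head_xy)

    # ----- receptor (atoms added in residue order within the chain) ------
    loop_home: dict[tuple[str, int], np.ndarray] = {}

    def _place_loop(resids, chain_id, row):
        # assign each loop residue a 'home' lower-leaflet head, snaking
        order = np.argsort(np.hypot(head_xy[:, 0] - cx, head_xy[:, 1] - cy))
        for k, r in enumerate(resids):
            hx, hy = head_xy[order[(row * 41 + k * 3) % len(head_xy)]]
            loop_home[(chain_id, r)] = np.array([hx, hy])
            add(chain_id, r,
                (_SPECIAL_RESNAMES if chain_id == "R" else
                 _ARRESTIN_RESNAMES).get(r, "GLY"),
                "CA", "C", _bead_charge(r) if chain_id == "R" else 0.0,
                (hx, hy, -spec.leaflet_z - 1.2))
            if chain_id == "R" and spec.phosphorylated and r in PHOSPHO_RESIDS:
                add(chain_id, r, "SER", "P", "P", -2.0,
                    (hx + 0.2, hy, -spec.leaflet_z - 1.2))

    helix_r = 1.2
    for h, (lo, hi) in enumerate(TM_RANGES):
        ang = 2.0 * np.pi * h / len(TM_RANGES)
        hx, hy = cx + helix_r * np.cos(ang), cy + helix_r * np.sin(ang)
        zs = np.linspace(-2.2, 2.2, hi - lo + 1)
        if h % 2 == 1:
            zs = zs[::-1]
        for r, z in zip(range(lo, hi + 1), zs):
            add("R", r, _SPECIAL_RESNAMES.get(r, "ALA"), "CA", "C",
                _bead_charge(r), (hx, hy, z))
        # keep residue order within the chain: ICL2 between TM3 and TM4,
        # ICL3 between TM5 and TM6
        if (lo, hi) == (103, 136):
            _add_icl2(add, spec, cx, cy)
        if (lo, hi) == (197, 229):
            _place_loop(ICL3_RESIDS, "R", row=0)

    # ----- receptor C-terminus ------------------------------------------
    _place_loop(CTERM_RESIDS, "R", row=1)

    # ----- arrestin ------------------------------------------------------
    z_nlobe = -spec.d0   # TM-bundle COM sits at z = 0 by construction
    for s, (lo, hi) in enumerate(NLOBE_STRANDS):
        for k, r in enumerate(range(lo, hi + 1)):
            add("A", r, "GLY", "CA", "C", 0.0,
                (cx - 1.0 + 0.5 * s, cy - 1.4 + 0.4 * k, z_nlobe))
    add("A", 135, "GLU", "CA", "C", -1.0, (cx + 0.6, cy - 0.8, z_nlobe - 0.4))
    # C-edge loops (scripted towards the membrane) come next in resid order
    cedge_sorted = sorted(CEDGE_RESIDS)
    patch_sorted = sorted(BASIC_PATCH_RESIDS)
    arrestin_rest = sorted(set(cedge_sorted) | set(patch_sorted)
                           | set(range(CLOBE_RESIDS[0], CLOBE_RESIDS[1] + 1))
                           | {314})
    pg_ref = np.array([cx + 3.0, cy])
    if lower_pg_heads:
        pg_near = sorted(lower_pg_heads,
                         key=lambda h: np.linalg.norm(h - pg_ref))
    else:
        pg_near = [pg_ref]
    cedge_count = 0
    patch_count = 0
    clobe_k = 0
    for r in arrestin_rest:
        if r in CEDGE_RESIDS:
            hx, hy = head_xy[np.argmin(
                np.hypot(head_xy[:, 0] - (cx + 2.0),
                         head_xy[:, 1] - (cy - 2.0 + cedge_count * 0.7)))]
            loop_home[("A", r)] = np.array([hx, hy])
            add("A", r, "GLY", "CA", "C", 0.0,
                (hx, hy, -spec.leaflet_z - 1.2))
            cedge_count += 1
        elif r in BASIC_PATCH_RESIDS:
            h = pg_near[patch_count % len(pg_near)]
            add("A", r, _ARRESTIN_RESNAMES[r], "CA", "N", 1.0,
                (h[0] + 0.15, h[1], -spec.leaflet_z - 0.35))
            patch_count += 1
        elif r == 314:
            add("A", r, "GLU", "CA", "C", -1.0,
                (cx + 2.2, cy + 0.6, z_nlobe - 0.2))
        else:  # C-lobe body
            add("A", r, "GLY", "CA", "C", 0.0,
                (cx + 2.6 + 0.35 * (clobe_k % 6),
                 cy - 0.9 + 0.35 * (clobe_k // 6), z_nlobe - 0.5))
            clobe_k += 1

    from .core import element_from_name, mass_of_element
    masses = np.asarray([mass_of_element(e, n) for e, n in zip(elem, name)])
    structure = Structure(
        chain_ids=np.asarray(chain, dtype=object),
        resids=np.asarray(resid, dtype=int),
        resnames=np.asarray(resname, dtype=object),
        names=np.asarray(name, dtype=object),
        elements=np.asarray(elem, dtype=object),
        masses=masses,
        coords=np.asarray(xyz),
        box=np.diag([Lx, Ly, Lz]),
        charges=np.asarray(charge, dtype=float),
        label="toy-complex",
    )
    _check_placements(structure, spec)

    icl2_templates = _icl2_templates(spec, cx, cy)
    # helical residue count of the noiseless helical template
    helical = structure.with_coords(_apply_icl2(structure, icl2_templates,
                                                "helical"))
    phi, psi = secondary.backbone_dihedrals(helical, list(ICL2_RESIDS), "R")
    n_icl2_full = int(secondary.assign_helix(phi, psi).sum())

    truth = {
        "seed": seed,
        "d0": spec.d0,
        "alpha0": 0.0,
        "box_nm": [Lx, Ly, Lz],
        "lipids_per_leaflet": {"PCX": spec.pc_per_leaflet,
                               "PGX": spec.pg_per_leaflet,
                               "CHX": spec.chol_per_leaflet},
        "phosphorylated": spec.phosphorylated,
        "selections": dict(SELECTIONS),
        "icl2_helical_residues_full": n_icl2_full,
        "contact_pose_nm": 0.35,
        "detached_pose_nm": 1.2,
    }
    layout = {"loop_home": loop_home, "icl2_templates": icl2_templates,
              "center": (cx, cy)}
    return ToyComplex(structure=structure, spec=spec, truth=truth,
                      _layout=layout)


def _bead_charge(r: int) -> float:
    resname = _SPECIAL_RESNAMES.get(r, "ALA")
    return {"ARG": 1.0, "LYS": 1.0, "GLU": -1.0}.get(resname, 0.0)


def _add_icl2(add, spec: ToySystemSpec, cx: float, cy: float) -> None:
    templates = _icl2_templates(spec, cx, cy)
    coords = templates["helical"]
    k = 0
    for r in ICL2_RESIDS:
        for n in ("N", "CA", "C"):
            e = "N" if n == "N" else "C"
            add("R", r, _SPECIAL_RESNAMES.get(r, "ALA"), n, e, 0.0, coords[k])
            k += 1


def _icl2_templates(spec: ToySystemSpec, cx: float, cy: float) -> dict:
    """Pre-built helical and coil ICL2 backbone coordinate sets."""
    n = len(ICL2_RESIDS)
    out = {}
    for label, (phi, psi) in (("helical", secondary.HELIX_PHI_PSI),
                              ("coil", (-120.0, 120.0))):
        bb = secondary.build_backbone([phi] * n, [psi] * n)
        aligned = _align_template(bb)
        aligned = aligned + np.array([cx - 2.8, cy, -spec.leaflet_z - 1.0])
        out[label] = aligned
    return out


def _apply_icl2(structure: Structure, templates: dict, state: str
                ) -> np.ndarray:
    coords = structure.coords.copy()
    mask = (structure.chain_ids == "R") & np.isin(structure.resids,
                                                  ICL2_RESIDS) \
        & np.isin(structure.names, ("N", "CA", "C"))
    coords[mask] = templates[state]
    return coords


def _check_placements(structure: Structure, spec: ToySystemSpec) -> None:
    """Fail on inter-component overlaps beyond tolerance."""
    from .core import distance_array
    mem = structure.select("resname PCX PGX CHX").indices
    prot = np.setdiff1d(np.arange(structure.n_atoms), mem)
    # protein beads must not sit inside lipid beads (basic-patch beads and
    # scripted contact poses legitimately come within 0.35 nm)
    d = distance_array(structure.coords[prot], structure.coords[mem],
                       structure.box)
    if d.min() < 0.25:
        raise ValueError("overlapping placements: protein bead within "
                         f"{d.min():.3f} nm of a lipid bead")


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------


def _ou_series(rng, spec: OUSpec, n: int, dt: float) -> np.ndarray:
    """Exact OU discretisation started from the stationary distribution."""
    lam = np.exp(-dt / spec.tau_ns)
    noise_sd = spec.sd * np.sqrt(1.0 - lam ** 2)
    x = np.empty(n)
    x[0] = spec.mean + spec.sd * rng.standard_normal()
    shocks = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = spec.mean + (x[i - 1] - spec.mean) * lam + noise_sd * shocks[i - 1]
    return x


def _markov_series(rng, proc: ContactProcess, n: int, dt: float) -> np.ndarray:
    """Exact two-state chain with the prescribed stationary probability."""
    lam = proc.decay(dt)
    p = proc.p
    stay_c = p + (1.0 - p) * lam
    go_c = p * (1.0 - lam)
    state = np.empty(n, dtype=bool)
    state[0] = rng.random() < p
    u = rng.random(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        state[i] = u[i - 1] < (stay_c if state[i - 1] else go_c)
    return state


def simulate_trajectory(toy: ToyComplex, dyn: DynamicsSpec | None = None
                        ) -> ToyBundle:
    """Generate a seeded toy trajectory with exported ground truth.

    Per frame: (1) the arrestin body is rigidly displaced along z and rotated
    about the receptor bundle axis so that d(t) and alpha(t) follow exact
    Ornstein-Uhlenbeck updates; (2) scripted loop residues toggle between
    their membrane-contact and detached poses per their Markov chains;
    (3) the ICL2 backbone toggles between helical and coil templates; (4)
    isotropic Gaussian jitter is added per atom.
    """
    dyn = dyn if dyn is not None else default_dynamics()
    s = toy.structure
    rng = np.random.default_rng(dyn.seed)
    n, dt = dyn.n_frames, dyn.dt
    cx, cy = toy._layout["center"]

    d_series = _ou_series(rng, dyn.ou_d, n, dt)
    a_series = _ou_series(rng, dyn.ou_alpha, n, dt)

    contact_states = {}
    for key, proc in dyn.contacts.items():
        if key not in toy._layout["loop_home"]:
            raise ValueError(f"no scripted loop residue {key} in the complex")
        contact_states[key] = _markov_series(rng, proc, n, dt)
    if dyn.icl2_p_helical is not None:
        helix_states = rng.random(n) < dyn.icl2_p_helical
    else:
        helix_states = np.ones(n, dtype=bool)

    # per-atom jitter amplitudes
    sigma = np.full(s.n_atoms, dyn.default_jitter)
    for (c, r), amp in dyn.jitter.items():
        sigma[(s.chain_ids == c) & (s.resids == r)] = amp

    arrestin = (s.chain_ids == "A") & ~np.isin(
        s.resids, np.asarray(CEDGE_RESIDS))
    loop_atoms = {
        key: np.nonzero((s.chain_ids == key[0]) & (s.resids == key[1]))[0]
        for key in contact_states
    }
    head_plane = -toy.spec.leaflet_z
    icl2_mask = ((s.chain_ids == "R") & np.isin(s.resids, ICL2_RESIDS)
                 & np.isin(s.names, ("N", "CA", "C")))

    base = s.coords
    coords = np.empty((n, s.n_atoms, 3))
    for f in range(n):
        xyz = base.copy()
        # (1) rigid arrestin body
        xyz[arrestin, 2] -= d_series[f] - toy.spec.d0
        xyz[arrestin] = rotate_about_normal(
            xyz[arrestin], np.array([cx, cy, 0.0]), a_series[f], (0, 0, 1))
        # (2) scripted membrane contacts
        for key, states in contact_states.items():
            pose = 0.35 if states[f] else 1.2
            idx = loop_atoms[key]
            home = toy._layout["loop_home"][key]
            dx = xyz[idx, 0] - xyz[idx[0], 0]   # preserve intra-residue offsets
            xyz[idx, 0] = home[0] + dx
            xyz[idx, 1] = home[1]
            xyz[idx, 2] = head_plane - pose
        # (3) ICL2 helicity
        xyz[icl2_mask] = toy._layout["icl2_templates"][
            "helical" if helix_states[f] else "coil"]
        # (4) jitter
        xyz += rng.standard_normal((s.n_atoms, 3)) * sigma[:, None]
        coords[f] = xyz

    traj = Trajectory(topology=s, times=dt * np.arange(n), coords=coords)

    derived = {
        "contact_lambda": {k: dyn.contacts[k].decay(dt)
                           for k in dyn.contacts},
        "contact_n_eff": {
            k: markov_effective_sample_size(dyn.contacts[k], n, dt)
            for k in dyn.contacts},
        "expected_icl2_helical": (
            (dyn.icl2_p_helical if dyn.icl2_p_helical is not None else 1.0)
            * toy.truth["icl2_helical_residues_full"]),
        "empirical_contact_fraction": {
            k: float(v.mean()) for k, v in contact_states.items()},
        "empirical_d_mean": float(d_series.mean()),
        "empirical_alpha_mean": float(a_series.mean()),
    }
    truth = GroundTruth(build=dict(toy.truth),
                        dynamics=_dynamics_dict(dyn),
                        derived=derived)
    return ToyBundle(structure=s, trajectory=traj, spec=toy.spec,
                     dynamics=dyn, ground_truth=truth)


def _dynamics_dict(dyn: DynamicsSpec) -> dict:
    d = dataclasses.asdict(dyn)
    d["contacts"] = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                     else v for k, v in dyn.contacts.items()}
    return d


# ---------------------------------------------------------------------------
# nonbonded defaults + fixture output
# ---------------------------------------------------------------------------


def default_params(structure: Structure, cutoff: float = 1.2):
    """Nonbonded parameters for a toy structure.

    Charges come from the structure's charge column; all beads share one LJ
    bead type (sigma 0.33 nm, epsilon 0.4 kJ/mol); phospho-Ser phosphate
    beads form the exclusion set, implementing the omit-the-phosphates
    comparability convention.
    """
    from .energetics import NonbondedParams
    n = structure.n_atoms
    protein = np.isin(structure.chain_ids, ("R", "A"))
    excluded = protein & (structure.names == "P")
    return NonbondedParams(
        charges=(structure.charges if structure.charges is not None
                 else np.zeros(n)),
        sigmas=np.full(n, 0.33),
        epsilons=np.full(n, 0.4),
        excluded=excluded,
        cutoff=cutoff,
    )


def write_fixture(bundle: ToyBundle, out_dir, traj_format: str = "XTC"):
    """Write a complete fixture: topology (PDB + GRO), trajectory, ground
    truth JSON, nonbonded parameter TSV and a config echo."""
    from .core import write_structure, write_trajectory
    from .energetics import write_params_tsv

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_structure(bundle.structure, out / "system.pdb")
    write_structure(bundle.structure, out / "system.gro")
    traj_name = "traj.xtc" if traj_format.upper() == "XTC" else "traj.pdb"
    write_trajectory(bundle.trajectory, out / traj_name,
                     format=traj_format.upper())
    bundle.ground_truth.to_json(out / "ground_truth.json")
    write_params_tsv(out / "nb_params.tsv", bundle.structure,
                     default_params(bundle.structure))
    echo = {
        "system": dataclasses.asdict(bundle.spec),
        "dynamics": bundle.ground_truth._plain()["dynamics"],
        "selections": dict(SELECTIONS),
        "trajectory": {"file": traj_name, "dt_ns": bundle.dynamics.dt,
                       "n_frames": bundle.dynamics.n_frames},
    }
    (out / "config.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    return out
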