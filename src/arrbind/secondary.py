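"""Backbone dihedrals and dihedral-window helix assignment.

Helicity is assigned from (phi, psi) windows rather than hydrogen-bond
patterns: a residue is helical when its backbone dihedrals fall inside an
alpha-helical Ramachandran window (phi in [-100, -30] deg, psi in [-80, -5]
deg by default) *and* it belongs to a consecutive run of at least
``min_run`` (default 4) such residues.  This purely geometric criterion
applies equally to experimental structures and to toy backbones that carry
no carbonyl hydrogen-bond geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnalysisWindows, Structure, Trajectory

__all__ = [
    "DihedralSeries",
    "dihedral_angle",
    "backbone_dihedrals",
    "assign_helix",
    "helicity_timeseries",
    "build_backbone",
    "HELIX_PHI_PSI",
]

#: Ideal alpha-helix backbone dihedrals (degrees).
HELIX_PHI_PSI = (-57.0, -47.0)

# ideal backbone internal coordinates (nm / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 0.1458, 0.1525, 0.1329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, wrapped to (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang != -180.0 else 180.0)


@dataclass
class DihedralSeries:
    """Per-residue phi/psi angles per frame; NaN marks undefined termini."""

    residue_keys: list[tuple[str, int]]
    phi: np.ndarray                # (F, R) degrees
    psi: np.ndarray                # (F, R)
    times: np.ndarray | None = None


def _backbone_index(structure: Structure, chain: str | None,
                    resids: list[int]):
    """Map resid -> {atom_name: index} for backbone atoms N, CA, C."""
    table: dict[int, dict[str, int]] = {r: {} for r in resids}
    wanted = set(resids)
    for i in range(structure.n_atoms):
        if chain is not None and str(structure.chain_ids[i]) != chain:
            continue
        r = int(structure.resids[i])
        if r in wanted and str(structure.names[i]) in ("N", "CA", "C"):
            table[r].setdefault(str(structure.names[i]), i)
    return table


def backbone_dihedrals(structure: Structure, resids: list[int],
                       chain: str | None = None,
                       frame_coords: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """phi/psi (degrees) for the listed residues in one frame.

    phi(i) uses C(i-1)-N(i)-CA(i)-C(i); psi(i) uses N(i)-CA(i)-C(i)-N(i+1).
    Angles whose atoms are missing (chain termini, gaps) are NaN.
    """
    coords = structure.coords if frame_coords is None else frame_coords
    needed = sorted({r + d for r in resids for d in (-1, 0, 1)})
    table = _backbone_index(structure, chain, needed)
    phi = np.full(len(resids), np.nan)
    psi = np.full(len(resids), np.nan)
    for j, r in enumerate(resids):
        this = table.get(r, {})
        prev = table.get(r - 1, {})
        nxt = table.get(r + 1, {})
        if all(k in this for k in ("N", "CA", "C")):
            if "C" in prev:
                phi[j] = dihedral_angle(coords[prev["C"]], coords[this["N"]],
                                        coords[this["CA"]], coords[this["C"]])
            if "N" in nxt:
                psi[j] = dihedral_angle(coords[this["N"]], coords[this["CA"]],
                                        coords[this["C"]], coords[nxt["N"]])
    return phi, psi


def trajectory_dihedrals(traj: Trajectory, resids: list[int],
                         chain: str | None = None) -> DihedralSeries:
    phis, psis = [], []
    for f in range(traj.n_frames):
        phi, psi = backbone_dihedrals(traj.topology, resids, chain,
                                      traj.coords[f])
        phis.append(phi)
        psis.append(psi)
    keys = [(chain or "", r) for r in resids]
    return DihedralSeries(keys, np.asarray(phis), np.asarray(psis),
                          traj.times)


def assign_helix(phi: np.ndarray, psi: np.ndarray,
                 phi_window: tuple[float, float] = (-100.0, -30.0),
                 psi_window: tuple[float, float] = (-80.0, -5.0),
                 min_run: int = 4) -> np.ndarray:
    """Boolean helicity per residue (and per frame for 2D input).

    A residue counts as helical when (phi, psi) fall inside the windows and
    it sits in a consecutive run of at least ``min_run`` such residues.
    Residues with undefined dihedrals never count.
    """
    if phi_window[0] > phi_window[1] or psi_window[0] > psi_window[1]:
        raise ValueError("malformed phi/psi windows")
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    single = phi.ndim == 1
    if single:
        phi, psi = phi[None, :], psi[None, :]
    with np.errstate(invalid="ignore"):
        inside = ((phi >= phi_window[0]) & (phi <= phi_window[1])
                  & (psi >= psi_window[0]) & (psi <= psi_window[1]))
    inside &= ~np.isnan(phi) & ~np.isnan(psi)
    out = np.zeros_like(inside)
    for f in range(inside.shape[0]):
        row = inside[f]
        start = 0
        for j in range(len(row) + 1):
            if j == len(row) or not row[j]:
                if j - start >= min_run:
                    out[f, start:j] = True
                start = j + 1
    return out[0] if single else out


@dataclass
class HelicityResult:
    times: np.ndarray
    counts: np.ndarray             # helical residues per frame
    window_means: np.ndarray
    mean: float
    sem: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame_time": self.times,
                             "n_helical": self.counts})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def helicity_timeseries(traj: Trajectory, resids: list[int],
                        windows: AnalysisWindows, chain: str | None = None,
                        phi_window=(-100.0, -30.0), psi_window=(-80.0, -5.0),
                        min_run: int = 4) -> HelicityResult:
    """Helical-residue count of a segment (e.g. ICL2) per frame and window."""
    if windows.n_windows == 0:
        raise ValueError("no analysis windows")
    frame_sets = windows.frame_indices(traj.times)
    for (a, b), idx in zip(windows.windows, frame_sets):
        if idx.size == 0:
            raise ValueError(f"analysis window ({a}, {b}) ns contains no frames")
    all_frames = np.concatenate(frame_sets)
    counts = {}
    for f in all_frames:
        phi, psi = backbone_dihedrals(traj.topology, resids, chain,
                                      traj.coords[f])
        counts[int(f)] = int(
            assign_helix(phi, psi, phi_window, psi_window, min_run).sum())
    window_means = np.asarray(
        [np.mean([counts[int(f)] for f in idx]) for idx in frame_sets])
    weights = np.asarray([len(i) for i in frame_sets], dtype=float)
    n = len(window_means)
    sem = float(np.std(window_means, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return HelicityResult(
        times=traj.times[all_frames],
        counts=np.asarray([counts[int(f)] for f in all_frames]),
        window_means=window_means,
        mean=float(np.average(window_means, weights=weights)),
        sem=sem,
    )


# ---------------------------------------------------------------------------
# ideal backbone builder (NeRF)
# ---------------------------------------------------------------------------


def _place_atom(a, b, c, bond: float, angle_deg: float,
                torsion_deg: float) -> np.ndarray:
    """Natural-extension place of atom d given a-b-c-d internal coordinates."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phis: np.ndarray, psis: np.ndarray,
                   omega: float = 180.0) -> np.ndarray:
    """Build ideal N/CA/C backbone coordinates (nm) from phi/psi sequences.

    ``phis[i]``/``psis[i]`` are the dihedrals of residue i; ``phis[0]`` and
    ``psis[-1]`` are still consumed to place the first/last atoms even though
    those torsions are undefined for a free terminus.  Returns an
    ``(3*R, 3)`` array ordered N, CA, C per residue.
    """
    phis = np.asarray(phis, dtype=float)
    psis = np.asarray(psis, dtype=float)
    if len(phis) != len(psis) or len(phis) == 0:
        raise ValueError("phi/psi sequences must be equal and non-empty")
    coords = [np.zeros(3),
              np.array([_B_N_CA, 0.0, 0.0])]
    # first C in the xy-plane at the ideal N-CA-C angle
    ang = np.radians(_A_N_CA_C)
    coords.append(coords[1] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang),
                                                  0.0]))
    for i in range(len(phis)):
        n_i, ca_i, c_i = coords[3 * i], coords[3 * i + 1], coords[3 * i + 2]
        if i == len(phis) - 1:
            break
        n_next = _place_atom(n_i, ca_i, c_i, _B_C_N, _A_CA_C_N, psis[i])
        ca_next = _place_atom(ca_i, c_i, n_next, _B_N_CA, _A_C_N_CA, omega)
        c_next = _place_atom(c_i, n_next, ca_next, _B_CA_C, _A_N_CA_C,
                             phis[i + 1])
        coords.extend([n_next, ca_next, c_next])
    return np.asarray(coords)
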