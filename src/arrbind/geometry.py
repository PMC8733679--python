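"""Binding-mode geometry of receptor-arrestin complexes.

The binding mode of arrestin on a membrane-embedded receptor is summarised by
two coordinates:

* insertion depth ``d``: the distance along the membrane normal between the
  center of mass of the receptor's transmembrane (TM) helix bundle and the
  center of mass of the four membrane-proximal beta-strands of arrestin's
  N-lobe;
* rotation ``alpha``: the signed in-plane rotation of arrestin about the
  membrane normal relative to its orientation in a reference complex
  (conventionally the rhodopsin/arrestin-1 structure).  ``alpha`` of the
  reference against itself is 0 by construction.

Sign convention: ``alpha`` is positive for rotations that appear
counterclockwise to a viewer on the cytosolic side of the membrane (the side
the arrestin occupies, i.e. the negative side of the membrane normal).

This module also provides the ionic-lock distance (Calpha R131-E268, the
classic reporter of receptor opening), engagement classification against the
d > 5.3 nm core-disengagement threshold, 2D (d, alpha) densities, the
windowed-SD dynamics metric and windowed per-residue RMSF profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import (AnalysisWindows, AtomGroup, Structure, Trajectory,
                   center_of_mass)

__all__ = [
    "MembraneFrame",
    "BindingModeReference",
    "BindingModeSeries",
    "DensityGrid2D",
    "DynamicsMetric",
    "RmsfProfile",
    "ionic_lock_distance",
    "membrane_frame",
    "insertion_depth",
    "rotation_angle",
    "classify_engagement",
    "binding_mode_series",
    "density2d",
    "dynamics_metric",
    "rmsf_profile",
    "rotate_about_normal",
    "wrap_angle",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class MembraneFrame:
    """Unit membrane normal plus the midplane offset along it (nm)."""

    normal: np.ndarray
    midplane: float
    provenance: str = "from-membrane-atoms"

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("membrane normal must be non-zero")
        self.normal = n / norm


@dataclass
class BindingModeReference:
    """A reference complex with resolved groups, against which alpha = 0."""

    structure: Structure
    fit: AtomGroup           # receptor TM Calpha used for superposition
    anchor_a: AtomGroup      # N-lobe edge of arrestin
    anchor_b: AtomGroup      # C-lobe edge of arrestin
    mframe: MembraneFrame
    descriptor: str = "reference"

    def in_plane_direction(self) -> np.ndarray:
        return _in_plane_direction(self.structure.coords, self.anchor_a,
                                   self.anchor_b, self.mframe)


@dataclass
class BindingModeSeries:
    times: np.ndarray
    d: np.ndarray                 # nm
    alpha: np.ndarray             # degrees, wrapped to (-180, 180]
    reference: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.d < 0):
            raise ValueError("insertion depth must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "d_nm": self.d,
                             "alpha_deg": self.alpha})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class DensityGrid2D:
    d_edges: np.ndarray
    alpha_edges: np.ndarray
    weights: np.ndarray           # (len(d_edges)-1, len(alpha_edges)-1)
    n_clamped: int = 0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# d_edges_nm\t" +
                     "\t".join(f"{e:g}" for e in self.d_edges) + "\n")
            fh.write("# alpha_edges_deg\t" +
                     "\t".join(f"{e:g}" for e in self.alpha_edges) + "\n")
            np.savetxt(fh, self.weights, delimiter="\t")


@dataclass
class DynamicsMetric:
    d_sd_mean: float              # nm
    d_sd_sem: float
    alpha_sd_mean: float          # degrees
    alpha_sd_sem: float
    window_length: float          # ns
    n_windows: int = 0


@dataclass
class RmsfProfile:
    residue_keys: list[tuple[str, int]]
    rmsf: np.ndarray              # (R,) nm, mean over windows
    sems: np.ndarray
    n_windows: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue_chain": [k[0] for k in self.residue_keys],
            "residue_id": [k[1] for k in self.residue_keys],
            "rmsf_nm": self.rmsf,
            "sem": self.sems,
            "n_windows": self.n_windows,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# small vector helpers
# ---------------------------------------------------------------------------


def wrap_angle(a) -> np.ndarray | float:
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    w = -(np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0)
    return float(w) if np.isscalar(a) or np.ndim(a) == 0 else w


def rotate_about_normal(coords: np.ndarray, center: np.ndarray,
                        angle_deg: float, normal) -> np.ndarray:
    """Rotate coordinates about an axis through ``center`` by ``angle_deg``.

    The sign follows the package convention for alpha: positive angles are
    counterclockwise as seen from the cytosolic (negative-normal) side,
    i.e. a right-handed rotation about ``-normal``.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * (-n))
    return rot.apply(coords - center) + center


def _project_in_plane(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - np.dot(v, normal) * normal


def _in_plane_direction(coords: np.ndarray, anchor_a: AtomGroup,
                        anchor_b: AtomGroup, mframe: MembraneFrame
                        ) -> np.ndarray:
    v = center_of_mass(anchor_b, coords) - center_of_mass(anchor_a, coords)
    p = _project_in_plane(v, mframe.normal)
    norm = np.linalg.norm(p)
    if norm < 1e-9:
        raise ValueError("anchor vector is parallel to the membrane normal; "
                         "in-plane direction is degenerate")
    return p / norm


def _superposition(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid transform mapping ``mobile`` onto ``target``."""
    cm_m = mobile.mean(axis=0)
    cm_t = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - cm_t, mobile - cm_m)
    return rot, cm_m, cm_t


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def ionic_lock_distance(structure: Structure, frame_coords=None,
                        chain: str | None = None, res_a: int = 131,
                        res_b: int = 268, atom_name: str = "CA") -> float:
    """Calpha-Calpha distance (nm) between the TM3 and TM6 lock residues.

    Defaults to R131-E268 (Ballesteros-Weinstein 3.50/6.30 of the
    beta2-adrenergic receptor).  Plain Euclidean distance: the pair is
    intramolecular, so no minimum image is applied.
    """
    coords = structure.coords if frame_coords is None else frame_coords

    def _ca(resid: int) -> np.ndarray:
        mask = (structure.resids == resid) & (structure.names == atom_name)
        if chain is not None:
            mask &= structure.chain_ids == chain
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(
                f"no {atom_name} atom for residue {resid}"
                + (f" in chain {chain}" if chain else ""))
        return coords[idx[0]]

    return float(np.linalg.norm(_ca(res_a) - _ca(res_b)))


def membrane_frame(coords: np.ndarray | None = None,
                   structure: Structure | None = None,
                   membrane: AtomGroup | None = None,
                   bundle: AtomGroup | None = None,
                   below: AtomGroup | None = None,
                   head_name: str = "P") -> MembraneFrame:
    """Determine the membrane normal and midplane.

    With membrane atoms, the normal is the box z-axis and the midplane is the
    mean z of the phosphate-like head atoms (falling back to all membrane
    atoms).  Without a membrane (experimental structures), the normal is the
    long principal axis of the TM-bundle Calpha cloud, oriented so that the
    ``below`` group (the arrestin) lies on its negative side.
    """
    if membrane is None and bundle is None:
        raise ValueError("need membrane atoms or a TM bundle")
    if membrane is not None:
        s = membrane.structure
        xyz = membrane.coords(coords)
        names = s.names[membrane.indices]
        head = xyz[np.asarray([str(n) == head_name for n in names])]
        if head.size == 0:
            head = xyz
        return MembraneFrame(np.array([0.0, 0.0, 1.0]),
                             float(head[:, 2].mean()),
                             provenance="from-membrane-atoms")
    xyz = bundle.coords(coords)
    centered = xyz - xyz.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    normal = evecs[:, np.argmax(evals)]      # long axis of the bundle
    if below is not None:
        v = center_of_mass(below, coords) - xyz.mean(axis=0)
        if np.dot(normal, v) > 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal
    frame = MembraneFrame(normal, 0.0, provenance="from-bundle-axis")
    frame.midplane = float(np.dot(xyz.mean(axis=0), frame.normal))
    return frame


def insertion_depth(frame_coords: np.ndarray | None, tm_bundle: AtomGroup,
                    nlobe_edge: AtomGroup, mframe: MembraneFrame) -> float:
    """|projection on the membrane normal of COM(TM bundle) - COM(N-lobe)|."""
    delta = (center_of_mass(tm_bundle, frame_coords)
             - center_of_mass(nlobe_edge, frame_coords))
    return float(abs(np.dot(delta, mframe.normal)))


def rotation_angle(frame_coords: np.ndarray, fit: AtomGroup,
                   anchor_a: AtomGroup, anchor_b: AtomGroup,
                   reference: BindingModeReference) -> float:
    """Arrestin rotation alpha (degrees) relative to the reference complex.

    The frame's receptor TM Calphas are superposed onto the reference
    receptor's, the transform is applied to the arrestin anchor centers, and
    alpha is the signed in-plane angle from the reference's N-lobe-to-C-lobe
    direction to the frame's, wrapped to (-180, 180].
    """
    rot, cm_m, cm_t = _superposition(fit.coords(frame_coords),
                                     reference.fit.coords())
    com_a = rot.apply(center_of_mass(anchor_a, frame_coords) - cm_m) + cm_t
    com_b = rot.apply(center_of_mass(anchor_b, frame_coords) - cm_m) + cm_t
    n = reference.mframe.normal
    p = _project_in_plane(com_b - com_a, n)
    norm = np.linalg.norm(p)
    if norm < 1e-9:
        raise ValueError("in-plane projection of the anchor vector is "
                         "degenerate")
    v_frame = p / norm
    v_ref = reference.in_plane_direction()
    # positive = counterclockwise viewed from the cytosolic (-normal) side
    sin_a = float(np.dot(-n, np.cross(v_ref, v_frame)))
    cos_a = float(np.dot(v_ref, v_frame))
    return float(wrap_angle(np.degrees(np.arctan2(sin_a, cos_a))))


def classify_engagement(series: BindingModeSeries, threshold: float = 5.3,
                        windows: AnalysisWindows | None = None):
    """Label frames core-engaged/core-disengaged at the d > threshold rule.

    Returns ``(labels, disengaged_fraction, per_window_fractions)``; the
    per-window fractions are None when no windows are given.
    """
    if len(series.d) == 0:
        raise ValueError("empty binding-mode series")
    disengaged = series.d > threshold
    labels = np.where(disengaged, "core-disengaged", "core-engaged")
    per_window = None
    if windows is not None:
        per_window = np.asarray([
            disengaged[idx].mean() if idx.size else np.nan
            for idx in windows.frame_indices(series.times)
        ])
    return labels, float(disengaged.mean()), per_window


def binding_mode_series(traj: Trajectory, tm_bundle: AtomGroup,
                        nlobe_edge: AtomGroup, fit: AtomGroup,
                        anchor_a: AtomGroup, anchor_b: AtomGroup,
                        reference: BindingModeReference,
                        windows: AnalysisWindows,
                        mframe: MembraneFrame | None = None
                        ) -> BindingModeSeries:
    """Evaluate d(t) and alpha(t) over the frames inside the analysis windows.

    ``mframe`` is the membrane frame of the *trajectory* system (defaults to
    a z-normal membrane, the convention of the toy builder); the reference
    carries its own frame.
    """
    if windows.n_windows == 0:
        raise ValueError("no analysis windows")
    frame_sets = windows.frame_indices(traj.times)
    for (a, b), idx in zip(windows.windows, frame_sets):
        if idx.size == 0:
            raise ValueError(f"analysis window ({a}, {b}) ns contains no frames")
    mf = mframe or MembraneFrame(np.array([0.0, 0.0, 1.0]), 0.0)
    frames = np.concatenate(frame_sets)
    d = np.empty(len(frames))
    alpha = np.empty(len(frames))
    for row, f in enumerate(frames):
        xyz = traj.coords[f]
        d[row] = insertion_depth(xyz, tm_bundle, nlobe_edge, mf)
        alpha[row] = rotation_angle(xyz, fit, anchor_a, anchor_b, reference)
    return BindingModeSeries(times=traj.times[frames], d=d, alpha=alpha,
                             reference=reference.descriptor)


def density2d(series: BindingModeSeries, d_edges, alpha_edges) -> DensityGrid2D:
    """Normalised 2D histogram of (d, alpha); outliers go to the edge bins."""
    d_edges = np.asarray(d_edges, dtype=float)
    alpha_edges = np.asarray(alpha_edges, dtype=float)
    for edges, what in ((d_edges, "d"), (alpha_edges, "alpha")):
        if edges.size < 2:
            raise ValueError(f"need at least 2 {what} edges")
        if np.any(np.diff(edges) <= 0):
            raise ValueError(f"{what} edges must be strictly increasing")
    d = series.d
    a = series.alpha
    outside = ((d < d_edges[0]) | (d > d_edges[-1])
               | (a < alpha_edges[0]) | (a > alpha_edges[-1]))
    n_clamped = int(outside.sum())
    if n_clamped:
        warnings.warn(f"{n_clamped} samples clamped into edge bins",
                      stacklevel=2)
    d = np.clip(d, d_edges[0], d_edges[-1])
    a = np.clip(a, alpha_edges[0], alpha_edges[-1])
    counts, _, _ = np.histogram2d(d, a, bins=[d_edges, alpha_edges])
    return DensityGrid2D(d_edges, alpha_edges, counts / counts.sum(),
                         n_clamped)


def dynamics_metric(series, windows: AnalysisWindows) -> DynamicsMetric:
    """Average per-window sample SD of d and alpha (complex 'dynamics').

    Accepts one series or a list of replica series; every complete window of
    every series contributes one SD, and the reported value is the mean of
    those SDs with its SEM.  Alpha SDs are computed on the angle series
    unwrapped within each window.
    """
    series_list = series if isinstance(series, (list, tuple)) else [series]
    d_sds, a_sds = [], []
    for s in series_list:
        for (w0, w1), idx in zip(windows.windows,
                                 windows.frame_indices(s.times)):
            if idx.size == 0:
                continue
            if idx.size < 2:
                raise ValueError(
                    f"window ({w0}, {w1}) ns has fewer than 2 frames")
            d_sds.append(np.std(s.d[idx], ddof=1))
            unwrapped = np.degrees(np.unwrap(np.radians(s.alpha[idx])))
            a_sds.append(np.std(unwrapped, ddof=1))
    if not d_sds:
        raise ValueError("no complete analysis windows in any series")
    d_sds = np.asarray(d_sds)
    a_sds = np.asarray(a_sds)
    n = len(d_sds)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    lengths = {w1 - w0 for w0, w1 in windows.windows}
    return DynamicsMetric(
        d_sd_mean=float(d_sds.mean()), d_sd_sem=sem(d_sds),
        alpha_sd_mean=float(a_sds.mean()), alpha_sd_sem=sem(a_sds),
        window_length=lengths.pop() if len(lengths) == 1 else float("nan"),
        n_windows=n,
    )


def _residue_positions(traj_coords: np.ndarray, residues: list[AtomGroup]
                       ) -> np.ndarray:
    """Representative (Calpha if present, else COM) position per residue."""
    out = np.empty((len(residues), 3))
    for i, r in enumerate(residues):
        names = r.structure.names[r.indices]
        ca = np.nonzero(names == "CA")[0]
        if ca.size:
            out[i] = traj_coords[r.indices[ca[0]]]
        else:
            out[i] = center_of_mass(r, traj_coords)
    return out


def rmsf_profile(traj, residues: list[AtomGroup], windows: AnalysisWindows,
                 fit: AtomGroup) -> RmsfProfile:
    """Windowed per-residue RMSF (nm) after superposition on the fit group.

    Within each window every frame is least-squares superposed (via the fit
    group, typically the receptor-core Calphas) onto the window-mean
    structure, and RMSF_i is the root-mean-square displacement of residue
    i's Calpha from its window-mean position.  Pass a list of trajectories to
    pool replicas: each replica contributes its windows.
    """
    trajs = traj if isinstance(traj, (list, tuple)) else [traj]
    window_rmsfs = []
    for t in trajs:
        for (w0, w1), idx in zip(windows.windows,
                                 windows.frame_indices(t.times)):
            if idx.size == 0:
                continue
            fitted = _superpose_window(t, idx, fit)
            positions = np.asarray(
                [_residue_positions(xyz, residues) for xyz in fitted])
            mean_pos = positions.mean(axis=0)
            sq = np.square(positions - mean_pos).sum(axis=-1)
            window_rmsfs.append(np.sqrt(sq.mean(axis=0)))
    if not window_rmsfs:
        raise ValueError("no frames inside the analysis windows")
    window_rmsfs = np.asarray(window_rmsfs)
    n = len(window_rmsfs)
    sems = (np.std(window_rmsfs, axis=0, ddof=1) / np.sqrt(n) if n > 1
            else np.zeros(window_rmsfs.shape[1]))
    return RmsfProfile(
        residue_keys=[r.residue_keys()[0] for r in residues],
        rmsf=window_rmsfs.mean(axis=0), sems=sems, n_windows=n,
    )


def _superpose_window(traj, idx: np.ndarray, fit: AtomGroup) -> np.ndarray:
    """Superpose window frames onto the window-mean structure (two passes)."""
    fit_idx = np.asarray(fit.indices, dtype=int)
    coords = traj.coords[idx].copy()
    reference = coords[0, fit_idx]
    for _pass in range(2):
        for k in range(len(coords)):
            rot, cm_m, cm_t = _superposition(coords[k, fit_idx], reference)
            coords[k] = rot.apply(coords[k] - cm_m) + cm_t
        reference = coords[:, fit_idx].mean(axis=0)
    return coords
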