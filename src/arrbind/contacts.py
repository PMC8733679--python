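"""Contact- and occupancy-based observables.

All observables here reduce to minimum-image distances between atom groups:

* per-residue membrane-contact probability profiles (a residue is "in
  contact" when any of its atoms lies closer than a cutoff, 0.5 nm by
  default, to any membrane atom -- close enough for direct interactions or
  ones bridged by a single water);
* anchoring fractions of loops (e.g. the arrestin C-edge loops that stay
  membrane-attached >90% of the time);
* counts of distinct lipid molecules bound at a site (e.g. DOPG at the basic
  patch of arrestin's C-lobe);
* residue-pair contact matrices between two partners;
* salt-bridge occupancy between charged side-chain atoms.

Averages are taken over analysis windows; the standard error of the mean is
computed over per-window means, and windows from several replicas may simply
be concatenated to pool them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnalysisWindows, AtomGroup, Trajectory, distance_array

__all__ = [
    "ContactProfile",
    "OccupancySeries",
    "PairContactMatrix",
    "min_distance_residue_to_group",
    "contact_probability_profile",
    "anchoring_fraction",
    "count_bound_lipids",
    "bound_lipid_series",
    "pair_contact_matrix",
    "salt_bridge_occupancy",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class ContactProfile:
    residue_keys: list[tuple[str, int]]
    residue_names: list[str]
    probabilities: np.ndarray        # (R,) in [0, 1], pooled over all frames
    sems: np.ndarray                 # (R,) SEM over per-window means
    n_windows: int
    window_means: np.ndarray | None = None   # (W, R)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue_chain": [k[0] for k in self.residue_keys],
            "residue_id": [k[1] for k in self.residue_keys],
            "residue_name": self.residue_names,
            "probability": self.probabilities,
            "sem": self.sems,
            "n_windows": self.n_windows,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class OccupancySeries:
    times: np.ndarray                # (F,) ns, analysed frames only
    values: np.ndarray               # (F,) bool or int
    window_means: np.ndarray         # (W,)
    pooled: float                    # frame-weighted mean over all windows
    label: str = ""

    @property
    def sem(self) -> float:
        w = self.window_means
        if len(w) < 2:
            return 0.0
        return float(np.std(w, ddof=1) / np.sqrt(len(w)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame_time": self.times, "value": self.values})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class PairContactMatrix:
    keys_a: list[tuple[str, int]]
    keys_b: list[tuple[str, int]]
    probabilities: np.ndarray        # (Ra, Rb) in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probabilities,
            index=[f"{c}:{r}" for c, r in self.keys_a],
            columns=[f"{c}:{r}" for c, r in self.keys_b],
        )


# ---------------------------------------------------------------------------
# frame-level primitives
# ---------------------------------------------------------------------------


def min_distance_residue_to_group(frame_coords: np.ndarray,
                                  residue: AtomGroup, target: AtomGroup,
                                  box=None) -> float:
    """Minimum over all atom pairs of the minimum-image distance (nm)."""
    if len(residue) == 0 or len(target) == 0:
        raise ValueError("minimum distance requires two non-empty groups")
    d = distance_array(residue.coords(frame_coords),
                       target.coords(frame_coords), box)
    return float(d.min())


def _block_min_distances(frame_coords: np.ndarray,
                         blocks: list[np.ndarray], target_idx: np.ndarray,
                         box) -> np.ndarray:
    """Per-block minimum distance to a target group, vectorised over blocks."""
    cat = np.concatenate(blocks)
    d = distance_array(frame_coords[cat], frame_coords[target_idx], box)
    per_atom = d.min(axis=1)
    starts = np.cumsum([0] + [len(b) for b in blocks[:-1]])
    return np.minimum.reduceat(per_atom, starts)


def _analysis_frames(traj: Trajectory, windows: AnalysisWindows
                     ) -> list[np.ndarray]:
    if windows.n_windows == 0:
        raise ValueError("no analysis windows")
    per_window = windows.frame_indices(traj.times)
    for (a, b), idx in zip(windows.windows, per_window):
        if idx.size == 0:
            raise ValueError(f"analysis window ({a}, {b}) ns contains no frames")
    return per_window


def _pooled(window_means: np.ndarray, window_frames: list[np.ndarray]):
    weights = np.asarray([len(i) for i in window_frames], dtype=float)
    pooled = float(np.average(window_means, weights=weights, axis=0)) \
        if window_means.ndim == 1 else \
        np.average(window_means, weights=weights, axis=0)
    return pooled


def _sem(window_means: np.ndarray) -> np.ndarray:
    n = window_means.shape[0]
    if n < 2:
        return np.zeros(window_means.shape[1:])
    return np.std(window_means, axis=0, ddof=1) / np.sqrt(n)


# ---------------------------------------------------------------------------
# trajectory-level observables
# ---------------------------------------------------------------------------


def contact_probability_profile(traj: Trajectory,
                                residues: list[AtomGroup],
                                target: AtomGroup,
                                windows: AnalysisWindows,
                                cutoff: float = 0.5) -> ContactProfile:
    """Per-residue probability of lying closer than ``cutoff`` to a target.

    The probability is the fraction of analysed simulation time in which the
    residue's minimum distance to the target group is below the cutoff; the
    SEM is taken over per-window means.  To pool replicas, concatenate their
    windows (each replica's windows must then be disjoint in time).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not residues:
        raise ValueError("no residues given")
    s = traj.topology
    blocks = [np.asarray(r.indices, dtype=int) for r in residues]
    for i, b in enumerate(blocks):
        if b.size == 0:
            raise ValueError(f"residue group {i} is empty")
    target_idx = np.asarray(target.indices, dtype=int)
    if target_idx.size == 0:
        raise ValueError("target group is empty")
    per_window_frames = _analysis_frames(traj, windows)
    window_means = []
    for idx in per_window_frames:
        hits = np.zeros((len(idx), len(blocks)), dtype=bool)
        for row, f in enumerate(idx):
            dmin = _block_min_distances(traj.coords[f], blocks, target_idx,
                                        traj.box_at(f))
            hits[row] = dmin < cutoff
        window_means.append(hits.mean(axis=0))
    window_means = np.asarray(window_means)
    keys, names = [], []
    for r in residues:
        ks = r.residue_keys()
        keys.append(ks[0])
        names.append(str(s.resnames[r.indices[0]]))
    return ContactProfile(
        residue_keys=keys, residue_names=names,
        probabilities=np.asarray(_pooled(window_means, per_window_frames)),
        sems=_sem(window_means),
        n_windows=windows.n_windows,
        window_means=window_means,
    )


def anchoring_fraction(traj: Trajectory, loop: AtomGroup, membrane: AtomGroup,
                       windows: AnalysisWindows,
                       cutoff: float = 0.5) -> OccupancySeries:
    """Fraction of time any loop atom lies within ``cutoff`` of the membrane."""
    per_window_frames = _analysis_frames(traj, windows)
    loop_idx = np.asarray(loop.indices, dtype=int)
    mem_idx = np.asarray(membrane.indices, dtype=int)
    if loop_idx.size == 0 or mem_idx.size == 0:
        raise ValueError("loop and membrane groups must be non-empty")
    all_frames = np.concatenate(per_window_frames)
    attached = {}
    for f in all_frames:
        d = distance_array(traj.coords[f][loop_idx], traj.coords[f][mem_idx],
                           traj.box_at(f))
        attached[int(f)] = bool(d.min() < cutoff)
    window_means = np.asarray(
        [np.mean([attached[int(f)] for f in idx]) for idx in per_window_frames]
    )
    values = np.asarray([attached[int(f)] for f in all_frames])
    return OccupancySeries(
        times=traj.times[all_frames], values=values,
        window_means=window_means,
        pooled=float(_pooled(window_means, per_window_frames)),
        label=f"anchoring:{loop.label}",
    )


def count_bound_lipids(frame_coords: np.ndarray, site: AtomGroup,
                       lipids: list[AtomGroup], cutoff: float = 0.5,
                       box=None) -> int:
    """Number of distinct lipid molecules with any atom within ``cutoff``
    of any site atom."""
    if len(site) == 0:
        raise ValueError("site group is empty")
    seen: set[int] = set()
    for g in lipids:
        for i in g.indices:
            ii = int(i)
            if ii in seen:
                raise ValueError("lipid groups overlap; molecules must be "
                                 "partitioned disjointly")
            seen.add(ii)
    site_xyz = site.coords(frame_coords)
    count = 0
    for g in lipids:
        d = distance_array(site_xyz, g.coords(frame_coords), box)
        if d.min() < cutoff:
            count += 1
    return count


def bound_lipid_series(traj: Trajectory, site: AtomGroup,
                       lipids: list[AtomGroup], windows: AnalysisWindows,
                       cutoff: float = 0.5) -> OccupancySeries:
    """Time series and window means of the bound-lipid count at a site."""
    per_window_frames = _analysis_frames(traj, windows)
    all_frames = np.concatenate(per_window_frames)
    counts = {
        int(f): count_bound_lipids(traj.coords[f], site, lipids, cutoff,
                                   traj.box_at(f))
        for f in all_frames
    }
    window_means = np.asarray(
        [np.mean([counts[int(f)] for f in idx]) for idx in per_window_frames]
    )
    return OccupancySeries(
        times=traj.times[all_frames],
        values=np.asarray([counts[int(f)] for f in all_frames]),
        window_means=window_means,
        pooled=float(_pooled(window_means, per_window_frames)),
        label=f"bound-lipids:{site.label}",
    )


def pair_contact_matrix(traj: Trajectory, residues_a: list[AtomGroup],
                        residues_b: list[AtomGroup],
                        windows: AnalysisWindows,
                        cutoff: float = 0.5) -> PairContactMatrix:
    """Residue-pair contact probabilities between two partners."""
    per_window_frames = _analysis_frames(traj, windows)
    blocks_a = [np.asarray(r.indices, dtype=int) for r in residues_a]
    blocks_b = [np.asarray(r.indices, dtype=int) for r in residues_b]
    cat_a, cat_b = np.concatenate(blocks_a), np.concatenate(blocks_b)
    starts_a = np.cumsum([0] + [len(b) for b in blocks_a[:-1]])
    starts_b = np.cumsum([0] + [len(b) for b in blocks_b[:-1]])
    window_means = []
    for idx in per_window_frames:
        acc = np.zeros((len(blocks_a), len(blocks_b)))
        for f in idx:
            d = distance_array(traj.coords[f][cat_a], traj.coords[f][cat_b],
                               traj.box_at(f))
            d = np.minimum.reduceat(d, starts_a, axis=0)
            d = np.minimum.reduceat(d, starts_b, axis=1)
            acc += d < cutoff
        window_means.append(acc / len(idx))
    window_means = np.asarray(window_means)
    weights = np.asarray([len(i) for i in per_window_frames], dtype=float)
    probs = np.average(window_means, weights=weights, axis=0)
    return PairContactMatrix(
        keys_a=[r.residue_keys()[0] for r in residues_a],
        keys_b=[r.residue_keys()[0] for r in residues_b],
        probabilities=probs,
    )


def salt_bridge_occupancy(traj: Trajectory, acidic: AtomGroup,
                          basic: AtomGroup, windows: AnalysisWindows,
                          cutoff: float = 0.4) -> OccupancySeries:
    """Occupancy of a salt bridge between charged heavy atoms.

    ``acidic`` should be restricted to the side-chain carboxylate/phosphate
    oxygens and ``basic`` to the side-chain nitrogen atoms; the bridge is
    formed in a frame when the closest charged-atom pair lies below the
    cutoff (0.4 nm by default).
    """
    per_window_frames = _analysis_frames(traj, windows)
    all_frames = np.concatenate(per_window_frames)
    formed = {}
    for f in all_frames:
        d = distance_array(acidic.coords(traj.coords[f]),
                           basic.coords(traj.coords[f]), traj.box_at(f))
        formed[int(f)] = bool(d.min() < cutoff)
    window_means = np.asarray(
        [np.mean([formed[int(f)] for f in idx]) for idx in per_window_frames]
    )
    return OccupancySeries(
        times=traj.times[all_frames],
        values=np.asarray([formed[int(f)] for f in all_frames]),
        window_means=window_means,
        pooled=float(_pooled(window_means, per_window_frames)),
        label=f"salt-bridge:{acidic.label}|{basic.label}",
    )
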