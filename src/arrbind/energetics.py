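"""Pairwise group-group nonbonded energetics (Coulomb + Lennard-Jones).

Energies are a short-range, plainly truncated sum over inter-group atom
pairs within a cutoff (1.2 nm default), with minimum-image distances:

    E = sum_ij [ f q_i q_j / (eps_r r_ij)
                 + 4 eps_ij ((sig_ij/r_ij)^12 - (sig_ij/r_ij)^6) ]

with f = 138.935458 kJ mol^-1 nm e^-2.  No Ewald/PME, switching or shifting
is applied: these energies are a defined approximation intended for
comparing scenarios (e.g. ICL3-membrane attachment across phosphorylation
states), not for reproducing force-field absolute values.

The exclusion set implements the convention of omitting the phosphate groups
of phosphorylated Ser/Thr side chains, so that phosphorylated and
non-phosphorylated receptors give comparable ICL3-membrane energies; an
excluded atom contributes to no pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnalysisWindows, AtomGroup, Structure, Trajectory, _min_image_sq

__all__ = [
    "COULOMB_CONSTANT",
    "NonbondedParams",
    "EnergyBreakdown",
    "pair_energy",
    "pair_force",
    "windowed_group_energy",
    "load_params_tsv",
    "write_params_tsv",
]

#: Electric conversion factor in MD units, kJ mol^-1 nm e^-2.
COULOMB_CONSTANT = 138.935458

# default atom names of a phospho-Ser/Thr phosphate group (P + bonded O)
PHOSPHATE_ATOM_NAMES = ("P", "O1P", "O2P", "O3P", "OP1", "OP2", "OP3", "OG",
                        "OG1")


@dataclass
class NonbondedParams:
    """Per-atom nonbonded parameters aligned with a Structure's atom table."""

    charges: np.ndarray            # (n,) e
    sigmas: np.ndarray             # (n,) nm
    epsilons: np.ndarray           # (n,) kJ/mol
    excluded: np.ndarray           # (n,) bool
    cutoff: float = 1.2            # nm
    permittivity: float = 1.0
    combination: str = "lorentz-berthelot"   # or "geometric"
    defined: np.ndarray | None = None        # (n,) bool; False = missing

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if np.any(self.sigmas < 0) or np.any(self.epsilons < 0):
            raise ValueError("sigma and epsilon must be non-negative")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.permittivity <= 0:
            raise ValueError("relative permittivity must be positive")
        if self.combination not in ("lorentz-berthelot", "geometric"):
            raise ValueError(f"unknown combination rule {self.combination!r}")
        if self.defined is None:
            self.defined = np.ones(len(self.charges), dtype=bool)


@dataclass
class EnergyBreakdown:
    coulomb: float                 # kJ/mol
    lj: float                      # kJ/mol
    n_pairs: int                   # pairs within cutoff

    @property
    def total(self) -> float:
        return self.coulomb + self.lj


def _check_groups(structure: Structure, group_a: AtomGroup,
                  group_b: AtomGroup, params: NonbondedParams) -> None:
    if np.intersect1d(group_a.indices, group_b.indices).size:
        raise ValueError("groups must be disjoint for pair energetics")
    for g in (group_a, group_b):
        active = g.indices[~params.excluded[g.indices]]
        missing = active[~params.defined[active]]
        if missing.size:
            raise ValueError(
                "missing nonbonded parameters for atom "
                f"{structure.atom_label(int(missing[0]))}")


def _pair_terms(frame_coords: np.ndarray, group_a: AtomGroup,
                group_b: AtomGroup, params: NonbondedParams, box):
    """Within-cutoff pair geometry and combined parameters."""
    ia = group_a.indices[~params.excluded[group_a.indices]]
    ib = group_b.indices[~params.excluded[group_b.indices]]
    if ia.size == 0 or ib.size == 0:
        z = np.zeros(0)
        return ia, ib, np.zeros((0, 2), dtype=int), np.zeros((0, 3)), z, z, z, z
    delta = frame_coords[ib][None, :, :] - frame_coords[ia][:, None, :]
    if box is None:
        d2 = np.square(delta).sum(axis=-1)
        dvec = delta
    else:
        d2 = _min_image_sq(delta, box)
        # reconstruct the minimum-image displacement for forces
        from .core import distance_array  # noqa: F401  (doc pointer)
        box_arr = np.asarray(box, dtype=float).reshape(3, 3)
        frac = delta @ np.linalg.inv(box_arr)
        frac -= np.round(frac)
        dvec = frac @ box_arr
        if np.any(box_arr[~np.eye(3, dtype=bool)]):
            # triclinic: pick the best of the 27 images explicitly
            best = np.full(d2.shape, np.inf)
            best_vec = dvec.copy()
            for i in (-1.0, 0.0, 1.0):
                for j in (-1.0, 0.0, 1.0):
                    for k in (-1.0, 0.0, 1.0):
                        shift = (i * box_arr[0] + j * box_arr[1]
                                 + k * box_arr[2])
                        cand = dvec + shift
                        c2 = np.square(cand).sum(axis=-1)
                        better = c2 < best
                        best = np.where(better, c2, best)
                        best_vec = np.where(better[..., None], cand, best_vec)
            dvec, d2 = best_vec, best
    within = d2 < params.cutoff ** 2
    pa, pb = np.nonzero(within)
    r = np.sqrt(d2[pa, pb])
    vec = dvec[pa, pb]
    qq = params.charges[ia[pa]] * params.charges[ib[pb]]
    if params.combination == "lorentz-berthelot":
        sig = 0.5 * (params.sigmas[ia[pa]] + params.sigmas[ib[pb]])
    else:
        sig = np.sqrt(params.sigmas[ia[pa]] * params.sigmas[ib[pb]])
    eps = np.sqrt(params.epsilons[ia[pa]] * params.epsilons[ib[pb]])
    pairs = np.stack([ia[pa], ib[pb]], axis=1)
    return ia, ib, pairs, vec, r, qq, sig, eps


def pair_energy(frame_coords: np.ndarray, group_a: AtomGroup,
                group_b: AtomGroup, params: NonbondedParams,
                box=None) -> EnergyBreakdown:
    """Truncated Coulomb + Lennard-Jones energy between two groups (kJ/mol)."""
    s = group_a.structure
    _check_groups(s, group_a, group_b, params)
    _, _, pairs, _, r, qq, sig, eps = _pair_terms(
        frame_coords, group_a, group_b, params, box)
    if r.size == 0:
        return EnergyBreakdown(0.0, 0.0, 0)
    coulomb = COULOMB_CONSTANT * qq / (params.permittivity * r)
    with np.errstate(divide="ignore"):
        sr6 = np.where(eps > 0, (sig / r) ** 6, 0.0)
    lj = 4.0 * eps * (sr6 ** 2 - sr6)
    return EnergyBreakdown(float(coulomb.sum()), float(lj.sum()), int(r.size))


def pair_force(frame_coords: np.ndarray, group_a: AtomGroup,
               group_b: AtomGroup, params: NonbondedParams, box=None):
    """Net force on group A from group B (kJ/mol/nm), plus per-residue-pair
    force magnitudes.

    The force is the exact negative gradient of :func:`pair_energy`;
    Newton's third law holds between the groups (the net force on B is the
    negative of the returned vector).
    """
    s = group_a.structure
    _check_groups(s, group_a, group_b, params)
    _, _, pairs, vec, r, qq, sig, eps = _pair_terms(
        frame_coords, group_a, group_b, params, box)
    if r.size == 0:
        return np.zeros(3), {}
    # dU/dr for each pair; vec points from a-atom to b-atom
    dcoul = -COULOMB_CONSTANT * qq / (params.permittivity * r ** 2)
    with np.errstate(divide="ignore"):
        sr6 = np.where(eps > 0, (sig / r) ** 6, 0.0)
    dlj = 4.0 * eps * (-12.0 * sr6 ** 2 + 6.0 * sr6) / r
    dudr = dcoul + dlj
    # force on the a-atom of each pair: -dU/dr * d r/d x_a = +dU/dr * vec/r
    f_pairs = (dudr / r)[:, None] * vec
    net = f_pairs.sum(axis=0)
    by_respair: dict[tuple, np.ndarray] = {}
    for (a_idx, b_idx), f in zip(pairs, f_pairs):
        key = (
            (str(s.chain_ids[a_idx]), int(s.resids[a_idx])),
            (str(s.chain_ids[b_idx]), int(s.resids[b_idx])),
        )
        by_respair[key] = by_respair.get(key, np.zeros(3)) + f
    magnitudes = {k: float(np.linalg.norm(v)) for k, v in by_respair.items()}
    return net, magnitudes


def windowed_group_energy(traj: Trajectory, group_a: AtomGroup,
                          group_b: AtomGroup, params: NonbondedParams,
                          window_length: float = 100.0,
                          burn_in: float = 0.0) -> pd.DataFrame:
    """Window-mean interaction energies along a trajectory.

    Returns one row per complete window after the burn-in with the signed
    Coulomb/LJ/total means and the mean absolute total (the quantity plotted
    against the ionic-lock distance in the source analysis).
    """
    from .core import make_windows
    windows = make_windows(traj, length=window_length, burn_in=burn_in)
    rows = []
    for (w0, w1), idx in zip(windows.windows,
                             windows.frame_indices(traj.times)):
        if idx.size == 0:
            continue
        e = [pair_energy(traj.coords[f], group_a, group_b, params,
                         traj.box_at(f)) for f in idx]
        totals = np.asarray([x.total for x in e])
        rows.append({
            "window_start_ns": w0, "window_end_ns": w1,
            "coulomb": float(np.mean([x.coulomb for x in e])),
            "lj": float(np.mean([x.lj for x in e])),
            "total": float(totals.mean()),
            "abs_total": float(np.abs(totals).mean()),
            "n_frames": int(idx.size),
        })
    if not rows:
        warnings.warn("no complete energy windows after burn-in", stacklevel=2)
    return pd.DataFrame(rows, columns=["window_start_ns", "window_end_ns",
                                       "coulomb", "lj", "total", "abs_total",
                                       "n_frames"])


# ---------------------------------------------------------------------------
# flat parameter table I/O
# ---------------------------------------------------------------------------


def load_params_tsv(path, structure: Structure, cutoff: float = 1.2,
                    permittivity: float = 1.0,
                    combination: str = "lorentz-berthelot") -> NonbondedParams:
    """Read per-atom parameters from a flat TSV keyed on (chain, resid, name).

    Columns: chain, resid, atom_name, charge_e, sigma_nm, epsilon_kjmol,
    excluded.  Atoms absent from the table are marked undefined and trigger
    an error only if an energy calculation actually touches them.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chain": str})
    lookup = {
        (str(row.chain), int(row.resid), str(row.atom_name)):
            (row.charge_e, row.sigma_nm, row.epsilon_kjmol, bool(row.excluded))
        for row in table.itertuples()
    }
    n = structure.n_atoms
    charges = np.zeros(n)
    sigmas = np.zeros(n)
    epsilons = np.zeros(n)
    excluded = np.zeros(n, dtype=bool)
    defined = np.zeros(n, dtype=bool)
    for i in range(n):
        key = (str(structure.chain_ids[i]), int(structure.resids[i]),
               str(structure.names[i]))
        if key in lookup:
            charges[i], sigmas[i], epsilons[i], excluded[i] = lookup[key]
            defined[i] = True
    return NonbondedParams(charges, sigmas, epsilons, excluded,
                           cutoff=cutoff, permittivity=permittivity,
                           combination=combination, defined=defined)


def write_params_tsv(path, structure: Structure,
                     params: NonbondedParams) -> None:
    pd.DataFrame({
        "chain": structure.chain_ids,
        "resid": structure.resids,
        "atom_name": structure.names,
        "charge_e": params.charges,
        "sigma_nm": params.sigmas,
        "epsilon_kjmol": params.epsilons,
        "excluded": params.excluded.astype(int),
    }).to_csv(path, sep="\t", index=False)
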