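"""Per-residue flexibility (RMSF) from trajectory frames.

RMSF_i = sqrt( < | r_i(t) - <r_i> |^2 >_t ) after rigid-body superposition of
every analysed frame onto the first analysed frame, so that global
rotation/translation of the molecule does not inflate the apparent internal
fluctuation.  Per-residue values average the atom RMSF over a reporting
selection (backbone by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Structure, Trajectory, select, superpose_frames


@dataclass
class RMSFProfile:
    """Per-residue fluctuation amplitude for one chain (or chain set)."""

    keys: list[tuple[str, int, str]]  # (chain_id, residue number, icode)
    res_names3: list[str]
    rmsf: np.ndarray  # Angstrom, one per key
    fit_selection: str
    report_selection: str
    n_frames_used: int

    def for_chain(self, chain_id: str) -> "RMSFProfile":
        idx = [i for i, k in enumerate(self.keys) if k[0] == chain_id]
        return RMSFProfile(
            keys=[self.keys[i] for i in idx],
            res_names3=[self.res_names3[i] for i in idx],
            rmsf=self.rmsf[idx],
            fit_selection=self.fit_selection,
            report_selection=self.report_selection,
            n_frames_used=self.n_frames_used,
        )


def _fitted_frames(traj: Trajectory, fit: str) -> np.ndarray:
    frames = traj.analysis_frames
    if frames.shape[0] < 2:
        raise ValueError("need >= 2 post-trim frames")
    fit_idx = select(traj.topology, fit)
    if len(fit_idx) < 3:
        raise ValueError(f"fit selection {fit!r} resolves to < 3 atoms")
    return superpose_frames(frames, fit_idx, frames[0])


def mean_structure(traj: Trajectory, fit: str = "backbone") -> np.ndarray:
    """Coordinate-wise mean conformation after superposition on ``fit``."""
    return _fitted_frames(traj, fit).mean(axis=0)


def rmsf_profile(
    traj: Trajectory,
    fit: str = "backbone",
    report: str = "backbone",
    per_chain_fit: bool = False,
) -> RMSFProfile:
    """Per-residue RMSF over the analysed frames.

    ``per_chain_fit`` fits each chain onto its own first-frame conformation
    instead of fitting the whole assembly at once; for an oligomer this
    removes inter-subunit motion from the profile.
    """
    topo = traj.topology
    report_idx = select(topo, report)
    if len(report_idx) == 0:
        raise ValueError(f"empty report selection {report!r}")

    if per_chain_fit:
        fitted = np.array(traj.analysis_frames, dtype=float)
        for cid in topo.chain_ids:
            chain_fit = f"chain {cid} and {fit}" if fit != "all" else f"chain {cid}"
            fit_idx = select(topo, chain_fit)
            if len(fit_idx) < 3:
                raise ValueError(f"fit selection for chain {cid} has < 3 atoms")
            chain_atoms = np.flatnonzero(topo.chain_id == cid)
            sub = superpose_frames(
                fitted[:, chain_atoms, :],
                np.searchsorted(chain_atoms, fit_idx),
                fitted[0, chain_atoms, :],
            )
            fitted[:, chain_atoms, :] = sub
    else:
        fitted = _fitted_frames(traj, fit)

    mean = fitted.mean(axis=0)
    dev2 = ((fitted - mean[None]) ** 2).sum(axis=2)  # (T, n_atoms)
    atom_rmsf = np.sqrt(dev2.mean(axis=0))

    keys: list[tuple[str, int, str]] = []
    names: list[str] = []
    values: list[float] = []
    res_of_report = topo.residue_index[report_idx]
    for r in range(topo.n_residues):
        sel = report_idx[res_of_report == r]
        if len(sel) == 0:
            continue
        keys.append(topo.res_keys[r])
        names.append(str(topo.res_names3[r]))
        values.append(float(atom_rmsf[sel].mean()))
    return RMSFProfile(
        keys=keys,
        res_names3=names,
        rmsf=np.asarray(values),
        fit_selection=fit,
        report_selection=report,
        n_frames_used=fitted.shape[0],
    )


def mean_rmsf(profile: RMSFProfile) -> tuple[float, float]:
    """Mean +/- SD (population) of the per-residue RMSF values."""
    return float(profile.rmsf.mean()), float(profile.rmsf.std())


def structure_rmsd(
    a: Structure, b: Structure, selection: str = "backbone"
) -> float:
    """Kabsch-fit RMSD between two conformations on a common selection."""
    from .structure import kabsch_superpose

    ia = select(a, selection)
    ib = select(b, selection)
    if len(ia) != len(ib):
        raise ValueError("selections resolve to different atom counts")
    return kabsch_superpose(a.coords[ia], b.coords[ib]).rmsd
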