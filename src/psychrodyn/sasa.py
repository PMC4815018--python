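"""Solvent-accessible surface area by the Shrake-Rupley rolling-probe method.

Each heavy atom is surrounded by a quasi-uniform shell of test points (a
golden-spiral lattice) at radius ``r_vdw + probe``; a point is accessible if
it lies outside the expanded sphere of every neighbouring atom.  The
accessible fraction times the shell area gives the per-atom SASA.

"Hydrophobic" SASA is defined atom-wise as the surface contributed by carbon
and sulfur atoms, which is robust to residues of mixed polarity; a
residue-category alternative (surface of non-polar residues) is available via
``hydrophobic="residue"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure, Trajectory, select

HYDROPHOBIC_ELEMENTS = ("C", "S")


@dataclass
class SurfaceResult:
    """SASA of one conformation (Angstrom^2)."""

    per_atom_sasa: np.ndarray
    per_residue_sasa: np.ndarray
    total: float
    hydrophobic: float
    probe_radius: float
    n_sphere_points: int
    atom_indices: np.ndarray  # indices (into the parent structure) evaluated


@dataclass
class TrajectorySurfaceStats:
    """Mean +/- SD of SASA metrics over analysed trajectory frames."""

    mean_total: float
    sd_total: float
    mean_hydrophobic: float
    sd_hydrophobic: float
    hydrophobic_ratio: float
    per_chain_normalized: bool
    n_frames_used: int


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    model: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    subset: str = "heavy",
    hydrophobic: str = "atom",
) -> SurfaceResult:
    """Per-atom and per-residue SASA of one conformation.

    Parameters
    ----------
    probe : solvent probe radius, Angstrom (1.4 emulates water).
    n_points : test points per atom; accuracy grows roughly as 1/n_points.
    subset : selection expression for the atoms included in the calculation
        (default ``heavy``: crystal structures lack hydrogens, and including
        them would make MD frames incomparable with X-ray models).
    hydrophobic : "atom" sums C/S-atom surface; "residue" sums the surface
        of non-polar-category residues.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    idx = select(model, subset)
    coords = model.coords[idx]
    radii = model.radius[idx] + probe
    n = len(idx)
    per_atom = np.zeros(n)
    if n > 0:
        dup = _has_coincident(coords)
        if dup:
            warnings.warn(
                "coincident atom coordinates detected; SASA proceeds but may "
                "double-count surface",
                stacklevel=2,
            )
        unit = sphere_points(n_points)
        tree = cKDTree(coords)
        max_r = radii.max()
        for a in range(n):
            neighbours = tree.query_ball_point(coords[a], radii[a] + max_r)
            neighbours = [b for b in neighbours if b != a]
            if neighbours:
                nb = np.asarray(neighbours, dtype=int)
                # orient the lattice in a frame built from the two nearest
                # neighbours, so the sampling co-rotates with the molecule and
                # SASA is invariant under rigid motion
                pts = coords[a] + radii[a] * (unit @ _local_frame(coords, a, nb))
                d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
                buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
                frac = 1.0 - buried.mean()
            else:
                frac = 1.0
            per_atom[a] = frac * 4.0 * np.pi * radii[a] ** 2

    per_residue = np.zeros(model.n_residues)
    np.add.at(per_residue, model.residue_index[idx], per_atom)
    if hydrophobic == "atom":
        hydro_mask = np.isin(model.element[idx], HYDROPHOBIC_ELEMENTS)
    elif hydrophobic == "residue":
        hydro_mask = model.res_categories[model.residue_index[idx]] == "non-polar"
    else:
        raise ValueError("hydrophobic must be 'atom' or 'residue'")
    return SurfaceResult(
        per_atom_sasa=per_atom,
        per_residue_sasa=per_residue,
        total=float(per_atom.sum()),
        hydrophobic=float(per_atom[hydro_mask].sum()),
        probe_radius=probe,
        n_sphere_points=n_points,
        atom_indices=idx,
    )


def _local_frame(coords: np.ndarray, a: int, nb: np.ndarray) -> np.ndarray:
    """Orthonormal frame rows from the two nearest neighbours of atom ``a``.

    Falls back to the lab frame when the geometry is degenerate (single
    neighbour along an axis, collinear neighbours).
    """
    d = np.linalg.norm(coords[nb] - coords[a], axis=1)
    order = np.argsort(d, kind="stable")
    e1 = coords[nb[order[0]]] - coords[a]
    n1 = np.linalg.norm(e1)
    if n1 < 1e-8:  # coincident neighbour: no usable direction
        return np.eye(3)
    e1 = e1 / n1
    e2 = None
    for k in order[1:]:
        v = coords[nb[k]] - coords[a]
        v = v - np.dot(v, e1) * e1
        norm = np.linalg.norm(v)
        if norm > 1e-6:
            e2 = v / norm
            break
    if e2 is None:  # collinear: any perpendicular completes the frame
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, e1)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e2 = helper - np.dot(helper, e1) * e1
        e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.array([e1, e2, e3])


def _has_coincident(coords: np.ndarray) -> bool:
    if len(coords) < 2:
        return False
    tree = cKDTree(coords)
    pairs = tree.query_pairs(1e-6)
    return len(pairs) > 0


def trajectory_surface_stats(
    traj: Trajectory,
    per_chain: bool = False,
    probe: float = 1.4,
    n_points: int = 960,
    subset: str = "heavy",
) -> TrajectorySurfaceStats:
    """Mean +/- SD (population) of total and hydrophobic SASA over frames.

    With ``per_chain`` both means and SDs are divided by the chain count, the
    convention used to compare an oligomer with a monomeric homologue on a
    per-subunit footing.
    """
    frames = traj.analysis_frames
    if frames.shape[0] < 2:
        raise ValueError("need >= 2 post-trim frames")
    totals = np.empty(frames.shape[0])
    hydros = np.empty(frames.shape[0])
    for t in range(frames.shape[0]):
        res = shrake_rupley_sasa(
            traj.topology.with_coords(frames[t]),
            probe=probe,
            n_points=n_points,
            subset=subset,
        )
        totals[t] = res.total
        hydros[t] = res.hydrophobic
    scale = 1.0 / len(traj.topology.chain_ids) if per_chain else 1.0
    mean_total = float(totals.mean())
    mean_hydro = float(hydros.mean())
    return TrajectorySurfaceStats(
        mean_total=mean_total * scale,
        sd_total=float(totals.std()) * scale,
        mean_hydrophobic=mean_hydro * scale,
        sd_hydrophobic=float(hydros.std()) * scale,
        hydrophobic_ratio=mean_hydro / mean_total if mean_total > 0 else 0.0,
        per_chain_normalized=per_chain,
        n_frames_used=frames.shape[0],
    )
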