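"""Hydrogen bonds, salt bridges, hydrophobic contacts, and their persistence.

Hydrogen bonds are scored by an energy that depends on the hydrogen-acceptor
distance: a linear ramp with a plateau, E = E_max for d_HA <= d_plateau,
falling linearly to 0 at d_zero (defaults 25 kJ/mol between 2.1 and 2.6 A).
A bond is retained when its energy reaches the detection threshold
(default 6.25 kJ/mol, i.e. d_HA <= 2.475 A with the default ramp) and, when
the hydrogen position is known, the D-H...A angle is at least 100 degrees.

Salt bridges ("electrostatic pairs") are oppositely charged side-chain groups
whose heavy atoms approach within 4 A.  Hydrophobic contacts are side-chain
carbon-carbon encounters (<= 5 A) between residues of the non-polar category.

Over a trajectory every interaction is tracked by a stable identity key and
summarised by its persistence: the percentage of analysed frames in which it
is present.  Interactions seen in fewer than 5% of frames are labelled
"unstable".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chem import (
    NEGATIVE_GROUP_ATOMS,
    POSITIVE_GROUP_ATOMS,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    BACKBONE_ATOMS,
    THREE_TO_ONE,
)
from .structure import Structure, Trajectory

AtomKey = tuple[str, int, str, str]  # chain, resnum, icode, atom name
ResKey = tuple[str, int, str]


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBond:
    donor: AtomKey
    hydrogen: AtomKey | None
    acceptor: AtomKey
    d_HA: float
    d_DA: float
    angle_DHA: float | None
    energy: float

    @property
    def key(self) -> tuple[AtomKey, AtomKey]:
        return (self.donor, self.acceptor)


@dataclass(frozen=True)
class SaltBridge:
    residue_a: ResKey  # charged-negative
    residue_b: ResKey  # charged-positive
    min_heavy_distance: float

    @property
    def key(self) -> tuple[ResKey, ResKey]:
        return (self.residue_a, self.residue_b)


@dataclass(frozen=True)
class HydrophobicContact:
    residue_a: ResKey
    residue_b: ResKey
    min_cc_distance: float

    @property
    def key(self) -> tuple[ResKey, ResKey]:
        return (self.residue_a, self.residue_b)


@dataclass
class InteractionTimeSeries:
    key: tuple
    presence: np.ndarray  # bool per analysed frame

    @property
    def persistence(self) -> float:
        """Percentage of analysed frames in which the interaction is present."""
        return 100.0 * float(self.presence.mean())


@dataclass
class NetworkSummary:
    total_unique: float
    unstable_count: float
    mean_per_frame: float
    sd_per_frame: float
    mean_persistence: float
    unstable_threshold: float
    per_chain_normalized: bool
    n_frames: int


# ---------------------------------------------------------------------------
# Hydrogen-bond energy model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondParams:
    """Parameters of the distance-dependent H-bond energy ramp."""

    e_max: float = 25.0       # kJ/mol at and below d_plateau
    d_plateau: float = 2.1    # A
    d_zero: float = 2.6       # A, energy reaches zero
    angle_min: float = 100.0  # degrees, D-H...A gate when H is known
    threshold: float = 6.25   # kJ/mol, retention threshold
    nh_bond_length: float = 1.0  # A, ideal N-H used to infer hydrogens

    def threshold_distance(self) -> float:
        """d_HA at which the ramp crosses the retention threshold."""
        frac = self.threshold / self.e_max
        return self.d_zero - frac * (self.d_zero - self.d_plateau)


DEFAULT_HBOND_PARAMS = HBondParams()


def hbond_energy(d_HA: float | np.ndarray, params: HBondParams = DEFAULT_HBOND_PARAMS):
    """H-bond energy (kJ/mol) as a function of hydrogen-acceptor distance."""
    d = np.asarray(d_HA, dtype=float)
    if (d <= 0).any():
        raise ValueError("d_HA must be positive")
    ramp = (params.d_zero - np.maximum(d, params.d_plateau)) / (
        params.d_zero - params.d_plateau
    )
    e = params.e_max * np.clip(ramp, 0.0, 1.0)
    return float(e) if np.isscalar(d_HA) else e


# ---------------------------------------------------------------------------
# Donor / acceptor assignment
# ---------------------------------------------------------------------------

def assign_donors_acceptors(
    structure: Structure,
) -> tuple[np.ndarray, np.ndarray]:
    """Donor and acceptor heavy-atom index arrays for a structure.

    Standard residues use the template chemistry tables; unknown residues
    contribute their backbone amide N / carbonyl O only (with a warning).
    """
    donors: list[int] = []
    acceptors: list[int] = []
    warned: set[str] = set()
    for i in range(structure.n_atoms):
        res3 = str(structure.res_name[i])
        name = str(structure.name[i])
        known = res3 in THREE_TO_ONE
        if not known and res3 not in warned:
            warnings.warn(
                f"unknown residue {res3}: backbone donors/acceptors only",
                stacklevel=2,
            )
            warned.add(res3)
        if name == "N" and res3 != "PRO":
            donors.append(i)
        elif name == "O":
            acceptors.append(i)
        if known:
            if name in SIDECHAIN_DONORS.get(res3, ()):
                donors.append(i)
            if name in SIDECHAIN_ACCEPTORS.get(res3, ()):
                acceptors.append(i)
    return np.asarray(donors, dtype=int), np.asarray(acceptors, dtype=int)


def _attached_hydrogens(structure: Structure, donor: int) -> np.ndarray:
    """Explicit hydrogens bonded to a donor (same residue, within 1.3 A)."""
    r = structure.residue_index[donor]
    idx = structure.residue_atom_indices(r)
    h = idx[structure.is_hydrogen[idx]]
    if len(h) == 0:
        return h
    d = np.linalg.norm(structure.coords[h] - structure.coords[donor], axis=1)
    return h[d < 1.3]


def _ideal_amide_hydrogen(
    structure: Structure, n_idx: int, nh: float
) -> np.ndarray | None:
    """Ideal backbone amide H: on the bisector opposite CA and C(prev)."""
    r = structure.residue_index[n_idx]
    res_idx = structure.residue_atom_indices(r)
    ca = res_idx[structure.name[res_idx] == "CA"]
    if len(ca) == 0 or r == 0:
        return None
    prev_idx = structure.residue_atom_indices(r - 1)
    if structure.chain_id[prev_idx[0]] != structure.chain_id[n_idx]:
        return None
    c_prev = prev_idx[structure.name[prev_idx] == "C"]
    if len(c_prev) == 0:
        return None
    n_pos = structure.coords[n_idx]
    u1 = structure.coords[ca[0]] - n_pos
    u2 = structure.coords[c_prev[0]] - n_pos
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    bis = u1 + u2
    norm = np.linalg.norm(bis)
    if norm < 1e-8:
        return None
    return n_pos - nh * bis / norm


# ---------------------------------------------------------------------------
# Detection on a single conformation
# ---------------------------------------------------------------------------

def detect_hbonds(
    model: Structure,
    threshold: float | None = None,
    params: HBondParams = DEFAULT_HBOND_PARAMS,
) -> list[HBond]:
    """All hydrogen bonds of one conformation, energy >= threshold.

    Structures with explicit hydrogens are evaluated at the true d_HA and
    D-H...A angle.  For hydrogen-free (X-ray) input the backbone amide H is
    rebuilt at ideal geometry; side-chain donors (whose H positions are
    rotamer-dependent) are scored through the donor-acceptor distance with an
    effective d_HA = d_DA - 1.0 A and no angle gate.  Intra-residue pairs are
    excluded and each donor/acceptor atom pair is reported once.
    """
    if threshold is not None:
        params = HBondParams(**{**params.__dict__, "threshold": threshold})
    donors, acceptors = assign_donors_acceptors(model)
    if len(donors) == 0 or len(acceptors) == 0:
        return []
    acc_tree = cKDTree(model.coords[acceptors])
    d_cut = params.d_zero
    out: list[HBond] = []
    seen: set[tuple[AtomKey, AtomKey]] = set()
    for don in donors:
        don_res = model.residue_index[don]
        hydrogens = _attached_hydrogens(model, don)
        h_positions: list[tuple[np.ndarray, int | None]] = []
        effective = False
        if len(hydrogens) > 0:
            h_positions = [(model.coords[h], int(h)) for h in hydrogens]
        elif str(model.name[don]) == "N":
            built = _ideal_amide_hydrogen(model, don, params.nh_bond_length)
            if built is not None:
                h_positions = [(built, None)]
            else:
                effective = True  # chain start: no geometry for an ideal H
        else:
            effective = True

        if effective:
            near = acc_tree.query_ball_point(
                model.coords[don], d_cut + params.nh_bond_length
            )
            for j in near:
                acc = acceptors[j]
                if model.residue_index[acc] == don_res:
                    continue
                d_da = float(
                    np.linalg.norm(model.coords[acc] - model.coords[don])
                )
                d_ha = d_da - params.nh_bond_length
                if d_ha <= 0 or d_ha > d_cut:
                    continue
                e = hbond_energy(d_ha, params)
                if e >= params.threshold:
                    pair = (model.atom_key(don), model.atom_key(acc))
                    if pair not in seen:
                        seen.add(pair)
                        out.append(
                            HBond(pair[0], None, pair[1], d_ha, d_da, None, e)
                        )
            continue

        for h_pos, h_idx in h_positions:
            near = acc_tree.query_ball_point(h_pos, d_cut)
            for j in near:
                acc = acceptors[j]
                if model.residue_index[acc] == don_res:
                    continue
                if acc == don:
                    continue
                a_pos = model.coords[acc]
                d_ha = float(np.linalg.norm(a_pos - h_pos))
                if d_ha > d_cut:
                    continue
                v1 = model.coords[don] - h_pos
                v2 = a_pos - h_pos
                cosang = float(
                    np.dot(v1, v2)
                    / (np.linalg.norm(v1) * np.linalg.norm(v2))
                )
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle < params.angle_min:
                    continue
                e = hbond_energy(d_ha, params)
                if e < params.threshold:
                    continue
                pair = (model.atom_key(don), model.atom_key(acc))
                if pair in seen:
                    continue
                seen.add(pair)
                d_da = float(np.linalg.norm(a_pos - model.coords[don]))
                hydrogen_key = model.atom_key(h_idx) if h_idx is not None else None
                out.append(
                    HBond(pair[0], hydrogen_key, pair[1], d_ha, d_da, angle, e)
                )
    return out


def detect_salt_bridges(
    model: Structure, cutoff: float = 4.0, neutral_his: bool = False
) -> list[SaltBridge]:
    """Oppositely charged residue pairs with charged-group heavy atoms < cutoff.

    One record per (negative, positive) residue pair, carrying the minimum
    distance over the charged-group atoms (Asp OD1/OD2, Glu OE1/OE2 versus
    Lys NZ, Arg NE/NH1/NH2, His ND1/NE2).
    """
    pos_atoms = dict(POSITIVE_GROUP_ATOMS)
    if neutral_his:
        pos_atoms.pop("HIS", None)
    neg_idx: list[int] = []
    pos_idx: list[int] = []
    for i in range(model.n_atoms):
        res3 = str(model.res_name[i])
        name = str(model.name[i])
        if name in NEGATIVE_GROUP_ATOMS.get(res3, ()):
            neg_idx.append(i)
        elif name in pos_atoms.get(res3, ()):
            pos_idx.append(i)
    if not neg_idx or not pos_idx:
        return []
    neg = np.asarray(neg_idx)
    pos = np.asarray(pos_idx)
    tree = cKDTree(model.coords[pos])
    best: dict[tuple[ResKey, ResKey], float] = {}
    for i in neg:
        near = tree.query_ball_point(model.coords[i], cutoff)
        for j in near:
            p = pos[j]
            d = float(np.linalg.norm(model.coords[p] - model.coords[i]))
            if d >= cutoff:
                continue
            key = (_res_key(model, i), _res_key(model, p))
            if key[0] == key[1]:
                continue
            if d < best.get(key, np.inf):
                best[key] = d
    return [
        SaltBridge(a, b, d) for (a, b), d in sorted(best.items(), key=lambda kv: kv[0])
    ]


def detect_hydrophobic_contacts(
    model: Structure, cutoff: float = 5.0, min_seq_sep: int = 2
) -> list[HydrophobicContact]:
    """Non-polar residue pairs with a side-chain C-C distance <= cutoff.

    Intra-chain pairs must be at least ``min_seq_sep`` apart in residue
    number; inter-chain pairs always qualify.
    """
    sc_carbon = (
        (model.element == "C")
        & ~np.isin(model.name, sorted(BACKBONE_ATOMS))
        & (model.res_categories[model.residue_index] == "non-polar")
    )
    idx = np.flatnonzero(sc_carbon)
    if len(idx) < 2:
        return []
    tree = cKDTree(model.coords[idx])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    best: dict[tuple[ResKey, ResKey], float] = {}
    for a_loc, b_loc in pairs:
        a, b = idx[a_loc], idx[b_loc]
        ka, kb = _res_key(model, a), _res_key(model, b)
        if ka == kb:
            continue
        if ka[0] == kb[0] and abs(ka[1] - kb[1]) < min_seq_sep:
            continue
        key = (ka, kb) if (ka < kb) else (kb, ka)
        d = float(np.linalg.norm(model.coords[a] - model.coords[b]))
        if d < best.get(key, np.inf):
            best[key] = d
    return [
        HydrophobicContact(a, b, d)
        for (a, b), d in sorted(best.items(), key=lambda kv: kv[0])
    ]


def _res_key(model: Structure, atom: int) -> ResKey:
    return (
        str(model.chain_id[atom]),
        int(model.res_num[atom]),
        str(model.icode[atom]),
    )


# ---------------------------------------------------------------------------
# Trajectory tracking
# ---------------------------------------------------------------------------

def track_interactions(
    traj: Trajectory,
    kind: str = "hbond",
    unstable_threshold: float = 5.0,
    per_chain: bool = False,
    **detect_kwargs,
) -> tuple[list[InteractionTimeSeries], NetworkSummary]:
    """Frame-by-frame interaction tracking with persistence statistics.

    ``kind`` is ``hbond``, ``saltbridge`` or ``hydrophobic``.  The summary
    reports the number of unique interactions seen at least once, how many
    are unstable (persistence < ``unstable_threshold`` %), the mean +/- SD
    (population) of the per-frame count, and the mean persistence over
    unique interactions.  ``per_chain`` divides the count statistics by the
    chain count, for per-subunit comparison of oligomers with monomers.
    """
    detect = {
        "hbond": detect_hbonds,
        "saltbridge": detect_salt_bridges,
        "hydrophobic": detect_hydrophobic_contacts,
    }.get(kind)
    if detect is None:
        raise ValueError(f"unknown interaction kind {kind!r}")
    frames = traj.analysis_frames
    if frames.shape[0] < 2:
        raise ValueError("need >= 2 post-trim frames")
    n_frames = frames.shape[0]
    presence: dict[tuple, np.ndarray] = {}
    per_frame_counts = np.zeros(n_frames, dtype=int)
    for t in range(n_frames):
        model = traj.topology.with_coords(frames[t])
        found = detect(model, **detect_kwargs)
        per_frame_counts[t] = len(found)
        for rec in found:
            key = rec.key
            if key not in presence:
                presence[key] = np.zeros(n_frames, dtype=bool)
            presence[key][t] = True

    series = [
        InteractionTimeSeries(key=k, presence=v)
        for k, v in sorted(presence.items(), key=lambda kv: repr(kv[0]))
    ]
    persistences = np.array([s.persistence for s in series])
    total = len(series)
    unstable = int((persistences < unstable_threshold).sum()) if total else 0
    if per_chain:
        scale = 1.0 / len(traj.topology.chain_ids)
        total_out: float = total * scale
        unstable_out: float = unstable * scale
    else:
        scale = 1.0
        total_out, unstable_out = total, unstable
    summary = NetworkSummary(
        total_unique=total_out,
        unstable_count=unstable_out,
        mean_per_frame=float(per_frame_counts.mean()) * scale,
        sd_per_frame=float(per_frame_counts.std()) * scale,
        mean_persistence=float(persistences.mean()) if total else 0.0,
        unstable_threshold=unstable_threshold,
        per_chain_normalized=per_chain,
        n_frames=n_frames,
    )
    return series, summary
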