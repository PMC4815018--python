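"""Synthetic structures and trajectories with known ground truth.

The generator builds idealised peptides (helix, strand or fully extended
backbone with amide hydrogens), assembles them into C2 dimers or D2 (222)
tetramers, and produces multi-frame trajectories whose statistical structure
is fully specified: iid per-coordinate Gaussian displacement of per-residue
amplitude sigma (so the expected RMSF is sigma * sqrt(3)), optional
rigid-body jitter that a superposition fit must remove, and interaction
schedules that hold a designated atom pair inside its detection cutoff in an
exactly prescribed fraction of the analysed frames.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import Structure, Trajectory, StructureError

# ideal backbone internal coordinates (Angstrom / degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_N_H = 1.0
B_CA_CB = 1.53
A_C_N_CA = 121.7
A_N_CA_C = 111.0
A_CA_C_N = 116.2
A_CA_C_O = 120.5

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
    "extended": (180.0, 180.0),
}

# probe atoms used by substitution hooks: a single characteristic side-chain
# atom, placed along the CA->CB direction at roughly its extended-rotamer
# distance from CA
PROBE_ATOMS = {
    "LYS": ("NZ", "N", 6.4),
    "ARG": ("NH1", "N", 7.0),
    "GLU": ("OE1", "O", 4.9),
    "ASP": ("OD1", "O", 3.7),
    "LEU": ("CD1", "C", 2.6),
    "SER": ("OG", "O", 2.4),
}


@dataclass
class InteractionSchedule:
    """Presence schedule for one synthetic interaction.

    ``atom_a`` stays where the base structure put it (plus noise); in
    "present" frames ``atom_b`` is re-placed at ``on_distance`` from the
    instantaneous position of ``atom_a`` along the base-structure direction,
    otherwise at ``off_distance``.  ``persistence`` is the percentage of
    post-trim frames in which the interaction is present; the frame subset is
    a seeded pseudo-random choice of exactly round(p/100 * n) frames.
    """

    atom_a: tuple[str, int, str]  # chain, resnum, atom name
    atom_b: tuple[str, int, str]
    persistence: float
    on_distance: float = 3.5
    off_distance: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 < self.persistence <= 100.0:
            raise ValueError("persistence must be in (0, 100]")


@dataclass
class SynthSpec:
    """Full recipe for one synthetic trajectory."""

    n_residues: int = 20
    geometry: str = "helix"
    chains: str = "monomer"          # monomer | C2 | D2
    separation: float = 30.0         # inter-centroid distance, Angstrom
    sigma_profile: float | np.ndarray = 0.3   # per-residue noise amplitude, A
    n_frames: int = 100
    seed: int = 0
    equilibration_fraction: float = 0.2
    jitter: bool = False
    jitter_rotation_deg: float = 8.0
    jitter_translation: float = 1.0
    substitutions: dict[int, str] = field(default_factory=dict)
    schedules: list[InteractionSchedule] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """NeRF: position of atom D given chain A-B-C and D's internal coords."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(angle),
            bond * np.cos(dihedral) * np.sin(angle),
            bond * np.sin(dihedral) * np.sin(angle),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


# ---------------------------------------------------------------------------
# Peptide builder
# ---------------------------------------------------------------------------

def build_peptide(
    n: int,
    geometry: str = "helix",
    substitutions: dict[int, str] | None = None,
    chain_id: str = "A",
    with_hydrogens: bool = True,
    with_cb: bool = True,
) -> Structure:
    """Ideal poly-Ala backbone of ``n`` residues in a canonical geometry.

    ``substitutions`` maps 1-based residue positions to residue names from
    the probe table (Lys, Arg, Glu, Asp, Leu, Ser); the residue is renamed
    and a single characteristic side-chain probe atom is added along the
    CA->CB direction.
    """
    if n < 2:
        raise StructureError("need at least 2 residues")
    if geometry not in PHI_PSI:
        raise StructureError(f"unknown geometry {geometry!r}")
    phi, psi = PHI_PSI[geometry]
    substitutions = substitutions or {}
    omega = 180.0

    # backbone trace: N, CA, C for every residue
    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([B_N_CA, 0.0, 0.0])]
    c0 = ca_pos[0] + B_CA_C * np.array(
        [np.cos(np.radians(180 - A_N_CA_C)), np.sin(np.radians(180 - A_N_CA_C)), 0.0]
    )
    c_pos = [c0]
    for i in range(1, n):
        ni = _place_atom(n_pos[-1], ca_pos[-1], c_pos[-1], B_C_N, A_CA_C_N, psi)
        cai = _place_atom(ca_pos[-1], c_pos[-1], ni, B_N_CA, A_C_N_CA, omega)
        ci = _place_atom(c_pos[-1], ni, cai, B_CA_C, A_N_CA_C, phi)
        n_pos.append(ni)
        ca_pos.append(cai)
        c_pos.append(ci)

    serial = 1
    rows: list[tuple] = []  # (serial, name, element, resnum, resname, coords)

    def emit(name: str, element: str, resnum: int, resname: str, xyz: np.ndarray):
        nonlocal serial
        rows.append((serial, name, element, resnum, resname, np.asarray(xyz)))
        serial += 1

    for i in range(n):
        resnum = i + 1
        resname = substitutions.get(resnum, "ALA").upper()
        emit("N", "N", resnum, resname, n_pos[i])
        if with_hydrogens and i > 0:
            u1 = ca_pos[i] - n_pos[i]
            u2 = c_pos[i - 1] - n_pos[i]
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            bis = u1 + u2
            h = n_pos[i] - B_N_H * bis / np.linalg.norm(bis)
            emit("H", "H", resnum, resname, h)
        emit("CA", "C", resnum, resname, ca_pos[i])
        # carbonyl O: in the peptide plane, anti to the next N
        if i < n - 1:
            o = _place_atom(n_pos[i], ca_pos[i], c_pos[i], B_C_O, A_CA_C_O, psi + 180.0)
        else:
            o = _place_atom(n_pos[i], ca_pos[i], c_pos[i], B_C_O, A_CA_C_O, psi + 180.0)
        cb_dir = None
        if with_cb or resname in PROBE_ATOMS:
            u1 = n_pos[i] - ca_pos[i]
            u2 = c_pos[i] - ca_pos[i]
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            bisn = u1 + u2
            bisn /= np.linalg.norm(bisn)
            perp = np.cross(u1, u2)
            perp /= np.linalg.norm(perp)
            cb_dir = -0.59 * bisn + 0.807 * perp
            cb = ca_pos[i] + B_CA_CB * cb_dir
            emit("CB", "C", resnum, resname, cb)
        emit("C", "C", resnum, resname, c_pos[i])
        emit("O", "O", resnum, resname, o)
        if resname in PROBE_ATOMS and cb_dir is not None:
            pname, pelem, pdist = PROBE_ATOMS[resname]
            emit(pname, pelem, resnum, resname, ca_pos[i] + pdist * cb_dir)

    return Structure(
        serial=np.array([r[0] for r in rows]),
        name=np.array([r[1] for r in rows]),
        element=np.array([r[2] for r in rows]),
        chain_id=np.array([chain_id] * len(rows)),
        res_num=np.array([r[3] for r in rows]),
        icode=np.array([""] * len(rows)),
        res_name=np.array([r[4] for r in rows]),
        coords=np.array([r[5] for r in rows]),
        source_id=f"synthetic-{geometry}",
    )


# ---------------------------------------------------------------------------
# Oligomer assembly
# ---------------------------------------------------------------------------

def assemble_oligomer(
    unit: Structure, symmetry: str = "D2", separation: float = 30.0
) -> Structure:
    """Assemble copies of a unit by two-fold rotations about orthogonal axes.

    C2 gives 2 chains (A, B); D2 ("222") gives 4 chains (A-D) whose centroids
    sit at the vertices of a regular tetrahedron with edge ``separation``.
    """
    import warnings as _warnings

    centroid = unit.coords.mean(axis=0)
    if symmetry == "C2":
        offset = np.array([separation / 2.0, 0.0, 0.0])
        ops = [np.eye(3), _rotation([0, 0, 1], 180.0)]
    elif symmetry == "D2":
        t = separation / (2.0 * np.sqrt(2.0))
        offset = np.array([t, t, t])
        ops = [
            np.eye(3),
            _rotation([0, 0, 1], 180.0),
            _rotation([0, 1, 0], 180.0),
            _rotation([1, 0, 0], 180.0),
        ]
    else:
        raise StructureError(f"unknown symmetry {symmetry!r}")

    base = unit.coords - centroid + offset
    parts = []
    chain_ids = "ABCD"
    n = unit.n_atoms
    all_coords = []
    for k, op in enumerate(ops):
        all_coords.append(base @ op.T)
    coords = np.vstack(all_coords)
    serial = np.arange(1, len(ops) * n + 1)
    rep = lambda a: np.concatenate([a] * len(ops))
    chain_id = np.concatenate(
        [np.array([chain_ids[k]] * n) for k in range(len(ops))]
    )
    olig = Structure(
        serial=serial,
        name=rep(unit.name),
        element=rep(unit.element),
        chain_id=chain_id,
        res_num=rep(unit.res_num),
        icode=rep(unit.icode),
        res_name=rep(unit.res_name),
        coords=coords,
        source_id=unit.source_id + f"-{symmetry}",
    )
    # clash warning: any inter-chain atom pair closer than 1 A
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(1.0):
        if chain_id[i] != chain_id[j]:
            _warnings.warn(
                "assembled chains overlap (inter-chain atoms < 1 A)",
                stacklevel=2,
            )
            break
    return olig


def add_probe(
    structure: Structure,
    chain: str,
    res_num: int,
    res_name: str,
    atom_name: str,
    element: str,
    xyz,
) -> Structure:
    """Insert one probe atom into a residue at an explicit position.

    The residue is renamed to ``res_name`` (e.g. ALA -> LYS) and the atom is
    appended to its atom block, so constructed interaction geometry can be
    placed exactly where a test specifies.
    """
    try:
        r = structure.res_keys.index((chain, res_num, ""))
    except ValueError as exc:
        raise StructureError(f"no residue {chain}{res_num}") from exc
    idx = structure.residue_atom_indices(r)
    pos = int(idx[-1]) + 1  # insert after the residue's last atom

    def ins(arr, value, dtype=None):
        out = np.insert(np.asarray(arr), pos, value)
        return out

    res_names = structure.res_name.copy()
    res_names[idx] = res_name.upper()
    return Structure(
        serial=ins(structure.serial, structure.n_atoms + 1),
        name=ins(structure.name, atom_name),
        element=ins(structure.element, element),
        chain_id=ins(structure.chain_id, chain),
        res_num=ins(structure.res_num, res_num),
        icode=ins(structure.icode, ""),
        res_name=ins(res_names, res_name.upper()),
        coords=np.insert(structure.coords, pos, np.asarray(xyz, dtype=float), axis=0),
        source_id=structure.source_id,
    )


# ---------------------------------------------------------------------------
# Trajectory generator
# ---------------------------------------------------------------------------

def _atom_index(structure: Structure, key: tuple[str, int, str]) -> int:
    cid, num, name = key
    hits = np.flatnonzero(
        (structure.chain_id == cid)
        & (structure.res_num == num)
        & (structure.name == name)
    )
    if len(hits) != 1:
        raise StructureError(f"schedule references absent atom {key}")
    return int(hits[0])


def make_trajectory(spec: SynthSpec, base: Structure | None = None) -> Trajectory:
    """Generate a trajectory realising the spec's noise model and schedules.

    Frame generation order is fixed, so identical specs (including the seed)
    produce bit-identical trajectories.
    """
    if base is None:
        unit = build_peptide(spec.n_residues, spec.geometry, spec.substitutions)
        if spec.chains == "monomer":
            base = unit
        else:
            base = assemble_oligomer(unit, spec.chains, spec.separation)

    rng = np.random.default_rng(spec.seed)
    n_atoms = base.n_atoms
    n_frames = spec.n_frames
    sigma = np.asarray(spec.sigma_profile, dtype=float)
    if sigma.ndim == 0:
        per_atom_sigma = np.full(n_atoms, float(sigma))
    else:
        if len(sigma) != base.n_residues:
            raise StructureError(
                "sigma_profile length must equal the residue count"
            )
        if (sigma < 0).any():
            raise StructureError("sigma_profile must be non-negative")
        per_atom_sigma = sigma[base.residue_index]

    first_used = int(np.floor(spec.equilibration_fraction * n_frames))
    n_used = n_frames - first_used

    # resolve schedules up front; scheduled "b" atoms carry no thermal noise
    sched: list[tuple[int, int, np.ndarray, np.ndarray]] = []
    frozen = np.zeros(n_atoms, dtype=bool)
    for s in spec.schedules:
        ia = _atom_index(base, s.atom_a)
        ib = _atom_index(base, s.atom_b)
        direction = base.coords[ib] - base.coords[ia]
        norm = np.linalg.norm(direction)
        direction = (
            direction / norm if norm > 1e-8 else np.array([1.0, 0.0, 0.0])
        )
        n_on = int(round(s.persistence / 100.0 * n_used))
        on_local = rng.choice(n_used, size=n_on, replace=False)
        on_mask = np.zeros(n_frames, dtype=bool)
        on_mask[first_used + on_local] = True
        sched.append((ia, ib, direction, on_mask))
        frozen[ib] = True

    frames = np.empty((n_frames, n_atoms, 3))
    for t in range(n_frames):
        noise = rng.normal(0.0, 1.0, size=(n_atoms, 3)) * per_atom_sigma[:, None]
        noise[frozen] = 0.0
        frame = base.coords + noise
        for (ia, ib, direction, on_mask), s in zip(sched, spec.schedules):
            d = s.on_distance if on_mask[t] else s.off_distance
            frame[ib] = frame[ia] + direction * d
        if spec.jitter:
            axis = rng.normal(size=3)
            angle = rng.uniform(-spec.jitter_rotation_deg, spec.jitter_rotation_deg)
            rot = _rotation(axis, angle)
            trans = rng.uniform(
                -spec.jitter_translation, spec.jitter_translation, size=3
            )
            centre = frame.mean(axis=0)
            frame = (frame - centre) @ rot.T + centre + trans
        frames[t] = frame

    return Trajectory(
        topology=base,
        frames=frames,
        frame_times=0.25 * np.arange(n_frames),
        equilibration_fraction=spec.equilibration_fraction,
    )


def synth_spec_from_file(path: str | Path) -> SynthSpec:
    """Load a SynthSpec from a YAML/JSON config file."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    schedules = [
        InteractionSchedule(
            atom_a=tuple(s["atom_a"]),
            atom_b=tuple(s["atom_b"]),
            persistence=float(s["persistence"]),
            on_distance=float(s.get("on_distance", 3.5)),
            off_distance=float(s.get("off_distance", 8.0)),
        )
        for s in data.pop("schedules", [])
    ]
    subs = {int(k): str(v) for k, v in data.pop("substitutions", {}).items()}
    return SynthSpec(**data, schedules=schedules, substitutions=subs)


def ground_truth(spec: SynthSpec) -> dict:
    """JSON-serialisable ground truth of a spec (for test harnesses)."""
    sigma = np.asarray(spec.sigma_profile, dtype=float)
    expected_rmsf = (sigma * np.sqrt(3.0)).tolist() if sigma.ndim else float(
        sigma
    ) * np.sqrt(3.0)
    return {
        "n_residues": spec.n_residues,
        "geometry": spec.geometry,
        "chains": spec.chains,
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "equilibration_fraction": spec.equilibration_fraction,
        "expected_rmsf": expected_rmsf,
        "schedules": [
            {
                "atom_a": list(s.atom_a),
                "atom_b": list(s.atom_b),
                "persistence": s.persistence,
                "on_distance": s.on_distance,
                "off_distance": s.off_distance,
            }
            for s in spec.schedules
        ],
    }


def write_ground_truth(spec: SynthSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ground_truth(spec), indent=2))
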