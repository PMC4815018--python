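"""Structures, trajectories, atom selections and rigid-body superposition.

A :class:`Structure` is a flat, array-backed model of one conformation of a
protein (chains -> residues -> atoms); a :class:`Trajectory` couples one
topology with an ordered stack of coordinate frames, as produced by reading a
multi-model PDB file.  Both are deliberately minimal: analysis code operates
on the numpy arrays directly.

PDB parsing and writing are delegated to biotite; this module owns the
in-memory model, the selection mini-language and the Kabsch fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .chem import residue_category, vdw_radius, BACKBONE_ATOMS, THREE_TO_ONE


class StructureError(ValueError):
    """Raised for unreadable or internally inconsistent structural input."""


class SelectionError(ValueError):
    """Raised for a malformed selection expression."""


# ---------------------------------------------------------------------------
# Lightweight per-atom / per-residue views
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    radius: float
    is_hydrogen: bool
    is_backbone: bool


@dataclass(frozen=True)
class Residue:
    chain_id: str
    number: int
    icode: str
    name3: str
    one_letter: str
    category: str
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)


@dataclass(frozen=True)
class Superposition:
    """Rigid transform mapping a mobile point set onto a reference.

    ``transform(x) = x @ rotation.T + translation`` attains ``rmsd``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

class Structure:
    """One conformation of a protein, stored as parallel per-atom arrays."""

    def __init__(
        self,
        serial: np.ndarray,
        name: np.ndarray,
        element: np.ndarray,
        chain_id: np.ndarray,
        res_num: np.ndarray,
        icode: np.ndarray,
        res_name: np.ndarray,
        coords: np.ndarray,
        source_id: str = "",
        model_index: int = 0,
    ) -> None:
        n = len(serial)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (n, 3):
            raise StructureError(f"coords shape {coords.shape} != ({n}, 3)")
        if not np.isfinite(coords).all():
            raise StructureError("non-finite coordinates")
        self.serial = np.asarray(serial, dtype=int)
        self.name = np.asarray(name, dtype="U6")
        self.element = np.char.upper(np.asarray(element, dtype="U2"))
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.res_num = np.asarray(res_num, dtype=int)
        self.icode = np.asarray(icode, dtype="U1")
        self.res_name = np.char.upper(np.asarray(res_name, dtype="U5"))
        self.coords = coords
        self.source_id = source_id
        self.model_index = model_index
        self._build_derived()

    # -- derived arrays ----------------------------------------------------

    def _build_derived(self) -> None:
        self.radius = np.array([vdw_radius(e) for e in self.element])
        self.is_hydrogen = self.element == "H"
        self.is_backbone = np.isin(self.name, sorted(BACKBONE_ATOMS))
        # residue boundaries: consecutive runs of identical (chain, num, icode)
        keys = list(
            zip(
                (str(c) for c in self.chain_id),
                (int(n) for n in self.res_num),
                (str(i) for i in self.icode),
            )
        )
        starts = [0]
        for i in range(1, len(keys)):
            if keys[i] != keys[i - 1]:
                starts.append(i)
        starts.append(len(keys))
        self._res_starts = np.array(starts, dtype=int)
        self.residue_index = np.empty(len(keys), dtype=int)
        for r, (a, b) in enumerate(zip(starts[:-1], starts[1:])):
            self.residue_index[a:b] = r
        res_keys = [keys[s] for s in starts[:-1]]
        if len(set(res_keys)) != len(res_keys):
            raise StructureError("duplicate (chain, residue number, icode) key")
        self.res_keys: list[tuple[str, int, str]] = res_keys
        self.res_names3 = np.array(
            [self.res_name[s] for s in starts[:-1]], dtype="U5"
        )
        self.res_categories = np.array(
            [residue_category(n3) for n3 in self.res_names3], dtype="U20"
        )

    # -- basic properties --------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def n_residues(self) -> int:
        return len(self.res_keys)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain_id:
            if str(c) not in seen:
                seen.append(str(c))
        return seen

    def residue_atom_indices(self, r: int) -> np.ndarray:
        a, b = self._res_starts[r], self._res_starts[r + 1]
        return np.arange(a, b)

    def atom_key(self, i: int) -> tuple[str, int, str, str]:
        return (
            str(self.chain_id[i]),
            int(self.res_num[i]),
            str(self.icode[i]),
            str(self.name[i]),
        )

    def residues(self) -> list[Residue]:
        out = []
        for r, (cid, num, ic) in enumerate(self.res_keys):
            idx = self.residue_atom_indices(r)
            atoms = tuple(
                Atom(
                    serial=int(self.serial[i]),
                    name=str(self.name[i]),
                    element=str(self.element[i]),
                    coords=self.coords[i].copy(),
                    radius=float(self.radius[i]),
                    is_hydrogen=bool(self.is_hydrogen[i]),
                    is_backbone=bool(self.is_backbone[i]),
                )
                for i in idx
            )
            name3 = str(self.res_names3[r])
            out.append(
                Residue(
                    chain_id=cid,
                    number=num,
                    icode=ic,
                    name3=name3,
                    one_letter=THREE_TO_ONE.get(name3, "X"),
                    category=str(self.res_categories[r]),
                    atoms=atoms,
                )
            )
        return out

    def chain_sequence(self, chain: str) -> str:
        """One-letter sequence of a chain in residue order (X for unknowns)."""
        letters = []
        for r, (cid, _, _) in enumerate(self.res_keys):
            if cid == chain:
                letters.append(THREE_TO_ONE.get(str(self.res_names3[r]), "X"))
        return "".join(letters)

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            serial=self.serial[idx],
            name=self.name[idx],
            element=self.element[idx],
            chain_id=self.chain_id[idx],
            res_num=self.res_num[idx],
            icode=self.icode[idx],
            res_name=self.res_name[idx],
            coords=self.coords[idx],
            source_id=self.source_id,
            model_index=self.model_index,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(
            serial=self.serial,
            name=self.name,
            element=self.element,
            chain_id=self.chain_id,
            res_num=self.res_num,
            icode=self.icode,
            res_name=self.res_name,
            coords=np.asarray(coords, dtype=float),
            source_id=self.source_id,
            model_index=self.model_index,
        )


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """An ordered stack of frames sharing one topology.

    ``equilibration_fraction`` of the leading frames is discarded by every
    analysis (default 0.2, i.e. the last 80% of the run is analysed).
    """

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray | None = None  # ns
    equilibration_fraction: float = 0.2

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (
            self.topology.n_atoms,
            3,
        ):
            raise StructureError(
                "inconsistent atom counts: frames do not match topology"
            )
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise StructureError("equilibration_fraction must be in [0, 1)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames_used(self) -> int:
        return self.n_frames - self.first_analysis_frame

    @property
    def first_analysis_frame(self) -> int:
        return int(np.floor(self.equilibration_fraction * self.n_frames))

    @property
    def analysis_frames(self) -> np.ndarray:
        """Frames after the equilibration trim (view, not copy)."""
        return self.frames[self.first_analysis_frame:]

    def frame_structure(self, t: int) -> Structure:
        return self.topology.with_coords(self.frames[t])


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def read_structure(
    path: str | Path,
    fmt: str = "pdb",
    keep_hetero: bool = False,
    equilibration_fraction: float = 0.0,
) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    Single-model files yield one frame.  Waters and hetero groups are
    excluded unless ``keep_hetero``; alternate locations are resolved to the
    highest-occupancy conformer (first listed on a tie).
    """
    if fmt != "pdb":
        raise StructureError(f"unsupported format: {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(
            model=None, altloc="occupancy", extra_fields=["atom_id"]
        )
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        msg = str(exc)
        if "atom" in msg.lower() and ("count" in msg.lower() or "number" in msg.lower()):
            raise StructureError(
                f"inconsistent atom counts across MODEL records in {path}"
            ) from exc
        raise StructureError(f"unreadable PDB file {path}: {msg}") from exc

    mask = np.ones(stack.array_length(), dtype=bool)
    if not keep_hetero:
        mask &= ~stack.hetero
    mask &= ~np.isin(stack.res_name, sorted(_WATER_NAMES))
    if not mask.any():
        raise StructureError(f"zero protein atoms in {path}")
    stack = stack[..., mask]

    element = np.array(
        [e if e else "C" for e in np.char.upper(stack.element)], dtype="U2"
    )
    topo = Structure(
        serial=stack.atom_id,
        name=stack.atom_name,
        element=element,
        chain_id=stack.chain_id,
        res_num=stack.res_id,
        icode=np.asarray(stack.ins_code, dtype="U1"),
        res_name=stack.res_name,
        coords=stack.coord[0],
        source_id=path.stem,
        model_index=0,
    )
    return Trajectory(
        topology=topo,
        frames=stack.coord.copy(),
        equilibration_fraction=equilibration_fraction,
    )


def _to_atom_array(structure: Structure, coords: np.ndarray) -> bst.AtomArray:
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = structure.chain_id
    arr.res_id = structure.res_num
    arr.ins_code = structure.icode
    arr.res_name = structure.res_name
    arr.atom_name = structure.name
    arr.element = structure.element
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("atom_id", np.arange(1, n + 1))
    return arr


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file (atom serials renumbered from 1)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure, structure.coords))
    pdb.write(str(Path(path)))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB file, one MODEL per frame."""
    n_frames = traj.n_frames
    stack = bst.stack(
        [_to_atom_array(traj.topology, traj.frames[t]) for t in range(n_frames)]
    )
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(Path(path)))


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------
# An expression is a conjunction of clauses joined by "and":
#   all | backbone | sidechain | heavy | hydrogen
#   chain <id>[,<id>...]
#   resid <n>|<a>-<b>[,...]
#   name <atom name>[,...]
# e.g. "chain A and backbone", "resid 5-10 and heavy".


def select(structure: Structure, spec: str) -> np.ndarray:
    """Resolve a selection expression to atom indices in topology order."""
    mask = np.ones(structure.n_atoms, dtype=bool)
    spec = spec.strip()
    if not spec:
        raise SelectionError("empty selection expression")
    for clause in (c.strip() for c in spec.split(" and ")):
        mask &= _clause_mask(structure, clause)
    return np.flatnonzero(mask)


def _clause_mask(s: Structure, clause: str) -> np.ndarray:
    if clause == "all":
        return np.ones(s.n_atoms, dtype=bool)
    if clause == "backbone":
        return s.is_backbone
    if clause == "sidechain":
        return ~s.is_backbone & ~s.is_hydrogen
    if clause == "heavy":
        return ~s.is_hydrogen
    if clause == "hydrogen":
        return s.is_hydrogen
    parts = clause.split(None, 1)
    if len(parts) != 2:
        raise SelectionError(f"malformed selection clause: {clause!r}")
    key, arg = parts
    values = [v.strip() for v in arg.split(",") if v.strip()]
    if not values:
        raise SelectionError(f"malformed selection clause: {clause!r}")
    if key == "chain":
        return np.isin(s.chain_id, values)
    if key == "name":
        return np.isin(s.name, values)
    if key == "resid":
        mask = np.zeros(s.n_atoms, dtype=bool)
        for v in values:
            if "-" in v[1:]:  # allow negative single ids
                lo_s, hi_s = v.rsplit("-", 1)
                try:
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError as exc:
                    raise SelectionError(f"bad resid range: {v!r}") from exc
                mask |= (s.res_num >= lo) & (s.res_num <= hi)
            else:
                try:
                    mask |= s.res_num == int(v)
                except ValueError as exc:
                    raise SelectionError(f"bad resid: {v!r}") from exc
        return mask
    raise SelectionError(f"unknown selection keyword: {key!r}")


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Least-squares optimal rigid superposition of two paired point sets.

    Returns the proper rotation (det = +1) and translation minimising the
    (weighted) RMSD of ``mobile`` onto ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise StructureError("point count mismatch between mobile and reference")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise StructureError("need >= 3 paired 3D points")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(mobile),) or (w < 0).any() or w.sum() == 0:
            raise StructureError("invalid weights")
    w = w / w.sum()

    mu_m = w @ mobile
    mu_r = w @ reference
    x = mobile - mu_m
    y = reference - mu_r
    cov = (x * w[:, None]).T @ y
    # degenerate (collinear or coincident) point sets have rank < 2
    if np.linalg.matrix_rank(cov, tol=1e-10) < 2:
        raise StructureError("degenerate point set: collinear or coincident")
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = mu_r - rot @ mu_m
    moved = mobile @ rot.T + translation
    rmsd = float(np.sqrt((w * ((moved - reference) ** 2).sum(axis=1)).sum()))
    return Superposition(rotation=rot, translation=translation, rmsd=rmsd)


def superpose_frames(
    frames: np.ndarray, fit_indices: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Superpose every frame onto ``reference`` using the fit selection."""
    out = np.empty_like(frames)
    ref_fit = reference[fit_indices]
    for t in range(frames.shape[0]):
        sup = kabsch_superpose(frames[t][fit_indices], ref_fit)
        out[t] = sup.apply(frames[t])
    return out
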