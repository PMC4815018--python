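"""Sequence-level comparison of homologous enzymes.

Covers amino-acid composition tables, pairwise identity on an alignment,
detection of positions specific to one (e.g. cold-adapted) homologue relative
to a reference set, chemical classification of those substitutions, and their
structural context: relative solvent accessibility and a phi/psi-based
secondary-structure class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .chem import (
    MAX_SASA_GXG,
    ONE_TO_THREE,
    STANDARD_AA1,
    merged_category,
    residue_category,
)
from .sasa import shrake_rupley_sasa
from .structure import Structure

AA_ORDER = list("GAPFYSTQDEHKRNCILMVW")  # reporting order; any full order works


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    description: str = ""
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"empty sequence for {self.id!r}")
        bad = set(self.residues.upper()) - set(STANDARD_AA1 + "X")
        if bad:
            raise SequenceError(
                f"{self.id!r}: unsupported residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class AlignmentView:
    """Gapped rows plus 1-based column <-> residue index maps."""

    def __init__(self, ids: list[str], rows: list[str]) -> None:
        if len(set(len(r) for r in rows)) != 1:
            raise SequenceError("ragged alignment: rows differ in length")
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]
        self.n_columns = len(rows[0])
        # column -> 1-based residue index (0 where the row has a gap)
        self._res_index = []
        for row in self.rows:
            out = np.zeros(self.n_columns, dtype=int)
            k = 0
            for c, ch in enumerate(row):
                if ch != "-":
                    k += 1
                    out[c] = k
            self._res_index.append(out)

    @property
    def n_records(self) -> int:
        return len(self.rows)

    def row_index(self, record_id: str) -> int:
        try:
            return self.ids.index(record_id)
        except ValueError as exc:
            raise SequenceError(f"no record {record_id!r} in alignment") from exc

    def residue_at(self, row: int, column: int) -> str | None:
        """Residue letter at a 1-based column, or None at a gap."""
        ch = self.rows[row][column - 1]
        return None if ch == "-" else ch

    def residue_index_at(self, row: int, column: int) -> int:
        """1-based residue index at a 1-based column (0 at a gap)."""
        return int(self._res_index[row][column - 1])

    def ungapped(self, row: int) -> SequenceRecord:
        return SequenceRecord(
            id=self.ids[row], residues=self.rows[row].replace("-", "")
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = []
    for r in SeqIO.parse(str(path), "fasta"):
        seq = str(r.seq).upper()
        if "-" in seq:
            raise SequenceError(
                f"{r.id!r}: gaps are only allowed in alignment input"
            )
        records.append(
            SequenceRecord(id=r.id, residues=seq, description=r.description)
        )
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def read_alignment(path: str | Path) -> AlignmentView:
    """Aligned FASTA or Clustal (auto-detected from the first character)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise SequenceError(f"empty alignment file {path}")
    fmt = "fasta" if text.lstrip().startswith(">") else "clustal"
    aln = AlignIO.read(str(path), fmt)
    return AlignmentView(
        ids=[r.id for r in aln], rows=[str(r.seq) for r in aln]
    )


# ---------------------------------------------------------------------------
# Point corrections
# ---------------------------------------------------------------------------

def apply_point_correction(
    seq: SequenceRecord, position: int, from_aa: str, to_aa: str
) -> SequenceRecord:
    """Apply a documented single-residue correction (1-based position).

    Refuses to edit if the stated original residue does not match, so a
    correction can never be applied silently to the wrong sequence.
    """
    if not 1 <= position <= len(seq):
        raise SequenceError(f"position {position} outside 1..{len(seq)}")
    actual = seq.residues[position - 1]
    if actual != from_aa.upper():
        raise SequenceError(
            f"correction mismatch at {position}: expected {from_aa}, found {actual}"
        )
    if from_aa.upper() == to_aa.upper():
        warnings.warn(f"identity correction at {position}: no change", stacklevel=2)
        return seq
    residues = seq.residues[: position - 1] + to_aa.upper() + seq.residues[position:]
    note = f"corrected {from_aa}{position}{to_aa}"
    return SequenceRecord(
        id=seq.id,
        residues=residues,
        description=seq.description,
        provenance=seq.provenance + (note,),
    )


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

@dataclass
class CompositionTable:
    """Counts and percentages of each amino acid in one sequence.

    Ratios use the full sequence length as denominator (X counted separately
    but included in the denominator) and are rounded to one decimal.
    """

    sequence_id: str
    length: int
    counts: dict[str, int]
    ratios: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "aa": ONE_TO_THREE.get(a, a),
                "letter": a,
                "count": self.counts[a],
                "ratio_pct": self.ratios[a],
            }
            for a in AA_ORDER + ["X"]
        ]
        return pd.DataFrame(rows)


def composition(seq: SequenceRecord) -> CompositionTable:
    s = seq.residues.upper()
    counts = {a: s.count(a) for a in STANDARD_AA1 + "X"}
    n = len(s)
    ratios = {a: round(100.0 * c / n, 1) for a, c in counts.items()}
    return CompositionTable(
        sequence_id=seq.id, length=n, counts=counts, ratios=ratios
    )


# ---------------------------------------------------------------------------
# Identity and pairwise alignment
# ---------------------------------------------------------------------------

def identity_percent(aln: AlignmentView, i: int, j: int) -> float:
    """Identity over columns where both rows have residues (raw percent)."""
    a, b = aln.rows[i], aln.rows[j]
    comparable = same = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            comparable += 1
            if x == y:
                same += 1
    if comparable == 0:
        return 0.0
    return 100.0 * same / comparable


def align_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentView:
    """Global pairwise alignment (Needleman-Wunsch with affine gaps)."""
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    best = aligner.align(a.residues, b.residues)[0]
    row_a, row_b = str(best[0]), str(best[1])
    return AlignmentView(ids=[a.id, b.id], rows=[row_a, row_b])


# ---------------------------------------------------------------------------
# Cold-specific substitutions
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionRecord:
    column: int                      # 1-based alignment column
    target_position: int             # 1-based residue index in the target
    target_residue: str
    reference_residues: str
    target_category: str             # merged 3-way category
    reference_categories: tuple[str, ...]
    non_conservative: bool
    label: str                       # e.g. "charged->neutral-polar"
    accessibility_class: str | None = None
    relative_sasa: float | None = None
    ss_class: str | None = None


def classify_substitution(target: str, refs: str) -> tuple[str, bool]:
    """Category-change label and non-conservative flag for a substitution.

    Categories are the merged three-way scheme (non-polar / neutral-polar /
    charged).  The substitution is non-conservative when the target category
    differs from the category of every reference residue.
    """
    t_cat = merged_category(residue_category(ONE_TO_THREE.get(target.upper(), "")))
    r_cats = [
        merged_category(residue_category(ONE_TO_THREE.get(r.upper(), "")))
        for r in refs
    ]
    non_conservative = all(c != t_cat for c in r_cats)
    uniq = sorted(set(r_cats))
    label = f"{'/'.join(uniq)}->{t_cat}"
    return label, non_conservative


def cold_specific_positions(
    aln: AlignmentView, target: int, references: list[int]
) -> list[SubstitutionRecord]:
    """Alignment columns where the target differs from every reference.

    Only fully comparable columns (residues present in the target and all
    references) are considered; gap-containing columns cannot be compared
    and are excluded.
    """
    if not references:
        raise SequenceError("need at least one reference row")
    if target in references:
        raise SequenceError("target row cannot also be a reference")
    out: list[SubstitutionRecord] = []
    for c in range(1, aln.n_columns + 1):
        t = aln.residue_at(target, c)
        rs = [aln.residue_at(r, c) for r in references]
        if t is None or any(r is None for r in rs):
            continue
        if any(t == r for r in rs):
            continue
        refs = "".join(rs)  # type: ignore[arg-type]
        label, non_cons = classify_substitution(t, refs)
        r_cats = tuple(
            merged_category(residue_category(ONE_TO_THREE.get(r, ""))) for r in refs
        )
        out.append(
            SubstitutionRecord(
                column=c,
                target_position=aln.residue_index_at(target, c),
                target_residue=t,
                reference_residues=refs,
                target_category=merged_category(
                    residue_category(ONE_TO_THREE.get(t, ""))
                ),
                reference_categories=r_cats,
                non_conservative=non_cons,
                label=label,
            )
        )
    return out


def comparable_columns(aln: AlignmentView, rows: list[int]) -> int:
    """Number of columns where every listed row has a residue."""
    n = 0
    for c in range(1, aln.n_columns + 1):
        if all(aln.residue_at(r, c) is not None for r in rows):
            n += 1
    return n


# ---------------------------------------------------------------------------
# Structural context: accessibility and secondary structure
# ---------------------------------------------------------------------------

ACCESSIBILITY_THRESHOLDS = (9.0, 36.0)  # percent: buried < 9 <= intermediate <= 36 < exposed


def accessibility_class(
    structure: Structure,
    chain: str,
    res_num: int,
    icode: str = "",
    thresholds: tuple[float, float] = ACCESSIBILITY_THRESHOLDS,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[str, float]:
    """Relative solvent accessibility class of one residue in monomer context.

    SASA is computed on the isolated single chain, normalised by the
    theoretical Gly-X-Gly maximum for the residue type.  Classes: buried
    (< 9%), intermediate (9-36%), exposed (> 36%); boundary values are
    assigned upward (exactly 9% -> intermediate, exactly 36% -> intermediate).
    """
    chain_atoms = np.flatnonzero(structure.chain_id == chain)
    if len(chain_atoms) == 0:
        raise ValueError(f"no chain {chain!r}")
    mono = structure.subset(chain_atoms)
    try:
        r = mono.res_keys.index((chain, res_num, icode))
    except ValueError as exc:
        raise ValueError(f"residue {chain}{res_num}{icode} absent") from exc
    surf = shrake_rupley_sasa(mono, probe=probe, n_points=n_points)
    res3 = str(mono.res_names3[r])
    max_sasa = MAX_SASA_GXG.get(res3)
    if max_sasa is None:
        raise ValueError(f"no reference maximum SASA for residue {res3}")
    rel = 100.0 * float(surf.per_residue_sasa[r]) / max_sasa
    lo, hi = thresholds
    if rel < lo:
        cls = "buried"
    elif rel <= hi:
        cls = "intermediate"
    else:
        cls = "exposed"
    return cls, rel


# phi/psi regions (degrees): a deliberately coarse Ramachandran heuristic
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -80.0)
STRAND_PSI_A = (80.0, 180.0)
STRAND_PSI_B = (-180.0, -170.0)


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def secondary_structure_class(
    structure: Structure, chain: str
) -> list[tuple[tuple[str, int, str], str]]:
    """Per-residue helix/strand/loop assignment from backbone dihedrals.

    Chain termini (undefined phi or psi) and residues with incomplete
    backbone are assigned loop.
    """
    res_ids = [
        r
        for r in range(structure.n_residues)
        if structure.res_keys[r][0] == chain
    ]
    if not res_ids:
        raise ValueError(f"no chain {chain!r}")

    def backbone(r: int) -> dict[str, np.ndarray] | None:
        idx = structure.residue_atom_indices(r)
        pos = {}
        for name in ("N", "CA", "C"):
            m = idx[structure.name[idx] == name]
            if len(m) == 0:
                return None
            pos[name] = structure.coords[m[0]]
        return pos

    out: list[tuple[tuple[str, int, str], str]] = []
    bbs = [backbone(r) for r in res_ids]
    for k, r in enumerate(res_ids):
        cls = "loop"
        if 0 < k < len(res_ids) - 1:
            prev, curr, nxt = bbs[k - 1], bbs[k], bbs[k + 1]
            if prev is None or curr is None or nxt is None:
                warnings.warn(
                    f"incomplete backbone near residue {structure.res_keys[r]};"
                    " assigned loop",
                    stacklevel=2,
                )
            else:
                phi = _dihedral(prev["C"], curr["N"], curr["CA"], curr["C"])
                psi = _dihedral(curr["N"], curr["CA"], curr["C"], nxt["N"])
                if HELIX_PHI[0] < phi < HELIX_PHI[1] and HELIX_PSI[0] < psi < HELIX_PSI[1]:
                    cls = "helix"
                elif STRAND_PHI[0] < phi < STRAND_PHI[1] and (
                    STRAND_PSI_A[0] < psi <= STRAND_PSI_A[1]
                    or STRAND_PSI_B[0] <= psi < STRAND_PSI_B[1]
                ):
                    cls = "strand"
        out.append((structure.res_keys[r], cls))
    return out
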