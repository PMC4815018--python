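"""Cross-homologue flexibility comparison through an alignment.

RMSF profiles of two proteins (e.g. an oligomer's chains versus a monomeric
homologue) are mapped onto common alignment columns; the per-column
difference dRMSF = target - reference, evaluated per target chain, drives
detection of flexibility-gain regions: runs of columns where dRMSF exceeds a
threshold in at least a minimum number of chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import THREE_TO_ONE
from .dynamics import RMSFProfile
from .seqcomp import AlignmentView, SequenceError


@dataclass
class MappedRMSF:
    """RMSF series of target chains and a reference on shared columns."""

    columns: np.ndarray              # 1-based alignment columns, ascending
    target_chain_ids: list[str]
    target_values: np.ndarray        # (n_chains, n_columns), Angstrom
    reference_values: np.ndarray     # (n_columns,), Angstrom
    target_keys: list[list[tuple[str, int, str]]]  # per chain, per column
    reference_keys: list[tuple[str, int, str]]

    @property
    def delta(self) -> np.ndarray:
        """dRMSF = target - reference, per chain per column (Angstrom)."""
        return self.target_values - self.reference_values[None, :]


@dataclass
class FlexGainRegion:
    start_column: int
    end_column: int
    n_chains_exceeding: list[int]    # per column in the region
    residues: list[tuple[str, int, str]]  # target keys (first chain)
    mean_delta: float                # Angstrom, mean over chains and columns


def _profile_sequence(profile: RMSFProfile) -> str:
    return "".join(THREE_TO_ONE.get(n, "X") for n in profile.res_names3)


def _resolve_row(aln: AlignmentView, profile: RMSFProfile) -> int:
    seq = _profile_sequence(profile)
    for i in range(aln.n_records):
        if aln.ungapped(i).residues == seq:
            return i
    raise SequenceError(
        "RMSF profile sequence does not match any alignment row "
        f"(profile length {len(seq)})"
    )


def map_rmsf(
    aln: AlignmentView,
    target_profiles: list[RMSFProfile],
    reference_profile: RMSFProfile,
    target_row: int | None = None,
    reference_row: int | None = None,
) -> MappedRMSF:
    """Map per-chain target profiles and a reference profile onto alignment
    columns where both proteins have residues.

    All target chains must share one sequence (one alignment row); rows are
    resolved by exact sequence match unless given explicitly.
    """
    if not target_profiles:
        raise ValueError("need at least one target profile")
    t_seqs = {_profile_sequence(p) for p in target_profiles}
    if len(t_seqs) != 1:
        raise SequenceError("target chains do not share one sequence")
    if target_row is None:
        target_row = _resolve_row(aln, target_profiles[0])
    if reference_row is None:
        reference_row = _resolve_row(aln, reference_profile)
    if aln.ungapped(target_row).residues != t_seqs.pop():
        raise SequenceError("target profiles disagree with the alignment row")
    if aln.ungapped(reference_row).residues != _profile_sequence(reference_profile):
        raise SequenceError("reference profile disagrees with the alignment row")

    cols: list[int] = []
    for c in range(1, aln.n_columns + 1):
        if (
            aln.residue_at(target_row, c) is not None
            and aln.residue_at(reference_row, c) is not None
        ):
            cols.append(c)
    columns = np.asarray(cols, dtype=int)

    n_chains = len(target_profiles)
    tv = np.empty((n_chains, len(cols)))
    tkeys: list[list[tuple[str, int, str]]] = [[] for _ in range(n_chains)]
    rv = np.empty(len(cols))
    rkeys: list[tuple[str, int, str]] = []
    for k, c in enumerate(cols):
        ti = aln.residue_index_at(target_row, c) - 1
        ri = aln.residue_index_at(reference_row, c) - 1
        for ch, prof in enumerate(target_profiles):
            tv[ch, k] = prof.rmsf[ti]
            tkeys[ch].append(prof.keys[ti])
        rv[k] = reference_profile.rmsf[ri]
        rkeys.append(reference_profile.keys[ri])
    return MappedRMSF(
        columns=columns,
        target_chain_ids=[p.keys[0][0] for p in target_profiles],
        target_values=tv,
        reference_values=rv,
        target_keys=tkeys,
        reference_keys=rkeys,
    )


def detect_gain_regions(
    mapped: MappedRMSF,
    threshold: float = 0.25,
    min_chains: int = 2,
    min_run: int = 1,
) -> list[FlexGainRegion]:
    """Maximal runs of columns with dRMSF > threshold in >= min_chains chains.

    The comparison is strictly greater-than.  Runs are consecutive alignment
    columns (gaps in the mapped column set break a run); runs shorter than
    ``min_run`` are discarded.
    """
    n_chains = mapped.target_values.shape[0]
    if min_chains > n_chains:
        raise ValueError(
            f"min_chains={min_chains} exceeds chain count {n_chains}"
        )
    exceeding = (mapped.delta > threshold).sum(axis=0)  # per column
    qualifies = exceeding >= min_chains
    regions: list[FlexGainRegion] = []
    i = 0
    cols = mapped.columns
    while i < len(cols):
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < len(cols)
            and qualifies[j + 1]
            and cols[j + 1] == cols[j] + 1
        ):
            j += 1
        if j - i + 1 >= min_run:
            regions.append(
                FlexGainRegion(
                    start_column=int(cols[i]),
                    end_column=int(cols[j]),
                    n_chains_exceeding=[int(x) for x in exceeding[i : j + 1]],
                    residues=mapped.target_keys[0][i : j + 1],
                    mean_delta=float(mapped.delta[:, i : j + 1].mean()),
                )
            )
        i = j + 1
    return regions


def format_mean_sd(mean: float, sd: float, decimals: int = 2) -> str:
    """Render a mean with its SD in ``0.48 (+/-0.21)`` style."""
    return f"{mean:.{decimals}f} (±{sd:.{decimals}f})"


def flexibility_report(
    mapped: MappedRMSF, regions: list[FlexGainRegion]
) -> dict:
    """Region table plus ensemble RMSF summaries.

    Returns a dict with a ``regions`` DataFrame (one row per region) and
    formatted mean-RMSF lines for the target ensemble and the reference.
    """
    rows = []
    for reg in regions:
        rows.append(
            {
                "start_column": reg.start_column,
                "end_column": reg.end_column,
                "n_columns": reg.end_column - reg.start_column + 1,
                "residues": ",".join(
                    f"{c}{n}{i}".strip() for c, n, i in reg.residues
                ),
                "max_chains_exceeding": max(reg.n_chains_exceeding),
                "mean_delta_A": round(reg.mean_delta, 3),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "start_column",
            "end_column",
            "n_columns",
            "residues",
            "max_chains_exceeding",
            "mean_delta_A",
        ],
    )
    tv = mapped.target_values
    rv = mapped.reference_values
    return {
        "regions": frame,
        "n_regions": len(regions),
        "target_mean_rmsf": format_mean_sd(float(tv.mean()), float(tv.std())),
        "reference_mean_rmsf": format_mean_sd(float(rv.mean()), float(rv.std())),
    }
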