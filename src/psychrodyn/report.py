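"""Report assembly: composition tables, network/surface summaries, pipelines.

Row names of the trajectory summary mirror the conventional comparison table
for MD-derived interaction statistics (total / unstable / per-frame hydrogen
bonds, salt bridges, accessible surface); counts are printed as integers,
ratios with one decimal, RMSF with two decimals, and every formatted value is
accompanied by its raw full-precision counterpart in JSON output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import mean_rmsf, rmsf_profile
from .flexibility import (
    detect_gain_regions,
    flexibility_report,
    format_mean_sd,
    map_rmsf,
)
from .interactions import track_interactions
from .interfaces import enumerate_interfaces
from .sasa import trajectory_surface_stats
from .seqcomp import (
    SequenceRecord,
    apply_point_correction,
    cold_specific_positions,
    composition,
    read_alignment,
    read_fasta,
)
from .structure import Trajectory, read_structure


def composition_frame(records: list[SequenceRecord]) -> pd.DataFrame:
    """Side-by-side composition table: one column per sequence,
    cells formatted ``count (ratio%)``."""
    tables = [composition(r) for r in records]
    from .chem import ONE_TO_THREE
    from .seqcomp import AA_ORDER

    data: dict[str, list] = {
        "residue": [ONE_TO_THREE[a].title() for a in AA_ORDER]
    }
    for t in tables:
        data[t.sequence_id] = [
            f"{t.counts[a]} ({t.ratios[a]:.1f}%)" for a in AA_ORDER
        ]
    frame = pd.DataFrame(data)
    lengths = pd.DataFrame(
        {"residue": ["Number of residues"], **{t.sequence_id: [str(t.length)] for t in tables}}
    )
    return pd.concat([lengths, frame], ignore_index=True)


def trajectory_summary(
    traj: Trajectory,
    per_chain: bool | None = None,
    sasa_n_points: int = 960,
    with_sasa: bool = True,
) -> dict:
    """Interaction-network and surface statistics of one trajectory.

    ``per_chain`` defaults to on for multi-chain systems, so that oligomer
    values are reported per subunit and are comparable with a monomer.
    """
    if per_chain is None:
        per_chain = len(traj.topology.chain_ids) > 1
    hb_series, hb = track_interactions(traj, "hbond", per_chain=per_chain)
    sb_series, sb = track_interactions(traj, "saltbridge", per_chain=per_chain)
    prof = rmsf_profile(traj)
    m, s = mean_rmsf(prof)
    out = {
        "Mean RMSF (backbone) (A)": format_mean_sd(m, s),
        "Total H bonds": hb.total_unique,
        "Unstable H bonds (persistence <5%)": hb.unstable_count,
        "Average H bonds per frame": format_mean_sd(hb.mean_per_frame, hb.sd_per_frame, 0),
        "Average H bonds persistence": f"{hb.mean_persistence:.0f}%",
        "Total salt bridges": sb.total_unique,
        "Unstable salt bridges (persistence <5%)": sb.unstable_count,
        "Average salt bridge per frame": format_mean_sd(sb.mean_per_frame, sb.sd_per_frame, 0),
        "Average salt bridge persistence": f"{sb.mean_persistence:.0f}%",
        "per_chain_normalized": per_chain,
        "raw": {
            "mean_rmsf": m,
            "sd_rmsf": s,
            "hbond_total": hb.total_unique,
            "hbond_unstable": hb.unstable_count,
            "hbond_mean_per_frame": hb.mean_per_frame,
            "hbond_sd_per_frame": hb.sd_per_frame,
            "hbond_mean_persistence": hb.mean_persistence,
            "saltbridge_total": sb.total_unique,
            "saltbridge_unstable": sb.unstable_count,
            "saltbridge_mean_per_frame": sb.mean_per_frame,
            "saltbridge_sd_per_frame": sb.sd_per_frame,
            "saltbridge_mean_persistence": sb.mean_persistence,
            "n_frames": hb.n_frames,
        },
    }
    if with_sasa:
        surf = trajectory_surface_stats(
            traj, per_chain=per_chain, n_points=sasa_n_points
        )
        out["Average total SAS (A^2)"] = format_mean_sd(
            surf.mean_total, surf.sd_total, 0
        )
        out["Average hydrophobic SAS (A^2)"] = format_mean_sd(
            surf.mean_hydrophobic, surf.sd_hydrophobic, 0
        )
        out["Hydrophobic SAS/Total SAS ratio"] = (
            f"{100.0 * surf.hydrophobic_ratio:.0f}%"
        )
        out["raw"].update(
            {
                "sas_mean_total": surf.mean_total,
                "sas_sd_total": surf.sd_total,
                "sas_mean_hydrophobic": surf.mean_hydrophobic,
                "sas_sd_hydrophobic": surf.sd_hydrophobic,
                "sas_hydrophobic_ratio": surf.hydrophobic_ratio,
            }
        )
    return out


def substitution_frame(records) -> pd.DataFrame:
    rows = [
        {
            "column": r.column,
            "target_position": r.target_position,
            "target": r.target_residue,
            "references": r.reference_residues,
            "category_change": r.label,
            "non_conservative": r.non_conservative,
            "accessibility": r.accessibility_class or "",
            "relative_sasa_pct": (
                round(r.relative_sasa, 1) if r.relative_sasa is not None else ""
            ),
            "secondary_structure": r.ss_class or "",
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "column",
            "target_position",
            "target",
            "references",
            "category_change",
            "non_conservative",
            "accessibility",
            "relative_sasa_pct",
            "secondary_structure",
        ],
    )


# ---------------------------------------------------------------------------
# Config-driven pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative pipeline configuration.

    Only the stages whose inputs are given are run.  All thresholds default
    to the documented analysis conventions.
    """

    output_dir: str = "psychrodyn_out"
    format: str = "tsv"  # tsv | json for tabular outputs
    seed: int = 0
    # stage inputs
    fasta: str | None = None
    corrections: list[str] = field(default_factory=list)  # "ID:POS:FROM:TO"
    alignment: str | None = None
    target_id: str | None = None
    reference_ids: list[str] = field(default_factory=list)
    trajectory: str | None = None
    reference_trajectory: str | None = None
    structure: str | None = None
    # thresholds
    hbond_threshold: float = 6.25
    saltbridge_cutoff: float = 4.0
    contact_cutoff: float = 5.0
    unstable_threshold: float = 5.0
    delta_rmsf_threshold: float = 0.25
    min_chains: int = 2
    equilibration_fraction: float = 0.2
    probe_radius: float = 1.4
    sphere_points: int = 960
    per_chain: bool | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _apply_corrections(records, corrections):
    by_id = {r.id: r for r in records}
    for spec in corrections:
        rid, pos, frm, to = spec.split(":")
        by_id[rid] = apply_point_correction(by_id[rid], int(pos), frm, to)
    return list(by_id.values())


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns {artifact name: path}."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    header = "# config: " + json.dumps(config.as_dict(), sort_keys=True)

    def write_table(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            frame.to_csv(fh, sep="\t", index=False)
        written[name] = path

    def write_json(name: str, payload: dict) -> None:
        path = outdir / f"{name}.json"
        path.write_text(
            json.dumps({"config": config.as_dict(), **payload}, indent=2, default=str)
        )
        written[name] = path

    if config.fasta:
        records = _apply_corrections(read_fasta(config.fasta), config.corrections)
        write_table("composition", composition_frame(records))

    if config.alignment and config.target_id and config.reference_ids:
        aln = read_alignment(config.alignment)
        t = aln.row_index(config.target_id)
        refs = [aln.row_index(r) for r in config.reference_ids]
        subs = cold_specific_positions(aln, t, refs)
        write_table("cold_specific", substitution_frame(subs))

    traj = ref_traj = None
    if config.trajectory:
        traj = read_structure(
            config.trajectory,
            equilibration_fraction=config.equilibration_fraction,
        )
        summary = trajectory_summary(
            traj, per_chain=config.per_chain, sasa_n_points=config.sphere_points
        )
        write_json("trajectory_summary", summary)
        prof = rmsf_profile(traj)
        write_table(
            "rmsf",
            pd.DataFrame(
                {
                    "chain": [k[0] for k in prof.keys],
                    "resnum": [k[1] for k in prof.keys],
                    "resname": prof.res_names3,
                    "rmsf_A": np.round(prof.rmsf, 4),
                }
            ),
        )

    if config.trajectory and config.reference_trajectory and config.alignment:
        ref_traj = read_structure(
            config.reference_trajectory,
            equilibration_fraction=config.equilibration_fraction,
        )
        aln = read_alignment(config.alignment)
        target_profiles = [
            rmsf_profile(traj).for_chain(c) for c in traj.topology.chain_ids
        ]
        ref_profile = rmsf_profile(ref_traj)
        mapped = map_rmsf(aln, target_profiles, ref_profile)
        regions = detect_gain_regions(
            mapped,
            threshold=config.delta_rmsf_threshold,
            min_chains=config.min_chains,
        )
        rep = flexibility_report(mapped, regions)
        write_table("flex_regions", rep["regions"])
        write_json(
            "flex_summary",
            {
                "n_regions": rep["n_regions"],
                "target_mean_rmsf": rep["target_mean_rmsf"],
                "reference_mean_rmsf": rep["reference_mean_rmsf"],
            },
        )

    if config.structure:
        model = read_structure(config.structure).topology
        reports = enumerate_interfaces(
            model,
            probe=config.probe_radius,
            n_points=config.sphere_points,
            saltbridge_cutoff=config.saltbridge_cutoff,
            contact_cutoff=config.contact_cutoff,
        )
        write_json(
            "interfaces",
            {
                "interfaces": [
                    {
                        "chain_pair": list(r.chain_pair),
                        "buried_area_A2": round(r.buried_area, 1),
                        "buried_area_half_A2": round(r.buried_area_half, 1),
                        "n_hbonds": len(r.hbonds),
                        "n_salt_bridges": len(r.salt_bridges),
                        "n_hydrophobic_clusters": len(r.hydrophobic_clusters),
                        "interface_residues": {
                            c: [[list(k), round(d, 2)] for k, d in v]
                            for c, v in r.interface_residues.items()
                        },
                    }
                    for r in reports
                ]
            },
        )

    return written
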