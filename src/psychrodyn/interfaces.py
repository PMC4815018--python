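"""Oligomer interface characterisation.

For a chain pair the buried area is SASA(A) + SASA(B) - SASA(AB), evaluated
with identical probe and sampling parameters; interface residues are those
losing accessible surface on complexation; cross-chain hydrogen bonds, salt
bridges and hydrophobic contacts are re-detected restricted to the pair, and
hydrophobic contacts are grouped into clusters (connected components of the
cross-chain contact graph).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .interactions import (
    HBond,
    HBondParams,
    DEFAULT_HBOND_PARAMS,
    HydrophobicContact,
    SaltBridge,
    detect_hbonds,
    detect_hydrophobic_contacts,
    detect_salt_bridges,
)
from .sasa import shrake_rupley_sasa
from .structure import Structure, kabsch_superpose

ResKey = tuple[str, int, str]


@dataclass
class InterfaceReport:
    chain_pair: tuple[str, str]
    buried_area: float                       # Angstrom^2, full two-chain value
    interface_residues: dict[str, list[tuple[ResKey, float]]]  # per chain
    hbonds: list[HBond]
    salt_bridges: list[SaltBridge]
    hydrophobic_contacts: list[HydrophobicContact]
    hydrophobic_clusters: list[set[ResKey]]

    @property
    def buried_area_half(self) -> float:
        """Buried area divided by two (the per-side convention)."""
        return self.buried_area / 2.0


def _spans_chains(key_a: ResKey, key_b: ResKey, a: str, b: str) -> bool:
    return {key_a[0], key_b[0]} == {a, b}


def interface_report(
    oligomer: Structure,
    chain_a: str,
    chain_b: str,
    probe: float = 1.4,
    n_points: int = 960,
    delta_sasa_min: float = 0.1,
    hbond_params: HBondParams = DEFAULT_HBOND_PARAMS,
    saltbridge_cutoff: float = 4.0,
    contact_cutoff: float = 5.0,
) -> InterfaceReport:
    """Characterise the interface between two chains of an oligomer."""
    for cid in (chain_a, chain_b):
        if cid not in oligomer.chain_ids:
            raise ValueError(f"unknown chain id {cid!r}")
    idx_a = np.flatnonzero(oligomer.chain_id == chain_a)
    idx_b = np.flatnonzero(oligomer.chain_id == chain_b)
    mono_a = oligomer.subset(idx_a)
    mono_b = oligomer.subset(idx_b)
    pair = oligomer.subset(np.concatenate([idx_a, idx_b]))

    surf_a = shrake_rupley_sasa(mono_a, probe=probe, n_points=n_points)
    surf_b = shrake_rupley_sasa(mono_b, probe=probe, n_points=n_points)
    surf_ab = shrake_rupley_sasa(pair, probe=probe, n_points=n_points)
    buried = max(0.0, surf_a.total + surf_b.total - surf_ab.total)

    # per-residue delta SASA: isolated minus in-complex
    interface_residues: dict[str, list[tuple[ResKey, float]]] = {
        chain_a: [],
        chain_b: [],
    }
    ab_index = {k: r for r, k in enumerate(pair.res_keys)}
    for mono, cid in ((mono_a, chain_a), (mono_b, chain_b)):
        surf_mono = surf_a if cid == chain_a else surf_b
        for r, key in enumerate(mono.res_keys):
            d = float(
                surf_mono.per_residue_sasa[r]
                - surf_ab.per_residue_sasa[ab_index[key]]
            )
            if d > delta_sasa_min:
                interface_residues[cid].append((key, d))

    hbonds = [
        hb
        for hb in detect_hbonds(pair, params=hbond_params)
        if _spans_chains(hb.donor[:3], hb.acceptor[:3], chain_a, chain_b)
    ]
    bridges = [
        sb
        for sb in detect_salt_bridges(pair, cutoff=saltbridge_cutoff)
        if _spans_chains(sb.residue_a, sb.residue_b, chain_a, chain_b)
    ]
    contacts = [
        hc
        for hc in detect_hydrophobic_contacts(pair, cutoff=contact_cutoff)
        if _spans_chains(hc.residue_a, hc.residue_b, chain_a, chain_b)
    ]
    graph = nx.Graph()
    for hc in contacts:
        graph.add_edge(hc.residue_a, hc.residue_b)
    clusters = [set(c) for c in nx.connected_components(graph)]
    clusters.sort(key=lambda s: sorted(s)[0])

    return InterfaceReport(
        chain_pair=(chain_a, chain_b),
        buried_area=buried,
        interface_residues=interface_residues,
        hbonds=hbonds,
        salt_bridges=bridges,
        hydrophobic_contacts=contacts,
        hydrophobic_clusters=clusters,
    )


def enumerate_interfaces(
    oligomer: Structure, min_buried: float = 100.0, **kwargs
) -> list[InterfaceReport]:
    """All chain-pair interfaces burying at least ``min_buried`` A^2,
    sorted by buried area, largest first."""
    chains = oligomer.chain_ids
    reports = []
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            rep = interface_report(oligomer, chains[i], chains[j], **kwargs)
            if rep.buried_area >= min_buried:
                reports.append(rep)
    reports.sort(key=lambda r: -r.buried_area)
    return reports


def chain_equivalence(
    oligomer: Structure, selection: str = "backbone"
) -> tuple[list[str], np.ndarray]:
    """Pairwise Kabsch RMSD matrix between chains on common residues.

    Chains are compared on atoms shared by (residue number, insertion code,
    atom name); the matrix is symmetric with a zero diagonal.
    """
    from .structure import select

    chains = oligomer.chain_ids
    atom_maps: list[dict[tuple[int, str, str], int]] = []
    for cid in chains:
        idx = select(oligomer, f"chain {cid} and {selection}")
        atom_maps.append(
            {
                (
                    int(oligomer.res_num[i]),
                    str(oligomer.icode[i]),
                    str(oligomer.name[i]),
                ): i
                for i in idx
            }
        )
    n = len(chains)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = sorted(set(atom_maps[i]) & set(atom_maps[j]))
            if len(common) < 3:
                raise ValueError(
                    f"no common residues between chains {chains[i]} and {chains[j]}"
                )
            xi = oligomer.coords[[atom_maps[i][k] for k in common]]
            xj = oligomer.coords[[atom_maps[j][k] for k in common]]
            rmsd = kabsch_superpose(xi, xj).rmsd
            matrix[i, j] = matrix[j, i] = rmsd
    return chains, matrix
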