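"""Shrake-Rupley solvent-accessible surface of a peptide and a tetramer.

Prints total and hydrophobic (carbon/sulfur) SASA of one helix, then the
same metrics for a D2 tetramer of that helix per chain -- burial at the
interfaces makes the per-chain value smaller than the isolated monomer's.
"""

from psychrodyn import assemble_oligomer, build_peptide, shrake_rupley_sasa

helix = build_peptide(18, "helix")
mono = shrake_rupley_sasa(helix)
print(f"monomer total SASA       : {mono.total:8.1f} A^2")
print(f"monomer hydrophobic SASA : {mono.hydrophobic:8.1f} A^2 "
      f"({100 * mono.hydrophobic / mono.total:.0f}%)")

tetramer = assemble_oligomer(helix, "D2", 28.0)
tet = shrake_rupley_sasa(tetramer)
print(f"tetramer total / 4       : {tet.total / 4:8.1f} A^2 "
      f"(interface burial lowers the per-chain surface)")
print(f"tetramer hydrophobic / 4 : {tet.hydrophobic / 4:8.1f} A^2")
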