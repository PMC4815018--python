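"""Energy-thresholded hydrogen-bond detection on an ideal alpha-helix.

The bond energy is a linear ramp in the hydrogen-acceptor distance
(25 kJ/mol at <= 2.1 A, zero at >= 2.6 A); bonds are retained at
>= 6.25 kJ/mol, i.e. d_HA <= 2.475 A.  An ideal 12-residue helix shows the
canonical i -> i-4 backbone ladder: donors 5..12, eight bonds.
"""

from psychrodyn import build_peptide, detect_hbonds, hbond_energy
from psychrodyn.interactions import DEFAULT_HBOND_PARAMS

d_thr = DEFAULT_HBOND_PARAMS.threshold_distance()
print(f"retention threshold : 6.25 kJ/mol  <=>  d_HA = {d_thr:.3f} A")
for d in (2.0, 2.3, d_thr, 2.5):
    print(f"  E(d_HA = {d:.3f} A) = {hbond_energy(d):5.2f} kJ/mol")

helix = build_peptide(12, "helix")
bonds = detect_hbonds(helix)
print(f"\nideal 12-residue helix: {len(bonds)} backbone hydrogen bonds")
for b in bonds:
    print(
        f"  N({b.donor[1]:2d}) -> O({b.acceptor[1]:2d})  "
        f"d_HA = {b.d_HA:.2f} A, angle = {b.angle_DHA:5.1f} deg, "
        f"E = {b.energy:.1f} kJ/mol"
    )
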