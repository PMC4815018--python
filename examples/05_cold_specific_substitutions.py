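"""Cold-specific substitution analysis on a toy three-way alignment.

Positions where the target (cold-adapted) sequence differs from every
reference are reported with their chemical category change; substitutions
that leave the three-way category (non-polar / neutral-polar / charged) are
flagged non-conservative.
"""

from psychrodyn import AlignmentView, cold_specific_positions, identity_percent

aln = AlignmentView(
    ids=["thermo", "meso", "cold"],
    rows=[
        "MKELDEWFGHKLMNPQRSTV",
        "MKELDEYFGHKLMNAQRSTV",
        "MKTLDAYFGHSLMNAQRSTV",
    ],
)
target = 2
refs = [0, 1]

subs = cold_specific_positions(aln, target, refs)
print(f"identity cold vs thermo: {identity_percent(aln, 2, 0):.0f}%")
print(f"{len(subs)} cold-specific positions out of {aln.n_columns} columns:")
for rec in subs:
    flag = "non-conservative" if rec.non_conservative else "conservative"
    print(
        f"  column {rec.column:2d}: {rec.reference_residues} -> "
        f"{rec.target_residue}  ({rec.label}, {flag})"
    )
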