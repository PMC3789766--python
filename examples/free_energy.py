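"""MM/PBSA-style bookkeeping over the bundled reference summary.

The package ships the published end-point summary for the 10074-A4 /
c-Myc system (two peptide segments x two ligand enantiomers).  This
example recomputes dG = dH - TdS for each row, compares the S and R
enantiomers on the target segment, and converts the free-energy gap into
a binding-affinity ratio.
"""

from ligandcloud import REFERENCE_THERMO, compare, free_energy

print("system                     dH           TdS          dG (derived)")
for (peptide, chirality), rec in REFERENCE_THERMO.items():
    dg = free_energy(rec.dH, rec.TdS)
    print(f"{peptide}/{chirality:1s}         {rec.dH!s:>12} {rec.TdS!s:>12} {dg!s:>12}")

s = REFERENCE_THERMO[("c-Myc_370-409", "S")]
r = REFERENCE_THERMO[("c-Myc_370-409", "R")]
c = compare(s, r, temperature=300.0)
print(f"\nS vs R on the target segment:")
print(f"  ddG = {c.ddG:+.1f} kcal/mol   ddH = {c.ddH:+.1f}   dU = {c.dU:+.1f}")
print(f"  affinity ratio exp(-ddG/kT) = {c.affinity_ratio:.1f}")

cross = compare(s, REFERENCE_THERMO[("c-Myc_410-437", "S")], temperature=300.0)
print(f"\ntarget segment vs negative control (S form): ddG = {cross.ddG:+.1f} kcal/mol")
print("\nA ~2 kcal/mol enantiomer gap makes the S form bind ~40x more often")
print("than the R form; the ~3.4 kcal/mol segment gap is why binding to the")
print("control segment cannot compete with the target site.")
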