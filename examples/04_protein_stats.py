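"""Physicochemical summaries: isoelectric point, molecular weight, gene G+C.

Halophile proteomes are strongly acid-shifted (excess D/E residues keep
proteins soluble in molar salt), so per-class pI averages are a standard
read-out alongside molecular weight and the G+C content of the coding genes.
"""

from panhog.annotation_stats import gene_gc, isoelectric_point, molecular_weight

acidic = "MDEEDLDAEDEGDVEDAEELAEDLGDE"   # halophile-style surface chemistry
basic = "MKRKKLAKRIRKKLRKAKAKAKRAK"

for name, seq in (("acid-shifted protein", acidic), ("basic protein", basic)):
    print(f"{name}: pI {isoelectric_point(seq):.2f}, "
          f"MW {molecular_weight(seq):.2f} kDa")

gene = "ATGGACGAGGAGGACCTCGACGCCGAGGACGAGGGCGACGTCGAG"
print(f"example gene G+C: {gene_gc(gene):.1f}%")
# pI is the pH of zero net charge (bisection on the charge curve with an
# EMBOSS-style pKa set); MW sums average residue masses plus one water
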