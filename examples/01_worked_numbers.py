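"""Back-of-the-envelope chromatin numbers for a diploid mESC nucleus.

The default nucleus model carries the printed constants of the census:
2.5 Gb haploid genome, 186 bp nucleosome repeat length, diploid.
"""
from organelle_census import (
    NucleusModel,
    dna_content,
    expected_satellite_dna,
    theoretical_h4_total,
)

nuc = NucleusModel(nucleus_volume=450.0)

h4 = theoretical_h4_total(nuc)
print(f"theoretical H4 copies per cell : {h4:.3e}  (~54 million)")
print(f"nucleosomes per cell           : {h4 / 2:.3e}")

# one heterochromatin focus holds ~180,000 nucleosomes
mb = dna_content(180_000, nuc) / 1e6
print(f"DNA in one heterochromatin focus: {mb:.1f} Mb; in all 10 foci: {10 * mb:.0f} Mb")
print(f"expected satellite DNA in foci  : {expected_satellite_dna(nuc) / 1e6:.0f} Mb")
print(f"DNA in one Polycomb body        : {dna_content(1400, nuc) / 1e3:.0f} kb")

# Each focus DNA figure converts nucleosome counts to genomic lengths via
# the repeat length; the satellite expectation is an independent estimate
# from genome composition, and the two should agree to tens of percent.
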