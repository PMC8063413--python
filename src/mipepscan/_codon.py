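"""Standard nuclear codon table with '*' for stops.

Built from Biopython's standard table; any codon containing an ambiguous
base (N) translates to 'X'.
"""

from Bio.Data.CodonTable import standard_dna_table

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"
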