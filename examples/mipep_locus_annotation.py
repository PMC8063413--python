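"""Annotate a miPEP-style miORF and apply a premature-stop variant.

Builds a pri-miR surrogate carrying a 71-codon ORF 5' of its pre-miR with
an internal in-frame ATG, selects the candidate miORF, scores its
initiation context, then applies a stop variant at codon 48 and reports
the resulting C-terminal truncation.
"""

from mipepscan import (
    TranscriptRecord, VariantSpec, select_miorf, apply_variant, truncation_report,
)
from mipepscan._codon import CODON_TABLE

AA2CODON = {}
for codon in sorted(CODON_TABLE):
    AA2CODON.setdefault(CODON_TABLE[codon], codon)

# 71-residue peptide; internal Met at codon 15 provides an ATG2; Gln at
# codon 48 (CAA) is one substitution away from a TAA stop.
peptide = "M" + "A" * 13 + "M" + "A" * 32 + "Q" + "A" * 23
orf = "ATG" + "".join(AA2CODON[a] for a in peptide[1:]) + "TAA"
seq = "C" * 30 + orf + "C" * (450 - 30 - len(orf)) + "G" * 80 + "C" * 70
primir = TranscriptRecord("pri_demo", "pri_miR", seq, premir_interval=(450, 530))

cand = select_miorf(primir, min_aa=10)
print(f"candidate miORF: {cand.orf.aa_len} aa at nt {cand.orf.start_nt}"
      f" (frame {cand.orf.frame}), wholly 5' of the pre-miR")
print(f"alternative in-frame starts (rank, aa): {list(cand.alt_starts)}")
print(f"initiation context score = {cand.context_score:.2f}"
      f" (favorable: {cand.context_favorable})")

pos = 30 + 47 * 3  # first base of codon 48
variant = VariantSpec("pri_demo", pos, "C", "T")  # CAA -> TAA premature stop
after = select_miorf(apply_variant(primir, variant), min_aa=10)
report = truncation_report(cand, after)
print(f"after stop variant at codon 48: {after.orf.aa_len} aa"
      f" -> C-terminal truncation of {report['truncation_aa']} aa")
# Mirrors the full-length/truncated peptide arithmetic used when a natural
# polymorphism introduces a premature stop into a miORF.
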