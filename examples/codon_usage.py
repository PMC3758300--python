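"""Codon usage and RSCU from the packaged coconut codon-count table.

RSCU (relative synonymous codon usage) is a codon's count times its
synonymous-family size over the family total; values above 1 mark codons
used more often than expected under equal synonymous usage.
"""

from plastkit import load_fixture
from plastkit.codons import (
    SENSE_CODONS,
    CodonUsageTable,
    round_half_up,
    rscu,
    third_position_at_bias,
)

df = load_fixture("table2")
counts = dict(zip(df["codon_dna"], df["count"]))
table = rscu(CodonUsageTable(counts={c: int(counts.get(c, 0)) for c in SENSE_CODONS}))

print(f"total codons        : {table.total}")
print(f"most prevalent aa   : Leu, {table.aa_totals['L']} codons")
print(f"least prevalent aa  : Cys, {table.aa_totals['C']} codons")
print(f"RSCU(UUU)           : {round_half_up(table.rscu['TTT'])}  (printed 1.23)")
print(f"RSCU(UUC)           : {round_half_up(table.rscu['TTC'])}  (printed 0.77)")
bias = third_position_at_bias(table)
print(f"A/T at 3rd position : {bias:.3f} of synonymous codons — the AT-rich "
      "third-position bias typical of plastomes.")
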