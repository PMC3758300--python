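"""Detect the inverted-repeat pair and quadripartite structure of a plastome.

Builds a seeded synthetic genome with the coconut region dimensions
(LSC 84,230 bp / SSC 17,391 bp / IRs 53,110 bp combined), runs IR
detection, and prints the recovered partition and a junction distance.
"""

from plastkit import (
    GeneAnnotation,
    Interval,
    SyntheticSpec,
    detect_inverted_repeat_pair,
    junction_profile,
    make_quadripartite_genome,
    partition_quadripartite,
)

seq, truth = make_quadripartite_genome(SyntheticSpec(seed=42))
pair = detect_inverted_repeat_pair(seq, min_length=1000)
part = partition_quadripartite(seq, pair)

print(f"genome length : {part.genome_length:>7} bp")
print(f"LSC           : {len(part.lsc):>7} bp")
print(f"IRb + IRa     : {part.ir_length:>7} bp (each {len(part.irb)} bp)")
print(f"SSC           : {len(part.ssc):>7} bp")
print(f"matches truth : {part == truth}")

# a gene ending 84 bp before the LSC/IRb junction, rpl22-style
gene = GeneAnnotation(
    "rpl22", "protein_coding", (Interval(part.lsc.end - 500, part.lsc.end - 84),)
)
(profile,) = junction_profile(part, [gene], ["rpl22"])
print(f"\n{profile.gene} sits {profile.distance} bp from the {profile.junction} "
      "junction (negative would mean it extends across it).")
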