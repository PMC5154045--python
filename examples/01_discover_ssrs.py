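"""Find perfect and compound microsatellites in a DNA sequence.

Builds a small synthetic sequence containing a (GT)8-CA-(GT)7 compound
repeat and a (TCT)4 run, detects all perfect runs, joins nearby runs into
compound loci, and prints the resulting locus table.
"""

from ssrchar import find_perfect_ssrs, merge_compound, simulate_ssr_sequence
from ssrchar.io import loci_to_table

seq, truth = simulate_ssr_sequence(
    [("GT", 8), ("GT", 7), ("TCT", 4)],
    gaps=["CA", "GGCTTAGC"],
    flank_lengths=(40, 40),
    seed=7,
    sequence_id="clone_01",
)

perfect = find_perfect_ssrs(seq)
loci = merge_compound(perfect, seq, max_gap=4)
print(f"sequence length {len(seq)} bp, {len(perfect)} perfect runs detected")
print(loci_to_table(loci).to_string(index=False))
# The (GT)8 and (GT)7 runs sit 2 bp apart, so they merge into one compound
# locus rendered "(GT)8CA(GT)7"; the (TCT)4 run is 8 bp further and stays
# a separate perfect locus.
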