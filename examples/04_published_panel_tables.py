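"""Recompute the published panel summaries from the packaged tables.

The packaged fixtures transcribe the per-locus summary tables of the
original marker panel (the raw band matrix was never published).  This
example recomputes the headline numbers: cross-species transferability
under both locus conventions, private-band summaries, and the per-locus
column means.
"""

from ssrchar import locus_table_means, table_fixtures, transferability

fx = table_fixtures()
print(f"panel: {int(fx.panel_sizes.sum())} genotypes, "
      f"{len(fx.species)} species, {len(fx.all_loci)} loci "
      f"({len(fx.retained_loci)} retained)")
print(f"excluded loci: {', '.join(fx.excluded_loci)}")

print("\ntransferability % (all 25 loci):")
print(transferability(fx.cross_amplification).to_string())
print("\ntransferability % (23 retained loci):")
print(transferability(fx.cross_amplification, fx.retained_loci).to_string())

loci_with = (fx.private_bands > 0).sum(axis=0)
pct = 100.0 * loci_with / len(fx.all_loci)
print("\nloci with private bands (count, % of 25):")
for species in fx.species:
    print(f"  {species:<28} {loci_with[species]:>2}  {pct[species]:5.1f}%")

means = locus_table_means(fx.locus_summary, fx.retained_loci)
print("\nmeans over the 23 retained loci:")
print(f"  bands/locus: focal {means['n_bands_focal']}, "
      f"all species {means['n_bands_all']}")
print(f"  PIC: focal {means['pic_focal']}, all species {means['pic_all']}")
print(f"  DP (focal): {means['dp_focal']}")
# The two transferability conventions differ because the retained-locus
# variant drops the two highest-missing loci; both are legitimate and the
# panel's most transferable species tops both lists.
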