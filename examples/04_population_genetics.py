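"""Presence/absence population genetics on the published genotype table.

Reconstructs the six-population, five-locus genotype table from the printed
frequencies, recomputes per-locus statistics, builds the Nei-distance NJ
tree, and runs a two-level AMOVA between ecotypes.
"""

from sinepop.pipeline import DEFAULT_GROUPING
from sinepop.popgen import (
    amova, ecotype_stats, frequencies_frame, locus_stats, nei_distance, nj_tree,
)
from sinepop.simulate import table1_fixture

table = table1_fixture()
stats = locus_stats(table)
print(f"{'locus':>6} {'pop':>4} {'n':>3} {'f_SINE':>7} {'Het':>5} {'HWE p':>8}")
for s in stats[:8]:
    print(f"{s.locus_id:>6} {s.population_id:>4} {s.n:>3} {s.f_sine:>7.2f} "
          f"{s.het_obs:>5.2f} {s.hwe_p:>8.3f}")
print(f"... ({len(stats)} rows total)")

eco_stats, eco_means = ecotype_stats(table, DEFAULT_GROUPING)
print("\necotype means (f_SINE, Het):", eco_means)

freqs = frequencies_frame(stats)
tree = nj_tree(nei_distance(freqs))
print("\nNJ tree:", tree.to_newick())
print("cherries:", tree.cherries())

res = amova(table, DEFAULT_GROUPING, n_permutations=999, seed=1)
print(f"\nAMOVA: Phi_CT={res.phi_ct:.3f} (p={res.p_phi_ct:.3f}), "
      f"Phi_ST={res.phi_st:.3f} (p={res.p_phi_st:.3f})")
print("variance explained (among groups / among pops / within pops): "
      f"{res.percentages[0]:.1f}% / {res.percentages[1]:.1f}% / {res.percentages[2]:.1f}%")

# f_SINE is the insertion-allele frequency and Het the observed
# heterozygosity; the two resident populations (PY, DT) join as neighbors in
# the tree, and the AMOVA apportions insertion-dosage variance between the
# migratory and resident ecotypes.
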