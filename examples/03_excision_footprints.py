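"""Characterize excision footprints: microsatellite fill and microhomology.

An imperfectly excised SINE leaves a footprint: deleted flank bases, a fill
(here a (TG)45 microsatellite), and a short microhomology copying the
retained 3' junction — the signature of template-switching repair.
"""

from sinepop.excision import call_footprint, summarize_footprints
from sinepop.simulate import SimConfig, make_consensus, plant_clean_excision

consensus = make_consensus(seed=1)
cfg = SimConfig(seed=13)
rng = cfg.rng()

footprints = []
for lid, (unit, copies, mh) in {
    "LsA": ("TG", 45, 8),   # large microsatellite fill, 8-bp microhomology
    "LsB": ("CT", 6, 3),
    "LsC": ("A", 12, 2),
}.items():
    locus, excised, _, _ = plant_clean_excision(
        consensus, cfg, rng, unit, copies, mh, locus_id=lid
    )
    fp = call_footprint(locus, excised)
    footprints.append(fp)
    print(f"{lid}: fill {fp.fill_len:>3} bp, repeat {fp.fill_repeat}, "
          f"microhomology {fp.microhomology_len} bp ({fp.microhomology_seq!r})")

summary = summarize_footprints(footprints)
print()
print(summary.to_string(index=False))
print("aggregates:", {k: v for k, v in summary.attrs.items() if k != "microhomology_distribution"})

# Each footprint recovers the planted fill unit/copies and microhomology
# exactly; the summary aggregates fills and microhomologies across loci.
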