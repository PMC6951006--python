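"""Published summary tables used as pipeline inputs.

The study's printed per-population statistics are data, not results of this
package: the genotype fixture in :mod:`sinepop.simulate` is reconstructed from
them by exact integer arithmetic, and the ecotype aggregate checks average the
printed per-locus values.
"""

from __future__ import annotations

POPULATIONS = ["XS", "CM", "JJ", "TH", "PY", "DT"]
LOCI = ["Ls40", "Ls5", "Ls58", "Ls60", "Ls29"]

#: Migratory (anadromous) vs freshwater-resident sampling sites.  TH is placed
#: with the migratory group by default, matching its position in the published
#: NJ tree; it is reassignable through the AMOVA/popgen grouping config.
ECOTYPE_GROUPS = {
    "migratory": ["XS", "CM", "JJ", "TH"],
    "resident": ["PY", "DT"],
}

#: Per-locus, per-population (f_SINE, observed heterozygosity), n = 10 diploids.
TABLE1 = {
    "Ls40": {"XS": (0.90, 0.20), "CM": (0.65, 0.50), "JJ": (0.50, 0.80),
             "TH": (0.45, 0.30), "PY": (1.00, 0.00), "DT": (1.00, 0.00)},
    "Ls5":  {"XS": (0.60, 0.00), "CM": (0.80, 0.00), "JJ": (0.60, 0.00),
             "TH": (0.50, 0.00), "PY": (0.00, 0.00), "DT": (0.20, 0.00)},
    "Ls58": {"XS": (1.00, 0.00), "CM": (1.00, 0.00), "JJ": (1.00, 0.00),
             "TH": (1.00, 0.00), "PY": (0.10, 0.00), "DT": (0.00, 0.00)},
    "Ls60": {"XS": (0.00, 0.00), "CM": (0.00, 0.00), "JJ": (0.00, 0.00),
             "TH": (0.00, 0.00), "PY": (0.50, 1.00), "DT": (0.50, 1.00)},
    "Ls29": {"XS": (1.00, 0.00), "CM": (1.00, 0.00), "JJ": (1.00, 0.00),
             "TH": (1.00, 0.00), "PY": (0.00, 0.00), "DT": (0.00, 0.00)},
}

#: Printed "Total Pop" column of Table 1: across-population unweighted means,
#: rounded to 2 decimals as published.
TABLE1_TOTAL = {
    "Ls40": (0.75, 0.30),
    "Ls5":  (0.45, 0.00),
    "Ls58": (0.68, 0.00),
    "Ls60": (0.17, 0.33),
    "Ls29": (0.67, 0.00),
}

#: Printed "Mean" row of Table 1: across-locus unweighted means per population.
#: Note: the published CM Het mean reads 0.01 but recomputes to 0.10 from the
#: CM column (0.50/5); the recomputed value is kept here.
TABLE1_MEAN = {
    "XS": (0.70, 0.04), "CM": (0.69, 0.10), "JJ": (0.62, 0.16),
    "TH": (0.59, 0.06), "PY": (0.32, 0.20), "DT": (0.34, 0.20),
    "Total": (0.54, 0.13),
}

#: Published per-locus ecotype values: (f migratory, Het migratory,
#: f resident, Het resident).  These come from the authors' own pooling and are
#: not derivable from TABLE1; they are inputs for the aggregate checks.
TABLE2 = {
    "Ls40": (0.57, 0.65, 1.00, 0.00),
    "Ls5":  (0.70, 0.00, 0.10, 0.00),
    "Ls58": (1.00, 0.00, 0.05, 0.00),
    "Ls60": (0.00, 0.00, 0.50, 1.00),
    "Ls29": (1.00, 0.00, 0.00, 0.00),
}

#: Printed Table 2 "Mean" row: across-locus means for each ecotype.
TABLE2_MEAN = {"migratory": (0.65, 0.13), "resident": (0.33, 0.20)}

#: Published flank tandem repeats: locus -> (flank side, unit, copies, offset
#: from the element junction; negative = upstream of the 5' junction).
TABLE3 = [
    ("Ls2", "5", "G", 38, -76),
    ("Ls61", "5", "A", 17, -1),
    ("Ls11", "5", "TG", 26, -55),
    ("Ls26", "5", "CA", 16, -56),
    ("Ls69", "5", "CA", 14, -48),
    ("Ls29", "5", "CG", 18, -16),
    ("Ls62", "5", "CT", 7, -85),
    ("Ls52", "5", "AAC", 17, -3),
    ("Ls52b", "5", "AAT", 8, -3),
    ("Ls32", "5", "ATTAC", 7, -2),
    ("Ls18", "5", "TTATTTAA", 3, -10),
    ("Ls12", "5", "TTGGACCAGC", 6, -3),
    ("Ls43", "5", "ACTAGGGAACTACCAGGGGG", 14, -8),
    ("Ls44", "3", "GT", 10, 115),
]

#: Published qPCR standard curve: Ct = slope * log10(copies) + intercept.
QPCR_SLOPE = -3.11
QPCR_INTERCEPT = 40.838

#: Average genome size used to normalize copy counts, in picograms.
GENOME_SIZE_PG = 3.534

#: Published mean SINE copy numbers per genome by ecotype.
COPYNUMBER_RESIDENT = 3.5e5
COPYNUMBER_MIGRATORY = 2.3e5

#: Published mean flank AT content (fraction) for the 50-bp windows.
FLANK_AT_5PRIME = 0.566
FLANK_AT_3PRIME = 0.57
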