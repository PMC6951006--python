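"""Seeded generators for every input class the pipeline consumes.

Planted features follow the study conditions: SINE copies at 77-94% identity
to a 208-bp consensus, TSDs of 2-31 nt with the mass on 3-8 nt, tails in the
three motif classes (poly(A), TGTAA, TGTAA-poly(A)), excision alleles with
microsatellite fill and short junction microhomologies, diploid
presence/absence genotype tables, and log-linear Ct dilution series.  Every
planted feature is recorded in a ground-truth row and recoverable by exact
string inspection of the emitted sequences; ambiguous plants (chance longer
duplications, non-unique anchors) are flagged, not silently dropped.

All randomness flows through a single ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from sinepop.io import SequenceRecord, LocusTable
from sinepop.annotate import SineConsensus, CONSENSUS_LEN, TRNA_LEN, TAIL_LEN
from sinepop.forensics import LocusAlleles, TSD_MIN, TSD_MAX
from sinepop import tables

BASES = np.array(list("ACGT"))

#: Concrete pol III promoter boxes planted in the consensus (match the IUPAC
#: consensus motifs with zero mismatches).
A_BOX_SEQ = "TAGCTTAACGAG"
B_BOX_SEQ = "GTTCGAGCC"
A_BOX_POS = 8
B_BOX_POS = 52

TGTAA_BLOCK = "TGTAA" * 5


def _default_tsd_weights() -> dict[int, float]:
    # Mode on 3-8 nt within the observed 2-31 range; the long tail of rare
    # large TSDs carries the remaining mass.
    w = {2: 0.05}
    for k in range(3, 9):
        w[k] = 0.13
    for k in range(9, TSD_MAX + 1):
        w[k] = 0.17 / 23
    return w


@dataclass
class SimConfig:
    """Parameters of a synthetic SINE insertion study."""

    seed: int = 0
    n_loci: int = 71
    n_pops: int = 6
    n_ind_per_pop: int = 10
    identity_range: tuple[float, float] = (0.77, 0.94)
    tsd_length_weights: dict[int, float] = field(default_factory=_default_tsd_weights)
    tail_motif_mix: dict[str, float] = field(
        default_factory=lambda: {"polyA": 0.4, "TGTAA": 0.3, "TGTAA_polyA": 0.3}
    )
    excision_fraction: float = 0.2
    ct_noise_sd: float = 0.2
    flank_len: int = 150
    #: Per-base probability of A and of T in random flanks (0.283 each gives
    #: the observed ~56.6% flank AT content).
    flank_at_prob: float = 0.283

    def __post_init__(self) -> None:
        lo, hi = self.identity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("identity_range must lie within (0, 1]")
        for name, probs in (
            ("tail_motif_mix", self.tail_motif_mix.values()),
            ("tsd_length_weights", self.tsd_length_weights.values()),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if any(k < TSD_MIN or k > TSD_MAX for k in self.tsd_length_weights):
            raise ValueError(f"TSD lengths must lie in [{TSD_MIN}, {TSD_MAX}]")
        for count in (self.n_loci, self.n_pops, self.n_ind_per_pop):
            if count < 1:
                raise ValueError("all counts must be >= 1")
        if not (0 <= self.excision_fraction <= 1):
            raise ValueError("excision_fraction must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class InsertionTruth:
    """Planted features of one insertion locus."""

    locus_id: str
    element_span: tuple[int, int]
    tsd_seq: str
    tsd_len: int
    tail_motif: str
    identity: float          # realized identity by direct base comparison
    body_indel: tuple[str, int] | None
    flank_dup_len: int
    duplication_free: bool   # no chance TSD longer than the planted one


@dataclass
class ExcisionTruth:
    """Planted features of one excision allele."""

    locus_id: str
    fill_unit: str
    fill_copies: int
    fill_len: int
    microhomology_len: int
    left_deletion: int
    clean: bool  # anchors unique and planted fields recoverable exactly


def _random_seq(rng: np.random.Generator, length: int, at_prob: float = 0.25) -> str:
    gc = (1.0 - 2.0 * at_prob) / 2.0
    return "".join(rng.choice(BASES, size=length, p=[at_prob, gc, gc, at_prob]))


def _seq_without(rng: np.random.Generator, length: int, banned: tuple[str, ...]) -> str:
    while True:
        s = _random_seq(rng, length)
        if not any(b in s for b in banned):
            return s


def make_consensus(seed: int) -> SineConsensus:
    """Deterministic 208-bp family consensus.

    The first 75 nt (tRNA-related region) embed exact A- and B-box promoter
    motifs; the last 56 nt (tail) carry exactly five tandem TGTAA copies
    followed by filler free of further TGTAA or poly(A) runs.
    """
    rng = np.random.default_rng(seed)
    trna = list(_seq_without(rng, TRNA_LEN, ("TGTAA",)))
    trna[A_BOX_POS: A_BOX_POS + len(A_BOX_SEQ)] = A_BOX_SEQ
    trna[B_BOX_POS: B_BOX_POS + len(B_BOX_SEQ)] = B_BOX_SEQ
    trna = "".join(trna)
    body_len = CONSENSUS_LEN - TRNA_LEN - TAIL_LEN
    body = _seq_without(rng, body_len, ("TGTAA",))
    filler = _seq_without(rng, TAIL_LEN - len(TGTAA_BLOCK), ("TGTAA", "AAAAA"))
    tail = TGTAA_BLOCK + filler
    # the block must not extend backwards across the body/tail boundary
    if (body + tail).count("TGTAA") != 5:
        body = body[:-1] + ("C" if body[-1] != "C" else "G")
    record = SequenceRecord(id=f"SINE_consensus_seed{seed}", seq=trna + body + tail)
    return SineConsensus(record=record)


def _plant_tail(consensus_tail: str, motif: str) -> str:
    """Rewrite the consensus tail into the requested motif class with the
    fewest substitutions (tails are strongly conserved, so divergence should
    come from the uniform mutation step, not from motif planting)."""
    tail = list(consensus_tail)
    if motif in ("polyA", "TGTAA_polyA"):
        tail[-8:] = "A" * 8  # poly(A) run after (or without) the TGTAA block
    if motif == "polyA":
        # one substitution per TGTAA copy destroys the tandem block
        for k in range(5):
            tail[5 * k + 2] = "C"
    elif motif not in ("TGTAA", "TGTAA_polyA"):
        raise ValueError(f"unknown tail motif {motif!r}")
    return "".join(tail)


def _mutate_to_identity(
    seq: str,
    reference: str,
    target_identity: float,
    rng: np.random.Generator,
    frozen: set[int],
) -> str:
    """Substitute bases (outside ``frozen``) until the identity of ``seq`` to
    ``reference`` reaches the target; mismatches already present (e.g. from a
    rewritten tail motif) count toward the budget."""
    existing = sum(a != b for a, b in zip(seq, reference))
    n_sub = max(0, int(round((1.0 - target_identity) * len(seq))) - existing)
    allowed = [
        i for i in range(len(seq)) if i not in frozen and seq[i] == reference[i]
    ]
    n_sub = min(n_sub, len(allowed))
    positions = rng.choice(len(allowed), size=n_sub, replace=False)
    out = list(seq)
    for k in positions:
        i = allowed[int(k)]
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def plant_insertion(
    consensus: SineConsensus,
    cfg: SimConfig,
    rng: np.random.Generator,
    locus_id: str = "locus",
    tsd_len: int | None = None,
    tail_motif: str | None = None,
    flank_dup_len: int = 0,
    body_indel: tuple[str, int] | None = None,
    max_tries: int = 50,
) -> tuple[LocusAlleles, InsertionTruth]:
    """Plant one SINE insertion with a known TSD, identity and tail motif.

    Emits an empty allele (flanks with a single target-site copy) and a filled
    allele (flanks + TSD + mutated element + TSD).  Flanks are resampled until
    no chance duplication longer than the planted TSD exists; if that fails
    within ``max_tries`` the locus is emitted with ``duplication_free=False``.
    """
    motif = tail_motif or rng.choice(
        list(cfg.tail_motif_mix), p=list(cfg.tail_motif_mix.values())
    )
    if tsd_len is None:
        lengths = sorted(cfg.tsd_length_weights)
        tsd_len = int(
            rng.choice(lengths, p=[cfg.tsd_length_weights[k] for k in lengths])
        )
    if cfg.flank_len < tsd_len:
        raise ValueError(f"flanks of {cfg.flank_len} nt shorter than requested TSD {tsd_len}")

    tail_start = CONSENSUS_LEN - TAIL_LEN
    element = consensus.seq[:tail_start] + _plant_tail(consensus.seq[tail_start:], motif)
    frozen = set(range(tail_start, CONSENSUS_LEN))
    target = rng.uniform(*cfg.identity_range)
    element = _mutate_to_identity(element, consensus.seq, target, rng, frozen)
    identity = _hamming_identity(element, consensus.seq)
    if body_indel is not None:
        kind, length = body_indel
        pos = int(rng.integers(TRNA_LEN + 5, tail_start - 5 - (length if kind == "del" else 0)))
        if kind == "ins":
            element = element[:pos] + _random_seq(rng, length) + element[pos:]
        elif kind == "del":
            element = element[:pos] + element[pos + length:]
        else:
            raise ValueError("body_indel kind must be 'ins' or 'del'")

    duplication_free = False
    for _ in range(max_tries):
        left = _random_seq(rng, cfg.flank_len, cfg.flank_at_prob)
        right = _random_seq(rng, cfg.flank_len, cfg.flank_at_prob)
        tsd = _random_seq(rng, tsd_len, cfg.flank_at_prob)
        left_filled = left
        if flank_dup_len:
            # duplicate a segment of the 5' flank: present twice in the filled
            # allele but once in the empty allele
            start = cfg.flank_len - 2 * flank_dup_len - int(rng.integers(1, 20))
            if start < 1:
                raise ValueError("flank too short for the requested duplication")
            seg = left[start: start + flank_dup_len]
            # the adjacent copies form a 2-copy tandem; resample if chance
            # context would extend the repeat beyond the planted length
            if (
                left[start - 1] == left[start + flank_dup_len - 1]
                or left[start + flank_dup_len] == left[start]
            ):
                continue
            left_filled = left[: start + flank_dup_len] + seg + left[start + flank_dup_len:]
        filled = left_filled + tsd + element + tsd + right
        s = len(left_filled) + tsd_len
        e = s + len(element)
        ok = True
        for k in range(tsd_len + 1, min(TSD_MAX, s, len(filled) - e) + 1):
            if filled[s - k: s] == filled[e: e + k]:
                ok = False
                break
        if ok:
            duplication_free = True
            break
    empty = left + tsd + right
    locus = LocusAlleles(
        locus_id=locus_id,
        filled=SequenceRecord(id=f"{locus_id}.filled", seq=filled),
        element_span=(s, e),
        empty=SequenceRecord(id=f"{locus_id}.empty", seq=empty),
    )
    truth = InsertionTruth(
        locus_id=locus_id,
        element_span=(s, e),
        tsd_seq=tsd,
        tsd_len=tsd_len,
        tail_motif=motif,
        identity=identity,
        body_indel=body_indel,
        flank_dup_len=flank_dup_len,
        duplication_free=duplication_free,
    )
    return locus, truth


def plant_excision(
    filled_locus: LocusAlleles,
    unit: str,
    copies: int,
    microhomology_len: int,
    rng: np.random.Generator,
    left_deletion: int = 0,
    tsd_len: int | None = None,
) -> tuple[SequenceRecord, ExcisionTruth]:
    """Plant an imperfect excision of a previously inserted element.

    The excised allele keeps the left flank (optionally minus
    ``left_deletion`` bases), replaces element plus one TSD copy with a
    microsatellite fill (``unit`` x ``copies``), and appends a copy of the
    first ``microhomology_len`` bases of the retained 3' flank to the fill —
    the template-switch signature.  ``clean`` in the truth row certifies that
    anchors are unique and every planted field is recoverable exactly.
    """
    from sinepop.forensics import call_tsd, find_tandem_repeats

    filled = filled_locus.filled.seq
    s, e = filled_locus.element_span
    if tsd_len is None:
        tsd = call_tsd(filled_locus)
        tsd_len = tsd.length if tsd else 0
    retained = filled[e + tsd_len:]
    if microhomology_len > len(retained):
        raise ValueError("microhomology longer than the retained 3' flank")
    if left_deletion >= s:
        raise ValueError("left deletion removes the whole 5' flank")
    fill = unit * copies + retained[:microhomology_len]
    excised_seq = filled[: s - left_deletion] + fill + retained
    excised = SequenceRecord(id=f"{filled_locus.locus_id}.excised", seq=excised_seq)

    # certify exact recoverability of each planted field
    lcp = 0
    for a, b in zip(filled, excised_seq):
        if a != b:
            break
        lcp += 1
    lcs = 0
    for a, b in zip(reversed(filled), reversed(excised_seq)):
        if a != b:
            break
        lcs += 1
    clean = lcp == s - left_deletion and lcs == len(retained)
    if clean and fill:
        mh = 0
        for m in range(1, min(25, len(fill), len(retained)) + 1):
            if fill[-m:] == retained[:m]:
                mh = m
        clean = mh == microhomology_len
        if clean and copies >= 3 and copies * len(unit) >= 8:
            # the planted array is above the reporting thresholds, so the
            # detector must recover it exactly
            arrays = find_tandem_repeats(fill)
            best = max(arrays, key=lambda c: c.length) if arrays else None
            clean = best is not None and best.unit == unit and best.copies == copies
    truth = ExcisionTruth(
        locus_id=filled_locus.locus_id,
        fill_unit=unit,
        fill_copies=copies,
        fill_len=len(fill),
        microhomology_len=microhomology_len,
        left_deletion=left_deletion,
        clean=clean,
    )
    return excised, truth


def plant_clean_excision(
    consensus: SineConsensus,
    cfg: SimConfig,
    rng: np.random.Generator,
    unit: str,
    copies: int,
    microhomology_len: int,
    locus_id: str = "locus",
    left_deletion: int = 0,
    max_tries: int = 100,
) -> tuple[LocusAlleles, SequenceRecord, InsertionTruth, ExcisionTruth]:
    """Plant insertion + excision loci until every planted field is
    unambiguously recoverable (unique anchors, exact microhomology, exact
    fill array); raises after ``max_tries`` failures."""
    for _ in range(max_tries):
        locus, ins_truth = plant_insertion(consensus, cfg, rng, locus_id=locus_id)
        if not ins_truth.duplication_free:
            continue
        excised, exc_truth = plant_excision(
            locus, unit, copies, microhomology_len, rng, left_deletion=left_deletion
        )
        if exc_truth.clean:
            return locus, excised, ins_truth, exc_truth
    raise RuntimeError(
        f"no ambiguity-free excision plant for unit={unit!r} copies={copies} "
        f"mh={microhomology_len} within {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# genotype tables


def simulate_genotypes(
    freqs_by_pop_locus: dict[str, dict[str, float]],
    n_ind: int,
    rng: np.random.Generator,
) -> LocusTable:
    """Draw diploid genotypes under Hardy-Weinberg sampling.

    Each individual draws two insertion alleles binomially at the stated
    frequency; genotypes are II/IA/AA.
    """
    rows = []
    for pop in sorted(freqs_by_pop_locus):
        for locus in sorted(freqs_by_pop_locus[pop]):
            f = freqs_by_pop_locus[pop][locus]
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency {f} outside [0, 1]")
            dosage = rng.binomial(2, f, size=n_ind)
            for i, d in enumerate(dosage, start=1):
                rows.append(
                    {
                        "locus_id": locus,
                        "population_id": pop,
                        "individual_id": f"{pop}_{i:02d}",
                        "genotype": {2: "II", 1: "IA", 0: "AA"}[int(d)],
                    }
                )
    return LocusTable(pd.DataFrame(rows))


def table1_fixture() -> LocusTable:
    """Deterministic genotype table reproducing the published per-population
    insertion frequencies and heterozygosities exactly.

    For each (locus, population) cell with printed (f, Het) and n = 10
    diploids, the genotype counts are reconstructed by exact integer
    arithmetic: het = round(Het*n), n_II = round(f*n - het/2),
    n_AA = n - n_II - het, then validated against the printed values.  No
    sampling is involved.
    """
    n = 10
    rows = []
    for locus, by_pop in tables.TABLE1.items():
        for pop in tables.POPULATIONS:
            f, het_frac = by_pop[pop]
            het = round(het_frac * n)
            n_ii = round(f * n - het / 2)
            n_aa = n - n_ii - het
            if min(n_ii, het, n_aa) < 0 or round((2 * n_ii + het) / (2 * n), 2) != round(
                f, 2
            ) or round(het / n, 2) != round(het_frac, 2):
                raise ValueError(
                    f"cell {pop}/{locus}: printed (f={f}, Het={het_frac}) not representable "
                    f"with n={n} diploids"
                )
            genotypes = ["II"] * n_ii + ["IA"] * het + ["AA"] * n_aa
            for i, g in enumerate(genotypes, start=1):
                rows.append(
                    {
                        "locus_id": locus,
                        "population_id": pop,
                        "individual_id": f"{pop}_{i:02d}",
                        "genotype": g,
                    }
                )
    return LocusTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# qPCR plates and transcripts


def simulate_qpcr(
    true_log10_copies_list: list[float],
    slope: float,
    intercept: float,
    noise_sd: float,
    rng: np.random.Generator,
    n_replicates: int = 1,
    role: str = "standard",
    sample_ids: list[str] | None = None,
    input_mass_pg: float = 1.0,
) -> pd.DataFrame:
    """Simulate qPCR wells: Ct = slope*log10(copies) + intercept + noise.

    Returns a plate frame with columns sample_id, role, log10_copies, ct,
    input_mass_pg; dilution-series wells carry role ``standard``.
    """
    if slope >= 0:
        raise ValueError("slope must be negative")
    if any(not np.isfinite(x) for x in true_log10_copies_list):
        raise ValueError("log10 copy numbers must be finite (copies must be positive)")
    if input_mass_pg <= 0:
        raise ValueError("input mass must be positive")
    rows = []
    for idx, x in enumerate(true_log10_copies_list):
        sid = sample_ids[idx] if sample_ids else f"{role}_{idx + 1:02d}"
        for _ in range(n_replicates):
            ct = slope * x + intercept + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            rows.append(
                {
                    "sample_id": sid,
                    "role": role,
                    "log10_copies": x if role == "standard" else np.nan,
                    "ct": ct,
                    "input_mass_pg": input_mass_pg,
                }
            )
    return pd.DataFrame(rows)


def simulate_transcripts(
    consensus: SineConsensus,
    n_full: int,
    n_partial_by_region: dict[str, int] | None,
    rng: np.random.Generator,
) -> tuple[list[SequenceRecord], dict]:
    """Assembled-transcript contigs embedding full or single-region SINE copies.

    Each contig is a planted copy inside random sequence, on a random strand.
    Returns (contigs, planted counts).
    """
    from sinepop.io import revcomp

    n_partial_by_region = n_partial_by_region or {}
    contigs = []
    planted = {"full": n_full, **{k: int(v) for k, v in n_partial_by_region.items()}}
    jobs = [("full", consensus.seq)] * n_full
    for region, count in n_partial_by_region.items():
        lo, hi = consensus.regions[region]
        jobs.extend([(region, consensus.seq[lo:hi])] * count)
    for idx, (kind, insert) in enumerate(jobs):
        if rng.random() < 0.5:
            insert = revcomp(insert)
        lead = _random_seq(rng, int(rng.integers(50, 150)))
        trail = _random_seq(rng, int(rng.integers(50, 150)))
        contigs.append(
            SequenceRecord(id=f"contig_{idx + 1:03d}_{kind}", seq=lead + insert + trail)
        )
    # decoy contigs with no SINE content
    for j in range(3):
        contigs.append(
            SequenceRecord(id=f"contig_decoy_{j + 1}", seq=_random_seq(rng, int(rng.integers(200, 400))))
        )
    order = rng.permutation(len(contigs))
    return [contigs[i] for i in order], planted


def truth_frame(truths: list) -> pd.DataFrame:
    """Ground-truth rows as a flat DataFrame (for the ground-truth TSV)."""
    return pd.DataFrame([asdict(t) for t in truths])
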