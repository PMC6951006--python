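"""Annotation of candidate SINE copies against the family consensus.

The family consensus is a 208-bp tRNA-derived SINE with three regions: a
75-bp tRNA-related region carrying the pol III internal promoter (A and B
boxes), a body region, and a 56-bp LINE-like tail ending in tandem TGTAA
repeats.  Annotation covers identity gating (family membership at >= 76% body
identity), projection of region boundaries onto each element, tail motif
classification, promoter box scanning, a max-pairing hairpin fold of the tail,
and region-wise transcript hit counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sinepop._align import Alignment, needleman_wunsch, smith_waterman
from sinepop.io import SequenceRecord, revcomp

TRNA_LEN = 75
TAIL_LEN = 56
CONSENSUS_LEN = 208
#: Body span on the consensus; the 2 nt the published region lengths leave
#: unaccounted (75 + 75 + 56 = 206 < 208) are assigned to the body.
BODY_SPAN = (TRNA_LEN, CONSENSUS_LEN - TAIL_LEN)

FAMILY_BODY_IDENTITY = 0.76

#: Canonical pol III internal promoter motifs (IUPAC).
A_BOX = "TRGCNNARYNNG"
B_BOX = "GWTCRANNC"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Local-alignment scores for transcript surveys (blastn-like), so that a
#: well-matched single-region hit (56-75 bp) can clear the published
#: score > 80 gate.
SURVEY_MATCH, SURVEY_MISMATCH, SURVEY_GAP = 2, -3, -5
SURVEY_SCORE_GATE = 80.0
SURVEY_COVER_FRACTION = 0.9


class NonFamilyError(ValueError):
    """Element rejected: too diverged from the consensus to annotate."""


@dataclass(frozen=True)
class SineConsensus:
    """The family consensus sequence and its fixed region boundaries."""

    record: SequenceRecord

    def __post_init__(self) -> None:
        if len(self.record) != CONSENSUS_LEN:
            raise ValueError(f"consensus must be {CONSENSUS_LEN} bp, got {len(self.record)}")

    @property
    def trna_span(self) -> tuple[int, int]:
        return (0, TRNA_LEN)

    @property
    def body_span(self) -> tuple[int, int]:
        return BODY_SPAN

    @property
    def tail_span(self) -> tuple[int, int]:
        return (CONSENSUS_LEN - TAIL_LEN, CONSENSUS_LEN)

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        return {"trna": self.trna_span, "body": self.body_span, "tail": self.tail_span}

    @property
    def seq(self) -> str:
        return self.record.seq


@dataclass
class SineAnnotation:
    element_id: str
    percent_identity: float
    body_identity: float
    region_spans: dict[str, tuple[int, int]]
    tail_motif: str
    tgtaa_copies: int
    body_indels: list[tuple[tuple[int, int], str]]
    family_member: bool


@dataclass
class HairpinCall:
    """The longest helical stem of a max-pairing nested fold."""

    stem_length: int
    loop_span: tuple[int, int]
    pairs: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class RegionHitCounts:
    n_full_length: int = 0
    hits_per_region: dict[str, int] = field(
        default_factory=lambda: {"trna": 0, "body": 0, "tail": 0}
    )


def align_global(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[Alignment, float]:
    """Needleman-Wunsch alignment; returns (alignment, percent identity).

    Identity is matches over alignment columns; traceback ties resolve
    diagonal, then up, then left, so results are deterministic.
    """
    aln = needleman_wunsch(a, b, match, mismatch, gap)
    return aln, aln.identity


def align_local(
    a: str, b: str, match: int = SURVEY_MATCH, mismatch: int = SURVEY_MISMATCH,
    gap: int = SURVEY_GAP,
) -> Alignment:
    """Smith-Waterman local alignment with the survey scoring scheme."""
    return smith_waterman(a, b, match, mismatch, gap)


def _project_boundary(pairs: list[tuple[int | None, int | None]], cons_pos: int) -> int:
    """Element coordinate where the alignment first reaches consensus position cons_pos."""
    last_elem = 0
    for ci, ei in pairs:
        if ci is not None and ci >= cons_pos:
            return last_elem if ei is None else ei
        if ei is not None:
            last_elem = ei + 1
    return last_elem


def annotate_element(element: SequenceRecord, consensus: SineConsensus) -> SineAnnotation:
    """Annotate one candidate copy: identity, projected regions, tail class, indels.

    Raises :class:`NonFamilyError` when overall identity to the consensus falls
    below 0.5 — such sequences cannot be meaningfully decomposed.
    """
    if len(element) < 100:
        raise ValueError(f"element {element.id}: shorter than 100 nt")
    aln, identity = align_global(consensus.seq, element.seq)
    if identity < 0.5:
        raise NonFamilyError(
            f"element {element.id}: identity {identity:.2f} to consensus is below 0.5"
        )
    pairs = aln.column_pairs()
    spans = {}
    for name, (lo, hi) in consensus.regions.items():
        spans[name] = (_project_boundary(pairs, lo), _project_boundary(pairs, hi))

    body_lo, body_hi = consensus.body_span
    body_matches = body_cols = 0
    # (column index, kind, element position) for every gap column in the body
    gap_cols: list[tuple[int, str, int]] = []
    inside_body = False
    last_elem = 0
    for col, ((ci, ei), (ca, cb)) in enumerate(zip(pairs, zip(aln.a_aln, aln.b_aln))):
        if ci is not None:
            inside_body = body_lo <= ci < body_hi
        if inside_body:
            body_cols += 1
            if ca != "-" and cb != "-" and ca == cb and ca != "N":
                body_matches += 1
            if ca == "-":
                gap_cols.append((col, "ins", ei))
            elif cb == "-":
                gap_cols.append((col, "del", last_elem + 1))
        if ei is not None:
            last_elem = ei
    # With a linear gap cost, co-optimal alignments may scatter one long
    # indel into nearby runs; same-kind runs separated by <= 3 aligned
    # columns are merged, and the reported length is the gap-column total.
    indels: list[tuple[tuple[int, int], str]] = []
    cluster: list[tuple[int, str, int]] = []

    def flush() -> None:
        if cluster and len(cluster) >= 3:
            kind = cluster[0][1]
            start = cluster[0][2]
            indels.append(((start, start + len(cluster)), kind))

    for item in gap_cols:
        if cluster and (item[1] != cluster[-1][1] or item[0] - cluster[-1][0] > 4):
            flush()
            cluster = []
        cluster.append(item)
    flush()

    body_identity = body_matches / body_cols if body_cols else 0.0
    tail = element.seq[spans["tail"][0]: spans["tail"][1]]
    if len(tail) >= 10:
        motif, copies = classify_tail(tail)
    else:
        motif, copies = "none", 0
    return SineAnnotation(
        element_id=element.id,
        percent_identity=identity,
        body_identity=body_identity,
        region_spans=spans,
        tail_motif=motif,
        tgtaa_copies=copies,
        body_indels=indels,
        family_member=body_identity >= FAMILY_BODY_IDENTITY,
    )


def classify_tail(tail: str) -> tuple[str, int]:
    """Classify a 3' tail into {polyA, TGTAA, TGTAA_polyA, none}.

    TGTAA copies count the maximal tandem (non-overlapping, adjacent) run;
    poly(A) requires a run of >= 5 A's at or after the last copy of that run
    (anywhere if no TGTAA).
    """
    if len(tail) < 10:
        raise ValueError("tail shorter than 10 nt")
    best_copies = 0
    best_end = 0
    for start in range(len(tail) - 4):
        k = 0
        while tail[start + 5 * k: start + 5 * (k + 1)] == "TGTAA":
            k += 1
        if k > best_copies:
            best_copies = k
            best_end = start + 5 * k
    search_from = best_end if best_copies else 0
    has_polya = "AAAAA" in tail[search_from:]
    if best_copies and has_polya:
        return "TGTAA_polyA", best_copies
    if best_copies:
        return "TGTAA", best_copies
    if has_polya:
        return "polyA", 0
    return "none", 0


def _iupac_mismatches(seq: str, pattern: str) -> int:
    mm = 0
    for s, p in zip(seq, pattern):
        if s == "N" or s not in _IUPAC[p]:
            mm += 1
    return mm


def _best_box(region: str, pattern: str, lo: int, hi: int, max_mm: int = 2):
    """Best (fewest mismatches, then leftmost) hit with start in [lo, hi)."""
    best = None
    for start in range(lo, min(hi, len(region) - len(pattern) + 1)):
        mm = _iupac_mismatches(region[start: start + len(pattern)], pattern)
        if mm <= max_mm and (best is None or mm < best[2]):
            best = (start, start + len(pattern), mm)
    return best


def scan_ab_boxes(trna_region: str) -> list[tuple[str, tuple[int, int], int]]:
    """Scan for the pol III A-box and B-box promoter motifs (<= 2 mismatches).

    The A-box is only reported when it starts within the first 40 nt; the
    B-box only downstream of the A-box.  Returns [(box, span, mismatches)].
    """
    if len(trna_region) < 50:
        raise ValueError("tRNA-related region shorter than 50 nt")
    hits = []
    a_hit = _best_box(trna_region, A_BOX, 0, 40)
    b_from = 0
    if a_hit:
        hits.append(("A", (a_hit[0], a_hit[1]), a_hit[2]))
        b_from = a_hit[1]
    b_hit = _best_box(trna_region, B_BOX, b_from, len(trna_region))
    if b_hit:
        hits.append(("B", (b_hit[0], b_hit[1]), b_hit[2]))
    return hits


MIN_LOOP = 3


def _can_pair(x: str, y: str, wobble: bool) -> bool:
    pair = {x, y}
    if pair == {"A", "T"} or pair == {"G", "C"}:
        return True
    return wobble and pair == {"G", "T"}


def fold_hairpin(tail: str, wobble: bool = True) -> HairpinCall:
    """Maximum-pairing nested fold (Nussinov) of a tail sequence.

    Pairs score 1 each (A-T, G-C and, when ``wobble``, G-T); hairpin loops are
    at least ``MIN_LOOP`` nt.  The call reports the single longest helical
    stem (maximal run of stacked pairs) and its loop.  Traceback is
    deterministic: the outermost pair is taken whenever it is optimal.
    This is a combinatorial proxy for thermodynamic folding: adequate for
    comparing stem-loop potential of SINE and LINE tails, not for energies.
    """
    n = len(tail)
    if not (10 <= n <= 400):
        raise ValueError("fold_hairpin accepts sequences of 10-400 nt")
    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            pairable[i, j] = _can_pair(tail[i], tail[j], wobble)
    M = np.zeros((n, n), dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]
            if pairable[i, j]:
                inner = M[i + 1, j - 1] if j - 1 >= i + 1 else 0
                best = max(best, inner + 1)
            # bifurcation / leaving j unpaired
            ks = np.arange(i, j)
            best = max(best, int(np.max(M[i, ks] + M[ks + 1, j])))
            M[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or M[i, j] == 0:
            continue
        inner = M[i + 1, j - 1] if j - 1 >= i + 1 else 0
        if pairable[i, j] and M[i, j] == inner + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        elif M[i, j] == M[i + 1, j]:
            stack.append((i + 1, j))
        elif M[i, j] == M[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i, j):
                if M[i, k] + M[k + 1, j] == M[i, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break

    pairs.sort()
    if not pairs:
        return HairpinCall(stem_length=0, loop_span=(0, 0), pairs=[])
    # longest run of stacked pairs (i, j), (i+1, j-1), ...
    best_run: list[tuple[int, int]] = []
    run: list[tuple[int, int]] = []
    pair_set = set(pairs)
    for p in pairs:
        if run and (run[-1][0] + 1, run[-1][1] - 1) == p:
            run.append(p)
        else:
            run = [p]
        if len(run) > len(best_run):
            best_run = list(run)
    del pair_set
    inner_i, inner_j = best_run[-1]
    return HairpinCall(
        stem_length=len(best_run),
        loop_span=(inner_i + 1, inner_j),
        pairs=pairs,
    )


def survey_transcripts(
    contigs: list[SequenceRecord], consensus: SineConsensus
) -> RegionHitCounts:
    """Count region-wise consensus hits in assembled transcript contigs.

    Each contig is locally aligned to the consensus on both strands; the best
    alignment counts as a hit when its score exceeds the survey gate (> 80).
    A hit increments every region whose consensus span is covered >= 90% by
    the aligned consensus interval; a hit covering all three regions counts as
    one full-length transcript copy.
    """
    counts = RegionHitCounts()
    for contig in contigs:
        fwd = align_local(consensus.seq, contig.seq)
        rev = align_local(consensus.seq, revcomp(contig.seq))
        aln = fwd if fwd.score >= rev.score else rev
        if aln.score <= SURVEY_SCORE_GATE:
            continue
        lo, hi = aln.a_span
        covered = []
        for name, (rlo, rhi) in consensus.regions.items():
            overlap = max(0, min(hi, rhi) - max(lo, rlo))
            if overlap >= SURVEY_COVER_FRACTION * (rhi - rlo):
                covered.append(name)
        for name in covered:
            counts.hits_per_region[name] += 1
        if len(covered) == 3:
            counts.n_full_length += 1
    return counts
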