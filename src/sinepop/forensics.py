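"""Insertion forensics: TSDs, insertion-generated flank duplications,
tandem repeats, and flank base composition.

A locus is represented by its insertion-bearing (filled) allele, an optional
insertion-free (empty) allele, and the element span on the filled allele.
The TSD convention is that both copies of the duplicated target site lie
outside the element span: the left copy ends at the span start, the right
copy begins at the span end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from sinepop.io import SequenceRecord

TSD_MIN, TSD_MAX = 2, 31
FLANK_WINDOW = 50

TR_MAX_UNIT = 20
TR_MIN_COPIES = 3
TR_MIN_LEN = 8


@dataclass
class LocusAlleles:
    """Filled and (optionally) empty alleles at one insertion locus."""

    locus_id: str
    filled: SequenceRecord
    element_span: tuple[int, int]
    empty: SequenceRecord | None = None

    def __post_init__(self) -> None:
        s, e = self.element_span
        if not (0 <= s < e <= len(self.filled)):
            raise ValueError(
                f"{self.locus_id}: element span [{s}, {e}) outside filled allele"
            )

    @property
    def element_seq(self) -> str:
        s, e = self.element_span
        return self.filled.seq[s:e]


@dataclass(frozen=True)
class TsdCall:
    length: int
    sequence: str
    left_span: tuple[int, int]
    right_span: tuple[int, int]


@dataclass(frozen=True)
class TandemRepeatCall:
    """A maximal tandem array of a primitive unit; copies may be fractional
    when the last copy is partial (at least half a unit)."""

    unit: str
    copies: float
    span: tuple[int, int]
    offset: int | None = None
    flank: str | None = None

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class FlankComposition:
    """AT content of the 50-bp windows flanking each element (TSD excluded)."""

    at_5prime: list[float]
    at_3prime: list[float]
    mean_5prime: float
    mean_3prime: float
    t_5prime: float
    p_5prime: float
    t_3prime: float
    p_3prime: float
    short_windows: list[str] = field(default_factory=list)


def call_tsd(locus: LocusAlleles) -> TsdCall | None:
    """Longest exact target-site duplication flanking the element (2-31 nt).

    Returns the longest k with ``filled[s-k:s] == filled[e:e+k]`` (N never
    matches); ``None`` when no such k exists or the element touches a
    sequence end.
    """
    s, e = locus.element_span
    seq = locus.filled.seq
    if s < TSD_MIN or len(seq) - e < TSD_MIN:
        return None
    best = None
    for k in range(TSD_MIN, min(TSD_MAX, s, len(seq) - e) + 1):
        left = seq[s - k: s]
        right = seq[e: e + k]
        if left == right and "N" not in left:
            best = k
    if best is None:
        return None
    return TsdCall(
        length=best,
        sequence=seq[s - best: s],
        left_span=(s - best, s),
        right_span=(e, e + best),
    )


def _substring_census(window: str, length: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(window) - length + 1):
        sub = window[i: i + length]
        if "N" not in sub:
            counts[sub] = counts.get(sub, 0) + 1
    return counts


def _align_offsets(locus: LocusAlleles) -> tuple[int, int]:
    """(prefix, suffix) lengths shared verbatim by filled and empty alleles,
    capped so they do not cross the element."""
    s, e = locus.element_span
    filled, empty = locus.filled.seq, locus.empty.seq
    lcp = 0
    for a, b in zip(filled, empty):
        if a != b:
            break
        lcp += 1
    lcp = min(lcp, s)
    lcs = 0
    for a, b in zip(reversed(filled), reversed(empty)):
        if a != b:
            break
        lcs += 1
    lcs = min(lcs, len(filled) - e, len(empty) - lcp)
    return lcp, lcs


def find_flank_duplications(
    locus: LocusAlleles, min_len: int = 10, window: int = 100
) -> list[tuple[tuple[int, int], tuple[int, int], int]]:
    """Insertion-generated repeats near the junctions.

    Compares ``window``-nt segments on each side of the insertion junction
    between the filled and empty alleles and reports maximal exact segments of
    length >= ``min_len`` that are repeats in the filled window (occur at
    least twice there) and occur more often than in the corresponding
    empty-allele window — i.e. repeats the insertion created.  Each report
    gives the segment's span in the filled allele, its span in the empty
    allele (first occurrence; (-1, -1) if absent), and its length, sorted by
    length descending.
    """
    if locus.empty is None:
        raise ValueError(f"{locus.locus_id}: empty allele required")
    s, e = locus.element_span
    filled, empty = locus.filled.seq, locus.empty.seq
    p, lcs = _align_offsets(locus)
    windows = [
        # (filled window start, empty window start, length)
        (max(0, s - window), max(0, p - window), min(window, s, p)),
        (len(filled) - lcs, len(empty) - lcs, min(window, lcs)),
    ]
    found: list[tuple[tuple[int, int], tuple[int, int], int]] = []
    claimed: list[tuple[int, int]] = []
    for fw_start, ew_start, wlen in windows:
        if wlen < min_len:
            continue
        fw = filled[fw_start: fw_start + wlen]
        ew = empty[ew_start: ew_start + wlen]
        for length in range(wlen, min_len - 1, -1):
            fc = _substring_census(fw, length)
            ec = _substring_census(ew, length)
            for sub, n_f in sorted(fc.items()):
                if n_f < 2 or n_f <= ec.get(sub, 0):
                    continue
                pos = fw.find(sub)
                f_span = (fw_start + pos, fw_start + pos + length)
                if any(f_span[0] >= a and f_span[1] <= b for a, b in claimed):
                    continue  # inside a longer reported segment
                ep = ew.find(sub)
                e_span = (ew_start + ep, ew_start + ep + length) if ep >= 0 else (-1, -1)
                found.append((f_span, e_span, length))
                claimed.append(f_span)
    found.sort(key=lambda x: (-x[2], x[0]))
    return found


def _primitive(unit: str) -> bool:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return False
    return True


def find_tandem_repeats(seq: str) -> list[TandemRepeatCall]:
    """All maximal tandem arrays of primitive units (1-20 nt).

    Arrays need >= 3 copies and >= 8 nt total; a trailing partial copy counts
    only when it is at least half a unit.  Overlapping arrays collapse to the
    longest one (ties: smallest unit, then leftmost).
    """
    n = len(seq)
    candidates: list[TandemRepeatCall] = []
    for u in range(1, min(TR_MAX_UNIT, n // 2) + 1):
        i = 0
        while i + 2 * u <= n:
            unit = seq[i: i + u]
            if "N" in unit or not _primitive(unit):
                i += 1
                continue
            # maximality on the left: the array must not extend backwards
            if i > 0 and i + u - 1 < n and seq[i - 1] == seq[i - 1 + u] and seq[i - 1] != "N":
                i += 1
                continue
            j = i + u
            while j < n and seq[j] == seq[j - u] and seq[j] != "N":
                j += 1
            run = j - i
            partial = run % u
            if partial * 2 < u:
                run -= partial  # drop a partial copy shorter than half a unit
            copies = run / u
            if copies >= TR_MIN_COPIES and run >= TR_MIN_LEN:
                candidates.append(
                    TandemRepeatCall(unit=unit, copies=copies, span=(i, i + run))
                )
            i = i + 1
    candidates.sort(key=lambda c: (-c.length, len(c.unit), c.span[0]))
    accepted: list[TandemRepeatCall] = []
    for cand in candidates:
        if all(cand.span[1] <= a.span[0] or cand.span[0] >= a.span[1] for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda c: c.span[0])
    return accepted


def flank_tandem_repeats(
    locus: LocusAlleles, window: int = 100
) -> list[TandemRepeatCall]:
    """Tandem repeats in the element's flanks, with signed junction offsets.

    Offsets are negative upstream of the 5' junction (array start relative to
    the element start) and positive downstream of the 3' junction (array start
    relative to the element end).
    """
    s, e = locus.element_span
    seq = locus.filled.seq
    calls: list[TandemRepeatCall] = []
    lo = max(0, s - window)
    for c in find_tandem_repeats(seq[lo:s]):
        start = lo + c.span[0]
        calls.append(
            TandemRepeatCall(
                unit=c.unit, copies=c.copies,
                span=(start, start + c.length),
                offset=start - s, flank="5",
            )
        )
    hi = min(len(seq), e + window)
    for c in find_tandem_repeats(seq[e:hi]):
        start = e + c.span[0]
        calls.append(
            TandemRepeatCall(
                unit=c.unit, copies=c.copies,
                span=(start, start + c.length),
                offset=start - e, flank="3",
            )
        )
    return calls


def _one_sample_t(values: np.ndarray, popmean: float) -> tuple[float, float]:
    if np.allclose(values.std(ddof=1), 0.0):
        if np.isclose(values.mean(), popmean):
            return 0.0, 1.0  # degenerate: no variance, mean on target
        return np.inf if values.mean() > popmean else -np.inf, 0.0
    t, p = stats.ttest_1samp(values, popmean)
    return float(t), float(p)


def flank_composition(loci: list[LocusAlleles]) -> FlankComposition:
    """AT content of the 50-bp windows immediately flanking each element.

    The TSD copies (when called) are excluded from the windows.  A one-sample
    two-sided t-test against 0.5 is run per side across loci.
    """
    if len(loci) < 2:
        raise ValueError("flank_composition needs at least 2 loci")
    at5, at3, short = [], [], []
    for locus in loci:
        s, e = locus.element_span
        seq = locus.filled.seq
        tsd = call_tsd(locus)
        k = tsd.length if tsd else 0
        w5 = seq[max(0, s - k - FLANK_WINDOW): s - k]
        w3 = seq[e + k: e + k + FLANK_WINDOW]
        for side, w in (("5", w5), ("3", w3)):
            if 0 < len(w) < FLANK_WINDOW:
                short.append(f"{locus.locus_id}:{side}")
        if w5:
            at5.append(sum(c in "AT" for c in w5) / len(w5))
        if w3:
            at3.append(sum(c in "AT" for c in w3) / len(w3))
    a5 = np.asarray(at5, dtype=float)
    a3 = np.asarray(at3, dtype=float)
    t5, p5 = _one_sample_t(a5, 0.5)
    t3, p3 = _one_sample_t(a3, 0.5)
    return FlankComposition(
        at_5prime=at5, at_3prime=at3,
        mean_5prime=float(a5.mean()), mean_3prime=float(a3.mean()),
        t_5prime=t5, p_5prime=p5, t_3prime=t3, p_3prime=p3,
        short_windows=short,
    )
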