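"""Insertion forensics: TSDs, flank duplications, tandem repeats, composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sinepop.forensics import (
    LocusAlleles,
    TandemRepeatCall,
    call_tsd,
    find_flank_duplications,
    find_tandem_repeats,
    flank_composition,
    flank_tandem_repeats,
)
from sinepop.io import SequenceRecord, revcomp
from sinepop.simulate import SimConfig, plant_insertion


def _locus(filled: str, span, empty: str | None = None, lid="L") -> LocusAlleles:
    return LocusAlleles(
        locus_id=lid,
        filled=SequenceRecord(id=f"{lid}.filled", seq=filled),
        element_span=span,
        empty=SequenceRecord(id=f"{lid}.empty", seq=empty) if empty else None,
    )


def brute_force_tsd(filled: str, s: int, e: int) -> int:
    best = 0
    for k in range(2, 32):
        if k <= s and e + k <= len(filled):
            if filled[s - k: s] == filled[e: e + k] and "N" not in filled[s - k: s]:
                best = k
    return best


# --- TSD calls ---------------------------------------------------------------


def test_tgt_style_tsd_called():
    # flank + TGT + element + TGT + flank, flanks free of longer duplication
    filled = "CCCCCCCCGG" + "TGT" + "AAAAAAAAAA" + "TGT" + "GGCCCCCCCC"
    locus = _locus(filled, (13, 23))
    call = call_tsd(locus)
    assert call is not None
    assert call.length == 3
    assert call.sequence == "TGT"
    assert call.left_span == (10, 13)
    assert call.right_span == (23, 26)


def test_no_duplication_returns_none():
    filled = "ACGTACGTAC" + "GGGGGGGGGG" + "TTCCTTCCAA"
    assert call_tsd(_locus(filled, (10, 20))) is None


def test_element_at_sequence_end_returns_none():
    assert call_tsd(_locus("ACGTACGT", (0, 4))) is None


def test_tsd_recovery_on_planted_loci(consensus):
    cfg = SimConfig(seed=31)
    rng = cfg.rng()
    for i in range(100):
        locus, truth = plant_insertion(consensus, cfg, rng, locus_id=f"L{i}")
        call = call_tsd(locus)
        s, e = locus.element_span
        if truth.duplication_free:
            assert call is not None and call.length == truth.tsd_len
            assert call.sequence == truth.tsd_seq
        else:  # certified: a longer chance duplication exists
            assert call.length == brute_force_tsd(locus.filled.seq, s, e)


def test_tsd_invariant_under_reverse_complement(consensus):
    cfg = SimConfig(seed=32)
    rng = cfg.rng()
    for i in range(20):
        locus, truth = plant_insertion(consensus, cfg, rng, locus_id=f"L{i}")
        n = len(locus.filled)
        s, e = locus.element_span
        rc = _locus(revcomp(locus.filled.seq), (n - e, n - s), lid=f"rc{i}")
        a, b = call_tsd(locus), call_tsd(rc)
        assert (a is None) == (b is None)
        if a is not None:
            assert a.length == b.length
            assert b.sequence == revcomp(a.sequence)


# --- insertion-generated flank duplications ---------------------------------


def brute_force_duplications(locus: LocusAlleles, min_len=10, window=100):
    """Quadratic census oracle: longest segments repeated in the filled
    window in excess of the empty window, not contained in a longer hit."""
    from sinepop.forensics import _align_offsets

    s, e = locus.element_span
    filled, empty = locus.filled.seq, locus.empty.seq
    p, lcs = _align_offsets(locus)
    results = []
    wins = [
        (max(0, s - window), max(0, p - window), min(window, s, p)),
        (len(filled) - lcs, len(empty) - lcs, min(window, lcs)),
    ]
    for fs, es, wl in wins:
        fw, ew = filled[fs: fs + wl], empty[es: es + wl]
        hits = []
        for length in range(wl, min_len - 1, -1):
            for i in range(wl - length + 1):
                sub = fw[i: i + length]
                if "N" in sub:
                    continue
                n_f = sum(fw[j: j + length] == sub for j in range(wl - length + 1))
                n_e = sum(ew[j: j + length] == sub for j in range(wl - length + 1))
                if n_f >= 2 and n_f > n_e:
                    span = (fs + fw.find(sub), fs + fw.find(sub) + length)
                    if not any(span[0] >= a and span[1] <= b for a, b in hits):
                        hits.append(span)
                        results.append((span, length))
    return sorted(results, key=lambda x: (-x[1], x[0]))


def test_planted_17bp_duplication_called(consensus):
    cfg = SimConfig(seed=33)
    rng = cfg.rng()
    locus, truth = plant_insertion(consensus, cfg, rng, flank_dup_len=17)
    calls = find_flank_duplications(locus)
    assert calls[0][2] == 17


def test_no_duplications_when_filled_equals_empty_outside_element(consensus):
    cfg = SimConfig(seed=34)
    rng = cfg.rng()
    locus, truth = plant_insertion(consensus, cfg, rng)
    assert truth.duplication_free
    assert find_flank_duplications(locus) == []


def test_duplication_calls_match_census_oracle(consensus):
    rng_top = np.random.default_rng(35)
    for rep in range(30):
        cfg = SimConfig(seed=int(rng_top.integers(0, 2**31)))
        rng = cfg.rng()
        dup = int(rng.integers(0, 2)) * int(rng.integers(12, 25))
        locus, _ = plant_insertion(consensus, cfg, rng, flank_dup_len=dup)
        got = [(span, length) for span, _, length in find_flank_duplications(locus)]
        assert got == brute_force_duplications(locus)


def test_duplications_require_empty_allele():
    with pytest.raises(ValueError):
        find_flank_duplications(_locus("A" * 60, (20, 40)))


# --- tandem repeats ----------------------------------------------------------


def oracle_tandem_repeats(seq: str):
    """Exhaustive enumeration over every (unit length, start) pair."""
    cands = []
    n = len(seq)
    for u in range(1, min(20, n // 2) + 1):
        for i in range(n - 2 * u + 1):
            unit = seq[i: i + u]
            if "N" in unit:
                continue
            if any(u % p == 0 and unit == unit[:p] * (u // p) for p in range(1, u)):
                continue
            if i > 0 and seq[i - 1] == seq[i - 1 + u] and seq[i - 1] != "N":
                continue  # not left-maximal
            j = i + u
            while j < n and seq[j] == seq[j - u] and seq[j] != "N":
                j += 1
            run = j - i
            if (run % u) * 2 < u:
                run -= run % u
            if run / u >= 3 and run >= 8:
                cands.append(TandemRepeatCall(unit=unit, copies=run / u, span=(i, i + run)))
    cands.sort(key=lambda c: (-c.length, len(c.unit), c.span[0]))
    chosen = []
    for c in cands:
        if all(c.span[1] <= a.span[0] or c.span[0] >= a.span[1] for a in chosen):
            chosen.append(c)
    return sorted(chosen, key=lambda c: c.span[0])


def test_published_style_repeat_units_admitted():
    # every published flank repeat class must pass the thresholds
    for unit, copies in [("G", 38), ("A", 17), ("TG", 26), ("CA", 14),
                         ("TTATTTAA", 3), ("ACTAGGGAACTACCAGGGGG", 14)]:
        calls = find_tandem_repeats(unit * copies)
        assert any(c.unit == unit and c.copies == copies for c in calls), unit


def test_two_and_a_half_copies_rejected():
    assert find_tandem_repeats("ACGTACGTAC") == []


def test_partial_final_copy_counted_when_at_least_half():
    calls = find_tandem_repeats("ACGT" * 3 + "AC")
    (call,) = calls
    assert call.unit == "ACGT"
    assert call.copies == pytest.approx(3.5)


@settings(deadline=None, derandomize=True, max_examples=150)
@given(st.text(alphabet="ACGT", min_size=0, max_size=60))
def test_tandem_calls_match_exhaustive_oracle(seq):
    got = find_tandem_repeats(seq)
    want = oracle_tandem_repeats(seq)
    assert [(c.unit, c.copies, c.span) for c in got] == [
        (c.unit, c.copies, c.span) for c in want
    ]


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.text(alphabet="ACGT", min_size=0, max_size=60))
def test_tandem_arrays_disjoint_and_decode(seq):
    calls = find_tandem_repeats(seq)
    for a, b in zip(calls, calls[1:]):
        assert a.span[1] <= b.span[0]
    for c in calls:
        lo, hi = c.span
        rebuilt = (c.unit * (int(np.ceil(c.copies)) + 1))[: hi - lo]
        assert seq[lo:hi] == rebuilt


def test_flank_repeat_offsets_signed_from_junctions(consensus):
    cfg = SimConfig(seed=36, identity_range=(1.0, 1.0), flank_len=160)
    rng = cfg.rng()
    locus, truth = plant_insertion(consensus, cfg, rng, tsd_len=3, tail_motif="TGTAA")
    s, e = locus.element_span
    filled = locus.filled.seq
    # embed (CA)14 ending 48 nt upstream of the 5' junction, as in the
    # published Ls69 flank
    array = "CA" * 14
    start = s - 48 - len(array)
    filled2 = filled[:start] + array + filled[start + len(array): ]
    locus2 = _locus(filled2, (s, e), lid="Ls69like")
    calls = [c for c in flank_tandem_repeats(locus2) if c.unit in ("CA", "AC")]
    assert calls, "planted (CA)14 not found"
    call = calls[0]
    assert call.flank == "5"
    assert call.offset == start - s


# --- flank composition -------------------------------------------------------


def test_all_at_flanks_give_mean_one(consensus):
    filled = "AT" * 40 + "G" * 30 + "AT" * 40
    loci = [_locus(filled, (80, 110), lid=f"L{i}") for i in range(3)]
    comp = flank_composition(loci)
    assert comp.mean_5prime == 1.0
    assert comp.p_5prime < 1e-10


def test_exactly_half_at_gives_degenerate_t():
    # aperiodic flanks, exactly 50% AT in each window, no flanking TSD
    filled = "C" * 50 + "A" * 25 + "G" * 25 + "GGGTTTCCC" + "T" * 25 + "C" * 50
    loci = [_locus(filled, (100, 109), lid=f"L{i}") for i in range(3)]
    comp = flank_composition(loci)
    assert comp.t_5prime == 0.0
    assert comp.p_5prime == 1.0


def test_flank_at_mean_near_simulated_level(consensus):
    cfg = SimConfig(seed=37)
    rng = cfg.rng()
    loci = [plant_insertion(consensus, cfg, rng, locus_id=f"L{i}")[0] for i in range(71)]
    comp = flank_composition(loci)
    se = np.sqrt(0.566 * (1 - 0.566) / 50) / np.sqrt(71)
    assert abs(comp.mean_5prime - 0.566) <= 4 * se


def test_composition_needs_two_loci(consensus):
    with pytest.raises(ValueError):
        flank_composition([_locus("ACGT" * 40, (60, 100))])
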