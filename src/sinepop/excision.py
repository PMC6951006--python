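"""Excision-footprint forensics.

When a SINE is imperfectly excised, the repaired locus retains a footprint:
some flanking bases may be deleted, the gap may be refilled with new sequence
(often a microsatellite), and the fill's terminal bases frequently copy the
sequence at the retained 3' junction — a microhomology signature of
template-switching repair.  This module anchors an excised allele to the
insertion-bearing allele by maximal exact end blocks and reads the footprint
off the anchor gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from sinepop.io import SequenceRecord
from sinepop.forensics import LocusAlleles, call_tsd, find_tandem_repeats

MIN_ANCHOR = 30
MH_WINDOW = 25


class AllelesNotComparable(ValueError):
    """Filled and excised alleles share too little flanking sequence."""


@dataclass
class ExcisionFootprint:
    locus_id: str
    left_breakpoint: int
    right_breakpoint: int
    deleted_flank_nt: int
    fill_seq: str
    microhomology_len: int
    microhomology_seq: str
    fill_repeat: tuple[str, float] | None
    anchors_unique: bool = True

    @property
    def fill_len(self) -> int:
        return len(self.fill_seq)


def _longest_common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            break
        n += 1
    return n


def call_footprint(filled: LocusAlleles, excised: SequenceRecord) -> ExcisionFootprint:
    """Characterize the excision footprint of ``excised`` against ``filled``.

    The left anchor is the longest shared prefix and the right anchor the
    longest shared suffix of the two alleles (both must reach ``MIN_ANCHOR``
    nt).  Everything between the anchors on the excised side is the fill;
    filled-allele flank bases lost between the anchors and the element (plus
    its right TSD copy) are counted as deleted; the microhomology is the
    longest exact suffix of the fill equal to the excised-side bases
    immediately following it (up to ``MH_WINDOW`` nt).
    """
    fseq = filled.filled.seq
    xseq = excised.seq
    s, e = filled.element_span
    la = _longest_common_prefix(fseq, xseq)
    lb = _longest_common_prefix(fseq[::-1], xseq[::-1])
    if la < MIN_ANCHOR or lb < MIN_ANCHOR:
        raise AllelesNotComparable(
            f"{filled.locus_id}: shared end blocks {la}/{lb} nt are below {MIN_ANCHOR}"
        )
    unique = True
    if la + lb > len(xseq):
        # clean excision: the anchors meet on the excised allele; trim the
        # right anchor so they abut (keeps the left anchor maximal).
        lb = len(xseq) - la
        unique = False
    fill = xseq[la: len(xseq) - lb]
    right_anchor_start_f = len(fseq) - lb

    tsd = call_tsd(filled)
    k = tsd.length if tsd else 0
    deleted = max(0, s - la) + max(0, right_anchor_start_f - (e + k))

    following = xseq[len(xseq) - lb:]
    mh = 0
    for m in range(1, min(MH_WINDOW, len(fill), len(following)) + 1):
        if fill[-m:] == following[:m] and "N" not in fill[-m:]:
            mh = m
    repeats = find_tandem_repeats(fill)
    fill_repeat = None
    if repeats:
        best = max(repeats, key=lambda c: c.length)
        if best.length * 2 >= len(fill):
            fill_repeat = (best.unit, best.copies)
    return ExcisionFootprint(
        locus_id=filled.locus_id,
        left_breakpoint=la,
        right_breakpoint=right_anchor_start_f,
        deleted_flank_nt=deleted,
        fill_seq=fill,
        microhomology_len=mh,
        microhomology_seq=fill[-mh:] if mh else "",
        fill_repeat=fill_repeat,
        anchors_unique=unique,
    )


def summarize_footprints(footprints: list[ExcisionFootprint]) -> pd.DataFrame:
    """Per-locus footprint table with aggregate attributes.

    The returned frame has one row per locus (sorted by locus id) and carries
    aggregates in ``df.attrs``: number with fill, number with microhomology of
    >= 2 nt, the maximum fill length, and the microhomology-length
    distribution.
    """
    if not footprints:
        raise ValueError("summarize_footprints needs at least one footprint")
    rows = [
        {
            "locus_id": fp.locus_id,
            "fill_len": fp.fill_len,
            "fill_unit": fp.fill_repeat[0] if fp.fill_repeat else "",
            "fill_copies": fp.fill_repeat[1] if fp.fill_repeat else 0.0,
            "deleted_flank_nt": fp.deleted_flank_nt,
            "microhomology_len": fp.microhomology_len,
            "microhomology_seq": fp.microhomology_seq,
        }
        for fp in sorted(footprints, key=lambda f: f.locus_id)
    ]
    df = pd.DataFrame(rows)
    mh_dist: dict[int, int] = {}
    for fp in footprints:
        mh_dist[fp.microhomology_len] = mh_dist.get(fp.microhomology_len, 0) + 1
    df.attrs["n"] = len(footprints)
    df.attrs["n_with_fill"] = int(sum(fp.fill_len > 0 for fp in footprints))
    df.attrs["n_with_microhomology"] = int(
        sum(fp.microhomology_len >= 2 for fp in footprints)
    )
    df.attrs["max_fill_len"] = int(max(fp.fill_len for fp in footprints))
    df.attrs["microhomology_distribution"] = dict(sorted(mh_dist.items()))
    return df
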