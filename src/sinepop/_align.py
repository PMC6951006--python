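"""Pairwise DNA alignment with linear gap costs.

Row-vectorized Needleman-Wunsch (global) and Smith-Waterman (local) dynamic
programming.  The within-row "left" dependency under a linear gap cost is a
running maximum, so each row is computed with ``np.maximum.accumulate`` instead
of an inner Python loop.  ``N`` never scores as a match: any column involving
``N`` takes the mismatch score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment: gapped strings, score and identity.

    ``a_span``/``b_span`` give the half-open region of each input consumed by
    the alignment (the full sequence for global alignments).
    """

    a_aln: str
    b_aln: str
    score: float
    matches: int
    columns: int
    a_span: tuple[int, int]
    b_span: tuple[int, int]

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    def column_pairs(self) -> list[tuple[int | None, int | None]]:
        """Per-column (index in a, index in b); None marks a gap."""
        out = []
        i, j = self.a_span[0], self.b_span[0]
        for ca, cb in zip(self.a_aln, self.b_aln):
            out.append((i if ca != "-" else None, j if cb != "-" else None))
            if ca != "-":
                i += 1
            if cb != "-":
                j += 1
        return out


def _substitution_rows(a: str, b: str, match: int, mismatch: int) -> np.ndarray:
    """sub[i, j] = score of aligning a[i] with b[j]; N never matches."""
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    eq = aa[:, None] == bb[None, :]
    is_n = (aa[:, None] == ord("N")) | (bb[None, :] == ord("N"))
    return np.where(eq & ~is_n, match, mismatch).astype(np.int64)


def _fill_matrix(
    a: str, b: str, match: int, mismatch: int, gap: int, local: bool
) -> tuple[np.ndarray, np.ndarray]:
    m, n = len(a), len(b)
    sub = _substitution_rows(a, b, match, mismatch)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    if not local:
        H[0, :] = gap * np.arange(n + 1)
        H[:, 0] = gap * np.arange(m + 1)
    js = np.arange(n + 1)
    for i in range(1, m + 1):
        diag = H[i - 1, :-1] + sub[i - 1]
        up = H[i - 1, 1:] + gap
        c = np.maximum(diag, up)
        # H[i, j] = max over k<=j of chain c[k] + gap*(j-k), incl. row start.
        cand = np.empty(n + 1, dtype=np.int64)
        cand[0] = H[i, 0]
        cand[1:] = c
        if local:
            cand = np.maximum(cand, 0)
        H[i] = gap * js + np.maximum.accumulate(cand - gap * js)
        if local:
            np.maximum(H[i], 0, out=H[i])
    return H, sub


def _traceback(
    a: str,
    b: str,
    H: np.ndarray,
    sub: np.ndarray,
    gap: int,
    start: tuple[int, int],
    local: bool,
) -> Alignment:
    i, j = start
    end_a, end_b = i, j
    a_parts: list[str] = []
    b_parts: list[str] = []
    matches = 0
    while i > 0 or j > 0:
        if local and H[i, j] == 0:
            break
        # Tie preference: diagonal, then up (consume a), then left (consume b).
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
            a_parts.append(a[i - 1])
            b_parts.append(b[j - 1])
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                matches += 1
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            a_parts.append(a[i - 1])
            b_parts.append("-")
            i -= 1
        else:
            a_parts.append("-")
            b_parts.append(b[j - 1])
            j -= 1
    a_aln = "".join(reversed(a_parts))
    b_aln = "".join(reversed(b_parts))
    return Alignment(
        a_aln=a_aln,
        b_aln=b_aln,
        score=float(H[start]),
        matches=matches,
        columns=len(a_aln),
        a_span=(i, end_a),
        b_span=(j, end_b),
    )


def needleman_wunsch(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> Alignment:
    """Optimal global alignment with deterministic diagonal-first traceback."""
    if not a or not b:
        raise ValueError("align_global requires two non-empty sequences")
    H, sub = _fill_matrix(a, b, match, mismatch, gap, local=False)
    return _traceback(a, b, H, sub, gap, (len(a), len(b)), local=False)


def smith_waterman(
    a: str, b: str, match: int = 2, mismatch: int = -3, gap: int = -5
) -> Alignment:
    """Best local alignment; returns a zero-length alignment if nothing scores > 0."""
    if not a or not b:
        raise ValueError("align_local requires two non-empty sequences")
    H, sub = _fill_matrix(a, b, match, mismatch, gap, local=True)
    flat = int(np.argmax(H))
    start = divmod(flat, H.shape[1])
    if H[start] == 0:
        return Alignment("", "", 0.0, 0, 0, (0, 0), (0, 0))
    return _traceback(a, b, H, sub, gap, start, local=True)
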