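"""Shared pairwise-alignment contract.

One aligner configuration is used across the package so that coordinates and
identities are comparable between stages:

* nucleotide: match +1, mismatch -1, gap open -5, gap extend -1
* protein (local): BLOSUM62, gap open -11, gap extend -1

Indels adjacent to homopolymers are left-aligned after alignment so that
event coordinates are deterministic regardless of aligner tie-breaking.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"

NUC_MATCH = 1.0
NUC_MISMATCH = -1.0
NUC_GAP_OPEN = -5.0
NUC_GAP_EXTEND = -1.0
PROT_GAP_OPEN = -11.0
PROT_GAP_EXTEND = -1.0


def nuc_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = NUC_MATCH
    aligner.mismatch_score = NUC_MISMATCH
    aligner.open_gap_score = NUC_GAP_OPEN
    aligner.extend_gap_score = NUC_GAP_EXTEND
    return aligner


def semiglobal_aligner() -> Align.PairwiseAligner:
    """Query must align end-to-end; target end gaps are free.

    Used to anchor a reference feature (the query) inside a larger window
    (the target).
    """
    aligner = nuc_aligner("global")
    # free end gaps in the query row (the unaligned flanks of the window)
    aligner.end_deletion_score = 0.0
    return aligner


def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = PROT_GAP_OPEN
    aligner.extend_gap_score = PROT_GAP_EXTEND
    return aligner


def _aligned_strings(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def left_normalize(a: str, b: str) -> tuple[str, str]:
    """Shift gaps leftward through repeated bases (homopolymer left-alignment).

    A gap run in one string may slide left by one column whenever the other
    string carries the same base at both ends of the slide, which preserves
    alignment content and score but fixes a canonical (leftmost) placement.
    """
    la, lb = list(a), list(b)

    def slide(gapped: list[str], other: list[str]) -> bool:
        moved = False
        i = 0
        n = len(gapped)
        while i < n:
            if gapped[i] != GAP:
                i += 1
                continue
            j = i
            while j < n and gapped[j] == GAP:
                j += 1
            s, e = i, j  # gap run [s, e)
            if e == n:  # terminal gap run (end raggedness), leave in place
                break
            while s > 0 and gapped[s - 1] != GAP and other[s - 1] == other[e - 1]:
                gapped[s - 1], gapped[e - 1] = GAP, gapped[s - 1]
                s -= 1
                e -= 1
                moved = True
            i = j
        return moved

    while slide(la, lb) or slide(lb, la):
        pass
    return "".join(la), "".join(lb)


def align_global(a: str, b: str) -> tuple[str, str, float]:
    """Global alignment; returns (aligned_a, aligned_b, score), left-normalized."""
    aligner = nuc_aligner("global")
    alignment = aligner.align(a, b)[0]
    aa, bb = _aligned_strings(alignment)
    aa, bb = left_normalize(aa, bb)
    return aa, bb, alignment.score


def align_semiglobal(reference: str, window: str) -> tuple[str, str, float]:
    """Anchor ``reference`` end-to-end inside ``window`` (free window end gaps)."""
    aligner = semiglobal_aligner()
    alignment = aligner.align(window, reference)[0]
    target, query = _aligned_strings(alignment)  # target=window, query=reference
    query, target = left_normalize(query, target)
    return query, target, alignment.score


def identity(aligned_a: str, aligned_b: str, count_gaps: bool = True) -> float:
    """Fraction of identical columns.

    With ``count_gaps`` the denominator is the full alignment length (gap
    columns count as differences); otherwise only ungapped columns count.
    """
    matches = 0
    cols = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP and y == GAP:
            continue
        if x == GAP or y == GAP:
            if count_gaps:
                cols += 1
            continue
        cols += 1
        if x == y:
            matches += 1
    if cols == 0:
        return 0.0
    return matches / cols


def matched_span(aligned_query: str, aligned_target: str) -> tuple[int, int]:
    """Target interval (0-based half-open) spanned by the query's aligned part.

    ``aligned_query``/``aligned_target`` are equal-length aligned strings; the
    span runs from the target position under the query's first non-gap column
    to one past the position under its last non-gap column.
    """
    first = last = None
    tpos = 0
    for qc, tc in zip(aligned_query, aligned_target):
        if qc != GAP and tc != GAP:
            if first is None:
                first = tpos
            last = tpos
        if tc != GAP:
            tpos += 1
    if first is None:
        raise ValueError("query aligns to no target position")
    return first, last + 1
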