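"""Insertion dating from 5'/3' LTR divergence.

At integration, the two long terminal repeats of an LTR retrotransposon are
identical (both are copied from the same template during reverse
transcription). Afterwards each LTR accumulates substitutions independently
at the neutral rate r, so the pairwise divergence K between the two LTRs of
one insertion grows at 2r per unit time, giving the insertion age

    T = K / (2 r)

with r in substitutions/site/Myr (default 0.0346 for Drosophila, a rate that
already folds in ten generations per year). K is the Jukes-Cantor-corrected
divergence by default (K = -(3/4) ln(1 - (4/3) p)); the raw p-distance is
available via model="p". Gapped alignment columns are excluded (pairwise
deletion): indel rates are not part of the clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import _align
from .seqcore_io import ConsensusElement, Feature, InsertionRecord, NucSequence

DEFAULT_RATE = 0.0346  # substitutions / site / Myr

#: minimum anchored identity for an LTR copy to count as present
MIN_LTR_IDENTITY = 0.6
#: window size for locating LTR copies, as a multiple of the reference LTR
LTR_WINDOW_FACTOR = 1.5


class SoloOrTruncatedError(ValueError):
    """Insertion lacks one of its LTR copies (solo LTR or truncation)."""


class DivergenceError(ValueError):
    """Divergence outside the model's domain (e.g. p >= 0.75 under JC69)."""


@dataclass
class LtrPair:
    insertion_id: str
    ltr5_seq: str
    ltr3_seq: str
    alignment: tuple[str, str] | None = None
    p_distance: float | None = None
    K: float | None = None
    model: str | None = None


@dataclass(frozen=True)
class AgeEstimate:
    K: float
    r: float
    T_years: float

    @property
    def T_tya(self) -> float:
        """Age in thousand years (TYA)."""
        return self.T_years / 1e3


def _locate_ltr(window: str, ref_ltr: str) -> tuple[str, float]:
    ref_aln, win_aln, _ = _align.align_semiglobal(ref_ltr, window)
    ident = _align.identity(ref_aln, win_aln, count_gaps=False)
    try:
        s, e = _align.matched_span(ref_aln, win_aln)
    except ValueError:
        return "", 0.0
    return window[s:e], ident


def extract_ltr_pair(
    insertion: InsertionRecord | NucSequence, reference: ConsensusElement
) -> LtrPair:
    """Locate and extract both LTR copies of an insertion.

    The reference LTR is anchored by semiglobal alignment inside the first
    and last 150%-of-LTR-length windows of the insertion. Raises
    :class:`SoloOrTruncatedError` when either copy falls below 60% identity.
    """
    seq = insertion.sequence if isinstance(insertion, InsertionRecord) else insertion
    for need in (Feature.LTR5, Feature.LTR3):
        if reference.feature(need) is None:
            raise ValueError(f"reference {reference.id} lacks {need.value}")
    ref5 = reference.region(Feature.LTR5)
    ref3 = reference.region(Feature.LTR3)
    w5 = int(round(LTR_WINDOW_FACTOR * len(ref5)))
    w3 = int(round(LTR_WINDOW_FACTOR * len(ref3)))
    ltr5, id5 = _locate_ltr(seq.seq[:w5], ref5)
    ltr3, id3 = _locate_ltr(seq.seq[-w3:], ref3)
    problems = []
    if id5 < MIN_LTR_IDENTITY:
        problems.append(f"5' LTR identity {id5:.2f}")
    if id3 < MIN_LTR_IDENTITY:
        problems.append(f"3' LTR identity {id3:.2f}")
    if problems:
        raise SoloOrTruncatedError(
            f"{seq.id}: {', '.join(problems)} below {MIN_LTR_IDENTITY:.2f} "
            "(solo or truncated insertion)"
        )
    return LtrPair(insertion_id=seq.id, ltr5_seq=ltr5, ltr3_seq=ltr3)


def divergence(ltr5: str, ltr3: str, model: str = "JC69") -> tuple[float, float]:
    """Pairwise divergence between the two LTRs of one insertion.

    Globally aligns the two copies, excludes gapped columns, and returns
    (p_distance, K) where K is p itself (model="p") or the JC69 correction
    (model="JC69").
    """
    if model not in ("p", "JC69"):
        raise ValueError("model must be 'p' or 'JC69'")
    if not ltr5 or not ltr3:
        raise ValueError("both LTR sequences must be non-empty")
    a, b, _ = _align.align_global(ltr5, ltr3)
    cols = mismatches = 0
    for x, y in zip(a, b):
        if x == _align.GAP or y == _align.GAP:
            continue
        cols += 1
        if x != y:
            mismatches += 1
    if cols == 0:
        raise DivergenceError("no ungapped aligned columns")
    p = mismatches / cols
    if model == "p":
        return p, p
    if p >= 0.75:
        raise DivergenceError(
            f"p-distance {p:.3f} >= 0.75: outside the JC69 domain"
        )
    K = -0.75 * math.log1p(-(4.0 / 3.0) * p)
    return p, K


def insertion_age(K: float, r: float = DEFAULT_RATE) -> AgeEstimate:
    """Insertion age T = K/(2r), reported in years (r in subs/site/Myr)."""
    if K < 0:
        raise ValueError("K must be >= 0")
    if r <= 0:
        raise ValueError("r must be > 0")
    return AgeEstimate(K=K, r=r, T_years=K / (2.0 * r) * 1e6)


def date_insertion(
    insertion: InsertionRecord | NucSequence,
    reference: ConsensusElement,
    model: str = "JC69",
    r: float = DEFAULT_RATE,
) -> tuple[LtrPair, AgeEstimate]:
    """Extract LTR pair, compute divergence, and estimate the insertion age."""
    pair = extract_ltr_pair(insertion, reference)
    p, K = divergence(pair.ltr5_seq, pair.ltr3_seq, model=model)
    pair.p_distance, pair.K, pair.model = p, K, model
    return pair, insertion_age(K, r=r)
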