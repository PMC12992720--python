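"""ORF integrity classification of proviral insertions.

An endogenous retrovirus insertion is classified by the intactness of its
gag, pol, and env-F open reading frames relative to a reference consensus:
an insertion with all three intact is an active retrovirus (infectious), one
with intact gag and pol but a defective env-F is an active retroelement
(replicates intracellularly), anything else is inactive.

Inactivating mutations are called from a pairwise global alignment of the
insertion's ORF region against the reference ORF: indels whose length is not
a multiple of three are frameshifts; substitutions that convert a codon into
a stop are premature stops. "Intact" additionally requires the translated
product to reach at least 90% of the reference ORF length, which tolerates
terminal raggedness while rejecting major truncations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from . import _align
from .seqcore_io import (
    ConsensusElement,
    Feature,
    InsertionRecord,
    NucSequence,
    ORF_FEATURES,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: minimum translated length relative to reference for "intact"
MIN_INTACT_AA_FRACTION = 0.9
#: aligned identity below which a region is considered unrelated
MIN_RELATED_IDENTITY = 0.5


class LowIdentityError(ValueError):
    """Query shares too little aligned identity with the reference."""


class UnrelatedElementError(LowIdentityError):
    """Insertion is unrelated to the reference consensus (<50% identity)."""


@dataclass(frozen=True)
class OrfHit:
    """An ATG-initiated '+'-strand ORF. end includes the stop codon (if any);
    aa_length counts codons excluding the stop."""

    start: int
    end: int
    frame: int
    aa_length: int
    open_ended: bool = False
    strand: str = "+"


class EventKind(str, enum.Enum):
    INSERTION = "insertion"
    DELETION = "deletion"
    SUBSTITUTION_STOP = "substitution_stop"


@dataclass(frozen=True)
class InactivationEvent:
    kind: EventKind
    ref_position: int  # 0-based on the reference ORF
    length: int  # nt; 0 for substitution_stop
    downstream_stop_aa: int | None = None  # 1-based aa index of first stop after event

    @property
    def frameshift(self) -> bool:
        return self.kind in (EventKind.INSERTION, EventKind.DELETION) and (
            self.length % 3 != 0
        )


class OrfStatus(str, enum.Enum):
    INTACT = "intact"
    FRAMESHIFT = "frameshift"
    PREMATURE_STOP = "premature_stop"
    TRUNCATED = "truncated"
    ABSENT = "absent"


class ActivityClass(str, enum.Enum):
    RETROVIRUS_ACTIVE = "retrovirus_active"
    RETROELEMENT_ACTIVE = "retroelement_active"
    INACTIVE = "inactive"


@dataclass
class IntegrityReport:
    insertion_id: str
    statuses: dict[Feature, OrfStatus]
    events: dict[Feature, list[InactivationEvent]] = field(default_factory=dict)

    @property
    def overall_class(self) -> ActivityClass:
        gag = self.statuses.get(Feature.GAG)
        pol = self.statuses.get(Feature.POL)
        env = self.statuses.get(Feature.ENVF)
        if gag is OrfStatus.INTACT and pol is OrfStatus.INTACT:
            if env is OrfStatus.INTACT:
                return ActivityClass.RETROVIRUS_ACTIVE
            return ActivityClass.RETROELEMENT_ACTIVE
        return ActivityClass.INACTIVE


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

def scan_orfs(seq: NucSequence | str, min_aa: int) -> list[OrfHit]:
    """All ATG-initiated ORFs of >= min_aa codons, '+' strand, three frames.

    Nested ORFs sharing a stop codon are reported once, from the longest
    (most 5') ATG. ORFs running off the sequence end are flagged open_ended.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    s = seq.seq if isinstance(seq, NucSequence) else seq
    hits: list[OrfHit] = []
    n = len(s)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = s[pos : pos + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    aa = (pos - start) // 3
                    if aa >= min_aa:
                        hits.append(OrfHit(start, pos + 3, frame, aa))
                    start = None
            elif codon == "ATG" and start is None:
                start = pos
        if start is not None:
            end = start + 3 * ((n - start) // 3)
            aa = (end - start) // 3
            if aa >= min_aa:
                hits.append(OrfHit(start, end, frame, aa, open_ended=True))
    hits.sort(key=lambda h: (h.start, h.frame))
    return hits


# ---------------------------------------------------------------------------
# inactivation calling
# ---------------------------------------------------------------------------

def _first_stop_at_or_after(query: str, q_start: int) -> int | None:
    """1-based index of the first stop codon in the straight translation of
    ``query`` whose codon covers or follows query position ``q_start``."""
    for k in range(q_start // 3, len(query) // 3):
        if query[3 * k : 3 * k + 3] in STOP_CODONS:
            return k + 1
    return None


def detect_inactivation(
    query_region: str, reference_orf: str, min_identity: float = MIN_RELATED_IDENTITY
) -> list[InactivationEvent]:
    """Call indels and stop-creating substitutions against a reference ORF.

    The query region is globally aligned to the reference ORF (homopolymer
    indels left-aligned); every indel is reported at its reference position,
    and every substitution that converts the query codon (read in the frame
    induced by upstream indels, i.e. straight translation of the query) into
    a stop is reported as a substitution_stop. downstream_stop_aa gives the
    1-based codon index of the first query stop at/after the event.
    """
    if len(reference_orf) % 3 != 0:
        raise ValueError("reference ORF length must be divisible by 3")
    if not reference_orf.startswith("ATG"):
        raise ValueError("reference ORF must start with ATG")
    ref_aln, qry_aln, _ = _align.align_global(reference_orf, query_region)
    ident = _align.identity(ref_aln, qry_aln, count_gaps=True)
    if ident < min_identity:
        raise LowIdentityError(
            f"aligned identity {ident:.2f} below {min_identity:.2f}"
        )

    events: list[InactivationEvent] = []
    rpos = qpos = 0
    i = 0
    ncol = len(ref_aln)
    # ignore events inside the reference's terminal stop codon
    ref_core_end = len(reference_orf) - 3
    while i < ncol:
        rc, qc = ref_aln[i], qry_aln[i]
        if rc == _align.GAP:  # insertion in query
            j = i
            while j < ncol and ref_aln[j] == _align.GAP:
                j += 1
            length = j - i
            if 0 < rpos <= ref_core_end:
                events.append(
                    InactivationEvent(
                        EventKind.INSERTION,
                        ref_position=rpos,
                        length=length,
                        downstream_stop_aa=_first_stop_at_or_after(
                            query_region, qpos
                        ),
                    )
                )
            qpos += length
            i = j
        elif qc == _align.GAP:  # deletion in query
            j = i
            while j < ncol and qry_aln[j] == _align.GAP:
                j += 1
            length = j - i
            if rpos + length <= ref_core_end and rpos > 0:
                events.append(
                    InactivationEvent(
                        EventKind.DELETION,
                        ref_position=rpos,
                        length=length,
                        downstream_stop_aa=_first_stop_at_or_after(
                            query_region, qpos
                        ),
                    )
                )
            rpos += length
            i = j
        else:
            if rc != qc and rpos < ref_core_end:
                # does this substitution create a stop in the query's frame?
                cidx = qpos // 3
                codon = query_region[3 * cidx : 3 * cidx + 3]
                if len(codon) == 3 and codon in STOP_CODONS:
                    within = qpos - 3 * cidx
                    reverted = codon[:within] + rc + codon[within + 1 :]
                    if reverted not in STOP_CODONS:
                        events.append(
                            InactivationEvent(
                                EventKind.SUBSTITUTION_STOP,
                                ref_position=rpos,
                                length=0,
                                downstream_stop_aa=cidx + 1,
                            )
                        )
            rpos += 1
            qpos += 1
            i += 1
    events.sort(key=lambda e: e.ref_position)
    return events


# ---------------------------------------------------------------------------
# per-insertion classification
# ---------------------------------------------------------------------------

def _orf_status(
    query_region: str, reference_orf: str
) -> tuple[OrfStatus, list[InactivationEvent]]:
    if not query_region:
        return OrfStatus.ABSENT, []
    events = detect_inactivation(query_region, reference_orf)
    if any(e.frameshift for e in events):
        return OrfStatus.FRAMESHIFT, events
    if any(e.kind is EventKind.SUBSTITUTION_STOP for e in events):
        return OrfStatus.PREMATURE_STOP, events
    # translated length up to the first stop, straight frame
    ref_aa = len(reference_orf) // 3 - 1
    stop_aa = _first_stop_at_or_after(query_region, 0)
    prod_aa = (stop_aa - 1) if stop_aa is not None else len(query_region) // 3
    if prod_aa >= MIN_INTACT_AA_FRACTION * ref_aa:
        return OrfStatus.INTACT, events
    return OrfStatus.TRUNCATED, events


def _locate_region(
    insertion_seq: str, ref_orf: str, expected_start: int, expected_end: int, pad: int
) -> tuple[str, float]:
    """Anchor a reference ORF inside the expected window of the insertion."""
    lo = max(0, expected_start - pad)
    hi = min(len(insertion_seq), expected_end + pad)
    window = insertion_seq[lo:hi]
    if len(window) < 0.1 * len(ref_orf):
        return "", 0.0
    ref_aln, win_aln, _ = _align.align_semiglobal(ref_orf, window)
    ident = _align.identity(ref_aln, win_aln, count_gaps=False)
    try:
        s, e = _align.matched_span(ref_aln, win_aln)
    except ValueError:
        return "", 0.0
    return window[s:e], ident


def classify_integrity(
    insertion: InsertionRecord | NucSequence,
    reference: ConsensusElement,
    pad: int = 200,
) -> IntegrityReport:
    """Classify one insertion's gag/pol/env-F intactness against a consensus.

    Each annotated reference ORF is anchored by semiglobal alignment inside
    the corresponding window of the insertion, then scored for inactivating
    events. Raises :class:`UnrelatedElementError` if no ORF region reaches
    50% aligned identity.
    """
    seq = insertion.sequence if isinstance(insertion, InsertionRecord) else insertion
    ins_id = seq.id
    for need in (Feature.GAG, Feature.POL):
        if reference.feature(need) is None:
            raise ValueError(f"reference {reference.id} lacks {need.value} annotation")

    statuses: dict[Feature, OrfStatus] = {}
    events: dict[Feature, list[InactivationEvent]] = {}
    identities: list[float] = []
    for feat in ORF_FEATURES:
        ann = reference.feature(feat)
        if ann is None:
            statuses[feat] = OrfStatus.ABSENT
            events[feat] = []
            continue
        ref_orf = reference.region(feat)
        region, ident = _locate_region(seq.seq, ref_orf, ann.start, ann.end, pad)
        identities.append(ident)
        if not region or ident < MIN_RELATED_IDENTITY:
            statuses[feat] = OrfStatus.ABSENT
            events[feat] = []
            continue
        try:
            statuses[feat], events[feat] = _orf_status(region, ref_orf)
        except LowIdentityError:
            statuses[feat] = OrfStatus.ABSENT
            events[feat] = []
    if identities and max(identities) < MIN_RELATED_IDENTITY:
        raise UnrelatedElementError(
            f"{ins_id}: no ORF region reaches "
            f"{MIN_RELATED_IDENTITY:.0%} identity with {reference.id}"
        )
    return IntegrityReport(insertion_id=ins_id, statuses=statuses, events=events)


# ---------------------------------------------------------------------------
# env-F remnant detection
# ---------------------------------------------------------------------------

def _translate_frame(region: str, frame: int) -> str:
    sub = region[frame:]
    sub = sub[: 3 * (len(sub) // 3)]
    out = []
    for i in range(0, len(sub), 3):
        codon = sub[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(_CODON_TABLE[codon])
    return "".join(out)


_CODON_TABLE = {}


def _build_codon_table() -> None:
    from Bio.Seq import Seq

    bases = "ACGT"
    for a in bases:
        for b in bases:
            for c in bases:
                codon = a + b + c
                _CODON_TABLE[codon] = str(Seq(codon).translate())


_build_codon_table()


def _best_frame_hit(
    ref_protein: str, region: str
) -> tuple[float, int, int, int, int] | None:
    """Best local protein hit over the three forward frames of a DNA region.

    Returns (score, nt_start, nt_end, ref_aa_start, ref_aa_end) or None.
    """
    aligner = _align.protein_aligner()
    best = None
    for frame in range(3):
        prot = _translate_frame(region, frame)
        if len(prot) < 3:
            continue
        try:
            alignments = aligner.align(ref_protein, prot)
            if len(alignments) == 0:
                continue
            top = alignments[0]
        except (ValueError, OverflowError, IndexError):
            continue
        rstart, rend = int(top.aligned[0][0][0]), int(top.aligned[0][-1][1])
        qstart, qend = int(top.aligned[1][0][0]), int(top.aligned[1][-1][1])
        cand = (float(top.score), frame + 3 * qstart, frame + 3 * qend,
                rstart, rend)
        if best is None or cand[0] > best[0]:
            best = cand
    return best


def _harvest_hits(
    ref_protein: str, region: str, min_score: float, offset: int
) -> list[tuple[tuple[int, int], tuple[int, int], float]]:
    """Best hit across frames, then recurse on the flanking DNA.

    Recursing at the DNA level keeps hits non-overlapping on the query and
    prevents a hit in one frame from extending through sequence already
    claimed by a better hit in another frame (different-frame readings of
    the same DNA are correlated through the genetic code, so purely
    per-frame searches bleed across frameshift points).
    """
    if len(region) < 9:
        return []
    best = _best_frame_hit(ref_protein, region)
    if best is None or best[0] < min_score:
        return []
    score, qs, qe, rs, re_ = best
    hit = ((offset + qs, offset + qe), (rs, re_), score)
    left = _harvest_hits(ref_protein, region[:qs], min_score, offset)
    right = _harvest_hits(ref_protein, region[qe:], min_score, offset + qe)
    return left + [hit] + right


def find_env_remnants(
    region: str, reference_env_protein: str, min_score: float = 60.0
) -> list[tuple[tuple[int, int], tuple[int, int], float]]:
    """Find degraded env-F fragments in a pol-to-3'LTR interval.

    All three forward-frame translations of ``region`` are locally aligned
    (BLOSUM62) against the reference Env protein. Returns non-overlapping
    hits with score >= min_score, sorted by query position, each as
    ((query_nt_start, query_nt_end), (ref_aa_start, ref_aa_end), score).
    """
    if not region:
        return []
    hits = _harvest_hits(reference_env_protein, region, min_score, 0)
    hits.sort(key=lambda h: h[0][0])
    return hits
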