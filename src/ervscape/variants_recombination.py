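"""LTR-variant typing, recombinant detection, and per-site MSA profiles.

Retroviral capsids are pseudo-diploid: two RNA genomes are co-packaged, and
reverse transcriptase can switch templates between them, producing
recombinant proviruses. Two complementary detectors are implemented:

* mismatched 5'/3' LTR types — a provirus normally carries identical LTRs,
  so an insertion whose two LTRs type as different named variants arose by
  recombination between variants;
* per-site parental painting — alignment columns at which two insertions of
  variant A share one allele and two insertions of variant B share a
  different allele are diagnostic sites; a query is called A, B, or
  non-reference at each site, and maximal parental runs delimit template
  switches, with breakpoints reported as the open interval between the
  flanking diagnostic sites of adjacent runs (resolution is bounded by the
  informative sites, so no point estimates are given).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _align
from .ltr_dating import extract_ltr_pair
from .seqcore_io import (
    ConsensusElement,
    GAP,
    InsertionRecord,
    Msa,
    NucSequence,
)

#: global-alignment identity below which an LTR cannot be typed
MIN_TYPE_IDENTITY = 0.8
#: a parental run must contain at least this many sites to form a segment
DEFAULT_MIN_SITES_PER_SEGMENT = 2

UNTYPED = "untyped"


class UnrelatedQueryError(ValueError):
    """Query matches neither parental type at any diagnostic site."""


@dataclass(frozen=True)
class VariantDef:
    name: str  # e.g. "LTR-408"
    ltr: NucSequence
    expected_length: int | None = None

    def __post_init__(self) -> None:
        if self.expected_length is not None and self.expected_length != len(self.ltr):
            raise ValueError(
                f"variant {self.name}: reference LTR length {len(self.ltr)} "
                f"!= expected {self.expected_length}"
            )


@dataclass
class VariantLibrary:
    variants: list[VariantDef]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variants]
        if len(names) != len(set(names)):
            raise ValueError("variant names must be unique")
        if not self.variants:
            raise ValueError("variant library is empty")


@dataclass(frozen=True)
class DiagnosticSite:
    column: int
    allele_a: str  # single alignment symbol, may be '-'
    allele_b: str


@dataclass
class DiagnosticSiteSet:
    msa_id: str
    type_a: str
    type_b: str
    sites: list[DiagnosticSite]
    degenerate_a: bool = False  # single-sequence parent (e.g. one good copy)
    degenerate_b: bool = False

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class Segment:
    call: str  # "A" | "B"
    first_column: int
    last_column: int
    n_sites: int


@dataclass
class RecombinationCall:
    query_id: str
    site_calls: list[tuple[int, str]]  # (column, "A"|"B"|"nonref")
    segments: list[Segment]
    breakpoints: list[tuple[int, int]]  # open column intervals between segments
    ltr_mismatch: bool | None = None

    @property
    def n_switches(self) -> int:
        return max(0, len(self.segments) - 1)


# ---------------------------------------------------------------------------
# LTR typing
# ---------------------------------------------------------------------------

def type_ltr(ltr_seq: str, library: VariantLibrary) -> tuple[str, float]:
    """Assign an LTR sequence to the best-matching named variant.

    Identity is computed over the full global alignment (gap columns count
    as differences). Ties are broken by smaller |length difference|, then by
    name. Below 80% identity the LTR is reported as "untyped".
    """
    best: tuple[float, int, str] | None = None
    best_identity = 0.0
    for var in library.variants:
        a, b, _ = _align.align_global(var.ltr.seq, ltr_seq)
        ident = _align.identity(a, b, count_gaps=True)
        key = (-ident, abs(len(var.ltr) - len(ltr_seq)), var.name)
        if best is None or key < (best[0], best[1], best[2]):
            best = key
            best_identity = ident
    assert best is not None
    if best_identity < MIN_TYPE_IDENTITY:
        return UNTYPED, best_identity
    return best[2], best_identity


def detect_ltr_mismatch(
    insertion: InsertionRecord,
    library: VariantLibrary,
    reference: ConsensusElement | None = None,
) -> tuple[bool | None, str, str]:
    """Flag a cross-variant recombinant by its mismatched 5'/3' LTR types.

    Uses the insertion's pre-extracted LTRs if present, otherwise extracts
    them against ``reference``. Returns (mismatch, type5, type3); mismatch is
    None (indeterminate) when either LTR is untyped.
    """
    ltr5, ltr3 = insertion.ltr5, insertion.ltr3
    if ltr5 is None or ltr3 is None:
        if reference is None:
            raise ValueError(
                "insertion has no extracted LTRs and no reference was given"
            )
        pair = extract_ltr_pair(insertion, reference)
        ltr5, ltr3 = pair.ltr5_seq, pair.ltr3_seq
        insertion.ltr5, insertion.ltr3 = ltr5, ltr3
    type5, _ = type_ltr(ltr5, library)
    type3, _ = type_ltr(ltr3, library)
    if UNTYPED in (type5, type3):
        return None, type5, type3
    return type5 != type3, type5, type3


# ---------------------------------------------------------------------------
# diagnostic sites and parental painting
# ---------------------------------------------------------------------------

def diagnostic_sites(
    msa: Msa,
    a1: str,
    a2: str,
    b1: str,
    b2: str,
    type_a: str = "A",
    type_b: str = "B",
) -> DiagnosticSiteSet:
    """Columns at which both A parents share one allele and both B parents a
    different one. '-' is a valid shared allele (captures indel variants);
    consecutive columns belonging to one indel event are collapsed to the
    event's first column. A degenerate parent pair (a1 == a2) is allowed and
    flagged — used when only one good copy of a variant exists.
    """
    rows = {rid: msa.row(rid) for rid in (a1, a2, b1, b2)}
    sites: list[DiagnosticSite] = []
    prev_col = None
    prev_alleles = None
    for j in range(msa.ncol):
        ca1, ca2, cb1, cb2 = (rows[a1][j], rows[a2][j], rows[b1][j], rows[b2][j])
        if ca1 != ca2 or cb1 != cb2 or ca1 == cb1:
            prev_col = None
            continue
        is_indel = GAP in (ca1, cb1)
        if (
            is_indel
            and prev_col == j - 1
            and prev_alleles is not None
            and (prev_alleles[0] == GAP) == (ca1 == GAP)
            and (prev_alleles[1] == GAP) == (cb1 == GAP)
        ):
            # continuation of the same indel event: keep only its first column
            prev_col = j
            prev_alleles = (ca1, cb1)
            continue
        sites.append(DiagnosticSite(column=j, allele_a=ca1, allele_b=cb1))
        prev_col = j if is_indel else None
        prev_alleles = (ca1, cb1) if is_indel else None
    return DiagnosticSiteSet(
        msa_id="|".join(msa.ids[:1]),
        type_a=type_a,
        type_b=type_b,
        sites=sites,
        degenerate_a=(a1 == a2),
        degenerate_b=(b1 == b2),
    )


def _segment(
    parental: list[tuple[int, str]], min_sites: int
) -> list[Segment]:
    """Collapse per-site parental calls into supported maximal runs.

    Runs with fewer than ``min_sites`` sites are discarded (their sites do
    not create a segment) and flanking same-call runs then merge; repeated
    until stable.
    """
    runs: list[list[tuple[int, str]]] = []
    for col, call in parental:
        if runs and runs[-1][0][1] == call:
            runs[-1].append((col, call))
        else:
            runs.append([(col, call)])
    changed = True
    while changed:
        changed = False
        kept = [r for r in runs if len(r) >= min_sites]
        if len(kept) != len(runs):
            changed = True
        merged: list[list[tuple[int, str]]] = []
        for r in kept:
            if merged and merged[-1][0][1] == r[0][1]:
                merged[-1].extend(r)
            else:
                merged.append(r)
        runs = merged
    return [
        Segment(
            call=r[0][1],
            first_column=r[0][0],
            last_column=r[-1][0],
            n_sites=len(r),
        )
        for r in runs
    ]


def call_recombinant(
    msa: Msa,
    query_id: str,
    sites: DiagnosticSiteSet,
    min_sites_per_segment: int = DEFAULT_MIN_SITES_PER_SEGMENT,
) -> RecombinationCall:
    """Paint a query along diagnostic sites and segment it into parental blocks.

    At each site the query symbol is called A, B, or nonref ("all other
    variations"). Maximal same-call runs with >= min_sites_per_segment sites
    (nonref calls ignored) form segments; each template switch is reported
    as the open column interval between the last site of one segment and the
    first site of the next.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 diagnostic sites")
    row = msa.row(query_id)
    site_calls: list[tuple[int, str]] = []
    for site in sites.sites:
        sym = row[site.column]
        if sym == site.allele_a:
            call = "A"
        elif sym == site.allele_b:
            call = "B"
        else:
            call = "nonref"
        site_calls.append((site.column, call))
    parental = [(c, call) for c, call in site_calls if call != "nonref"]
    if not parental:
        raise UnrelatedQueryError(
            f"{query_id}: all {len(site_calls)} diagnostic sites are non-reference"
        )
    segments = _segment(parental, min_sites_per_segment)
    breakpoints = [
        (a.last_column, b.first_column)
        for a, b in zip(segments, segments[1:])
    ]
    return RecombinationCall(
        query_id=query_id,
        site_calls=site_calls,
        segments=segments,
        breakpoints=breakpoints,
    )


# ---------------------------------------------------------------------------
# per-site frequency profile
# ---------------------------------------------------------------------------

def site_frequency_profile(msa: Msa) -> pd.DataFrame:
    """Per-column occupancy and ranked non-gap symbol frequencies.

    Returns a DataFrame with columns: column, occupancy, base1, f1, base2,
    f2, base3, f3 — occupancy is the non-gap fraction of rows; f1 >= f2 >= f3
    are the frequencies of the three most frequent non-gap symbols among
    non-gap rows (0 and '.' placeholder when absent). Rank ties are broken
    by symbol lexicographic order.
    """
    if len(msa.rows) < 2:
        raise ValueError("need at least 2 alignment rows")
    nrow = len(msa.rows)
    records = []
    for j in range(msa.ncol):
        col = msa.column(j)
        nongap = [c for c in col if c != GAP]
        occupancy = len(nongap) / nrow
        counts: dict[str, int] = {}
        for c in nongap:
            counts[c] = counts.get(c, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        bases, freqs = [], []
        for rank in range(3):
            if rank < len(ranked):
                bases.append(ranked[rank][0])
                freqs.append(ranked[rank][1] / len(nongap))
            else:
                bases.append(".")
                freqs.append(0.0)
        records.append(
            dict(
                column=j,
                occupancy=occupancy,
                base1=bases[0],
                f1=freqs[0],
                base2=bases[1],
                f2=freqs[1],
                base3=bases[2],
                f3=freqs[2],
            )
        )
    return pd.DataFrame.from_records(records)
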