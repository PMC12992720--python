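"""Core sequence types, coordinate conventions, and file I/O.

All coordinates in this package are 0-based, half-open. 1-based coordinates
appear only in human-readable report headers, where they are labelled as such.

Sequences are held as plain uppercase strings over the alphabet {A,C,G,T,N}.
On input, lowercase is uppercased and RNA ``U`` is converted to ``T``; any
other IUPAC ambiguity code is rejected rather than silently converted, because
exact k-mer matching downstream must be unambiguous.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
GAP = "-"


class SequenceError(ValueError):
    """Malformed sequence input (bad alphabet, empty record, duplicate id)."""


class AnnotationError(ValueError):
    """Malformed or inconsistent feature annotation."""


def normalize_seq(raw: str, record_id: str | None = None) -> str:
    """Uppercase, convert U->T, and validate against {A,C,G,T,N}.

    Raises :class:`SequenceError` naming ``record_id`` on illegal characters.
    """
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - ALPHABET
    if bad:
        who = f" in record {record_id!r}" if record_id else ""
        raise SequenceError(
            f"illegal character(s) {sorted(bad)}{who}; allowed alphabet is ACGTN"
        )
    if not seq:
        who = f" {record_id!r}" if record_id else ""
        raise SequenceError(f"empty sequence{who}")
    return seq


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence (normalized on construction)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_seq(self.seq, self.id))

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - ALPHABET
    if bad:
        raise SequenceError(f"illegal character(s) {sorted(bad)} in revcomp input")
    return seq.translate(_COMPLEMENT)[::-1]


class Feature(str, enum.Enum):
    """Canonical proviral features on a consensus (always '+' strand)."""

    LTR5 = "LTR5"
    UTR5 = "UTR5"
    GAG = "GAG"
    POL = "POL"
    ENVF = "ENVF"
    UTR3 = "UTR3"
    LTR3 = "LTR3"


#: ORF-bearing features, in genomic order.
ORF_FEATURES = (Feature.GAG, Feature.POL, Feature.ENVF)


@dataclass(frozen=True)
class FeatureAnnotation:
    element_id: str
    feature: Feature
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"{self.element_id}/{self.feature.value}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand != "+":
            raise AnnotationError("consensus features are always on the '+' strand")

    def __len__(self) -> int:
        return self.end - self.start


class EnvStatus(str, enum.Enum):
    FULL_LENGTH = "full_length"
    REMNANT = "remnant"
    ABSENT = "absent"
    UNKNOWN = "unknown"


@dataclass
class ConsensusElement:
    """A TE consensus sequence plus its feature map and subclade label."""

    sequence: NucSequence
    features: list[FeatureAnnotation]
    subclade: str = ""
    env_status: EnvStatus = EnvStatus.UNKNOWN

    def __post_init__(self) -> None:
        length = len(self.sequence)
        seen: dict[Feature, FeatureAnnotation] = {}
        for f in self.features:
            if f.element_id != self.sequence.id:
                raise AnnotationError(
                    f"annotation for {f.element_id!r} bound to element "
                    f"{self.sequence.id!r}"
                )
            if f.end > length:
                raise AnnotationError(
                    f"{f.element_id}/{f.feature.value}: end {f.end} exceeds "
                    f"element length {length}"
                )
            if f.feature in seen:
                raise AnnotationError(f"duplicate feature {f.feature.value}")
            seen[f.feature] = f
        for need in (Feature.LTR5, Feature.LTR3):
            if need not in seen:
                raise AnnotationError(
                    f"{self.sequence.id}: consensus must annotate {need.value}"
                )
        # env-F may overlap pol / UTRs (overlapping reading frames occur in
        # LTR elements); all other features must be mutually non-overlapping.
        plain = [f for f in self.features if f.feature is not Feature.ENVF]
        plain.sort(key=lambda f: f.start)
        for a, b in zip(plain, plain[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"overlapping features {a.feature.value} and {b.feature.value}"
                )
        self._by_feature = seen

    @property
    def id(self) -> str:
        return self.sequence.id

    def feature(self, which: Feature) -> FeatureAnnotation | None:
        return self._by_feature.get(which)

    def region(self, which: Feature) -> str:
        f = self._by_feature.get(which)
        if f is None:
            raise AnnotationError(f"{self.id}: no {which.value} annotation")
        return self.sequence.seq[f.start:f.end]


@dataclass
class InsertionRecord:
    """One genomic TE insertion, extracted in element orientation."""

    sequence: NucSequence
    source_genome: str = ""
    locus: str = ""
    flank5: str = ""
    flank3: str = ""
    ltr5: str | None = None
    ltr3: str | None = None

    @property
    def id(self) -> str:
        return self.sequence.id


@dataclass
class Msa:
    """A multiple sequence alignment (aligned FASTA dialect, '-' gaps only)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise SequenceError("empty alignment")
        ncol = len(self.rows[0][1])
        ids = set()
        allowed = ALPHABET | {GAP}
        for rid, aligned in self.rows:
            if len(aligned) != ncol:
                raise SequenceError(
                    f"row {rid!r} has length {len(aligned)}, expected {ncol}"
                )
            bad = set(aligned) - allowed
            if bad:
                raise SequenceError(
                    f"row {rid!r}: illegal alignment character(s) {sorted(bad)} "
                    "(only '-' is accepted as gap)"
                )
            if rid in ids:
                raise SequenceError(f"duplicate row id {rid!r}")
            ids.add(rid)
        self.ncol = ncol
        self._index = {rid: aligned for rid, aligned in self.rows}

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        try:
            return self._index[rid]
        except KeyError:
            raise KeyError(f"row id {rid!r} not in alignment") from None

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def column(self, j: int) -> list[str]:
        return [aligned[j] for _, aligned in self.rows]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a FASTA file into normalized :class:`NucSequence` records."""
    records: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(NucSequence(rec.id, str(rec.seq), rec.description))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[NucSequence], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_msa(path: str | Path) -> Msa:
    """Read an aligned FASTA file; '.' gaps are rejected ('-' only)."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        aligned = str(rec.seq).upper().replace("U", "T")
        rows.append((rec.id, aligned))
    if not rows:
        raise SequenceError(f"no alignment rows found in {path}")
    return Msa(rows)


def write_msa(msa: Msa, path: str | Path) -> None:
    seqrecs = [SeqRecord(Seq(aligned), id=rid, description="") for rid, aligned in msa.rows]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_annotation_table(path: str | Path) -> list[FeatureAnnotation]:
    """Read a tab-separated feature table (element_id, feature, start, end)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"element_id", "feature", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation table missing column(s) {sorted(missing)}")
    annots = []
    for _, row in df.iterrows():
        try:
            feat = Feature(row["feature"])
        except ValueError:
            raise AnnotationError(
                f"unknown feature {row['feature']!r} for element {row['element_id']!r}"
            ) from None
        annots.append(
            FeatureAnnotation(
                element_id=row["element_id"],
                feature=feat,
                start=int(row["start"]),
                end=int(row["end"]),
            )
        )
    return annots


def write_annotation_table(annots: Iterable[FeatureAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tsv_header(coordinates="0-based half-open"))
        fh.write("element_id\tfeature\tstart\tend\n")
        for a in annots:
            fh.write(f"{a.element_id}\t{a.feature.value}\t{a.start}\t{a.end}\n")


def bind_annotations(
    sequences: Sequence[NucSequence],
    annotations: Sequence[FeatureAnnotation],
    subclades: dict[str, str] | None = None,
) -> dict[str, ConsensusElement]:
    """Join sequences with their feature annotations into consensus elements."""
    by_element: dict[str, list[FeatureAnnotation]] = {}
    for a in annotations:
        by_element.setdefault(a.element_id, []).append(a)
    seq_ids = {s.id for s in sequences}
    orphans = set(by_element) - seq_ids
    if orphans:
        raise AnnotationError(
            f"annotations reference absent element(s) {sorted(orphans)}"
        )
    out = {}
    for s in sequences:
        feats = by_element.get(s.id)
        if feats is None:
            continue
        out[s.id] = ConsensusElement(
            sequence=s,
            features=feats,
            subclade=(subclades or {}).get(s.id, ""),
        )
    return out


# ---------------------------------------------------------------------------
# coverage runs / BED
# ---------------------------------------------------------------------------

def coverage_runs(mask: np.ndarray | Sequence[bool]) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean track, as 0-based half-open intervals."""
    arr = np.asarray(mask, dtype=bool)
    if arr.size == 0:
        return []
    padded = np.concatenate(([False], arr, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def tsv_header(**params) -> str:
    """Standard '#'-prefixed header line with tool version and parameters."""
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# ervscape v{__version__} {kv}".rstrip() + "\n"


def write_coverage_bed(profile, path: str | Path) -> None:
    """Write maximal covered runs of a CoverageProfile as BED6 intervals.

    The BED name field holds the cluster id and orientation; score is the
    covered fraction scaled to 0-1000 as is conventional for BED scores.
    """
    with open(path, "w") as fh:
        fh.write(
            tsv_header(
                format="BED6",
                consensus=profile.consensus_id,
                cluster=profile.cluster_id,
                orientation=profile.orientation,
                k=profile.k,
            )
        )
        score = int(round(1000 * profile.fraction))
        name = f"{profile.cluster_id}|{profile.orientation}"
        for start, end in coverage_runs(profile.covered):
            fh.write(
                f"{profile.consensus_id}\t{start}\t{end}\t{name}\t{score}\t+\n"
            )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False, **params) -> None:
    """Write a DataFrame as TSV with the standard '#' header line."""
    with open(path, "w") as fh:
        fh.write(tsv_header(**params))
        df.to_csv(fh, sep="\t", index=index)
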