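"""piRNA-cluster silencing potential of TE consensus sequences.

A piRNA cluster silences a transposon in trans through the piRNAs it
produces. As a sequence-level proxy, the cluster is parsed into all
overlapping k-mers (default k=25, the piRNA length), and a consensus
position counts as covered when it lies inside a window whose reverse
complement (antisense orientation) occurs among the cluster k-mers. The
covered fraction of the consensus is its "silencing potential" for that
cluster. Uni-strand clusters are indexed in their transcribed orientation;
dual-strand clusters are indexed on both strands.

Coverage is binary: k-mer multiplicity in the cluster is ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore_io import NucSequence, revcomp

DEFAULT_K = 25

_BASE_CODE = {c: i for i, c in enumerate("ACGTN")}


@dataclass
class KmerIndex:
    """Distinct k-mers of one cluster sequence (N-containing k-mers dropped)."""

    k: int
    source_id: str
    kmers: frozenset[str]
    both_strands: bool = False

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers

    def __len__(self) -> int:
        return len(self.kmers)


@dataclass
class CoverageProfile:
    consensus_id: str
    cluster_id: str
    orientation: str  # "antisense" | "sense"
    covered: np.ndarray  # bool, length = consensus length
    k: int

    @property
    def fraction(self) -> float:
        if self.covered.size == 0:
            return 0.0
        return float(self.covered.mean())


def build_kmer_index(
    cluster: NucSequence, k: int = DEFAULT_K, both_strands: bool = False
) -> KmerIndex:
    """Index all length-k substrings of a cluster (step 1, set semantics)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = [cluster.seq]
    if both_strands:
        seqs.append(revcomp(cluster.seq))
    kmers: set[str] = set()
    for s in seqs:
        if len(s) < k:
            continue
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" not in w:
                kmers.add(w)
    if not kmers:
        warnings.warn(
            f"cluster {cluster.id!r} (length {len(cluster)}) yields no {k}-mers",
            stacklevel=2,
        )
    return KmerIndex(k=k, source_id=cluster.id, kmers=frozenset(kmers),
                     both_strands=both_strands)


def _window_matches(consensus_seq: str, index: KmerIndex, orientation: str) -> np.ndarray:
    k = index.k
    n = len(consensus_seq)
    nwin = max(0, n - k + 1)
    match = np.zeros(nwin, dtype=bool)
    for s in range(nwin):
        w = consensus_seq[s : s + k]
        probe = revcomp(w) if orientation == "antisense" else w
        if probe in index.kmers:
            match[s] = True
    return match

def _mark_covered(match: np.ndarray, n: int, k: int) -> np.ndarray:
    covered = np.zeros(n, dtype=bool)
    for s in np.flatnonzero(match):
        covered[s : s + k] = True
    return covered


def coverage(
    consensus: NucSequence, index: KmerIndex, orientation: str = "antisense"
) -> CoverageProfile:
    """Exact-match k-mer coverage of a consensus by a cluster index.

    Position i is covered iff some window [s, s+k) containing i matches the
    index (rev-complemented first for antisense orientation). A consensus
    shorter than k has an all-false track.
    """
    if orientation not in ("antisense", "sense"):
        raise ValueError("orientation must be 'antisense' or 'sense'")
    match = _window_matches(consensus.seq, index, orientation)
    covered = _mark_covered(match, len(consensus), index.k)
    return CoverageProfile(consensus.id, index.source_id, orientation, covered, index.k)


def coverage_mismatch(
    consensus: NucSequence,
    index: KmerIndex,
    orientation: str = "antisense",
    max_mm: int = 0,
) -> CoverageProfile:
    """Coverage allowing up to max_mm Hamming mismatches per window.

    max_mm = 0 reproduces :func:`coverage` exactly (and takes that fast
    path). The mismatch tolerance is Hamming (substitutions only), which is
    flagged in output headers.
    """
    if not (0 <= max_mm <= 5):
        raise ValueError("max_mm must be in 0..5")
    if max_mm == 0:
        return coverage(consensus, index, orientation)
    k = index.k
    n = len(consensus)
    nwin = max(0, n - k + 1)
    match = np.zeros(nwin, dtype=bool)
    if index.kmers and nwin > 0:
        mat = np.array(
            [[_BASE_CODE[c] for c in kmer] for kmer in sorted(index.kmers)],
            dtype=np.uint8,
        )
        seq = consensus.seq
        exact = index.kmers
        for s in range(nwin):
            w = seq[s : s + k]
            probe = revcomp(w) if orientation == "antisense" else w
            if probe in exact:
                match[s] = True
                continue
            if "N" in probe:
                continue
            vec = np.frombuffer(
                bytes(_BASE_CODE[c] for c in probe), dtype=np.uint8
            )
            if int((mat != vec).sum(axis=1).min()) <= max_mm:
                match[s] = True
    covered = _mark_covered(match, n, k)
    return CoverageProfile(consensus.id, index.source_id, orientation, covered, k)


def silencing_matrix(
    clusters: list[NucSequence],
    consensuses: list[NucSequence],
    k: int = DEFAULT_K,
    max_mm: int = 0,
    both_strands: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """All-vs-all antisense coverage fractions.

    One row per consensus, one column per cluster. Clusters named in
    ``both_strands`` (dual-strand piRNA loci) are indexed on both strands;
    all others in their given (transcribed) orientation only.
    """
    if not clusters or not consensuses:
        raise ValueError("clusters and consensuses must be non-empty")
    for group, name in ((clusters, "cluster"), (consensuses, "consensus")):
        ids = [s.id for s in group]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate {name} ids")
    mat = pd.DataFrame(
        index=[c.id for c in consensuses],
        columns=[c.id for c in clusters],
        dtype=float,
    )
    for cluster in clusters:
        index = build_kmer_index(cluster, k=k, both_strands=cluster.id in both_strands)
        for consensus in consensuses:
            prof = coverage_mismatch(consensus, index, "antisense", max_mm)
            mat.loc[consensus.id, cluster.id] = prof.fraction
    mat.index.name = "consensus_id"
    return mat
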