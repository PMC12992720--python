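"""Synthetic data with ground truth for every analysis stage.

Generates structured consensus elements (LTR5-UTR5-gag-pol-envF-UTR3-LTR3
with identical terminal repeats), insertions aged under a Jukes-Cantor-style
clock (each LTR accumulates Poisson(r*T*L) substitutions independently, so
pairwise LTR divergence grows at 2r per Myr — exactly the generative
assumption the dating estimator inverts), piRNA-cluster-like assemblies of
oriented TE fragments separated by random spacers, recombinant proviruses
produced by coordinate-based template switches between two variant genomes,
and single injected inactivating mutations (frameshift indels, premature
stops).

No indel evolution occurs in the clock model — indels enter only through
inject_inactivation and recombination — which keeps the ground truth exact.
Same parameters and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _align
from .seqcore_io import (
    ConsensusElement,
    EnvStatus,
    Feature,
    FeatureAnnotation,
    InsertionRecord,
    NucSequence,
    revcomp,
)

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SimParams:
    """Generator defaults emulate a mid-sized errantivirus-like element.

    Lengths are in nt; ORF lengths include start and stop codons and are
    rounded up to full codons. r is in substitutions/site/Myr and ages in
    Myr (the dating stage reports kyr downstream).
    """

    seed: int = 0
    ltr_len: int = 400
    utr5_len: int = 300
    utr3_len: int = 150
    gag_len: int = 900
    pol_len: int = 1500
    envf_len: int = 900
    r: float = 0.0346
    ages_myr: tuple[float, ...] = (0.05, 0.15, 0.5)
    base_comp: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    spacer_len: int = 500

    def __post_init__(self) -> None:
        for name in ("ltr_len", "utr5_len", "utr3_len", "gag_len", "pol_len",
                     "envf_len", "spacer_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if abs(sum(self.base_comp) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_seq(rng: np.random.Generator, n: int,
               comp: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list(BASES), size=n, p=list(comp)))


def random_orf(rng: np.random.Generator, n_nt: int) -> str:
    """ATG + stop-free random codons + stop, exactly ceil codons of n_nt."""
    n_codons = max(3, (n_nt + 2) // 3)
    internal = []
    while len(internal) < n_codons - 2:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in STOP_CODONS:
            internal.append(codon)
    stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
    return "ATG" + "".join(internal) + stop


def make_consensus(params: SimParams, name: str = "cons1") -> ConsensusElement:
    """A structured element LTR5+UTR5+gag+pol+envF+UTR3+LTR3, LTR5 == LTR3."""
    rng = _rng(params.seed)
    ltr = random_seq(rng, params.ltr_len, params.base_comp)
    utr5 = random_seq(rng, params.utr5_len, params.base_comp)
    gag = random_orf(rng, params.gag_len)
    pol = random_orf(rng, params.pol_len)
    envf = random_orf(rng, params.envf_len)
    utr3 = random_seq(rng, params.utr3_len, params.base_comp)
    parts = [ltr, utr5, gag, pol, envf, utr3, ltr]
    seq = "".join(parts)
    feats = []
    pos = 0
    for part, feat in zip(
        parts,
        (Feature.LTR5, Feature.UTR5, Feature.GAG, Feature.POL, Feature.ENVF,
         Feature.UTR3, Feature.LTR3),
    ):
        feats.append(FeatureAnnotation(name, feat, pos, pos + len(part)))
        pos += len(part)
    return ConsensusElement(
        sequence=NucSequence(name, seq),
        features=feats,
        subclade="synthetic",
        env_status=EnvStatus.FULL_LENGTH,
    )


# ---------------------------------------------------------------------------
# clock evolution
# ---------------------------------------------------------------------------

def _substitute(rng: np.random.Generator, seq: list[str], start: int, end: int,
                n: int) -> int:
    """Place n substitutions uniformly on seq[start:end]; returns number of
    positions actually changed (multiple hits may overlap)."""
    changed = 0
    for _ in range(n):
        pos = int(rng.integers(start, end))
        old = seq[pos]
        choices = [b for b in BASES if b != old]
        seq[pos] = choices[int(rng.integers(3))]
        if seq[pos] != old:
            changed += 1
    return n


def evolve_insertion(
    consensus: ConsensusElement,
    age_myr: float,
    r: float = 0.0346,
    seed: int = 0,
    insertion_id: str | None = None,
) -> tuple[InsertionRecord, dict]:
    """Age a copy of the consensus: Poisson(r*T*L) substitutions per region.

    The 5' LTR, internal sequence, and 3' LTR each drift independently; the
    substitution model is JC-symmetric (uniform target base != source), with
    no indels.
    """
    if age_myr < 0:
        raise ValueError("age must be >= 0")
    rng = _rng(seed)
    seq = list(consensus.sequence.seq)
    ltr5 = consensus.feature(Feature.LTR5)
    ltr3 = consensus.feature(Feature.LTR3)
    regions = {
        "ltr5": (ltr5.start, ltr5.end),
        "internal": (ltr5.end, ltr3.start),
        "ltr3": (ltr3.start, ltr3.end),
    }
    counts = {}
    for name, (start, end) in regions.items():
        lam = r * age_myr * (end - start)
        n = int(rng.poisson(lam))
        counts[name] = _substitute(rng, seq, start, end, n)
    iid = insertion_id or f"{consensus.id}_age{age_myr:g}_s{seed}"
    record = InsertionRecord(sequence=NucSequence(iid, "".join(seq)),
                             source_genome="synthetic")
    truth = {
        "insertion_id": iid,
        "consensus_id": consensus.id,
        "age_myr": age_myr,
        "r": r,
        "n_sub_ltr5": counts["ltr5"],
        "n_sub_ltr3": counts["ltr3"],
        "n_sub_internal": counts["internal"],
    }
    return record, truth


# ---------------------------------------------------------------------------
# cluster assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentPlan:
    consensus_id: str
    start: int
    end: int
    orientation: str  # "antisense" | "sense" relative to cluster transcription

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid fragment interval")
        if self.orientation not in ("antisense", "sense"):
            raise ValueError("orientation must be 'antisense' or 'sense'")


def assemble_cluster(
    plan: list[FragmentPlan],
    consensuses: dict[str, ConsensusElement],
    spacer_len: int = 500,
    seed: int = 0,
    cluster_id: str = "cluster1",
) -> tuple[NucSequence, list[dict]]:
    """Interleave random spacers with oriented consensus fragments.

    An antisense fragment is inserted as the reverse complement of the
    consensus interval, which is what produces TE-complementary piRNAs from
    the cluster transcript. Truth records, per fragment, the source interval
    and orientation: with exact k-mer matching, antisense fragments cover
    their source interval up to junction effects confined to < k-1 positions
    at each edge.
    """
    rng = _rng(seed)
    pieces = [random_seq(rng, spacer_len)]
    truth = []
    offset = spacer_len
    for frag in plan:
        cons = consensuses[frag.consensus_id]
        if frag.end > len(cons.sequence):
            raise ValueError(
                f"fragment [{frag.start},{frag.end}) exceeds "
                f"{frag.consensus_id} length {len(cons.sequence)}"
            )
        sub = cons.sequence.seq[frag.start : frag.end]
        inserted = revcomp(sub) if frag.orientation == "antisense" else sub
        pieces.append(inserted)
        truth.append(
            {
                "cluster_id": cluster_id,
                "consensus_id": frag.consensus_id,
                "start": frag.start,
                "end": frag.end,
                "orientation": frag.orientation,
                "cluster_offset": offset,
            }
        )
        offset += len(inserted)
        spacer = random_seq(rng, spacer_len)
        pieces.append(spacer)
        offset += spacer_len
    return NucSequence(cluster_id, "".join(pieces)), truth


# ---------------------------------------------------------------------------
# recombination
# ---------------------------------------------------------------------------

def make_recombinant(
    parent1: NucSequence,
    parent2: NucSequence,
    breakpoints: list[int],
    recombinant_id: str = "recombinant",
) -> tuple[NucSequence, dict]:
    """Template-switch chimera: parent1 up to breakpoint 1, then parent2 to
    breakpoint 2, alternating. Breakpoints are strictly increasing parent1
    coordinates; homologous parent2 coordinates are mapped through the
    shared global aligner (1:1 when the parents align gap-free).
    """
    if any(b <= 0 or b >= len(parent1) for b in breakpoints):
        raise ValueError("breakpoints must lie strictly inside parent1")
    if any(b >= c for b, c in zip(breakpoints, breakpoints[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    if not breakpoints:
        return NucSequence(recombinant_id, parent1.seq), {
            "recombinant_id": recombinant_id,
            "parent1": parent1.id,
            "parent2": parent2.id,
            "breakpoints_parent1": [],
        }
    if len(parent1) == len(parent2):
        coord_map = {b: b for b in breakpoints}
    else:
        a1, a2, _ = _align.align_global(parent1.seq, parent2.seq)
        p1_to_p2 = {}
        p1 = p2 = 0
        for x, y in zip(a1, a2):
            if x != _align.GAP:
                p1_to_p2[p1] = p2
                p1 += 1
            if y != _align.GAP:
                p2 += 1
        coord_map = {b: p1_to_p2[b] for b in breakpoints}
    parts = []
    sources = [parent1.seq, parent2.seq]
    cur = 0
    prev1 = 0
    prev = 0  # position in current source's coordinates
    for b in breakpoints:
        pos = b if cur == 0 else coord_map[b]
        parts.append(sources[cur][prev:pos])
        prev1 = b
        cur = 1 - cur
        prev = b if cur == 0 else coord_map[b]
    parts.append(sources[cur][prev:])
    truth = {
        "recombinant_id": recombinant_id,
        "parent1": parent1.id,
        "parent2": parent2.id,
        "breakpoints_parent1": list(breakpoints),
    }
    return NucSequence(recombinant_id, "".join(parts)), truth


def make_variant(
    consensus: ConsensusElement,
    n_substitutions: int,
    seed: int,
    name: str,
    regions: list[tuple[int, int]] | None = None,
    mirror_ltr: bool = True,
) -> tuple[ConsensusElement, list[int]]:
    """Derive a named variant by scattering substitutions at distinct sites.

    A variant genome carries identical LTRs at both ends (both are copied
    from one template at each replication), so with ``mirror_ltr`` any
    substitution landing in the 5' LTR is mirrored into the 3' LTR and the
    3' LTR is excluded from the sampling pool. Returns the variant and the
    sorted list of all substituted positions (the variant's private alleles
    — candidate diagnostic sites versus the source).
    """
    rng = _rng(seed)
    seq = list(consensus.sequence.seq)
    ltr5 = consensus.feature(Feature.LTR5)
    ltr3 = consensus.feature(Feature.LTR3)
    if regions is None:
        hi = ltr3.start if mirror_ltr else len(seq)
        regions = [(0, hi)]
    pool = np.concatenate([np.arange(s, e) for s, e in regions])
    if n_substitutions > pool.size:
        raise ValueError("more substitutions than available positions")
    positions = sorted(
        int(p) for p in rng.choice(pool, size=n_substitutions, replace=False)
    )
    mirrored: list[int] = []
    for pos in positions:
        old = seq[pos]
        choices = [b for b in BASES if b != old]
        seq[pos] = choices[int(rng.integers(3))]
        if mirror_ltr and ltr5.start <= pos < ltr5.end:
            twin = ltr3.start + (pos - ltr5.start)
            seq[twin] = seq[pos]
            mirrored.append(twin)
    positions = sorted(positions + mirrored)
    variant = ConsensusElement(
        sequence=NucSequence(name, "".join(seq)),
        features=[replace(f, element_id=name) for f in consensus.features],
        subclade=consensus.subclade,
        env_status=consensus.env_status,
    )
    return variant, positions


# ---------------------------------------------------------------------------
# inactivating mutations
# ---------------------------------------------------------------------------

def _in_homopolymer(seq: str, pos: int) -> bool:
    """True when seq[pos] equals either neighbour (alignment-ambiguous site
    for single-base indels)."""
    left = seq[pos - 1] if pos > 0 else None
    right = seq[pos + 1] if pos + 1 < len(seq) else None
    return seq[pos] in (left, right)


def _shift_from_homopolymer(seq: str, pos: int, lo: int, hi: int) -> int:
    for delta in range(0, hi - lo):
        for cand in (pos + delta, pos - delta):
            if lo <= cand < hi and not _in_homopolymer(seq, cand):
                return cand
    return pos


def inject_inactivation(
    consensus: ConsensusElement,
    orf: Feature,
    kind: str,
    position: int,
    seed: int = 0,
    avoid_homopolymers: bool = True,
) -> tuple[ConsensusElement, dict]:
    """Apply one inactivating event inside the named ORF.

    kind is "insertion" (one extra base), "deletion" (one base removed), or
    "substitution_stop" (a single substitution turning a codon into a stop).
    ``position`` is 0-based relative to the ORF start; indel positions
    falling in homopolymers are shifted to the nearest unambiguous site by
    default (recorded in the truth). Returns the mutated element (features
    downstream of an indel are re-shifted) and the truth record.
    """
    ann = consensus.feature(orf)
    if ann is None:
        raise ValueError(f"{consensus.id} has no {orf.value} annotation")
    if not (0 <= position < len(ann)):
        raise ValueError(f"position {position} outside {orf.value}")
    rng = _rng(seed)
    seq = consensus.sequence.seq
    abs_pos = ann.start + position
    shift = 0
    new_seq = seq
    if kind == "insertion":
        if avoid_homopolymers:
            abs_pos = _shift_from_homopolymer(seq, abs_pos, ann.start + 1,
                                              ann.end - 1)
        # inserted base must differ from both neighbours for an unambiguous
        # left-aligned event coordinate
        avoid = {seq[abs_pos - 1], seq[abs_pos]}
        choices = [b for b in BASES if b not in avoid]
        base = choices[int(rng.integers(len(choices)))]
        new_seq = seq[:abs_pos] + base + seq[abs_pos:]
        shift = 1
        event_len = 1
    elif kind == "deletion":
        if avoid_homopolymers:
            abs_pos = _shift_from_homopolymer(seq, abs_pos, ann.start + 1,
                                              ann.end - 1)
        new_seq = seq[:abs_pos] + seq[abs_pos + 1 :]
        shift = -1
        event_len = 1
    elif kind == "substitution_stop":
        abs_pos, new_seq = _make_premature_stop(seq, ann, position)
        event_len = 0
    else:
        raise ValueError(f"unknown inactivation kind {kind!r}")

    new_feats = []
    for f in consensus.features:
        start, end = f.start, f.end
        if start > abs_pos:
            start += shift
        if end > abs_pos:
            end += shift
        new_feats.append(replace(f, start=start, end=end))
    mutated = ConsensusElement(
        sequence=NucSequence(consensus.id, new_seq),
        features=new_feats,
        subclade=consensus.subclade,
        env_status=consensus.env_status,
    )
    truth = {
        "element_id": consensus.id,
        "orf": orf.value,
        "kind": kind,
        "requested_position": position,
        "orf_position": abs_pos - ann.start,
        "length": event_len,
    }
    return mutated, truth


def _make_premature_stop(seq: str, ann, position: int) -> tuple[int, str]:
    """Find, at/near the requested ORF position, a codon convertible into a
    stop by a single substitution; apply it. Returns (absolute nt position
    of the substitution, mutated sequence)."""
    orf_seq = seq[ann.start : ann.end]
    n_codons = len(orf_seq) // 3
    want = position // 3
    # skip start codon and the terminal stop
    candidates = sorted(range(1, n_codons - 1), key=lambda c: abs(c - want))
    for cidx in candidates:
        codon = orf_seq[3 * cidx : 3 * cidx + 3]
        if codon in STOP_CODONS:
            continue
        for stop in STOP_CODONS:
            diff = [i for i in range(3) if codon[i] != stop[i]]
            if len(diff) == 1:
                within = diff[0]
                abs_pos = ann.start + 3 * cidx + within
                new_seq = seq[:abs_pos] + stop[within] + seq[abs_pos + 1 :]
                return abs_pos, new_seq
    raise ValueError("no codon near the requested position can become a stop "
                     "by a single substitution")
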