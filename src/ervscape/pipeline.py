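"""End-to-end orchestration: simulate -> annotate -> date -> silencing -> recombination.

Plain-file orchestration: stages communicate only through the declared
FASTA/TSV/BED formats, each stage is idempotent (re-running a completed
stage with unchanged inputs and config is a checksum-verified no-op), and a
manifest of outputs with checksums is written at the end. All randomness
flows from the single config seed; each stage derives its own stream by
hashing the stage name into the seed, so stages are reproducible
independently of one another.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ltr_dating, orf_integrity, silencing_potential, synthetic_data
from . import variants_recombination as vr
from .seqcore_io import (
    ConsensusElement,
    Feature,
    FeatureAnnotation,
    InsertionRecord,
    Msa,
    NucSequence,
    bind_annotations,
    read_annotation_table,
    read_fasta,
    write_annotation_table,
    write_coverage_bed,
    write_fasta,
    write_tsv,
)

log = logging.getLogger("ervscape")

STAGES = ("simulate", "annotate", "date", "silencing", "recombination")

_KNOWN_TOP = {"seed", "out_dir", "stages", "log_level", "inputs"} | set(STAGES)
_KNOWN_STAGE_KEYS = {
    "simulate": {"n_elements", "ages_myr", "ltr_len", "utr5_len", "utr3_len",
                 "gag_len", "pol_len", "envf_len", "r", "spacer_len",
                 "n_insertions_per_age", "n_diagnostic", "breakpoint"},
    "annotate": {"min_aa"},
    "date": {"model", "r"},
    "silencing": {"k", "max_mm", "both_strands", "write_bed"},
    "recombination": {"min_sites_per_segment"},
}
_KNOWN_INPUT_KEYS = {"consensus_fasta", "annotation_tsv", "insertions_fasta",
                     "clusters_fasta", "msa_fasta"}


class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad value)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: Path = Path("ervscape_run")
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    log_level: str = "INFO"
    inputs: dict = field(default_factory=dict)
    stage_params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_TOP
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        stages = list(raw.get("stages", STAGES))
        bad = [s for s in stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stage(s): {bad}")
        stage_params = {}
        for stage in STAGES:
            params = raw.get(stage, {}) or {}
            extra = set(params) - _KNOWN_STAGE_KEYS[stage]
            if extra:
                raise ConfigError(
                    f"unknown key(s) in stage {stage!r}: {sorted(extra)}"
                )
            stage_params[stage] = params
        inputs = raw.get("inputs", {}) or {}
        extra = set(inputs) - _KNOWN_INPUT_KEYS
        if extra:
            raise ConfigError(f"unknown input key(s): {sorted(extra)}")
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "ervscape_run")),
            stages=stages,
            log_level=str(raw.get("log_level", "INFO")),
            inputs=inputs,
            stage_params=stage_params,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(raw)

    def stage_seed(self, stage: str) -> int:
        """Per-stage derived seed: stage name hashed into the run seed."""
        return (self.seed ^ zlib.crc32(stage.encode())) % (2**31)

    def serialized(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "stages": self.stages,
                "inputs": {k: str(v) for k, v in self.inputs.items()},
                "stage_params": self.stage_params,
            },
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class ValidationReport:
    warnings: list[str] = field(default_factory=list)
    fatal: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(
    sequences: list[NucSequence], annotations: list[FeatureAnnotation]
) -> ValidationReport:
    """Cross-check annotations against sequences (ids, coordinate bounds)."""
    report = ValidationReport()
    lengths = {s.id: len(s) for s in sequences}
    annotated: set[str] = set()
    for a in annotations:
        annotated.add(a.element_id)
        if a.element_id not in lengths:
            report.fatal.append(
                f"annotation references absent element {a.element_id!r}"
            )
            continue
        if a.end > lengths[a.element_id]:
            report.fatal.append(
                f"{a.element_id}/{a.feature.value}: end {a.end} exceeds "
                f"sequence length {lengths[a.element_id]}"
            )
    for sid in lengths:
        if sid not in annotated:
            report.warnings.append(f"sequence {sid!r} has no annotations")
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_done_path(out_dir: Path, stage: str) -> Path:
    return out_dir / f".{stage}.done.json"


def _stage_is_current(cfg: RunConfig, stage: str, outputs: list[Path]) -> bool:
    done = _stage_done_path(cfg.out_dir, stage)
    if not done.exists():
        return False
    try:
        record = json.loads(done.read_text())
    except json.JSONDecodeError:
        return False
    if record.get("config") != cfg.serialized():
        return False
    for path_str, digest in record.get("outputs", {}).items():
        path = Path(path_str)
        if not path.exists() or _sha256(path) != digest:
            return False
    return True


def _mark_stage_done(cfg: RunConfig, stage: str, outputs: list[Path]) -> None:
    record = {
        "config": cfg.serialized(),
        "outputs": {str(p): _sha256(p) for p in outputs},
    }
    _stage_done_path(cfg.out_dir, stage).write_text(json.dumps(record, indent=1))


def _run_simulate(cfg: RunConfig) -> list[Path]:
    p = cfg.stage_params["simulate"]
    seed = cfg.stage_seed("simulate")
    params = synthetic_data.SimParams(
        seed=seed,
        ltr_len=p.get("ltr_len", 400),
        utr5_len=p.get("utr5_len", 300),
        utr3_len=p.get("utr3_len", 150),
        gag_len=p.get("gag_len", 900),
        pol_len=p.get("pol_len", 1500),
        envf_len=p.get("envf_len", 900),
        r=p.get("r", 0.0346),
        ages_myr=tuple(p.get("ages_myr", (0.05, 0.15, 0.5))),
        spacer_len=p.get("spacer_len", 500),
    )
    n_elements = p.get("n_elements", 3)
    per_age = p.get("n_insertions_per_age", 2)
    out = cfg.out_dir
    consensuses = []
    for i in range(n_elements):
        sub = synthetic_data.SimParams(
            seed=seed + 1 + i, ltr_len=params.ltr_len, utr5_len=params.utr5_len,
            utr3_len=params.utr3_len, gag_len=params.gag_len,
            pol_len=params.pol_len, envf_len=params.envf_len, r=params.r,
            ages_myr=params.ages_myr, spacer_len=params.spacer_len,
        )
        consensuses.append(synthetic_data.make_consensus(sub, f"cons{i+1}"))
    write_fasta([c.sequence for c in consensuses], out / "consensus.fasta")
    annots = [f for c in consensuses for f in c.features]
    write_annotation_table(annots, out / "consensus_annotation.tsv")

    insertions, truth_rows = [], []
    k = 0
    for cons in consensuses:
        for age in params.ages_myr:
            for j in range(per_age):
                rec, truth = synthetic_data.evolve_insertion(
                    cons, age, r=params.r, seed=seed + 1000 + k,
                    insertion_id=f"{cons.id}_ins{k}",
                )
                insertions.append(rec)
                truth_rows.append(truth)
                k += 1
    write_fasta([r.sequence for r in insertions], out / "insertions.fasta")
    write_tsv(pd.DataFrame(truth_rows), out / "insertions_truth.tsv",
              seed=seed, r=params.r)

    plan = [
        synthetic_data.FragmentPlan(c.id, 0, len(c.sequence), "antisense")
        for c in consensuses[: max(1, n_elements // 2)]
    ]
    cluster, cluster_truth = synthetic_data.assemble_cluster(
        plan, {c.id: c for c in consensuses},
        spacer_len=params.spacer_len, seed=seed + 5000,
    )
    write_fasta([cluster], out / "clusters.fasta")
    write_tsv(pd.DataFrame(cluster_truth), out / "cluster_truth.tsv", seed=seed)

    # recombinant panel: two variants of consensus 1 + one mid-element switch
    cons = consensuses[0]
    n_diag = p.get("n_diagnostic", 40)
    bp = p.get("breakpoint", len(cons.sequence) // 2)
    var_a, _ = synthetic_data.make_variant(cons, n_diag, seed + 7000, "varA")
    var_b, _ = synthetic_data.make_variant(cons, n_diag, seed + 7001, "varB")
    recombinant, rec_truth = synthetic_data.make_recombinant(
        var_a.sequence, var_b.sequence, [bp], "recombinant1"
    )
    rows = [
        ("A1", var_a.sequence.seq), ("A2", var_a.sequence.seq),
        ("B1", var_b.sequence.seq), ("B2", var_b.sequence.seq),
        ("recombinant1", recombinant.seq),
    ]
    msa = Msa(rows)
    from .seqcore_io import write_msa

    write_msa(msa, out / "recombinant_panel.fasta")
    write_tsv(pd.DataFrame([rec_truth]), out / "recombinant_truth.tsv", seed=seed)
    return [
        out / "consensus.fasta", out / "consensus_annotation.tsv",
        out / "insertions.fasta", out / "insertions_truth.tsv",
        out / "clusters.fasta", out / "cluster_truth.tsv",
        out / "recombinant_panel.fasta", out / "recombinant_truth.tsv",
    ]


def _load_consensuses(cfg: RunConfig) -> dict[str, ConsensusElement]:
    cons_path = cfg.inputs.get("consensus_fasta", cfg.out_dir / "consensus.fasta")
    annot_path = cfg.inputs.get(
        "annotation_tsv", cfg.out_dir / "consensus_annotation.tsv"
    )
    seqs = read_fasta(cons_path)
    annots = read_annotation_table(annot_path)
    report = validate_inputs(seqs, annots)
    if not report.ok:
        raise StageError("input validation failed: " + "; ".join(report.fatal))
    return bind_annotations(seqs, annots)


def _load_insertions(cfg: RunConfig) -> list[InsertionRecord]:
    path = cfg.inputs.get("insertions_fasta", cfg.out_dir / "insertions.fasta")
    return [InsertionRecord(sequence=s) for s in read_fasta(path)]


def _match_reference(
    ins: InsertionRecord, consensuses: dict[str, ConsensusElement]
) -> ConsensusElement:
    for cid, cons in consensuses.items():
        if ins.id.startswith(cid):
            return cons
    return next(iter(consensuses.values()))


def _run_annotate(cfg: RunConfig) -> list[Path]:
    consensuses = _load_consensuses(cfg)
    insertions = _load_insertions(cfg)
    rows = []
    for ins in insertions:
        ref = _match_reference(ins, consensuses)
        try:
            rep = orf_integrity.classify_integrity(ins, ref)
        except orf_integrity.UnrelatedElementError as exc:
            rows.append(dict(insertion_id=ins.id, gag_status="error",
                             pol_status="error", envF_status="error",
                             **{"class": "unrelated_element"}, events=str(exc)))
            continue
        ev = ";".join(
            f"{e.kind.value}@{e.ref_position}"
            for feat in rep.events for e in rep.events[feat]
        )
        rows.append(dict(
            insertion_id=ins.id,
            gag_status=rep.statuses[Feature.GAG].value,
            pol_status=rep.statuses[Feature.POL].value,
            envF_status=rep.statuses[Feature.ENVF].value,
            **{"class": rep.overall_class.value},
            events=ev,
        ))
    out = cfg.out_dir / "orf_report.tsv"
    write_tsv(pd.DataFrame(rows), out, stage="annotate")
    return [out]


def _run_date(cfg: RunConfig) -> list[Path]:
    p = cfg.stage_params["date"]
    model = p.get("model", "JC69")
    r = p.get("r", 0.0346)
    consensuses = _load_consensuses(cfg)
    insertions = _load_insertions(cfg)
    rows = []
    for ins in insertions:
        ref = _match_reference(ins, consensuses)
        try:
            pair, age = ltr_dating.date_insertion(ins, ref, model=model, r=r)
        except ltr_dating.SoloOrTruncatedError:
            rows.append(dict(insertion_id=ins.id, ltr_len5="NA", ltr_len3="NA",
                             p="NA", K="NA", T_years="NA", T_TYA="NA",
                             note="solo_or_truncated"))
            continue
        rows.append(dict(
            insertion_id=ins.id,
            ltr_len5=len(pair.ltr5_seq), ltr_len3=len(pair.ltr3_seq),
            p=round(pair.p_distance, 6), K=round(pair.K, 6),
            T_years=round(age.T_years, 1), T_TYA=round(age.T_tya, 3), note="",
        ))
    out = cfg.out_dir / "ages.tsv"
    write_tsv(pd.DataFrame(rows), out, stage="date", model=model, r=r)
    return [out]


def _run_silencing(cfg: RunConfig) -> list[Path]:
    p = cfg.stage_params["silencing"]
    k = p.get("k", 25)
    max_mm = p.get("max_mm", 0)
    both = set(p.get("both_strands", []))
    clusters = read_fasta(
        cfg.inputs.get("clusters_fasta", cfg.out_dir / "clusters.fasta")
    )
    cons_path = cfg.inputs.get("consensus_fasta", cfg.out_dir / "consensus.fasta")
    consensuses = read_fasta(cons_path)
    mat = silencing_potential.silencing_matrix(
        clusters, consensuses, k=k, max_mm=max_mm, both_strands=both
    )
    out = cfg.out_dir / "silencing_matrix.tsv"
    write_tsv(mat, out, index=True, stage="silencing", k=k, max_mm=max_mm,
              mismatch_metric="hamming",
              both_strands=",".join(sorted(both)) or "none")
    outputs = [out]
    if p.get("write_bed", True):
        bed_dir = cfg.out_dir / "coverage_bed"
        bed_dir.mkdir(exist_ok=True)
        for cluster in clusters:
            index = silencing_potential.build_kmer_index(
                cluster, k=k, both_strands=cluster.id in both
            )
            for cons in consensuses:
                prof = silencing_potential.coverage_mismatch(
                    cons, index, "antisense", max_mm
                )
                bed = bed_dir / f"{cons.id}__{cluster.id}.bed"
                write_coverage_bed(prof, bed)
                outputs.append(bed)
    return outputs


def _run_recombination(cfg: RunConfig) -> list[Path]:
    p = cfg.stage_params["recombination"]
    min_seg = p.get("min_sites_per_segment", 2)
    from .seqcore_io import read_msa

    msa = read_msa(
        cfg.inputs.get("msa_fasta", cfg.out_dir / "recombinant_panel.fasta")
    )
    ids = msa.ids
    if len(ids) < 5:
        raise StageError("recombination stage needs >= 5 rows (4 parents + query)")
    a1, a2, b1, b2, *queries = ids
    sites = vr.diagnostic_sites(msa, a1, a2, b1, b2)
    rows = []
    for q in queries:
        call = vr.call_recombinant(msa, q, sites, min_sites_per_segment=min_seg)
        rows.append(dict(
            query_id=q,
            n_sites=len(sites),
            n_switches=call.n_switches,
            segments=";".join(
                f"{s.call}:{s.first_column}-{s.last_column}" for s in call.segments
            ),
            breakpoints=";".join(f"({a},{b})" for a, b in call.breakpoints),
        ))
    out = cfg.out_dir / "recombination_calls.tsv"
    write_tsv(pd.DataFrame(rows), out, stage="recombination",
              min_sites_per_segment=min_seg)
    return [out]


_STAGE_FUNCS = {
    "simulate": _run_simulate,
    "annotate": _run_annotate,
    "date": _run_date,
    "silencing": _run_silencing,
    "recombination": _run_recombination,
}


def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Execute the configured stages in dependency order.

    Returns the manifest (path, sha256) of all outputs; also written to
    ``<out_dir>/manifest.tsv``. A completed stage with unchanged inputs and
    config is skipped.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    handler = logging.FileHandler(cfg.out_dir / "run.log")
    log.addHandler(handler)
    log.info("run config: %s", cfg.serialized())
    all_outputs: list[Path] = []
    try:
        for stage in STAGES:
            if stage not in cfg.stages:
                continue
            func = _STAGE_FUNCS[stage]
            done = _stage_done_path(cfg.out_dir, stage)
            if _stage_is_current(cfg, stage, []):
                record = json.loads(done.read_text())
                outputs = [Path(p) for p in record["outputs"]]
                log.info("stage %s: up to date, skipping", stage)
            else:
                log.info("stage %s: running (seed %d)", stage,
                         cfg.stage_seed(stage))
                try:
                    outputs = func(cfg)
                except Exception as exc:
                    raise StageError(f"stage {stage!r} failed: {exc}") from exc
                _mark_stage_done(cfg, stage, outputs)
            all_outputs.extend(outputs)
    finally:
        log.removeHandler(handler)
        handler.close()
    manifest = pd.DataFrame(
        [(str(p), _sha256(p)) for p in all_outputs], columns=["path", "sha256"]
    )
    write_tsv(manifest, cfg.out_dir / "manifest.tsv", seed=cfg.seed)
    return manifest
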