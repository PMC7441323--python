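"""End-to-end orchestration: simulate -> search -> screen -> classify.

Each stage writes its outputs under the run directory and records them in
a JSON manifest (config hash, seeds, per-stage outputs with content
hashes, wall times, and the candidate funnel). ``resume=True`` skips a
stage when all of its recorded outputs still exist with matching hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .homology import ScoringScheme, default_scoring, seeded_search
from .io_formats import (
    ScreenConfig,
    load_screen_config,
    read_fasta,
    write_hit_table,
)
from .motifs import (
    DomainAnnotation,
    NoveltyClass,
    SegmentLabel,
    classify_gene,
    read_domain_annotations,
)
from .records import MolType
from .screen import ScreenResult, run_screen, write_report
from .simulate import SimulationConfig, simulate_clade, write_clade

log = logging.getLogger("trgscreen")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class StageRecord:
    name: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    wall_time: float = 0.0
    counts: dict[str, int] = field(default_factory=dict)
    skipped: bool = False


@dataclass
class RunManifest:
    config_hash: str
    tool_version: str
    seed: int | None
    stages: list[StageRecord] = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        stages = [StageRecord(**s) for s in raw.pop("stages", [])]
        return cls(stages=stages, **raw)


def _prev_stage(prev: RunManifest | None, name: str) -> StageRecord | None:
    if prev is None:
        return None
    for stage in prev.stages:
        if stage.name == name:
            return stage
    return None


def _stage_is_current(prev: RunManifest | None, name: str) -> bool:
    stage = _prev_stage(prev, name)
    if stage is None or not stage.outputs:
        return False
    return all(
        Path(p).exists() and _sha256(Path(p)) == digest
        for p, digest in stage.outputs.items()
    )


def classify_candidates(
    result: ScreenResult,
    config: ScreenConfig,
    domains: dict[str, list[DomainAnnotation]],
    scoring: ScoringScheme | None = None,
) -> pd.DataFrame:
    """Classify every candidate that passes the ingroup criterion.

    Ortholog members are the best annotated hit per ingroup genome; genes
    whose only ingroup evidence is rescued (no annotated ortholog
    sequence available) stay unclassified.
    """
    if scoring is None:
        scoring = default_scoring()
    focal_proteome = {
        r.seq_id: r
        for r in read_fasta(
            config.proteomes[config.focal_genome],
            MolType.protein,
            genome_id=config.focal_genome,
        )
    }
    ingroup = [g for g in config.ingroup_genomes if g != config.focal_genome]
    seq_index: dict[str, dict[str, object]] = {}
    rows = []
    for cand in result.candidates:
        row = {"gene_id": cand.gene_id,
               "novelty_class": NoveltyClass.unclassified.value,
               "conserved_segments": "", "verdict": cand.verdict.value}
        if cand.passes_ingroup:
            best: dict[str, tuple[float, str]] = {}
            for hit in result.genome_hits:
                if hit.query_id != cand.gene_id or hit.frame != 0:
                    continue
                if hit.subject_genome not in ingroup:
                    continue
                if hit.evalue >= config.e_ingroup:
                    continue
                prev = best.get(hit.subject_genome)
                if prev is None or hit.evalue < prev[0]:
                    best[hit.subject_genome] = (hit.evalue, hit.subject_id)
            members = []
            for genome, (_, sid) in sorted(best.items()):
                if genome not in seq_index:
                    seq_index[genome] = {
                        r.seq_id: r
                        for r in read_fasta(
                            config.proteomes[genome], MolType.protein,
                            genome_id=genome,
                        )
                    }
                rec = seq_index[genome].get(sid)
                if rec is not None:
                    members.append(rec)
            if members:
                cls, segments = classify_gene(
                    members,
                    focal_proteome[cand.gene_id],
                    domains.get(cand.gene_id, []),
                    scoring,
                )
                row["novelty_class"] = cls.value
                row["conserved_segments"] = ";".join(
                    f"{s.start}-{s.end}:{s.label.value}"
                    for s in segments
                    if s.label is not SegmentLabel.unconserved
                )
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["gene_id", "verdict", "novelty_class",
                       "conserved_segments"]
    ).sort_values("gene_id").reset_index(drop=True)


def run_all(
    outdir,
    sim_config: SimulationConfig | None = None,
    screen_config_path=None,
    domains_path=None,
    resume: bool = False,
    scoring: ScoringScheme | None = None,
) -> RunManifest:
    """Run the whole pipeline in one reproducible pass.

    With ``sim_config`` the run starts from a seeded synthetic clade;
    otherwise ``screen_config_path`` (and optionally ``domains_path``)
    point at real inputs and the simulate stage is skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if scoring is None:
        scoring = default_scoring()
    if (sim_config is None) == (screen_config_path is None):
        raise ValueError("provide exactly one of sim_config / screen_config_path")

    manifest_path = outdir / "manifest.json"
    prev = RunManifest.read(manifest_path) if (resume and manifest_path.exists()) else None
    cfg_desc = (
        json.dumps(asdict(sim_config), sort_keys=True, default=str)
        if sim_config is not None
        else _sha256(Path(screen_config_path))
    )
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_desc.encode()).hexdigest(),
        tool_version=__version__,
        seed=sim_config.seed if sim_config is not None else None,
    )
    if prev is not None and prev.config_hash != manifest.config_hash:
        prev = None  # configuration changed: recompute everything

    def finish_stage(rec: StageRecord, t0: float, outputs: list[Path]) -> None:
        rec.outputs = {str(p): _sha256(p) for p in outputs}
        rec.wall_time = round(time.monotonic() - t0, 3)
        manifest.stages.append(rec)
        manifest.write(manifest_path)
        log.info("stage %s done in %.2fs: %s", rec.name, rec.wall_time,
                 rec.counts)

    # -- simulate ----------------------------------------------------------
    data_dir = outdir / "data"
    if sim_config is not None:
        rec = StageRecord("simulate")
        t0 = time.monotonic()
        if _stage_is_current(prev, "simulate"):
            rec = _prev_stage(prev, "simulate")
            rec.skipped = True
            manifest.stages.append(rec)
            manifest.write(manifest_path)
        else:
            clade = simulate_clade(sim_config)
            cfg_path = write_clade(clade, data_dir)
            outputs = sorted(data_dir.iterdir())
            rec.counts = {
                "families": len(clade.truth.families),
                "focal_genes": len(clade.focal_proteome),
            }
            finish_stage(rec, t0, outputs)
        screen_config_path = data_dir / "screen_config.yaml"
        domains_path = data_dir / "domains.tsv"

    config = load_screen_config(screen_config_path)

    # -- search ------------------------------------------------------------
    hits_dir = outdir / "hits"
    rec = StageRecord("search")
    t0 = time.monotonic()
    if _stage_is_current(prev, "search"):
        rec = _prev_stage(prev, "search")
        rec.skipped = True
        manifest.stages.append(rec)
        manifest.write(manifest_path)
    else:
        hits_dir.mkdir(exist_ok=True)
        focal = read_fasta(config.proteomes[config.focal_genome],
                           MolType.protein, genome_id=config.focal_genome)
        focal = sorted(focal, key=lambda r: r.seq_id)
        outputs = []
        n_hits = 0
        targets = [(g, config.proteomes[g]) for g in config.all_genomes
                   if g != config.focal_genome]
        targets += [(db.name, db.fasta_path) for db in config.exclusion_dbs]
        for name, fasta in targets:
            subjects = read_fasta(fasta, MolType.protein, genome_id=name)
            hits = []
            for gene in focal:
                hits.extend(seeded_search(gene, subjects, scoring))
            path = hits_dir / f"{name}.tsv"
            write_hit_table(hits, path)
            outputs.append(path)
            n_hits += len(hits)
        rec.counts = {"hits": n_hits, "targets": len(targets)}
        finish_stage(rec, t0, outputs)

    # -- screen ------------------------------------------------------------
    screen_cfg = ScreenConfig(
        **{
            **{k: getattr(config, k) for k in (
                "focal_genome", "ingroup_phyla", "outgroup_genomes",
                "exclusion_dbs", "e_ingroup", "e_exclusion", "e_rescue",
                "proteomes", "genome_dna", "ingroup_taxa",
                "count_focal_genome", "rescue_outgroups",
            )},
            "engine": "external_hits",
            "hits_dir": str(hits_dir),
        }
    )
    report_path = outdir / "report.tsv"
    rec = StageRecord("screen")
    t0 = time.monotonic()
    result = run_screen(screen_cfg, scoring)
    n_pass = sum(c.passes_ingroup for c in result.candidates)
    n_ls = sum(c.verdict.value == "lineage_specific" for c in result.candidates)
    write_report(result.report, report_path)
    rec.counts = {
        "focal_genes": len(result.candidates),
        "pass_ingroup": n_pass,
        "lineage_specific": n_ls,
    }
    finish_stage(rec, t0, [report_path])

    # -- classify ----------------------------------------------------------
    classify_path = outdir / "classification.tsv"
    rec = StageRecord("classify")
    t0 = time.monotonic()
    domains = read_domain_annotations(domains_path) if domains_path and Path(domains_path).exists() else {}
    classification = classify_candidates(result, screen_cfg, domains, scoring)
    classification.to_csv(classify_path, sep="\t", index=False)
    by_class = (
        classification[classification.verdict == "lineage_specific"]
        .novelty_class.value_counts().to_dict()
    )
    rec.counts = {f"ls_{k}": int(v) for k, v in sorted(by_class.items())}
    finish_stage(rec, t0, [classify_path])

    # funnel sanity: counts never increase across successive filters
    funnel = [len(result.candidates), n_pass, n_ls]
    if any(a < b for a, b in zip(funnel, funnel[1:])):
        raise AssertionError(f"non-monotone candidate funnel: {funnel}")
    return manifest
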