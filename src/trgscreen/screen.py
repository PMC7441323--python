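"""The lineage-specificity screen: presence/absence filtering of a focal
proteome across a clade.

A focal gene is called lineage-specific when (i) it has a homolog below
``e_ingroup`` in at least one *non-focal* genome of every ingroup phylum
(the focal genome's trivial self-hit cannot vouch for its own phylum), and
(ii) it has no hit below ``e_exclusion`` in any outgroup genome or in any
extra-clade entry of a reference exclusion database. Between building the
evidence matrix and applying the criteria, a translated rescue round
re-tests absent ingroup cells against genomic DNA, catching genes the
annotation missed. All thresholds are strict ("below").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import ScoringScheme, default_scoring, seeded_search, translated_search
from .io_formats import ScreenConfig, read_fasta, read_hit_table
from .records import HomologyHit, MolType, SequenceRecord


class Evidence(str, Enum):
    annotated = "annotated"
    rescued = "rescued"
    none = "none"


class Verdict(str, Enum):
    lineage_specific = "lineage_specific"
    rejected_ingroup = "rejected_ingroup"
    rejected_outgroup = "rejected_outgroup"


@dataclass
class PresenceMatrix:
    """Focal-gene x genome evidence table.

    ``best_evalue`` holds the minimum E-value observed per cell (NaN when
    no hit); ``evidence`` records whether it came from the annotated
    proteome or the translated rescue round. Presence is derived, never
    stored: an ingroup cell is present iff its best E-value is strictly
    below e_ingroup (annotated) or e_rescue (rescued); an outgroup cell
    iff strictly below e_exclusion.
    """

    config: ScreenConfig
    best_evalue: pd.DataFrame  # float, NaN = no hit
    evidence: pd.DataFrame  # str, one of Evidence values

    @classmethod
    def empty(cls, gene_ids: Sequence[str], config: ScreenConfig) -> "PresenceMatrix":
        genomes = [g for g in config.all_genomes if g != config.focal_genome]
        idx = pd.Index(sorted(gene_ids), name="gene_id")
        cols = pd.Index(genomes, name="genome_id")
        return cls(
            config=config,
            best_evalue=pd.DataFrame(np.nan, index=idx, columns=cols),
            evidence=pd.DataFrame(Evidence.none.value, index=idx, columns=cols),
        )

    def _threshold(self, genome: str, evid: str) -> float:
        cfg = self.config
        if genome in cfg.outgroup_genomes:
            return cfg.e_exclusion
        return cfg.e_rescue if evid == Evidence.rescued.value else cfg.e_ingroup

    @property
    def present(self) -> pd.DataFrame:
        out = pd.DataFrame(False, index=self.best_evalue.index,
                           columns=self.best_evalue.columns)
        for genome in self.best_evalue.columns:
            ev = self.best_evalue[genome]
            evid = self.evidence[genome]
            thr = np.array([self._threshold(genome, s) for s in evid])
            out[genome] = ev.notna().to_numpy() & (ev.to_numpy() < thr)
        return out

    def copy(self) -> "PresenceMatrix":
        return PresenceMatrix(self.config, self.best_evalue.copy(),
                              self.evidence.copy())


@dataclass
class CandidateGene:
    """One focal gene's screen verdict with its evidence trail."""

    gene_id: str
    passes_ingroup: bool
    excluded_by: list[tuple[str, float]] = field(default_factory=list)
    rescued_in: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> Verdict:
        if not self.passes_ingroup:
            return Verdict.rejected_ingroup
        if self.excluded_by:
            return Verdict.rejected_outgroup
        return Verdict.lineage_specific


def build_presence_matrix(
    focal_proteome: Sequence[SequenceRecord],
    hits: Iterable[HomologyHit],
    config: ScreenConfig,
) -> PresenceMatrix:
    """Fold per-genome hits into the evidence matrix.

    For each (focal gene, genome) cell the minimum E-value is kept; hits
    whose subject genome is the focal genome (self-hits) carry no
    cross-species information and are discarded. Hits referencing a genome
    absent from the configuration are an error; exclusion-database hits
    must not be passed here.
    """
    matrix = PresenceMatrix.empty([r.seq_id for r in focal_proteome], config)
    known = set(config.all_genomes)
    gene_ids = set(matrix.best_evalue.index)
    for hit in hits:
        if hit.subject_genome == config.focal_genome:
            continue
        if hit.subject_genome not in known:
            raise ValueError(
                f"hit {hit.query_id}->{hit.subject_id} references unknown "
                f"genome {hit.subject_genome!r}"
            )
        if hit.query_id not in gene_ids:
            raise ValueError(f"hit for unknown focal gene {hit.query_id!r}")
        cell = matrix.best_evalue.at[hit.query_id, hit.subject_genome]
        if np.isnan(cell) or hit.evalue < cell:
            matrix.best_evalue.at[hit.query_id, hit.subject_genome] = hit.evalue
            matrix.evidence.at[hit.query_id, hit.subject_genome] = (
                Evidence.annotated.value
            )
    return matrix


def ingroup_criterion(
    matrix: PresenceMatrix, gene_id: str, config: ScreenConfig | None = None
) -> bool:
    """True iff every ingroup phylum has >= 1 present (non-focal) genome."""
    config = config or matrix.config
    present = matrix.present.loc[gene_id]
    for phylum, members in config.ingroup_phyla.items():
        genomes = [
            g for g in members
            if g != config.focal_genome or config.count_focal_genome
        ]
        # the focal genome never appears as a matrix column, so even with
        # count_focal_genome the check runs over available columns
        if not any(g in present.index and present[g] for g in genomes):
            return False
    return True


def outgroup_exclusion(
    gene_id: str,
    outgroup_hits: Iterable[HomologyHit],
    exclusion_db_hits: Iterable[HomologyHit],
    config: ScreenConfig,
) -> tuple[bool, list[tuple[str, float]]]:
    """Apply the outgroup / reference-database disqualification rule.

    Any outgroup-genome hit strictly below ``e_exclusion`` disqualifies.
    An exclusion-database hit disqualifies only when its subject's taxon
    label lies outside the ingroup clade (``config.ingroup_taxa``) — an
    nr-style database inevitably contains clade entries, which must not
    count. Returns (excluded, offending (source, best E) list).
    """
    offending: dict[str, float] = {}
    for hit in outgroup_hits:
        if hit.query_id != gene_id:
            continue
        if hit.subject_genome not in config.outgroup_genomes:
            raise ValueError(
                f"{hit.subject_genome!r} is not a configured outgroup genome"
            )
        if hit.evalue < config.e_exclusion:
            prev = offending.get(hit.subject_genome)
            if prev is None or hit.evalue < prev:
                offending[hit.subject_genome] = hit.evalue
    db_taxa = {db.name: db.taxon_of for db in config.exclusion_dbs}
    ingroup_taxa = set(config.ingroup_taxa)
    for hit in exclusion_db_hits:
        if hit.query_id != gene_id:
            continue
        taxon_of = db_taxa.get(hit.subject_genome)
        if taxon_of is None:
            raise ValueError(
                f"hit subject db {hit.subject_genome!r} is not a configured "
                f"exclusion database"
            )
        if hit.subject_id not in taxon_of:
            raise ValueError(
                f"exclusion-db sequence {hit.subject_id!r} has no taxon label"
            )
        if taxon_of[hit.subject_id] in ingroup_taxa:
            continue
        if hit.evalue < config.e_exclusion:
            key = hit.subject_genome
            prev = offending.get(key)
            if prev is None or hit.evalue < prev:
                offending[key] = hit.evalue
    items = sorted(offending.items())
    return bool(items), items


def rescue_unannotated(
    matrix: PresenceMatrix,
    focal_proteome: Sequence[SequenceRecord],
    config: ScreenConfig,
    dna: Mapping[str, Sequence[SequenceRecord]],
    scoring: ScoringScheme | None = None,
) -> PresenceMatrix:
    """Translated rescue round for genes the annotation missed.

    Only ingroup cells that are currently absent and whose genome has
    scaffold DNA configured are re-tested; a qualifying translated hit
    (E < e_rescue) flips the cell to present with evidence "rescued".
    Present cells are never touched and outgroup cells are never rescued.
    """
    if scoring is None:
        scoring = default_scoring()
    out = matrix.copy()
    present = out.present
    proteome = {r.seq_id: r for r in focal_proteome}
    targets = set(config.ingroup_genomes)
    if config.rescue_outgroups:
        targets |= set(config.outgroup_genomes)
    for genome in out.best_evalue.columns:
        if genome not in targets or genome not in dna:
            continue
        scaffolds = dna[genome]
        thr = (config.e_exclusion if genome in config.outgroup_genomes
               else config.e_rescue)
        for gene_id in out.best_evalue.index:
            if present.at[gene_id, genome]:
                continue
            hits = translated_search(
                proteome[gene_id], scaffolds, scoring, threshold=thr
            )
            if not hits:
                continue
            best = min(hits, key=lambda h: (h.evalue, -h.raw_score))
            out.best_evalue.at[gene_id, genome] = best.evalue
            out.evidence.at[gene_id, genome] = Evidence.rescued.value
    return out


# ---------------------------------------------------------------------------
# Full screen


def _internal_engine_hits(
    focal_proteome: Sequence[SequenceRecord],
    config: ScreenConfig,
    scoring: ScoringScheme,
) -> tuple[list[HomologyHit], list[HomologyHit]]:
    """Run the internal search engine: focal proteome vs every other
    genome proteome (per-genome search spaces) and vs every exclusion db."""
    genome_hits: list[HomologyHit] = []
    for genome in config.all_genomes:
        if genome == config.focal_genome:
            continue
        subjects = read_fasta(
            config.proteomes[genome], MolType.protein, genome_id=genome
        )
        for gene in focal_proteome:
            genome_hits.extend(seeded_search(gene, subjects, scoring))
    db_hits: list[HomologyHit] = []
    for db in config.exclusion_dbs:
        subjects = read_fasta(db.fasta_path, MolType.protein, genome_id=db.name)
        for gene in focal_proteome:
            db_hits.extend(seeded_search(gene, subjects, scoring))
    return genome_hits, db_hits


def _external_engine_hits(
    config: ScreenConfig,
) -> tuple[list[HomologyHit], list[HomologyHit]]:
    if not config.hits_dir:
        raise ValueError("engine=external_hits requires hits_dir")
    db_names = {db.name for db in config.exclusion_dbs}
    genome_hits: list[HomologyHit] = []
    db_hits: list[HomologyHit] = []
    for path in sorted(Path(config.hits_dir).glob("*.tsv")):
        for hit in read_hit_table(path):
            (db_hits if hit.subject_genome in db_names else genome_hits).append(hit)
    return genome_hits, db_hits


@dataclass
class ScreenResult:
    """Everything the screen computed: verdicts, evidence matrix, the
    per-gene report table, and the raw hits (used by the novelty
    classifier to pick ortholog sequences)."""

    candidates: list[CandidateGene]
    matrix: PresenceMatrix
    report: pd.DataFrame
    genome_hits: list[HomologyHit]
    db_hits: list[HomologyHit]

    def __iter__(self):
        # allow tuple-style unpacking: candidates, matrix, report
        return iter((self.candidates, self.matrix, self.report))


def run_screen(
    config: ScreenConfig,
    scoring: ScoringScheme | None = None,
    focal_proteome: Sequence[SequenceRecord] | None = None,
) -> ScreenResult:
    """Execute the whole screen.

    Stages run in a fixed order: evidence matrix, translated rescue,
    per-phylum ingroup criterion, outgroup/reference exclusion. The result
    is deterministic given the inputs and independent of input file order
    (genes are reported sorted by id).
    """
    if scoring is None:
        scoring = default_scoring()
    if focal_proteome is None:
        focal_proteome = read_fasta(
            config.proteomes[config.focal_genome],
            MolType.protein,
            genome_id=config.focal_genome,
        )
    focal_proteome = sorted(focal_proteome, key=lambda r: r.seq_id)
    if not focal_proteome:
        empty = PresenceMatrix.empty([], config)
        return ScreenResult([], empty, _make_report([], empty, config), [], [])

    if config.engine == "internal":
        genome_hits, db_hits = _internal_engine_hits(focal_proteome, config, scoring)
    else:
        genome_hits, db_hits = _external_engine_hits(config)

    ingroup_set = set(config.ingroup_genomes)
    matrix = build_presence_matrix(focal_proteome, genome_hits, config)

    dna = {
        genome: read_fasta(path, MolType.dna, genome_id=genome)
        for genome, path in config.genome_dna.items()
    }
    if dna:
        matrix = rescue_unannotated(matrix, focal_proteome, config, dna, scoring)

    outgroup_hits = [h for h in genome_hits if h.subject_genome not in ingroup_set
                     and h.subject_genome != config.focal_genome]
    candidates: list[CandidateGene] = []
    for gene in focal_proteome:
        passes = ingroup_criterion(matrix, gene.seq_id, config)
        excluded, offending = outgroup_exclusion(
            gene.seq_id, outgroup_hits, db_hits, config
        )
        if config.rescue_outgroups:
            # translated-exclusion extension: rescued outgroup cells count
            seen = dict(offending)
            for genome in config.outgroup_genomes:
                ev = matrix.best_evalue.at[gene.seq_id, genome]
                if (matrix.evidence.at[gene.seq_id, genome]
                        == Evidence.rescued.value
                        and not np.isnan(ev) and ev < config.e_exclusion):
                    prev = seen.get(genome)
                    if prev is None or ev < prev:
                        seen[genome] = float(ev)
            offending = sorted(seen.items())
            excluded = bool(offending)
        rescued_in = [
            g for g in matrix.evidence.columns
            if matrix.evidence.at[gene.seq_id, g] == Evidence.rescued.value
        ]
        candidates.append(
            CandidateGene(
                gene_id=gene.seq_id,
                passes_ingroup=passes,
                excluded_by=offending,
                rescued_in=rescued_in,
            )
        )
    report = _make_report(candidates, matrix, config)
    return ScreenResult(candidates, matrix, report, genome_hits, db_hits)


def _make_report(
    candidates: Sequence[CandidateGene],
    matrix: PresenceMatrix,
    config: ScreenConfig,
) -> pd.DataFrame:
    """One row per focal gene: verdict, per-phylum and per-outgroup best
    E-values, rescue evidence, exclusion trail."""
    rows = []
    for cand in candidates:
        row: dict[str, object] = {
            "gene_id": cand.gene_id,
            "verdict": cand.verdict.value,
            "passes_ingroup": cand.passes_ingroup,
        }
        for phylum, members in sorted(config.ingroup_phyla.items()):
            cols = [g for g in members if g in matrix.best_evalue.columns]
            vals = matrix.best_evalue.loc[cand.gene_id, cols].dropna()
            row[f"best_e_{phylum}"] = vals.min() if len(vals) else np.nan
        for genome in config.outgroup_genomes:
            row[f"best_e_{genome}"] = matrix.best_evalue.at[cand.gene_id, genome]
        row["rescued_in"] = ",".join(cand.rescued_in)
        row["excluded_by"] = ",".join(
            f"{src}:{ev:.3e}" for src, ev in cand.excluded_by
        )
        rows.append(row)
    columns = (
        ["gene_id", "verdict", "passes_ingroup"]
        + [f"best_e_{p}" for p in sorted(config.ingroup_phyla)]
        + [f"best_e_{g}" for g in config.outgroup_genomes]
        + ["rescued_in", "excluded_by"]
    )
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values("gene_id").reset_index(drop=True)


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6e")
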