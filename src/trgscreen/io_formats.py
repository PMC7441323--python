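"""On-disk artifacts: FASTA, tabular hit files, screen configuration.

FASTA goes through Bio.SeqIO (wrapped at 60 columns on write); hit tables
are 11-column TSV with a header row; the screen configuration is YAML.

Hit-table columns (native dialect)::

    query_id  subject_id  subject_genome  raw_score  bit_score  evalue
    q_start  q_end  s_start  s_end  frame

A 12-column BLAST ``outfmt 6`` table can be ingested with
``dialect="outfmt6"``; the missing columns (subject genome, raw score,
frame) are filled from arguments / inverted from the bit score.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .records import LN2, ExclusionDB, HomologyHit, MolType, SequenceRecord

HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "subject_genome",
    "raw_score",
    "bit_score",
    "evalue",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "frame",
)

OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

DEFAULT_E_INGROUP = 1e-7
DEFAULT_E_EXCLUSION = 1e-5
DEFAULT_E_RESCUE = 1e-7


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(
    path: str | os.PathLike,
    moltype: MolType | str,
    genome_id: str | None = None,
) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes ``seq_id``;
    wrapped lines are concatenated. ``genome_id`` defaults to the file's
    stem. Duplicate ids or out-of-alphabet residues raise.
    """
    moltype = MolType(moltype)
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        if bio_rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {bio_rec.id!r}")
        seen.add(bio_rec.id)
        records.append(
            SequenceRecord(
                seq_id=bio_rec.id,
                genome_id=genome_id,
                residues=str(bio_rec.seq),
                moltype=moltype,
            )
        )
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60
) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    bio_records = [
        _BioSeqRecord(Seq(rec.residues), id=rec.seq_id, description="")
        for rec in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(bio_records)


# ---------------------------------------------------------------------------
# Hit tables


def _parse_native_row(fields: Sequence[str], lineno: int, path: Path) -> HomologyHit:
    if len(fields) != len(HIT_COLUMNS):
        raise ValueError(
            f"{path}:{lineno}: expected {len(HIT_COLUMNS)} columns, "
            f"got {len(fields)}"
        )
    try:
        return HomologyHit(
            query_id=fields[0],
            subject_id=fields[1],
            subject_genome=fields[2],
            raw_score=int(float(fields[3])),
            bit_score=float(fields[4]),
            evalue=float(fields[5]),
            q_start=int(fields[6]),
            q_end=int(fields[7]),
            s_start=int(fields[8]),
            s_end=int(fields[9]),
            frame=int(fields[10]),
        )
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc


def read_hit_table(
    path: str | os.PathLike,
    dialect: str = "native",
    subject_genome: str | None = None,
    scoring=None,
) -> list[HomologyHit]:
    """Read a tabular hit file.

    ``dialect="native"`` expects the 11-column format written by
    :func:`write_hit_table` (header row optional). ``dialect="outfmt6"``
    ingests 12-column BLAST tabular output; ``subject_genome`` must then be
    given, and ``scoring`` (a ScoringScheme) lets the raw score be inverted
    from the bit score (otherwise raw_score is set to 0).
    """
    path = Path(path)
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] in ("query_id", "qseqid"):
                continue
            if dialect == "native":
                hits.append(_parse_native_row(fields, lineno, path))
            elif dialect == "outfmt6":
                if subject_genome is None:
                    raise ValueError("outfmt6 dialect requires subject_genome")
                if len(fields) != 12:
                    raise ValueError(
                        f"{path}:{lineno}: outfmt6 expects 12 columns"
                    )
                try:
                    bit = float(fields[11])
                    raw = 0
                    if scoring is not None:
                        raw = int(round((bit * LN2 + math.log(scoring.K)) / scoring.lam))
                    hits.append(
                        HomologyHit(
                            query_id=fields[0],
                            subject_id=fields[1],
                            subject_genome=subject_genome,
                            raw_score=raw,
                            bit_score=bit,
                            evalue=float(fields[10]),
                            q_start=int(fields[6]),
                            q_end=int(fields[7]),
                            s_start=int(fields[8]),
                            s_end=int(fields[9]),
                            frame=0,
                        )
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
            else:
                raise ValueError(f"unknown hit-table dialect {dialect!r}")
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | os.PathLike) -> None:
    """Write hits as 11-column TSV; E-values keep 6 significant digits."""
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    (
                        h.query_id,
                        h.subject_id,
                        h.subject_genome,
                        str(h.raw_score),
                        f"{h.bit_score:.6g}",
                        f"{h.evalue:.6e}",
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        str(h.frame),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Screen configuration


@dataclass
class ScreenConfig:
    """Validated description of one screen run.

    The ingroup is organised into phyla; the focal genome belongs to
    exactly one of them. Presence in the ingroup is judged at
    ``e_ingroup`` (strictly below), disqualifying outgroup/reference hits
    at ``e_exclusion``, and the translated annotation-rescue round at
    ``e_rescue``. ``ingroup_taxa`` lists the taxon labels inside the clade
    for taxon-aware exclusion-database filtering.
    """

    focal_genome: str
    ingroup_phyla: dict[str, list[str]]
    outgroup_genomes: list[str]
    exclusion_dbs: list[ExclusionDB] = field(default_factory=list)
    e_ingroup: float = DEFAULT_E_INGROUP
    e_exclusion: float = DEFAULT_E_EXCLUSION
    e_rescue: float = DEFAULT_E_RESCUE
    proteomes: dict[str, str] = field(default_factory=dict)
    genome_dna: dict[str, str] = field(default_factory=dict)
    ingroup_taxa: list[str] = field(default_factory=list)
    engine: str = "internal"
    hits_dir: str | None = None
    count_focal_genome: bool = False
    rescue_outgroups: bool = False

    def __post_init__(self) -> None:
        phyla_of_focal = [
            name for name, members in self.ingroup_phyla.items()
            if self.focal_genome in members
        ]
        if len(phyla_of_focal) != 1:
            raise ValueError(
                f"focal genome {self.focal_genome!r} must belong to exactly "
                f"one ingroup phylum (found in {phyla_of_focal})"
            )
        seen: dict[str, str] = {}
        for name, members in self.ingroup_phyla.items():
            if not members:
                raise ValueError(f"phylum {name!r} has no member genomes")
            for g in members:
                if g in seen:
                    raise ValueError(
                        f"genome {g!r} listed in phyla {seen[g]!r} and {name!r}"
                    )
                seen[g] = name
        overlap = set(seen) & set(self.outgroup_genomes)
        if overlap:
            raise ValueError(f"genomes in both ingroup and outgroup: {sorted(overlap)}")
        for thr_name in ("e_ingroup", "e_exclusion", "e_rescue"):
            if getattr(self, thr_name) <= 0:
                raise ValueError(f"{thr_name} must be strictly positive")
        if self.engine not in ("internal", "external_hits"):
            raise ValueError(f"unknown engine {self.engine!r}")

    @property
    def focal_phylum(self) -> str:
        for name, members in self.ingroup_phyla.items():
            if self.focal_genome in members:
                return name
        raise AssertionError("unreachable: validated at construction")

    @property
    def ingroup_genomes(self) -> list[str]:
        out: list[str] = []
        for members in self.ingroup_phyla.values():
            out.extend(members)
        return out

    @property
    def all_genomes(self) -> list[str]:
        return self.ingroup_genomes + list(self.outgroup_genomes)


def _read_taxon_table(path: str | os.PathLike) -> dict[str, str]:
    taxa: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'seq_id<TAB>taxon'")
            taxa[fields[0]] = fields[1]
    return taxa


def load_screen_config(path: str | os.PathLike) -> ScreenConfig:
    """Load and validate a YAML screen configuration.

    Relative paths inside the file resolve against the file's directory.
    Omitted thresholds default to 1e-7 (ingroup), 1e-5 (exclusion) and
    1e-7 (rescue).
    """
    path = Path(path)
    base = path.parent
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")

    def resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    dbs: list[ExclusionDB] = []
    for entry in raw.get("exclusion_dbs", []) or []:
        taxa = _read_taxon_table(resolve(entry["taxa"])) if "taxa" in entry else {}
        dbs.append(
            ExclusionDB(
                name=entry.get("name", Path(entry["fasta"]).stem),
                fasta_path=resolve(entry["fasta"]),
                taxon_of=taxa,
            )
        )
    kwargs = dict(
        focal_genome=raw["focal_genome"],
        ingroup_phyla={k: list(v) for k, v in raw["ingroup_phyla"].items()},
        outgroup_genomes=list(raw.get("outgroup_genomes", [])),
        exclusion_dbs=dbs,
        proteomes={g: resolve(p) for g, p in (raw.get("proteomes") or {}).items()},
        genome_dna={g: resolve(p) for g, p in (raw.get("genome_dna") or {}).items()},
        ingroup_taxa=list(raw.get("ingroup_taxa", [])),
        engine=raw.get("engine", "internal"),
        hits_dir=resolve(raw["hits_dir"]) if raw.get("hits_dir") else None,
        count_focal_genome=bool(raw.get("count_focal_genome", False)),
        rescue_outgroups=bool(raw.get("rescue_outgroups", False)),
    )
    for thr in ("e_ingroup", "e_exclusion", "e_rescue"):
        if thr in raw and raw[thr] is not None:
            kwargs[thr] = float(raw[thr])
    return ScreenConfig(**kwargs)
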