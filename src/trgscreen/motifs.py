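"""Novelty classification: fully-novel proteins vs. chimeras of an ancient
domain and a clade-specific conserved motif.

The candidate's ingroup orthologs are stacked into a center-star multiple
alignment anchored on the focal sequence, per-column conservation is
profiled from normalised pairwise substitution scores, conserved segments
are intersected with externally supplied domain annotations, and the gene
is called ``chimeric`` (a conserved segment sits on an extra-clade-known
domain while another conserved segment does not), ``fully_novel`` (no
conserved segment is covered by a known domain) or ``known`` (every
conserved segment is).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .homology import AMINO_ACIDS, ScoringScheme, default_scoring
from .records import SequenceRecord

GAP = "-"

DEFAULT_HIGH = 0.7
DEFAULT_MIN_LEN = 20
DEFAULT_WINDOW = 11


class SegmentLabel(str, Enum):
    known_domain_overlap = "known_domain_overlap"
    novel_conserved = "novel_conserved"
    unconserved = "unconserved"


class NoveltyClass(str, Enum):
    fully_novel = "fully_novel"
    chimeric = "chimeric"
    known = "known"
    unclassified = "unclassified"  # no conserved segment to judge


@dataclass
class OrthologAlignment:
    """Center-star MSA of a candidate's ingroup orthologs.

    Row 0 is the focal (center) sequence; the focal row defines the
    column -> focal-coordinate map.
    """

    gene_id: str
    seq_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    @property
    def column_map(self) -> list[int | None]:
        """Per column: 1-based focal coordinate, or None at focal gaps."""
        out: list[int | None] = []
        pos = 0
        for ch in self.rows[0]:
            if ch == GAP:
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out


@dataclass
class ConservationTrack:
    """Per-column conservation in [0, 1]; NaN marks masked columns
    (fewer than two aligned residues)."""

    scores: np.ndarray
    smoothed: np.ndarray
    window: int
    column_map: list[int | None]


@dataclass
class MotifSegment:
    start: int  # 1-based inclusive, focal coordinates
    end: int
    mean_conservation: float
    label: SegmentLabel

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainAnnotation:
    """An externally produced domain call in focal-sequence coordinates.

    ``is_extraclade`` marks domains known from outside the ingroup clade;
    only those make a segment "known"."""

    gene_id: str
    start: int
    end: int
    domain_id: str
    is_extraclade: bool


# ---------------------------------------------------------------------------
# Center-star alignment


def _pairwise_glocal(center: str, member: str, scoring: ScoringScheme):
    aln = scoring.glocal_aligner.align(center, member)[0]
    return str(aln[0]), str(aln[1])


def _merge(master: str, rows: list[str], c_new: str, m_new: str):
    """Merge a new pairwise (center, member) alignment into the master
    center string under "once a gap, always a gap"."""
    out_master: list[str] = []
    out_rows: list[list[str]] = [[] for _ in rows]
    out_new: list[str] = []
    i = j = 0
    while i < len(master) or j < len(c_new):
        a = master[i] if i < len(master) else None
        b = c_new[j] if j < len(c_new) else None
        if a is not None and b is not None and a != GAP and b != GAP:
            # same center residue consumed on both sides
            out_master.append(a)
            for r, row in enumerate(rows):
                out_rows[r].append(row[i])
            out_new.append(m_new[j])
            i += 1
            j += 1
        elif a == GAP and b == GAP:
            out_master.append(GAP)
            for r, row in enumerate(rows):
                out_rows[r].append(row[i])
            out_new.append(m_new[j])
            i += 1
            j += 1
        elif a == GAP:
            out_master.append(GAP)
            for r, row in enumerate(rows):
                out_rows[r].append(row[i])
            out_new.append(GAP)
            i += 1
        else:  # b == GAP or master exhausted
            if b == GAP:
                out_master.append(GAP)
                for r in range(len(rows)):
                    out_rows[r].append(GAP)
                out_new.append(m_new[j])
                j += 1
            else:  # a is None handled above; only master leftover
                out_master.append(a)  # type: ignore[arg-type]
                for r, row in enumerate(rows):
                    out_rows[r].append(row[i])
                out_new.append(GAP)
                i += 1
    return (
        "".join(out_master),
        ["".join(r) for r in out_rows],
        "".join(out_new),
    )


def star_align(
    members: Sequence[SequenceRecord],
    center: SequenceRecord,
    scoring: ScoringScheme | None = None,
) -> OrthologAlignment:
    """Center-star multiple alignment anchored on the focal sequence.

    Each member is globally aligned to the center with free end gaps, and
    the pairwise alignments are merged through the center's gap pattern.
    ``members`` may or may not include the center record itself.
    """
    if scoring is None:
        scoring = default_scoring()
    others = [m for m in members if m.seq_id != center.seq_id]
    if not others:
        raise ValueError("star alignment needs at least one non-center member")
    master = center.residues
    rows: list[str] = []
    ids: list[str] = []
    for member in others:
        c_gapped, m_gapped = _pairwise_glocal(master.replace(GAP, ""),
                                              member.residues, scoring)
        # re-express the pairwise center row on the current master pattern
        master, rows, new_row = _merge(master, rows, c_gapped, m_gapped)
        rows.append(new_row)
        ids.append(member.seq_id)
    return OrthologAlignment(
        gene_id=center.seq_id,
        seq_ids=[center.seq_id] + ids,
        rows=[master] + rows,
    )


# ---------------------------------------------------------------------------
# Conservation profiling


def conservation_profile(
    alignment: OrthologAlignment,
    scoring: ScoringScheme | None = None,
    w: int = DEFAULT_WINDOW,
) -> ConservationTrack:
    """Per-column conservation from normalised pairwise matrix scores.

    Each residue pair (a, b) scores (M[a,b] - Mmin) / (min(M[a,a], M[b,b])
    - Mmin), clipped to [0, 1], so a pair of identical residues scores 1
    for every residue; the column score is the mean over all non-gap pairs
    and columns with fewer than two residues are masked. Smoothing is a
    centered sliding mean of width ``w`` (odd), shrinking at the edges and
    ignoring masked columns.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError("window width must be odd and >= 1")
    if scoring is None:
        scoring = default_scoring()
    M = scoring.matrix
    m_min = min(M[a, b] for a in AMINO_ACIDS for b in AMINO_ACIDS)
    ncol = alignment.n_columns
    scores = np.full(ncol, np.nan)
    for c in range(ncol):
        residues = [row[c] for row in alignment.rows if row[c] != GAP]
        if len(residues) < 2:
            continue
        total = 0.0
        npairs = 0
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                a, b = residues[i], residues[j]
                denom = min(M[a, a], M[b, b]) - m_min
                if denom <= 0:
                    val = 1.0 if a == b else 0.0
                else:
                    val = (M[a, b] - m_min) / denom
                total += min(max(val, 0.0), 1.0)
                npairs += 1
        scores[c] = total / npairs
    smoothed = (
        pd.Series(scores)
        .rolling(window=w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    smoothed[np.isnan(scores)] = np.nan
    return ConservationTrack(
        scores=scores, smoothed=smoothed, window=w,
        column_map=alignment.column_map,
    )


# ---------------------------------------------------------------------------
# Segment detection and classification


def detect_segments(
    track: ConservationTrack,
    high: float = DEFAULT_HIGH,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[MotifSegment]:
    """Partition the focal sequence into conserved and unconserved
    segments.

    Maximal runs of >= ``min_len`` consecutive columns whose smoothed
    score is >= ``high`` (masked columns break runs) become conserved
    segments; everything else is labelled unconserved. Coordinates are
    mapped to the focal sequence through the alignment's column map.
    """
    sm = track.smoothed
    ncol = len(sm)
    conserved_cols = np.zeros(ncol, dtype=bool)
    run_start = None
    for c in range(ncol + 1):
        hot = c < ncol and not np.isnan(sm[c]) and sm[c] >= high
        if hot and run_start is None:
            run_start = c
        elif not hot and run_start is not None:
            if c - run_start >= min_len:
                conserved_cols[run_start:c] = True
            run_start = None

    # project column runs onto focal coordinates
    focal_len = max((p for p in track.column_map if p is not None), default=0)
    if focal_len == 0:
        return []
    is_conserved_pos = np.zeros(focal_len + 1, dtype=bool)
    mean_by_pos = np.full(focal_len + 1, np.nan)
    for c, pos in enumerate(track.column_map):
        if pos is not None:
            is_conserved_pos[pos] = conserved_cols[c]
            mean_by_pos[pos] = sm[c]

    segments: list[MotifSegment] = []
    start = 1
    for pos in range(2, focal_len + 2):
        if pos > focal_len or is_conserved_pos[pos] != is_conserved_pos[start]:
            vals = mean_by_pos[start:pos]
            mean = float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else 0.0
            label = (SegmentLabel.novel_conserved if is_conserved_pos[start]
                     else SegmentLabel.unconserved)
            segments.append(MotifSegment(start, pos - 1, mean, label))
            start = pos
    return segments


def _coverage_mask(segment: MotifSegment,
                   domains: list[DomainAnnotation]) -> np.ndarray:
    """Per-position boolean: covered by the union of the domains."""
    covered = np.zeros(len(segment), dtype=bool)
    for d in domains:
        lo = max(segment.start, d.start)
        hi = min(segment.end, d.end)
        if lo <= hi:
            covered[lo - segment.start : hi - segment.start + 1] = True
    return covered


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def classify_novelty(
    segments: Sequence[MotifSegment],
    domain_annotations: Sequence[DomainAnnotation],
    focal_length: int | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    overlap_frac: float = 0.5,
) -> NoveltyClass:
    """Call a candidate fully_novel, chimeric or known.

    Each conserved segment is intersected with the union of extra-clade
    domain annotations. A segment contributes a *known* part when its
    covered positions form a run of >= ``min_len`` (or >= ``overlap_frac``
    of the segment is covered), and a *novel* part when its uncovered
    positions form a run of >= ``min_len`` — so one long conserved
    segment spanning both an ancient domain and a clade-specific motif is
    read as both, while overhangs shorter than ``min_len`` are treated as
    fuzzy domain boundaries and ignored. chimeric: known and novel parts
    both occur; fully_novel: conserved segments exist and no known part
    does; known: known parts exist and no novel part does. With no
    conserved segment at all the call is unclassified.
    """
    if focal_length is None:
        focal_length = max((s.end for s in segments), default=0)
    for d in domain_annotations:
        if d.start < 1 or d.end > focal_length or d.start > d.end:
            raise ValueError(
                f"domain {d.domain_id} [{d.start},{d.end}] out of bounds "
                f"for sequence of length {focal_length}"
            )
    known_domains = [d for d in domain_annotations if d.is_extraclade]
    conserved = [
        s for s in segments
        if s.label in (SegmentLabel.novel_conserved,
                       SegmentLabel.known_domain_overlap)
    ]
    if not conserved:
        return NoveltyClass.unclassified
    has_known = has_novel = False
    for seg in conserved:
        covered = _coverage_mask(seg, known_domains)
        seg_known = (covered.mean() >= overlap_frac
                     or _longest_run(covered) >= min_len)
        seg_novel = _longest_run(~covered) >= min_len
        if not seg_known and not seg_novel:
            # a short segment nowhere near a domain still argues novelty
            seg_novel = not covered.any()
        has_known = has_known or seg_known
        has_novel = has_novel or seg_novel
        seg.label = (SegmentLabel.known_domain_overlap if seg_known
                     else SegmentLabel.novel_conserved)
    if has_known and has_novel:
        return NoveltyClass.chimeric
    if not has_known:
        return NoveltyClass.fully_novel
    return NoveltyClass.known


# ---------------------------------------------------------------------------
# Domain-annotation I/O


def read_domain_annotations(
    path: str | os.PathLike,
) -> dict[str, list[DomainAnnotation]]:
    """Read the 5-column domain TSV: gene_id, start, end, domain_id,
    extraclade flag (0/1/true/false)."""
    out: dict[str, list[DomainAnnotation]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            flag = fields[4].strip().lower() in ("1", "true", "yes")
            ann = DomainAnnotation(
                gene_id=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                domain_id=fields[3],
                is_extraclade=flag,
            )
            out.setdefault(ann.gene_id, []).append(ann)
    return out


def write_domain_annotations(
    annotations: Sequence[DomainAnnotation], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tdomain_id\tis_extraclade\n")
        for a in annotations:
            fh.write(
                f"{a.gene_id}\t{a.start}\t{a.end}\t{a.domain_id}\t"
                f"{1 if a.is_extraclade else 0}\n"
            )


def classify_gene(
    members: Sequence[SequenceRecord],
    focal: SequenceRecord,
    domain_annotations: Sequence[DomainAnnotation],
    scoring: ScoringScheme | None = None,
    high: float = DEFAULT_HIGH,
    min_len: int = DEFAULT_MIN_LEN,
    w: int = DEFAULT_WINDOW,
) -> tuple[NoveltyClass, list[MotifSegment]]:
    """Convenience: align orthologs, profile conservation, detect
    segments, classify. Returns (novelty class, segments)."""
    alignment = star_align(members, focal, scoring)
    track = conservation_profile(alignment, scoring, w=w)
    segments = detect_segments(track, high=high, min_len=min_len)
    cls = classify_novelty(
        segments, domain_annotations, focal_length=len(focal), min_len=min_len
    )
    return cls, segments
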