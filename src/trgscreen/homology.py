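"""Desk-scale homology search with Karlin-Altschul E-value statistics.

Protein-protein search is k-mer-seeded Smith-Waterman with affine gaps
(BLOSUM62 by default); protein-vs-DNA search translates all six reading
frames, splits them at stop codons and searches the fragments, reporting
subject coordinates back on the forward DNA strand. Significance uses the
ungapped Karlin-Altschul formula E = K*m*n*exp(-lambda*S); the gapped
edge-effect/length-adjustment refinements are deliberately omitted (the
screen only thresholds E-values, and at desk scale the refinement changes
no verdict; see docs/methods.md).

The alignment kernel is Biopython's PairwiseAligner; the tie-break among
co-optimal alignments is the engine's deterministic enumeration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .records import (
    DNA_ALPHABET,
    AlphabetError,
    HomologyHit,
    MolType,
    SequenceRecord,
    bit_score,
)

# Robinson & Robinson amino-acid background frequencies, the standard
# composition behind BLOSUM statistics; used for the negative-expectation
# sanity check at scoring-scheme load and as the stationary distribution of
# the simulator's substitution model.
BACKGROUND_FREQS: dict[str, float] = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Ungapped Karlin-Altschul parameters for BLOSUM62 (nats).
DEFAULT_LAMBDA = 0.3176
DEFAULT_K = 0.134


@dataclass
class ScoringScheme:
    """Substitution matrix + affine gap costs + Karlin-Altschul parameters.

    A gap of length L scores ``gap_open + L * gap_extend`` (the BLASTp
    11/1 convention with the defaults -11/-1). X scores 0 against
    everything and '*' scores -4 against everything.
    """

    matrix: substitution_matrices.Array
    gap_open: int = -11
    gap_extend: int = -1
    lam: float = DEFAULT_LAMBDA
    K: float = DEFAULT_K
    _local: Align.PairwiseAligner | None = field(
        default=None, repr=False, compare=False
    )
    _glocal: Align.PairwiseAligner | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValueError("lambda must be finite and > 0")
        if not (self.K > 0 and math.isfinite(self.K)):
            raise ValueError("K must be finite and > 0")
        alpha = self.matrix.alphabet
        for a in AMINO_ACIDS:
            if a not in alpha:
                raise ValueError(f"matrix alphabet lacks {a!r}")
            for b in AMINO_ACIDS:
                if self.matrix[a, b] != self.matrix[b, a]:
                    raise ValueError("substitution matrix must be symmetric")
        exp_score = sum(
            BACKGROUND_FREQS[a] * BACKGROUND_FREQS[b] * self.matrix[a, b]
            for a in AMINO_ACIDS
            for b in AMINO_ACIDS
        )
        if exp_score >= 0:
            raise ValueError(
                f"expected score under background frequencies must be "
                f"negative (got {exp_score:.4f})"
            )

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[a, b])

    def _make_aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = self.matrix
        # PairwiseAligner charges open_gap_score for the first gapped
        # position; fold one extension in so a length-L gap costs
        # gap_open + L*gap_extend.
        aligner.open_gap_score = self.gap_open + self.gap_extend
        aligner.extend_gap_score = self.gap_extend
        aligner.mode = mode
        return aligner

    @property
    def local_aligner(self) -> Align.PairwiseAligner:
        if self._local is None:
            self._local = self._make_aligner("local")
        return self._local

    @property
    def glocal_aligner(self) -> Align.PairwiseAligner:
        """Global aligner with free end gaps (for star alignments)."""
        if self._glocal is None:
            aligner = self._make_aligner("global")
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
            self._glocal = aligner
        return self._glocal


def default_scoring(
    gap_open: int = -11,
    gap_extend: int = -1,
    lam: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> ScoringScheme:
    """BLOSUM62 with X scored 0 and '*' scored -4 against everything."""
    m = substitution_matrices.load("BLOSUM62").copy()
    for ch in m.alphabet:
        m["X", ch] = m[ch, "X"] = 0
    for ch in m.alphabet:
        m["*", ch] = m[ch, "*"] = -4
    return ScoringScheme(matrix=m, gap_open=gap_open, gap_extend=gap_extend,
                         lam=lam, K=K)


def _check_protein(seq: str, label: str) -> None:
    alpha = set("ACDEFGHIKLMNPQRSTVWYX*")
    for pos, ch in enumerate(seq, start=1):
        if ch not in alpha:
            raise AlphabetError(f"{label}: invalid residue {ch!r} at {pos}")


def local_align(
    query: str, subject: str, scoring: ScoringScheme | None = None
) -> tuple[int, int, int, int, int] | None:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Returns ``(raw_score, q_start, q_end, s_start, s_end)`` with 1-based
    inclusive coordinates, or None if no alignment scores above zero (the
    empty-hit convention).
    """
    if scoring is None:
        scoring = default_scoring()
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    query, subject = query.upper(), subject.upper()
    _check_protein(query, "query")
    _check_protein(subject, "subject")
    score = scoring.local_aligner.score(query, subject)
    if score <= 0:
        return None
    aln = scoring.local_aligner.align(query, subject)[0]
    q_blocks, s_blocks = aln.aligned
    q_start, q_end = int(q_blocks[0][0]) + 1, int(q_blocks[-1][1])
    s_start, s_end = int(s_blocks[0][0]) + 1, int(s_blocks[-1][1])
    return int(round(score)), q_start, q_end, s_start, s_end


def evalue(raw_score: float, m: int, n: int, scoring: ScoringScheme) -> float:
    """Ungapped Karlin-Altschul expectation: E = K*m*n*exp(-lambda*S)."""
    if raw_score < 0:
        raise ValueError("raw score must be >= 0")
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return scoring.K * m * n * math.exp(-scoring.lam * raw_score)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def seeded_search(
    query: SequenceRecord,
    subjects: Sequence[SequenceRecord],
    scoring: ScoringScheme | None = None,
    k: int = 3,
    x_drop: float | None = None,
    n_search: int | None = None,
) -> list[HomologyHit]:
    """Search a protein query against a set of protein subjects.

    Subjects sharing at least one exact k-mer with the query are aligned
    (Smith-Waterman, run to completion); at most the best hit per
    (query, subject) pair is emitted. E-values use the total residue count
    of ``subjects`` as the database size n unless ``n_search`` overrides
    it. ``x_drop`` is reserved for an extension-truncation heuristic and
    currently ignored: extensions run to completion, so emitted scores
    equal the exact Smith-Waterman score.
    """
    if k < 2:
        raise ValueError("word size k must be >= 2")
    if scoring is None:
        scoring = default_scoring()
    if query.moltype is not MolType.protein:
        raise ValueError("query must be a protein record")
    qseq = query.residues
    qk = _kmer_set(qseq, k)
    n_total = n_search if n_search is not None else sum(len(s) for s in subjects)
    n_total = max(n_total, 1)
    hits: list[HomologyHit] = []
    for subj in subjects:
        if subj.moltype is not MolType.protein:
            raise ValueError(f"subject {subj.seq_id} is not protein")
        sseq = subj.residues
        if not any(sseq[i : i + k] in qk for i in range(len(sseq) - k + 1)):
            continue
        res = local_align(qseq, sseq, scoring)
        if res is None:
            continue
        raw, q_start, q_end, s_start, s_end = res
        hits.append(
            HomologyHit(
                query_id=query.seq_id,
                subject_id=subj.seq_id,
                subject_genome=subj.genome_id,
                raw_score=raw,
                bit_score=bit_score(raw, scoring.lam, scoring.K),
                evalue=evalue(raw, len(qseq), n_total, scoring),
                q_start=q_start,
                q_end=q_end,
                s_start=s_start,
                s_end=s_end,
                frame=0,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Translated (protein vs DNA) search


def six_frame_translate(dna: str) -> list[tuple[int, str]]:
    """Translate a nucleotide string in all six reading frames.

    Returns ``[(frame, protein), ...]`` for frames +1,+2,+3 (forward) and
    -1,-2,-3 (reverse complement), standard genetic code, stops as '*',
    N-containing ambiguous codons as 'X'; trailing partial codons dropped.
    """
    dna = dna.upper()
    if len(dna) < 3:
        raise ValueError("DNA must be at least one codon long")
    for pos, ch in enumerate(dna, start=1):
        if ch not in DNA_ALPHABET:
            raise AlphabetError(f"invalid nucleotide {ch!r} at position {pos}")
    fwd = Seq(dna)
    rev = fwd.reverse_complement()
    out: list[tuple[int, str]] = []
    for frame in (1, 2, 3):
        for strand, seq in ((1, fwd), (-1, rev)):
            sub = seq[frame - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            prot = list(str(sub.translate()))
            # any codon containing N is reported as X, even where the
            # ambiguity would not change the amino acid
            raw = str(sub)
            for i in range(len(prot)):
                if "N" in raw[3 * i : 3 * i + 3]:
                    prot[i] = "X"
            out.append((strand * frame, "".join(prot)))
    out.sort(key=lambda t: (0, t[0]) if t[0] > 0 else (1, -t[0]))
    return out


def _dna_span(frame: int, aa_start: int, aa_end: int, dna_len: int) -> tuple[int, int]:
    """Map a 1-based aa span within a frame translation to forward-strand
    1-based inclusive DNA coordinates."""
    off = abs(frame) - 1
    start = off + 3 * (aa_start - 1) + 1
    end = off + 3 * aa_end
    if frame > 0:
        return start, end
    return dna_len - end + 1, dna_len - start + 1


def translated_search(
    query: SequenceRecord,
    genome_dna: Sequence[SequenceRecord],
    scoring: ScoringScheme | None = None,
    threshold: float = 1e-7,
    k: int = 3,
) -> list[HomologyHit]:
    """tblastn-style search of a protein query against genomic scaffolds.

    Every scaffold is translated in six frames; frame translations are
    split at stop codons (so no hit crosses a stop) and each fragment is
    searched with the seeded protein engine. Subject coordinates are
    reported on the DNA, 1-based, forward-strand orientation, with the
    frame recorded. At most the best hit per (query, scaffold) is emitted;
    hits with E-value >= ``threshold`` are suppressed.
    """
    if scoring is None:
        scoring = default_scoring()
    if query.moltype is not MolType.protein:
        raise ValueError("query must be protein")
    qseq = query.residues
    qk = _kmer_set(qseq, k)

    translations: list[tuple[SequenceRecord, int, str]] = []
    n_total = 0
    for scaf in genome_dna:
        if scaf.moltype is not MolType.dna:
            raise ValueError(f"scaffold {scaf.seq_id} is not DNA")
        for frame, prot in six_frame_translate(scaf.residues):
            translations.append((scaf, frame, prot))
            n_total += len(prot)
    n_total = max(n_total, 1)

    best: dict[str, HomologyHit] = {}
    for scaf, frame, prot in translations:
        offset = 0
        for fragment in prot.split("*"):
            frag_off = offset
            offset += len(fragment) + 1
            if len(fragment) < k:
                continue
            if not any(
                fragment[i : i + k] in qk for i in range(len(fragment) - k + 1)
            ):
                continue
            res = local_align(qseq, fragment, scoring)
            if res is None:
                continue
            raw, q_start, q_end, f_start, f_end = res
            ev = evalue(raw, len(qseq), n_total, scoring)
            if ev >= threshold:
                continue
            aa_start, aa_end = frag_off + f_start, frag_off + f_end
            s_start, s_end = _dna_span(frame, aa_start, aa_end, len(scaf))
            hit = HomologyHit(
                query_id=query.seq_id,
                subject_id=scaf.seq_id,
                subject_genome=scaf.genome_id,
                raw_score=raw,
                bit_score=bit_score(raw, scoring.lam, scoring.K),
                evalue=ev,
                q_start=q_start,
                q_end=q_end,
                s_start=s_start,
                s_end=s_end,
                frame=frame,
            )
            prev = best.get(scaf.seq_id)
            if prev is None or hit.raw_score > prev.raw_score:
                best[scaf.seq_id] = hit
    return [best[key] for key in sorted(best)]
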