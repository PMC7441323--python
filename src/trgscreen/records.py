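"""Core domain types shared across the screen.

A :class:`SequenceRecord` is one protein or nucleotide sequence tagged with
its genome of origin; a :class:`HomologyHit` is one local-alignment hit
between a query protein and a subject sequence, carrying the raw
Smith-Waterman score, the bit score and the Karlin-Altschul E-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
DNA_ALPHABET = frozenset("ACGTN")

LN2 = math.log(2.0)


class MolType(str, Enum):
    protein = "protein"
    dna = "dna"


class AlphabetError(ValueError):
    """A residue outside the declared alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with its genome-of-origin label.

    Residues are stored uppercase; validation happens at construction so
    every downstream stage can assume a clean alphabet.
    """

    seq_id: str
    genome_id: str
    residues: str
    moltype: MolType = MolType.protein

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise AlphabetError(f"record {self.seq_id!r}: empty sequence")
        moltype = MolType(self.moltype)
        object.__setattr__(self, "moltype", moltype)
        alphabet = PROTEIN_ALPHABET if moltype is MolType.protein else DNA_ALPHABET
        for pos, ch in enumerate(residues, start=1):
            if ch not in alphabet:
                raise AlphabetError(
                    f"record {self.seq_id!r}: invalid {moltype.value} residue "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HomologyHit:
    """One query->subject local alignment hit.

    Coordinates are 1-based and inclusive, on the query/subject as given.
    ``frame`` is 0 for protein-protein hits and +/-1..3 for translated
    (protein vs six-frame DNA) hits; for translated hits the subject
    coordinates are on the DNA in forward-strand orientation.
    """

    query_id: str
    subject_id: str
    subject_genome: str
    raw_score: int
    bit_score: float
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    frame: int = 0

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: q_start > q_end"
            )
        if self.s_start > self.s_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: s_start > s_end"
            )
        if min(self.q_start, self.s_start) < 1:
            raise ValueError("coordinates are 1-based; must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.frame not in (0, 1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")


def bit_score(raw_score: float, lam: float, K: float) -> float:
    """Normalised (bit) score: (lambda*S - ln K) / ln 2."""
    return (lam * raw_score - math.log(K)) / LN2


@dataclass
class ExclusionDB:
    """A reference-database descriptor for the exclusion stage.

    ``taxon_of`` maps each sequence id in the database to a taxon label;
    only hits whose subject taxon lies outside the ingroup clade can
    disqualify a candidate (an nr-style database inevitably contains
    ingroup entries, which must not count against a lineage-specific gene).
    """

    name: str
    fasta_path: str
    taxon_of: dict[str, str] = field(default_factory=dict)
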