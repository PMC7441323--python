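"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: the aligner oracle is
a textbook full-DP Gotoh recursion, the translation oracle a literal
codon-table lookup, and the filter-logic oracle a direct restatement of
the screen's written rule.
"""

from __future__ import annotations

# Standard genetic code, written out independently of the package.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

NEG_INF = float("-inf")


def sw_score(query: str, subject: str, score, gap_open: int,
             gap_extend: int) -> int:
    """Full-DP Smith-Waterman with affine gaps (Gotoh), score only.

    A gap of length L costs gap_open + L * gap_extend. ``score(a, b)``
    returns the substitution score.
    """
    m, n = len(query), len(subject)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in query row
    F = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in subject row
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend,
                          E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend,
                          F[i - 1][j] + gap_extend)
            diag = H[i - 1][j - 1] + score(query[i - 1], subject[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


def translate_oracle(dna: str) -> list[tuple[int, str]]:
    """Literal six-frame codon-table translation."""
    rc = "".join(COMPLEMENT[b] for b in reversed(dna))
    out = []
    for frame in (1, 2, 3):
        for signed, seq in ((frame, dna), (-frame, rc)):
            prot = []
            for i in range(frame - 1, len(seq) - 2, 3):
                codon = seq[i : i + 3]
                prot.append(GENETIC_CODE.get(codon, "X") if "N" not in codon
                            else "X")
            out.append((signed, "".join(prot)))
    return sorted(out, key=lambda t: (0, t[0]) if t[0] > 0 else (1, -t[0]))


def screen_decision_oracle(
    present_ingroup: dict[str, bool],
    phyla: dict[str, list[str]],
    focal: str,
    outgroup_evalues: dict[str, float],
    db_hits: list[tuple[str, float]],  # (taxon, evalue)
    ingroup_taxa: set[str],
    e_exclusion: float,
) -> str:
    """Direct restatement of the composed screen rule."""
    passes = all(
        any(present_ingroup.get(g, False) for g in members if g != focal)
        for members in phyla.values()
    )
    if not passes:
        return "rejected_ingroup"
    excluded = any(e < e_exclusion for e in outgroup_evalues.values()) or any(
        taxon not in ingroup_taxa and e < e_exclusion for taxon, e in db_hits
    )
    return "rejected_outgroup" if excluded else "lineage_specific"


def column_conservation_oracle(rows: list[str], matrix, m_min: float) -> list:
    """Independent per-column mean normalised pairwise score (None when
    fewer than two residues)."""
    out = []
    for col in range(len(rows[0])):
        res = [r[col] for r in rows if r[col] != "-"]
        if len(res) < 2:
            out.append(None)
            continue
        vals = []
        for i in range(len(res)):
            for j in range(i + 1, len(res)):
                a, b = res[i], res[j]
                denom = min(matrix[a, a], matrix[b, b]) - m_min
                v = (matrix[a, b] - m_min) / denom if denom > 0 else (
                    1.0 if a == b else 0.0
                )
                vals.append(min(max(v, 0.0), 1.0))
        out.append(sum(vals) / len(vals))
    return out
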