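"""Synthetic clade proteomes with known ground truth.

Emulates the genome panel the screen expects — a focal genome inside an
ingroup clade organised into phyla, plus distant outgroups — by evolving
protein families down a species tree under a stationary substitution
model. Families come in four classes:

* ``pan``              born at the root, present clade-wide and in outgroups;
* ``clade_specific``   born on the clade-ancestor branch, never in outgroups;
* ``chimera``          an ancient domain (root-born, emitted standalone into
                       outgroup proteomes) fused to a clade-born motif;
* ``fast``             root-born but evolving with a large rate multiplier,
                       producing realistic borderline cases.

Per branch a family can be lost; per ingroup tip a carried gene can be
"unannotated": dropped from the proteome but embedded (reverse-translated,
random strand, random-nucleotide flanks) in that genome's scaffold DNA, so
only the translated rescue round can find it. A decoy reference database
carries diverged copies of ancient families under extra-clade taxon labels
and of clade families under an ingroup taxon label, exercising the
taxon-aware exclusion rule. Everything is driven by one seed;
identical (config, seed) gives byte-identical outputs.

The focal lineage is protected from loss and unannotation: the screen
takes the focal proteome as its query set, so a family missing from the
focal tip would simply not be screened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .homology import BACKGROUND_FREQS
from .io_formats import write_fasta
from .motifs import DomainAnnotation, write_domain_annotations
from .records import MolType, SequenceRecord

AA = "".join(sorted(BACKGROUND_FREQS))
AA_PROBS = np.array([BACKGROUND_FREQS[a] for a in AA])
AA_PROBS = AA_PROBS / AA_PROBS.sum()

CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_TABLE):
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    CODONS.setdefault(_aa, []).append(_codon)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass
class TreeNode:
    """Rooted species tree; ``length`` is the branch above the node in
    expected substitutions per site."""

    name: str
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def tips(self) -> list[str]:
        return [n.name for n in self.walk() if not n.children]

    def find(self, name: str) -> "TreeNode | None":
        for node in self.walk():
            if node.name == name:
                return node
        return None

    def path_to(self, tip: str) -> list["TreeNode"] | None:
        if self.name == tip and not self.children:
            return [self]
        for child in self.children:
            sub = child.path_to(tip)
            if sub is not None:
                return [self] + sub
        return None


def default_panel_tree() -> tuple[TreeNode, dict[str, list[str]], list[str]]:
    """The default clade panel: 8 ingroup tips in three phyla of sizes
    {2, 2, 4} plus 10 outgroup tips, mirroring a mollusc/annelid/flatworm
    ingroup with distant bilaterian and non-bilaterian outgroups."""
    phyla = {
        "mollusc": ["MOL1", "MOL2"],
        "annelid": ["ANN1", "ANN2"],
        "flatworm": ["FLA1", "FLA2", "FLA3", "FLA4"],
    }
    outgroups = [f"OUT{i:02d}" for i in range(1, 11)]
    clade = TreeNode("clade_ancestor", 0.15)
    for phylum, members in phyla.items():
        anc = TreeNode(f"{phylum}_ancestor", 0.10)
        anc.children = [TreeNode(m, 0.10) for m in members]
        clade.children.append(anc)
    root = TreeNode("root", 0.0)
    root.children = [clade] + [TreeNode(o, 0.45) for o in outgroups]
    return root, phyla, outgroups


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic clade.

    Defaults encode the panel shape of the screen's intended use (three
    ingroup phyla of 2+2+4 genomes, 10 outgroups) with branch lengths
    calibrated so that ortholog divergence keeps within-clade E-values
    far below the 1e-7 presence threshold at typical protein lengths.
    """

    tree: TreeNode = field(default_factory=lambda: default_panel_tree()[0])
    phyla: dict[str, list[str]] = field(
        default_factory=lambda: default_panel_tree()[1]
    )
    focal_genome: str = "MOL1"
    clade_ancestor: str = "clade_ancestor"
    n_pan: int = 5
    n_clade_specific: int = 5
    n_chimera: int = 2
    n_fast: int = 2
    fast_rate: float = 8.0
    loss_prob: float = 0.05
    unannotated_prob: float = 0.1
    seq_len: tuple[int, int] = (150, 300)  # uniform inclusive range
    domain_len: int = 100
    motif_len: int = 80
    refdb_divergence: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        tips = set(self.tree.tips())
        ingroup = [g for members in self.phyla.values() for g in members]
        if len(set(ingroup)) != len(ingroup):
            raise ValueError("phyla must be pairwise disjoint")
        missing = set(ingroup) - tips
        if missing:
            raise ValueError(f"phylum genomes not in tree: {sorted(missing)}")
        clade = self.tree.find(self.clade_ancestor)
        if clade is None:
            raise ValueError(f"clade ancestor {self.clade_ancestor!r} not in tree")
        clade_tips = set(clade.tips())
        if clade_tips != set(ingroup):
            raise ValueError(
                "clade-ancestor subtree tips must equal the union of phyla"
            )
        if self.focal_genome not in set(ingroup):
            raise ValueError("focal genome must be an ingroup tip")
        for p in (self.loss_prob, self.unannotated_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    @property
    def ingroup_genomes(self) -> list[str]:
        return [g for members in self.phyla.values() for g in members]

    @property
    def outgroup_genomes(self) -> list[str]:
        ingroup = set(self.ingroup_genomes)
        return [t for t in self.tree.tips() if t not in ingroup]


# ---------------------------------------------------------------------------
# Substitution model


def evolve_sequence(
    parent: str, t: float, rho: float = 1.0, rng: np.random.Generator | None = None
) -> str:
    """Evolve a protein along a branch of length ``t`` (expected
    substitution events per site) at rate multiplier ``rho``.

    Stationary model: each site is hit by at least one substitution event
    with probability 1 - exp(-rho*t); a hit site is redrawn from the
    background amino-acid frequencies (possibly landing on the same
    residue). The expected fraction of *visibly* changed sites is
    therefore (1 - exp(-rho*t)) * (1 - pi_a) at a site carrying residue
    a. t = 0 returns the parent unchanged.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if rho <= 0:
        raise ValueError("rate multiplier must be > 0")
    if rng is None:
        rng = np.random.default_rng()
    if t == 0:
        return parent
    p_hit = 1.0 - np.exp(-rho * t)
    hit = rng.random(len(parent)) < p_hit
    if not hit.any():
        return parent
    replacements = rng.choice(list(AA), size=int(hit.sum()), p=AA_PROBS)
    out = list(parent)
    for idx, new in zip(np.flatnonzero(hit), replacements):
        out[idx] = new
    return "".join(out)


def expected_diff_fraction(parent: str, t: float, rho: float = 1.0) -> float:
    """Closed-form expected fraction of sites differing from the parent."""
    p_hit = 1.0 - np.exp(-rho * t)
    return p_hit * float(
        np.mean([1.0 - BACKGROUND_FREQS[a] for a in parent])
    )


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA), size=length, p=AA_PROBS))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice; no stop codon appended."""
    return "".join(rng.choice(CODONS[aa]) for aa in protein)


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class TruthTable:
    """Ground truth of one simulated clade.

    ``families``: one row per family — class, expected screen verdict
    (empty for "fast" families, whose detectability is deliberately
    borderline), expected novelty class. ``tip_status``: one row per
    (family, tip) with status carried / lost / unannotated / absent.
    Expected verdicts are derived from the realised per-tip statuses (a
    clade family that loss erased from an entire phylum is *expected* to
    fail the ingroup criterion), never from running the screen.
    """

    families: pd.DataFrame
    tip_status: pd.DataFrame
    embeddings: pd.DataFrame | None = None

    def write(self, path) -> None:
        merged = self.tip_status.merge(self.families, on="family_id")
        merged.to_csv(path, sep="\t", index=False)

    def status(self, family_id: str, tip: str) -> str:
        sel = self.tip_status[
            (self.tip_status.family_id == family_id)
            & (self.tip_status.tip == tip)
        ]
        return sel.status.iloc[0] if len(sel) else "absent"


@dataclass
class SimulatedClade:
    config: SimulationConfig
    proteomes: dict[str, list[SequenceRecord]]
    scaffolds: dict[str, list[SequenceRecord]]
    decoy_records: list[SequenceRecord]
    decoy_taxa: dict[str, str]
    domain_annotations: list[DomainAnnotation]
    truth: TruthTable

    @property
    def focal_proteome(self) -> list[SequenceRecord]:
        return self.proteomes[self.config.focal_genome]


# ---------------------------------------------------------------------------
# Simulation


def _evolve_down(
    node: TreeNode,
    seq: str,
    rho: float,
    rng: np.random.Generator,
    loss_prob: float,
    protected: set[str],
    out: dict[str, str],
    lost: set[str],
) -> None:
    """Recursively evolve ``seq`` into the subtree below ``node``;
    branches on the path to a protected tip never lose the gene."""
    for child in node.children:
        is_protected = bool(protected & set(child.tips()))
        if not is_protected and rng.random() < loss_prob:
            lost.update(child.tips())
            continue
        child_seq = evolve_sequence(seq, child.length, rho, rng)
        if child.children:
            _evolve_down(child, child_seq, rho, rng, loss_prob, protected,
                         out, lost)
        else:
            out[child.name] = child_seq


def _embed_in_scaffold(
    protein: str, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Reverse-translate and embed in random flanks on a random strand.

    Returns (scaffold, start, frame): ``start`` is the 1-based position of
    the embedded coding block on the forward strand and ``frame`` the
    six-frame-translation frame in which the protein reads back exactly.
    """
    cds = reverse_translate(protein, rng)
    left = "".join(rng.choice(list("ACGT"), size=int(rng.integers(150, 401))))
    right = "".join(rng.choice(list("ACGT"), size=int(rng.integers(150, 401))))
    strand = 1 if rng.random() < 0.5 else -1
    block = cds if strand == 1 else revcomp(cds)
    scaffold = left + block + right
    start = len(left) + 1
    if strand == 1:
        frame = (start - 1) % 3 + 1
    else:
        rc_start = len(scaffold) - (start + len(block) - 1) + 1
        frame = -((rc_start - 1) % 3 + 1)
    return scaffold, start, frame


def simulate_clade(config: SimulationConfig) -> SimulatedClade:
    """Generate proteomes, scaffold DNA, a decoy reference database and
    the ground-truth table for one seeded clade."""
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    clade = tree.find(config.clade_ancestor)
    assert clade is not None
    ingroup = config.ingroup_genomes
    outgroups = config.outgroup_genomes
    focal = config.focal_genome
    protected = {focal}

    proteomes: dict[str, list[SequenceRecord]] = {
        g: [] for g in ingroup + outgroups
    }
    scaffold_seqs: dict[str, list[tuple[str, str]]] = {g: [] for g in ingroup}
    decoy_records: list[SequenceRecord] = []
    decoy_taxa: dict[str, str] = {}
    annotations: list[DomainAnnotation] = []
    fam_rows: list[dict] = []
    status_rows: list[dict] = []
    embeddings: list[dict] = []

    def new_len() -> int:
        lo, hi = config.seq_len
        return int(rng.integers(lo, hi + 1))

    families: list[tuple[str, str]] = (
        [(f"pan{i:02d}", "pan") for i in range(1, config.n_pan + 1)]
        + [(f"cld{i:02d}", "clade_specific")
           for i in range(1, config.n_clade_specific + 1)]
        + [(f"chi{i:02d}", "chimera") for i in range(1, config.n_chimera + 1)]
        + [(f"fst{i:02d}", "fast") for i in range(1, config.n_fast + 1)]
    )

    for family_id, fam_class in families:
        rho = config.fast_rate if fam_class == "fast" else 1.0
        tips_seq: dict[str, str] = {}
        lost: set[str] = set()
        motif_tips: dict[str, str] = {}

        if fam_class in ("pan", "fast"):
            root_seq = random_protein(new_len(), rng)
            _evolve_down(tree, root_seq, rho, rng, config.loss_prob,
                         protected, tips_seq, lost)
        elif fam_class == "clade_specific":
            anc_seq = random_protein(new_len(), rng)
            _evolve_down(clade, anc_seq, rho, rng, config.loss_prob,
                         protected, tips_seq, lost)
        else:  # chimera: root-born domain + clade-born motif
            domain_root = random_protein(config.domain_len, rng)
            domain_tips: dict[str, str] = {}
            _evolve_down(tree, domain_root, rho, rng, config.loss_prob,
                         protected, domain_tips, lost)
            motif_anc = random_protein(config.motif_len, rng)
            motif_lost: set[str] = set()
            _evolve_down(clade, motif_anc, rho, rng, 0.0, protected,
                         motif_tips, motif_lost)
            for tip, dom in domain_tips.items():
                if tip in motif_tips:  # ingroup: fused protein
                    tips_seq[tip] = dom + motif_tips[tip]
                else:  # outgroup: standalone ancient domain
                    tips_seq[tip] = dom

        # annotation / unannotated placement per tip
        for tip in ingroup + outgroups:
            if tip not in tips_seq:
                status_rows.append(
                    dict(family_id=family_id, tip=tip,
                         status="lost" if tip in lost else "absent")
                )
                continue
            gene_id = f"{family_id}.{tip}"
            unannotated = (
                tip in ingroup
                and tip != focal
                and rng.random() < config.unannotated_prob
            )
            if unannotated:
                scaffold, start, frame = _embed_in_scaffold(tips_seq[tip], rng)
                scaf_id = f"scaf_{gene_id}"
                scaffold_seqs[tip].append((scaf_id, scaffold))
                embeddings.append(
                    dict(family_id=family_id, tip=tip, scaffold_id=scaf_id,
                         start=start, frame=frame, protein=tips_seq[tip])
                )
                status_rows.append(
                    dict(family_id=family_id, tip=tip, status="unannotated")
                )
            else:
                proteomes[tip].append(
                    SequenceRecord(gene_id, tip, tips_seq[tip],
                                   MolType.protein)
                )
                status_rows.append(
                    dict(family_id=family_id, tip=tip, status="carried")
                )

        # decoy reference-database entries
        ref_id = f"ref_{family_id}"
        if fam_class in ("pan", "fast"):
            decoy_records.append(
                SequenceRecord(
                    ref_id, "refdb",
                    evolve_sequence(root_seq, config.refdb_divergence, rho, rng),
                )
            )
            decoy_taxa[ref_id] = "extraclade"
        elif fam_class == "chimera":
            decoy_records.append(
                SequenceRecord(
                    ref_id, "refdb",
                    evolve_sequence(domain_root, config.refdb_divergence,
                                    rho, rng),
                )
            )
            decoy_taxa[ref_id] = "extraclade"
        else:
            decoy_records.append(
                SequenceRecord(
                    ref_id, "refdb",
                    evolve_sequence(anc_seq, 0.15, rho, rng),
                )
            )
            decoy_taxa[ref_id] = "ingroup_clade"

        # domain annotations on the focal copy
        focal_gene = f"{family_id}.{focal}"
        focal_seq = tips_seq.get(focal)
        if focal_seq is not None:
            if fam_class == "chimera":
                annotations.append(
                    DomainAnnotation(focal_gene, 1, config.domain_len,
                                     f"DOM_{family_id}", True)
                )
            elif fam_class in ("pan", "fast"):
                annotations.append(
                    DomainAnnotation(focal_gene, 1, len(focal_seq),
                                     f"DOM_{family_id}", True)
                )

        fam_rows.append(
            dict(
                family_id=family_id,
                family_class=fam_class,
                expected_verdict="",  # filled below
                expected_novelty={
                    "pan": "known",
                    "fast": "",
                    "clade_specific": "fully_novel",
                    "chimera": "chimeric",
                }[fam_class],
            )
        )

    status_df = pd.DataFrame(status_rows)
    fam_df = pd.DataFrame(fam_rows)

    # expected verdicts from realised statuses
    detectable = {"carried", "unannotated"}
    for idx, row in fam_df.iterrows():
        if row.family_class == "fast":
            continue  # borderline by design: unscored
        sub = status_df[status_df.family_id == row.family_id]
        stat = dict(zip(sub.tip, sub.status))
        if stat.get(focal) != "carried":
            continue  # not screenable (cannot happen for protected focal)
        passes = all(
            any(stat.get(g) in detectable for g in members if g != focal)
            for members in config.phyla.values()
        )
        if not passes:
            fam_df.at[idx, "expected_verdict"] = "rejected_ingroup"
        elif row.family_class == "clade_specific":
            fam_df.at[idx, "expected_verdict"] = "lineage_specific"
        else:  # pan and chimera carry extra-clade evidence by construction
            fam_df.at[idx, "expected_verdict"] = "rejected_outgroup"

    # scaffold FASTA records; every ingroup genome gets at least one decoy
    # scaffold so the rescue stage always has DNA to scan
    scaffolds: dict[str, list[SequenceRecord]] = {}
    for genome in ingroup:
        recs = [
            SequenceRecord(sid, genome, seq, MolType.dna)
            for sid, seq in scaffold_seqs[genome]
        ]
        decoy_len = int(rng.integers(600, 1200))
        recs.append(
            SequenceRecord(
                f"scaf_decoy_{genome}", genome,
                "".join(rng.choice(list("ACGT"), size=decoy_len)),
                MolType.dna,
            )
        )
        scaffolds[genome] = recs

    truth = TruthTable(families=fam_df, tip_status=status_df,
                       embeddings=pd.DataFrame(embeddings))
    return SimulatedClade(
        config=config,
        proteomes=proteomes,
        scaffolds=scaffolds,
        decoy_records=decoy_records,
        decoy_taxa=decoy_taxa,
        domain_annotations=annotations,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# On-disk emission


def write_clade(clade: SimulatedClade, outdir) -> Path:
    """Write FASTAs, decoy db + taxon labels, truth and domain TSVs, and
    a ready-to-run screen configuration. Returns the config path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = clade.config
    proteome_paths: dict[str, str] = {}
    for genome, records in sorted(clade.proteomes.items()):
        path = outdir / f"{genome}.faa"
        write_fasta(records, path)
        proteome_paths[genome] = path.name
    dna_paths: dict[str, str] = {}
    for genome, records in sorted(clade.scaffolds.items()):
        path = outdir / f"{genome}_scaffolds.fna"
        write_fasta(records, path)
        dna_paths[genome] = path.name
    write_fasta(clade.decoy_records, outdir / "refdb.faa")
    with open(outdir / "refdb_taxa.tsv", "w") as fh:
        for sid in sorted(clade.decoy_taxa):
            fh.write(f"{sid}\t{clade.decoy_taxa[sid]}\n")
    clade.truth.write(outdir / "truth.tsv")
    write_domain_annotations(
        sorted(clade.domain_annotations, key=lambda a: (a.gene_id, a.start)),
        outdir / "domains.tsv",
    )
    screen_cfg = dict(
        focal_genome=cfg.focal_genome,
        ingroup_phyla={k: list(v) for k, v in cfg.phyla.items()},
        outgroup_genomes=list(cfg.outgroup_genomes),
        proteomes=proteome_paths,
        genome_dna=dna_paths,
        exclusion_dbs=[dict(name="refdb", fasta="refdb.faa",
                            taxa="refdb_taxa.tsv")],
        ingroup_taxa=["ingroup_clade"],
        engine="internal",
    )
    config_path = outdir / "screen_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(screen_cfg, fh, sort_keys=True)
    return config_path


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study conditions with a caller-chosen seed."""
    return SimulationConfig(seed=seed, **overrides)
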