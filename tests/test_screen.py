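import itertools

import numpy as np
import pytest

from _oracles import screen_decision_oracle
from trgscreen import (
    ExclusionDB,
    HomologyHit,
    MolType,
    ScreenConfig,
    SequenceRecord,
    build_presence_matrix,
    ingroup_criterion,
    outgroup_exclusion,
    rescue_unannotated,
)
from trgscreen.records import bit_score
from trgscreen.screen import Evidence


PHYLA = {
    "mollusc": ["MOL1", "MOL2"],
    "annelid": ["ANN1", "ANN2"],
    "flatworm": ["FLA1", "FLA2", "FLA3", "FLA4"],
}
OUTGROUPS = [f"OUT{i:02d}" for i in range(1, 11)]


def panel_config(**kw):
    base = dict(
        focal_genome="MOL1",
        ingroup_phyla={k: list(v) for k, v in PHYLA.items()},
        outgroup_genomes=list(OUTGROUPS),
        ingroup_taxa=["ingroup_clade"],
    )
    base.update(kw)
    return ScreenConfig(**base)


def _hit(gene, genome, ev, subject="sX"):
    return HomologyHit(
        query_id=gene, subject_id=subject, subject_genome=genome,
        raw_score=50, bit_score=bit_score(50, 0.3176, 0.134), evalue=ev,
        q_start=1, q_end=10, s_start=1, s_end=10,
    )


def _proteome(gene_ids):
    rng = np.random.default_rng(0)
    return [
        SequenceRecord(g, "MOL1",
                       "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30)))
        for g in gene_ids
    ]


# ---------------------------------------------------------------------------
# Presence matrix


def test_minimum_evalue_kept_per_cell():
    cfg = panel_config()
    prot = _proteome(["g1"])
    hits = [_hit("g1", "MOL2", 1e-8), _hit("g1", "MOL2", 1e-12),
            _hit("g1", "MOL2", 1e-3)]
    m = build_presence_matrix(prot, hits, cfg)
    assert m.best_evalue.at["g1", "MOL2"] == 1e-12
    assert m.present.at["g1", "MOL2"]


def test_self_hits_excluded_from_evidence():
    cfg = panel_config()
    m = build_presence_matrix(_proteome(["g1"]), [_hit("g1", "MOL1", 1e-50)],
                              cfg)
    assert "MOL1" not in m.best_evalue.columns
    assert not ingroup_criterion(m, "g1", cfg)


def test_boundary_evalue_is_absent():
    """A best E exactly at the threshold fails presence (strict below)."""
    cfg = panel_config()
    m = build_presence_matrix(
        _proteome(["g1"]),
        [_hit("g1", "MOL2", 1e-7), _hit("g1", "ANN1", 0.99e-7)],
        cfg,
    )
    assert not m.present.at["g1", "MOL2"]
    assert m.present.at["g1", "ANN1"]


def test_unknown_genome_rejected():
    cfg = panel_config()
    with pytest.raises(ValueError, match="unknown genome"):
        build_presence_matrix(_proteome(["g1"]), [_hit("g1", "NOPE", 1e-9)],
                              cfg)


def test_matrix_matches_per_cell_minimum_oracle():
    """Random 20-gene hit set vs an independent minimum-and-compare scan."""
    rng = np.random.default_rng(5)
    cfg = panel_config()
    genes = [f"g{i:02d}" for i in range(20)]
    genomes = cfg.all_genomes
    hits = []
    for _ in range(400):
        g = genes[rng.integers(len(genes))]
        genome = genomes[rng.integers(len(genomes))]
        hits.append(_hit(g, genome, float(10.0 ** -rng.uniform(0, 12))))
    m = build_presence_matrix(_proteome(genes), hits, cfg)
    for gene in genes:
        for genome in m.best_evalue.columns:
            cell = [h.evalue for h in hits
                    if h.query_id == gene and h.subject_genome == genome]
            expect = min(cell) if cell else None
            got = m.best_evalue.at[gene, genome]
            if expect is None:
                assert np.isnan(got)
            else:
                assert got == expect
                thr = (cfg.e_exclusion if genome in OUTGROUPS
                       else cfg.e_ingroup)
                assert m.present.at[gene, genome] == (expect < thr)


# ---------------------------------------------------------------------------
# Ingroup criterion


def test_presence_in_one_genome_per_phylum_passes():
    cfg = panel_config()
    hits = [_hit("g1", g, 1e-9) for g in ("MOL2", "ANN2", "FLA3")]
    m = build_presence_matrix(_proteome(["g1"]), hits, cfg)
    assert ingroup_criterion(m, "g1", cfg)


def test_one_empty_phylum_fails():
    # both annelids and all four flatworms, but no non-focal mollusc
    cfg = panel_config()
    hits = [_hit("g1", g, 1e-9)
            for g in ("ANN1", "ANN2", "FLA1", "FLA2", "FLA3", "FLA4")]
    m = build_presence_matrix(_proteome(["g1"]), hits, cfg)
    assert not ingroup_criterion(m, "g1", cfg)


def test_exhaustive_truth_table_matches_oracle():
    """All 2^8 ingroup presence patterns against an independently coded
    per-phylum rule."""
    cfg = panel_config()
    ingroup = cfg.ingroup_genomes
    prot = _proteome(["g1"])
    for bits in itertools.product([False, True], repeat=8):
        pattern = dict(zip(ingroup, bits))
        hits = [_hit("g1", g, 1e-9) for g, b in pattern.items() if b]
        m = build_presence_matrix(prot, hits, cfg)
        expect = all(
            any(pattern[g] for g in members if g != "MOL1")
            for members in PHYLA.values()
        )
        assert ingroup_criterion(m, "g1", cfg) == expect


# ---------------------------------------------------------------------------
# Outgroup exclusion


def _db_config():
    db = ExclusionDB(
        name="refdb", fasta_path="unused.faa",
        taxon_of={"clade_seq": "ingroup_clade", "alien_seq": "extraclade"},
    )
    return panel_config(exclusion_dbs=[db])


def test_subthreshold_outgroup_hit_excludes():
    cfg = _db_config()
    excluded, offending = outgroup_exclusion(
        "g1", [_hit("g1", "OUT02", 1e-6)], [], cfg
    )
    assert excluded and offending == [("OUT02", 1e-6)]


def test_above_threshold_hit_does_not_exclude():
    cfg = _db_config()
    excluded, _ = outgroup_exclusion("g1", [_hit("g1", "OUT02", 1e-4)], [], cfg)
    assert not excluded


def test_boundary_exclusion_evalue_does_not_exclude():
    cfg = _db_config()
    excluded, _ = outgroup_exclusion("g1", [_hit("g1", "OUT02", 1e-5)], [], cfg)
    assert not excluded


def test_ingroup_taxon_db_entry_never_disqualifies():
    """A decoy database carrying the gene's own clade ortholog must not
    reject the gene; an extra-clade entry at the same E-value must."""
    cfg = _db_config()
    clade_hit = _hit("g1", "refdb", 1e-30, subject="clade_seq")
    excluded, _ = outgroup_exclusion("g1", [], [clade_hit], cfg)
    assert not excluded
    alien_hit = _hit("g1", "refdb", 1e-6, subject="alien_seq")
    excluded, offending = outgroup_exclusion("g1", [], [alien_hit], cfg)
    assert excluded and offending == [("refdb", 1e-6)]


def test_db_sequence_without_taxon_label_rejected():
    cfg = _db_config()
    with pytest.raises(ValueError, match="no taxon label"):
        outgroup_exclusion(
            "g1", [], [_hit("g1", "refdb", 1e-9, subject="unlabeled")], cfg
        )


# ---------------------------------------------------------------------------
# Rescue


def _rescue_setup(scoring):
    from trgscreen.simulate import random_protein, reverse_translate

    rng = np.random.default_rng(11)
    prot = random_protein(120, rng)
    gene = SequenceRecord("g1", "MOL1", prot)
    cds = reverse_translate(prot, rng)
    flank = lambda: "".join(rng.choice(list("ACGT"), 200))
    scaffold = SequenceRecord("scaf1", "ANN1", flank() + cds + flank(),
                              MolType.dna)
    return gene, scaffold


def test_absent_gene_with_planted_cds_is_rescued(scoring):
    cfg = panel_config(genome_dna={"ANN1": "unused"})
    gene, scaffold = _rescue_setup(scoring)
    m = build_presence_matrix([gene], [_hit("g1", "MOL2", 1e-9),
                                       _hit("g1", "FLA1", 1e-9)], cfg)
    assert not ingroup_criterion(m, "g1", cfg)  # annelid phylum empty
    m2 = rescue_unannotated(m, [gene], cfg, {"ANN1": [scaffold]}, scoring)
    assert m2.evidence.at["g1", "ANN1"] == Evidence.rescued.value
    assert m2.present.at["g1", "ANN1"]
    assert ingroup_criterion(m2, "g1", cfg)


def test_rescue_never_touches_present_cells_or_outgroups(scoring):
    cfg = panel_config(genome_dna={"ANN1": "unused"})
    gene, scaffold = _rescue_setup(scoring)
    m = build_presence_matrix([gene], [_hit("g1", "ANN1", 1e-9),
                                       _hit("g1", "OUT01", 1e-9)], cfg)
    m2 = rescue_unannotated(m, [gene], cfg,
                            {"ANN1": [scaffold], "OUT01": [scaffold]}, scoring)
    assert m2.best_evalue.at["g1", "ANN1"] == 1e-9  # untouched
    assert m2.evidence.at["g1", "ANN1"] == Evidence.annotated.value
    assert m2.evidence.at["g1", "OUT01"] == Evidence.annotated.value


def test_rescue_is_identity_without_absent_cells(scoring):
    cfg = panel_config(genome_dna={"ANN1": "unused"})
    gene, scaffold = _rescue_setup(scoring)
    hits = [_hit("g1", g, 1e-9) for g in cfg.all_genomes if g != "MOL1"]
    m = build_presence_matrix([gene], hits, cfg)
    m2 = rescue_unannotated(m, [gene], cfg, {"ANN1": [scaffold]}, scoring)
    assert m2.best_evalue.equals(m.best_evalue)
    assert m2.evidence.equals(m.evidence)


# ---------------------------------------------------------------------------
# Threshold monotonicity


def test_relaxing_ingroup_threshold_grows_passing_set():
    rng = np.random.default_rng(9)
    genes = [f"g{i}" for i in range(15)]
    hits = []
    for g in genes:
        for genome in ("MOL2", "ANN1", "FLA2"):
            if rng.random() < 0.8:
                hits.append(_hit(g, genome, float(10.0 ** -rng.uniform(4, 10))))
    tight = panel_config(e_ingroup=1e-7)
    loose = panel_config(e_ingroup=1e-4)
    prot = _proteome(genes)
    m_tight = build_presence_matrix(prot, hits, tight)
    m_loose = build_presence_matrix(prot, hits, loose)
    pass_tight = {g for g in genes if ingroup_criterion(m_tight, g, tight)}
    pass_loose = {g for g in genes if ingroup_criterion(m_loose, g, loose)}
    assert pass_tight <= pass_loose


def test_relaxing_exclusion_threshold_shrinks_surviving_set():
    rng = np.random.default_rng(10)
    genes = [f"g{i}" for i in range(15)]
    out_hits = [
        _hit(g, "OUT03", float(10.0 ** -rng.uniform(2, 8)))
        for g in genes if rng.random() < 0.7
    ]
    tight = panel_config(e_exclusion=1e-5)
    loose = panel_config(e_exclusion=1e-3)
    surv_tight = {g for g in genes
                  if not outgroup_exclusion(g, out_hits, [], tight)[0]}
    surv_loose = {g for g in genes
                  if not outgroup_exclusion(g, out_hits, [], loose)[0]}
    assert surv_loose <= surv_tight


def test_composed_decision_matches_oracle_with_boundaries():
    """Composed ingroup + exclusion decision vs the written rule, over
    presence patterns crossed with boundary E-values."""
    cfg = _db_config()
    ingroup = cfg.ingroup_genomes
    prot = _proteome(["g1"])
    boundary_cases = [
        {}, {"OUT01": 1e-5}, {"OUT01": 0.99e-5}, {"OUT07": 1e-9},
    ]
    db_cases = [[], [("ingroup_clade", 1e-20, "clade_seq")],
                [("extraclade", 1e-6, "alien_seq")]]
    rng = np.random.default_rng(3)
    for bits in itertools.product([False, True], repeat=8):
        pattern = dict(zip(ingroup, bits))
        out_evs = boundary_cases[rng.integers(len(boundary_cases))]
        db = db_cases[rng.integers(len(db_cases))]
        hits = [_hit("g1", g, 1e-9) for g, b in pattern.items() if b]
        out_hits = [_hit("g1", g, e) for g, e in out_evs.items()]
        db_hits = [_hit("g1", "refdb", e, subject=sid) for _, e, sid in db]
        m = build_presence_matrix(prot, hits, cfg)
        if not ingroup_criterion(m, "g1", cfg):
            got = "rejected_ingroup"
        elif outgroup_exclusion("g1", out_hits, db_hits, cfg)[0]:
            got = "rejected_outgroup"
        else:
            got = "lineage_specific"
        expect = screen_decision_oracle(
            pattern, PHYLA, "MOL1", out_evs,
            [(t, e) for t, e, _ in db], {"ingroup_clade"}, 1e-5,
        )
        assert got == expect, (bits, out_evs, db)
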