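# trgscreen

Detection of **taxonomically restricted genes** (TRGs, also called
lineage-specific or orphan genes): genes of a focal genome that are
strongly conserved *within* one clade but undetectable *outside* it.
Screens of this kind identified clade-specific developmental genes such
as the spiralian prototroch markers; `trgscreen` re-implements the
screening logic as a general, tested pipeline for anyone who wants to
run — or critically re-examine — a presence/absence TRG screen on a
panel of proteomes.

A focal gene *g* with query length *m* is called **lineage-specific**
when, using local-alignment E-values
`E = K·m·n·e^(−λS)` (ungapped Karlin–Altschul statistics over a search
space of *n* residues):

1. every ingroup **phylum** has ≥ 1 genome with a hit at
   `E < e_ingroup` (default `1e-7`; the focal genome's self-hit never
   counts),
2. no outgroup genome, and no *extra-clade* entry of a reference
   exclusion database, has a hit at `E < e_exclusion` (default `1e-5`),
3. where an ingroup genome's annotation lacks the gene, a tblastn-style
   six-frame translated search of its scaffold DNA
   (`E < e_rescue`, default `1e-7`) may **rescue** the missing evidence
   before criterion 1 is judged.

Surviving candidates are then classified from the conservation profile
of their ingroup ortholog alignment intersected with externally supplied
domain annotations: **fully_novel** (conserved, no known domain — the de
novo pattern), **chimeric** (an ancient extra-clade domain fused to a
clade-specific conserved motif), or **known**.

Because real screens of this kind hinge on which genomes and database
snapshot are used, the package ships a first-class **simulator** that
generates clade proteomes (8 ingroup genomes in 3 phyla + 10 outgroups
by default) with planted pan-taxon, clade-specific, chimeric,
fast-evolving and unannotated genes, plus a ground-truth table — so
every stage of the screen is verifiable at desk scale.

## Worked example

Run the whole pipeline on a seeded synthetic clade:

```bash
trgscreen run-all --outdir demo --seed 11
```

which finishes with the candidate funnel:

```
done; manifest at demo/manifest.json; funnel: {'simulate': {'families': 14,
'focal_genes': 14}, 'search': {'hits': 2551, 'targets': 18},
'screen': {'focal_genes': 14, 'pass_ingroup': 10, 'lineage_specific': 5},
'classify': {'ls_fully_novel': 5}}
```

Of the 14 focal genes, 10 pass the per-phylum ingroup criterion and 5
survive outgroup/reference exclusion; all 5 classify as fully novel —
exactly the clade-specific families this seed planted. `demo/report.tsv`
holds the per-gene evidence trail (verdict, best E-value per phylum and
per outgroup, rescue and exclusion records):

```
gene_id     verdict            passes_ingroup  best_e_annelid  best_e_flatworm  best_e_mollusc
chi01.MOL1  rejected_ingroup   False           1.001915e-72    5.338425e-75     8.003122e-01
chi02.MOL1  rejected_outgroup  True            9.254530e-72    2.377867e-77     2.406237e-89
cld01.MOL1  lineage_specific   True            6.447139e-98    4.026744e-94     6.526125e-117
```

`chi02` (a planted chimera) passes the ingroup stage but is rejected by
its ancient domain's outgroup hits; `demo/classification.tsv` records
the conserved segments behind each novelty call, e.g.

```
cld01.MOL1  lineage_specific  fully_novel  1-202:novel_conserved
```

The same stages are available individually (`trgscreen simulate`,
`search`, `screen`, `classify`) and as library functions
(`simulate_clade`, `run_screen`, `classify_gene`, ...).

## Layout

- `src/trgscreen/io_formats.py` — FASTA, 11-column hit TSV (plus BLAST
  outfmt-6 ingestion), YAML screen config.
- `src/trgscreen/homology.py` — scoring schemes, seeded Smith–Waterman
  search, Karlin–Altschul E-values, six-frame translated search.
- `src/trgscreen/screen.py` — presence matrix, ingroup criterion,
  outgroup/reference exclusion, translated rescue, `run_screen`.
- `src/trgscreen/motifs.py` — center-star ortholog alignment,
  conservation profiling, segment detection, novelty classification.
- `src/trgscreen/simulate.py` — species-tree sequence evolution,
  clade/proteome simulator, ground truth.
- `src/trgscreen/pipeline.py`, `cli.py` — orchestration with manifest
  and resume; `trgscreen` CLI.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.
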