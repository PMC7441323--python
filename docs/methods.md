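# Methods

## The screen

`trgscreen` detects taxonomically restricted genes (TRGs): protein-coding
genes of a focal genome that are strongly conserved across an ingroup
clade but have no detectable homology outside it. The decision rule for a
focal gene *g* is the conjunction of three filters, applied in a fixed
order:

1. **Ingroup criterion.** The ingroup is organised into phyla. *g* passes
   iff every phylum contains at least one genome with a local-alignment
   hit at `E < e_ingroup` (default `1e-7`). The focal genome's trivial
   self-hit carries no cross-species information, so the focal genome is
   excluded from the evidence and its own phylum must be vouched for by a
   non-focal member (a config flag `count_focal_genome` restores the
   laxer reading).
2. **Translated rescue.** Gene annotations miss real genes. Before the
   criteria are applied, every *absent* ingroup cell whose genome has
   scaffold DNA configured is re-tested by a tblastn-style search of the
   focal protein against all six reading frames of the scaffolds
   (`E < e_rescue`, default `1e-7`). A qualifying hit flips the cell to
   present with evidence `rescued`. Present cells are never touched and
   outgroup cells are never rescued (a `rescue_outgroups` flag extends
   translated search to outgroup *exclusion* as an opt-in).
3. **Outgroup / reference exclusion.** *g* is disqualified by any hit at
   `E < e_exclusion` (default `1e-5`) in an outgroup proteome, or in an
   exclusion database entry whose **taxon label lies outside the
   clade**. The taxon condition matters: an nr-style reference database
   inevitably contains clade entries, and a taxon-blind rule would reject
   every true TRG through its own orthologs.

All thresholds are strict (`<`). The stage order — rescue before the
ingroup criterion, exclusion last — follows from the rescue round's
purpose (it exists to satisfy the ingroup criterion).

## Homology engine

Desk-scale search engine so the screen runs with no external tool:

- **Scoring.** BLOSUM62, affine gaps with `gap_open = -11`,
  `gap_extend = -1`; a gap of length L costs `open + L*extend` (the
  BLASTp 11/1 convention). `X` scores 0 against everything; `*` scores
  −4. The expected score under Robinson–Robinson background frequencies
  is checked to be negative at scheme construction.
- **Alignment.** Smith–Waterman with affine gaps via Biopython's
  `PairwiseAligner` (C kernel). Among co-optimal alignments the engine
  reports the aligner's deterministic first enumeration; only scores are
  contract-exact.
- **Seeding.** A subject is aligned only if it shares an exact k-mer
  (k = 3) with the query; the extension then runs to completion, so the
  emitted score *equals* the exact Smith–Waterman score (the `x_drop`
  parameter is reserved; truncated extension is unnecessary at the
  problem sizes this engine targets). At most one hit per
  (query, subject) pair is emitted.
- **Statistics.** Ungapped Karlin–Altschul:
  `E = K·m·n·exp(−λS)` with defaults `λ = 0.3176`, `K = 0.134`
  (the standard ungapped BLOSUM62 values), `m` the query length and `n`
  the total residues of the searched genome (per-genome search spaces,
  matching per-genome searches rather than one pooled database). The
  gapped refinements (edge-effect and length adjustment) are omitted:
  the screen only thresholds E-values, and at the score margins involved
  (λS in the hundreds versus thresholds at λS ≈ 30–45) the refinement
  changes no verdict. Low-complexity (SEG-style) masking is not applied.
- **Translated search.** Scaffolds are translated in six frames
  (stops as `*`, N-containing codons as `X`, partial codons dropped);
  frame translations are split at stops so no hit crosses one; subject
  coordinates are mapped back to forward-strand DNA with the frame
  recorded. `n` is the total translated residue count.

## Novelty classification

Candidates are classified against their ingroup ortholog set:

- **Alignment.** Center-star MSA anchored on the focal sequence: each
  ortholog is globally aligned to the focal with free end gaps and the
  pairwise alignments are merged under "once a gap, always a gap". The
  focal row defines the column → focal-coordinate map.
- **Conservation.** Per column, the mean normalised pairwise
  substitution score over non-gap pairs. A pair (a, b) is normalised as
  `(M[a,b] − Mmin) / (min(M[a,a], M[b,b]) − Mmin)`, clipped to [0, 1]
  (`Mmin` = the matrix minimum over the 20 standard residues), so a pair
  of identical residues scores exactly 1 whatever the residue — a plain
  min–max rescale against the global diagonal range cannot satisfy that,
  because BLOSUM62 diagonal entries differ (A/A = 4, W/W = 11). Columns
  with fewer than two residues are masked. Scores are smoothed with a
  centred sliding mean (default width `w = 11`, shrinking at edges,
  masked columns ignored).
- **Segments.** Maximal runs of ≥ `min_len` (default 20) columns with
  smoothed score ≥ `high` (default 0.7) become conserved segments;
  the rest is unconserved. The defaults are calibrated on the simulator
  (at ≤ 40 % pairwise ortholog divergence, conserved blocks profile at
  ≈ 0.8, background at ≈ 0.35) and are exposed as flags; conservation
  thresholds are not derived from any real dataset.
- **Classification.** Domain annotations are *inputs* (5-column TSV),
  not computed — profile-scan tools are out of scope; the
  `is_extraclade` flag marks domains known outside the clade. Each
  conserved segment is intersected with the union of extra-clade
  domains: a covered run ≥ `min_len` (or ≥ 50 % of the segment)
  contributes a *known* part, an uncovered run ≥ `min_len` a *novel*
  part. The gene is **chimeric** when known and novel parts both occur,
  **fully_novel** when no known part occurs, **known** when only known
  parts occur, and **unclassified** when there is no conserved segment
  at all. Judging runs rather than whole-segment coverage matters
  because a chimera's ancient domain and young motif are *equally*
  conserved within the clade and smoothing fuses them into one segment;
  overhangs shorter than `min_len` are still read as fuzzy domain
  boundaries, which is what the 50 % fraction is for.

## Synthetic clades

The simulator generates the study conditions end to end. The default
panel mirrors the screen's intended use: 8 ingroup genomes in three
phyla of sizes {2, 2, 4} (focal = first genome of the first phylum) and
10 outgroups. Branch lengths (expected substitution events per site):
root → clade ancestor 0.15, clade ancestor → phylum ancestor 0.10,
phylum ancestor → tip 0.10, root → outgroup 0.45. These were chosen once
so that within-clade ortholog divergence (≤ 0.4 on any tip pair path)
keeps E-values orders of magnitude below `1e-7` at typical lengths,
while outgroup copies of ancient families (path ≈ 0.8) remain clearly
detectable at `1e-5` — i.e. the screen's margins are generous by
construction, and failures in tests indicate logic errors, not
statistical bad luck.

- **Substitution model.** Stationary: each site is hit with probability
  `1 − exp(−ρt)` and redrawn from Robinson–Robinson frequencies; the
  expected visibly-changed fraction has the closed form
  `(1 − e^{−ρt})(1 − π_a)` per site, which the tests check by
  simulation. No indels (alignment columns stay in register — a
  documented simplification; the star aligner is still exercised on its
  own fixtures with real gaps).
- **Family classes.** Per replicate: 5 `pan` (root-born, clade-wide +
  outgroups), 5 `clade_specific` (born on the clade-ancestor branch),
  2 `chimera` (root-born 100-aa domain fused to a clade-born 80-aa
  motif in ingroup tips; the domain alone emitted into outgroup
  proteomes), 2 `fast` (root-born, rate multiplier ρ = 8, effectively
  randomised — they exist to create realistic borderline cases and are
  excluded from recovery denominators). Root/ancestor sequence lengths
  are uniform on [150, 300].
- **Loss and annotation noise.** Per-branch loss probability 0.05
  (a loss erases the whole subtree); per ingroup tip, a carried gene is
  "unannotated" with probability 0.1 — dropped from the proteome and
  embedded in scaffold DNA (uniform synonymous reverse translation,
  random 150–400-nt flanks, random strand; no introns). The focal
  lineage is protected from loss and unannotation, since a family
  missing from the focal proteome would never be queried at all.
- **Decoy reference database.** Diverged copies (t = 0.4) of every
  ancient family under the taxon label `extraclade`, and of every clade
  family under `ingroup_clade` — the latter must *not* disqualify, which
  is exactly the taxon-aware exclusion rule under test.
- **Ground truth.** The truth table records each family's class, every
  tip's realised status (carried / lost / unannotated / absent), and the
  *expected* screen verdict derived purely from those statuses (e.g. a
  clade family that loss erased from an entire phylum is expected to
  fail the ingroup criterion). Expected verdicts for `fast` families are
  left blank. Identical (config, seed) yields byte-identical output
  files.

What passing tests on these clades do **not** show about real data:
real proteomes have paralogy, domain shuffling beyond the two-block
chimera, introns splitting rescued genes across exons, compositional
bias that ungapped Karlin–Altschul statistics handle imperfectly, and
annotation errors that are not simple omissions. The simulator verifies
the *logic* of the screen under controlled conditions, not BLAST-parity
on any particular genome panel.

## Pipeline and reproducibility

`run_all` executes simulate → search → screen → classify, writing a JSON
manifest (config hash, tool version, seed, per-stage outputs with
SHA-256 hashes, wall times, and the candidate funnel). `--resume` skips
a stage only when all its recorded outputs still hash-match; the funnel
(focal genes → passing ingroup → lineage-specific) is asserted
non-increasing. Reports are TSV, sorted by gene id, so identical inputs
give byte-identical files and input record order is irrelevant.

Problem sizes used by the test suite and `scripts/acceptance.py`
(20 replicates of the default 18-genome panel, ~14 focal genes each,
sequences of 150–300 residues) were chosen as the smallest scale at
which every filter, the rescue round and both novelty patterns are
exercised with comfortable statistical margins.

## Known limitations

- Ungapped E-value statistics with fixed (λ, K); no composition-based
  score adjustment, no SEG masking, no two-hit seeding heuristics.
- Center-star MSA is O(k²) in alignment quality terms only for the
  star topology; deep or gappy ortholog sets would warrant a proper
  progressive aligner.
- Chimera detection depends on externally supplied domain annotations;
  without them a chimera is indistinguishable from a fully novel gene.
- The rescue stage assumes contiguous (intron-free) coding embeddings.
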