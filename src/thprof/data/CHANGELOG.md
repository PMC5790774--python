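# Fixture changelog

All fixtures in this directory are transcriptions of printed source tables.
Symbols are stored exactly as printed wherever the print is unambiguous; every
departure from the printed text is recorded here.

## regulator_catalog.tsv / .json

- 61 entries; category histogram: 20 transcription factors, 5 transcription
  activators, 1 transcription repressor, 2 signal transducers, 20 cytokines,
  5 lineage-inducing factors, 6 receptors, 2 others.
- Subset labels normalised to the codes Th1, Th2, Th9, Tfh, Th17, Treg, Th22,
  Th25 (the source prints TH1/TFH/Thl etc. inconsistently).
- Greek letters in common names transliterated (RORγt → RORgammaT, RORα →
  RORalpha, IL10Rβ → IL10Rbeta, IFNγ → IFNgamma, TGFβ → TGFbeta).
- Absent UniGene IDs stored as `N/A` as printed.

## table2_calls.tsv (human tissue call matrix, 56 genes × 32 tissues)

- Blank cells in the printed matrix are stored as `-` (not expressed), per the
  table legend's three-way convention (`++`, `+`, `-`).
- Tissue-name misprints corrected: "Prostrate" → "Prostate",
  "Umbilic chord" → "Umbilical cord" (the running text uses the
  corrected names).
- Row-label misprints corrected to the catalog symbols: CCLL5 → CCL15,
  L12RB1 → IL12RB1, L13 → IL13, IL7B → IL17B, L10RB → IL10RB.
  Parenthetical subset annotations on row labels (e.g. "(Tfh*)", "(Thl)")
  are dropped; note the printed table annotates STAT3 as "(Th2)" although
  the catalog assigns it to Tfh and the text discusses it as a Th22
  regulator — the annotation is ignored, the cells are kept.
- HNF1A, Liver: printed as `+ +` (stray space); stored as `++`.
- **BCL6 discrepancy:** the printed matrix marks BCL6 expressed in 29
  tissues, while the accompanying text states 28. The two counts cannot both
  be right. This fixture follows the text: the `+` in *Embryonic tissue* is
  dropped (chosen because the text separately lists embryonic tissue among
  the tissues with "no or very low" resident Th-subset activity, making a
  printed `+` there the most plausible transcription artefact). With this
  single change BCL6 counts 28 expressed / 3 high, matching the text.
- **FOXP3 row reconstructed from text:** the machine-readable table omits
  FOXP3. The row is rebuilt from the running text (expressed in trachea,
  thymus, spleen, mammary gland, lymph node, lung, eye, blood; high in
  trachea only). Treat FOXP3 cells as text-derived, not table-derived.
- Rows for ACT1, IL21, IL23, IL25 and CD28 are absent from the
  machine-readable table and are not reconstructed (no per-tissue
  information in the text); the fixture therefore has 56 of 61 genes.

## mhc2_diff_table.tsv (MHC class II signed fold changes, 3 knockout contrasts)

- 14 rows; blank cells mean "not significantly changed" (the printed table is
  pre-gated) and are stored as empty fields.
- Symbol misprints corrected: H2-Abl → H2-Ab1, Mrl → Mr1 (OCR l/1 confusion;
  the corrected symbols are the official mouse symbols and the ones the
  running text implies).
- Unicode minus signs normalised to ASCII `-`.

## gene_sets.json

- `housekeeping_human` keeps the printed spellings PRS27A and GADPH (official
  symbols RPS27A and GAPDH); `symbol_aliases.json` records the mapping, which
  is never applied silently.
- `cosignal_partial` is flagged incomplete: the full 28-receptor co-signaling
  panel exists only as a figure; only the eight receptors named in running
  text are packaged, with their co-stimulation/co-inhibition direction.
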