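# Methods

## The annotation model

`secloc` treats subcellular localization as a deterministic rule cascade
over two evidence sources: curated UniProt annotation and the categorical
verdicts of seven sequence-based predictors. The design assumption is the
standard one for knowledgebase construction: manual curation, where it
exists, is more reliable than any predictor, and among predictors a
consensus with explicit exclusion rules beats any single tool.

The cascade fires in a fixed order; each step is terminal:

1. **Curated annotation.** If a reviewed record carries a mapped curated
   location, that category is assigned with evidence `curated`. Multi-
   location records take the first category in a fixed precedence list
   (secreted first); the full list is kept in the rule trace. Cytoskeleton
   outranks cytoplasm because curated cytoskeleton proteins are routinely
   co-annotated as cytoplasm. Unreviewed (TrEMBL-style) annotation is
   ignored unless `honor_unreviewed` is set, since the package cannot tell
   curator-reviewed statements from propagated ones.
2. **Secretion.** SignalP 4, Phobius, TargetP (`S`) and WoLF PSORT
   (`extr`) vote. ≥ 1 vote, no transmembrane helix starting after residue
   70, and no C-terminal ER-retention motif ⇒ secreted, tiered by vote
   count: 3–4 highly likely, 2 likely, 1 weakly likely. Within this set, a
   SignalP 3 signal-peptide call plus a FragAnchor class at or above the
   threshold (default *highly probable* only; no published class cutoff
   exists, so the strictest class is the default) reassigns the protein to
   the GPI-anchored category. GPI-anchored proteins carry no secretion
   tier and are never counted in secretome totals — they are a separate
   category, since published secretome totals do not state whether they
   were included.
3. **Mitochondria.** TargetP `M` AND WoLF PSORT `mito`; the AND is
   deliberate — on the reference benchmark it raises specificity to 98.5%
   at equal MCC (0.53) versus either tool alone. TMHMM splits membrane
   from non-membrane.
4. **ER.** WoLF PSORT `E.R.` OR (SignalP 4 signal peptide AND the
   ER-retention motif); membrane vs lumen split by TMHMM. The OR is a
   documented choice: the two signals are individually sufficient in the
   source protocol's description, which never states the connective.
5. **Other WoLF PSORT compartments** (`cyto`, `cysk`, `golg`, `lyso`,
   `nucl`, `pero`, `plas`, `vacu`), with a TMHMM membrane split for
   Golgi, nucleus and vacuole.
6. **Other membrane**: any remaining protein with a helix beyond residue
   70.
7. **Unknown** otherwise.

The cascade order mirrors the presentation order of the underlying
protocol's rule descriptions; since that protocol never states conflict
resolution, the order is fixed here and logged per protein (`rule_trace`),
making every assignment reproducible and auditable.

### Interpretation choices that were genuinely open

* *"Membrane domain not located within the N-terminus (first 70 amino
  acids)"* is interpreted as helix **start** ≤ 70 being disregarded — an
  N-terminal helix is indistinguishable from a signal peptide/anchor.
* WoLF PSORT dual labels (`extr_plas`) are split on `_` and the first
  component is used — WoLF PSORT lists the dominant compartment first. The
  `E.R.` label is matched whole (its dots are not separators).
* SignalP 4's printed decision is taken as-is (default cutoffs, no
  re-thresholding); SignalP 3 contributes only to the GPI route and
  cleavage sites, where it is the more accurate version.
* Strict mode (default) refuses incomplete predictor bundles; lenient
  mode counts a missing tool as a negative verdict and warns.

## Benchmark and metrics

The curated benchmark keeps reviewed records with exactly one mapped
curated location, no hedged qualifier ("by similarity", "probable",
"potential"), no fragment flag, a methionine start and ≥ 70 residues; an
exclusion tally is always reported. Cell-membrane annotation populates the
plasma-membrane category; cytoskeleton entries stay out of cytoplasm.
Each category is scored one-vs-rest over all retained proteins:
Sn = TP/(TP+FN)·100, Sp = TN/(TN+FP)·100, and MCC with an exact integer
numerator over the square root of the four marginal products. MCC is
reported on the −1..1 scale; display rounding is half-up to 0.1 (Sn/Sp)
and 0.01 (MCC). A zero marginal makes a metric undefined and it is
flagged (`-`/NaN) rather than coerced. The packaged fixture
`reference_benchmark_counts.tsv` freezes the 17 published rule/category
confusion counts (benchmark of 18 874 proteins: 1 870 mitochondrial vs
17 004 others; 5 724 secreted vs 13 150 others) together with their
printed metrics; the regression test recomputes every row. Where the
surrounding narrative and the printed table disagree (nucleus 0.72 vs
plasma membrane 0.78 MCC), recomputation from the counts supports the
table, which is therefore the reference.

Arbitrary predictor combinations can be scored through a small rule
language (`votes>=3 AND NOT tm AND NOT kdel`, `targetp=M AND wolf=mito`,
parentheses, `OR`, `NOT`).

## Motif scanning

The PROSITE compiler supports exactly the syntax subset needed for
KDEL-class patterns: literals, `[...]` classes, `{...}` exclusions, `x`,
and the `>` C-terminal anchor. Repetition counts and N-terminal anchors
raise an explicit unsupported-construct error — scope control, failing
loudly. The PS00014 pattern string ships in `data/prosite_patterns.yaml`
so a PROSITE revision is a data update. Anchored scanning tests only the
final k residues; a sequence shorter than the pattern is a miss, not an
error. Plain pattern matching is assumed (no profile scanning or
skip-flag post-processing).

## Synthetic data

The generator exists to make the cascade and the evaluation machinery
testable end-to-end without the licensed predictors. It plants a truth
category per protein (default mix ≈ the per-species averages across
animal proteomes: cytoplasm 31%, nucleus 30%, plasma membrane 12%,
secreted 8%, mitochondria 6%, small organellar classes and a 3.5%
unassignable remainder), builds a consistent random sequence (Met start,
KDEL-type C-terminus for ER-luminal truth, helices beyond residue 70 for
membrane truth, spurious C-terminal motif matches scrubbed), derives each
tool's ideal verdict from the truth, and passes it through an independent
per-tool error channel. Errors are injected at the *verdict* level —
false-negative/false-positive flips, label substitutions — not by
simulating sequence biology, because the unit under test is the cascade,
not the predictors. Sequence lengths default to 100–400 residues
(membrane truths ≥ 130 so a helix can sit beyond residue 70).

About 10% of proteins carry curated (reviewed) annotation instead, with
small fractions given hedged qualifiers, secondary locations, fragment
flags, non-Met starts or short sequences so every benchmark filter is
exercised; secondary locations always rank below the truth category in
the curated precedence list, so noiseless classification still recovers
the truth exactly. Output files use the exact dialects the predictor
parsers read and round-trip losslessly; identical seeds give
byte-identical files.

What passing these tests shows — and does not show: they verify that the
engine implements its stated rules exactly, that the evaluation machinery
is unbiased (measured accuracies track analytic expectations under known
error rates), and that all plumbing is lossless. They cannot certify
accuracy on real proteomes, where predictor errors are correlated with
sequence properties and with each other, curated annotation is
incomplete, and category frequencies vary by species.

## Numerical and scale choices

* Validation problem sizes: 5 000 proteins for noiseless end-to-end
  recovery, 20 000 for the planted-error checks (3-binomial-SD bands),
  10 000 random sequences for the motif oracle, and the full 10 368-case
  cross-product for the decision-table oracle — sizes chosen so sampling
  error is far below the effects being checked while the whole suite runs
  in seconds.
* The secretome-size vs proteome-size relation is an ordinary
  least-squares fit (with Pearson r) of secretome size on total entries;
  it requires ≥ 3 species and non-degenerate proteome-size variance, and
  exclusion of species with heavily redundant entry sets is a caller-
  supplied predicate rather than a hard-coded list, because reference-
  proteome sizes are dataset-dependent.
* Percentages use half-up decimal rounding throughout, matching the
  display convention of the reference tables.

## Known limitations

* Leaderless (non-classical) secretion is out of scope by design; only
  signal-peptide-routed secretion is modelled.
* Isoform-specific locations, UniProt XML/RDF dialects and GO terms are
  not parsed.
* The predictor parsers accept the batch short/summary formats only, as
  reconstructed from the tools' documentation; graphical or verbose
  outputs are rejected.
* Curated-vocabulary coverage is the shipped table
  (`data/curated_locations.yaml`); unrecognized terms are preserved as
  `UNMAPPED`, never dropped, and the table is user-replaceable.
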