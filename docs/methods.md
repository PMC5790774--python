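# Methods

## Expression calling

The caller reproduces EST-profile mining of gene×tissue transcripts-per-
million (TPM) tables. Three rules, applied per cell:

1. **Arbitrary units.** AU(g,t) = TPM(g,t)/TPM(ref,t) with ref = β-actin
   (ACTB) by default. A zero or absent reference TPM in any tissue is a hard
   error naming the tissues — no imputation; division by near-zero would
   silently inflate every AU in that tissue.
2. **Housekeeping limit.** upper = mean + 2·SD of the AU values of a fixed
   three-gene housekeeping panel. The SD is the sample SD (n−1): the limit
   is an estimate from a small sample, and the choice is configurable
   (`ddof`). Default scope is **pooled** — one scalar limit from all
   housekeeping AU values across tissues (3 genes × T tissues). The
   alternative `per_tissue` scope (one limit per tissue from that tissue's
   3 values) is implemented; pooled is the default because a single global
   reference limit is the only reading that yields one "upper limit" to
   compare every gene and tissue against, and per-tissue limits from n=3
   are extremely noisy.
3. **Trichotomy.** TPM < 1 → not expressed (−); else AU > upper → highly
   expressed (++); else expressed (+). Both inequalities are strict, so
   ties fall to the lower category (TPM exactly 1 is expressed; AU exactly
   at the limit is not "high"). The AU value itself — not a dispersion
   statistic — is what is compared to the limit; that is the only reading
   under which a per-cell ++/+/− matrix is even defined.

Missing cells must be pre-filled as TPM 0 and therefore call "−": in EST
data, absence of tags is indistinguishable from non-expression. The
housekeeping panels are fixed gene lists, never runtime-sampled, for
reproducibility. No multiple-testing correction is applied anywhere in the
caller — the procedure is a descriptive screen, not inference.

The housekeeping symbols are stored exactly as the source prints them
(PRS27A, GADPH — officially RPS27A, GAPDH); an alias map is packaged but
never applied silently (`src/thprof/data/CHANGELOG.md` has the full
transcription record, including one reconciled count discrepancy and one
row reconstructed from running text).

## Aggregation

Per (tissue, subset): n_regulators (measured catalog genes mapped to the
subset), n_expressed (+ or ++), n_high (++). Multi-subset genes count once
in each of their subsets. Only measured regulators enter denominators, so
adding an unmeasured catalog gene changes nothing.

- **Tissue pyramid**: tissues ranked by the number of subsets with ≥1 HIGH
  regulator; ties broken by subsets with ≥1 expressed regulator, then
  name — a deterministic total order.
- **Dominance**: score(S,t) = n_high(S,t)/n_regulators(S), size-normalised
  because subset panels range from 1 to ~20 genes (a raw-count option
  exists). The argmax set is reported; dominance has no published
  quantitative definition, so this is a declared convention.
- **Immune privilege**: a tissue is flagged when it has no HIGH call at all
  (min_high = 0) and under 60% of its regulator slots expressed. The 0.6
  fraction was calibrated once on the packaged human reference matrix,
  where it flags exactly the five tissues described as having no/very low
  resident Th activity; it is a documented convention, not ground truth.

## Differential regulation

Signed fold change: r = (mean_case+ε)/(mean_control+ε); reported as r when
r ≥ 1, else −1/r, so |sfc| ≥ 1 always and the sign carries direction.
ε defaults to 0; a zero mean (one or both groups) is then an error rather
than a fabricated fold change — ε = 0.5 is the documented rescue for
count-like data.

Significance uses a two-sided Welch (unequal-variance) t-test; the source
procedure never names its test, so Welch is a declared stand-in chosen for
robustness to unequal group variances at n≈5. Both groups flat and equal →
p = 1. Calls: UP iff sfc ≥ fc_min and p < α; DOWN symmetrically; otherwise
UNCHANGED. An sfc of exactly +1 (no change) is UNCHANGED even at
fc_min = 1. Defaults fc_min = 1.2, α = 0.05, no correction: sub-2-fold
changes of functionally related master genes are treated as meaningful when
raw p < 0.05, and the smallest magnitude in the packaged knockout tables is
1.22. Benjamini–Hochberg is available (`correction="bh"`) but off by
default. Printed signed-FC tables are pre-gated: blanks load as UNCHANGED
and are not re-tested (replicate-level data are not available). Replicate
matrices must declare their scale (`linear`/`log2`); log detection is never
automatic. For probe-level input, collapse to the probe with the highest
mean expression before calling `diff_table` (a deterministic convention;
the source is silent on this).

`DifferentialExpressionClassifier.fit` is vectorised; its per-gene results
are pinned to the scalar reference functions (`signed_fold_change`,
`test_two_groups`, `classify_regulation`) by a dedicated agreement test.

## Venn overlap

`set_overlap` assigns every item in the union of 2–8 named sets to exactly
one exclusive region (its membership pattern), so region counts always sum
to the union size. Items are trimmed, with opt-in case-folding, and the
normalisation map is reported. Region item order is sorted for determinism.

## Synthetic data

**Tissue panels** emulate EST sampling: per tissue, each gene's expected
tag count is its target TPM share of a 100,000-tag library; counts are
drawn negative-binomially (count CV c ⇒ NB size 1/c², the Poisson term
being negligible at the mean counts used) and converted to TPM against the
full library size (the assayed panel is a small slice of the library, the
remainder is unassayed mass). Defaults: 32 tissues; β-actin at 10,000 TPM
(1% of tags, the order observed for β-actin in EST libraries); three
housekeeping genes at AU 0.5 with 10% CV; 10 planted HIGH genes at 3× the
*expected* limit (the AU of a housekeeping gene is a ratio of two noisy
counts, so its CV is ≈ √2·c and the expected limit is
hk_mean_au·(1+2√2·c)); 12 planted absent genes (0 tags in every library —
true EST absence; a planted mean between 0 and 1 TPM would make the truth
ill-defined whenever a single tag is sampled, since 1 tag in 10⁵ is
already 10 TPM); the rest background genes at AU 0.1. The truth table
records each gene's role and expected call in every tissue.

**Case/control matrices**: per-gene baseline means are log-normal
(ln-mean 5, ln-SD 1); replicates are baseline × effect × unit-mean
log-normal noise with the configured CV. Defaults: 1000 genes, 5 replicates
per group, 20% of genes with 2-fold effects (half up, half down), CV 0.1.

What the simulator does **not** model: real tissue biology and co-expression
structure, probe effects, library-composition biases, batch effects, and
heavy-tailed biological variance. Recovery results on synthetic panels
therefore demonstrate correctness of the calling logic under its own
assumptions, not performance on real EST or microarray data.

All generators use a single `numpy.random.default_rng(seed)` stream; seeds
are explicit everywhere (no wall-clock defaults).

## Problem sizes used in the reproduction script and recovery suites

Chosen to give stable estimates while keeping a full run in seconds:
200 random tables (≤ 24 genes × 10 tissues) for caller/oracle agreement;
20 seeded panels (76 genes × 32 tissues) for planted-call recovery;
one 1000-gene null simulation for type-I error and 20 seeded 1000-gene
simulations for sensitivity/specificity at fc_min = 1.5; 100 randomized
2–5-set inputs over 50 items for the Venn partition property.

## Known limitations

- The packaged human call matrix is a transcription of a published symbol
  matrix covering 56 of the 61 catalog genes; five rows are not recoverable
  in machine-readable form (fixture changelog documents all edits).
- The co-signaling receptor panel is knowingly partial (8 of 28 receptors)
  and flagged as such.
- Pre-gated signed tables carry no p-values, so their calls cannot be
  re-examined at other thresholds.
- The AU scale is a pure ratio; any constant per-table scale factor in
  published "arbitrary unit" figures does not affect calls (they are
  scale-invariant away from the 1-TPM floor) but absolute AU values are not
  comparable across sources.
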