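# Methods

## The statistical model

The pipeline's core question is posed per protein: do this protein's
missense mutations concentrate in its ligand-binding pocket region beyond
what the cohort-wide background would predict? For protein *g*, let *a*
and *b* be its pocket and non-pocket missense occurrence counts, and *c*,
*d* the pooled pocket and non-pocket missense counts of every other
mapped protein. With margins fixed, *a* follows a hypergeometric
distribution under the null of no association; the one-sided
(greater) Fisher exact p-value is

&nbsp;&nbsp;P = Σ<sub>x ≥ a</sub> C(a+b, x) · C(c+d, n₁−x) / C(N, n₁),

with n₁ = a+c and N = a+b+c+d. The alternative is directional because the
scientific hypothesis is directional (pocket concentration, not mere
association); a `two-sided` option exists and the choice is recorded in
the output. The p-value is evaluated by exact enumeration over the
hypergeometric support with all mass terms computed through
log-factorials (`math.lgamma`), so cells of any magnitude neither
overflow nor lose the extreme tails (p-values down to ~1e-300 are
representable). The two-sided sum includes every table whose probability
is at most the observed one, with the conventional 1e-7 relative
tolerance for ties.

Benjamini–Hochberg adjustment is applied separately within each testing
family — the pan-cancer screen and each per-cancer-type screen — over
exactly the proteins with ≥ 1 pocket missense occurrence in that scope.
Significance means FDR < 0.1. BH delegates to
`statsmodels.stats.multitest.multipletests`; the test suite verifies it
against a direct implementation of the step-up formula
q₍ᵢ₎ = min<sub>j≥i</sub> (m·p₍ⱼ₎/j).

Decisions a reader should know about:

- **Counting unit.** Statistics count occurrences (one per sample
  carrying the variant), not unique variants: recurrence is the signal
  that makes hotspot drivers detectable. A
  `collapse_unique_variants` helper (CLI `--unique-variants`) supports
  catalog-style summaries on unique (accession, wt, position, alt)
  variants.
- **Deduplication.** A residue annotated in several pockets yields one
  mapped occurrence carrying all matching pocket ids, so pocket overlap
  never double-counts; mapping is invariant to duplicated pocket rows.
- **Background row.** The target protein is excluded from the background
  row, so the four cells are disjoint and the table is a valid 2×2.
- **Universe.** Mutations on proteins without pocket annotation are
  excluded entirely: they can contribute neither pocket counts nor
  comparable non-pocket counts at the structure level.
- **Odds ratio.** Reported as the sample cross-product ratio with a
  +0.5 Haldane correction when any cell is zero — descriptive only;
  inference is exact.
- **Aggregation level.** Counts are pooled per UniProt accession (one
  protein may be served by several structures); results are reported per
  accession joined to its gene symbol.
- **Ties.** Top-k rankings (genes, cancer types) break ties
  lexicographically for reproducibility.

## Pocket annotation

`PKT` blocks follow a documented dialect: a header
`PKT <pocket_index> <n_residues> <ligand_tag>` followed by exactly
`n_residues` lines `PKT  RES <res_name> <chain> <res_seq>[<icode>]` in
author (PDB) numbering. The declared count is enforced; any malformed
line rejects the whole file with its line number. Only the 20 standard
residues are accepted — modified residues (e.g. MSE) are a parse error,
never silently translated. SIFTS-style translation to 1-based UniProt
coordinates drops unmapped residues and residues whose identity
disagrees with the mapping, counting both in a report (real SIFTS
coverage is incomplete, so lossy translation is expected behaviour, and
|input| = |output| + unmapped + mismatched always holds). Chains mapping
to more than one accession (chimeric chains) are rejected as malformed:
the intended structure library is monomeric and single-domain.

## Downstream arms

- **CePIN.** Expression is quantile normalized (every tissue column is
  forced onto the mean-of-sorted-columns reference; tied values receive
  the mean of the reference values their ranks span — implemented
  directly since no installed package exposes this as a function), probes
  would be averaged per gene after normalization (synthetic data is
  generated at gene level). Pearson correlations are attached to the
  cleaned PPI edge list (upper-cased, canonically ordered, self-loops and
  duplicates removed). "Functionally similar" is strict: PCC > 0.5. The
  contrast — pocket pairs (≥ 1 endpoint with a pocket missense mutation)
  vs the rest, similar vs not — uses the same one-sided Fisher machinery;
  the direction follows the stated hypothesis.
- **Drug response.** IC50 is analysed on the natural-log scale,
  transformed at load (`--raw-ic50`). Stratification is a partition of
  the cell lines with pharmacology for the drug; in pocket-only mode,
  lines with only non-pocket mutations in the gene stay wild-type by
  default (an `exclude_nonpocket_mutants` option removes them). The
  Wilcoxon rank-sum test (scipy) uses the exact tie-free distribution up
  to combined n = 20 and the tie- and continuity-corrected normal
  approximation beyond; it is two-sided by default, with sensitivity /
  resistance reported descriptively from the group medians at α = 0.05.
  Groups smaller than 2 make a comparison untestable rather than an
  error.
- **Survival.** Median-split dichotomization assigns ties at the median
  to the low group (deterministic; the convention is stated in the
  output). An optional follow-up horizon (e.g. 2,000 days) converts
  later times to censored observations; truncation is idempotent and
  commutes with estimation. The product-limit estimator is computed
  directly (the curve object exposes event times, at-risk counts and
  S(t)); the Mantel-Cox log-rank test (hypergeometric variance, no
  continuity correction) delegates to lifelines and is verified against
  a hand-worked O−E / variance fixture.

## The synthetic universe

The generator emulates the statistical structure of the real inputs at
desk scale; all draws are deterministic under the configured seed
(per-component child streams), and every output file records the seed.

- **Structures**: 100 proteins of 40–250 i.i.d.-uniform residues, each
  with 1–3 pockets mixing a contiguous run with scattered residues.
  Total pocket content is drawn as 10–14% of chain length and split
  across the pockets. Parameterizing pocket content by chain fraction
  (rather than absolute size) keeps pocket fractions comparable across
  chains — realistic for single-domain ligand pockets, and it is what
  makes the pooled-background Fisher null approximately calibrated, so
  the all-null configuration behaves as a null. The SIFTS table covers
  each residue with probability 0.9 to exercise unmapped-residue
  handling.
- **Catalog**: 500 tumour samples over 10 weighted cancer-type labels;
  background occurrences land uniformly at 0.05 per residue over the
  cohort with class mix 70.9 / 20.6 / 5.1 / 3.4%
  (missense/silent/nonsense/indel); wild-types always match the
  sequence. One planted driver gene receives 30 extra missense
  occurrences whose pocket probability is 5 × its pocket fraction
  (capped at 1). The background rate is set so a gene's diffuse
  background load (~5 missense) stays small against the recurrent
  planted load, mirroring the real contrast where hotspot drivers
  dominate their own gene's background.
- **Co-expression**: 500 genes × 126 tissues. Every gene loads
  Uniform(−1, 1) on a shared tissue factor, giving the network a broad,
  sign-balanced PCC spectrum; sign balance keeps the factor out of the
  per-tissue location so the correlations survive quantile
  normalization. With a positive boost, pocket genes load at least
  √boost (default √0.8), so pocket-pocket pairs correlate at ≥ 0.8;
  with boost 0 pocket genes are distributionally identical to the rest
  and the contrast is exactly null.
- **Pharmacology**: 100 cell lines; 12% carry a pocket mutation in the
  sensitivity gene (the planted driver), 22% a non-pocket mutation, plus
  Poisson passenger load elsewhere. ln IC50 ~ Normal(3, 1) per drug,
  shifted by −1.5 for pocket-mutant lines only — so the pocket-only
  split detects what the all-mutations split dilutes.
- **Survival**: 200 patients, bimodal expression (Normal(2, 0.5) vs
  Normal(6, 0.5)) so the median split recovers the arms; exponential
  event times at 1/1500 per day, × 2.5 for the high arm; independent
  Uniform(0, 4000-day) censoring.
- **Paper fixture**: a fixed 2,262-occurrence catalog over 369 proteins
  (1,603 missense, 467 silent, 115 nonsense, 76 indel, 1 complex), every
  occurrence on an annotated pocket residue, for checking the summary
  arithmetic without simulation. The per-class counts as published sum
  to 3 more than the published total; the fixture trims the indel count
  so the catalog totals 2,262, the figure the published percentages and
  means are computed from.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: mutational signatures and
sequence-context effects (APOBEC-style), inter-gene correlation of
mutation rates, realistic PPI topology (degree distributions, modules),
probe-level microarray structure, cohort-level confounding in survival,
and dose-response measurement error. The operating characteristics
measured here (sensitivity, false-discovery proportion, detection rates)
certify the machinery, not field performance.

## Problem sizes and numerical choices

Test and acceptance runs use 100-protein / ~800-occurrence catalogs,
2,000-edge networks, 100 cell lines and 200 patients per replicate, with
60–200 seeded replicates per operating characteristic — sizes chosen so
the full suite replays in about a minute while keeping Monte-Carlo error
well inside the asserted margins. Exactness of the primitives is
checked against exact-rational enumeration oracles (all 2×2 tables with
total ≤ 30 plus 1,000 random tables with totals to 60; all tie-free
rank-sum splits with combined n ≤ 12) at 10 significant digits.

Degenerate inputs are handled explicitly: empty inputs yield empty
outputs (parsers, BH, summaries); an all-constant expression vector
drops the edge; a degenerate similarity margin returns p = 1 with a
warning; zero observed events make the log-rank test return
(0, 1) with a warning; an empty mutant group is an error because the
comparison is undefined.

## Known limitations

- Protein-level input only: no DNA-coordinate lifting or transcript
  consequence calling; the catalog must already carry UniProt positions.
- Single-chain structures; chimeric chains are rejected, not resolved.
- Indels are mapped by position only, flagged, and excluded from the
  missense statistics.
- No permutation or 3D-clustering statistics; the screen is counting-
  based by design.
- No Cox modelling or multivariate adjustment in the survival arm.
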