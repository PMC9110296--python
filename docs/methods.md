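# Methods

## The screen model

A pooled screen compares barcode abundances after competitive growth under a
treatment against a control grown in parallel in the same screening round.
Raw per-sample barcode counts are normalized to a fixed total of 10⁸
("normalized reads") so samples of different sequencing depth are
comparable. Replicate controls from one round are combined by averaging
their normalized reads per barcode (a barcode missing from one replicate
contributes zero to the mean, since absence after deep sequencing is an
observation, not missing data) while their raw counts are summed — the
downstream control-read floor therefore sees the pooled depth of the
averaged sample.

The per-mutant phenotype is Φ = treatment normalized / control normalized,
computed only where the (averaged) control has **raw** reads strictly above
50; below that the denominator is too noisy to interpret. A mutant present
in the control but absent from the treatment gets Φ = 0 — this is the
dropout signal, and "below the detection limit" is operationalized as a
treatment raw count of exactly zero (the only threshold that needs no
depth model; it is configurable).

## The exact 2×k allele test

For each gene in a screen, the phenotypes of its insertion alleles are
binned at powers of two: Φ < 0.0625, [0.0625, 0.125), [0.125, 0.25),
[0.25, 0.5), [0.5, 2), [2, 4), [4, 8), [8, 16), plus a ninth overflow bin
for Φ ≥ 16. The overflow bin is a deliberate choice: the bin ladder stops at
16 and silently discarding extremely enriched alleles would bias the test;
`BinScheme(overflow=False)` reproduces the strict eight-bin reading by
raising on such alleles. Alleles enter the test only if the insertion is
*disruptive* (5′UTR, CDS or intron — 3′UTR and unmapped insertions are not
expected to break the gene), mapped with confidence level ≤ 4, and measured
with > 50 control reads.

The gene's bin-count vector (row sum n) is compared against the bin counts
of **all** admissible insertions in the screen. We take "all insertions"
literally, so the background row contains the gene's own alleles; with a
realistic background of thousands of alleles the self-contamination is
negligible, and `exclude_self=True` subtracts the gene row for the other
reading. Conditional on both margins the gene row X follows a multivariate
hypergeometric law over the column totals c:

    P(X = x) = Π_j C(c_j, x_j) / C(N, n)

and the two-sided p-value is Σ P(x) over all feasible gene rows with
P(x) ≤ P(observed)·(1 + 10⁻¹²) — the Freeman–Halton probability-mass
ordering; the relative tolerance guards floating-point ties, and for k = 2
the statistic reduces exactly to the classical two-sided Fisher test.
Enumeration is depth-first over compositions of n bounded by the column
totals and is exact for n ≤ 30 (the default `mc_threshold`; at the 1–10
alleles per gene of real libraries it always enumerates). Larger rows fall
back to a Monte Carlo estimate: 10⁵ multivariate-hypergeometric null draws,
p̂ = (1 + #{draws at most as probable}) / (1 + n_draws), reported with a
binomial standard error on request. All Monte Carlo seeding flows from one
integer through `numpy.random.SeedSequence`, so results are reproducible
and per-gene streams are independent.

Benjamini–Hochberg FDR (step-up, via statsmodels) is applied to the p-values
of genes with **more than two** alleles — with one or two alleles a
convincing bin pattern cannot be distinguished from a second-site artifact,
so such genes receive a p-value but never an FDR and are never called
high-confidence. FDR is computed per screen by default (the screen is the
unit of discovery); `fdr_scope="global"` pools all screens instead. A gene's
representative phenotype is the median Φ of its tested alleles.

GO-term enrichment reuses the same machinery at the annotation level: a
term's row pools the binned phenotypes of all admissible insertions in genes
carrying the term, a gene annotated with several terms contributes its
alleles to each of them, and the background row is the sum of all term rows
(duplicates included). When a term's row equals the entire background
(single-term degenerate case) there is no contrast and p is defined as 1.
BH is applied over all terms within a screen. No GO-graph propagation is
performed; annotations are used as given.

## Barcode quantification

Reads are barcode + constant adapter + downstream sequence. The trimmer
searches for the adapter (GGCAAGCTAGAGA on 5′-side libraries, TAGCGCGGGGCGT
on 3′-side) at every offset, counting substitution mismatches per candidate
placement (N counts as a mismatch) and accepting placements with at most
⌊0.1 × aligned adapter length⌋ errors; partial adapter occurrences running
off the 3′ read end are accepted down to a 3-nt overlap. The earliest
acceptable placement wins, ties broken by fewer mismatches. Matching is
substitution-only by design: the barcode is the exact prefix before the
adapter and later counting collapses *identical* sequences only, so an
indel-tolerant match that shifts the trimmed boundary by one base would
split a mutant's reads across two barcode strings; at a 13-nt adapter and
10% error rate the tolerance is one substitution either way. The retained
prefix (the whole read when no adapter is found) must be 21–23 nt; shorter
or longer candidates are rejected with a reason. There is no quality
filtering or sequencing-error correction of barcodes.

One insertion can carry a 5′ barcode, a 3′ barcode or both; barcodes
sharing (gene, plate, well) are assumed to tag the same insertion and the
one with the highest summed raw count across the initial (pre-screen)
samples represents it, ties broken by lexicographically smallest barcode
for run-to-run determinism.

## The synthetic generator

`synthetic_screen` emulates the structure of the real library and screens:

- allele counts per gene ~ 1 + Poisson(mean − 1), default mean 3 (min 1);
- insertion features drawn at the library-wide frequencies (intron 25%,
  3′UTR 23%, CDS 19%, not mapped 14%, intergenic 6%, 5′UTR 5%,
  multiple/other 8%); intergenic/unmapped alleles carry no gene id;
- mapping confidence on 1–6 with mass 0.40/0.20/0.15/0.10/0.10/0.05 — the
  real distribution is not printed, so this was chosen once to put ~85% of
  insertions at the usable confidence ≤ 4 while exercising the filter;
- clonal inoculum abundances log-normal(0, σ = 1) — a realistic spread for
  a plate-pooled library, giving ~2 orders of magnitude between the 5th and
  95th percentile clone;
- growth is deterministic exponential in expectation: abundance multiplies
  by 2^(d(1+s)) over d pool doublings (default 7, the scale of the emulated
  screens). s = 0 is neutral; s = −1 freezes the clone at its inoculum
  abundance, so after 7 doublings its expected Φ is 2⁻⁷ ≈ 0.008, below the
  lowest bin boundary — dropout "below the detection limit" at realistic
  depth; s < −1 is rejected;
- sequencing is multinomial: R reads (default 10⁷) drawn from the final
  abundance distribution, independently per control replicate (default 2).
  An optional Dirichlet (gamma-weight) overdispersion parameter adds
  between-replicate biological noise for robustness checks; the default is
  pure multinomial, since plain read-ratio phenotypes assume no more.

What the generator deliberately does **not** model: PCR jackpotting,
barcode collisions and chimeras, batch effects between rounds,
growth-phase-dependent fitness, or mutants with multiple causal insertions
(alleles inherit a single gene's effect). Passing recovery tests therefore
demonstrates the statistical machinery under the stated sampling model, not
robustness to those real-data artifacts.

Design constants are derived, not asserted: inoculation at 2×10⁴ cells/ml
in a 2-liter vessel gives 4×10⁷ cells over 58,101 mutants ≈ 690 cells per
mutant (~700), and growth to 2×10⁶ cells/ml is log₂(100) ≈ 6.6 ≈ 7 pool
doublings.

## Clustering

Gene profiles are log₂ median phenotypes (Φ clipped into [2⁻⁷, 2⁷] so
dropouts stay finite; the floor sits below the lowest bin boundary),
median-centered per screen over non-missing entries (idempotent by
construction). Distances are Pearson correlation distance d = 1 − r over
pairwise-complete screens; a zero-variance profile gets d = 1 to everything
(r treated as 0, with a warning) because a flat profile carries no
co-variation signal and would otherwise propagate NaNs. GO × screen
enrichment matrices are clustered on −log₁₀(FDR) floored at 10⁻³⁰⁰, with
Euclidean distance.

Average linkage (UPGMA) is implemented in-package with the unweighted
Lance–Williams update and a deterministic tie-break — among equally close
cluster pairs, the pair whose smallest member leaves come first — so merge
sequences are bit-for-bit reproducible and independent of input row order
(scipy's linkage serves as an independent cross-check on tie-free inputs in
the tests). UPGMA merge heights are monotone non-decreasing, so no
dendrogram inversions occur.

## Compound similarity

Fingerprints are consumed as bit-index sets (extended-connectivity
fingerprints generated by external tooling; radius and length are the
producer's choice). Similarity is the Tanimoto coefficient |A∩B|/|A∪B|;
the network connects pairs at or above a user threshold (the emulated
analysis does not state one, so it is a required parameter), components are
labelled by their lexicographically smallest member, and per component the
most potent member(s) are selected with a lexicographic tie-break. The
curated cluster/compound selection of a real campaign mixes chemical
judgment with activity; the deterministic rule here is not claimed to
reproduce any particular curated list.

## Problem sizes and numerical choices

- Exact-test enumeration tolerance for probability ties: relative 10⁻¹²;
  test-suite agreement with an exact rational-arithmetic oracle: 10⁻⁹.
- Simulation studies run at 200 genes (~600 alleles), 10⁷ reads per sample,
  2 control replicates — 10 seeds for null calibration, 20 for hit recovery
  (10 arrested genes per screen); each seed takes well under a second, and
  the exact test enumerates throughout (allele counts ≤ ~10).
- BH input validation rejects p ∉ (0, 1]; p = 0 cannot arise from a
  discrete exact test and indicates an upstream bug.
- Degenerate inputs: empty gene rows, k < 2, negative cells, empty
  fingerprints, all-zero count tables and mixed-round control averaging all
  raise; all-missing profile columns and zero-variance profiles warn and
  continue.
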