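# Methods

## Data model

A genotype matrix is samples × allele columns, columns grouped into SSR
loci, cells in {0, 1, 9}. Two invariants reflect how polyploid SSR gels
are scored: missingness is **locus-level** (a lane fails as a whole, so
a 9 in any allele cell of a locus forces the entire sample-locus to
missing), and a sample can show at most `ploidy` distinct alleles at a
locus. Validation reports violations per sample and locus; readers
refuse invalid files.

Panel merging unions allele columns per locus, matching alleles by
exact (locus name, size label). A sample from a panel that never scored
a given allele column receives **0** (absent) there when its locus was
scored: presence/absence scoring registers every detected band, so an
unreported size is an absence, not missing data. Loci present in only
one panel are kept (all-missing for the other panel) by default; a
`drop` policy is available. An optional ±1 bp binning tolerance was
considered and rejected for the default path: reference SSR databases
use fixed calibrated bins, so silent re-binning would hide real
mismatches.

## Allele frequencies under dosage ambiguity

Binary scoring hides dosage: a hexaploid showing {A, B} may be any of
5A+1B … 1A+5B. The **uniform-split** estimator credits `ploidy/k`
copies to each of the k observed alleles; it is simple and widely used
but systematically underestimates common alleles (their true dosage is
usually above the split value) and overestimates rare ones.

The **EM estimator** treats the dosage genotype as latent. The genotype
prior under polysomic inheritance with partial selfing rate `s` is the
two-component mixture

    P(g | p, s) = (1 - F) · Multinomial(g; ploidy, p)
                + F · [g monomorphic for allele a] · p_a,

with the equilibrium inbreeding coefficient `F = s/(2-s)`. This is the
simplest exchangeable model with the right limits — plain multinomial
at `s = 0`, all copies identical with probability 1 as `s → 1` — and
the synthetic-data generator draws from exactly the same model, so
parameter recovery is a well-posed check of the estimator rather than a
model-mismatch experiment. A published polysomic genotype prior could
be substituted without touching the EM scaffolding.

The E step enumerates every dosage genotype compatible with an observed
presence set (compositions of `ploidy` copies over the observed
alleles, each ≥ 1 — at most C(5, k−1) ≤ 10 genotypes for a hexaploid,
plus the inbred branch for singleton sets). The M step normalises
expected *founder-draw* counts: an outbred genotype contributes its
copy counts, the inbred branch contributes a single draw of its allele.
Counting the collapsed branch once (rather than `ploidy` times) is what
makes the update the exact EM M-step for the mixture, so the
observed-data log-likelihood is non-decreasing every iteration — a
property the test suite asserts on the recorded trace. Initialisation
is the uniform-split estimate; convergence is declared when the L∞
change in `p` drops below `tol` (default 1e-8, iteration cap 500).
Alleles never observed at a locus keep frequency 0, which is their MLE.
Loci missing in every sample are flagged undefined, never silently
zero. Missing sample-loci are excluded, not imputed. The selfing rate
is an input (default 0.07, the panel's published estimate), not
estimated here: identity-disequilibrium estimation of `s` is a separate
problem outside this package's scope.

## Diversity statistics

`H_uncorrected = 1 - Σ p_i²`, `H_corrected = n/(n-1) · H_uncorrected`,
`PIC = 1 - Σ p_i² - Σ_{i<j} 2 p_i² p_j²`. The correction's `n` is the
total number of observed allele presences at the locus (summed over
non-missing samples): with dosage hidden, distinct bands are the
countable sampling units. No single alternative (samples, or
ploidy × samples) reproduces the published percent-change column across
all loci, so percent changes are reported but not treated as a
reference quantity. Aggregate rows are unweighted means over loci.
The correlation analysis pairs each locus's overall mean allele number
per individual with its corrected Nei diversity and with its
EM-corrected PIC.

## Discrimination and panel selection

The confusion probability is computed in count form,
`C = Σ c_i(c_i - 1) / (N(N-1))`, which equals the published
frequency form `Σ p_i(N p_i - 1)/(N-1)` exactly and is verified in
tests against brute-force enumeration of all unordered pairs.
`D = 1 - C`; `DL = 1 - Σ p_i²`; the identity `D = N·DL/(N-1)` holds to
machine precision and is also used to recover `D` from published `DL`
values.

Combined profiles over a locus subset key each sample on the tuple of
its per-locus patterns. A missing locus contributes a sentinel symbol
rather than excluding the sample, keeping `N` constant across subsets
so cumulative `D` values are comparable along the greedy curve. (A
consequence: on data with missing calls, the single-locus combined
profile differs from the per-locus profile, which excludes missing
samples — both behaviours are intentional.) Greedy selection starts
from the best single locus and adds, at each step, the remaining locus
with the highest combined `D`, ties broken by input order for
determinism. Both cumulative series are non-decreasing because adding
a locus only refines the pattern partition. Greedy selection is a
heuristic; optimal subset search is out of scope (the test suite uses
exhaustive search only as an oracle on three loci).

## Clustering and duplicates

Jaccard dissimilarity treats every allele column as an independent
dominant marker; each pair is restricted to columns of loci scored in
both samples, and a pair with no co-scored locus is flagged undefined
and excluded from duplicate calling. Trees use unweighted Saitou–Nei
neighbor joining (scikit-bio's implementation). Negative NJ branch
lengths are retained by default and can be clamped to zero on request.

Bootstrap support resamples **loci** (not individual allele columns)
with replacement, preserving the within-locus dependence between the
columns of one marker; support for each internal bipartition of the
reference tree is the percentage of replicates containing it, written
into the Newick output as internal labels. Replicates whose resampled
loci leave some pair with no co-scored locus are skipped (they cannot
produce a tree), which can only deflate support, never inflate it.

Duplicates are pairs with `d` strictly below the threshold (default
0.05, the dissimilarity level below which previously confirmed genebank
duplicates fall); groups are connected components of the flagged-pair
graph (single linkage). Every flagged pair can be verified locus by
locus, listing the discordant allele labels — the computational
analogue of manually re-reading the gel lanes of a candidate pair.
The ROC sweeps thresholds over the observed dissimilarities, with
same-clone pairs as positives; AUC is the trapezoid integral, and a
labelling with no negative pairs yields NaN specificity/AUC rather
than a fabricated value.

## Synthetic data generator

The generator emulates the structure of a clonal hexaploid SSR study:
19 loci with 3–12 alleles (frequencies from a symmetric Dirichlet,
concentration 1.0), 20 founders with selfing rate 0.07, 2–4 clonal
copies per founder, dosage collapsed to presence/absence, then noise:
dropout 0.01 per present cell, false allele 0.005 per absent cell,
whole-locus failure 0.02. With these defaults the per-locus mean number
of alleles per individual spans ≈2.4–4.3 (average ≈3.4), matching the
range reported for the real 19-locus sweetpotato panel; the noise rates
are generator choices at levels typical of careful manual gel scoring,
as no error-rate estimates are published for such panels. A scored
locus is never left bandless (one original allele is re-instated if
dropout empties it, since a bandless lane would have been scored as
failed) and false alleles never push a lane past the ploidy cap. All
randomness flows from one seeded generator in a fixed order, so
datasets are byte-reproducible.

What it does **not** model: stutter or size-shift artefacts, linkage
between loci, population structure among founders, or mutation within
clone lineages. Passing tests on this generator therefore demonstrate
correctness of the estimators and the detection machinery under the
stated model, not robustness to every artefact of real gel data.

A quantitative consequence worth knowing: with ~66 present bands per
sample, a within-clone pair accumulates on average ≈2.2 discordant
band columns at the default noise rates, i.e. an expected within-clone
Jaccard distance ≈0.033 — close to the 0.05 duplicate threshold. A
strict 0.05 cut-off therefore recovers roughly 80–90% of true clone
pairs under this noise model (precision stays at 1.0 and ROC AUC at
1.0, since between-founder distances are far larger). Real duplicate
curation compensates by inspecting the NJ tree and verifying profiles
per locus; raising the threshold or lowering the assumed error rates
shifts the recall/precision balance accordingly.

## Numerical choices

- Frequency vectors are validated to sum to 1 within 1e-6 on input and
  1e-12 where the package produces them.
- EM: `tol` 1e-8 (L∞ on `p`), `max_iter` 500, monotonicity asserted
  with 1e-9 slack for floating-point accumulation.
- Greedy and duplicate-grouping tie-breaks are deterministic (input
  order; sorted group members).
- Pipeline outputs are written only after all stages succeed, so a
  failed run leaves no partial output directory.

## Problem sizes

Default test and pipeline runs use ~20 founders (~60 samples) × 19
loci, bootstrap replicate counts of 5–50 in tests (1000 by default in
the CLI, matching standard practice), 500 samples for EM recovery
checks, and 1000 random profiles/triples for the enumeration oracles.
These sizes give stable statistics while keeping the full suite fast.
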