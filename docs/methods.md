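# Methods

## The analysis problem

A pooled CRISPR-Cas9 knockout screen under a cytotoxic selection reads out,
for every single-guide RNA (sgRNA) in a genome-wide library, how the
abundance of cells carrying that guide changes between an untreated control
and drug-treated survivor populations. Knockouts that blunt the
death pathway (here: p53-mediated apoptosis triggered by an MDM2
antagonist) enrich; knockouts of generally essential genes deplete. The
package turns a guide × sample table of integer read counts into
gene-level scores, significance calls and hit lists.

The experimental design the package models has 7 samples: one untreated
control harvested before selection, and two timepoints for each of three
drug concentrations. Each timepoint is treated as one replicate whose
members are the three concentration samples; the single control sample is
shared by both replicates.

## Normalization

Between-sample scale is removed in two steps: library size (total reads)
and trimmed-mean-of-M-values (TMM) factors that correct composition bias —
under strong selection a few enriched guides consume a large share of a
sample's reads and would otherwise make every unselected guide look
depleted. The implementation follows the published TMM algorithm exactly:
per-guide log-ratios (M) and average log-abundances (A) against a
reference sample over guides positive in both members, two-sided rank
trimming at 30% (M) and 5% (A), inverse delta-method-variance weighting of
the retained M values, and the upper-quartile rule for automatic reference
selection (lexicographic tie-break so reruns are bit-stable). Factors are
rescaled to geometric mean 1. The implementation agrees with the
reference R implementation (edgeR `calcNormFactors`) to 1e-12 on test
matrices; this is exercised in the test suite through `Rscript`.

Two idealized invariants one might expect — exact factor invariance under
scaling one sample's counts, and exact invariance of normalized
log-abundance under doubling depth — hold only approximately (to ~0.3%
and ~prior/count respectively), because the precision weights are not
scale-free and the pseudo-count is additive. The tests assert the
near-invariance at the tolerance the algorithm actually has.

## Per-sgRNA model

Within one replicate, every guide's counts follow a negative-binomial (NB)
log-linear model with per-sample offsets log(library_size × TMM factor)
and a two-group mean structure (treated vs control). The reported effect
is the log2 ratio of treated to control mean abundance; significance is a
likelihood-ratio test against a shared-mean null, referred to chi-square
with 1 df. p-values are clipped at 1e-300 so −log transforms stay finite.

Numerics. For a single group coefficient with fixed offsets the NB score
function is strictly decreasing in the coefficient, so the MLE is the
unique root; it is found by bracketing and bisection, which is
deterministic, derivative-free and robust at extreme counts (including a
single-sample control group, where the fitted mean equals the observed
count). Each group's fitted total expected count is floored at 0.125
reads: a guide absent from the control but present after selection gets a
large, finite, deterministic log fold change instead of an infinity, with
no pseudo-count added to the likelihood. Guides with zero counts across
every member sample of a replicate carry no information and are dropped
from that replicate (logged).

Dispersion. The NB dispersion φ (variance = μ + φμ²) is estimated per
replicate. The common φ maximizes the Cox–Reid adjusted profile
likelihood (APL) summed over guides; each guide's tagwise φ_g maximizes
its own APL plus (prior_df / residual df) times the across-guide mean APL,
i.e. empirical-Bayes shrinkage toward the common value. The default
prior_df = 10 is deliberately strong: with one control and three treated
samples there are only 2 residual degrees of freedom per guide, and a raw
per-guide maximizer is biased low (measured on simulated data: raw-based
shrinkage gave mean tagwise 0.041 against a truth of 0.05, while the
weighted-APL scheme gives 0.0496, matching the reference implementation
to three decimals and keeping null LRT p-values uniform within
Kolmogorov distance 0.016 at 10,000 guides).

Modelling choice left open by the design: the three concentrations are
treated as one group rather than as a dose covariate — the minimal
reading of a two-group comparison, and the only one that yields a single
per-guide fold change per replicate.

## Gene-level score and significance

The CRISPR score (CS) of a gene is the median of the log2 fold changes of
all its guides pooled across both replicates (even-length medians are
midpoints). Genes contributing fewer than `min_guides = 3` pooled values
are filtered out and excluded from the multiple-testing family.

Significance is a two-sided two-sample Kolmogorov–Smirnov test of the
gene's pooled guide values against the pooled values of every other
guide. The exact conditional null (over label assignments) is used when
the gene contributes at most 10 values, the asymptotic Kolmogorov
distribution beyond. Benjamini–Hochberg adjustment runs over the genes
passing the guide filter. Hit classes: `strong_enriched` (FDR < 0.05 and
CS > 1.5), `enriched` (FDR < 0.05, 0 < CS ≤ 1.5), `depleted_significant`
(FDR < 0.05, CS ≤ 0), `not_significant`, `filtered`. Ranks order
FDR-significant genes by CS (ties: smaller p, then gene symbol). The CS
threshold 1.5 is kept on the log2 scale as published; on the fold-change
scale it corresponds to log2(1.5) ≈ 0.58.

Known limitation — pooled-replicate dependence. The two pooled values a
guide contributes (one per replicate) are positively correlated (~0.7 in
simulation): both compare against the same single control sample, and the
second timepoint's population is grown out of the first's. The KS test
treats all pooled values as independent draws, so its gene-level p-values
are anti-conservative: on all-neutral simulated screens the p-value ECDF
deviates from uniform by Kolmogorov distance ≈ 0.15, entirely
attributable to this dependence (with independent values the same
pipeline is calibrated to 0.02). The FDR+CS double gate absorbs this in
practice — measured strong-enrichment false positives on 2,000-gene
all-neutral screens are 0 per screen over 10 seeds — but the p-values
themselves should be read as rankings rather than calibrated error rates.
This is a property of the pooled-median design itself, not of a
particular noise setting: it persists when bottleneck drift is removed
entirely.

## Rank comparison and enrichment

Two scored screens (e.g. drug-selected vs untreated essentialome) are
outer-joined on gene symbol; ranks exist only for FDR-significant genes
and are never imputed, and the rank shift is reported where both exist.
Over-representation of the strong hit list in user-supplied GMT gene-set
collections uses the upper-tail hypergeometric p-value P(X ≥ k) with the
tested population (genes passing the guide filter) as universe, BH
adjustment across sets, and skips sets with fewer than 3 members inside
the universe.

## Synthetic screens

The simulator emulates the selection design at desk scale: 2,000 genes ×
10 guides (the real library is ~18k × ~10), baseline guide abundances
log-normal (σ = 1), one control sample read out before selection, and for
each concentration two selection rounds per timepoint with the second
timepoint continuing from the first's population. A selection round
draws cells per guide multinomially at the population size (default 2×10⁶,
~100 cells per guide), kills each cell independently — survival
probability min(1, survival_fraction × fitness) — and renormalizes.
The per-round survivor fraction of unprotected cells maps linearly from
30% at 14 µM to 15% at 18 µM, matching the observed 70–85% kill band with
dose monotone. Gene classes: resistant (default 2.5%, fitness multiplier
U(2.5, 5.5), one apex gene at 8 standing in for TP53), essential (10%,
fitness 0.4), neutral. Guide efficiency is Beta(9, 1) — most guides carry
the full gene effect, a minority are partially or fully inert, which
stresses the median aggregation. Sequencing is NB with φ_seq = 0.05 at
5×10⁶ reads per sample. All randomness flows from one mandatory seed.

What the simulator does not model: editing kinetics, cell-cycle structure,
ploidy (the modelled system is haploid precisely so one knockout event
suffices), guide off-target effects, PCR jackpotting beyond the NB noise,
and dose–response shapes beyond linear kill scaling. Passing recovery
tests therefore demonstrate that the statistics recover multiplicative
fitness effects through bottlenecked, overdispersed counts — not that
every biological artifact of a real screen is handled.

## Problem sizes and determinism

Default test and acceptance problem sizes are 2,000 genes × 10 guides per
screen (about 15–20 s per full pipeline run), with 10 seeds for null
calibration; unit tests use 40–200 gene screens. Every stage is a pure
function of its inputs plus the seed: two runs from the same manifest are
byte-identical, which the test suite asserts at file level.
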