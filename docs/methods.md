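# Methods

This note records the models, estimators, numerical conventions and
design choices behind the package, in enough detail to judge what a
passing test suite does and does not establish.

## The generative model

Gene trees are simulated under the multispecies coalescent (MSC) on a
rooted ultrametric species tree with branch lengths in coalescent units
(time / 2N per branch). Hybridization is modeled as instantaneous
admixture pulses: a hybrid edge (donor branch, recipient branch, time
τ_m, proportion γ) makes every gene lineage present in the recipient
branch at τ_m independently reroute into the donor branch with
probability γ; a bidirectional edge carries a second proportion for the
reverse move, with both moves decided from the same pre-pulse snapshot
so no lineage moves twice at one instant. Within every branch,
co-resident lineage pairs coalesce at rate 1 per pair. This pulse
formulation matches the γ interpretation of every downstream estimator;
continuous migration is deliberately out of scope.

Sequences evolve by Jukes–Cantor along the simulated gene trees, with a
single rate parameter (substitutions per site per coalescent unit,
default 0.01) converting coalescent lengths to expected substitutions.
There is no rate heterogeneity, no indels, no sequencing error and no
within-locus recombination — so the simulator exercises the statistical
logic of the tests (topology frequencies, site patterns, divergence
strata) but not their robustness to alignment error, GC bias, or
model misspecification. Passing tests on synthetic data therefore
demonstrate correctness of the estimators under their own assumptions,
not performance on real sequence data.

Randomness is keyed per locus by (seed, locus index), so any prefix of
loci reproduces bit-identically regardless of the total locus count.

### The study-scale preset

The preset emulates a young radiation: 54 ingroup tips on a fixed
random pure-birth (Yule) topology rescaled to root age 5 coalescent
units (many short internal branches, hence pervasive ILS), one outgroup
attached at 12 coalescent units (deep enough that rooting is safe and
outgroup alleles are effectively ancestral), 756 loci of 1951 bp, and
three planted hybrid edges with γ = 0.45 (tip→tip), 0.10 (tip→tip) and
0.22 (tip into the stem branch of a cherry, i.e. an ancestral
recipient). Edge placements are chosen by deterministic structural
rules; for the ancestral edge the pulse is placed early in the
recipient stem's span and the donor is a member of a sister pair with
deep divergence, because the triplet-γ expectation for the detecting
test is γ(1 − e^(−t′)) with t′ the time the introgressed lineage spends
co-resident with the donor lineage *alone* — the donor's own sister
divergence caps that window. The preset is bit-stable: the same tree,
edges and times on every call.

## Rooted-triplet machinery

Triplet topologies are read off MRCA-depth comparisons on gene trees
rooted at the outgroup: within a triplet, the pair whose MRCA is
strictly deepest is sister; ties (polytomies after support collapsing)
are UNRESOLVED. This is pruning-invariant, so no explicit pruning is
done. Unresolved loci are excluded from the binomial denominator —
the conservative choice, since assigning them at random would dilute
real signal and fabricating resolution would invent it. Edges without a
support annotation are never collapsed (absence of evidence is not low
support).

The test is an exact two-sided binomial (scipy's `binomtest`), not a
normal approximation: after Holm correction at α = 0.001, decisions can
hinge on small minor counts where the approximation is poorest. The
Holm family is all tests of one scan invocation. Degenerate tests
(minor₁ = minor₂ = 0 → p = 1) stay in the family.

γ̂ = (minor₂ − minor₁)/(major + minor₁ + minor₂) is reported
non-negative with the implicated partner recorded separately. Its
expectation under a pulse, γ(1 − e^(−t′)), is exact in the pulse-MSC
model by conditioning on whether a locus introgressed: non-introgressed
loci contribute symmetrically to both minors; introgressed loci yield
the excess minor exactly when the rerouted lineage coalesces with the
donor lineage within the co-residency window t′ (afterwards the pool
contains a second triplet taxon and contributions are symmetric again).

### Event collapse

Significant tests link the implicated pair member with P3. Links are
grouped into maximal (clade × clade) blocks of the species tree in
which *every* cross pair is significantly linked; blocks are accepted
largest-first, must not partially overlap an accepted block, and a
clade-level side needs ≥2 linked descendant tips — singleton leftovers
become tip–tip events. The event γ is the f-branch-style summary:
median over one side's tips of the minimum γ̂ across the other side's
tips (the larger clade is the summary's "recipient" side; deterministic
tie-break). Events are flagged, not deleted, when they match the bridge
pattern (A–B and B–C strong, A–C present but weaker): deciding whether
a weak A–C event is an indirect signal is judgment, not arithmetic.

## D-statistics

One haploid sequence per taxon: pattern counts are integer tallies and
sites where the outgroup carries a globally minor allele still polarize
by the outgroup state. Sites with gaps or ambiguity in any of the four
selected taxa are excluded before the biallelic filter (exactly two
distinct alleles among the four). Thinning is greedy left-to-right on
concatenated 0-based coordinates with 500 bp minimum spacing; it is
idempotent and applied before pattern counting, so the jackknife blocks
(contiguous runs of thinned SNPs, sizes differing by ≤1) are blocks of
the same table the totals come from. The jackknife variance is
((n−1)/n) Σ_j (D_−j − mean)² over n = 40 blocks; Z = D/SE with a
two-sided normal p. SE = 0 with D ≠ 0 yields a signed infinite Z and
p = 0 rather than an error. The scan's hot path is a numba kernel that
fuses validity, biallelic classification and thinning into one pass per
trio; its equivalence to the step-by-step operations is asserted in the
tests.

The f₄-ratio is intentionally not implemented: with 0/1 "frequencies"
it degenerates, and the f-branch step uses RT-derived γ̂ instead —
signed per trio (+γ̂ if the test implicates the branch-side taxon, −γ̂
if the control-side taxon, 0 for non-significant tests, NA for untested
trios). Scoring non-significant tests 0 rather than NA keeps the
f-branch medians grounded (NA-skipping would bias cells upward toward
whatever happened to be significant); both imputations are exposed.
Because RT tests only cover sister pairs, deeper f-branch rows are
sparser — cells with no scored trio are NA with a reason code.

## DIP: direction from divergence strata

For triplet (P1,P2)+P3 with flow established between P3 and P2, loci
are stratified by gene-tree class (C concordant, D23, D13) and the
per-locus p-distances d12, d13, d23 are contrasted:

* `delta12 = mean_D23[d12] − mean_C[d12]` (uncorrected, 1×) — positive
  even under pure ILS, since discordant loci coalesce deeper; kept as
  the documented-bias baseline.
* `delta12_corr = mean_D23[d12] − mean_D13[d12]` and the auxiliary
  `delta13_corr = mean_D23[d13] − mean_D13[d23]` — zero-mean under ILS
  by the exchangeability of the two discordant strata under P1↔P2, and
  exactly antisymmetric under that relabeling.
* `delta_gap = mean_D23[d12 − d23] − mean_D13[d12 − d13]` — the
  within-stratum gap between the deep join and the recent sister-pair
  coalescence; also exactly zero-mean under ILS.
* `delta_shallow` — the D23-vs-D13 contrast of the fraction of loci
  whose d12 falls below the concordant-stratum median.

Working out the pulse model shows the two directions separate jointly,
not by the sign of any single contrast. Flow P3→P2 leaves the D13
stratum *exactly* at its ILS distribution (neither P1 nor P3 lineages
are rerouted) while introgressed D23 loci pair a recent P2/P3
coalescence with a deep P1 join: `delta_gap` goes strongly positive,
`delta12_corr` only mildly negative (introgressed loci skip the
three-lineage waiting time, they do not deepen d12). Flow P2→P3 funnels
introgressed P3 lineages through P2's ancestral populations, creating
genuinely shallow-d12 discordant loci — below the concordant median,
which is impossible under ILS or P3→P2 up to mutational noise — so
`delta_shallow` goes strongly positive. `polarize` calls P3→P2 on a
significant positive `delta_gap`, P2→P3 on a significant positive
`delta_shallow` (falling back to a significantly negative
`delta12_corr`), resolves double-fires by bootstrap z-magnitude, and
returns "none" otherwise (rendered as a bidirectional arrow in event
tables). Significance is a locus bootstrap (default 1000 resamples;
two-sided p = doubled opposite-sign fraction, floored at 1/n_reps),
with one set of resamples driving all statistics.

These contrasts are this package's operationalization of
divergence-based polarization; they are validated by direction recovery
on simulations with known flow (≥80% per direction at γ = 0.3, 2000
loci in the acceptance suite), not by numeric agreement with any other
implementation. The 2× idea — comparing both candidate recipient
framings by magnitude — survives in the double-fire rule.

## Pipeline conventions

* All scan outputs are TSVs written with a fixed float format; given
  identical inputs, config and seed, every analytic output is
  byte-identical across reruns (the manifest embeds the output
  directory path and is identical up to that path).
* Trios in the D-scan are arranged so the species-tree sister pair
  occupies (P1, P2) — polytomies tie-break lexicographically — and
  flipped after counting so D ≥ 0, making P2 the taxon sharing excess
  derived alleles with P3.
* The cross-method table marks an event Yes/Partial/No by whether all,
  some or none of its defined f-branch cells exceed 0.04 — a declared
  convention for "more than weak gene flow", not an estimated
  threshold. DIP directions are attached per event as the consensus
  over its tip pairs.
* Multiple samples per species are handled by an optional two-column
  taxon map; species-level scans use the lexicographically first sample
  per species, deterministically.
* Per-stage failures are logged and recorded in the manifest; partial
  outputs are preserved.

## Problem sizes used in the tests

Unit tests run on 3–10-taxon trees with hundreds of loci. The
acceptance suite uses: 50,000 loci for the γ̂ closed-form check
(Monte-Carlo SE ≈ 0.0013); 50 seeds × 1000 loci on 10 ingroup taxa for
RT null calibration and 10 of those seeds for D-statistic calibration
at the study locus length of 1951 bp (shorter loci starve trios of
informative sites and visibly fatten the jackknife-Z tails beyond the
nominal normal rate); 20 replicates per direction at γ = 0.3 and 2000
loci for DIP; and one full preset run (54+1 taxa, 756 × 1951 bp, three
planted edges) through the whole pipeline for event recovery.
Full-pipeline byte-identity is asserted at 10-taxon scale and the
RT stage plus simulator determinism additionally at preset scale.

## Known limitations

* The simulator's JC69/no-recombination assumptions are idealized; see
  above for what that implies about test coverage.
* RT tests only interrogate sister pairs, so donors are typically
  localized to a clade, not a tip; the f-branch step sharpens but
  cannot always resolve this, and γ̂ summaries for clade-level events
  are diluted relative to the per-test maximum.
* DIP direction calls assume a single unidirectional pulse per pair;
  genuinely bidirectional flow of similar magnitude lands in
  "bidirectional/unresolved".
* VCF ingestion, f₄/f_d-style window statistics, site concordance
  factors and phylogenetic-network optimization are out of scope;
  externally inferred event tables can be joined to the concordance
  output by the caller.
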