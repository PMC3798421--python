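# Methods

## Study design and scope

The package analyses multilocus nuclear sequence data from two pairs of
sibling-species populations — one sympatric pair and one allopatric pair —
to separate shared ancestral polymorphism from post-split gene flow. The
bundled reference design mirrors the *Lutzomyia longipalpis* complex survey:
21 loci of 89–664 aligned bp, 10–42 sequences per population per locus,
populations Sobral 1S / Sobral 2S (sympatric) and Lapinha / Pancas
(allopatric). All coordinates are 0-based half-open internally and 1-based
in emitted reports.

## Site filtering

All statistics run on a single per-locus column universe: complete deletion
removes every column containing a gap or an ambiguous base in any sequence.
This matches the preprocessing used for non-recombining-block extraction and
avoids mixing site universes between statistics. Pairwise deletion is not
offered; where a column retains missing data (filtering policy `none`),
per-column sample sizes are used and the behaviour is pairwise-deletion-like
for that column only.

## Polymorphism and neutrality statistics

π (per site) is the mean pairwise difference over all C(n,2) sequence pairs
divided by the kept length; θ_W = S/(a₁L) with a₁ = Σ_{i<n} 1/i. Tajima's
*D* uses the standard 1989 constants; it is undefined (reported as a dash)
when S = 0. Fu's *F*s is computed from the Ewens sampling distribution of
the haplotype count: S′ = P(K ≥ k_obs | θ̂ = π_total) with unsigned Stirling
numbers of the first kind held as exact integers and the tail sum done in
rational arithmetic for n ≤ 64 (a float path serves bulk simulation; the two
agree to 1e-9 relative). When S′ is exactly 0 or 1 the log-odds is clamped
at ±700 and flagged. *R*² follows the singleton-load definition
√(Σᵢ(Uᵢ − π/2)²/n)/S.

Significance for *D*, *F*s and *R*² comes from the standard neutral
coalescent conditional on (n, S): genealogies are simulated (Kingman
topology and exponential waiting times), S mutations are placed multinomially
proportional to branch length, and the statistics recomputed; *D* is tested
two-sided, *F*s and *R*² on the lower tail. Report layers apply Bonferroni
across loci. Default 10,000 replicates; pipeline default 1,000 (configurable).

## Differentiation

FST is Hudson's 1 − H_w/H_b on mean pairwise difference counts, H_w the
average of the two within-population means. Negative estimates are reported
as computed (flooring would bias the normalized-difference statistic), and
FST is NaN when there is no variation at all. Significance uses label
permutations preserving sample sizes with the add-one estimator
p = (1 + #{F* ≥ F})/(B + 1), B = 1000 by default. Site classes: a kept
column is *fixed* when both populations are monomorphic for different
residues, *shared* when at least two residues segregate in both, otherwise
*exclusive* to the polymorphic population. A column polymorphic in both
populations with fewer than two common residues cannot occur under infinite
sites; it is assigned to the exclusive class of the population with more
distinct residues (ties to population 1) so the four classes always
partition the non-monomorphic-identical columns.

## Multilocus HKA

The two-population three-cell variant: per locus i,
E[S1ᵢ] = θᵢa(n1ᵢ), E[S2ᵢ] = f θᵢ a(n2ᵢ), E[Dᵢ] = θᵢ(T + (1+f)/2), where Dᵢ
is the mean between-population pairwise difference on the count scale (the
(1+f)/2 term absorbs within-species coalescence). Variances add the squared
coalescent-scale part: Var[S] = E[S] + θ²a₂(n), Var[D] = E[D] + (θ(1+f)/2)².
θᵢ is solved exactly from the per-locus totals given (T, f); the two
aggregate moment equations are solved by `scipy.optimize.root` (hybr,
residual tolerance 1e-8 relative to the data scale). χ² sums the 3L cells
and is referred to χ² with df = 2L − 2 (40 for 21 loci). Loci with
S1 = S2 = D = 0 are excluded with a warning.

## Comparison layer

The mean-FST contrast is a pooled-variance two-sample t with sign convention
t = (mean_symp − mean_allo)/SE. The differential-introgression statistic
ranks dᵢ = (alloᵢ − sympᵢ)/alloᵢ against the chosen FST vector and takes
Pearson's correlation of the average ranks (Spearman; ties get average
ranks). Direction is a parameter: the sympatric direction is the headline
statistic; the allopatric direction's published sign convention is not
recoverable from the definition, so no particular value is asserted for it.
The population tree is Saitou–Nei neighbor joining (scikit-bio) on the
entrywise mean across loci of all six pairwise FSTs, with negative means
floored at zero (flagged) for tree building only; support values bootstrap
the loci (not sequences), 100 replicates by default.

## Non-recombining blocks

Biallelic, gap-free kept columns are testable; a pair of testable sites with
all four haplotypic combinations is a four-gamete violation. The extractor
searches contiguous windows delimited by testable sites crossed with
sequence-removal sets, maximizing sites × sequences^w (w = `seq_weight`,
default 1). Because a violation can only be resolved by emptying one of its
four gamete classes, the minimum removal set is found by branch-and-bound
over classes — exact up to a 200k-node cap, beyond which a greedy cover
takes over. Ties keep the earlier window and drop lexicographically later
ids. A floor of 4 retained sequences is enforced; if no feasible block
exists the whole alignment is returned flagged degenerate. Note that adding
sequences can legitimately move the optimum to a different window: the
score, not the block width, is monotone under adding duplicates. Multi-allelic
or gapped columns are never tested but remain inside the emitted block. A
block interval computed on one pair can be forced onto another dataset
(`apply_block`) to keep loci comparable across pairs.

## Isolation-with-migration model

Parameters are in mutational units: θ = 4Nμ per locus, t = t_years·μ_year,
and m = m_gen/μ is the backward rate at which lineages sampled in a
population trace their ancestry to the other. On this time scale a pair of
lineages coalesces at rate 2/θ within its population, each lineage migrates
at rate m, and mutations fall at rate 1 per unit branch length, giving the
calibrations E[π] = θ (n = 2) and E[S] = θa_n used as simulator tests, and
the migrant-number identity 2Nm = θm/2. Ancestry comes from msprime (haploid
samples, population sizes θ/2, population split at t); infinite-sites
mutations are placed directly on the single genealogy (Poisson with mean the
total branch length, multinomial across branches) and mapped to distinct
uniformly chosen alignment columns, so simulated loci are ordinary
alignments. Zero-valued sizes and split times are floored at 1e-6 (msprime
rejects exact zeros); this is negligible against O(1) parameter scales.

### Summary statistics

Per locus: π₁, π₂, FST, the four site-class counts, D_xy, and four
directional statistics — π₂−π₁, Sx2−Sx1, and the mean nearest-neighbour
cross-population Hamming distances min12/min21 (for each sequence of one
population, the distance to its closest counterpart in the other, averaged;
per site) plus their contrast. Asymmetric introgression into population 2
pulls π₂ toward the donor's diversity, inflates Sx2, and collapses min12
(every donor haplotype has a near-copy among the migrants). Dataset-level
vectors stack means and across-locus variances; NaN FSTs (invariant loci)
are excluded from the moments.

### Estimation

Rejection ABC over the six-parameter model replaces the original
genealogy-sampling MCMC: parameters are drawn from uniform boxes (defaults
θ ≤ 10, t ≤ 5, m ≤ 25, mirroring the reference analysis' run settings), the
full multilocus design is simulated per draw, and the accepted fraction
(default 2%) closest in SD-normalised Euclidean distance is returned.
A second pass, `abc_migration_estimate`, fixes the demography (e.g. at the
stage-1 posterior mean) and re-estimates (m₁, m₂) alone — mirroring the
reference analysis' separate migration-rate runs — and
`per_locus_migration_profile` does the same locus by locus, flagging flat
posteriors (accepted spread ≈ prior spread) at weakly informative loci.
An optional local-linear regression adjustment (Beaumont-style) is
implemented but disabled by default: with a few hundred accepted draws and
13–26 summary dimensions it overfits and degrades calibration.

### What direction inference can and cannot do

Two caveats, both measured with this package's own simulators. First, if the
fixed demography in a migration-only pass misses the true θ₁ > θ₂ contrast,
the observed π₁ > π₂ is misattributed to migration *into* population 1 — a
systematic direction error; migration passes should therefore propagate
demography uncertainty or use well-estimated θs. Second, direction
information at the reference parameter values (≈7-fold 2Nm asymmetry but
small absolute rates) is intrinsically weak in small designs: a two-model
classifier given the true demography and the true per-locus rate multipliers
identifies the direction in only ~60% of 5-locus studies, rising to ~80% at
the full 21-locus design. Direction claims from few-locus datasets should
not be trusted regardless of estimator.

### Unit conversion

N = θ·g/(4μ) individuals, t_years = t/μ, and 2Nm = θm/2 per direction, with
g = 10 generations per year and μ the geometric mean per-locus per-year
mutation rate (default 1.77e-6; alternatively derived from per-locus lengths
and synonymous-site fractions at 1.56e-8 and 1.91e-9 per site per year).
The conversions are exactly invertible; reproduced effective sizes and split
years agree with the reference values to ~0.5% (their printed μ is rounded).

## Synthetic studies

Each locus gets two independent IM simulations sharing length and reference
sequence: the sympatric pair uses the reference point estimates with
per-locus migration multipliers — zero with probability 0.3 ("barrier"
loci), otherwise Exponential(mean 1) — times an optional extra direction
bias; the allopatric pair uses the low reference rates unmodified. Sample
sizes are drawn uniformly from 10–42 per population per locus unless pinned.
The multiplier mixture expresses the study system's differential
introgression (selection filtering gene flow locus by locus); the barrier
fraction and multiplier scale are package defaults chosen to produce both
near-zero-flow and freely introgressing loci in a typical draw. Ground truth
(all parameters, realized multipliers, migration-event counts) is serialized
beside every dataset. Limits: the two pairs are simulated independently (no
four-population joint genealogy), sequences carry no codon structure or
indels, and within-locus recombination is absent by construction — so tests
passing on synthetic data say nothing about recombination handling or
alignment quality on real data.

## Numerical and reproducibility notes

Every stochastic operation takes an explicit seed; per-locus streams derive
from the study seed, and seeded reruns are byte-identical. Permutation
p-values use the add-one estimator (never exactly zero). The infinite-sites
mapper retries a locus on the rare mutation-count overflow (bounded, then
errors). Test problem sizes: simulator calibration 10,000 replicates; ABC
recovery 10 studies × 5 loci × 2,000 simulations; HKA null calibration 40
datasets of 6 loci — sized so the full suite runs in minutes on one CPU.
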