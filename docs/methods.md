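# Methods

This note documents the models, parameter choices and limitations behind
`coconserve`, in the order the pipeline runs.

## Synthetic data: what it emulates and what it does not

The generators produce the statistical structure the analysis consumes,
not biological realism.

**Families.** A master sequence is drawn i.i.d. from the background
(uniform over the 20 amino acids). Each member evolves site-wise: a
Poisson(d) number of substitutions per site, each replacing the residue
uniformly among the other 19 (no rate matrix, no site-rate variation).
The divergence parameter d is the expected number of substitutions per
site; the expected identity to the master is
`1/20 + (19/20)·exp(−(20/19)·d)`, ≈ `exp(−d)` for moderate d (81.9% at
d = 0.2). Indels occur per site with total probability `indel_rate`
(half deletions, half insertions of 1–3 background residues). The true
column-tracked alignment is retained, so profile building never depends
on a heuristic aligner. Defaults: master length 200, 12 members,
d = 0.2, indel rate 0.01.

**Proteomes.** One family member (never the master) is planted per
present gene per genome; decoys are within-sequence shuffles of randomly
chosen real members, so they preserve amino-acid composition exactly
while destroying positional homology — no decoy is homologous to a
profile by construction. Headers follow `genomeID|speciesID|label`.
Default: 20 decoys per genome, one genome per species.

**Species sets.** Categories are drawn i.i.d. from a configurable
frequency map. The default `OBSERVED_CATEGORY_FREQS` encodes the observed
distribution the analysis targets: 55% of species carry an NQ pathway
(classical or futalosine variant, chosen 50/50), 65.4% of those also
carry NDH-2, and 0.9% of all species pair NDH-2 with UQ; the remainder
are UQ + NDH-1. The 55% NQ share is a choice (only the two headline
fractions are externally constrained); it fixes the remaining degree of
freedom at a value typical of menaquinone prevalence among bacteria.
Species are i.i.d. — there is no phylogenetic correlation, which real
genome collections emphatically have. Passing tests therefore show the
machinery is correct under the planted model, not that the biological
inference is robust to phylogenetic structure.

**Growth curves.** Exponential `OD(t) = OD0·e^{μ(t−lag)}` or logistic
with carrying capacity K, multiplied by mean-one lognormal noise with a
stated coefficient of variation. `noise_cv=0` returns the exact model.

All generators take a single integer seed and keep no global state;
identical seeds give byte-identical output.

## Clustering

Identity between two sequences is the number of identical aligned pairs
in one optimal global alignment, divided by the length of the shorter
sequence (the CD-HIT convention — appropriate for de-redundification,
where a short fragment of a long sequence should count as redundant).
Alignment: BLOSUM62, gap open 11, extend 1 (BLAST-style affine costs);
among co-optimal alignments the aligner's deterministic first traceback
is used, so clustering is reproducible for a fixed input. Greedy
assignment runs longest-first (ties by id), joining the first
representative at or above the threshold (default 0.50). Consequences:
the result is a partition; representatives are pairwise below the
threshold; members are above the threshold to their representative. Note
that two sequences with no identical aligned pair have identity 0 and
never co-cluster, whatever the threshold.

## Profile HMMs

Architecture: match states 1..L, insert states I₀..I_L, delete states
D₁..D_L, with all nine M/I/D transition types (the full Krogh/Durbin
profile architecture; permitting I↔D keeps estimation closed under any
observed alignment path). Traversal is glocal: every path runs
begin → column 1..L → end, with flanks absorbed by I₀ and I_L. Local
alignment mode is out of scope.

**Estimation.** Columns with gap fraction strictly below 0.5 (default)
become match states. Match emissions are residue counts plus a
background-proportional pseudocount (default total weight 1.0); insert
emissions equal the background; transition distributions are counted
from each sequence's implied state path with the pseudocount mass split
uniformly over the allowed targets. The null model is uniform over the
20 amino acids by default — consistent with the synthetic generator;
swap in empirical frequencies via `background=` for real proteomes.

**Scoring.** The bit score is the forward log-odds
`log2 P(x|HMM)/P(x|null)` with the null an i.i.d. model of the same
length. Because insert emissions equal the background, inserts score
zero and the bit score measures match-state evidence. The forward kernel
runs in scaled linear space (odds ratios with per-row renormalisation)
for speed; Viterbi runs in log space and also returns the argmax path.
`X` residues score as background (log-odds 0). Both algorithms agree
with brute-force path enumeration to better than 1e-9 relative on all
tested tiny instances.

**E-value calibration.** Forward bit scores of `n_random` background
sequences (lengths uniform within ±20% of L by default) are fitted with
a Gumbel law; `E(S) = db_size · P_gumbel(score ≥ S)`, with `db_size`
defaulting to the number of sequences in the scanned proteome. The fit
is a censored maximum likelihood on the upper tail (default: top 25% of
scores exact, the rest contributing only `P(S < threshold)`), initialised
by the method of moments. The censoring matters: the body of the
forward-score null is lighter-skewed than a Gumbel (skewness ≈ 0.3
versus 1.14), and a full-sample fit systematically overestimates tail
probabilities — measured fractions of fresh null sequences with
`E ≤ x·db_size` came out at 0.0015/0.016/0.062 for x = 0.01/0.05/0.1.
With tail fitting the same check lands on x within binomial error.
`tail_fraction=1.0` restores the plain MLE.

## Search and filtering

Every sequence is scored against every profile; no cross-gene
competition (a sequence satisfying two profiles is logged and kept for
both). Both filters are inclusive: E-value ≤ the gene's cutoff and bit
score ≥ 100 ("minimum" read as inclusive, so a 100.0-bit hit passes and
99.5 does not). The per-gene default cutoff is a conservative 1e-10;
a thresholds table (YAML or two-column TSV) overrides per gene. At most
one hit — the best by bit score — is retained per (genome, gene).
Genome→species collapse is `any` by default (`majority` and `all`
available); how the original genome set was resolved into species is not
derivable from the data this package sees, so the rule is configuration,
not an assertion.

## Pathway calling and co-occurrence

A pathway variant is present when all of its representative genes are
present (`presence_rule="all"`; `at_least_k` exposed for sensitivity
analysis — the markers are joint evidence, and requiring all three
guards against single spurious hits). NQ = classical OR futalosine.
Species fall into one quinone category (NQ-only / UQ-only / both /
neither) and one dehydrogenase category (NDH1-only / NDH2-only / both /
neither); the 4×4 table counts each species once.

`frac_nq_with_ndh2` = |NQ ∧ NDH2| / |NQ|, the numerator counting NDH-2
exclusively or together with NDH-1. `frac_ndh2_with_uq` defaults to
|UQ ∧ NDH2| / (all species); because the natural denominator of that
statistic is ambiguous, the NDH-2-species and UQ-species denominators
are always computed alongside. Species with neither quinone pathway nor
either dehydrogenase are retained by default (a drop flag exists).
`recompute_from_sheet` accepts a wide per-genome presence sheet or a
long hit table with raw scores (then filtered), and `sensitivity_sweep`
reports the statistics under every presence/collapse/denominator
combination so a reported value can be attributed to a configuration.

## Growth kinetics

μ_max is the maximum least-squares slope of `ln(OD − blank)` over
contiguous windows of `window_points` readings (default 5); windows with
non-positive blanked readings are skipped. Two caveats are inherent to
the estimator and documented rather than hidden. First, the window must
match the expected exponential-phase span: on a record that is
exponential throughout, short windows turn μ_max into a maximum over
many noisy slope estimates and bias it upward (at 5% noise and 5-min
sampling, a 5-point window overestimates a 0.6 h⁻¹ rate by ~70%, while
a window covering ~80% of the record recovers it within 1%). Second,
the estimator is scale-invariant but not blank-robust; the blank is a
parameter, not estimated.

CCD: divisions per passage are net new cells `N_f − N_0` (each division
adds one cell under binary fission); CCD is the running sum. When inputs
are ODs, cells = OD × volume × 8×10⁸ cells·OD⁻¹·mL⁻¹ (the conversion is
a configurable constant, and only used in OD mode).

The fitness trajectory is fitted by isotonic regression (projection of
the fitness values onto the nearest non-decreasing sequence) followed by
PCHIP interpolation through the projected knots. PCHIP through
non-decreasing knots is non-decreasing and C¹, so the result is a
smooth, monotone piecewise cubic; monotone inputs are interpolated
exactly. A `smooth` mode first passes the data through a cubic
smoothing spline before projection, for noisy trajectories. This
construction was chosen as the simplest one satisfying smooth +
monotone + cubic simultaneously; a penalised monotone spline would also
qualify.

## Docking energy accounting

`ΔH = E_complex − (E_protein + E_DNA)` in whatever unit the input table
carries (the module is unit-agnostic). More negative ΔH is read as more
favourable binding; `ΔΔH = ΔH(mutant) − ΔH(WT)` per DNA box, with
|ΔΔH| ≤ tolerance called "unchanged". ΔΔH is antisymmetric under
swapping the variant labels and invariant under adding a constant to all
three energies of both variants. Producing the energies (docking,
structure modelling) is out of scope; the module consumes a CSV.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: tiny-profile
oracle checks at L ≤ 3 and sequence length ≤ 4 (exhaustive enumeration
is exact there); the end-to-end recovery at 500 species × 13 genes with
20 decoys per genome; calibration consistency at 2,000 calibration plus
2,000 fresh null sequences; the sheet recomputation at 7,783 species.
Tolerances: 1e-9 relative for scoring against enumeration; 3 binomial
standard deviations for all frequency-recovery checks; 1e-6 h⁻¹ for
noise-free growth-rate recovery. Emission/transition rows must sum to 1
within 1e-9. Degenerate inputs fail loudly: empty sequence sets, zero
usable growth readings, zero-variance calibration scores, alignments
with no match column, and unpaired docking records all raise with a
description of what was missing.

## Known limitations

- No phylogenetic correction anywhere: species are treated as
  independent draws, in the generator and in the tabulation.
- Glocal-only alignment; fragmented or multi-domain proteins would be
  scored poorly against a full-length profile.
- The Gumbel tail fit is honest in the calibrated region (E-values down
  to ~1/n_random · db_size) but extrapolates beyond it.
- The clustering is quadratic in the number of sequences per family;
  it is meant for seed sets, not whole databases.
- Growth-rate estimation assumes the exponential phase is sampled and
  the window sized accordingly; no lag/capacity model is fitted.
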