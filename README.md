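# coconserve

Cross-species co-conservation analysis of respiratory quinone biosynthesis
pathways and NADH dehydrogenase types in bacteria, plus the supporting
computations used alongside it: adaptive-laboratory-evolution (ALE) growth
kinetics and protein–DNA docking energy accounting.

## The scientific question

Bacterial respiratory chains pair an NADH:quinone oxidoreductase with a
quinone pool. The low-potential naphthoquinones (NQ: menaquinone and
relatives) appear to be the preferred partners of the non-proton-pumping
type-II NADH dehydrogenase (NDH-2, gene *ndh*), while the high-potential
ubiquinone (UQ) is the canonical partner of the proton-pumping type-I
complex (NDH-1, *nuo* operon). One line of evidence is comparative
genomics: across thousands of bacterial species, the presence of an NQ
biosynthesis pathway co-occurs with NDH-2 far more often than UQ does.

`coconserve` implements that analysis as a tested, reusable pipeline:

1. **Marker panel.** Thirteen representative genes indicate five
   pathway/complex variants — classical NQ biosynthesis (*menB, menC,
   menF*), the futalosine NQ route (*mqnA, mqnC, mqnD*), UQ biosynthesis
   (*ubiA, ubiC, ubiG*), NDH-1 (*nuoA, nuoE, nuoJ*) and NDH-2 (*ndh*).
2. **Seed de-redundification.** Greedy clustering at 50% identity
   (identity = identical aligned pairs / shorter length, from one optimal
   global alignment under BLOSUM62 with affine gaps).
3. **Profile HMMs.** Position-specific probabilistic models built from
   the clustered alignments (match/insert/delete states, glocal
   traversal). A sequence's **bit score** is the log₂ odds of the sequence
   under the profile versus an i.i.d. background null,
   `S = log2 P(x|HMM) / P(x|null)`, computed with the forward algorithm.
4. **E-values.** An extreme-value (Gumbel) law fitted to forward scores
   of random background sequences gives `E(S) = N · P_gumbel(score ≥ S)`
   for a database of `N` sequences.
5. **Filtering.** A hit is retained iff its E-value is at or below the
   gene-specific cutoff **and** its bit score is ≥ 100.
6. **Calling and tabulation.** A pathway variant is present in a genome
   when all of its representative genes are found (configurable);
   genome-level presence collapses to species level (any/majority/all);
   species are cross-tabulated by quinone category × dehydrogenase
   category, yielding the headline fractions
   `P(NDH-2 | NQ pathway)` and `P(NDH-2 ∧ UQ)`.

A first-class synthetic-data module generates every input with planted
ground truth — divergent protein families for the 13 markers, proteomes of
planted orthologs plus shuffled-sequence decoys, species sets with
controlled category frequencies, and noisy growth curves — so the entire
pipeline is testable without downloads.

The ancillary modules cover the defined computations around the ALE
experiment: the maximum specific growth rate as the steepest rolling
log-linear slope of ln OD₆₀₀, cumulative cell divisions (CCD) as the
running sum of net new cells per passage, a smooth monotone cubic spline
of fitness versus CCD, and the docking enthalpy proxy
`ΔH = E_complex − (E_protein + E_DNA)` with wild-type/mutant comparison.

## Worked example

```python
import coconserve as cc
from coconserve.synthetic import OBSERVED_CATEGORY_FREQS

families = cc.generate_marker_families(seed=7, master_length=150, n_members=10)
profiles = cc.build_marker_profiles(families, n_random=500, seed=7)
species = cc.generate_species_set(
    200, category_freqs=OBSERVED_CATEGORY_FREQS, seed=7, families=families, n_decoys=20
)
hits, presence, table = cc.run_cooccurrence_pipeline(species, profiles)
print(f"species analysed:        {table.n_species}")
print(f"retained hits:           {len(hits)}")
print(f"presence accuracy:       {cc.presence_accuracy(presence, species.truth):.3f}")
print(f"NQ species with NDH-2:   {100 * table.frac_nq_with_ndh2:.1f}%")
print(f"NDH-2 coexisting w/ UQ:  {100 * table.frac_ndh2_with_uq:.1f}%")
print(table.counts)
```

prints

```
species analysed:        200
retained hits:           1060
presence accuracy:       1.000
NQ species with NDH-2:   63.3%
NDH-2 coexisting w/ UQ:  0.5%
         NDH1-only  NDH2-only  both  neither
NQ-only         40         69     0        0
UQ-only         90          1     0        0
both             0          0     0        0
neither          0          0     0        0
```

Reading the output: 200 species were generated with planted categories
drawn from `OBSERVED_CATEGORY_FREQS` (65.4% of NQ species carry NDH-2; 0.9% of all
species pair NDH-2 with UQ). Every planted ortholog was recovered and no
shuffled decoy passed the ≥ 100-bit filter (accuracy 1.000); the recovered
fractions (63.3%, 0.5%) sit within binomial sampling error of the planted
values at this sample size. The 4×4 table counts each species exactly
once by (quinone category × dehydrogenase category).

Everything is also reachable from a thin CLI (`coconserve --help`):
`simulate families|species-set|growth`, `cluster`, `build-hmm`,
`calibrate`, `search`, `cooccur`, `growth rate|ccd|trajectory`, `deltah`.

## Layout

```
src/coconserve/
  synthetic.py      generators with planted ground truth
  seqcluster.py     sequence I/O + greedy identity clustering
  profilehmm.py     profile HMM build / forward / Viterbi / calibration
  search.py         panel search and hit filtering
  cooccurrence.py   pathway calling, co-occurrence tables, sheet recompute
  growth.py         growth rates, CCD, monotone fitness spline
  energetics.py     ΔH accounting and variant comparison
  pipeline.py       end-to-end wiring
  cli.py            thin command-line layer
docs/methods.md     model assumptions, parameter choices, limitations
```
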