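# Methods

`regblock` identifies promoter regions that are recurrently mutated across
the patients of a cancer cohort and asks which transcription factors (TFs)
gain or lose binding affinity because of those mutations. It proceeds in
two steps: block discovery, then biophysical scoring with a
background-resampling significance test.

## Step 1 — recurrent mutation blocks

Somatic SNVs (one VCF per patient, SNVs only; indels are skipped at parse
time) are restricted to promoter windows, defined symmetrically as TSS
± 1000 bp for every transcript of every annotated gene. The pooled
promoter SNVs are clustered per chromosome by single linkage: two
mutations — from the same or different patients — belong to the same
*mutation block* when their distance is smaller than `max_gap` (default
30 bp; the merge is applied recurrently, which a single sorted sweep
realizes exactly, and the strict `< 30` boundary means positions 100 and
129 merge but 100 and 130 do not). Blocks must contain at least two SNVs
from at least two distinct patients; the rest are discarded.

Each surviving block is assigned to every gene whose promoter window
contains at least one member SNV (a block inside two overlapping promoters
is duplicated, once per gene). Finally, a differential-expression gate: the
assigned gene's tumor RPKM values are compared with the normal samples by a
two-sample Kolmogorov–Smirnov test, and the block is kept iff p < 0.05.
The KS statistic is the sup of |ECDF difference|; the p-value uses the
Kolmogorov limiting distribution with the standard small-sample
effective-n correction `(sqrt(en) + 0.12 + 0.11/sqrt(en)) · D`,
`en = n·m/(n+m)`. At this study's sample sizes (12 tumor vs 4 normal) the
gate's measured null keep rate is ~5% (see `regblock.calibration`).

The pipeline applies cluster → recurrence filter → promoter assignment →
KS gate, in that order.

For every patient carrying ≥1 SNV in a kept block, a *patient-specific
alternative sequence* is built: the reference sequence spanning the block
plus a 30-bp flank on each side (so that motif windows can straddle the
block edges), with **all** of that patient's block SNVs substituted at
once. Nearby mutations from one patient are thereby scored jointly. A
parallel per-SNV mode scores 61-bp windows centered on each variant
(`regblock rank-snv`); block-level analysis is the default because single
SNV windows ignore cooperative effects of nearby mutations.

## Step 2 — binding affinity change and significance

**Occupancy model.** A probability PWM is converted to a mismatch energy
matrix, `E[i][b] = ln(max_b' p[i][b']) − ln(p[i][b])`, so the consensus
base has energy 0 at every position (dimensionless, in ln-probability
units). A site at window `w` is bound with Fermi–Dirac probability
`P = 1/(1 + exp(β(E(w) − μ)))`, with inverse temperature β = 1 and
chemical potential μ playing the role of (unknown) nuclear TF
concentration. The sequence-level binding score is the log total occupancy
over every window on both strands,

    dbA(s) = ln Σ_w P_w ,

a soft-max-like aggregation chosen so that multiple nearby sites
contribute — required for blocks carrying several sites. Windows
containing non-ACGT characters are skipped, not imputed. Because μ is
unknown, dbA is evaluated on the grid μ ∈ {−2, 0, 2, 4} and the
*differential binding affinity* of a mutation is the grid mean

    δdbA = mean_μ [ dbA(alt) − dbA(ref) ] ,

positive when the patient sequence gains binding, negative when a site is
disrupted, and exactly 0 for identical sequences (δdbA is antisymmetric in
its arguments and invariant to reverse complementation of the input).

**Normalization.** Raw δdbA magnitudes are not comparable between PWMs of
different length and information content. Per TF, δdbA values are z-scored
against the pooled distribution of that TF's δdbA over all patient units
of the run *plus* the first replicate's background blocks (below). Pooling
the backgrounds anchors the mean near zero, so a recurrent effect shared
by every patient keeps its sign and magnitude after normalization; the
per-TF scale estimate is what makes magnitudes comparable across TFs. (A
z-score over patient units alone would subtract away exactly the shared,
recurrent component the pipeline is looking for whenever most units are
carriers, as in small cohorts.) The rank-based significance test below
operates on raw δdbA and is unaffected by this choice.

**Direct-binding filter.** A TF with no plausible site on the reference
block cannot meaningfully lose or gain one. The expected p-value of direct
binding is estimated empirically: the reference sequence is shuffled
preserving dinucleotide counts (Altschul–Erickson Eulerian-path shuffling,
which preserves CpG composition), and
`p = (1 + #{shuffled dbA ≥ observed}) / (1 + n)` with n = 100 shuffles by
default. Generation may stop early once ⌈0.2·n⌉ shuffles have beaten the
observed score — p is then already guaranteed > 0.1, the ranking cutoff —
which never changes the filter decision (`--exact` disables early
stopping).

**Ranking.** For each patient unit, TFs with p_direct < 0.1 are kept,
those whose |normalized δdbA| falls below the 80th percentile of the
surviving set are dropped, and the rest are split by sign and ranked by
magnitude, reporting the top 15 in each direction (ties broken by PWM id).

**Background model and test.** Each (TF, block) candidate — any PWM ranked
for at least one patient unit of the block — is tested against randomly
generated background mutation blocks: intervals of the same sequence
length drawn uniformly from the 1000-bp-upstream window of random
annotated genes (never the gene carrying the tested block), carrying the
same number of mutations as a typical patient (the rounded mean per-patient
SNV count of the block), each mutation substituting a uniformly chosen
different base. When more backgrounds are requested than eligible regions
exist (only possible in miniature simulated cohorts) regions are re-drawn
with replacement; placement and mutations still differ per draw. The
default background count is one per eligible upstream region; the test
profile uses 500.

Patient δdbA values are compared with background δdbA by a two-sided
Wilcoxon rank-sum test. The implementation enumerates the exact rank-sum
null distribution (dynamic program over rank subsets) whenever the data
are untied and n_patient·n_background ≤ 10,000 — which covers every test
the pipeline actually runs, at ~10 ms per test — and otherwise falls back
to the normal approximation with tie and continuity corrections. The
approximation tracks the exact p to within ~0.02 for n_patient ≥ 3
(~0.03 at n_patient = 2, where the rank-sum lattice itself is that
coarse). The test direction is the sign of median(patient) −
median(background). P-values are Bonferroni-corrected with m = the number
of PWM hypotheses scored for the block (after the expression filter): each
PWM is a separate hypothesis, since one TF may have several alternative
PWMs. The whole test is repeated three times with freshly sampled
backgrounds; a TF is reported significant only when all three replicates
reach Bonferroni p < 0.05, and the reported p is the replicate median.
Per-patient *tail probabilities* — the chance that random background
mutations affect the TF as strongly as that patient's mutations,
`(1 + #{bg as extreme}) / (1 + n_bg)` in the test's direction — accompany
every record.

Measured on null worlds (patient blocks themselves drawn from the
background generator), the stage's type-I error at α = 0.05 is 0.04–0.05
over 600 (TF, block) pairs.

## Annotation

**Expression filter.** A TF whose gene has median tumor RPKM < 0.03 (the
conventional threshold separating lowly expressed genes from experimental
noise) is removed from rankings and significance outputs. TF names are
matched to expression rows case-insensitively with a user-extensible alias
table; heterodimers ("AHR::ARNT") use the minimum of the components'
medians; unmatched TFs are filtered with a warning. Surviving TFs get a
quartile category over their medians: "+" top 25%, "−" bottom 25%, "•"
otherwise.

**SHM hotspot test.** Germinal-center B-cell lymphomas accumulate
aberrant somatic hypermutation at AID hotspot motifs DGYW/WRCH (reverse
complements of one another; IUPAC D = A/G/T, Y = C/T, W = A/T, R = A/G,
H = A/C/T). For each block, the fraction p₀ of reference-block positions
covered by a hotspot occurrence on either strand defines the null rate,
and the number of block mutations falling inside hotspot positions is
tested with an exact two-sided binomial test (two-sided p = sum of outcome
probabilities no larger than that of the observed count). This
self-contained null — hotspot coverage of the block's own reference
sequence — is a design choice; p₀ is exposed for alternative nulls.

## Synthetic cohorts

The generator writes a complete miniature study in the exact formats the
readers consume: a 200-kb uniform-random chromosome carrying 50 genes
(alternating strands, promoters disjoint), 12 patients, tumor expression
for the patients plus 4 normal samples, a PWM file with 1 planted + 50
decoy motifs, and a truth table. Two driver genes carry a planted block:
three copies of a high-information 10-bp motif (consensus probability
0.85; a unique worst base per position) embedded 20 bp apart inside the
promoter. Each patient independently carries block mutations with
probability 0.7; a carrier disrupts two of the three occurrences, each at
a uniformly chosen motif position, replacing the consensus base with that
position's worst base — so δdbA for the planted PWM is strongly negative
for every carrier while the mutated positions differ between patients, as
in real cohorts. Background SNVs arrive genome-wide at 5×10⁻⁶ per bp per
patient (sparse, like real promoter SNV counts; singletons are removed by
the recurrence filter anyway).

Expression values are log-normal (σ = 0.5) around per-gene means; driver
genes are scaled 6-fold in tumor samples, reproducing the near-complete
tumor/normal separation (KS p ≈ 0.001–0.01 at 12 vs 4 samples) that
strongly dysregulated lymphoma driver genes show. Five decoy TFs are
generated below the 0.03 RPKM floor to exercise the expression filter.
Decoy PWMs are sharp motifs around random consensus words, re-drawn until
they share no 5-mer with the planted consensus on either strand: a decoy
that chance-matches the planted word would have real binding sites inside
the planted block and would be *genuinely* affected by the patient
mutations — informative biology, but useless as a specificity control. A
`weak_effect` flag halves the per-patient disruptions for power studies.

What the simulation does **not** emulate: trinucleotide-context mutational
signatures, indels and structural variants, correlated gene expression,
multiple chromosomes, GC/repeat structure of real promoters, and PWM
redundancy within TF families. Passing the recovery tests therefore shows
the pipeline's machinery is correct and calibrated at realistic effect
sizes — not that real-cohort performance matches any particular number.

## Numerical and design notes

- Coordinates are 1-based inclusive internally (VCF convention); BED
  output is 0-based half-open. Chromosome names are normalized by
  stripping `chr`.
- Count PWMs get a +1 pseudocount per cell; probability PWMs are
  renormalized and get a +0.001 pseudocount only when they contain zeros
  (a zero probability would give an infinite energy).
- z-scores use the population (1/n) standard deviation so that two units
  normalize deterministically to ±1; a single scored unit gets z = 0 with
  a warning.
- Occupancy is computed in log space (`-log1p(exp(β(E−μ)))` via
  `logaddexp`) and aggregated with `logsumexp`; energies of windows
  containing N are +∞, which drops them from the sum exactly.
- The scored problem sizes in the test suite (50 genes, 500 backgrounds,
  3 replicates, 10 seeds) were chosen as the smallest cohort at which all
  pipeline stages — including the expression filter and triplicate
  consensus — operate away from degenerate edge cases; a full-scale run
  (~20k regions, ~1772 PWMs) uses the same code paths with the default
  background count of one per eligible region.
- Serial and parallel (`threads > 1`, joblib) execution produce identical
  tables; all randomness derives from the run seed via stable CRC-derived
  stream keys.

## Limitations

Only promoter-proximal blocks are considered; enhancers and long-range
regulation are out of scope. The occupancy model ignores TF cooperativity
and indirect (tethered) binding — the direct-binding p-value is the only
binding-plausibility gate. Bonferroni over PWMs is conservative when many
PWMs of one TF family are near-duplicates. The KS gate's asymptotic
p-value is approximate at very small sample sizes (it is calibrated at
the 12 vs 4 design used here, but fewer than ~4 normal samples would make
the gate unreliable).
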