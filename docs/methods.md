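# Methods

This note documents the models behind `tescan`, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Windowed SFS statistics

All estimators operate on the unfolded site frequency spectrum of a window: the
multiset of derived-allele counts `x_i` (0 < x_i < n) at segregating sites, with
orientation taken from an `AA` (ancestral allele) VCF annotation, compared
case-insensitively against REF and ALT.  Sites whose ancestral allele matches
neither allele, multi-allelic sites (an infinite-sites assumption), sites with
missing genotypes, and sites monomorphic after polarization are skipped and
tallied so filter effects are auditable.

Definitions are the canonical ones: π is the mean pairwise Hamming distance
written in terms of counts; θ_W = S/a₁; θ_H = Σ2x²/(n(n−1)); Tajima's D uses the
standard normalization constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ as functions of
n only); Fay & Wu's H is the *unnormalized* π − θ_H.  The scan consumes only
within-population ranks, which are invariant to any monotone per-window
normalization at fixed n, so the normalized H variant is deliberately not
implemented.

Conventions for degenerate input: windows with S = 0 have undefined D and H,
propagated as missing (`NA` in tables) and excluded from ranking — a zero would
spuriously rank such windows as non-extreme.  At n = 2 the variance term of D
vanishes and D is likewise undefined.  Window tiling is 0-based half-open;
windows slide until one reaches the chromosome end, and the final window is
truncated rather than dropped.  Defaults for real data are 50 kb windows with a
10 kb step.

## The coalescent simulator

Each locus of `window_length_bp` (default 2.5 kb) coalesces independently under
a neutral Kingman coalescent (pairwise rate k(k−1)/2); mutations fall on
branches at rate θ/2 per unit branch length with distinct uniform coordinates
(collisions rejected).  θ defaults to 2.5 per 2.5-kb locus, i.e. 0.001/bp,
human-like.  Loci are statistically independent — free recombination between
loci, none within.  A 50-kb analysis window therefore pools ~20 independent
genealogies.  This matters: with a single genealogy per 50-kb window the
neutral null of windowed H is so heavy-tailed that no sweep signal of realistic
magnitude reliably reaches the 5% tail; pooling independent loci is also the
more faithful picture of a 50-kb human window, where the population-scaled
recombination rate is far above 1.  No recombination *process* is simulated —
no demography, migration, or genotype likelihoods either; shared sweeps across
populations are induced simply by reusing sweep window indices.

**Sweep model.**  A completed hard sweep is represented as a star-merger
distortion at backward time `sweep_age` (coalescent units): each lineage
surviving to that time is captured into a single star ancestor with probability
`sweep_strength · (1 − sweep_escape)`; the remaining lineages — at least one,
whenever two or more survive — continue coalescing neutrally together with the
star ancestor.  `sweep_escape` (default 0.1) models recombinational escape from
the sweep across a physical window; it is what gives the model the
high-frequency-derived signature of real sweeps: mutations on the star
ancestor's upper branch segregate near frequency n − 1, driving H strongly
negative, while the truncated lower tree yields the singleton excess that
drives D negative.  With capture of *every* lineage a star tree carries only
low-frequency derived alleles and H is weakly positive — a model without
escape cannot produce the H signature at all, which is why the escape floor is
built in rather than optional.  At `sweep_strength = 0` the code path is the
neutral one, byte-for-byte.

Default study conditions are scaled-down but realistic: 12 populations of 30
haplotypes (~15 diploid individuals each, matching the per-population average
of a worldwide diversity panel), 150 genes of 50 kb (the acceptance study uses
500), sweeps of age 0.05 and strength 1 planted in 5 genes shared across
populations.  The default pipeline tiles windows at step = size because the
simulated loci recombine freely between windows: a 10-kb step would re-use the
same genealogies in up to five windows, inflating rank correlation between
neighbours without adding information.

Measured operating characteristics under these conditions (see
`tests/test_acceptance.py` and `scripts/acceptance.py`): mean neutral D ≈ −0.1,
mean neutral H ≈ 0, mean S within Monte-Carlo error of θ·a₁; sweep-gene
recovery 1.0 with zero neutral concurrent calls; per-population neutral
extreme-tag rates ≈ 4% (slightly below the nominal 5% because planted sweeps
occupy part of the tail).

## Scan conventions

Ranks are ascending (rank 1 = most extreme for low tails) with ties sharing the
minimum rank of the tied block — conservative toward extremeness.  The tail
boundary is inclusive: a gene is extreme when `min_rank ≤ ceil(q · N_ranked)`.
Whether the 5% tail lives on windows or on genes' min-ranks is genuinely
ambiguous in rank-tail scans; the default tags a gene whose best window is in
the window-level tail, and `tail_unit="genes"` switches to the gene-level
quantile without choosing for the user.  Gene-level diversity is the median
per-bp π over overlapping windows (median for robustness; the window→gene
aggregation is otherwise unconstrained).  The resampled Wilcoxon comparison
reports the full p-value vector, its median, the fraction of iterations in
which the candidate median is lower, and one pooled candidates-vs-all-background
test — no single aggregated p-value is manufactured from the iteration vector.

## Consensus sites and IDRs

Thresholds are applied literally: BEB and FUBAR pass at posterior ≥ 0.90
(inclusive), MEME and FEL at p < 0.1 (strict), and a column needs ≥ 2 of the
four methods.  BEB and FUBAR count as independent voters.  SLAC identifies
purifying selection at p ≤ 0.1 (inclusive; no cutoff is standard, so it is
configurable and mirrors FEL's) and never contributes to the positive
consensus.  Positive/negative overlap is reported as a warning, not an error.
Alignment columns map to reference residues by skipping reference gap columns;
per-IDR purifying fractions use the IDR residue length as denominator, with
boundary residues counting as inside (closed intervals).

Consensus IDRs: per alignment column, the fraction of species *with a residue
at that column* that are called disordered; columns at ≥ 50% (inclusive) are
consensus-disordered; maximal runs of ≥ 30 consensus reference residues become
intervals.  The construction is invariant to species order and to all-gap rows.

**Sequence descriptors.**  FCR and NCPR count K/R as positive and D/E as
negative; histidine is excluded by default (mostly neutral at physiological
pH) and can be included by flag.  SHD is implemented as
`(1/N) Σ_{i<j} (λ_i + λ_j) (j − i)^(−β)` with β = 1 and λ the Kyte–Doolittle
hydropathy rescaled to [0, 1]; the scale is configurable, and any fixed
positive scale preserves the reversal symmetry and the group-comparison
semantics used downstream.  Ensemble descriptors (Sconf/N, ν) come from
trained predictors outside this package's scope; they are *joined* from an
external per-ortholog table (matched by maximal interval overlap) and never
computed.  The synthetic generator emits them as noisy decreasing functions of
SHD purely so the comparison machinery has signal to exercise.  Across-ortholog
standard deviations (n − 1 denominator) give the single per-IDR conservation
measure; ortholog segments shorter than 2 residues are skipped with a warning.

## Enrichment statistics

The IDR enrichment test is an exact binomial: successes = consensus sites
inside IDRs, trials = all consensus sites, success probability = total IDR
length over total analyzed length (the regions retained in the alignments);
one-sided "greater" by default since enrichment is the hypothesis, two-sided
by flag.  Exact tail p-values of a discrete statistic are conservative —
stochastically larger than uniform under the null — so the module also offers
Lancaster's mid-p variant (`mid_p=True`), which is the appropriate quantity for
calibration studies: measured over 1,000 simulated null datasets, the exact
p-value's rejection rate never exceeds its nominal level while the mid-p values
are indistinguishable from U(0, 1) by Kolmogorov–Smirnov.  Power at enrichment
ratio 5 with ~100 sites and IDR fraction 0.4 is ≈ 1.0 at α = 0.05.

Group comparisons use the two-sided Wilcoxon rank-sum test, exact enumeration
for groups of ≤ 20 without ties and the tie-corrected normal approximation
otherwise.  Constraint-feature correlations use Kendall's τ-b; cross-predictor
disorder-fraction agreement uses Pearson's r, reported as missing when either
vector is constant.

## The proteome generator

Geometry (protein lengths ~ Normal(500, 80), per-protein IDR fractions ~ Beta
with mean 0.43, one to three segments of ≥ 30 residues each) is drawn
deterministically from the seed.  Positively selected sites are planted with
per-residue probability `site_rate` outside IDRs and `site_rate · ρ` inside
(defaults 0.0018 and ρ = 5, targeting ~150 sites per 60-protein set, consistent
with a strong observed enrichment); purifying sites are planted uniformly.
Ortholog sequences diverge from the reference at 5% per residue (35% at
selected sites), drawing replacements from disorder- or order-biased residue
pools so that IDR composition is realistic.  Each method's call table contains
each true site with probability `method_sensitivity` (default 0.8) and each
non-site with probability `1 − method_specificity` (default 0.995), scores
drawn on the correct side of that method's threshold.  Under perfect detection
the consensus caller recovers the planted set exactly; at sensitivity s with
perfect specificity, recovery matches P(Binomial(4, s) ≥ 2).

**What the synthetic data does not emulate** — and hence what passing tests do
not show about real data: genotype likelihoods and sequencing error,
linkage disequilibrium within loci, demography and migration, alignment error
and trimming decisions, correlated errors between site-call methods (they are
independent here; real BEB and FUBAR share assumptions), disorder-predictor
biases, and the real relationship between sequence and ensemble features.
Calibration results transfer to real data only to the extent those factors are
secondary.

## Problem sizes

Test-suite and acceptance-script scales were chosen for Monte-Carlo precision
at interactive runtimes: 10,000 windows for neutral calibration (the H
standard error is then ~0.024, making the ±0.1 acceptance band a ~4σ test of
unbiasedness rather than a coin flip at 2,000 windows), 500 genes × 12
populations for the sweep study, and 1,000 replicates for enrichment
calibration and power.

## Known limitations

- The sweep model is a two-parameter distortion, not a forward simulation with
  selection coefficients; `sweep_age`/`sweep_strength` do not map directly onto
  s and fixation times.
- Fay & Wu's H here assumes correct polarization; ancestral misidentification
  in real data biases H and is not modelled.
- The proteome-wide IDR-fraction comparison against a reference proteome
  requires real external data and is supported only as a user-supplied input
  path, not exercised by the test suite.
- SHD's published functional form is fixed here (β = 1, normalized
  Kyte–Doolittle λ); comparisons across packages require matching the scale.
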