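# Methods

This note documents the models, conventions and design choices behind
`adniche`, stage by stage, in enough detail to reimplement them.

## Free-ammonia chemistry

TAN partitions as `NH3 = TAN / (1 + 10^(-pH)/Ka)` with `NH4 = TAN − NH3`.
`Ka` is a configurable scalar defaulting to 1.20e-9 (mesophilic, 37 °C);
no temperature dependence is modelled. Concentrations are stored as
g N L⁻¹ throughout (numerically identical to mg N mL⁻¹, which appears in
some source material for the same quantities). Report rounding is 2 d.p.
for concentrations and 1 d.p. for ratios; full precision is retained
internally. Inputs are validated (`TAN ≥ 0`, `0 < pH < 14`, `Ka > 0`)
and the identity `NH3 + NH4 = TAN` holds to 1e-9 by construction.

## Abundance tables

`AsvTable` wraps a taxa × samples DataFrame with a `mode` flag (`raw`,
`rarefied`, `relative`, `absolute`) so that unit errors fail loudly.
Rarefaction draws each sample without replacement (multivariate
hypergeometric via NumPy's generator); samples under the target depth
(default 15 000) are dropped with a logged warning — the drop policy is
ours, as is keeping singletons and doubletons (no abundance filtering).
Absolute abundance is relative abundance (%) × qPCR 16S copies mL⁻¹ /
100, so each column sums to that sample's total community size.

Alpha diversity: richness S = non-zero entries; Pielou J = H′/ln S with
natural-log Shannon H′; J is reported as missing (NaN) when S = 1, not
as zero. Bray–Curtis is Σ|x−y| / Σ(x+y) on absolute abundances (scipy's
implementation); a pair of all-zero samples is an error rather than a
silent zero.

ANOSIM uses Clarke's statistic R = (r̄_between − r̄_within) / (n(n−1)/4)
on average-tie ranks of all pairwise dissimilarities, with the
permutation p-value (1 + #{R_perm ≥ R_obs}) / (1 + n_perm); labels are
permuted with a seeded generator (999 permutations by default). R is
checked against scikit-bio's ANOSIM in the test suite; the p-value
convention is the standard add-one estimate.

## Ammonia niche breadth

Resource states are the distinct experimental NH3 conditions — medium ×
sampling day — with availability r_j proportional to the state's mean
NH3 and the taxon profile p_j averaged over that state's replicate
bottles (per-sample states are available via `resource_groups=None`).
Replicate averaging stabilises p_j, and with ~8 states a flat taxon sits
near B′ ≈ 0.6 while sensitive and enriched taxa approach the ends of the
scale, which is also the scale on which the fixed 0.24/0.88 thresholds
operate. With every sample its own state the B′ scale compresses so far
that a perfectly flat taxon lands near 0.26 and the classes cannot be
separated by any null.

The null model draws `n_null` (default 999) *randomly generated taxa*
as Dirichlet(α = 2) proportion vectors over the resource states — random
taxa with no structured NH3 response and mild evenness. α = 1 (uniform
on the simplex) admits profiles more concentrated than any noise process
with flat expectation produces, which pads both tails and destroys
power; α = 2 keeps the null's spread comparable to a real unstructured
taxon under the pipeline's residual noise. An alternative null
(`kind="permutation"`) permutes randomly chosen observed profiles across
states; it preserves the observed abundance distribution but its tails
track the strongest true responders in the data (the null inherits the
signal it is meant to test), making it very conservative whenever strong
responders are common — it is provided for sensitivity analyses, not as
the default.

Classification: thresholds at the α and 1−α null quantiles (α = 0.05);
p-values are two-sided empirical tail probabilities with add-one
correction, BH-adjusted across taxa; *sensitive* requires B′ below the
lower threshold with q < α, *enriched* above the upper threshold with
q < α, everything else *tolerant*. The fixed-constant mode applies
0.24/0.88 directly with no significance gate. Taxa observed in fewer
than 3 samples are excluded from classification (logged), as their B′ is
unstable. B′ is invariant to rescaling NH3, and B ≤ 1 with equality iff
p ≡ r (Cauchy–Schwarz); both are property-tested.

## Profile-HMM methanogen screen

Alignment columns with < 50% gaps become match states. Emissions are
column counts with Laplace pseudocount 1.0; transitions are estimated
from each sequence's local state path (first to last emitting match)
with the same pseudocount. The scoring architecture is local:
uniform entry B→M_k (1/L), early exit M_k→E with probability ε = 0.01
(core transitions scaled by 1−ε; the final match exits with probability
1), and geometric flanking states (self-loop η = 0.9) that absorb
unmodelled sequence at background emission. Insert and flank emissions
equal the uniform background, so they cancel in the log-odds; scores are
`log2 P(seq|profile)/P(seq|background)` in bits, computed by the forward
algorithm over all paths (delete chains are handled with a log-sum-exp
prefix scan, so scoring is O(nL) with vectorised inner steps). The
forward recursion is verified against brute-force path enumeration on
toy models.

Calls are calibrated on a null of `n_null` (default 200) dinucleotide-
shuffled input sequences (Altschul–Erickson Euler-path shuffling, which
preserves exact dinucleotide counts); an ASV is called when its score
exceeds the 0.99 null quantile. Raising the quantile can only shrink
the called set (tested). Hits are aligned to the match states along the
Viterbi path for identity p-distances (mismatches over columns where
both sequences carry a residue); hits covering less than half the match
states are left off the tree. Neighbour joining uses Q-matrix selection
with ties broken on the lexicographically smallest id pair,
Studier–Keppler branch lengths with negatives clamped to zero (logged),
and is exact on additive matrices (tested against hand-run values and
scikit-bio).

## Co-occurrence networks

Per condition, the `top_n` (default 1000) most abundant taxa (ties at
the cut broken lexicographically) are correlated pairwise with Spearman
on average-tie ranks across the condition's samples. The default
p-value is a seeded Monte-Carlo permutation estimate (999 permutations;
one shared permutation per iteration applied to the rank matrix, which
keeps the per-pair marginal null exact while allowing the whole matrix
to be computed as one product per iteration); exact enumeration is used
for single pairs with n ≤ 7, and a t-approximation (n−2 df) is available
by configuration. BH adjustment runs over all tested pairs within one
network; edges require ρ > 0 and q < α. Every retained taxon remains a
node; constant series contribute no edges (logged). Node types combine
the ammonia class (enriched taxa count as tolerant-of-NH3 in the two-way
typing) with methanogen status. Clusters are connected components;
composition across networks is a Pearson chi-square without continuity
correction on the networks × node-type table (all-zero rows/columns are
an error; a Monte-Carlo multinomial oracle backs the p-value in tests).

## Synthetic experiments

The generator emulates a two-community incubation study: un-adapted and
high-ammonia pre-adapted slurry communities, each grown in a low-NH3
(0.09 g N L⁻¹ at day 1, declining linearly to 0.04 at day 14) and a
high-NH3 medium (0.30 → 0.22, staying above the 0.2 inhibition level),
destructively sampled at days 1, 3, 7, 14 with 3 replicate bottles — 48
samples. Per-sample pH ~ N(7.6, 0.05); TAN is back-computed from the
true NH3 and pH through the speciation equation, so the chemistry stage
recovers the planted NH3 exactly.

Expected abundance of taxon i in bottle s is

    λ_is = baseline_i(community) · class_i(NH3_s) · exp(g(guild_i, s))

* `baseline`: log-normal (σ = 0.8) with a ×3 community-adaptation bias —
  the pre-adapted community favours tolerant over sensitive baselines,
  the un-adapted the reverse; enriched specialists are seeded equally.
* `class`: sensitive `exp(−k·NH3)` with k = 30 L (g N)⁻¹ — an effectively
  extirpating response at inhibitory NH3, consistent with archaeal
  die-off under inhibition; enriched ∝ NH3 (so its profile tracks
  resource availability and its B′ approaches 1; a 0.15 g L⁻¹ reference
  keeps its mean abundance comparable); tolerant flat. Class fractions
  default to 0.5/0.4/0.1.
* `g`: a per-bottle latent shared by all members of a guild (4 guilds by
  default), i.i.d. N(0, guild_sd²) across bottles. Each replicate is its
  own bottle, so this is a bottle-level growth trajectory.

Counts are negative-binomial around λ scaled to a log-normal library
size (mean 40 000, rarefied to 15 000 downstream), with dispersion 0.2
(variance μ + 0.2μ²; NB size 5, within the range fitted to biological
amplicon replicates). Dispersion beyond ~0.4 makes the enriched class
statistically unidentifiable at 3 replicates — replicate-averaged noise
censors enriched B′ below any class-free null's upper tail — so the
default is deliberately in the identifiable regime. qPCR totals track
the summed λ per bottle with log-normal measurement noise (σ = 0.2).

Two amplitude regimes are provided because one guild amplitude cannot
serve both planted structures: the default `guild_sd = 0.2` keeps
resource-state noise small enough that the three ammonia classes are
recoverable (measured ≥ 95% per class over 10 seeds), while
`SyntheticConfig.guild_network_demo()` (3 guilds, all tolerant,
`guild_sd = 2.0`, 60 taxa) represents succession-bloom dynamics in which
guild covariation dominates the counts and single-condition (n = 12)
Spearman networks recover ≥ 95% of within-guild pairs with ~2%
cross-guild edges. Real AD data contain both effects at once; passing
both recovery checks shows each inference works where its signal is
identifiable, not that the two signals can always be separated in one
dataset.

Methanogen taxa (20 of 150 by default) receive sequences mutated (3%
per site) from leaves of a generated reference alignment — 94 references
in 27 clusters by default, built by a two-rate root→ancestor→leaf
mutation scheme (between-cluster 0.15, within 0.03, 1% gap columns,
250 columns) — so the screen's HMM, built from the same references, has
a planted recoverable signal; non-methanogens get uniform random
sequences of the same length. All assignments are exported as ground
truth.

What the generator does **not** emulate: mechanistic AD kinetics and gas
production, taxon turnover between communities (the taxon pool is
shared; communities differ by abundance bias), phylogenetic signal in
abundance, compositional sequencing biases, chimeras or read-level
error. Passing recovery tests therefore demonstrates correctness of the
inference machinery under the stated generative model, not performance
on real amplicon data.

## Pipeline and determinism

`run_pipeline` executes chemistry → abundance → niche → screen →
networks → report. One global seed is expanded through a NumPy
`SeedSequence` into per-stage seeds (logged in the report provenance
with the config hash and version), making every artifact bit-identical
under a fixed seed. Stage failures are re-raised with the stage name.
The report is JSON with sorted keys; all tabular artifacts are TSV,
trees Newick, networks GraphML.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the default experiment
(150 taxa × 48 samples) for class recovery, a 100-taxon / 20-methanogen
experiment for the screen, and the 60-taxon bloom-regime preset for
networks, each over 10 independent seeds; oracle checks use toy models
small enough for exhaustive enumeration (≤ 4 match states, n ≤ 6
permutation tests, 4-sample ANOSIM). The full-pipeline statistics in the
acceptance script use `top_n = 100` of 150 taxa so that node sets are
condition-dependent, mirroring the role of a top-1000 rule in datasets
with thousands of ASVs.

## Known limitations

* The niche classification's power depends on the number of distinct
  NH3 conditions; with fewer than ~6 resource states the null quantiles
  become coarse.
* The Dirichlet-null concentration (α = 2) is a modelling choice; very
  heavy-tailed real communities may warrant matching α to observed
  profile evenness, which is not automated.
* Monte-Carlo network p-values share permutations across pairs within an
  iteration; per-pair marginals are exact but p-values are weakly
  dependent across pairs, which BH tolerates in practice.
* The NJ tree is unrooted and intended for visual placement, not formal
  phylogenetic inference; no bootstrap support is computed.
* ANOSIM assumes exchangeability under the null; with the incubation
  design's time structure, its p-values test the combined
  condition effect, not time-adjusted differences.
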