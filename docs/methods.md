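# Methods

`assemblytrace` quantifies the contributions of selection, dispersal and
drift to soil community assembly along a press-disturbance
chronosequence: soils currently heated by a subsurface fire
(fire-affected), soils that have cooled back to ambient (recovered),
and never-affected references. The package implements the full analysis
chain — preprocessing, diversity, neutral-model fitting, beta-null
deviation modeling, multivariate testing, dominance analysis — plus
synthetic generators with known assembly processes so every stage can
be validated against ground truth.

## Data model and preprocessing

The central object is an integer sample × taxon count matrix; taxa with
zero total count are dropped at construction. Preprocessing follows a
fixed order: technical replicates are summed per soil, every soil is
subsampled to one even depth (a single multivariate-hypergeometric draw
per sample, i.e. without replacement, seed recorded in provenance), and
taxa observed exactly once in the whole data set are then removed.
Counts stay integer until relative-abundance conversion; relative
abundances are renormalized to sum to 1 within 1e-12 per sample.

Phylogenies are rooted trees with non-negative branch lengths; an
unrooted input is rejected unless midpoint rooting is requested. Taxa
missing from the tree abort phylogenetic metrics unless pruning is
explicitly requested, because silent pruning changes UniFrac
denominators.

## Diversity

Alpha diversity reports richness, Shannon H′ in nats, Pielou's
J = H′/ln S (undefined for S = 1, reported as NaN with a warning), and
Faith's PD under the whole-tree convention: the sum of branch lengths
over all branches with at least one observed descendant, which for a
rooted tree equals the minimal subtree connecting the observed tips and
the root.

Beta diversity is computed from a branch × taxon incidence
decomposition of the tree, so a full distance matrix is a few dense
matrix products rather than a per-pair traversal — this is what makes
the permutation loops of the beta-null model affordable. With
per-sample branch proportions p_X(b):

* unweighted UniFrac = (branch length unique to either sample) /
  (branch length in either sample);
* raw weighted UniFrac = Σ_b l_b |p_A(b) − p_B(b)|, which is not
  bounded by 1;
* normalized weighted UniFrac divides by Σ_j d_j (p_A(j) + p_B(j)) over
  tips j with root-to-tip distance d_j, bounding the value to [0, 1].

Bray–Curtis is computed on counts (equal depth is ensured upstream).
Every metric is cross-checked in the test suite against two independent
routes: a naive per-branch brute-force implementation and scikit-bio.

## Neutral model

Each local community is modeled as N individuals renewed one death at a
time; the replacement is an immigrant drawn from metacommunity relative
abundances p_i with probability m, otherwise a local birth proportional
to abundance. The detection probability of taxon i at detection limit
d (default one read, d = 1/N) is

    f_pred_i = 1 − I_d(N·m·p_i, N·m·(1 − p_i)),

with I the regularized incomplete beta function. The composite
parameter is fitted by bounded least squares of f_pred against observed
occurrence frequencies (search bracket (1e-6, 1] on the model scale,
boundary hits flagged; a binomial maximum-likelihood mode is available
behind a flag). R² = 1 − SSR/SST about the mean observed frequency and
may be negative; it is reported as-is.

Two immigration scales are reported. `m_sloan` is the fitted parameter
as canonical implementations print it. `m` converts to the per-death
immigration probability of the exact stationary urn via
I = m(N−1)/(1−m), i.e. m = N·m_sloan/(N·m_sloan + N − 1). The scales
agree for small immigration and diverge near saturation; the urn scale
is what a forward simulation's immigration probability means, and it is
the scale the parameter-recovery tests check.

The 95% envelope around f_pred uses exact binomial quantiles of the
occurrence count over n samples rather than a normal-approximation
band: at high predicted frequencies the discreteness of k/n matters,
and a Wilson band excludes f_obs = 1 even when it is the most probable
outcome. Taxa below the envelope occur in fewer communities than their
pool abundance predicts — under a press disturbance these are
candidates for locally successful, regionally over-predicted taxa.

Known limitation: the continuous beta detection formula deviates from
the exact beta-binomial occupancy of the urn by up to ~0.05 in
frequency, which the fitted parameter partially absorbs; at
intermediate immigration (m ≈ 0.15) this leaves an upward bias of
roughly +25% in m̂ — inside the ±30% band the recovery tests allow, and
a property of the canonical formula rather than of the optimizer. The
detection limit is configurable for sensitivity analysis.

## Beta-null deviation model

One null iteration builds, per sample, a random community preserving
observed richness S_j and depth N_j: occurring taxa are drawn without
replacement with probability proportional to occupancy (number of
samples occupied), then one individual is seeded per chosen taxon and
the remaining N_j − S_j individuals are allocated multinomially in
proportion to regional relative abundances. Seeding guarantees chosen
taxa are present and preserves both margins exactly; rejection sampling
is the alternative but can stall on skewed pools. Both weightings can
be switched to uniform.

The deviation of a sample pair is d_obs − mean(d_null) across
iterations (default 999; fewer than 99 warns); the standardized
deviation (SES) is also reported, NaN where the null spread
degenerates. The same machinery runs on Bray–Curtis and on weighted
UniFrac — the phylogenetic extension holds the tree fixed and permutes
only the table.

Per-sample summaries support two comparison scopes. The default
`all_pairs` averages a sample's deviations against every other sample.
Group analyses (`deviation_by_group`) default to `within_group`: a
class's divergence is measured on its own pairs, because with mixed
scopes the between-class pairs dominate every sample's mean and the
class contrast washes out. Group comparisons report Welch's t and
Mann–Whitney (two-sided and one-sided), plus a temperature-ordered
trajectory and, within the hot class, a Spearman correlation of
deviation against temperature.

A centering caveat: the null operator re-estimates occupancy weights
from the table it randomizes. Applied to a table that is itself a
single null draw from a *different* base table, this feedback leaves a
small transient (≈0.05 in Bray–Curtis units at 20 samples); iterating
the operator to its weight fixed point removes it. The self-centering
test therefore draws its input from self-consistent weights.

## Multivariate statistics

One-way PERMANOVA partitions squared distances (SS_total from all
pairs/n; SS_within per group/group size); pseudo-F uses (k−1, n−k)
degrees of freedom and R² = SS_between/SS_total; p-values come from
label permutation with the observed statistic included in the
reference set, so p ≥ 1/(n_perm + 1). Groups of size 1 are refused.

The dispersion test embeds samples by PCoA, measures distances to each
group's spatial median (Weiszfeld iteration, tolerance 1e-8), and
permutes those distances across groups; per-group median dispersions
and their pairwise differences are reported. PCoA axes with negative
eigenvalues (possible for Bray–Curtis and raw UniFrac) are dropped and
their absolute mass reported; no Cailliez correction is applied.
Environmental vector fitting regresses each variable on the first two
axis scores and reports the squared multiple correlation with a
permutation p; constant variables are skipped with a warning. The
temperature-partialled ordination regresses PCoA coordinates on the
conditioning variable and re-ordinates the residuals — a distance-based
approximation to constrained ordination, documented as such. Mantel
tests (Pearson, matrix permutation) and PCoA delegate to scikit-bio
behind this module's surface; the spatial variant builds Euclidean
distances from planar coordinates. Default permutation counts: 999
(Mantel, dispersion, envfit) and 1000 (PERMANOVA).

## Dominance analysis

Per sample, the k (default 10) highest-count taxa, ties broken
lexicographically by taxon id for determinism. Group reports give the
union of top-k sets (between k and k × n_samples), each union taxon's
share of the group's total count ("cumulative % abundance", read as the
per-taxon share), and its % occurrence across group samples. Phylum
summaries collapse taxa to phylum (unassignable taxa to an
"unidentified" bin), average per-sample relative abundances within
class, and pool phyla with overall mean below 0.01 into a "below 0.01"
bin; class means sum to 1 across bins.

## Synthetic generators

The generators define the study conditions every downstream property is
tested under.

* **Metacommunity**: S = 300 taxa; lognormal relative abundances
  (σ = 1.5); thermal optima uniform on [5, 65] °C; Gaussian tolerance
  breadths uniform on [4, 12] °C.
* **Neutral/niche urn**: N = 1000 individuals per local community; one
  death + one replacement per event; immigration probability m per
  death (chronosequence default 0.5 for the convergent ambient
  classes); fitness w_i(T) = exp(−(T − opt_i)²/2·breadth_i²)^σ
  reweights immigration and birth, with σ = 0 reducing exactly to the
  neutral process (same seed, same draws). Burn-in is
  max(10, ⌈3/m⌉) generations of N events — three relaxation times of
  the immigration process — so low-m communities reach stationarity.
* **Divergent dominants (priority effects)**: hot samples are assigned
  round-robin to priority groups (default 3, matching the three
  observed subsets of fire-affected soils); each group elevates its own
  random set of 8 thermotolerant taxa (optimum ≥ 38 °C) to a fixed
  probability share of 0.10 each before a multinomial draw, with a
  lognormal per-sample jitter (σ = 0.8) on the shares so group-mates
  share dominant membership but not ranks. A boost is a share, not a
  multiplier, because a priority effect decouples local dominance from
  regional abundance. All boosted taxa keep a background share of 0.004
  (half jitter) everywhere else — rare but detectable, so one group's
  dominants sit in another group's rare biosphere. Non-boosted taxa
  split the remaining mass by pool abundance × thermal fitness
  (filter σ = 2.5).
* **Chronosequence**: 2 reference + 7 recovered soils at 12–15 °C
  assembled neutrally, 9 fire-affected soils at 21–58 °C assembled by
  the divergent process; ammonium and nitrate increase with
  temperature, recovered soils have lower pH than references,
  coordinates are uniform on a 500 m box with no spatial process.
* **Trees**: ultrametric Kingman coalescent (exponential coalescence
  intervals). An optional clustered mode coalesces thermotolerant tips
  first so thermophily is phylogenetically aggregated; the
  chronosequence default is unclustered — with all thermophiles in one
  clade, hot communities become phylogenetically homogeneous and the
  phylogenetic beta-null signal is suppressed by construction.
* **Taxonomy**: phyla assigned by contiguous tree clades, ~8% of taxa
  left unassigned, ~20% flagged de novo.

What the generators do **not** emulate: sequencing noise and depth
(local communities hold 10³ individuals, not 3.2 × 10⁵ reads), OTU
clustering artifacts, chimera or contaminant removal, a two-compartment
dormant/active seed-bank model (priority effects are emulated through
dominance shares), spatially explicit dispersal, or mechanistic fire
geochemistry. Passing tests therefore demonstrate that each statistic
recovers known assembly structure at desk scale — not that the
pipeline reproduces any field study's printed magnitudes, which depend
on the real sequence data.

## Determinism and problem sizes

All randomness flows through numpy Generators seeded from explicit
arguments; the pipeline derives stage seeds from one master seed, and
reruns are numerically identical. Simulator provenance (config echo,
seeds, boosted-taxon sets) travels with each table.

Test and acceptance problem sizes are chosen to keep the full suite in
tens of seconds to a few minutes: metric-oracle checks use exhaustive
instances up to 6 tips × 6 samples; immigration recovery uses a
{0.05, 0.15, 0.5} × {500, 1000} grid with 50 communities per fit and
5 replicate fits per cell (median error within ±30%); self-null
centering uses 20 samples at depth 1000 with 999 iterations;
niche-detection direction uses 20 replicate chronosequences with
99-iteration nulls; permutation-test calibration uses 200 replicates at
n = 18 with 199 permutations.
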