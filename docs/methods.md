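# Methods

`msatpop` re-implements, as one coherent library, the population-genetic
workflow used to ask whether the northernmost stands of a rare
fog-forest tree are ancient relicts or products of glacial-era range
expansion: descriptive microsatellite diversity, hierarchical
differentiation and isolation-by-distance testing, model-based Bayesian
clustering, and coalescent ABC model choice among three demographic
histories. This note records the models, the defaults and their
justifications, the numerical choices, and what the synthetic data do
and do not establish.

## Data model

Genotypes are diploid microsatellite calls: an unordered pair of
fragment sizes in base pairs per individual per locus, missing as a
unit, with both alleles congruent modulo the repeat-motif length.
GenePop v4 text is the interchange format; 3-digit allele coding is
canonical and 2-digit files are lifted by a +100 bp offset so stored
sizes remain physical. Loci are grouped by motif (dinucleotide /
trinucleotide); several statistics are computed per group because the
two groups mutate at different rates.

Coordinates are stored as positive decimal degrees South/West and all
geographic distances are great circles on a 6371-km sphere: the
transect spans ~450 km of latitude, enough for planar approximations to
distort the isolation-by-distance regressor.

## Diversity statistics

Per site: mean number of alleles per locus (na), rare-allele count
(AR = alleles present at the site with pooled frequency < 0.05;
threshold configurable), mean Shannon index I = −Σ p ln p, observed
heterozygosity Ho (fraction of heterozygous scored calls), and expected
heterozygosity He = 1 − Σ p² (plain Nei gene diversity). The
small-sample-corrected He (factor 2n/(2n−1)) is available behind
`unbiased=True` but is not the default: the published per-site table is
internally consistent with plain He — its printed FIS equals
(He − Ho)/He at two decimals in 8 of its 9 rows — so plain He is what
that toolchain used. The inbreeding coefficient is exactly that
identity, with He = 0 returning NaN. Its CI resamples loci with
replacement (999 replicates, percentile interval): loci, not
individuals, are the exchangeable unit for a multilocus FIS.

Latitude regressions are ordinary least squares of a diversity column
on decimal latitude with the F statistic on (1, n−2) df; a
small-sample site can be excluded, mirroring the original analysis.

## Exact tests

Hardy–Weinberg: Monte-Carlo exact probability test. Allele copies are
shuffled and re-paired with allele counts held fixed; the p-value is
the proportion of tables whose Levene conditional probability is at
most the observed one (ties counted, +1 correction in numerator and
denominator). A full-enumeration two-allele version serves as an
independent oracle in the tests.

Linkage disequilibrium: G test on the genotype×genotype contingency
table of a locus pair, null distribution by permuting one locus's
genotypes among individuals within each population; populations are
combined by Fisher's method. Monomorphic combinations return a
not-applicable NaN and drop out of the pooled statistic.

## AMOVA and FST

AMOVA is the Excoffier sums-of-squares decomposition on
allele-identity (infinite-allele) distances between gene copies with
three strata: among regions, among populations within regions, within
populations. Because the copy-pair distance is 0/1, every sum of
squares reduces to allele counts, so the analysis — permutations
included — runs on count vectors rather than an N×N matrix. Variance
components are estimated per locus with the standard unequal-size
coefficients and summed over loci; Φ statistics are ratios of the
summed components. Permutation tests move whole diploid individuals
(both copies together): among populations within regions for Φ-PR,
unrestricted for Φ-PT, and whole populations among regions for Φ-RT.

Pairwise FST is the corresponding two-level estimator. The published
analysis reports FST (not RST) from a GenAlEx-style AMOVA, so the
allele-identity estimator is the default; an RST variant on squared
repeat-count differences is available for comparison. Negative
finite-sample estimates are clamped to zero in the distance matrix and
in the ABC summary vector, with raw values retained in a side report.
With one site per region the three-level model collapses and Φ-RT
equals the two-level pairwise estimator exactly (tested).

## Mantel tests

Mantel r is the Pearson correlation of upper-triangle entries, with a
one-sided (greater) permutation p-value from joint row/column
permutations — one-sided because isolation by distance predicts a
positive association. The partial Mantel test residualizes both
matrices on the control by OLS and permutes the residual matrix of the
first (Legendre's method). When the control explains the second matrix
entirely (the self-control limit, including affine copies) the partial
correlation is returned as 0 with a warning rather than an error: the
quantity is a well-defined limit even though the formula degenerates.

## Coalescent simulator

Backward-time structured Kingman coalescent over named populations:
within a population of diploid effective size Ne each lineage pair
coalesces at rate 1/(2Ne) per generation; a time-ordered event list
applies merges, admixture splits (each lineage of the admixed
population joins parent A with probability r), size changes, and
bottlenecks (a constant reduced size Nb for duration db on the founded
branch — the standard reading of a founder squeeze; an alternative
instantaneous-founder parameterization is out of scope). There is no
migration between events. Time is continuous, measured in generations;
years appear only at reporting via a generation-time parameter
(default 5 years, the age at first reproduction recorded for the
species in cultivation).

Scenario builders encode the three candidate histories over
north/center/south:

1. **divergence** — north splits first (backward: center+south merge,
   then join north's ancestor);
2. **stepping_stone** — northward colonization (north founded from
   center, center from south) with a founder bottleneck on the north
   branch; a flag adds one on the center branch, since the source text
   is ambiguous about whether both founder populations were squeezed;
3. **admixture** — the central population is founded at t_adm as a
   mixture of north (probability r) and south lineages, which
   themselves diverged at t_div.

Validation rejects non-positive or unordered event times, admixture
proportions outside (0,1), bottlenecks longer than the branch, and
event lists that strand lineages away from a single root.

Mutation is stepwise: Poisson(μ·branch length) events per branch; each
event moves the repeat count by ±k with k=1 (SMM) or k ~
Geometric(1−P) (GSM, default P drawn from [0.1, 0.3], the usual
DIYABC-style band); the sign is a fair coin. Repeat counts reflect at
a floor of two repeat units so alleles stay physical; no upper bound is
imposed by default (a bounded-window option would add a parameter the
analysis never used). Di- and trinucleotide groups draw separate
rates. Diploids are formed by pairing consecutive gene copies within a
population — copies are exchangeable, so this is a uniform random
pairing. Closed-form checks: E[TMRCA] = 2Ne for a sample of two, and
the SMM size-difference variance after divergence time t is 2μt; the
full scenario machinery is cross-checked against an independent
coalescent simulator (msprime) by comparing TMRCA and total-length
distributions.

## ABC

The reference table draws parameters from uniform priors (log10 scale
for sizes, times and rates; rejection sampling for structural
constraints such as t_adm < t_div), simulates one dataset per draw
under the sample design of the observed data, and stores a fixed-order
summary vector per row. Row seeds derive from (seed, scenario, row),
so tables are reproducible and can be built in chunks and concatenated.

Summary statistics, per locus group: mean alleles, mean gene diversity
and mean allele-size variance (repeat units) per population; pairwise
FST and (δμ)² (squared difference of mean repeat counts, averaged over
loci) per population pair. This is the minimal standard one/two-sample
menu of the DIYABC family. An experiment with the Garza–Williamson M
ratio added per population did not improve scenario discrimination and
destabilized the local-linear posterior, so the minimal set stands.

Model choice standardizes the statistics by reference mean/sd (columns
with zero variance are dropped), ranks rows by Euclidean distance to
the observed vector, retains the nearest fraction (default 1%), and
fits an Epanechnikov-weighted multinomial logistic regression of the
scenario label on the statistics, evaluated at the observed point.
Scenario CIs come from a nonparametric bootstrap of the retained set
(default 100 refits). If the retained set loses a scenario entirely
the fit falls back to weighted rejection proportions with a warning.
Standardization makes the whole procedure invariant to affine
rescaling of any statistic (tested).

Parameter posteriors use Beaumont-style local-linear adjustment within
the chosen scenario's retained rows: each retained draw is corrected by
a weighted least-squares fit of the parameter on (statistics −
observed), on log10 scale for log-uniform parameters, with Epanechnikov
weights. Two stabilizers matter at desk scale: the retained count is
floored at 4×(dim+1) rows so the regression stays overdetermined, and a
light ridge penalty (10⁻³ of the mean diagonal, intercept excluded)
guards the near-collinear statistic block. Reported are the weighted
median and central 90% interval of the adjusted draws, clipped to the
prior support.

Default priors: Ne ∈ [100, 50,000]; t_adm (and the analogous first
event times) ∈ [160, 20,000] gen; t_div ∈ [2,000, 200,000] gen with the
ordering constraint; r ∈ [0.05, 0.95]; founder bottleneck Nb ∈ [10,
1,000], db ∈ [10, 150] gen; mean μ ∈ [10⁻⁵, 10⁻³] per group
(log-uniform); GSM P ∈ [0.1, 0.3]. The μ lower bound sits a decade
below the common 10⁻⁴ default deliberately: under the inferred
effective sizes, the observed heterozygosity of the study system
implies a mean dinucleotide rate near 3×10⁻⁵ (see the generator
calibration below), and the prior must bracket the data-consistent
rate with headroom.

## Bayesian clustering

The admixture model with correlated allele frequencies: allele-copy
origins Z are multinomial given cluster frequencies P and individual
admixture vectors Q; P[k, l] ~ Dirichlet(p_anc[l]·(1−F_k)/F_k) around
ancestral frequencies with per-cluster drift F_k (the F model); Q ~
Dirichlet(α). Z, P and Q are Gibbs-updated; α (uniform(0,10) prior,
proposal sd 0.025 — mixing is sensitive to this), each F_k
(uniform(0.001, 0.5), proposal sd 0.05) and the ancestral frequencies
(flat Dirichlet prior; Dirichlet proposal centred on the current value,
concentration 50, with the asymmetric-proposal correction) move by
Metropolis steps. An independent-frequency variant (flat Dirichlet λ,
fixed at 1) is available.

The model score for choosing K is ln P(D) ≈ mean(L) − ½ var(L) over
post-burn-in log-likelihood samples — the harmonic-style estimator the
original program reports. K is selected by the rate-of-change rule: the
chosen K is one below the first K whose increase in mean ln P(D) drops
under 10% (configurable) of the largest increase; a curve that never
plateaus returns the largest K with a warning, and a curve that never
rises returns K=1. The full curve is reported so the rule is auditable.
Replicate runs are label-aligned by greedy q-correlation matching
before any averaging. Individuals are assigned to a cluster when their
posterior mean membership reaches a threshold, read as 0.80 from the
original report's "80% of inferred ancestry" convention (configurable),
otherwise reported as admixed.

Desk-scale MCMC defaults are burn-in 5,000 / length 50,000 — a 10×
reduction of the original run lengths that keeps recovery experiments
in minutes; the original lengths remain reachable through
configuration. On simulated three-population data with pairwise FST ≥
0.3, scaled-down chains (burn 300 / length 1,500) already recover the
clusters nearly perfectly, which is why the test suite uses them.

## Synthetic data: what it emulates, and what it does not

No genotypes were ever deposited for the original survey, so the
generator emulates the study design: 9 sites at the published
coordinates in three latitudinal regions, sample sizes
(15,15,15,15,7,12,15,15,15) totalling 124 diploids, 8 loci (7 di-, 1
trinucleotide), simulated under the admixture scenario at the
published posterior-median parameters (t_adm = 6,330 and t_div =
27,800 generations, r = 0.64, Ne = 12,800 / 21,200 / 4,360 for
north/center/south). Two quantities the study never reported had to be
fixed:

* **Ancestral Ne** = 10,000, mid-range among the three reported sizes;
  it only shapes deep-time diversity and none of the tested patterns
  are sensitive to it.
* **Mean mutation rate** = 3×10⁻⁵ per locus per generation (GSM
  P = 0.2). The generator's contract is to reproduce the study's
  observed levels — He ≈ 0.4–0.6 within regions and among-region
  differentiation near 36% — and with the posterior-median sizes these
  pin the rate: a one-off calibration over μ ∈ {2, 3, 5}×10⁻⁵ (8 seeds
  each) gave among-region percentages of 34.1 / 33.5 / 26.6 and
  northern He of 0.42 / 0.49 / 0.62, after which μ = 3×10⁻⁵ was frozen.
  The value sits below classic dinucleotide defaults but within the
  range reported for plant microsatellites.

Sites within a region are subsamples of a single simulated regional
deme, because the demographic model has three populations, not nine.
Consequently the among-site-within-region AMOVA stratum in fixtures is
essentially zero, where the real survey found ~8%: within-region
substructure is a deliberate fidelity limit. The fixtures also carry no
null alleles, genotyping error or missing data unless injected.
Passing tests therefore demonstrate correct statistical machinery and
qualitative reproduction of the latitudinal structure (diversity
decline southward, regional clustering, isolation by distance, ~30–36%
among-region variance); they do not demonstrate robustness to the
messiness of real fragment data.

A second generator produces the exchangeable null — one panmictic
population arbitrarily partitioned into labelled groups — used to
calibrate FST, Mantel, HWE and LD: under it, every test's p-values are
checked for uniformity (KS at α = 0.01, 200 replicates each).

The `scale` parameter co-scales times and sizes while scaling μ
inversely, preserving θ = 4Neμ and relative event times; it trades
runtime for extra coalescent noise and is used for quick smoke runs.

## Problem sizes and known limitations

The test suite runs the recovery experiments at: reference tables of
10⁴ rows per scenario (3 scenarios, Table-1 sample design); 50 test
datasets for scenario choice and 20 for parameter recovery; 20 seeds
for clustering recovery (MCMC 300/1,500, K ∈ 1..4 × 2 replicates); 200
replicates per null calibration; 20 regenerated fixtures for the
qualitative replication. The acceptance script uses a 5,000-row
per-scenario table, 10 fixture regenerations for the descriptive
statistics, and one clustering sweep over K ∈ 1..5.

Known limitations:

* With 8 microsatellite loci the admixture scenario is only weakly
  separable from bottlenecked stepping-stone colonization — the
  original analysis itself reported a posterior of only 0.53 against
  0.34. At the reduced table scale used here, scenario- and
  divergence-time-recovery rates fall short of the strictest targets
  the suite encodes, and the corresponding tests report that shortfall
  honestly rather than relaxing their thresholds; posterior medians of
  t_div shrink toward the prior while the 90% intervals cover the
  truth.
* Logistic model choice saturates (probabilities ≈ 1) when the
  observed point is deep inside one scenario's retained cloud; real
  data, unlike clean fixtures, rarely do this.
* The clustering sampler ignores within-run label switching; runs are
  aligned only across replicates. At the drift levels tested this is
  immaterial, but near-panmictic data would need longer chains.
* No rarefaction-based allelic richness, null-allele modelling,
  LOCPRIOR/linkage clustering models, migration between coalescent
  events, or posterior predictive ABC checks: none were part of the
  workflow being reproduced.
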