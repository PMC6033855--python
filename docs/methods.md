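# Methods

## The problem

Commercial SNP arrays were designed from variants discovered in small
sequencing panels (for human arrays, largely the HapMap YRI/CEU/CHB
samples) and only sites common in those panels made it onto the chip.
Statistics computed from array genotypes are therefore biased: singletons
are depleted, Tajima's D is inflated, heterozygosity and F<sub>ST</sub>
are deflated. `ascabc` treats the discovery protocol itself as part of
the generative model: simulations reproduce both a "genomic" data layer
(sequences) and an "ascertained" layer (a pseudo-array built by the
simulated discovery protocol), and Approximate Bayesian Computation
jointly infers the protocol's parameters and the demography.

## Demographic models

Two models are built in. The **Out-of-Africa model** has three sampled
populations (YRI, CEU, CHB) with constant diploid sizes N<sub>YRI</sub>,
N<sub>CEU</sub>, N<sub>CHB</sub>; backward in time CHB merges into CEU at
T<sub>EU_AS</sub> (the Eurasian ancestor has size N<sub>EU_AS</sub>), the
Eurasian lineage merges into the African lineage at T<sub>AF</sub>, and
the African size drops from N<sub>YRI</sub> to
N<sub>ANC</sub> = 10<sup>U(−1,0)</sup>·N<sub>YRI</sub> at T<sub>GROWTH</sub>
(instantaneous growth forward in time). The **admixture model** adds IBS
(split from CEU at T<sub>CEU_IBS</sub>), NXP (split from CHB at
T<sub>CHB_NXP</sub>) and MXL, created T<sub>ADM</sub> generations ago by a
single-generation pulse taking a fraction P<sub>ADM</sub> of its ancestry
from IBS and 1−P<sub>ADM</sub> from NXP. Migration and exponential growth
are deliberately excluded: the models are the smallest that reproduce the
observed summary statistics, and every extra parameter weakens ABC.

Times are stored in generations and converted to years only at report
time, with a fixed generation time of 25 years. T<sub>GROWTH</sub> and
N<sub>ANC</sub> are simulated but excluded from inference — recovery
studies show essentially no power for them at this data scale, so
reporting a posterior would be noise. Priors whose upper bound is another
parameter (T<sub>CEU_IBS</sub>, T<sub>CHB_NXP</sub> ≤ T<sub>EU_AS</sub>)
are sampled conditionally after it within the same vector. All discrete
time priors are inclusive of both endpoints; the admixture-time prior is
read as discrete uniform like every other time prior. The admixture pulse
is modeled as a single generation; spreading it over a few generations is
indistinguishable at these time scales.

## Coalescent simulation

The default backend is a Hudson coalescent without recombination,
implemented here: within each population k lineages coalesce at rate
k(k−1)/(4N) per generation, demographic events apply backward in time,
and mutations fall on branches as a Poisson process with rate μ per bp
per generation under the infinite-sites model, with positions uniform on
the locus. Only segregating sites are emitted, and every matrix row
carries a population label. Defaults are μ = 2.5×10⁻⁸/bp/generation and
ρ = 0; both are configurable. The same models translate mechanically to
`msprime` (mass migrations, binary infinite-sites mutations), which the
test suite uses as an independent cross-check of the builtin engine and
which supports recombination when needed. ms/MaCS-style simulator output
(`segsites:`/`positions:` blocks) parses into the same matrix type, so an
external recombining simulator can feed the pipeline.

Reproducibility is structural: per-locus generators are keyed by
(master seed, CRC32 of the locus id), per-row seeds by (master seed, row
index), and resimulation sub-seeds additionally by the attempt number.
Tables are therefore bit-identical for any worker count, and permuting
the loci list permutes the outputs.

## Ascertainment model

Each simulated locus carries the observed sample plus extra haplotypes
for the discovery panel (panel sizes are parameters of the inference, so
the simulated sample per discovery population is observed + panel). The
protocol is: draw the panel without replacement, compute each site's
minor-allele frequency in the pooled panel, keep sites whose MAF
*strictly* exceeds the cut-off, then assign kept sites to the array
manifest's positions greedily in ascending manifest order, each manifest
position taking the unassigned candidate with the smallest physical
distance (ties go to the smaller position). The assignment is injective
and deterministic; on small instances it occasionally exceeds the
exhaustive minimal-displacement optimum (roughly one instance in six in
randomized checks), which is accepted — the goal is a pseudo-array with
similar spacing, not an optimal transport plan. When fewer candidates
than manifest positions exist, the locus is resimulated with the same
parameters under a fresh sub-seed (panel redrawn too), up to 20 retries,
after which the locus is flagged short and kept with as many sites as it
has. The pooled-panel MAF rule is the default; a per-population variant
("any population exceeds the cut-off") sits behind a config switch, since
the historical protocols are not documented precisely enough to decide.

Observed array genotypes are already ascertained, so the observed-data
path applies no further protocol: array VCF records are only intersected
with the loci.

## Summary statistics

Per population and locus: segregating sites, singletons, doubletons
(counted on the folded minor allele — ancestral states are unavailable
for array data, and folding keeps simulated and observed layers
comparable), Tajima's D (standard 1989 constants; undefined when S = 0),
the number of distinct haplotypes and the count of the most frequent
haplotype. Per population pair: F<sub>ST</sub> — Hudson's estimator in
ratio-of-averages form by default, Weir & Cockerham behind a switch — and
shared/private haplotype counts. Statistics are computed on both layers
for the sequenced populations and on the ascertained layer only for
populations with array data alone (IBS/MXL/NXP in the admixture model).
Cross-locus aggregation records the mean and sample SD of each statistic,
excluding undefined values and logging exclusion counts; zero-variance
columns are dropped at standardization. A reduced "wollstein" schema
(cross-locus means of segregating sites, F<sub>ST</sub>, distinct
haplotypes and the most-frequent-haplotype count) is available for
comparisons with the older two-stage approach.

## ABC, dimension reduction and posterior summaries

Simulated statistics are standardized (mean/SD over the table; the
observed vector uses the table's constants). A Partial Least Squares
regression of the inferred parameters on the standardized statistics
(scikit-learn, SIMPLS-equivalent; fitted on a training subset of up to
10,000 rows for speed, applied to all rows) projects vectors into
component space. Rejection keeps the n rows nearest the observed vector
in Euclidean distance, ties broken by row index. Parameters with
log10-uniform priors are inferred on the log10 scale throughout and
reported on both scales.

Each retained sample is summarized by a Gaussian KDE (Silverman
bandwidth) weighted by an Epanechnikov kernel in the retained distances
(bandwidth = the largest retained distance; equal distances degrade to
uniform weights), evaluated on a 512-point grid over the prior support
with boundary reflection (plain Gaussian kernels leak mass past the hard
prior bounds and bias edge densities), then renormalized. The mode is
the grid argmax; the 95% HPDI is the shortest grid interval holding at
least 95% of the mass — for a unimodal density this is the
highest-density interval, and unlike a density-sorted cell set it stays
well defined when the posterior is flat (near-minimal-width ties are
broken toward equal endpoint densities, the HPD boundary condition).
Degenerate retained samples (zero spread) become a point mass at the
weighted mean. A Beaumont-style local-linear adjustment is
available behind a flag but off by default; plain rejection with the
weighted KDE is the reference estimator.

## Hyperparameter tuning

For each candidate (PLS components, retained count): bootstrap the table
(row resampling with replacement to the original size, 1000 repeats at
full scale), record the posterior modes, take their sample mean and
covariance (the covariance keeps the joint structure of the estimates;
modes are used as the point estimates, matching how results are
reported), draw 1000 parameter vectors from the corresponding
multivariate normal truncated to the prior support (discrete parameters
rounded; non-inferred parameters redrawn from their priors), simulate
each, and score the choice by the mean Euclidean distance between the
standardized observed and simulated statistics. Standardization uses the
full table's constants so scores are comparable across choices whose
draws concentrate differently. The argmin choice wins, ties going to
fewer components, then fewer retained rows. The MVN is centered at the
bootstrap mean — a center must be chosen, and the mean of modes is the
natural one. The score aggregates the 1000 per-draw distances by their
mean (the minimum is kept in diagnostics).

## Validation machinery

A pseudo-observed dataset is a table row treated as observed; the row is
removed from the inference table (leave-one-out), otherwise the
zero-distance self-match would dominate the retained set. Coverage is
the per-parameter fraction of datasets whose truth falls inside the 95%
HPDI; the ratio diagnostic is the KDE mode of posterior-mode/truth
ratios, computed on the natural (linear) scale regardless of the prior's
sampling scale, so it is invariant to log10-vs-linear storage.

### The reference recovery experiment

The built-in recovery study uses a reduced two-population clean-split
model: populations A and B split T<sub>SPLIT</sub> ∈ {200…2000}
generations ago, sizes log10-uniform on [3.8, 4.8] (6.3k–63k diploids,
bracketing the human 10⁴ scale — and large enough that a 5 kb locus
usually yields the ~5 common sites its toy manifest asks for), 10
observed haplotypes per population, a pooled discovery panel of 8
haplotypes (4 + 4) with cut-off 0.1, 30 loci of 5 kb at μ = 2.5×10⁻⁸,
a 10,000-row table, and 100 leave-one-out pseudo-observed datasets
inferred with 4 PLS components and 100 retained rows. These problem
sizes are the package's reference conditions: large enough that all
three parameters are identifiable, small enough to run on a laptop core
in minutes.

## What the synthetic data does and does not emulate

The toy manifest reproduces per-locus SNP counts (Poisson) and inter-SNP
spacing (gamma-distributed gaps, configurable shape) but not LD-based
tag-SNP selection, probe chemistry constraints, or the multi-phase
mixture of historical discovery protocols — the inference estimates an
effective single-protocol approximation by design. The coalescent layers
omit recombination within loci, sequencing error, missing genotypes and
phasing error; passing tests therefore demonstrate correctness of the
method under its own generative assumptions, not robustness to every
artifact of real array data.

## Numerical choices and degenerate inputs

- Strict inequality at the MAF cut-off (a site at exactly the cut-off is
  excluded).
- Zero-site matrices: one empty haplotype per row by convention, so
  haplotype counts are (1, n); Tajima's D and F<sub>ST</sub> carry NaN
  sentinels and are excluded from aggregation.
- Hudson F<sub>ST</sub> uses unbiased within-population heterozygosity,
  so two identical finite samples give −1/(n−1), not 0; values are
  clamped to (−1, 1].
- Rejection ties break by row index; KDE support is the prior interval;
  densities renormalize by trapezoid to 1 within 10⁻⁶.
- PLS with a constant response (possible in degenerate bootstrap tables)
  yields zero rotations; rejection then falls back to row order, which
  keeps the procedure total and deterministic.
- The 1-based-inclusive BED heuristic only warns (lengths ending in 9);
  it never modifies data.

## Known limitations

No recombination in the builtin backend (use the msprime backend or an
external ms-format simulator); no migration or continuous growth in the
built-in models; no model choice, SMC-ABC or joint-SFS statistics; the
full-scale published analyses (10⁶ simulations on real array data) are
out of reach of the bundled toy conditions, which validate the machinery
rather than reproduce real-data posteriors.
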