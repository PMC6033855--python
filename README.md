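# ascabc

Ascertainment-aware Approximate Bayesian Computation for demographic
inference from SNP-array data.

## Why

SNP arrays were built from variants discovered in small sequencing panels,
keeping only sites common in those panels. Statistics computed from array
genotypes are therefore systematically biased — Tajima's D is inflated,
singletons, heterozygosity and F<sub>ST</sub> are depleted — and so are
demographic inferences that ignore this. `ascabc` makes the discovery
protocol part of the model: every simulation draws demographic parameters
*and* ascertainment parameters (discovery-panel sizes n<sub>YRI</sub>,
n<sub>CEU</sub>, n<sub>CHB</sub> and a minor-allele-frequency cut-off),
builds a pseudo-array whose per-locus SNP counts and physical spacing
mirror a real array manifest, and summarizes both the genomic and the
ascertained data layers. Rejection ABC on PLS-reduced statistics then
jointly infers protocol and demography, so array data can be used for
inference without a separate bias correction.

It is aimed at population geneticists who have array genotypes (often for
populations with no sequencing data) plus whole genomes for the discovery
populations, and at anyone who needs a transparent, fully seeded
ABC-with-ascertainment reference implementation.

## The method in brief

1. **Simulate.** For each prior draw θ = (demography, panel sizes, cut-off),
   simulate independent neutral loci under the demographic model (builtin
   Hudson coalescent, infinite sites, μ = 2.5×10⁻⁸/bp/gen by default;
   msprime and external ms-format backends available).
2. **Ascertain.** Draw the discovery panel, keep sites with pooled-panel
   MAF > cut-off, and match them to the array manifest's positions
   (greedy nearest-position, injective); resimulate a locus that yields
   too few candidate sites.
3. **Summarize.** Per population: segregating sites, singletons,
   doubletons, Tajima's D, distinct-haplotype and most-frequent-haplotype
   counts; per pair: Hudson's F<sub>ST</sub>, shared/private haplotypes —
   each on the genomic and the ascertained layer, aggregated to means and
   SDs across loci.
4. **Infer.** Standardize, project onto Partial Least Squares components
   of the parameters, retain the simulations nearest the observed vector,
   and summarize each parameter by an Epanechnikov-weighted KDE, its
   posterior mode and 95% highest-posterior-density interval. A
   bootstrap-covariance loop selects the number of PLS components and
   retained simulations; pseudo-observed datasets validate coverage and
   bias.

Built-in models: a three-population Out-of-Africa divergence model
(YRI/CEU/CHB) and its extension with IBS, NXP and an admixed Mexican
population (admixture time T<sub>ADM</sub> and European proportion
P<sub>ADM</sub>). Times are in generations (25 years/generation at report
time). See `docs/methods.md` for the full model and every numerical
choice.

## Worked example

Simulate a table under the reduced two-population split model (sizes
N<sub>A</sub>, N<sub>B</sub> and split time T<sub>SPLIT</sub> inferred;
the discovery panel is 8 haplotypes with cut-off 0.1), then treat one row
as observed data and infer its parameters from the rest:

```python
from ascabc import (two_population_toy_spec, build_simulation_table,
                    generate_toy_loci, generate_toy_manifest, estimate)
from ascabc.validation import make_pseudo_observed

spec = two_population_toy_spec()
loci = generate_toy_loci(30, length=5000)
manifest = generate_toy_manifest(loci, 5.0, seed=2, min_snps=1)
table = build_simulation_table(spec, 1500, loci, manifest, seed=7)

obs, truth, rest = make_pseudo_observed(table, 7)
result = estimate(rest, obs, choice=(4, 100), priors=spec.priors)
for name, p in result.params.items():
    print(name, truth[name], p.mode, (p.hpdi_lower, p.hpdi_upper))
```

Output (diploid sizes, generations):

```
parameter     truth      mode              95% HPDI
NA            35527     30960     [   21396,    48584]
NB            24486     63096     [    9423,    63096]
TSPLIT         1312      2000     [     447,     2000]
```

Every true value falls inside its 95% HPDI. N<sub>A</sub> is estimated
cleanly; N<sub>B</sub> is only weakly identified (the ancestral lineage
carries A's size, so B's size matters only since the split) — its
posterior is broad and its mode sits at the prior's upper edge at this
small table size. The validation study below, at 10,000 rows and 100
pseudo-observed datasets, shows near-nominal HPDI coverage and
ratio-distribution modes near 1 for all three parameters. The same pipeline runs from the shell:

```bash
ascabc fixtures --model two_pop_toy --n-loci 30 --seed 4 --out fix/
ascabc simulate --config cfg.yaml --out run/
ascabc infer --config cfg.yaml --table run/simulations.tsv \
             --observed fix/pseudo_observed/observed_stats.tsv --out post/
```

with `tune` (bootstrap-covariance hyperparameter selection), `stats`
(observed vector from phased VCFs) and `validate` (coverage/ratio report)
completing the workflow.

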