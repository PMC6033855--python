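"""Orchestration: one simulation = prior draw -> coalescent dataset ->
discovery-panel ascertainment -> summary-statistic vector.

A :class:`ModelSpec` bundles everything one demographic scenario needs:
its priors, how a parameter vector becomes a
:class:`~ascabc.demography.DemographicModel`, which populations form the
discovery panel (and where their panel sizes come from), the observed
sample sizes the statistics are computed on, and the statistic schema.

Discovery-panel haplotypes are simulated on top of the observed sample
(panel sizes are parameters, so the simulated sample per discovery
population is observed + panel); statistics always use the fixed observed
rows so their sampling properties do not drift with the panel-size draw.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .abc_core import SimulationTable
from .ascertainment import ArrayManifest, AscertainedLocus, DiscoveryConfig, ascertain_locus
from .coalsim import HaplotypeMatrix, SimulationConfig, locus_rng, simulate_locus
from .demography import (
    DemographicModel,
    ParameterPrior,
    PopulationSplit,
    PriorSet,
    admixture_priors,
    build_admixture_model,
    build_ooa_model,
    ooa_priors,
)
from .sumstats import StatSchema, SummaryStatVector, assemble_vector, compute_locus_stats

__all__ = [
    "ModelSpec",
    "ooa_spec",
    "admixture_spec",
    "two_population_toy_spec",
    "simulate_stats_row",
    "build_simulation_table",
    "observed_vector_from_matrices",
]


@dataclass
class ModelSpec:
    """One demographic scenario, ready for table building and inference."""

    kind: str
    priors: PriorSet
    schema: StatSchema
    observed_samples: dict[str, int]
    build_model: Callable[[Mapping[str, float], Mapping[str, int]], DemographicModel]
    discovery: Callable[[Mapping[str, float]], DiscoveryConfig]
    sim_config: SimulationConfig = field(default_factory=SimulationConfig)

    def simulation_samples(self, params: Mapping[str, float]) -> dict[str, int]:
        """Haplotypes to simulate per population: observed + panel."""
        panel = self.discovery(params).panel_sizes
        return {
            pop: n + int(panel.get(pop, 0))
            for pop, n in self.observed_samples.items()
        }


def _hapmap_discovery(params: Mapping[str, float]) -> DiscoveryConfig:
    return DiscoveryConfig(
        panel_sizes={"YRI": int(params["nYRI"]), "CEU": int(params["nCEU"]),
                     "CHB": int(params["nCHB"])},
        cutoff=float(params["CUTOFF"]),
    )


def ooa_spec(sim_config: SimulationConfig | None = None) -> ModelSpec:
    """Out-of-Africa model: 9+9+4 diploid observed samples, HapMap
    discovery panel with panel sizes and cut-off drawn from the priors."""
    return ModelSpec(
        kind="ooa",
        priors=ooa_priors(),
        schema=StatSchema.for_model("ooa"),
        observed_samples={"YRI": 18, "CEU": 18, "CHB": 8},
        build_model=lambda p, s: build_ooa_model(p, samples=s),
        discovery=_hapmap_discovery,
        sim_config=sim_config or SimulationConfig(locus_length=10_000),
    )


def admixture_spec(sim_config: SimulationConfig | None = None) -> ModelSpec:
    """Mexican admixture model; IBS/MXL/NXP carry ascertained-layer
    statistics only (array genotypes are all that exists for them)."""
    return ModelSpec(
        kind="admixture",
        priors=admixture_priors(),
        schema=StatSchema.for_model("admixture"),
        observed_samples={"YRI": 18, "CEU": 18, "CHB": 8,
                          "IBS": 324, "MXL": 208, "NXP": 44},
        build_model=lambda p, s: build_admixture_model(p, samples=s),
        discovery=_hapmap_discovery,
        sim_config=sim_config or SimulationConfig(locus_length=10_000),
    )


def two_population_toy_spec() -> ModelSpec:
    """Reduced two-population clean-split model used for validation studies.

    Populations A and B split TSPLIT generations ago (ancestor keeps A's
    size); sizes are log10-uniform on [3.8, 4.8] (6.3k-63k diploids, around
    the human 10^4 scale), the split time discrete-uniform on [200, 2000]
    generations.  10 observed haplotypes per population, a fixed pooled
    discovery panel of 8 haplotypes (4 + 4) with MAF cut-off 0.1, and 5 kb
    loci at mu = 2.5e-8.
    """
    priors = PriorSet([
        ParameterPrior("NA", "log10_uniform", 3.8, 4.8),
        ParameterPrior("NB", "log10_uniform", 3.8, 4.8),
        ParameterPrior("TSPLIT", "discrete_uniform", 200, 2000),
    ])

    def build(params: Mapping[str, float], samples: Mapping[str, int]) -> DemographicModel:
        return DemographicModel(
            populations={"A": params["NA"], "B": params["NB"]},
            events=[PopulationSplit(params["TSPLIT"], "B", "A")],
            samples=dict(samples),
        )

    return ModelSpec(
        kind="two_pop_toy",
        priors=priors,
        schema=StatSchema.two_population("A", "B"),
        observed_samples={"A": 10, "B": 10},
        build_model=build,
        discovery=lambda p: DiscoveryConfig(panel_sizes={"A": 4, "B": 4}, cutoff=0.1),
        sim_config=SimulationConfig(locus_length=5_000),
    )


@dataclass
class RowDiagnostics:
    retries: int = 0
    short_loci: int = 0


def simulate_stats_row(
    spec: ModelSpec,
    params: Mapping[str, float],
    loci: Sequence,
    manifest: ArrayManifest,
    seed: int,
    max_retries: int = 20,
) -> tuple[SummaryStatVector, RowDiagnostics]:
    """Run one full simulation (all loci) and return its statistic vector.

    Per-locus randomness is keyed by (seed, locus id); resimulation after
    an insufficient-sites signal uses sub-seeds keyed additionally by the
    attempt number.
    """
    samples = spec.simulation_samples(params)
    model = spec.build_model(params, samples)
    disc = spec.discovery(params)
    obs_rows = _observed_rows(spec, samples)
    diag = RowDiagnostics()
    locus_stats = []
    for locus in loci:
        locus_id = getattr(locus, "id", locus)
        length = getattr(locus, "length", spec.sim_config.locus_length)
        cfg = replace(spec.sim_config, locus_length=int(length))
        rng = locus_rng(seed, locus_id)
        H = simulate_locus(model, cfg, rng)

        def resim(attempt: int, _id=locus_id, _cfg=cfg) -> HaplotypeMatrix:
            key = zlib.crc32(f"retry:{_id}:{attempt}".encode())
            sub = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key])
            ))
            return simulate_locus(model, _cfg, sub)

        asc = ascertain_locus(
            H, str(locus_id), manifest[str(locus_id)] if str(locus_id) in manifest else [],
            disc, rng, resimulate=resim, max_retries=max_retries,
        )
        diag.retries += asc.retry_count
        diag.short_loci += int(asc.short)
        locus_stats.append(
            compute_locus_stats(asc.haplotypes, asc.site_indices, spec.schema,
                                rows_by_pop=obs_rows)
        )
    return assemble_vector(spec.schema, locus_stats), diag


def _observed_rows(spec: ModelSpec, samples: Mapping[str, int]) -> dict[str, np.ndarray]:
    """First observed_samples[pop] rows of each population block (builtin
    and msprime backends both lay rows out contiguously per population in
    model.samples order)."""
    rows: dict[str, np.ndarray] = {}
    offset = 0
    for pop, n_total in samples.items():
        n_obs = spec.observed_samples[pop]
        rows[pop] = np.arange(offset, offset + n_obs)
        offset += n_total
    return rows


def _row_seed(master_seed: int, row: int) -> int:
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, int(row)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] >> 1)


def _one_row(spec, loci, manifest, master_seed, row, max_retries):
    seed = _row_seed(master_seed, row)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    params = spec.priors.sample_vector(rng)
    vec, diag = simulate_stats_row(spec, params, loci, manifest, seed,
                                   max_retries=max_retries)
    return seed, params, vec, diag


def build_simulation_table(
    spec: ModelSpec,
    n_rows: int,
    loci: Sequence,
    manifest: ArrayManifest,
    seed: int,
    n_jobs: int = 1,
    max_retries: int = 20,
    progress: bool = False,
) -> SimulationTable:
    """Draw ``n_rows`` parameter vectors from the priors and simulate each.

    Rows are independent with per-row seeds derived from the master seed
    and the row index, so results are identical for any ``n_jobs``.
    """
    rows = range(n_rows)
    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_one_row)(spec, loci, manifest, seed, r, max_retries)
            for r in rows
        )
    else:
        results = []
        for r in rows:
            results.append(_one_row(spec, loci, manifest, seed, r, max_retries))
            if progress and (r + 1) % 500 == 0:
                print(f"  simulated {r + 1}/{n_rows} rows", flush=True)
    seeds = np.array([r[0] for r in results], dtype=np.int64)
    params = pd.DataFrame([r[1] for r in results])
    stat_names = results[0][2].names
    stats = pd.DataFrame(
        np.vstack([r[2].values for r in results]), columns=stat_names
    )
    return SimulationTable(params, stats, seeds, model_kind=spec.kind,
                           stat_names=list(stat_names))


def observed_vector_from_matrices(
    schema: StatSchema,
    genomic_by_locus: Mapping[str, HaplotypeMatrix],
    ascertained_by_locus: Mapping[str, HaplotypeMatrix],
) -> SummaryStatVector:
    """Observed summary vector from per-locus matrices.

    The genomic layer comes from sequence data, the ascertained layer from
    array genotypes restricted to the loci (observed array data is already
    ascertained; no further protocol is applied).  Loci present in both
    mappings are used, in the genomic mapping's order.
    """
    from .sumstats import locus_stats_from_layers

    locus_stats = []
    for locus_id, G in genomic_by_locus.items():
        if locus_id not in ascertained_by_locus:
            continue
        layers = {"genomic": G, "ascertained": ascertained_by_locus[locus_id]}
        locus_stats.append(locus_stats_from_layers(layers, schema))
    if len(locus_stats) < 2:
        raise ValueError("need at least 2 loci present in both layers")
    return assemble_vector(schema, locus_stats)
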