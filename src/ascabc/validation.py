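"""Pseudo-observed-dataset validation.

A pseudo-observed dataset is a simulation with known ("true") parameters
treated as observed data.  Running the inference on many such datasets
measures (a) HPDI coverage — how often the 95% highest-density interval
contains the truth — and (b) the distribution of posterior-mode / truth
ratios, whose kernel-density mode should sit near 1 for an unbiased,
well-identified parameter.  Ratios are always computed on the natural
(linear) scale, so they are invariant to whether a size parameter is
stored as log10 or linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .abc_core import PosteriorResult, SimulationTable, estimate
from .demography import PriorSet
from .sumstats import SummaryStatVector

__all__ = [
    "DatasetReport",
    "ValidationReport",
    "make_pseudo_observed",
    "run_recovery",
    "hpdi_coverage",
    "ratio_distribution",
    "toy_recovery_experiment",
]


@dataclass
class DatasetReport:
    """Inference outcome for one pseudo-observed dataset."""

    truth: dict[str, float]                    # natural scale
    modes: dict[str, float]                    # natural scale
    hpdi: dict[str, tuple[float, float]]       # natural scale


@dataclass
class ValidationReport:
    reports: list[DatasetReport]
    parameters: list[str]

    @property
    def n_datasets(self) -> int:
        return len(self.reports)


def make_pseudo_observed(
    table: SimulationTable,
    index: int,
) -> tuple[SummaryStatVector, dict[str, float], SimulationTable]:
    """Take table row ``index`` as a pseudo-observed dataset.

    Returns its statistics vector, its true parameters, and the table with
    that row removed (leave-one-out, so the trivial zero-distance match
    cannot dominate the retained set).
    """
    if not 0 <= index < table.n_rows:
        raise IndexError(f"row {index} out of range for {table.n_rows}-row table")
    obs = SummaryStatVector(list(table.stat_names),
                            table.stats.iloc[index].to_numpy(dtype=float))
    truth = {k: float(v) for k, v in table.params.iloc[index].items()}
    rest = np.delete(np.arange(table.n_rows), index)
    return obs, truth, table.subset(rest)


def run_recovery(
    table: SimulationTable,
    priors: PriorSet,
    choice: tuple[int, int],
    n_datasets: int,
    rng: np.random.Generator,
    inferred: Sequence[str] | None = None,
    pls_training_rows: int = 10_000,
) -> ValidationReport:
    """Leave-one-out recovery study over ``n_datasets`` table rows.

    Rows are drawn without replacement; each is treated as observed and the
    remaining table is used for inference.
    """
    if inferred is None:
        inferred = [n for n in priors.inferred_names if n in table.params.columns]
    inferred = list(inferred)
    rows = rng.choice(table.n_rows, size=n_datasets, replace=False)
    reports: list[DatasetReport] = []
    for row in rows:
        obs, truth, rest = make_pseudo_observed(table, int(row))
        result = estimate(rest, obs, choice, priors, inferred=inferred,
                          pls_training_rows=pls_training_rows, rng=rng)
        reports.append(DatasetReport(
            truth={k: truth[k] for k in inferred},
            modes={k: result.params[k].mode for k in inferred},
            hpdi={k: (result.params[k].hpdi_lower, result.params[k].hpdi_upper)
                  for k in inferred},
        ))
    return ValidationReport(reports, inferred)


def hpdi_coverage(report: ValidationReport) -> dict[str, tuple[float, float]]:
    """Per-parameter fraction of datasets whose truth lies inside the HPDI,
    with its binomial standard error."""
    if not report.reports:
        raise ValueError("no reports")
    out: dict[str, tuple[float, float]] = {}
    n = report.n_datasets
    for name in report.parameters:
        hits = sum(
            r.hpdi[name][0] <= r.truth[name] <= r.hpdi[name][1]
            for r in report.reports
        )
        frac = hits / n
        out[name] = (frac, float(np.sqrt(frac * (1 - frac) / n)))
    return out


def ratio_distribution(
    report: ValidationReport,
) -> dict[str, tuple[np.ndarray, float]]:
    """Per-parameter (mode/truth ratio samples, KDE mode of their density).

    Parameters with a zero true value in any dataset are skipped for that
    dataset.  The KDE uses the same Silverman-bandwidth Gaussian density as
    the posterior machinery.
    """
    out: dict[str, tuple[np.ndarray, float]] = {}
    for name in report.parameters:
        ratios = np.array([
            r.modes[name] / r.truth[name]
            for r in report.reports
            if r.truth[name] != 0
        ])
        if ratios.size == 0:
            continue
        out[name] = (ratios, _kde_mode(ratios))
    return out


def toy_recovery_experiment(
    seed: int,
    n_rows: int = 10_000,
    n_datasets: int = 100,
    n_loci: int = 30,
    choice: tuple[int, int] = (4, 100),
    snps_per_locus: float = 5.0,
    n_jobs: int = 1,
    progress: bool = False,
):
    """Reference recovery study on the reduced two-population split model.

    Conditions: ``n_loci`` 5 kb loci, a toy array manifest of about
    ``snps_per_locus`` SNPs per locus (at least one), an ``n_rows``-row
    simulation table under the toy priors, and ``n_datasets`` leave-one-out
    pseudo-observed datasets inferred with ``choice`` = (PLS components,
    retained simulations).  Returns (report, coverage, ratios).
    """
    from .io_cli import generate_toy_loci, generate_toy_manifest
    from .pipeline import build_simulation_table, two_population_toy_spec

    spec = two_population_toy_spec()
    loci = generate_toy_loci(n_loci, length=spec.sim_config.locus_length)
    manifest = generate_toy_manifest(loci, snps_per_locus,
                                     seed=(int(seed) + 1) & 0x7FFFFFFF, min_snps=1)
    table = build_simulation_table(spec, n_rows, loci, manifest, seed=int(seed),
                                   n_jobs=n_jobs, progress=progress)
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x7A1])
    ))
    report = run_recovery(table, spec.priors, choice, n_datasets, rng)
    return report, hpdi_coverage(report), ratio_distribution(report)


def _kde_mode(samples: np.ndarray, grid_size: int = 512) -> float:
    samples = np.asarray(samples, dtype=float)
    if samples.size == 1 or np.ptp(samples) < 1e-12:
        return float(samples[0])
    kde = gaussian_kde(samples, bw_method="silverman")
    grid = np.linspace(samples.min(), samples.max(), grid_size)
    return float(grid[int(np.argmax(kde(grid)))])
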