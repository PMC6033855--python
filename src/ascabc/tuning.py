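"""Hyperparameter selection for the ABC step.

For each candidate (number of PLS components, number of retained
simulations): resample the simulation table with replacement, re-estimate
the posterior modes many times, take the bootstrap mean and covariance of
those modes (preserving the joint structure of the estimates), draw
parameter vectors from the corresponding multivariate normal truncated to
the prior support, simulate each and score the choice by the mean
standardized Euclidean distance between the simulated and observed summary
statistics.  The choice minimizing that distance wins.

All steps run on the sampling scale (log10 for log-uniform priors), where
the priors are uniform and the MVN approximation is sensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .abc_core import SimulationTable, estimate, standardize
from .ascertainment import ArrayManifest
from .demography import PriorSet
from .pipeline import ModelSpec, simulate_stats_row
from .sumstats import SummaryStatVector

__all__ = [
    "TuningChoice",
    "bootstrap_point_estimates",
    "estimate_covariance",
    "draw_parameter_vectors",
    "score_choice",
    "select_hyperparameters",
]


@dataclass
class TuningChoice:
    """A candidate hyperparameter pair and its distance score."""

    n_pls: int
    n_retain: int
    score: float
    per_draw_distances: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.n_pls < 1 or self.n_retain < 10:
            raise ValueError("need n_pls >= 1 and n_retain >= 10")


def bootstrap_point_estimates(
    table: SimulationTable,
    observed: SummaryStatVector,
    choice: tuple[int, int],
    priors: PriorSet,
    n_boot: int,
    rng: np.random.Generator,
    inferred: Sequence[str] | None = None,
    pls_training_rows: int = 10_000,
) -> tuple[np.ndarray, list[str]]:
    """(n_boot x n_inferred) matrix of posterior modes on the sampling
    scale; each repeat resamples table rows with replacement to the
    original row count and re-runs the full estimate."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if inferred is None:
        inferred = [n for n in priors.inferred_names if n in table.params.columns]
    modes = np.empty((n_boot, len(inferred)))
    for b in range(n_boot):
        rows = rng.integers(0, table.n_rows, size=table.n_rows)
        sub = table.subset(rows, reseed=True)
        try:
            result = estimate(sub, observed, choice, priors, inferred=inferred,
                              pls_training_rows=pls_training_rows, rng=rng)
        except Exception as exc:
            raise RuntimeError(f"bootstrap repeat {b} failed") from exc
        sampling_modes = result.modes(sampling_scale=True)
        modes[b] = [sampling_modes[n] for n in inferred]
    return modes, list(inferred)


def estimate_covariance(estimates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and covariance over bootstrap repeats; the covariance is
    symmetrized and eigenvalue-floored at zero so it is always PSD."""
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    if estimates.shape[0] < 2:
        raise ValueError("need at least 2 repeats")
    mean = estimates.mean(axis=0)
    cov = np.atleast_2d(np.cov(estimates, rowvar=False, ddof=1))
    cov = (cov + cov.T) / 2.0
    vals = np.linalg.eigvalsh(cov)
    if vals.min() < 0:  # floor only when numerically indefinite
        v, vecs = np.linalg.eigh(cov)
        cov = (vecs * np.maximum(v, 0.0)) @ vecs.T
        cov = (cov + cov.T) / 2.0
    return mean, cov


def draw_parameter_vectors(
    mean: np.ndarray,
    covariance: np.ndarray,
    n_draws: int,
    priors: PriorSet,
    rng: np.random.Generator,
    inferred: Sequence[str] | None = None,
    max_oversample: int = 100,
) -> list[dict[str, float]]:
    """Multivariate-normal draws (sampling scale) truncated to the prior
    support, returned as full natural-scale parameter vectors.

    Draws outside the support are rejected and redrawn, up to
    ``max_oversample`` times the requested count.  Discrete parameters are
    rounded to the nearest integer in support.  Non-inferred parameters
    (and derived ones) are drawn fresh from their priors per vector.
    """
    if inferred is None:
        inferred = priors.inferred_names
    inferred = list(inferred)
    mean = np.asarray(mean, dtype=float)
    covariance = np.atleast_2d(np.asarray(covariance, dtype=float))
    accepted: list[np.ndarray] = []
    drawn_total = 0
    while len(accepted) < n_draws:
        batch = max(n_draws - len(accepted), 64)
        drawn_total += batch
        if drawn_total > max_oversample * n_draws:
            raise RuntimeError(
                "prior support too improbable under the bootstrap MVN"
            )
        draws = rng.multivariate_normal(mean, covariance, size=batch,
                                        method="eigh")
        for row in draws:
            values: dict[str, float] = {}
            ok = True
            for j, name in enumerate(inferred):
                prior = priors[name]
                v = float(row[j])
                if prior.kind == "discrete_uniform":
                    v = float(np.rint(v))
                lo, hi = prior.sampling_support(values)
                if not (np.isfinite(hi) and lo <= v <= hi):
                    ok = False
                    break
                values[name] = v
            if ok:
                accepted.append(np.array([values[n] for n in inferred]))
            if len(accepted) == n_draws:
                break
    out: list[dict[str, float]] = []
    for row in accepted:
        vec: dict[str, float] = {}
        for prior in priors.priors:
            if prior.name in inferred:
                v = row[inferred.index(prior.name)]
                vec[prior.name] = prior.from_sampling_scale(float(v))
            else:
                from .demography import sample_from_prior
                # context carries natural values for derived/referenced priors
                vec[prior.name] = sample_from_prior(prior, rng, context=vec)
        out.append(vec)
    return out


def score_choice(
    vectors: Sequence[Mapping[str, float]],
    observed: SummaryStatVector,
    spec: ModelSpec,
    loci: Sequence,
    manifest: ArrayManifest,
    seed: int,
    constants=None,
) -> tuple[float, np.ndarray, int]:
    """Mean standardized Euclidean distance between the observed vector and
    datasets simulated at each parameter vector.

    ``constants`` supplies the standardization frame (normally the full
    simulation table's, so scores are comparable across hyperparameter
    choices whose posterior draws concentrate differently); without it the
    constants come from the scoring batch itself.  Failed simulations are
    skipped and counted.
    """
    if not len(vectors):
        raise ValueError("vector list must be nonempty")
    stats_rows = []
    n_skipped = 0
    for i, params in enumerate(vectors):
        try:
            vec, _ = simulate_stats_row(spec, params, loci, manifest,
                                        seed=_score_seed(seed, i))
            stats_rows.append(vec.values)
        except Exception:
            n_skipped += 1
    if not stats_rows:
        raise RuntimeError("all scoring simulations failed")
    X = np.vstack(stats_rows)
    if constants is None:
        Z, constants = standardize(X, names=observed.names)
    else:
        Z, _ = standardize(X, names=observed.names, constants=constants)
    obs_z, _ = standardize(observed.values.reshape(1, -1), names=observed.names,
                           constants=constants)
    distances = np.sqrt(((Z - obs_z.ravel()) ** 2).sum(axis=1))
    return float(distances.mean()), distances, n_skipped


def _score_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5C0, int(index)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] >> 1)


def select_hyperparameters(
    grid: Sequence[tuple[int, int]],
    table: SimulationTable,
    observed: SummaryStatVector,
    spec: ModelSpec,
    loci: Sequence,
    manifest: ArrayManifest,
    seed: int,
    n_boot: int = 1000,
    n_draws: int = 1000,
    pls_training_rows: int = 10_000,
) -> TuningChoice:
    """Run the full bootstrap-covariance loop per grid cell and return the
    argmin-score choice (ties: smaller n_pls, then smaller n_retain)."""
    if not len(grid):
        raise ValueError("grid must be nonempty")
    _, table_constants = standardize(table.stats)
    results: list[TuningChoice] = []
    for n_pls, n_retain in sorted(grid):
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, n_pls, n_retain])
        ))
        modes, inferred = bootstrap_point_estimates(
            table, observed, (n_pls, n_retain), spec.priors, n_boot, rng,
            pls_training_rows=pls_training_rows,
        )
        mean, cov = estimate_covariance(modes)
        vectors = draw_parameter_vectors(mean, cov, n_draws, spec.priors, rng,
                                         inferred=inferred)
        score, distances, skipped = score_choice(
            vectors, observed, spec, loci, manifest, seed,
            constants=table_constants,
        )
        results.append(TuningChoice(n_pls, n_retain, score, distances, skipped))
    return min(results, key=lambda c: (c.score, c.n_pls, c.n_retain))
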