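"""Site-frequency-spectrum and haplotype summary statistics.

Per population and locus: segregating sites, singletons, doubletons
(folded, i.e. counted on the minor allele), Tajima's D, number of distinct
haplotypes and the count of the most frequent haplotype.  Per population
pair: Hudson's FST (ratio of averages) or Weir & Cockerham's theta, and
shared/private haplotype counts.  Statistics are computed on two layers —
``genomic`` (all simulated/observed sites) and ``ascertained`` (pseudo-array
sites only) — and aggregated to means and sample standard deviations
across loci under a fixed, named schema.

Undefined values (Tajima's D with S = 0, FST with no between-population
diversity) carry a NaN sentinel and are excluded from cross-locus means;
exclusion counts are reported alongside the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coalsim import HaplotypeMatrix

__all__ = [
    "UNDEFINED",
    "per_pop_sfs_stats",
    "tajimas_d",
    "haplotype_counts",
    "pairwise_fst",
    "shared_private_haplotypes",
    "StatSchema",
    "locus_stats_from_layers",
    "compute_locus_stats",
    "aggregate",
    "assemble_vector",
    "SummaryStatVector",
]

#: Sentinel for statistics undefined on a locus.
UNDEFINED = float("nan")

POP_STATS = ("segsites", "singletons", "doubletons", "tajimas_d",
             "n_haplotypes", "max_haplotype")
PAIR_STATS = ("fst", "shared_haps", "private_haps_1", "private_haps_2")


def _allele_counts(alleles: np.ndarray) -> np.ndarray:
    return alleles.sum(axis=0).astype(np.int64)


def per_pop_sfs_stats(alleles: np.ndarray) -> tuple[int, int, int]:
    """(segregating sites, singletons, doubletons) within one population.

    ``alleles`` is the 0/1 matrix restricted to that population's rows.
    Singletons and doubletons are sites whose within-population minor-allele
    count is exactly 1 or 2.
    """
    n = alleles.shape[0]
    if n < 2:
        raise ValueError("at least 2 haplotypes required")
    ones = _allele_counts(alleles)
    minor = np.minimum(ones, n - ones)
    seg = int(np.count_nonzero((ones > 0) & (ones < n)))
    singletons = int(np.count_nonzero(minor == 1))
    # minor == 2 implies 2 <= ones <= n-2, so the site is segregating.
    doubletons = int(np.count_nonzero(minor == 2))
    return seg, singletons, doubletons


def _pairwise_pi(alleles: np.ndarray) -> float:
    """Mean pairwise difference (sum over sites) within a sample."""
    n = alleles.shape[0]
    ones = _allele_counts(alleles)
    return float(np.sum(ones * (n - ones)) / (n * (n - 1) / 2.0))


def tajimas_d(alleles: np.ndarray) -> float:
    """Tajima's (1989) D for one population; NaN when S = 0.

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the standard constants
    a1, a2, b1, b2, c1, c2, e1, e2 depending only on sample size n.
    """
    n = alleles.shape[0]
    if n < 2:
        raise ValueError("at least 2 haplotypes required")
    ones = _allele_counts(alleles)
    seg_mask = (ones > 0) & (ones < n)
    S = int(np.count_nonzero(seg_mask))
    if S == 0:
        return UNDEFINED
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = _pairwise_pi(alleles)
    denom = np.sqrt(e1 * S + e2 * S * (S - 1.0))
    if denom == 0:
        return UNDEFINED
    return float((pi - S / a1) / denom)


def _haplotype_keys(alleles: np.ndarray) -> np.ndarray:
    """Integer key per row for exact haplotype-string comparison."""
    if alleles.shape[1] == 0:
        return np.zeros(alleles.shape[0], dtype=np.int64)
    contiguous = np.ascontiguousarray(alleles, dtype=np.uint8)
    view = contiguous.view(np.dtype((np.void, contiguous.shape[1])))
    _, keys = np.unique(view.ravel(), return_inverse=True)
    return keys


def haplotype_counts(alleles: np.ndarray) -> tuple[int, int]:
    """(number of distinct haplotypes, count of the most frequent one).

    With zero sites every row is the single empty haplotype: (1, n).
    """
    n = alleles.shape[0]
    if n < 1:
        raise ValueError("at least 1 haplotype required")
    if alleles.shape[1] == 0:
        return 1, n
    keys = _haplotype_keys(alleles)
    counts = np.bincount(keys)
    return int(counts.size), int(counts.max())


def pairwise_fst(
    alleles1: np.ndarray,
    alleles2: np.ndarray,
    estimator: str = "hudson",
) -> float:
    """FST between two populations sharing the same site set.

    Hudson's estimator in ratio-of-averages form (Bhatia et al. style):
    F = 1 - mean(Hw) / mean(Hb), where per site Hw is the average of the
    two unbiased within-population heterozygosities and Hb = p1*q2 + p2*q1.
    NaN when between-population diversity is zero at every site.  Result
    clamped to (-1, 1].
    """
    n1, n2 = alleles1.shape[0], alleles2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("both populations need >= 2 haplotypes")
    if alleles1.shape[1] != alleles2.shape[1]:
        raise ValueError("populations must share the same sites")
    if alleles1.shape[1] == 0:
        return UNDEFINED
    p1 = _allele_counts(alleles1) / n1
    p2 = _allele_counts(alleles2) / n2
    if estimator == "hudson":
        hw1 = 2.0 * p1 * (1 - p1) * n1 / (n1 - 1.0)
        hw2 = 2.0 * p2 * (1 - p2) * n2 / (n2 - 1.0)
        hw = (hw1 + hw2) / 2.0
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        if hb.sum() == 0:
            return UNDEFINED
        fst = 1.0 - hw.mean() / hb.mean()
    elif estimator == "weir_cockerham":
        fst = _weir_cockerham(p1, n1, p2, n2)
        if np.isnan(fst):
            return UNDEFINED
    else:
        raise ValueError(f"unknown FST estimator {estimator!r}")
    return float(min(max(fst, -1.0 + 1e-12), 1.0))


def _weir_cockerham(p1, n1, p2, n2) -> float:
    """Weir & Cockerham (1984) theta, haploid-allele form, two populations,
    summed over sites (ratio of sums)."""
    r = 2.0
    n_bar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - (r - 1.0) / r * s2) / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * (p_bar * (1 - p_bar) - (r - 1.0) / r * s2)
    denom = (a + b).sum()
    if denom == 0:
        return UNDEFINED
    return float(a.sum() / denom)


def shared_private_haplotypes(
    alleles1: np.ndarray, alleles2: np.ndarray
) -> tuple[int, int, int]:
    """(shared, private to pop1, private to pop2) distinct haplotypes."""
    if alleles1.shape[1] != alleles2.shape[1]:
        raise ValueError("populations must share the same sites")
    if alleles1.shape[1] == 0:
        return 1, 0, 0
    both = np.vstack([alleles1, alleles2])
    keys = _haplotype_keys(both)
    set1 = set(keys[: alleles1.shape[0]].tolist())
    set2 = set(keys[alleles1.shape[0]:].tolist())
    return (len(set1 & set2), len(set1 - set2), len(set2 - set1))


# ---------------------------------------------------------------------------
# Schema and aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatSchema:
    """Canonical ordering of the summary-statistic vector.

    ``layers_by_pop`` maps each population to the layers its per-population
    statistics are computed on; pair statistics are computed on the layers
    both members share.  The reduced ``wollstein`` variant keeps only the
    cross-locus means of segregating sites, FST, distinct haplotypes and
    most-frequent-haplotype count.
    """

    layers_by_pop: tuple[tuple[str, tuple[str, ...]], ...]
    pairs: tuple[tuple[str, str], ...]
    fst_estimator: str = "hudson"
    wollstein: bool = False

    @staticmethod
    def for_model(kind: str, wollstein: bool = False,
                  fst_estimator: str = "hudson") -> "StatSchema":
        both = ("genomic", "ascertained")
        if kind == "ooa":
            pops = [("YRI", both), ("CEU", both), ("CHB", both)]
        elif kind == "admixture":
            pops = [("YRI", both), ("CEU", both), ("CHB", both),
                    ("IBS", ("ascertained",)), ("MXL", ("ascertained",)),
                    ("NXP", ("ascertained",))]
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        names = [p for p, _ in pops]
        pairs = tuple(combinations(names, 2)) if kind == "ooa" else tuple(
            combinations(("YRI", "CEU", "CHB"), 2)
        ) + tuple(combinations(("IBS", "MXL", "NXP"), 2))
        return StatSchema(tuple((p, tuple(l)) for p, l in pops), pairs,
                          fst_estimator=fst_estimator, wollstein=wollstein)

    @staticmethod
    def two_population(pop_a: str = "A", pop_b: str = "B",
                       fst_estimator: str = "hudson") -> "StatSchema":
        both = ("genomic", "ascertained")
        return StatSchema(((pop_a, both), (pop_b, both)), ((pop_a, pop_b),),
                          fst_estimator=fst_estimator)

    def _pair_layers(self, pair: tuple[str, str]) -> tuple[str, ...]:
        by_pop = dict(self.layers_by_pop)
        return tuple(l for l in ("genomic", "ascertained")
                     if l in by_pop[pair[0]] and l in by_pop[pair[1]])

    @property
    def locus_entries(self) -> list[str]:
        """Per-locus statistic names, fixed canonical order."""
        pop_stats = POP_STATS if not self.wollstein else ("segsites", "n_haplotypes", "max_haplotype")
        pair_stats = PAIR_STATS if not self.wollstein else ("fst",)
        names = []
        for pop, layers in self.layers_by_pop:
            for layer in layers:
                for stat in pop_stats:
                    names.append(f"{layer}.{pop}.{stat}")
        for pair in self.pairs:
            for layer in self._pair_layers(pair):
                for stat in pair_stats:
                    names.append(f"{layer}.{pair[0]}-{pair[1]}.{stat}")
        return names

    @property
    def vector_entries(self) -> list[str]:
        """Aggregated vector names: mean (and SD unless reduced) per entry."""
        moments = ("mean",) if self.wollstein else ("mean", "sd")
        return [f"{name}.{m}" for name in self.locus_entries for m in moments]


def locus_stats_from_layers(
    layers: Mapping[str, HaplotypeMatrix],
    schema: StatSchema,
    rows_by_pop: Mapping[tuple[str, str], np.ndarray] | None = None,
) -> dict[str, float]:
    """Per-locus statistics from per-layer haplotype matrices.

    ``layers`` maps layer name to the matrix carrying that layer's sites
    (the two layers may hold different samples, as with observed data where
    sequences and array genotypes come from different files).
    ``rows_by_pop`` maps (layer, population) to row indices; by default each
    layer's own population labels are used.
    """
    def rows(layer: str, pop: str) -> np.ndarray:
        if rows_by_pop is not None and (layer, pop) in rows_by_pop:
            return np.asarray(rows_by_pop[(layer, pop)], dtype=int)
        return layers[layer].rows_for(pop)

    out: dict[str, float] = {}
    for pop, pop_layers in schema.layers_by_pop:
        for layer in pop_layers:
            sub = layers[layer].alleles[rows(layer, pop)]
            seg, sing, doub = per_pop_sfs_stats(sub)
            n_hap, max_hap = haplotype_counts(sub)
            vals = {
                "segsites": seg, "singletons": sing, "doubletons": doub,
                "tajimas_d": tajimas_d(sub),
                "n_haplotypes": n_hap, "max_haplotype": max_hap,
            }
            for stat in (POP_STATS if not schema.wollstein
                         else ("segsites", "n_haplotypes", "max_haplotype")):
                out[f"{layer}.{pop}.{stat}"] = float(vals[stat])
    for pair in schema.pairs:
        for layer in schema._pair_layers(pair):
            a = layers[layer].alleles[rows(layer, pair[0])]
            b = layers[layer].alleles[rows(layer, pair[1])]
            fst = pairwise_fst(a, b, estimator=schema.fst_estimator)
            out[f"{layer}.{pair[0]}-{pair[1]}.fst"] = fst
            if not schema.wollstein:
                shared, p1, p2 = shared_private_haplotypes(a, b)
                out[f"{layer}.{pair[0]}-{pair[1]}.shared_haps"] = float(shared)
                out[f"{layer}.{pair[0]}-{pair[1]}.private_haps_1"] = float(p1)
                out[f"{layer}.{pair[0]}-{pair[1]}.private_haps_2"] = float(p2)
    return out


def compute_locus_stats(
    genomic: HaplotypeMatrix,
    ascertained_sites: Sequence[int],
    schema: StatSchema,
    rows_by_pop: Mapping[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """Per-locus statistics for the simulation path: the ascertained layer
    is the genomic matrix restricted to the pseudo-array site indices.

    ``rows_by_pop`` optionally restricts each population to a fixed row
    subset (e.g. the observed sample, excluding extra panel haplotypes).
    """
    layers = {
        "genomic": genomic,
        "ascertained": genomic.take_sites(np.asarray(ascertained_sites, dtype=int)),
    }
    rows = None
    if rows_by_pop is not None:
        rows = {(layer, pop): idx
                for layer in layers
                for pop, idx in rows_by_pop.items()}
    return locus_stats_from_layers(layers, schema, rows_by_pop=rows)


@dataclass
class SummaryStatVector:
    """Ordered aggregate vector (means/SDs across loci) plus its names."""

    names: list[str]
    values: np.ndarray
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names and values must align")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def aggregate(
    locus_stats: Sequence[Mapping[str, float]],
    schema: StatSchema,
) -> SummaryStatVector:
    """Mean and sample SD of each statistic across loci.

    NaN sentinels are excluded per statistic, with exclusion counts
    recorded; a statistic undefined on every locus stays NaN (degenerate,
    to be dropped at standardization).
    """
    if len(locus_stats) < 2:
        raise ValueError("at least 2 loci required for aggregation")
    entries = schema.locus_entries
    mat = np.array([[ls[name] for name in entries] for ls in locus_stats], dtype=float)
    exclusions: dict[str, int] = {}
    names: list[str] = []
    values: list[float] = []
    moments = ("mean",) if schema.wollstein else ("mean", "sd")
    for j, name in enumerate(entries):
        col = mat[:, j]
        defined = col[~np.isnan(col)]
        n_excluded = col.shape[0] - defined.shape[0]
        if n_excluded:
            exclusions[name] = n_excluded
        for m in moments:
            names.append(f"{name}.{m}")
            if defined.shape[0] == 0:
                values.append(UNDEFINED)
            elif m == "mean":
                values.append(float(defined.mean()))
            else:
                values.append(float(defined.std(ddof=1)) if defined.shape[0] > 1 else 0.0)
    return SummaryStatVector(names, np.asarray(values), exclusions)


def assemble_vector(
    schema: StatSchema,
    locus_stats: Sequence[Mapping[str, float]],
) -> SummaryStatVector:
    """Aggregate per-locus stats into the canonical ordered vector for the
    schema (layer provenance is embedded in each entry name)."""
    vec = aggregate(locus_stats, schema)
    expected = schema.vector_entries
    if vec.names != expected:
        raise ValueError("aggregated names do not match schema ordering")
    return vec
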