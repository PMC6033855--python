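"""Coalescent simulation of haplotype matrices per locus.

Two simulation backends produce :class:`HaplotypeMatrix` objects under a
:class:`~ascabc.demography.DemographicModel`:

``builtin``
    A reference Hudson coalescent without recombination, authored here.
    Lineages coalesce within populations at rate k(k-1)/(4N) per generation
    (N diploid), demographic events (splits, size changes, admixture pulses)
    are applied backward in time, and mutations fall on branches as a
    Poisson process under the infinite-sites model with uniform positions.
``msprime``
    The same model translated to :mod:`msprime` (binary infinite-sites
    mutations, continuous genome).  Useful as an independent cross-check
    and when recombination is needed.

An adapter for external ms/MaCS-style simulators parses their text output
(`segsites:` / `positions:` blocks) into the same matrix type.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .demography import (
    AdmixturePulse,
    DemographicModel,
    PopulationSplit,
    SizeChange,
    validate_model,
)

__all__ = [
    "SimulationConfig",
    "HaplotypeMatrix",
    "CapabilityError",
    "MsParseError",
    "simulate_locus",
    "simulate_dataset",
    "parse_ms_haplotypes",
    "iter_ms_blocks",
    "to_msprime_demography",
    "locus_rng",
]


class CapabilityError(RuntimeError):
    """A backend was asked for a feature it does not support."""


class MsParseError(ValueError):
    """Malformed ms/MaCS output."""


@dataclass
class SimulationConfig:
    """Per-locus simulation settings.

    mutation_rate and recombination_rate are per bp per generation;
    locus_length in bp.  The builtin backend requires recombination_rate 0.
    """

    mutation_rate: float = 2.5e-8
    recombination_rate: float = 0.0
    locus_length: int = 10_000
    backend: str = "builtin"

    def __post_init__(self) -> None:
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.locus_length <= 0:
            raise ValueError("locus_length must be > 0")


@dataclass
class HaplotypeMatrix:
    """Binary haplotypes x segregating sites for one locus.

    ``alleles`` is an (n_haplotypes, n_sites) 0/1 array, ``positions`` holds
    strictly increasing bp offsets in [0, locus_length), and ``pop_labels``
    gives the population of each haplotype row.
    """

    alleles: np.ndarray
    positions: np.ndarray
    pop_labels: np.ndarray
    locus_length: int

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        self.pop_labels = np.asarray(self.pop_labels)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must equal number of sites")
        if self.alleles.shape[0] != self.pop_labels.shape[0]:
            raise ValueError("pop_labels length must equal number of haplotypes")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def rows_for(self, population: str) -> np.ndarray:
        """Row indices of one population, in matrix order."""
        return np.flatnonzero(self.pop_labels == population)

    def take_sites(self, site_indices: Sequence[int]) -> "HaplotypeMatrix":
        idx = np.asarray(site_indices, dtype=int)
        return HaplotypeMatrix(
            self.alleles[:, idx], self.positions[idx], self.pop_labels, self.locus_length
        )

    def take_rows(self, row_indices: Sequence[int]) -> "HaplotypeMatrix":
        idx = np.asarray(row_indices, dtype=int)
        return HaplotypeMatrix(
            self.alleles[idx], self.positions, self.pop_labels[idx], self.locus_length
        )

    def validate(self) -> list[str]:
        """Invariant violations: strictly increasing positions, in-range
        positions, every site polymorphic in the full matrix."""
        out = []
        if self.n_sites and not np.all(np.diff(self.positions) > 0):
            out.append("positions_not_increasing")
        if self.n_sites and (self.positions.min() < 0 or self.positions.max() >= self.locus_length):
            out.append("positions_out_of_range")
        if self.n_sites:
            counts = self.alleles.sum(axis=0)
            if np.any(counts == 0) or np.any(counts == self.n_haplotypes):
                out.append("monomorphic_site")
        return out


# ---------------------------------------------------------------------------
# Builtin Hudson coalescent
# ---------------------------------------------------------------------------

def _simulate_builtin(
    model: DemographicModel, config: SimulationConfig, rng: np.random.Generator
) -> HaplotypeMatrix:
    if config.recombination_rate != 0:
        raise CapabilityError("builtin backend does not support recombination")
    pops = list(model.samples)
    labels = np.concatenate([np.repeat(p, model.samples[p]) for p in pops])
    n_leaves = int(labels.shape[0])

    # active[pop] = list of lineage node ids; desc[node] = boolean leaf mask
    sizes = dict(model.populations)
    active: dict[str, list[int]] = {p: [] for p in model.populations}
    desc: list[np.ndarray] = []
    node_time: list[float] = []
    parent: list[int] = []
    nid = 0
    for row, pop in enumerate(labels):
        active[pop].append(nid)
        mask = np.zeros(n_leaves, dtype=bool)
        mask[row] = True
        desc.append(mask)
        node_time.append(0.0)
        parent.append(-1)
        nid += 1

    events = model.sorted_events()
    ei = 0
    t = 0.0
    n_active = n_leaves
    while n_active > 1:
        rates = []
        rate_pops = []
        for p in pops:
            k = len(active[p])
            if k >= 2:
                rates.append(k * (k - 1) / (4.0 * sizes[p]))
                rate_pops.append(p)
        total = float(sum(rates))
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        next_t = events[ei].time if ei < len(events) else np.inf
        if t + wait < next_t:
            t += wait
            u = rng.uniform(0.0, total)
            acc = 0.0
            pop = rate_pops[-1]
            for p, r in zip(rate_pops, rates):
                acc += r
                if u < acc:
                    pop = p
                    break
            lin = active[pop]
            i, j = rng.choice(len(lin), size=2, replace=False)
            a, b = lin[int(i)], lin[int(j)]
            for x in sorted((int(i), int(j)), reverse=True):
                lin.pop(x)
            desc.append(desc[a] | desc[b])
            node_time.append(t)
            parent.append(-1)
            parent[a] = nid
            parent[b] = nid
            lin.append(nid)
            nid += 1
            n_active -= 1
        else:
            if not np.isfinite(next_t):
                raise ValueError("model does not coalesce: disconnected populations")
            t = next_t
            while ei < len(events) and events[ei].time == t:
                ev = events[ei]
                ei += 1
                if isinstance(ev, PopulationSplit):
                    if ev.derived in active:
                        active.setdefault(ev.ancestral, [])
                        active[ev.ancestral].extend(active[ev.derived])
                        active[ev.derived] = []
                        if ev.ancestral not in pops:
                            pops.append(ev.ancestral)
                elif isinstance(ev, SizeChange):
                    sizes[ev.population] = ev.size
                elif isinstance(ev, AdmixturePulse):
                    moving = active.get(ev.derived, [])
                    active[ev.derived] = []
                    probs = np.asarray(ev.proportions, dtype=float)
                    for node in moving:
                        dest = ev.sources[int(rng.choice(len(ev.sources), p=probs))]
                        active.setdefault(dest, [])
                        active[dest].append(node)
                        if dest not in pops:
                            pops.append(dest)

    # Mutations: Poisson on total branch length (root branch excluded).
    parent_arr = np.asarray(parent)
    times = np.asarray(node_time)
    has_parent = parent_arr >= 0
    branch_nodes = np.flatnonzero(has_parent)
    lengths = times[parent_arr[branch_nodes]] - times[branch_nodes]
    total_length = float(lengths.sum())
    n_mut = int(rng.poisson(config.mutation_rate * config.locus_length * total_length))
    if n_mut == 0:
        return HaplotypeMatrix(
            np.zeros((n_leaves, 0), dtype=np.uint8),
            np.empty(0),
            labels,
            config.locus_length,
        )
    probs = lengths / total_length
    which = rng.choice(branch_nodes.shape[0], size=n_mut, p=probs)
    positions = rng.uniform(0.0, config.locus_length, size=n_mut)
    # Infinite sites: position collisions have measure zero, but guard anyway.
    while np.unique(positions).shape[0] < n_mut:
        positions = rng.uniform(0.0, config.locus_length, size=n_mut)
    order = np.argsort(positions)
    cols = [desc[int(branch_nodes[w])] for w in which]
    alleles = np.stack(cols, axis=1).astype(np.uint8)[:, order]
    return HaplotypeMatrix(alleles, positions[order], labels, config.locus_length)


# ---------------------------------------------------------------------------
# msprime backend
# ---------------------------------------------------------------------------

def to_msprime_demography(model: DemographicModel):
    """Translate a DemographicModel into an msprime.Demography.

    Splits and pulses become mass migrations (ms-style), preserving the
    exact backward-time semantics of the builtin backend.
    """
    import msprime

    dem = msprime.Demography()
    for pop, size in model.populations.items():
        dem.add_population(name=pop, initial_size=size)
    for ev in model.sorted_events():
        if isinstance(ev, PopulationSplit):
            dem.add_mass_migration(time=ev.time, source=ev.derived,
                                   dest=ev.ancestral, proportion=1.0)
        elif isinstance(ev, SizeChange):
            dem.add_population_parameters_change(
                time=ev.time, population=ev.population, initial_size=ev.size)
        elif isinstance(ev, AdmixturePulse):
            remaining = 1.0
            for src, prop in zip(ev.sources[:-1], ev.proportions[:-1]):
                dem.add_mass_migration(time=ev.time, source=ev.derived,
                                       dest=src, proportion=prop / remaining)
                remaining -= prop
            dem.add_mass_migration(time=ev.time, source=ev.derived,
                                   dest=ev.sources[-1], proportion=1.0)
    dem.sort_events()
    return dem


def _simulate_msprime(
    model: DemographicModel, config: SimulationConfig, rng: np.random.Generator
) -> HaplotypeMatrix:
    import msprime

    dem = to_msprime_demography(model)
    sample_sets = [
        msprime.SampleSet(n, population=pop, ploidy=1)
        for pop, n in model.samples.items()
    ]
    seed1, seed2 = rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        sequence_length=config.locus_length,
        recombination_rate=config.recombination_rate,
        ploidy=2,
        random_seed=int(seed1),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=int(seed2),
    )
    labels = np.concatenate([np.repeat(p, n) for p, n in model.samples.items()])
    geno = ts.genotype_matrix().T.astype(np.uint8)
    positions = np.array([s.position for s in ts.sites()])
    # Drop sites monomorphic after recurrent hits (none under infinite sites,
    # but keep the invariant robust).
    if geno.shape[1]:
        counts = geno.sum(axis=0)
        keep = (counts > 0) & (counts < geno.shape[0])
        geno, positions = geno[:, keep], positions[keep]
    return HaplotypeMatrix(geno, positions, labels, config.locus_length)


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

_BACKENDS = {"builtin": _simulate_builtin, "msprime": _simulate_msprime}


def simulate_locus(
    model: DemographicModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> HaplotypeMatrix:
    """Simulate one locus; deterministic given the generator state."""
    problems = validate_model(model)
    if problems:
        raise ValueError(f"invalid model: {problems}")
    if config.backend == "external":
        raise CapabilityError(
            "the external backend consumes ms-format text via parse_ms_haplotypes"
        )
    try:
        backend = _BACKENDS[config.backend]
    except KeyError:
        raise CapabilityError(f"unknown backend {config.backend!r}") from None
    return backend(model, config, rng)


def _stable_id_hash(locus_id) -> int:
    return zlib.crc32(str(locus_id).encode())


def locus_rng(master_seed: int, locus_id) -> np.random.Generator:
    """Per-locus generator keyed by locus id, not list position."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, _stable_id_hash(locus_id)])
    return np.random.Generator(np.random.PCG64(ss))


def simulate_dataset(
    model: DemographicModel,
    loci: Sequence,
    config: SimulationConfig,
    seed: int,
) -> list[HaplotypeMatrix]:
    """One HaplotypeMatrix per locus, in input order.

    Loci may be io_cli.Locus objects (their length overrides
    config.locus_length) or bare ids.  Per-locus seeds derive from the
    master seed and the locus id, so permuting loci permutes outputs.
    """
    if not len(loci):
        raise ValueError("loci must be nonempty")
    out = []
    for locus in loci:
        locus_id = getattr(locus, "id", locus)
        length = getattr(locus, "length", None)
        cfg = config
        if length is not None and length != config.locus_length:
            cfg = SimulationConfig(config.mutation_rate, config.recombination_rate,
                                   int(length), config.backend)
        try:
            out.append(simulate_locus(model, cfg, locus_rng(seed, locus_id)))
        except Exception as exc:
            raise RuntimeError(f"simulation failed for locus {locus_id!r}") from exc
    return out


# ---------------------------------------------------------------------------
# ms / MaCS text adapter
# ---------------------------------------------------------------------------

def parse_ms_haplotypes(
    text: str,
    locus_length: int,
    sample_layout: Sequence[tuple[str, int]],
) -> HaplotypeMatrix:
    """Parse one ms/MaCS output block into a HaplotypeMatrix.

    ``sample_layout`` lists (population, n_haplotypes) pairs in row order.
    Positions on the unit interval are scaled by ``locus_length``.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    seg = None
    positions: np.ndarray | None = None
    rows: list[str] = []
    n_expected = sum(n for _, n in sample_layout)
    for ln in lines:
        if ln.startswith("segsites:"):
            try:
                seg = int(ln.split(":", 1)[1])
            except ValueError as exc:
                raise MsParseError(f"bad segsites line: {ln!r}") from exc
        elif ln.startswith("positions:"):
            positions = np.array([float(x) for x in ln.split(":", 1)[1].split()])
        elif seg is not None and set(ln) <= {"0", "1"}:
            rows.append(ln)
    if seg is None:
        raise MsParseError("no 'segsites:' line found")
    if seg == 0:
        return HaplotypeMatrix(
            np.zeros((n_expected, 0), dtype=np.uint8),
            np.empty(0),
            np.concatenate([np.repeat(p, n) for p, n in sample_layout]),
            locus_length,
        )
    if positions is None or positions.shape[0] != seg:
        raise MsParseError("positions line missing or wrong length")
    if len(rows) < n_expected:
        raise MsParseError(f"expected {n_expected} haplotype rows, found {len(rows)}")
    rows = rows[:n_expected]
    for i, row in enumerate(rows):
        if len(row) != seg:
            raise MsParseError(f"haplotype row {i} has length {len(row)}, expected {seg}")
    alleles = np.array([[int(c) for c in row] for row in rows], dtype=np.uint8)
    labels = np.concatenate([np.repeat(p, n) for p, n in sample_layout])
    return HaplotypeMatrix(alleles, positions * locus_length, labels, locus_length)


def iter_ms_blocks(text: str) -> Iterable[str]:
    """Split multi-replicate ms output into per-replicate blocks (separated
    by '//' lines, per ms conventions)."""
    block: list[str] = []
    for ln in text.splitlines():
        if ln.strip() == "//":
            if block:
                yield "\n".join(block)
            block = []
        else:
            block.append(ln)
    if any(b.strip().startswith("segsites") for b in block):
        yield "\n".join(block)
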