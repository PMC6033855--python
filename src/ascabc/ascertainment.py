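"""SNP-array discovery-protocol model.

Array SNPs were historically found by sequencing a small discovery panel
and keeping sites whose minor-allele frequency in that panel exceeded a
cut-off.  This module reproduces that protocol on simulated loci: draw a
discovery panel of haplotypes, compute pooled-panel MAF per site, keep
sites strictly above the cut-off, and from those build a "pseudo-array"
whose per-locus site count and physical spacing mirror a real array
manifest (greedy nearest-position matching).  When a locus yields too few
candidate sites the locus is resimulated (same parameters, fresh sub-seed)
up to a retry cap, after which it is flagged short.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .coalsim import HaplotypeMatrix

__all__ = [
    "DiscoveryConfig",
    "ArrayManifest",
    "AscertainedLocus",
    "InsufficientSites",
    "draw_discovery_panel",
    "panel_maf",
    "apply_cutoff",
    "match_sites_to_manifest",
    "ascertain_locus",
]


class InsufficientSites(RuntimeError):
    """Fewer post-cutoff candidate sites than manifest positions."""


@dataclass(frozen=True)
class DiscoveryConfig:
    """Discovery panel sizes (haploid, per population) and MAF cut-off.

    ``pooled`` selects whether the cut-off applies to the pooled panel MAF
    (default) or is satisfied when any single population's panel MAF
    exceeds it.
    """

    panel_sizes: Mapping[str, int]
    cutoff: float
    pooled: bool = True

    def __post_init__(self) -> None:
        if not self.panel_sizes:
            raise ValueError("panel_sizes must be nonempty")
        if any(int(n) < 2 for n in self.panel_sizes.values()):
            raise ValueError("each panel size must be >= 2")
        if not 0.0 < self.cutoff < 0.5:
            raise ValueError("cutoff must be in (0, 0.5)")


@dataclass
class ArrayManifest:
    """Per-locus ordered SNP positions (bp offsets within each locus)."""

    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for locus_id, pos in self.positions.items():
            arr = np.asarray(pos, dtype=float)
            if arr.size and not np.all(np.diff(arr) > 0):
                raise ValueError(f"manifest positions for locus {locus_id!r} not strictly increasing")
            clean[locus_id] = arr
        self.positions = clean

    def __getitem__(self, locus_id: str) -> np.ndarray:
        return self.positions[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.positions

    def n_sites(self, locus_id: str) -> int:
        return int(self.positions.get(locus_id, np.empty(0)).shape[0])

    @property
    def total_sites(self) -> int:
        return int(sum(p.shape[0] for p in self.positions.values()))


@dataclass
class AscertainedLocus:
    """Sites of one simulated locus selected to mimic the array manifest."""

    locus_id: str
    site_indices: np.ndarray          # into the locus HaplotypeMatrix, sorted
    simulated_positions: np.ndarray   # bp, aligned with site_indices
    manifest_positions: np.ndarray    # matched manifest positions, aligned
    panel_maf: np.ndarray             # pooled-panel MAF, aligned
    panel_rows: np.ndarray            # haplotype rows forming the panel
    retry_count: int = 0
    short: bool = False
    haplotypes: HaplotypeMatrix | None = None  # matrix the indices refer to

    @property
    def n_sites(self) -> int:
        return int(self.site_indices.shape[0])


def draw_discovery_panel(
    H: HaplotypeMatrix,
    config: DiscoveryConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Without-replacement draw of panel_sizes[p] haplotype rows per
    discovery population; returns sorted row indices."""
    chosen: list[np.ndarray] = []
    for pop, n in config.panel_sizes.items():
        rows = H.rows_for(pop)
        if rows.shape[0] < n:
            raise ValueError(
                f"population {pop!r} has {rows.shape[0]} haplotypes, panel needs {n}"
            )
        chosen.append(rng.choice(rows, size=int(n), replace=False))
    return np.sort(np.concatenate(chosen))


def panel_maf(H: HaplotypeMatrix, panel: Sequence[int]) -> np.ndarray:
    """Per-site minor-allele frequency in the pooled panel rows."""
    panel = np.asarray(panel, dtype=int)
    if panel.size == 0:
        raise ValueError("panel must be nonempty")
    ones = H.alleles[panel].sum(axis=0).astype(float)
    n = float(panel.size)
    return np.minimum(ones, n - ones) / n


def apply_cutoff(mafs: np.ndarray, cutoff: float) -> np.ndarray:
    """Indices of sites whose MAF strictly exceeds the cut-off (order kept)."""
    if not 0.0 < cutoff < 0.5:
        raise ValueError("cutoff must be in (0, 0.5)")
    return np.flatnonzero(np.asarray(mafs) > cutoff)


def match_sites_to_manifest(
    candidate_positions: Sequence[float],
    manifest_positions: Sequence[float],
    allow_short: bool = False,
) -> np.ndarray:
    """Greedy injective assignment of candidates to manifest positions.

    Manifest positions are visited in ascending order; each takes the
    unassigned candidate minimizing |candidate - manifest| (ties broken by
    the smaller candidate position).  Returns candidate indices aligned
    with the manifest order; raises :class:`InsufficientSites` when
    candidates run out, unless ``allow_short`` (then the partial assignment
    is returned).
    """
    cand = np.asarray(candidate_positions, dtype=float)
    manifest = np.asarray(manifest_positions, dtype=float)
    if cand.size and np.any(np.diff(cand) < 0):
        raise ValueError("candidate positions must be sorted ascending")
    if manifest.size and np.any(np.diff(manifest) < 0):
        raise ValueError("manifest positions must be sorted ascending")
    if cand.size < manifest.size and not allow_short:
        raise InsufficientSites(
            f"{cand.size} candidates for {manifest.size} manifest positions"
        )
    free = np.ones(cand.size, dtype=bool)
    assignment: list[int] = []
    for m in manifest:
        idx = np.flatnonzero(free)
        if idx.size == 0:
            break
        dist = np.abs(cand[idx] - m)
        # argmin takes the first minimum; candidates are ascending, so the
        # first minimal distance is the smaller position.
        best = idx[int(np.argmin(dist))]
        assignment.append(int(best))
        free[best] = False
    return np.asarray(assignment, dtype=int)


def ascertain_locus(
    H: HaplotypeMatrix,
    locus_id: str,
    manifest_positions: Sequence[float],
    config: DiscoveryConfig,
    rng: np.random.Generator,
    resimulate: Callable[[int], HaplotypeMatrix] | None = None,
    max_retries: int = 20,
) -> AscertainedLocus:
    """Panel draw -> MAF -> cut-off -> manifest matching, with resimulation.

    ``resimulate(attempt)`` must return a fresh HaplotypeMatrix for the same
    parameters under a new sub-seed; the panel is redrawn on each attempt.
    After ``max_retries`` failed attempts the best-effort assignment of the
    last matrix is returned with ``short=True``.  The returned object's
    ``haplotypes`` field holds the matrix the site indices refer to (it may
    differ from the input after resimulation).
    """
    manifest = np.asarray(manifest_positions, dtype=float)
    if manifest.size == 0:
        return AscertainedLocus(
            locus_id, np.empty(0, int), np.empty(0), np.empty(0), np.empty(0),
            panel_rows=np.empty(0, int), retry_count=0, haplotypes=H,
        )
    retries = 0
    while True:
        panel = draw_discovery_panel(H, config, rng)
        mafs = panel_maf(H, panel)
        if config.pooled:
            candidates = apply_cutoff(mafs, config.cutoff)
        else:
            per_pop = [
                panel_maf(H, panel[np.isin(panel, H.rows_for(pop))])
                for pop in config.panel_sizes
            ]
            above = np.zeros(H.n_sites, dtype=bool)
            for m in per_pop:
                above |= m > config.cutoff
            candidates = np.flatnonzero(above)
        short = candidates.size < manifest.size
        if not short or resimulate is None or retries >= max_retries:
            sel = match_sites_to_manifest(
                H.positions[candidates], manifest, allow_short=True
            )
            chosen = candidates[sel]
            order = np.argsort(chosen)
            return AscertainedLocus(
                locus_id=locus_id,
                site_indices=chosen[order],
                simulated_positions=H.positions[chosen[order]],
                manifest_positions=manifest[: sel.size][order],
                panel_maf=mafs[chosen[order]],
                panel_rows=panel,
                retry_count=retries,
                short=short,
                haplotypes=H,
            )
        retries += 1
        H = resimulate(retries)
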