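"""Parameter priors and demographic models.

Two models are provided: a three-population Out-of-Africa (OoA) divergence
model for the HapMap populations (YRI, CEU, CHB), and an extension that adds
Iberians (IBS), Nahuas (NXP) and an admixed Mexican population (MXL) created
by a single-generation two-way admixture pulse.

Times are stored in generations throughout; conversion to years happens only
at report time via :data:`GENERATION_TIME_YEARS`.  Effective sizes are
diploid.  Priors on effective sizes are either uniform on a linear scale or
uniform on a log10 scale; the ancestral African size NANC is derived from
NYRI as ``10**Uniform(-1, 0) * NYRI`` so that the backward size change at
TGROWTH always shrinks the population by a factor in (0.1, 1).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "GENERATION_TIME_YEARS",
    "generations_to_years",
    "ParameterPrior",
    "PriorSet",
    "DemographicModel",
    "PopulationSplit",
    "SizeChange",
    "AdmixturePulse",
    "ConfigurationError",
    "ModelError",
    "sample_from_prior",
    "ooa_priors",
    "admixture_priors",
    "build_ooa_model",
    "build_admixture_model",
    "validate_model",
    "OOA_POSTERIOR_MODES_GENERATIONS",
    "ADMIXTURE_POSTERIOR_MODES_GENERATIONS",
]

#: Years per generation used when reporting times in years.
GENERATION_TIME_YEARS = 25.0

#: Parameters simulated but excluded from inference (no power; see methods note).
NON_INFERRED = ("TGROWTH", "NANC", "NANC_FACTOR")


def generations_to_years(generations: float) -> float:
    """Convert a time in generations to years (25 years per generation)."""
    return float(generations) * GENERATION_TIME_YEARS


class ConfigurationError(ValueError):
    """Raised for invalid prior or configuration definitions."""


class ModelError(ValueError):
    """Raised when a demographic model violates its ordering constraints."""


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterPrior:
    """Prior distribution for one scalar parameter.

    Parameters
    ----------
    name
        Parameter identifier.
    kind
        One of ``uniform``, ``discrete_uniform``, ``log10_uniform``,
        ``derived``.
    lower, upper
        Bounds.  ``upper`` may be the name of another parameter, in which
        case the bound is resolved at sampling time from the values drawn
        earlier in the same vector (e.g. TCEU_IBS <= TEU_AS).
    derivation
        Formula tag for derived parameters.  ``"scaled_by"`` multiplies
        ``10**Uniform(lower, upper)`` by the value of :attr:`reference`.
    reference
        Name of the parameter a derived prior scales.
    inferred
        Whether the parameter enters the inference (PLS response, rejection
        posterior).  Non-inferred parameters are simulated but not reported.
    """

    name: str
    kind: str
    lower: float
    upper: float | str
    derivation: str | None = None
    reference: str | None = None
    inferred: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "discrete_uniform", "log10_uniform", "derived"):
            raise ConfigurationError(f"unknown prior kind {self.kind!r} for {self.name}")
        if not isinstance(self.upper, str) and self.kind != "derived":
            if not self.lower < self.upper:
                raise ConfigurationError(
                    f"prior {self.name}: lower {self.lower} must be < upper {self.upper}"
                )
        if self.kind == "discrete_uniform" and not isinstance(self.upper, str):
            if int(self.lower) != self.lower or int(self.upper) != self.upper:
                raise ConfigurationError(f"prior {self.name}: discrete bounds must be integers")

    # -- scale helpers ------------------------------------------------------
    @property
    def log_scale(self) -> bool:
        """True when the parameter is sampled on a log10 scale."""
        return self.kind == "log10_uniform"

    def to_sampling_scale(self, value: float) -> float:
        return math.log10(value) if self.log_scale else float(value)

    def from_sampling_scale(self, value: float) -> float:
        return 10.0 ** value if self.log_scale else float(value)

    def sampling_support(self, context: dict[str, float] | None = None) -> tuple[float, float]:
        """Bounds of the prior on the sampling scale.

        Referenced upper bounds resolve through ``context``; without a
        context the reference's own upper bound is unknown and ``inf`` is
        returned.
        """
        upper: float
        if isinstance(self.upper, str):
            upper = float(context[self.upper]) if context else math.inf
        else:
            upper = float(self.upper)
        return float(self.lower), upper


def sample_from_prior(
    prior: ParameterPrior,
    rng: np.random.Generator,
    context: dict[str, float] | None = None,
) -> float:
    """Draw one value from ``prior``.

    ``context`` maps previously drawn parameter names to values; it resolves
    referenced upper bounds and derived-prior references.
    """
    lower, upper = prior.sampling_support(context)
    if not math.isfinite(upper):
        raise ConfigurationError(
            f"prior {prior.name}: upper bound {prior.upper!r} not resolvable without context"
        )
    if prior.kind == "uniform":
        return float(rng.uniform(lower, upper))
    if prior.kind == "discrete_uniform":
        return float(rng.integers(int(lower), int(upper) + 1))
    if prior.kind == "log10_uniform":
        return float(10.0 ** rng.uniform(lower, upper))
    if prior.kind == "derived":
        if prior.derivation != "scaled_by" or prior.reference is None:
            raise ConfigurationError(f"prior {prior.name}: unsupported derivation")
        if context is None or prior.reference not in context:
            raise ConfigurationError(f"prior {prior.name}: missing reference {prior.reference}")
        return float(10.0 ** rng.uniform(lower, upper) * context[prior.reference])
    raise ConfigurationError(f"unknown prior kind {prior.kind!r}")  # pragma: no cover


@dataclass
class PriorSet:
    """Ordered collection of priors forming one model's parameter space."""

    priors: list[ParameterPrior]

    def __post_init__(self) -> None:
        names = [p.name for p in self.priors]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate prior names")
        self._by_name = {p.name: p for p in self.priors}

    def __getitem__(self, name: str) -> ParameterPrior:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.priors]

    @property
    def inferred_names(self) -> list[str]:
        return [p.name for p in self.priors if p.inferred]

    def sample_vector(self, rng: np.random.Generator) -> dict[str, float]:
        """Draw a full parameter vector; referenced bounds resolve in order."""
        values: dict[str, float] = {}
        for prior in self.priors:
            values[prior.name] = sample_from_prior(prior, rng, context=values)
        return values


def ooa_priors() -> PriorSet:
    """Priors of the Out-of-Africa model (HapMap divergence + discovery set).

    Panel sizes (``nYRI``/``nCEU``/``nCHB``) are haploid discovery-panel
    sizes; ``CUTOFF`` is the minor-allele-frequency threshold of the
    discovery protocol.  TGROWTH and the NANC scaling factor are simulated
    but not inferred.
    """
    return PriorSet([
        ParameterPrior("nYRI", "discrete_uniform", 2, 20),
        ParameterPrior("nCEU", "discrete_uniform", 2, 20),
        ParameterPrior("nCHB", "discrete_uniform", 2, 20),
        ParameterPrior("CUTOFF", "uniform", 0.05, 0.10),
        ParameterPrior("NYRI", "log10_uniform", 3.7, 5.0),
        ParameterPrior("NCEU", "log10_uniform", 3.0, 5.0),
        ParameterPrior("NCHB", "log10_uniform", 3.0, 5.0),
        ParameterPrior("NEU_AS", "uniform", 1500, 5000),
        ParameterPrior("TEU_AS", "discrete_uniform", 200, 1599),
        ParameterPrior("TAF", "discrete_uniform", 1600, 4100),
        ParameterPrior("NANC", "derived", -1.0, 0.0,
                       derivation="scaled_by", reference="NYRI", inferred=False),
        ParameterPrior("TGROWTH", "discrete_uniform", 1, 4100, inferred=False),
    ])


def admixture_priors() -> PriorSet:
    """Priors of the Mexican admixture model (OoA parameters + IBS/NXP/MXL).

    TCEU_IBS and TCHB_NXP have TEU_AS as a referenced upper bound and are
    sampled conditionally after it within the same vector; TADM is bounded
    well below both so the pulse always predates the source splits going
    backward in time.
    """
    base = [p for p in ooa_priors().priors if p.name != "TEU_AS"]
    # The admixture model uses a tighter TEU_AS lower bound.
    teu_as = ParameterPrior("TEU_AS", "discrete_uniform", 500, 1599)
    extra = [
        ParameterPrior("NNXP", "log10_uniform", 3.0, 5.0),
        ParameterPrior("NIBS", "log10_uniform", 3.0, 5.0),
        ParameterPrior("NMXL", "log10_uniform", 3.0, 5.0),
        ParameterPrior("TCEU_IBS", "discrete_uniform", 400, "TEU_AS"),
        ParameterPrior("TCHB_NXP", "discrete_uniform", 400, "TEU_AS"),
        ParameterPrior("TADM", "discrete_uniform", 16, 24),
        ParameterPrior("PADM", "uniform", 0.0, 1.0),
    ]
    priors = base[:8] + [teu_as] + base[8:] + extra
    return PriorSet(priors)


# ---------------------------------------------------------------------------
# Demographic model assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSplit:
    """Backward in time at ``time``, lineages of ``derived`` join ``ancestral``."""
    time: float
    derived: str
    ancestral: str


@dataclass(frozen=True)
class SizeChange:
    """Backward in time at ``time``, ``population`` takes diploid size ``size``."""
    time: float
    population: str
    size: float


@dataclass(frozen=True)
class AdmixturePulse:
    """Single-generation pulse: backward at ``time`` each lineage of
    ``derived`` moves to ``sources[i]`` with probability ``proportions[i]``."""
    time: float
    derived: str
    sources: tuple[str, ...]
    proportions: tuple[float, ...]


Event = PopulationSplit | SizeChange | AdmixturePulse


@dataclass
class DemographicModel:
    """Populations, present-day diploid sizes, backward-time event list and
    sample configuration (haplotypes per population)."""

    populations: dict[str, float]
    events: list[Event] = field(default_factory=list)
    samples: dict[str, int] = field(default_factory=dict)
    generation_time_years: float = GENERATION_TIME_YEARS

    def sorted_events(self) -> list[Event]:
        """Events in backward-time order; splits apply before size changes
        and pulses at equal times (a merged population may be resized at the
        merge time)."""
        rank = {AdmixturePulse: 0, PopulationSplit: 1, SizeChange: 2}
        return sorted(self.events, key=lambda e: (e.time, rank[type(e)]))

    def copy(self) -> "DemographicModel":
        return copy.deepcopy(self)


#: Default haplotype counts matching the observed study samples
#: (9 YRI, 9 CEU, 4 CHB diploids; 162 IBS, 104 MXL, 22 NXP diploids).
OOA_SAMPLES = {"YRI": 18, "CEU": 18, "CHB": 8}
ADMIXTURE_SAMPLES = {**OOA_SAMPLES, "IBS": 324, "MXL": 208, "NXP": 44}


def _require(params: dict[str, float], names: list[str]) -> None:
    missing = [n for n in names if n not in params]
    if missing:
        raise ModelError(f"parameter vector missing {missing}")


def build_ooa_model(
    params: dict[str, float],
    samples: dict[str, int] | None = None,
) -> DemographicModel:
    """Assemble the three-population Out-of-Africa model.

    YRI, CEU and CHB exist at present with sizes NYRI, NCEU, NCHB.  Backward
    in time CHB merges into CEU at TEU_AS (the merged Eurasian ancestor has
    size NEU_AS), the Eurasian lineage merges into YRI at TAF, and the
    African lineage changes size from NYRI to NANC at TGROWTH (instantaneous
    growth forward in time).
    """
    _require(params, ["NYRI", "NCEU", "NCHB", "NEU_AS", "TEU_AS", "TAF", "NANC", "TGROWTH"])
    if params["TEU_AS"] >= params["TAF"]:
        raise ModelError(
            f"TEU_AS ({params['TEU_AS']}) must be < TAF ({params['TAF']})"
        )
    model = DemographicModel(
        populations={"YRI": params["NYRI"], "CEU": params["NCEU"], "CHB": params["NCHB"]},
        samples=dict(samples if samples is not None else OOA_SAMPLES),
    )
    model.events = [
        SizeChange(params["TGROWTH"], "YRI", params["NANC"]),
        PopulationSplit(params["TEU_AS"], "CHB", "CEU"),
        SizeChange(params["TEU_AS"], "CEU", params["NEU_AS"]),
        PopulationSplit(params["TAF"], "CEU", "YRI"),
    ]
    return model


def build_admixture_model(
    params: dict[str, float],
    samples: dict[str, int] | None = None,
) -> DemographicModel:
    """Assemble the Mexican admixture model on top of the OoA model.

    IBS splits from CEU at TCEU_IBS, NXP from CHB at TCHB_NXP; MXL is
    created at TADM by a single-generation pulse receiving a fraction PADM
    of its ancestry from IBS and 1-PADM from NXP.
    """
    _require(params, ["NNXP", "NIBS", "NMXL", "TCEU_IBS", "TCHB_NXP", "TADM", "PADM"])
    if not 0.0 <= params["PADM"] <= 1.0:
        raise ModelError(f"PADM ({params['PADM']}) must be in [0, 1]")
    if params["TADM"] >= min(params["TCEU_IBS"], params["TCHB_NXP"]):
        raise ModelError(
            f"TADM ({params['TADM']}) must predate the source splits "
            f"(TCEU_IBS={params['TCEU_IBS']}, TCHB_NXP={params['TCHB_NXP']})"
        )
    if params["TCEU_IBS"] > params["TEU_AS"] or params["TCHB_NXP"] > params["TEU_AS"]:
        raise ModelError("source split times must not exceed TEU_AS")
    model = build_ooa_model(params, samples=samples or ADMIXTURE_SAMPLES)
    model.populations.update(
        {"IBS": params["NIBS"], "NXP": params["NNXP"], "MXL": params["NMXL"]}
    )
    model.events.extend([
        AdmixturePulse(params["TADM"], "MXL", ("IBS", "NXP"),
                       (params["PADM"], 1.0 - params["PADM"])),
        PopulationSplit(params["TCEU_IBS"], "IBS", "CEU"),
        PopulationSplit(params["TCHB_NXP"], "NXP", "CHB"),
    ])
    return model


def validate_model(model: DemographicModel) -> list[str]:
    """Return machine-readable codes for every invariant violation.

    An empty list means the model is simulatable.  Codes:
    ``nonpositive_size``, ``unknown_population``, ``nonpositive_time``,
    ``bad_proportions``, ``no_samples``, ``does_not_coalesce``.
    """
    violations: list[str] = []
    pops = set(model.populations)
    if any(size <= 0 for size in model.populations.values()):
        violations.append("nonpositive_size")
    for ev in model.events:
        if ev.time <= 0:
            violations.append("nonpositive_time")
        if isinstance(ev, PopulationSplit):
            if ev.derived not in pops or ev.ancestral not in pops:
                violations.append("unknown_population")
        elif isinstance(ev, SizeChange):
            if ev.population not in pops:
                violations.append("unknown_population")
            if ev.size <= 0:
                violations.append("nonpositive_size")
        elif isinstance(ev, AdmixturePulse):
            if ev.derived not in pops or any(s not in pops for s in ev.sources):
                violations.append("unknown_population")
            if (len(ev.sources) != len(ev.proportions)
                    or any(p < 0 for p in ev.proportions)
                    or abs(sum(ev.proportions) - 1.0) > 1e-9):
                violations.append("bad_proportions")
    for pop, n in model.samples.items():
        if pop not in pops:
            violations.append("unknown_population")
        if n <= 0:
            violations.append("no_samples")
    # All sampled populations must merge into a single lineage going backward.
    if "unknown_population" not in violations:
        alive = set(model.samples) or pops
        for ev in model.sorted_events():
            if isinstance(ev, PopulationSplit) and ev.derived in alive:
                alive.discard(ev.derived)
                alive.add(ev.ancestral)
            elif isinstance(ev, AdmixturePulse) and ev.derived in alive:
                alive.discard(ev.derived)
                alive.update(ev.sources)
        if len(alive) > 1:
            violations.append("does_not_coalesce")
    return sorted(set(violations))


# ---------------------------------------------------------------------------
# Published posterior modes (input data for report-time unit conversion)
# ---------------------------------------------------------------------------

#: Posterior-mode divergence/admixture times in generations, OoA model.
OOA_POSTERIOR_MODES_GENERATIONS = {"TEU_AS": 1401.16, "TAF": 2786.87}

#: Posterior-mode times in generations, Mexican admixture model.
ADMIXTURE_POSTERIOR_MODES_GENERATIONS = {
    "TEU_AS": 1410.28,
    "TAF": 1953.54,
    "TCEU_IBS": 976.0,
    "TCHB_NXP": 688.73,
    "TADM": 21.5,
}
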