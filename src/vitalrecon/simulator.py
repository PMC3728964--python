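"""Artificial species and noisy observation datasets for validation.

Reconstruction methods for changing vital rates can only be validated
against species whose true demography is known.  This module generates
such species and the kind of data a field crew would bring back:

1. intervals for every kernel parameter, wide enough to cover contrasting
   demographic behaviours (each vital rate may increase or decrease with
   size and with time, or ignore either);
2. a species drawn uniformly within those intervals, kept only if its
   population neither explodes nor collapses over the study horizon
   (a non-viable species could not have been sampled in the first place);
3. a deterministic 100-year trajectory from the stable structure;
4. a handful of random observation years — data for most species exist
   only for a few, sparse years;
5. per-year samples: the number of individuals is lognormal with mean
   equal to the population density (constant sampling effort), and each
   individual's log-size is a Monte-Carlo draw from that year's size
   structure.

The generator doubles as the ground-truth provider: every dataset carries
its generating parameters as provenance so recovery can be scored.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .kernel_model import PARAM_NAMES, KernelParams, SizeMesh, param_count
from .likelihood import ObservedSeries
from .projection import SizeStructure, simulate_series

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesIntervals",
    "SamplingConfig",
    "default_intervals",
    "draw_species",
    "draw_observation_times",
    "sample_count",
    "sample_sizes",
    "make_dataset",
]

#: Parameters that are spreads and must stay strictly positive.
_SPREAD_NAMES = ("grow_sd", "off_sd")


@dataclass(frozen=True)
class SpeciesIntervals:
    """Per-parameter (lower, upper) bounds, in canonical order."""

    lower: np.ndarray
    upper: np.ndarray
    variant: str = "standard"

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        k = param_count(self.variant)
        if lower.shape != (k,) or upper.shape != (k,):
            raise InvalidInputError(
                f"variant {self.variant!r} needs {k} interval pairs"
            )
        if np.any(lower > upper):
            raise InvalidInputError("interval lower bounds must not exceed uppers")
        for name in _SPREAD_NAMES:
            i = PARAM_NAMES[self.variant].index(name)
            if lower[i] <= 0:
                raise InvalidInputError(f"{name} lower bound must be > 0")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.variant]

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(theta, self.lower, self.upper)

    def contains(self, params: KernelParams, atol: float = 1e-9) -> bool:
        theta = params.to_vector()
        return bool(
            np.all(theta >= self.lower - atol) and np.all(theta <= self.upper + atol)
        )

    def midpoint(self) -> KernelParams:
        return KernelParams.from_vector(
            0.5 * (self.lower + self.upper), variant=self.variant
        )

    def to_json(self) -> dict:
        return {
            "variant": self.variant,
            "names": list(self.names),
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SpeciesIntervals":
        return cls(
            lower=obj["lower"], upper=obj["upper"], variant=obj.get("variant", "standard")
        )


def default_intervals(variant: str = "standard") -> SpeciesIntervals:
    """Bundled default parameter intervals (this package's own choice).

    Loaded from ``data/default_intervals.json``.  They span positive,
    negative and absent size/time effects for every vital rate while
    keeping randomly drawn species demographically viable over a century.
    """
    ref = importlib.resources.files("vitalrecon.data") / "default_intervals.json"
    table = json.loads(ref.read_text())
    names = PARAM_NAMES[variant]
    lower = [table[name][0] for name in names]
    upper = [table[name][1] for name in names]
    return SpeciesIntervals(lower=lower, upper=upper, variant=variant)


@dataclass(frozen=True)
class SamplingConfig:
    """Observation-protocol settings for the artificial-species pipeline."""

    n_times: int = 10
    horizon: int = 100
    sigma_c: float = 0.3
    initial_density: float = 200.0
    effort: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_times < 2:
            raise InvalidInputError("need at least 2 observation times")
        if self.horizon < self.n_times:
            raise InvalidInputError("horizon must be >= number of observation times")
        if self.sigma_c < 0:
            raise InvalidInputError("sigma_c must be >= 0")
        if self.initial_density <= 0 or self.effort <= 0:
            raise InvalidInputError("initial_density and effort must be > 0")


#: Density band for the viability screen, relative to an initial density
#: of `initial_density`: populations leaving it within the horizon are
#: rejected (they would have gone extinct or become unsampleable).
_DENSITY_FLOOR = 1.0
_DENSITY_CEIL = 5e4


def is_viable(
    params: KernelParams,
    mesh: SizeMesh,
    horizon: int = 100,
    initial_density: float = 200.0,
) -> bool:
    """Whether a species yields a computable, bounded century of densities."""
    try:
        traj = simulate_series(params, mesh, t0=1, horizon=horizon - 1,
                               initial_density=initial_density)
    except Exception:  # noqa: BLE001 - any numerical failure means non-viable
        return False
    d = traj.densities
    return bool(
        np.all(np.isfinite(d)) and d.min() >= _DENSITY_FLOOR and d.max() <= _DENSITY_CEIL
    )


def draw_species(
    intervals: SpeciesIntervals,
    rng: np.random.Generator,
    mesh: SizeMesh | None = None,
    horizon: int = 100,
    initial_density: float = 200.0,
    max_tries: int = 100,
) -> KernelParams:
    """Draw kernel parameters uniformly within intervals, rejecting
    non-viable species.

    Raises after ``max_tries`` consecutive non-viable draws, which
    indicates the intervals should be narrowed.
    """
    if mesh is None:
        mesh = SizeMesh(0.0, 5.0, 50)
    for _ in range(max_tries):
        theta = rng.uniform(intervals.lower, intervals.upper)
        params = KernelParams.from_vector(theta, variant=intervals.variant)
        if is_viable(params, mesh, horizon=horizon, initial_density=initial_density):
            return params
    raise InvalidInputError(
        f"no viable species in {max_tries} draws; narrow the parameter intervals"
    )


def draw_observation_times(config: SamplingConfig, rng: np.random.Generator) -> np.ndarray:
    """Distinct, sorted integer observation years in ``[1, horizon]``."""
    if config.n_times > config.horizon:
        raise InvalidInputError("cannot draw more distinct years than the horizon")
    years = rng.choice(np.arange(1, config.horizon + 1), size=config.n_times,
                       replace=False)
    return np.sort(years)


def sample_count(density: float, sigma_c: float, rng: np.random.Generator) -> int:
    """Noisy sampled-individual count for one observation year.

    Lognormal with arithmetic mean equal to ``density`` (log-mean
    ``ln(density) - sigma_c^2 / 2``), rounded to the nearest integer.
    Non-positive densities yield 0 (degenerate population) with a warning.
    """
    if density <= 0:
        logger.warning("non-positive density %s: sampled count is 0", density)
        return 0
    if sigma_c == 0:
        return int(round(density))
    mu = np.log(density) - 0.5 * sigma_c**2
    return int(round(rng.lognormal(mean=mu, sigma=sigma_c)))


def sample_sizes(n: SizeStructure, count: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo log-sizes drawn from a size structure.

    Inverse-CDF sampling of the piecewise-constant density: a cell is
    chosen with probability proportional to its mass, then the size is
    uniform within the cell.  All draws lie within the mesh bounds.
    """
    if count < 0:
        raise InvalidInputError("count must be >= 0")
    if count == 0:
        return np.empty(0)
    mass = n.values * n.mesh.h
    total = mass.sum()
    if total <= 0:
        raise InvalidInputError("cannot sample sizes from a zero-mass structure")
    cells = rng.choice(n.mesh.n, size=count, p=mass / total)
    offsets = rng.uniform(0.0, n.mesh.h, size=count)
    return n.mesh.lower + cells * n.mesh.h + offsets


def make_dataset(
    params: KernelParams,
    config: SamplingConfig,
    rng: np.random.Generator | None = None,
    mesh: SizeMesh | None = None,
) -> ObservedSeries:
    """Full artificial-species observation pipeline.

    Simulates the deterministic trajectory over the horizon (years 1 to
    ``horizon``), draws the observation years, then at each one samples a
    noisy count and that many individual log-sizes.  The observed density
    is the sampled count divided by the sampling effort.  The generating
    parameters, seed and configuration are attached as provenance.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if mesh is None:
        mesh = SizeMesh(0.0, 5.0, 50)
    traj = simulate_series(params, mesh, t0=1, horizon=config.horizon - 1,
                           initial_density=config.initial_density)
    times = draw_observation_times(config, rng)
    sizes: list[np.ndarray] = []
    densities = np.empty(times.size)
    counts = np.empty(times.size, dtype=int)
    for i, t in enumerate(times):
        structure = traj.structure_at(t)
        count = sample_count(structure.density * config.effort, config.sigma_c, rng)
        counts[i] = count
        densities[i] = count / config.effort
        sizes.append(sample_sizes(structure, count, rng) if count > 0 else np.empty(0))
    return ObservedSeries(
        times=times.astype(float),
        sizes=sizes,
        densities=densities,
        provenance={
            "true_params": params.to_json(),
            "seed": config.seed,
            "config": {
                "n_times": config.n_times,
                "horizon": config.horizon,
                "sigma_c": config.sigma_c,
                "initial_density": config.initial_density,
                "effort": config.effort,
            },
            "sample_counts": counts.tolist(),
            "mesh": {"lower": mesh.lower, "upper": mesh.upper, "n": mesh.n},
        },
    )
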