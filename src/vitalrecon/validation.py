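"""Accuracy metrics and biological-plausibility screening.

Recovery of a known species is scored by Pearson correlations between
the true and reconstructed vital-rate surfaces over a size x time grid:
``r_s`` (survival), ``r_g`` (growth conditional mean — correlating full
conditional densities is not Pearson-shaped), ``r_f`` (newborn count),
plus ``r_d``, the correlation between reconstructed and observed
densities at the observation times.  Their mean ``r_m`` is the overall
accuracy score; values above 0.9 indicate an essentially correct
reconstruction.

Because the likelihood surface is multimodal, some optima reconstruct
biology that contradicts basic knowledge of the species — wrong sign of
the size-survival or size-fecundity relation, implausibly high seedling
survival, or strong size dependence where none exists.  Such "type-1"
solutions are discarded by :func:`screen_plausibility`.  Biologically
plausible but wrong ("type-2") optima cannot be detected without ground
truth; the label is therefore advisory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .kernel_model import KernelParams, SizeMesh, fecundity_count_fn, survival_fn
from .likelihood import ObservedSeries
from .projection import simulate_series

logger = logging.getLogger(__name__)

__all__ = [
    "FitMetrics",
    "PlausibilityRules",
    "surface_grid",
    "vitalrate_correlations",
    "density_correlation",
    "mean_correlation",
    "evaluate_fit",
    "screen_plausibility",
    "select_solution",
]

_VAR_EPS = 1e-12


@dataclass
class FitMetrics:
    """Correlation metrics of one reconstruction against the truth."""

    r_s: float = np.nan
    r_g: float = np.nan
    r_f: float = np.nan
    r_d: float = np.nan
    flags: list[str] = field(default_factory=list)

    @property
    def r_m(self) -> float:
        return mean_correlation(self)

    def to_json(self) -> dict:
        return {"r_s": self.r_s, "r_g": self.r_g, "r_f": self.r_f,
                "r_d": self.r_d, "r_m": self.r_m, "flags": list(self.flags)}


@dataclass(frozen=True)
class PlausibilityRules:
    """Coarse biological knowledge used to screen solutions.

    Signs are +1 (rate must increase with size), -1 (decrease), 0 (no
    size dependence expected; violated when the standardised size slope
    of the fitted surface exceeds ``slope_threshold`` in magnitude) or
    ``None`` (unconstrained).  ``max_seedling_survival`` bounds survival
    at the smallest modelled size.
    """

    survival_size_sign: int | None = None
    fecundity_size_sign: int | None = None
    max_seedling_survival: float | None = None
    slope_threshold: float = 0.5

    def __post_init__(self):
        for s in (self.survival_size_sign, self.fecundity_size_sign):
            if s not in (None, -1, 0, 1):
                raise InvalidInputError("signs must be one of None, -1, 0, 1")


def surface_grid(mesh: SizeMesh, t_start: float, t_end: float,
                 n_x: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Default evaluation grid: ``n_x`` sizes x all integer years."""
    x = np.linspace(mesh.lower, mesh.upper, n_x)
    t = np.arange(np.floor(t_start), np.floor(t_end) + 1)
    return x, t


def _pearson(a: np.ndarray, b: np.ndarray, label: str,
             flags: list[str]) -> float:
    """Pearson correlation with the constant-surface convention.

    Both surfaces constant -> 1 (they trivially agree); exactly one
    constant -> 0, flagged, since the correlation is undefined.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    va, vb = a.var(), b.var()
    if va < _VAR_EPS and vb < _VAR_EPS:
        flags.append(f"{label}: both surfaces constant")
        return 1.0
    if va < _VAR_EPS or vb < _VAR_EPS:
        flags.append(f"{label}: one surface constant, correlation undefined")
        return 0.0
    return float(np.clip(np.corrcoef(a, b)[0, 1], -1.0, 1.0))


def _surfaces(params: KernelParams, x: np.ndarray, t: np.ndarray):
    xx = x[None, :]
    tt = t[:, None]
    s = survival_fn(xx, tt, params)
    g_mean = (params.grow_icpt + params.grow_size * xx
              + params.grow_time * tt + params.grow_size_time * xx * tt)
    f1 = fecundity_count_fn(xx, tt, params)
    return s, g_mean, f1


def vitalrate_correlations(
    true_params: KernelParams,
    est_params: KernelParams,
    x: np.ndarray,
    t: np.ndarray,
) -> FitMetrics:
    """Correlations of the survival, growth-mean and fecundity surfaces.

    Variants may differ between truth and estimate: the comparison is on
    the surfaces, never on raw parameters.
    """
    s_true, g_true, f_true = _surfaces(true_params, x, t)
    s_est, g_est, f_est = _surfaces(est_params, x, t)
    m = FitMetrics()
    m.r_s = _pearson(s_true, s_est, "r_s", m.flags)
    m.r_g = _pearson(g_true, g_est, "r_g", m.flags)
    m.r_f = _pearson(f_true, f_est, "r_f", m.flags)
    return m


def density_correlation(reconstructed, observed) -> float:
    """Pearson correlation between reconstructed and observed densities.

    Needs at least 3 observation times; fewer leave the statistic
    undefined (NaN, with a warning).
    """
    reconstructed = np.asarray(reconstructed, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if reconstructed.shape != observed.shape:
        raise InvalidInputError("density series have different lengths")
    if reconstructed.size < 3:
        logger.warning("fewer than 3 observation times: r_d undefined")
        return np.nan
    flags: list[str] = []
    return _pearson(reconstructed, observed, "r_d", flags)


def mean_correlation(metrics: FitMetrics) -> float:
    """Overall accuracy ``r_m``: the arithmetic mean of the four
    component correlations (all must be present)."""
    parts = np.array([metrics.r_s, metrics.r_g, metrics.r_f, metrics.r_d])
    if np.any(np.isnan(parts)):
        raise InvalidInputError("all four correlations are required for r_m")
    return float(parts.mean())


def reconstructed_densities(
    params: KernelParams,
    obs: ObservedSeries,
    mesh: SizeMesh,
    scale0: float | None,
) -> np.ndarray:
    """Model densities at the observation times for a fitted solution."""
    traj = simulate_series(params, mesh, obs.t0, obs.span,
                           initial_density=scale0 if scale0 else 1.0)
    return np.array([traj.density_at(t) for t in obs.times])


def evaluate_fit(
    true_params: KernelParams,
    fit,
    obs: ObservedSeries,
    mesh: SizeMesh,
    n_x: int = 50,
) -> FitMetrics:
    """Full metric set (r_s, r_g, r_f, r_d) for one fit against the truth."""
    x, t = surface_grid(mesh, obs.times[0], obs.times[-1], n_x=n_x)
    m = vitalrate_correlations(true_params, fit.params, x, t)
    pred = reconstructed_densities(fit.params, obs, mesh, fit.loglik.scale0)
    m.r_d = density_correlation(pred, obs.densities)
    return m


# -- plausibility screening ---------------------------------------------------


def _standardised_size_slope(surface: np.ndarray, x: np.ndarray) -> float:
    """Slope of the standardised surface on standardised size.

    Equivalent to the correlation between the surface and the size
    coordinate; sign gives the average partial trend in size.
    """
    z = np.broadcast_to(x[None, :], surface.shape).ravel()
    s = np.asarray(surface, dtype=float).ravel()
    if s.var() < _VAR_EPS:
        return 0.0
    z = (z - z.mean()) / z.std()
    s = (s - s.mean()) / s.std()
    return float(np.mean(z * s))


def plausibility_violations(
    params: KernelParams,
    rules: PlausibilityRules,
    mesh: SizeMesh,
    t: np.ndarray,
    n_x: int = 50,
) -> list[str]:
    """List of rule violations of a fitted parameter set (empty = plausible)."""
    x = np.linspace(mesh.lower, mesh.upper, n_x)
    s, _g, f1 = _surfaces(params, x, t)
    out: list[str] = []

    def check_sign(surface, expected, label):
        slope = _standardised_size_slope(surface, x)
        if expected == 0:
            if abs(slope) > rules.slope_threshold:
                out.append(f"{label}: size dependence (slope {slope:.2f}) "
                           "where none is expected")
        elif expected * slope < 0:
            out.append(f"{label}: size trend has sign {np.sign(slope):+.0f}, "
                       f"expected {expected:+d}")

    if rules.survival_size_sign is not None:
        check_sign(s, rules.survival_size_sign, "survival")
    if rules.fecundity_size_sign is not None:
        check_sign(f1, rules.fecundity_size_sign, "fecundity")
    if rules.max_seedling_survival is not None:
        seedling = survival_fn(mesh.nodes[0], t, params)
        worst = float(np.max(seedling))
        if worst > rules.max_seedling_survival:
            out.append(
                f"seedling survival {worst:.2f} exceeds "
                f"{rules.max_seedling_survival:.2f}"
            )
    return out


def screen_plausibility(
    fit,
    rules: PlausibilityRules | None,
    mesh: SizeMesh,
    t: np.ndarray,
    n_x: int = 50,
) -> str:
    """Label a fit ``"plausible"`` or ``"type1"`` under the given rules.

    Deterministic given the fit and rules; with no rules everything is
    plausible.  Type-2 errors (plausible but wrong) are by definition
    invisible here.
    """
    if rules is None:
        return "plausible"
    params = fit.params if hasattr(fit, "params") else fit
    violations = plausibility_violations(params, rules, mesh, t, n_x=n_x)
    return "type1" if violations else "plausible"


def select_solution(
    fits: list,
    rules: PlausibilityRules | None,
    mesh: SizeMesh,
    obs: ObservedSeries,
    bounds,
    sigma_d: float = 0.3,
) -> "FitResult":
    """Pick the working solution from a multi-start sweep.

    Within each weight the converged fits are clustered into distinct
    optima; the chosen solution is the best-likelihood plausible cluster
    head at the smallest productive nonzero weight (the empirically
    reliable choice), falling back to ``w = 0`` and finally to the
    overall best fit if no plausible solution exists anywhere.
    """
    from .inference import cluster_solutions  # local import: avoid cycle

    if not fits:
        raise InvalidInputError("no fits to select from")
    t_grid = np.arange(np.floor(obs.times[0]), np.floor(obs.times[-1]) + 1)
    clusters = cluster_solutions([f for f in fits], bounds)

    def plausible_best(w):
        heads = [c.best for c in clusters if c.w == w and np.isfinite(c.best.l)]
        heads = [h for h in heads if h.converged]
        heads.sort(key=lambda r: -r.l)
        for head in heads:
            if screen_plausibility(head, rules, mesh, t_grid) == "plausible":
                return head
        return None

    ws = sorted({f.w for f in fits})
    for w in [w for w in ws if w > 0] + [w for w in ws if w == 0]:
        head = plausible_best(w)
        if head is not None:
            return head
    logger.warning("no plausible converged solution; returning overall best")
    return max(fits, key=lambda r: r.l if np.isfinite(r.l) else -np.inf)
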