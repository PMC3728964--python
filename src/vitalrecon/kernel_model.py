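"""Parametric vital-rate functions and the discretised projection kernel.

A size-structured population with log-size ``x`` evolving under a
directionally changing environment is described by an integral projection
model (IPM) whose kernel

    k(y, x, t) = s(x, t) * g(y | x, t) + f1(x, t) * f2(y, t)

combines four vital rates: the survival probability ``s``, the growth
transition density ``g`` (distribution of next year's log-size ``y`` given
this year's ``x``), the expected per-capita number of newborns ``f1`` and
the distribution of newborn log-sizes ``f2``.

Each rate responds to log-size and time through a linear predictor

    a0 + a1 * x + a2 * t + a3 * x * t

on a link scale appropriate to the rate: logit for survival, identity for
the growth mean (Gaussian residual with constant spread), log for the
newborn count, and identity for the newborn-size mean (Gaussian, constant
spread; newborn size carries a time trend but cannot depend on parent size
because the kernel factorises fecundity as ``f1(x, t) * f2(y, t)``).
This gives 4 + 5 + 4 + 3 = 16 free scalars.  A ``bounded_survival``
variant multiplies the logistic survival by a time-varying asymptote

    s_max(t) = 1 / (1 + exp(b1 + b2 * t))

adding two scalars (18 in total); it prevents the largest individuals
from becoming effectively immortal, which matters for long-lived species
such as globose cacti.

The kernel is discretised on a midpoint mesh over the modelled log-size
range.  Probability mass of ``g`` and ``f2`` that falls outside the range
("eviction") is handled by truncate-and-renormalise: each growth column
and the newborn-size vector are rescaled to unit within-range mass, so
survivors and newborn counts are conserved exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "KernelParams",
    "SizeMesh",
    "KernelMatrix",
    "VARIANTS",
    "PARAM_NAMES",
    "param_count",
    "survival_fn",
    "growth_fn",
    "fecundity_count_fn",
    "offspring_size_fn",
    "evaluate_kernel",
    "evaluate_kernels",
]

VARIANTS = ("standard", "bounded_survival")

#: Canonical flat ordering of the parameter vector per variant:
#: survival block, growth block, fecundity block, offspring block,
#: then the bounded-survival asymptote block.
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "standard": (
        "surv_icpt", "surv_size", "surv_time", "surv_size_time",
        "grow_icpt", "grow_size", "grow_time", "grow_size_time", "grow_sd",
        "fec_icpt", "fec_size", "fec_time", "fec_size_time",
        "off_icpt", "off_time", "off_sd",
    ),
}
PARAM_NAMES["bounded_survival"] = PARAM_NAMES["standard"] + ("smax_icpt", "smax_time")

#: Cap on the log-link linear predictor of the newborn count; exp(30) ~ 1e13.
FECUNDITY_LINK_CAP = 30.0


def param_count(variant: str) -> int:
    """Number of free kernel parameters for a model variant.

    ``standard`` uses 16 scalars, ``bounded_survival`` adds the two
    asymptote scalars for 18.
    """
    if variant not in PARAM_NAMES:
        raise InvalidInputError(
            f"unknown variant {variant!r}; expected one of {VARIANTS}"
        )
    return len(PARAM_NAMES[variant])


@dataclass(frozen=True)
class KernelParams:
    """The scalars defining all vital-rate functions and their time trends.

    Attributes are grouped in blocks (see module docstring).  ``surv_*``
    live on the logit scale, ``grow_*`` and ``off_*`` in log-size units,
    ``fec_*`` on the log-count scale, and ``smax_*`` on the logit scale of
    the survival asymptote.
    """

    surv_icpt: float
    surv_size: float
    surv_time: float
    surv_size_time: float
    grow_icpt: float
    grow_size: float
    grow_time: float
    grow_size_time: float
    grow_sd: float
    fec_icpt: float
    fec_size: float
    fec_time: float
    fec_size_time: float
    off_icpt: float
    off_time: float
    off_sd: float
    smax_icpt: float = 0.0
    smax_time: float = 0.0
    variant: str = "standard"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise InvalidParameterError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if not (self.grow_sd > 0):
            raise InvalidParameterError(f"grow_sd must be > 0, got {self.grow_sd}")
        if not (self.off_sd > 0):
            raise InvalidParameterError(f"off_sd must be > 0, got {self.off_sd}")

    # -- flat-vector interface ------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.variant]

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical parameter vector (length 16 or 18)."""
        return np.array([getattr(self, name) for name in self.names], dtype=float)

    @classmethod
    def from_vector(cls, theta: Sequence[float], variant: str = "standard") -> "KernelParams":
        theta = np.asarray(theta, dtype=float)
        expected = param_count(variant)
        if theta.shape != (expected,):
            raise InvalidParameterError(
                f"variant {variant!r} needs {expected} scalars, got shape {theta.shape}"
            )
        kwargs = dict(zip(PARAM_NAMES[variant], theta.tolist()))
        return cls(variant=variant, **kwargs)

    def replace(self, **changes) -> "KernelParams":
        return replace(self, **changes)

    # -- JSON serialisation ---------------------------------------------------

    def to_json(self) -> dict:
        return {
            "variant": self.variant,
            "theta": self.to_vector().tolist(),
            "names": list(self.names),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "KernelParams":
        variant = obj["variant"]
        names = obj.get("names")
        if names is not None and tuple(names) != PARAM_NAMES.get(variant, ()):
            raise InvalidParameterError(
                "parameter names do not match the canonical ordering for "
                f"variant {variant!r}"
            )
        return cls.from_vector(obj["theta"], variant=variant)

    def dumps(self) -> str:
        return json.dumps(self.to_json(), indent=1)

    @classmethod
    def loads(cls, s: str) -> "KernelParams":
        return cls.from_json(json.loads(s))


@dataclass
class SizeMesh:
    """Midpoint discretisation of the log-size axis.

    ``n`` equal cells on ``[lower, upper]``; nodes are cell midpoints and
    the quadrature weight of every node is the cell width ``h``.
    """

    lower: float
    upper: float
    n: int
    nodes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise InvalidInputError("mesh bounds must be finite")
        if not self.lower < self.upper:
            raise InvalidInputError("mesh requires lower < upper")
        if self.n < 2:
            raise InvalidInputError("mesh requires at least 2 nodes")
        self.n = int(self.n)
        self.nodes = self.lower + (np.arange(self.n) + 0.5) * self.h

    @property
    def h(self) -> float:
        """Cell width (the quadrature weight of each node)."""
        return (self.upper - self.lower) / self.n

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.n, self.h)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def cell_index(self, x) -> np.ndarray:
        """Index of the cell containing ``x``, clipped into the mesh."""
        idx = np.floor((np.asarray(x, dtype=float) - self.lower) / self.h).astype(int)
        return np.clip(idx, 0, self.n - 1)

    def clip(self, x) -> tuple[np.ndarray, int]:
        """Clip values into ``[lower, upper]``; return (clipped, n_clipped)."""
        x = np.asarray(x, dtype=float)
        n_out = int(np.sum((x < self.lower) | (x > self.upper)))
        return np.clip(x, self.lower, self.upper), n_out

    def __eq__(self, other):
        return (
            isinstance(other, SizeMesh)
            and self.lower == other.lower
            and self.upper == other.upper
            and self.n == other.n
        )


@dataclass
class KernelMatrix:
    """Discretised kernel at one evaluation time.

    ``array[i, j] ~ k(y_i, x_j, t) * h`` maps a size structure at time ``t``
    to the structure at ``t + 1`` by matrix-vector product.
    """

    array: np.ndarray
    mesh: SizeMesh
    t: float

    def __post_init__(self):
        a = np.asarray(self.array, dtype=float)
        if a.shape != (self.mesh.n, self.mesh.n):
            raise InvalidInputError(
                f"kernel array shape {a.shape} does not match mesh ({self.mesh.n})"
            )
        if not np.all(np.isfinite(a)):
            raise InvalidParameterError("kernel contains non-finite entries")
        if np.any(a < 0):
            raise InvalidParameterError("kernel contains negative entries")
        self.array = a


# -- vital-rate functions -----------------------------------------------------


def _check_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")
    return arr


def _expit(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def survival_fn(x, t, params: KernelParams):
    """Annual survival probability at log-size ``x`` and time ``t``.

    Logistic in the linear predictor; in the ``bounded_survival`` variant
    the logistic is multiplied by the asymptote ``s_max(t)``, so the value
    never exceeds ``1 / (1 + exp(b1 + b2 t))``.
    """
    x = _check_finite("x", x)
    t = _check_finite("t", t)
    eta = (
        params.surv_icpt
        + params.surv_size * x
        + params.surv_time * t
        + params.surv_size_time * x * t
    )
    s = _expit(eta)
    if params.variant == "bounded_survival":
        s = s * _expit(-(params.smax_icpt + params.smax_time * t))
    return s


def growth_fn(y, x, t, params: KernelParams):
    """Growth transition density: next log-size ``y`` given ``x`` at time ``t``.

    Gaussian with mean linear in ``x``, ``t`` and their interaction, and
    constant spread ``grow_sd``; integrates to 1 over the whole real line.
    """
    y = _check_finite("y", y)
    x = _check_finite("x", x)
    t = _check_finite("t", t)
    mu = (
        params.grow_icpt
        + params.grow_size * x
        + params.grow_time * t
        + params.grow_size_time * x * t
    )
    sd = params.grow_sd
    return np.exp(-0.5 * ((y - mu) / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))


def fecundity_count_fn(x, t, params: KernelParams):
    """Expected newborns per individual per year (log link).

    The linear predictor is capped at ``FECUNDITY_LINK_CAP`` to avoid
    overflow; a cap event is logged.
    """
    x = _check_finite("x", x)
    t = _check_finite("t", t)
    eta = (
        params.fec_icpt
        + params.fec_size * x
        + params.fec_time * t
        + params.fec_size_time * x * t
    )
    eta = np.asarray(eta, dtype=float)
    if np.any(eta > FECUNDITY_LINK_CAP):
        logger.warning(
            "fecundity linear predictor exceeded %g and was clipped",
            FECUNDITY_LINK_CAP,
        )
        eta = np.minimum(eta, FECUNDITY_LINK_CAP)
    return np.exp(eta)


def offspring_size_fn(y, t, params: KernelParams):
    """Newborn log-size density at time ``t`` (Gaussian, constant spread)."""
    y = _check_finite("y", y)
    t = _check_finite("t", t)
    mu = params.off_icpt + params.off_time * t
    sd = params.off_sd
    return np.exp(-0.5 * ((y - mu) / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))


# -- kernel assembly ----------------------------------------------------------


def _normalise_columns(pdf: np.ndarray, mu: np.ndarray, mesh: SizeMesh) -> np.ndarray:
    """Renormalise density columns to unit within-mesh mass (eviction fix).

    ``pdf`` has densities along axis -2 (the destination-size axis).  Each
    column is divided by its discrete mass so it sums to exactly 1 after
    quadrature.  Columns whose mass underflowed to zero (mean far outside
    the mesh with a narrow spread) degenerate to a point mass in the cell
    nearest the mean.
    """
    mass = pdf.sum(axis=-2, keepdims=True) * mesh.h
    dead = mass <= 0.0
    if np.any(dead):
        pdf = pdf.copy()
        mass = mass.copy()
        idx = mesh.cell_index(np.broadcast_to(mu, mass.shape))
        dead_pos = np.argwhere(dead)
        for pos in dead_pos:
            col = tuple(pos)
            target = idx[col]
            sel = list(col)
            sel[-2] = target
            pdf[tuple(sel)] = 1.0 / mesh.h
            mass[col] = 1.0
    return pdf / mass


def _kernel_stack(params: KernelParams, mesh: SizeMesh, times: np.ndarray) -> np.ndarray:
    """Vectorised kernel evaluation: returns array of shape (T, N, N)."""
    x = mesh.nodes                                  # (N,) source sizes
    t = np.asarray(times, dtype=float)[:, None]     # (T, 1)
    s = survival_fn(x, t, params)                   # (T, N)
    f1 = fecundity_count_fn(x, t, params)           # (T, N)

    mu_g = (
        params.grow_icpt
        + params.grow_size * x
        + params.grow_time * t
        + params.grow_size_time * x * t
    )                                               # (T, N)
    sd_g = params.grow_sd
    # G[k, i, j] = Normal(y_i; mu_g[k, j], sd_g)
    G = np.exp(-0.5 * ((x[None, :, None] - mu_g[:, None, :]) / sd_g) ** 2)
    G /= sd_g * np.sqrt(2.0 * np.pi)
    G = _normalise_columns(G, mu_g[:, None, :], mesh)

    mu_f = params.off_icpt + params.off_time * t    # (T, 1)
    sd_f = params.off_sd
    F2 = np.exp(-0.5 * ((x[None, :] - mu_f) / sd_f) ** 2) / (sd_f * np.sqrt(2.0 * np.pi))
    F2 = _normalise_columns(F2[:, :, None], mu_f[:, None], mesh)[:, :, 0]

    K = (s[:, None, :] * G + f1[:, None, :] * F2[:, :, None]) * mesh.h
    return K


def evaluate_kernel(params: KernelParams, mesh: SizeMesh, t: float) -> KernelMatrix:
    """Assemble the discretised kernel ``K(t)`` on ``mesh``.

    Entry ``(i, j)`` approximates ``k(y_i, x_j, t) * h`` with the survival
    and fecundity sub-kernels eviction-corrected (see module docstring),
    so the survival sub-kernel column ``j`` sums exactly to ``s(x_j, t)``.
    """
    t = float(_check_finite("t", t))
    K = _kernel_stack(params, mesh, np.array([t]))[0]
    return KernelMatrix(array=K, mesh=mesh, t=t)


def evaluate_kernels(params: KernelParams, mesh: SizeMesh, times: Iterable[float]) -> np.ndarray:
    """Kernel arrays for several times at once; shape ``(len(times), N, N)``."""
    times = _check_finite("times", np.asarray(list(times), dtype=float))
    if times.size == 0:
        return np.empty((0, mesh.n, mesh.n))
    return _kernel_stack(params, mesh, times)
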