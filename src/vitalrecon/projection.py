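"""Iteration of the time-varying IPM and stable-structure computation.

The projection step is the discretised one-year operator

    n(y, t + 1) = sum_j K(t)[i, j] * n(x_j, t)

with ``K(t)`` from :mod:`vitalrecon.kernel_model`.  Population density is
the quadrature of the size structure.  Trajectories are initialised at
their first year with the stable (asymptotic) structure of the kernel at
that year — the natural assumption when the environment was constant
before observations began — scaled to a chosen initial density.  Because
the model is linear in ``n``, that initial density is a free scale; the
inference module treats it as a nuisance parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, InvalidInputError, MeshMismatchError
from .kernel_model import KernelMatrix, KernelParams, SizeMesh, evaluate_kernels

logger = logging.getLogger(__name__)

__all__ = [
    "SizeStructure",
    "TrajectorySeries",
    "project",
    "stable_structure",
    "total_density",
    "simulate_series",
]


@dataclass
class SizeStructure:
    """Density of individuals over log-size at one time.

    ``values[i]`` is in individuals per unit area per unit log-size at
    mesh node ``i``; integrating over the mesh gives population density.
    """

    mesh: SizeMesh
    values: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.mesh.n,):
            raise InvalidInputError(
                f"structure has {v.shape} values for a mesh of {self.mesh.n} nodes"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("structure values must be finite")
        if np.any(v < 0):
            raise InvalidInputError("structure values must be nonnegative")
        self.values = v

    @property
    def density(self) -> float:
        return float(self.values.sum() * self.mesh.h)

    def normalized(self) -> np.ndarray:
        """Values rescaled to a probability density over the mesh."""
        d = self.density
        if d <= 0:
            raise InvalidInputError("cannot normalise a zero-mass structure")
        return self.values / d


def total_density(n: SizeStructure) -> float:
    """Population density (individuals per unit area): quadrature of ``n``."""
    return n.density


def project(n: SizeStructure, K: KernelMatrix) -> SizeStructure:
    """Apply the one-year projection operator: ``n(t) -> n(t + 1)``."""
    if n.mesh != K.mesh:
        raise MeshMismatchError("structure and kernel are on different meshes")
    return SizeStructure(mesh=n.mesh, values=K.array @ n.values, t=K.t + 1.0)


def stable_structure(
    K: KernelMatrix,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[SizeStructure, float]:
    """Dominant eigenpair of the kernel: stable structure and growth rate.

    Power iteration with L1 normalisation each step (robust for
    nonnegative kernels, no complex arithmetic); if the iteration stalls
    — e.g. for a degenerate spectrum with near-tied leading eigenvalues —
    a dense eigendecomposition finishes the job.  The returned structure
    is nonnegative and quadrature-normalised to density 1.

    Raises :class:`ConvergenceError` (carrying the residual) if no
    eigenpair with relative residual below 1e-8 can be produced.
    """
    A = K.array
    n_nodes = A.shape[0]
    v = np.full(n_nodes, 1.0 / n_nodes)
    lam = 0.0
    for _ in range(max_iter):
        w = A @ v
        s = w.sum()
        if s <= 0.0:
            # nilpotent/zero kernel: growth rate 0, structure is arbitrary
            lam = 0.0
            v = np.full(n_nodes, 1.0 / n_nodes)
            break
        lam = s  # since v sums to 1, lam = sum(A v) is the L1 growth factor
        w /= s
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w

    def _residual(vec, val):
        denom = max(abs(val), 1e-300) * np.linalg.norm(vec)
        return float(np.linalg.norm(A @ vec - val * vec) / denom)

    if lam > 0 and _residual(v, lam) > 1e-8:
        # dense fallback for slow/oscillatory power iteration
        vals, vecs = np.linalg.eig(A)
        i = int(np.argmax(vals.real))
        lam_d = float(vals[i].real)
        v_d = np.abs(vecs[:, i].real)
        if v_d.sum() > 0:
            v_d /= v_d.sum()
        if lam_d > 0 and _residual(v_d, lam_d) <= _residual(v, lam):
            v, lam = v_d, lam_d
    res = _residual(v, lam) if lam > 0 else 0.0
    if lam > 0 and res > 1e-8:
        raise ConvergenceError(
            f"stable structure did not converge (residual {res:.3e})", residual=res
        )

    values = np.maximum(v, 0.0)
    mass = values.sum() * K.mesh.h
    if mass > 0:
        values = values / mass
    else:
        values = np.full(n_nodes, 1.0 / (K.mesh.width))
    return SizeStructure(mesh=K.mesh, values=values, t=K.t), float(lam)


@dataclass
class TrajectorySeries:
    """Annual trajectory of size structures and their densities."""

    mesh: SizeMesh
    times: np.ndarray
    values: np.ndarray  # shape (len(times), mesh.n)
    densities: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, self.mesh.n):
            raise InvalidInputError("trajectory values shape mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("trajectory times must be strictly increasing")
        self.densities = self.values.sum(axis=1) * self.mesh.h

    def index_of(self, t: float) -> int:
        i = int(np.searchsorted(self.times, t))
        if i >= self.times.size or self.times[i] != t:
            raise InvalidInputError(f"time {t} not covered by trajectory")
        return i

    def structure_at(self, t: float) -> SizeStructure:
        i = self.index_of(t)
        return SizeStructure(mesh=self.mesh, values=self.values[i], t=float(t))

    def density_at(self, t: float) -> float:
        return float(self.densities[self.index_of(t)])

    def to_structure_frame(self) -> pd.DataFrame:
        """Tidy long-format frame with columns (time, node, n_value)."""
        times = np.repeat(self.times, self.mesh.n)
        nodes = np.tile(self.mesh.nodes, self.times.size)
        return pd.DataFrame(
            {"time": times, "node": nodes, "n_value": self.values.ravel()}
        )

    def to_density_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "density": self.densities})


def simulate_series(
    params: KernelParams,
    mesh: SizeMesh,
    t0: float,
    horizon: int,
    initial_density: float = 1.0,
) -> TrajectorySeries:
    """Deterministic annual trajectory of the time-varying IPM.

    Starts at ``t0`` from the stable structure of ``K(t0)`` scaled to
    ``initial_density`` and applies ``K(t)`` year by year for ``horizon``
    steps, re-evaluating the kernel at each integer year.
    """
    if horizon < 0:
        raise InvalidInputError("horizon must be >= 0")
    t0 = float(t0)
    if not t0.is_integer():
        logger.info("initial time %s snapped to nearest integer year", t0)
        t0 = round(t0)
    horizon = int(horizon)

    kernels = evaluate_kernels(params, mesh, t0 + np.arange(max(horizon, 1)))
    n0, _lam = stable_structure(KernelMatrix(array=kernels[0], mesh=mesh, t=t0))
    values = np.empty((horizon + 1, mesh.n))
    values[0] = n0.values * initial_density
    for step in range(horizon):
        values[step + 1] = kernels[step] @ values[step]
    times = t0 + np.arange(horizon + 1)
    return TrajectorySeries(mesh=mesh, times=times, values=values)
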