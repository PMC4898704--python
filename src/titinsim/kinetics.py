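"""Force-dependent unfolding/refolding kinetics and Ig stability clusters.

Each proximal Ig domain is a two-state system (folded/unfolded) whose
transition rates follow Bell kinetics: an external force F tilts the
activation barrier, giving

    u(F) = omega0 * exp(+F * x_u / kT)      (unfolding)
    r(F) = omega1 * exp(-F * x_f / kT)      (refolding)

with spontaneous rates omega0/omega1 at zero force and barrier widths
x_u/x_f.  Hierarchical mechanical stability is encoded by partitioning the
N proximal domains into m clusters, each with its own spontaneous unfolding
rate, ordered so that u_1(F) <= ... <= u_m(F) at every force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._constants import BOLTZMANN
from .errors import ValidationError

__all__ = [
    "unfold_rate",
    "refold_rate",
    "Cluster",
    "RefoldingParams",
    "ClusterModel",
    "total_hazard",
    "default_cluster_model",
    "single_cluster_model",
    "equidistant_log_clusters",
    "noisy_linear_clusters",
]

#: Cap on the Bell exponent; rates saturate at omega0 * e^cap.  Prevents
#: overflow for the astronomically stiff near-contour states while keeping
#: them effectively instantaneous on any simulated time scale.
EXPONENT_CAP = 500.0

# Default spontaneous-rate span of the five-cluster model (1/s).  These are
# placeholders calibrated only so that unfolding happens within a
# 1 -> 2 um ramp at 1 um/s; see docs/methods.md.
DEFAULT_OMEGA0_MIN = 1e-5
DEFAULT_OMEGA0_MAX = 1e-3
DEFAULT_X_U = 0.25e-9
DEFAULT_X_F = 2.2e-9
DEFAULT_OMEGA1 = 1.0


def unfold_rate(F, omega0: float, x_u: float, temperature: float):
    """Bell unfolding rate u(F) = omega0 * exp(F*x_u/kT).

    Strictly increasing in F; the exponent is capped at ``EXPONENT_CAP``.
    """
    if omega0 < 0 or x_u < 0 or temperature <= 0:
        raise ValidationError("omega0, x_u must be >= 0 and temperature > 0")
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValidationError("force must be non-negative")
    expo = np.minimum(F * x_u / (BOLTZMANN * temperature), EXPONENT_CAP)
    out = omega0 * np.exp(expo)
    return out if out.ndim else float(out)


def refold_rate(F, omega1: float, x_f: float, temperature: float):
    """Bell refolding rate r(F) = omega1 * exp(-F*x_f/kT), decreasing in F."""
    if omega1 < 0 or x_f < 0 or temperature <= 0:
        raise ValidationError("omega1, x_f must be >= 0 and temperature > 0")
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValidationError("force must be non-negative")
    out = omega1 * np.exp(-F * x_f / (BOLTZMANN * temperature))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Cluster:
    """A group of Ig domains sharing one spontaneous unfolding rate.

    ``x_u`` may override the model-wide barrier width, allowing clusters
    that differ by activation barrier instead of prefactor.
    """

    n: int
    omega0: float
    x_u: float | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n > 0):
            raise ValidationError("cluster size n must be a positive integer")
        if self.omega0 < 0:
            raise ValidationError("omega0 must be non-negative")
        if self.x_u is not None and self.x_u < 0:
            raise ValidationError("x_u must be non-negative")


@dataclass(frozen=True)
class RefoldingParams:
    omega1: float = DEFAULT_OMEGA1
    x_f: float = DEFAULT_X_F

    def __post_init__(self) -> None:
        if self.omega1 < 0 or self.x_f < 0:
            raise ValidationError("omega1 and x_f must be non-negative")


@dataclass(frozen=True)
class ClusterModel:
    """Partition of the proximal Ig domains into stability clusters.

    Clusters are stored in order of increasing unfolding rate, i.e.
    u_1(F) <= u_2(F) <= ... <= u_m(F) for every force.  With a shared
    barrier width this is equivalent to non-decreasing omega0; the
    constructor verifies the ordering on a force sweep when per-cluster
    barrier widths are used.
    """

    clusters: tuple[Cluster, ...]
    x_u: float = DEFAULT_X_U
    temperature: float = 300.0
    refolding: RefoldingParams | None = None

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValidationError("at least one cluster is required")
        if self.x_u < 0 or self.temperature <= 0:
            raise ValidationError("x_u must be >= 0 and temperature > 0")
        object.__setattr__(self, "clusters", tuple(self.clusters))
        # Rate ordering u_1 <= ... <= u_m must hold for all F; with shared
        # x_u it reduces to the omega0 ordering, otherwise check a sweep up
        # to a generous force bound.
        F_probe = np.linspace(0.0, 600e-12, 7)
        rates = np.vstack([
            unfold_rate(F_probe, c.omega0, self.barrier_width(k),
                        self.temperature)
            for k, c in enumerate(self.clusters)
        ])
        if np.any(np.diff(rates, axis=0) < -1e-300):
            raise ValidationError(
                "clusters must be ordered so u_1(F) <= ... <= u_m(F); "
                "sort by increasing rate")

    @property
    def m(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.n for c in self.clusters], dtype=int)

    @property
    def n_domains(self) -> int:
        return int(self.sizes.sum())

    @property
    def omega0(self) -> np.ndarray:
        return np.array([c.omega0 for c in self.clusters], dtype=float)

    def barrier_width(self, k: int) -> float:
        xu = self.clusters[k].x_u
        return self.x_u if xu is None else xu

    @property
    def barrier_widths(self) -> np.ndarray:
        return np.array([self.barrier_width(k) for k in range(self.m)])

    def unfold_rates(self, F):
        """Per-cluster unfolding rates u_k(F); F scalar or array.

        Returns shape ``(m,)`` for scalar F, ``F.shape + (m,)`` otherwise.
        """
        F = np.asarray(F, dtype=float)
        expo = np.minimum(
            F[..., None] * self.barrier_widths
            / (BOLTZMANN * self.temperature),
            EXPONENT_CAP)
        return self.omega0 * np.exp(expo)

    def refold_rates(self, F):
        """Refolding rate r(F), shared by all clusters; 0 if refolding off."""
        if self.refolding is None:
            return np.zeros_like(np.asarray(F, dtype=float))
        return refold_rate(F, self.refolding.omega1, self.refolding.x_f,
                           self.temperature)

    def with_refolding(self, refolding: RefoldingParams | None
                       ) -> "ClusterModel":
        return ClusterModel(self.clusters, self.x_u, self.temperature,
                            refolding)


def total_hazard(state, F, model: ClusterModel) -> np.ndarray:
    """Effective per-cluster event rates at unfolded counts ``state``.

    Returns the vector of unfolding hazards (n_k - i_k) * u_k(F), followed
    by the per-cluster refolding hazards i_k * r(F) when refolding is
    enabled.  Exhausted clusters contribute zero, which enforces the
    boundary terms of the master equation.
    """
    state = np.asarray(state, dtype=int)
    sizes = model.sizes
    if state.shape != (model.m,):
        raise ValidationError(f"state must have shape ({model.m},)")
    if np.any(state < 0) or np.any(state > sizes):
        raise ValidationError("unfolded counts out of [0, n_k]")
    u = model.unfold_rates(float(F))
    hazards = (sizes - state) * u
    if model.refolding is not None:
        r = model.refold_rates(float(F))
        hazards = np.concatenate([hazards, state * r])
    return hazards


# ---------------------------------------------------------------------------
# Cluster-model builders
# ---------------------------------------------------------------------------

def default_cluster_model(n_domains: int = 50, m: int = 5,
                          omega0_min: float = DEFAULT_OMEGA0_MIN,
                          omega0_max: float = DEFAULT_OMEGA0_MAX,
                          x_u: float = DEFAULT_X_U,
                          temperature: float = 300.0,
                          refolding: RefoldingParams | None = None
                          ) -> ClusterModel:
    """Equal-size clusters with geometrically spaced spontaneous rates.

    The default partitions 50 domains into 5 clusters of 10 with omega0
    spanning 1e-5 .. 1e-3 1/s geometrically.
    """
    if n_domains % m:
        raise ValidationError("n_domains must be divisible by m")
    omega0 = np.geomspace(omega0_min, omega0_max, m)
    clusters = tuple(Cluster(n_domains // m, w) for w in omega0)
    return ClusterModel(clusters, x_u=x_u, temperature=temperature,
                        refolding=refolding)


def single_cluster_model(n_domains: int = 50, omega0: float = 1e-4,
                         x_u: float = DEFAULT_X_U, temperature: float = 300.0,
                         refolding: RefoldingParams | None = None
                         ) -> ClusterModel:
    """One cluster covering all domains (hysteresis-loop setting)."""
    return ClusterModel((Cluster(n_domains, omega0),), x_u=x_u,
                        temperature=temperature, refolding=refolding)


def equidistant_log_clusters(n_domains: int = 50, m: int = 5,
                             omega0_min: float = DEFAULT_OMEGA0_MIN,
                             omega0_max: float = DEFAULT_OMEGA0_MAX,
                             **kw) -> ClusterModel:
    """m clusters with log10(omega0) equidistant between the envelope ends."""
    return default_cluster_model(n_domains, m, omega0_min, omega0_max, **kw)


def noisy_linear_clusters(n_domains: int = 50,
                          omega0_min: float = DEFAULT_OMEGA0_MIN,
                          omega0_max: float = DEFAULT_OMEGA0_MAX,
                          noise_sd: float = 0.2,
                          noise_scale: str = "log10",
                          rng: np.random.Generator | None = None,
                          x_u: float = DEFAULT_X_U,
                          temperature: float = 300.0) -> ClusterModel:
    """One cluster per domain with linearly declining spontaneous rates.

    The rate ordinate declines linearly across the domains between the same
    envelope as the coarse model and is perturbed by additive Gaussian
    noise (SD ``noise_sd``).  ``noise_scale`` selects whether the linear
    decline and the perturbation act on log10(omega0) (default) or on
    omega0 itself; the resulting rates are sorted increasing to satisfy the
    cluster ordering.
    """
    rng = np.random.default_rng(rng)
    if noise_scale == "log10":
        ordinate = np.linspace(np.log10(omega0_max), np.log10(omega0_min),
                               n_domains)
        ordinate = ordinate + noise_sd * rng.standard_normal(n_domains)
        omega0 = 10.0 ** ordinate
    elif noise_scale == "linear":
        ordinate = np.linspace(omega0_max, omega0_min, n_domains)
        ordinate = ordinate * (1.0 + noise_sd * rng.standard_normal(n_domains))
        omega0 = np.clip(ordinate, 1e-12, None)
    else:
        raise ValidationError("noise_scale must be 'log10' or 'linear'")
    clusters = tuple(Cluster(1, w) for w in np.sort(omega0))
    return ClusterModel(clusters, x_u=x_u, temperature=temperature)
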