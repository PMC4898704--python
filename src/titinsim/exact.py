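"""Exact unfolding-state probabilities via the chemical master equation.

The joint state of a strand is the vector (i_1, ..., i_m) of unfolded
counts per stability cluster.  Its probability evolves under a linear ODE
system whose rates depend on time through the force F_i(l(t)) of the
current total unfolding level i = i_1 + ... + i_m:

    dp_s/dt = - sum_k (n_k - i_k) u_k(F_i(t)) p_s
              + sum_k (n_k - i_k + 1) u_k(F_{i-1}(t)) p_{s - e_k}

with the obvious boundary guards.  Without refolding every transition
increases the level, so the backward-Euler update is solved exactly by a
single sweep over levels — no matrix factorisation is needed, which keeps
the 11^5-state default model fast.  With refolding the system is solved
per step (tridiagonal for one cluster, sparse LU otherwise).

Aggregating over the level sets gives P_0..P_N, and the expected strand
force is E[F](t) = sum_l P_l(t) F_l(t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solve_banded
from scipy.sparse.linalg import splu

from .errors import ConfigError, SolverError, ValidationError
from .kinetics import ClusterModel
from .mechanics import ForceCurveFamily
from .protocols import LengthProtocol

__all__ = [
    "ClusterStateSpace",
    "StateProbabilities",
    "MasterSolution",
    "generator_matrix",
    "solve_master",
    "solve_master_with_refolding",
    "aggregate",
    "expected_force",
    "first_unfolding_distribution",
    "FirstUnfoldingDensity",
]

logger = logging.getLogger(__name__)

_RENORM_TOL = 1e-12
_NEG_TOL = -1e-10
_STORE_FULL_MAX = 4096


class ClusterStateSpace:
    """Enumeration of cluster-occupancy states grouped by unfolding level.

    States are ordered by total unfolded count l (the "level"), and within
    a level by their mixed-radix key over (n_1+1, ..., n_m+1).  The space
    precomputes, per level and cluster, the sparse inflow stencils
    B[l][k] (level l-1 -> l, entries n_k - i_k of the source state) and
    the outflow count matrix C[l] (entries n_k - i_k per state), from
    which the generator at any force vector follows by scalar weighting.
    """

    def __init__(self, sizes) -> None:
        sizes = np.asarray(sizes, dtype=int)
        if sizes.ndim != 1 or np.any(sizes < 1):
            raise ValidationError("cluster sizes must be positive integers")
        self.sizes = sizes
        self.m = sizes.size
        self.N = int(sizes.sum())
        radix = sizes + 1
        self.n_states = int(np.prod(radix))
        # all states as rows, keyed by their mixed-radix index
        grids = np.meshgrid(*[np.arange(r) for r in radix], indexing="ij")
        states = np.stack([g.ravel() for g in grids], axis=1)
        level = states.sum(axis=1)
        order = np.lexsort((np.arange(self.n_states), level))
        self.states = states[order]          # (S, m), level-major
        self.level = level[order]
        self.level_start = np.searchsorted(self.level, np.arange(self.N + 2))
        # key -> position in the level-major ordering
        self._radix_weights = np.cumprod(
            np.concatenate([[1], radix[::-1][:-1]]))[::-1]
        keys = self.states @ self._radix_weights
        self._pos_of_key = np.empty(self.n_states, dtype=np.int64)
        self._pos_of_key[keys] = np.arange(self.n_states)
        self._build_stencils()

    def _build_stencils(self) -> None:
        B: list[list[sp.csr_matrix | None]] = [[None] * self.m]
        C: list[np.ndarray] = []
        R: list[list[sp.csr_matrix | None]] = []
        for l in range(self.N + 1):
            C.append(self.sizes - self.level_states(l))
        for l in range(1, self.N + 1):
            src = self.level_states(l - 1)
            src_keys = src @ self._radix_weights
            rows_l = []
            for k in range(self.m):
                open_k = src[:, k] < self.sizes[k]
                n_src = src.shape[0]
                n_tgt = self.level_size(l)
                if not np.any(open_k):
                    rows_l.append(None)
                    continue
                cols = np.nonzero(open_k)[0]
                tgt_keys = src_keys[cols] + self._radix_weights[k]
                rows = self._pos_of_key[tgt_keys] - self.level_start[l]
                data = (self.sizes[k] - src[cols, k]).astype(float)
                rows_l.append(sp.csr_matrix(
                    (data, (rows, cols)), shape=(n_tgt, n_src)))
            B.append(rows_l)
        # refolding stencils: level l+1 -> l, entries i_k of the source
        for l in range(self.N):
            src = self.level_states(l + 1)
            src_keys = src @ self._radix_weights
            rows_l = []
            for k in range(self.m):
                occ = src[:, k] > 0
                if not np.any(occ):
                    rows_l.append(None)
                    continue
                cols = np.nonzero(occ)[0]
                tgt_keys = src_keys[cols] - self._radix_weights[k]
                rows = self._pos_of_key[tgt_keys] - self.level_start[l]
                data = src[cols, k].astype(float)
                rows_l.append(sp.csr_matrix(
                    (data, (rows, cols)),
                    shape=(self.level_size(l), src.shape[0])))
            R.append(rows_l)
        R.append([None] * self.m)
        self.B = B
        self.C = C
        self.R_stencil = R

    def level_size(self, l: int) -> int:
        return int(self.level_start[l + 1] - self.level_start[l])

    def level_states(self, l: int) -> np.ndarray:
        return self.states[self.level_start[l]:self.level_start[l + 1]]

    def index_of(self, state) -> int:
        state = np.asarray(state, dtype=int)
        if state.shape != (self.m,) or np.any(state < 0) \
                or np.any(state > self.sizes):
            raise ValidationError("state out of bounds")
        return int(self._pos_of_key[state @ self._radix_weights])

    def split_levels(self, p: np.ndarray) -> list[np.ndarray]:
        return [p[self.level_start[l]:self.level_start[l + 1]]
                for l in range(self.N + 1)]


@dataclass
class StateProbabilities:
    """Full occupancy-state distribution at one time point."""

    space: ClusterStateSpace
    p: np.ndarray
    time: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.space.n_states,):
            raise ValidationError("probability vector has wrong size")


@dataclass
class MasterSolution:
    """Time-resolved solution of the master equation."""

    times: np.ndarray
    lengths: np.ndarray
    aggregated: np.ndarray            # (T, N+1) level probabilities P_l(t)
    space: ClusterStateSpace
    final: StateProbabilities
    full: np.ndarray | None = None    # (T, S) when retained
    expected_force: np.ndarray | None = None
    renormalizations: int = 0


def _unfold_rate_table(model: ClusterModel, F_levels: np.ndarray
                       ) -> np.ndarray:
    """u_k at every level force; F_levels (..., N+1) -> (..., N+1, m)."""
    return model.unfold_rates(F_levels)


def generator_matrix(space: ClusterStateSpace, model: ClusterModel,
                     forces_by_level: np.ndarray) -> sp.csr_matrix:
    """Assemble the full sparse generator A at given per-level forces.

    ``forces_by_level`` holds F_0..F_N (shape (N+1,)).  Columns of A sum
    to zero (probability conservation).  Used by the per-step refolding
    solver and as an explicit object for oracle tests.
    """
    forces_by_level = np.asarray(forces_by_level, dtype=float)
    if forces_by_level.shape != (space.N + 1,):
        raise ConfigError(
            f"need one force per unfolding level (got "
            f"{forces_by_level.shape}, expected {(space.N + 1,)})")
    if tuple(model.sizes) != tuple(space.sizes):
        raise ConfigError("cluster model does not match the state space")
    u = _unfold_rate_table(model, forces_by_level)       # (N+1, m)
    r = model.refold_rates(forces_by_level)              # (N+1,)
    blocks = sp.lil_matrix((space.n_states, space.n_states))
    diag = np.zeros(space.n_states)
    for l in range(space.N + 1):
        s0, s1 = space.level_start[l], space.level_start[l + 1]
        out_unfold = space.C[l] @ u[l]                   # (S_l,)
        diag[s0:s1] -= out_unfold
        if model.refolding is not None:
            diag[s0:s1] -= space.level_states(l).sum(axis=1) * r[l]
        for k in range(space.m):
            Bk = space.B[l][k] if l >= 1 else None
            if Bk is not None:
                p0, p1 = space.level_start[l - 1], space.level_start[l]
                blocks[s0:s1, p0:p1] += Bk * u[l - 1, k]
            if model.refolding is not None:
                Rk = space.R_stencil[l][k]
                if Rk is not None:
                    q0, q1 = space.level_start[l + 1], space.level_start[l + 2]
                    blocks[s0:s1, q0:q1] += Rk * r[l + 1]
    A = blocks.tocsr()
    A += sp.diags(diag)
    return A


def _initial_vector(space: ClusterStateSpace, initial_state) -> np.ndarray:
    """Delta distribution at ``initial_state`` (default: fully folded)."""
    p = np.zeros(space.n_states)
    if initial_state is None:
        initial_state = np.zeros(space.m, dtype=int)
    p[space.index_of(initial_state)] = 1.0
    return p


def _prepare(protocol: LengthProtocol, model: ClusterModel,
             family: ForceCurveFamily, dt: float):
    if family.n_domains != model.n_domains:
        raise ConfigError(
            f"force-curve family has {family.n_domains} domains but the "
            f"cluster model has {model.n_domains}")
    t_grid = protocol.time_grid(dt)
    lengths = protocol.length_at(t_grid)
    F_table = family.table(lengths)                      # (T, N+1)
    return t_grid, lengths, F_table


def solve_master(protocol: LengthProtocol, model: ClusterModel,
                 family: ForceCurveFamily, *, dt: float = 1e-3,
                 store_full: bool | None = None,
                 initial_state=None) -> MasterSolution:
    """Backward-Euler solution of the unfolding master equation.

    The initial condition is the fully folded state.  The generator is
    evaluated at each step's end time (fully implicit).  Because unfolding
    only moves probability upward in level, each implicit step is solved
    exactly by one forward sweep over levels; probability is conserved to
    roundoff and renormalised (and logged) only if the drift exceeds 1e-12.
    """
    if model.refolding is not None:
        return solve_master_with_refolding(protocol, model, family, dt=dt,
                                           store_full=store_full,
                                           initial_state=initial_state)
    space = ClusterStateSpace(model.sizes)
    t_grid, lengths, F_table = _prepare(protocol, model, family, dt)
    T = t_grid.size
    u_all = _unfold_rate_table(model, F_table)           # (T, N+1, m)
    if store_full is None:
        store_full = space.n_states <= _STORE_FULL_MAX
    p = space.split_levels(_initial_vector(space, initial_state))
    p = [pl.copy() for pl in p]
    agg = np.zeros((T, space.N + 1))
    agg[0] = [pl.sum() for pl in p]
    full = np.zeros((T, space.n_states)) if store_full else None
    if store_full:
        full[0] = np.concatenate(p)
    renorms = 0
    for n in range(T - 1):
        u = u_all[n + 1]                                 # (N+1, m)
        p_new: list[np.ndarray] = []
        for l in range(space.N + 1):
            denom = 1.0 + dt * (space.C[l] @ u[l])
            rhs = p[l].copy()
            if l >= 1:
                for k in range(space.m):
                    Bk = space.B[l][k]
                    if Bk is not None:
                        rhs += dt * u[l - 1, k] * (Bk @ p_new[l - 1])
            p_new.append(rhs / denom)
        p = p_new
        tot = sum(float(pl.sum()) for pl in p)
        if abs(tot - 1.0) > _RENORM_TOL:
            logger.debug("renormalising probabilities at t=%g "
                           "(drift %.3e)", t_grid[n + 1], tot - 1.0)
            p = [pl / tot for pl in p]
            renorms += 1
        mins = min(float(pl.min()) for pl in p)
        if mins < _NEG_TOL:
            raise SolverError(
                f"negative probability {mins:.3e} at t={t_grid[n + 1]:.6g}; "
                f"reduce dt")
        agg[n + 1] = [pl.sum() for pl in p]
        if store_full:
            full[n + 1] = np.concatenate(p)
    final = StateProbabilities(space, np.concatenate(p), float(t_grid[-1]))
    ef = np.einsum("tl,tl->t", agg, F_table)
    return MasterSolution(t_grid, lengths, agg, space, final, full,
                          expected_force=ef, renormalizations=renorms)


def solve_master_with_refolding(protocol: LengthProtocol,
                                model: ClusterModel,
                                family: ForceCurveFamily, *,
                                dt: float = 1e-3,
                                store_full: bool | None = None,
                                initial_state=None) -> MasterSolution:
    """Backward-Euler master equation with unfolding and refolding flows.

    For a single cluster the system is tridiagonal in the unfolded count
    and solved with a banded solver; for several clusters the sparse
    generator is assembled and LU-factorised per step (intended for
    small-to-moderate state spaces).
    """
    if model.refolding is None:
        raise ConfigError("model has no refolding parameters")
    space = ClusterStateSpace(model.sizes)
    t_grid, lengths, F_table = _prepare(protocol, model, family, dt)
    T = t_grid.size
    if store_full is None:
        store_full = space.n_states <= _STORE_FULL_MAX
    N = space.N
    p0_vec = _initial_vector(space, initial_state)
    agg = np.zeros((T, N + 1))
    agg[0] = [p0_vec[space.level_start[l]:space.level_start[l + 1]].sum()
              for l in range(N + 1)]
    full = np.zeros((T, space.n_states)) if store_full else None
    renorms = 0

    if space.m == 1:
        n = N
        i = np.arange(n + 1)
        p = p0_vec.copy()
        if store_full:
            full[0] = p
        u_all = _unfold_rate_table(model, F_table)[:, :, 0]  # (T, N+1)
        r_all = model.refold_rates(F_table)                  # (T, N+1)
        for step_ in range(T - 1):
            u = u_all[step_ + 1]
            r = r_all[step_ + 1]
            out = (n - i) * u + i * r
            ab = np.zeros((3, n + 1))
            ab[0, 1:] = -dt * (i[1:] * r[1:])            # superdiag: refold
            ab[1] = 1.0 + dt * out
            ab[2, :-1] = -dt * ((n - i[:-1]) * u[:-1])   # subdiag: unfold
            p = solve_banded((1, 1), ab, p)
            tot = p.sum()
            if abs(tot - 1.0) > _RENORM_TOL:
                logger.debug("renormalising at t=%g (drift %.3e)",
                               t_grid[step_ + 1], tot - 1.0)
                p = p / tot
                renorms += 1
            if p.min() < _NEG_TOL:
                raise SolverError(
                    f"negative probability {p.min():.3e} at "
                    f"t={t_grid[step_ + 1]:.6g}; reduce dt")
            agg[step_ + 1] = p
            if store_full:
                full[step_ + 1] = p
        p_full = p
    else:
        if space.n_states > 200_000:
            raise SolverError(
                "refolding solver with sparse LU per step is impractical "
                f"for {space.n_states} states; use Monte Carlo")
        p_full = p0_vec.copy()
        if store_full:
            full[0] = p_full
        eye = sp.identity(space.n_states, format="csc")
        for step_ in range(T - 1):
            A = generator_matrix(space, model, F_table[step_ + 1])
            try:
                p_full = splu((eye - dt * A).tocsc()).solve(p_full)
            except RuntimeError as exc:  # pragma: no cover
                raise SolverError(f"sparse LU failed at step {step_}: {exc}")
            tot = p_full.sum()
            if abs(tot - 1.0) > _RENORM_TOL:
                logger.debug("renormalising at t=%g (drift %.3e)",
                               t_grid[step_ + 1], tot - 1.0)
                p_full = p_full / tot
                renorms += 1
            if p_full.min() < _NEG_TOL:
                raise SolverError(
                    f"negative probability {p_full.min():.3e} at "
                    f"t={t_grid[step_ + 1]:.6g}; reduce dt")
            agg[step_ + 1] = [p_full[space.level_start[l]:
                                     space.level_start[l + 1]].sum()
                              for l in range(N + 1)]
            if store_full:
                full[step_ + 1] = p_full
    final = StateProbabilities(space, np.asarray(p_full, dtype=float).copy(),
                               float(t_grid[-1]))
    ef = np.einsum("tl,tl->t", agg, F_table)
    return MasterSolution(t_grid, lengths, agg, space, final, full,
                          expected_force=ef, renormalizations=renorms)


def aggregate(states: StateProbabilities) -> np.ndarray:
    """Level probabilities P_0..P_N from a full state distribution."""
    space = states.space
    return np.array([states.p[space.level_start[l]:
                              space.level_start[l + 1]].sum()
                     for l in range(space.N + 1)])


def expected_force(aggregated: np.ndarray, family: ForceCurveFamily,
                   lengths: np.ndarray,
                   n_strands: float | None = None) -> np.ndarray:
    """Expected force E[F](t) = sum_l P_l(t) F_l(l(t)).

    ``aggregated`` is (T, N+1), ``lengths`` the matching l(t).  With
    ``n_strands`` the single-strand expectation is scaled to a
    half-sarcomere (parallel, independent strands).
    """
    aggregated = np.asarray(aggregated, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if aggregated.ndim != 2 or aggregated.shape[0] != lengths.size:
        raise ValidationError("aggregated must be (T, N+1) matching lengths")
    F_table = family.table(lengths)
    if F_table.shape != aggregated.shape:
        raise ValidationError(
            f"family has {F_table.shape[1]} states but aggregated has "
            f"{aggregated.shape[1]} columns")
    ef = np.einsum("tl,tl->t", aggregated, F_table)
    return ef * n_strands if n_strands else ef


@dataclass
class FirstUnfoldingDensity:
    """Density of the force at the first unfolding event under a protocol.

    ``density_force`` integrates (over force) to ``1 - no_event_mass``;
    when the all-folded force curve is not strictly monotone over the
    protocol the density is reported in the time domain only.
    """

    times: np.ndarray
    forces: np.ndarray
    survival: np.ndarray
    density_time: np.ndarray
    density_force: np.ndarray | None
    no_event_mass: float

    def conditional_cdf(self, F) -> np.ndarray:
        """CDF of the first-unfolding force, conditional on an event."""
        if self.density_force is None:
            raise ValidationError("force-domain density unavailable")
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (self.density_force[1:] + self.density_force[:-1])
            * np.diff(self.forces))])
        cdf /= cdf[-1]
        return np.interp(F, self.forces, cdf)


def first_unfolding_distribution(model: ClusterModel,
                                 family: ForceCurveFamily,
                                 protocol: LengthProtocol, *,
                                 dt: float = 1e-4) -> FirstUnfoldingDensity:
    """Exact distribution of the force at the first unfolding event.

    The survival of the all-folded state is
    P_0(t) = exp(-sum_k n_k int_0^t u_k(F_0(tau)) dtau) (quadrature on the
    protocol grid); the first-event hazard sum_k n_k u_k(F_0(t)) maps the
    time density through the monotone F_0(l(t)) to a force density.
    Refolding must be disabled.
    """
    if model.refolding is not None:
        raise ConfigError("first-unfolding distribution requires "
                          "refolding to be off")
    t_grid, lengths, F_table = _prepare(protocol, model, family, dt)
    F0 = F_table[:, 0]
    u = model.unfold_rates(F0)                           # (T, m)
    hazard = u @ model.sizes.astype(float)
    cumh = np.concatenate([[0.0], np.cumsum(
        0.5 * (hazard[1:] + hazard[:-1]) * np.diff(t_grid))])
    survival = np.exp(-cumh)
    density_time = hazard * survival
    dFdt = np.gradient(F0, t_grid)
    density_force = None
    if np.all(dFdt > 0):
        density_force = density_time / dFdt
    return FirstUnfoldingDensity(t_grid, F0, survival, density_time,
                                 density_force, float(survival[-1]))
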