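"""Monte Carlo simulation of titin strand ensembles under length ramps.

Fixed-time-step Bernoulli scheme: at every step one uniform draw z is
compared against the cumulative intervals of the per-cluster event
probabilities (n_k - i_k) * u_k(F) * dt (and i_k * r(F) * dt when refolding
is enabled), so at most one unfolding/refolding event happens per step.
The per-step total event probability must stay small for the scheme to be
valid; a configurable guard raises :class:`TimeStepError` when it exceeds
its bound (default 0.1).

Strand randomness is counter-seeded: strand ``i`` of a run with seed ``s``
always consumes the stream of ``default_rng([s, i])``, so results are
reproducible regardless of batching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import TimeStepError, ValidationError
from .kinetics import ClusterModel
from .mechanics import ForceCurveFamily
from .protocols import LengthProtocol

__all__ = [
    "Event",
    "StrandTrace",
    "EnsembleResult",
    "FirstUnfoldingSample",
    "step",
    "simulate_ensemble",
    "mce",
    "first_unfolding_forces",
]

ForceEval = Literal["as_printed", "start", "end"]

_Z_CHUNK = 512  # time steps of uniforms generated per strand at a time


@dataclass(frozen=True)
class Event:
    time: float
    strand: int
    cluster: int
    kind: str  # "unfold" | "refold"
    force: float


@dataclass
class StrandTrace:
    """Per-strand trajectory: force and unfolded count over the time grid."""

    times: np.ndarray
    lengths: np.ndarray
    forces: np.ndarray
    unfolded: np.ndarray  # total unfolded count per time point
    events: list[Event]


@dataclass
class EnsembleResult:
    times: np.ndarray
    lengths: np.ndarray
    mean_force: np.ndarray
    R: int
    seed: int
    first_unfold_force: np.ndarray  # NaN where a strand never unfolded
    traces: list[StrandTrace] | None = None
    forces: np.ndarray | None = None  # (R, T) when retained
    final_counts: np.ndarray | None = None  # (R, m) per-cluster at end
    max_step_prob_observed: float = 0.0

    @property
    def final_unfolded(self) -> np.ndarray:
        """Total unfolded domains per strand at the end of the protocol."""
        return self.final_counts.sum(axis=1)


@dataclass
class FirstUnfoldingSample:
    forces: np.ndarray
    n_excluded: int


def _event_probabilities(counts: np.ndarray, F_ev: np.ndarray,
                         model: ClusterModel, dt: float) -> np.ndarray:
    """Per-cluster event probabilities for one step; shape (S, m) or (S, 2m)."""
    sizes = model.sizes
    u = model.unfold_rates(F_ev)              # (S, m)
    P = (sizes - counts) * u * dt
    if model.refolding is not None:
        r = model.refold_rates(F_ev)          # (S,)
        P = np.concatenate([P, counts * r[:, None] * dt], axis=1)
    return P


def _apply_events(counts: np.ndarray, z: np.ndarray, P: np.ndarray,
                  m: int) -> np.ndarray:
    """Select at most one event per strand from z; returns event column or -1."""
    cum = np.cumsum(P, axis=1)
    total = cum[:, -1]
    hit = (z > 0.0) & (z <= total)
    idx = np.where(hit, (cum < z[:, None]).sum(axis=1), -1)
    unfold = hit & (idx < m)
    refold = hit & (idx >= m)
    if np.any(unfold):
        rows = np.nonzero(unfold)[0]
        counts[rows, idx[rows]] += 1
    if np.any(refold):
        rows = np.nonzero(refold)[0]
        counts[rows, idx[rows] - m] -= 1
    return idx


def step(state, t: float, dt: float, rng: np.random.Generator, *,
         protocol: LengthProtocol, model: ClusterModel,
         family: ForceCurveFamily, max_step_prob: float = 0.1,
         force_eval: ForceEval = "as_printed") -> np.ndarray:
    """Advance one strand by one time step; returns the new count vector.

    Draws a single uniform z and selects at most one event by comparing z
    against the cumulative per-cluster probability intervals.  Unfolding
    hazards are evaluated at the force at the start of the step; with
    refolding enabled the published scheme evaluates both hazard kinds at
    the end-of-step length (``force_eval="as_printed"``, the default;
    "start"/"end" force one convention for both modes).
    """
    state = np.asarray(state, dtype=int)
    if state.shape != (model.m,) or np.any(state < 0) \
            or np.any(state > model.sizes):
        raise ValidationError("state must hold per-cluster counts in [0, n_k]")
    if dt <= 0:
        raise ValidationError("dt must be positive")
    counts = state[None, :].copy()
    level = int(counts.sum())
    refold_mode = model.refolding is not None
    if force_eval == "end" or (force_eval == "as_printed" and refold_mode):
        t_ev = t + dt
    else:
        t_ev = t
    F_ev = np.array([family.forces_at(float(protocol.length_at(t_ev)))[level]])
    P = _event_probabilities(counts, F_ev, model, dt)
    if P.sum() > max_step_prob:
        raise TimeStepError(
            f"total event probability {P.sum():.3g} exceeds "
            f"{max_step_prob} at t={t:.6g}; reduce dt")
    z = np.array([rng.random()])
    _apply_events(counts, z, P, model.m)
    return counts[0]


def _strand_rngs(seed: int, strand_ids: np.ndarray
                 ) -> list[np.random.Generator]:
    return [np.random.default_rng([int(seed), int(i)]) for i in strand_ids]


def _run_batch(protocol: LengthProtocol, model: ClusterModel,
               family: ForceCurveFamily, dt: float, seed: int,
               strand_ids: np.ndarray, *, max_step_prob: float = 0.1,
               force_eval: ForceEval = "as_printed",
               group_ids: np.ndarray | None = None,
               retain_forces: bool = False, retain_counts: bool = False,
               record_events: bool = False):
    """Vectorised simulation of a batch of strands on the protocol grid.

    Returns a dict with the time grid, group-summed forces (or the full
    force matrix), first-unfolding forces, final counts and event logs.
    """
    t_grid = protocol.time_grid(dt)
    T = t_grid.size
    lengths = protocol.length_at(t_grid)
    F_table = family.table(lengths)               # (T, N+1)
    S = strand_ids.size
    m = model.m
    counts = np.zeros((S, m), dtype=np.int64)
    level = counts.sum(axis=1)
    refold_mode = model.refolding is not None
    use_end = force_eval == "end" or (force_eval == "as_printed"
                                      and refold_mode)
    rngs = _strand_rngs(seed, strand_ids)
    rows = np.arange(S)

    if group_ids is None:
        group_ids = np.zeros(S, dtype=int)
    n_groups = int(group_ids.max()) + 1
    group_sums = np.zeros((n_groups, T))
    group_n = np.bincount(group_ids, minlength=n_groups).astype(float)

    forces = np.empty((S, T)) if retain_forces else None
    levels = np.empty((S, T), dtype=np.int16) if retain_counts else None
    first_force = np.full(S, np.nan)
    events: list[Event] = []
    max_prob = 0.0

    z_block = np.empty((S, 0))
    z_off = 0
    for n in range(T - 1):
        if z_off >= z_block.shape[1]:
            width = min(_Z_CHUNK, T - 1 - n)
            z_block = np.stack([g.random(width) for g in rngs])
            z_off = 0
        F_now = F_table[n, level]
        group_sums[:, n] += np.bincount(group_ids, weights=F_now,
                                        minlength=n_groups)
        if retain_forces:
            forces[:, n] = F_now
        if retain_counts:
            levels[:, n] = level
        F_ev = F_table[n + 1, level] if use_end else F_now
        P = _event_probabilities(counts, F_ev, model, dt)
        total = P.sum(axis=1)
        worst = total.max() if S else 0.0
        max_prob = max(max_prob, float(worst))
        if worst > max_step_prob:
            s_bad = int(strand_ids[int(np.argmax(total))])
            raise TimeStepError(
                f"total event probability {worst:.3g} exceeds "
                f"{max_step_prob} at t={t_grid[n]:.6g} (strand {s_bad}); "
                f"reduce dt")
        z = z_block[:, z_off]
        z_off += 1
        idx = _apply_events(counts, z, P, m)
        hit = idx >= 0
        if np.any(hit):
            level = counts.sum(axis=1)
            new_first = hit & (idx < m) & np.isnan(first_force)
            first_force[new_first] = F_ev[new_first]
            if record_events:
                for r_ in np.nonzero(hit)[0]:
                    kind = "unfold" if idx[r_] < m else "refold"
                    events.append(Event(float(t_grid[n]),
                                        int(strand_ids[r_]),
                                        int(idx[r_] % m), kind,
                                        float(F_ev[r_])))
    F_now = F_table[T - 1, level]
    group_sums[:, T - 1] += np.bincount(group_ids, weights=F_now,
                                        minlength=n_groups)
    if retain_forces:
        forces[:, T - 1] = F_now
    if retain_counts:
        levels[:, T - 1] = level
    return {
        "times": t_grid,
        "lengths": lengths,
        "group_means": group_sums / group_n[:, None],
        "forces": forces,
        "levels": levels,
        "first_force": first_force,
        "counts": counts,
        "events": events,
        "max_prob": max_prob,
    }


def simulate_ensemble(protocol: LengthProtocol, R: int, model: ClusterModel,
                      family: ForceCurveFamily, *, dt: float = 1e-3,
                      seed: int = 0, max_step_prob: float = 0.1,
                      force_eval: ForceEval = "as_printed",
                      retain_traces: bool = False,
                      record_events: bool = False) -> EnsembleResult:
    """Simulate R independent strands, all starting fully folded.

    Returns the ensemble-mean force on the protocol's uniform time grid;
    per-strand traces and event logs are retained on request.  Identical
    (seed, R, protocol, model) inputs give bitwise-identical results.
    """
    if R < 1:
        raise ValidationError("R must be >= 1")
    out = _run_batch(protocol, model, family, dt, seed, np.arange(R),
                     max_step_prob=max_step_prob, force_eval=force_eval,
                     retain_forces=retain_traces, retain_counts=retain_traces,
                     record_events=record_events or retain_traces)
    traces = None
    if retain_traces:
        by_strand: dict[int, list[Event]] = {i: [] for i in range(R)}
        for ev in out["events"]:
            by_strand[ev.strand].append(ev)
        traces = [StrandTrace(out["times"], out["lengths"],
                              out["forces"][i], out["levels"][i],
                              by_strand[i]) for i in range(R)]
    return EnsembleResult(
        times=out["times"], lengths=out["lengths"],
        mean_force=out["group_means"][0], R=R, seed=seed,
        first_unfold_force=out["first_force"], traces=traces,
        forces=out["forces"], final_counts=out["counts"],
        max_step_prob_observed=out["max_prob"])


def mce(R: int, H: int, protocol: LengthProtocol, model: ClusterModel,
        family: ForceCurveFamily, *, dt: float = 1e-3, seed: int = 0,
        max_step_prob: float = 0.1,
        force_eval: ForceEval = "as_printed") -> float:
    """Monte Carlo error of the R-strand ensemble mean (SI force units, N).

    Runs H independent ensembles of R strands and returns
    sqrt(sup over the length grid of the across-repeat variance of the
    ensemble-mean force): MCE(R)^2 = || <F_h^2(.)> - <F_h(.)>^2 ||_inf.
    """
    if R < 2 or H < 2:
        raise ValidationError("R and H must be >= 2")
    child = np.random.SeedSequence(seed).generate_state(H) & 0x7FFFFFFF
    # Each repeat h uses its own root seed, so its strands are independent
    # of every other repeat's; all H*R strands run in one vectorised batch
    # per repeat to bound memory.
    means = []
    for h in range(H):
        out = _run_batch(protocol, model, family, dt, int(child[h]),
                         np.arange(R), max_step_prob=max_step_prob,
                         force_eval=force_eval)
        means.append(out["group_means"][0])
    means = np.vstack(means)                     # (H, T)
    var = means.var(axis=0)                      # population variance
    return float(np.sqrt(var.max()))


def first_unfolding_forces(ensemble: EnsembleResult) -> FirstUnfoldingSample:
    """Forces at each strand's first unfolding event.

    Strands that never unfolded are excluded; their count is reported.
    """
    ff = ensemble.first_unfold_force
    sample = ff[~np.isnan(ff)]
    return FirstUnfoldingSample(np.sort(sample), int(np.isnan(ff).sum()))
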