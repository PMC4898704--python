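"""Force-length mechanics of a single titin strand.

A titin strand spanning the half sarcomere is modelled as a series chain of
one-dimensional elastic elements:

* the PEVK segment — a modified worm-like chain (WLC) with stretch modulus
  ``F0`` accounting for enthalpic elasticity,
* the folded proximal Ig domains — a WLC whose contour length shrinks as
  domains unfold,
* the unfolded proximal Ig domains — a WLC whose contour length grows by the
  unfolding gain ``d_u`` per unfolded domain,
* the distal-Ig end filament and the A-band/slack region — two very stiff
  linear springs, the latter carrying the zero-force slack length.

At a prescribed half-sarcomere length ``l`` and a given number of unfolded
domains ``i`` the chain is in mechanical equilibrium when every element
carries the same tension ``F`` and the element extensions sum to ``l``.
Solving this balance for every ``i = 0..N`` yields the family of force
curves ``F_i(l)`` — the discrete random variable whose distribution the
kinetic solvers evolve.

All quantities are SI internally (m, N, K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._constants import BOLTZMANN
from .errors import DomainError, SolverError, ValidationError

__all__ = [
    "MechanicalParams",
    "Isoform",
    "SegmentLengths",
    "ForceCurveFamily",
    "WormLikeChain",
    "ModifiedWormLikeChain",
    "LinearSpring",
    "wlc_force",
    "modified_wlc_force",
    "element_length_at_force",
    "solve_strand",
    "build_force_curves",
    "default_length_grid",
    "strand_elements",
]

# Fraction of the contour length at which the WLC inversion is bracketed.
_WLC_EPS = 1e-9


@dataclass(frozen=True)
class MechanicalParams:
    """Mechanical parameters of the strand model.

    Defaults are literature averages for skeletal-muscle titin:
    persistence/contour lengths of the PEVK and Ig chains, the PEVK stretch
    modulus ``F0``, the contour gain per unfolded Ig domain ``d_u``, and the
    stiffnesses of the end-filament and A-band/slack springs.

    ``cl_pevk_per_residue`` and ``cl_ig_per_unit`` are per-residue /
    per-unit contour lengths; whole-chain contours are assembled from the
    isoform counts.  A folded Ig domain contributes
    ``folded_units_per_domain * cl_ig_per_unit`` (default 4.5 nm) of contour
    to the folded chain, and unfolding moves it to the unfolded chain with a
    net contour gain of exactly ``d_u``.

    ``slack_length`` is absorbed by the A-band/slack element at zero force;
    below it the strand is slack and the force is exactly zero.  The default
    places force onset at a half-sarcomere length of 1 um.
    """

    pl_pevk: float = 6.0e-10
    cl_pevk_per_residue: float = 3.6e-10
    F0: float = 150.0e-12
    pl_ig: float = 8.5e-10
    cl_ig_per_unit: float = 4.5e-10
    d_u: float = 25.0e-9
    k_end: float = 2.0
    k_rest: float = 2.0
    temperature: float = 300.0
    slack_length: float = 1.0e-6
    folded_units_per_domain: int = 10

    def __post_init__(self) -> None:
        for name in (
            "pl_pevk", "cl_pevk_per_residue", "F0", "pl_ig", "cl_ig_per_unit",
            "d_u", "k_end", "k_rest", "temperature",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.slack_length < 0:
            raise ValidationError("slack_length must be non-negative")
        if self.folded_units_per_domain < 1:
            raise ValidationError("folded_units_per_domain must be >= 1")

    @property
    def kT(self) -> float:
        """Thermal energy k_B * T in joules."""
        return BOLTZMANN * self.temperature

    @property
    def folded_contour_per_domain(self) -> float:
        return self.folded_units_per_domain * self.cl_ig_per_unit


@dataclass(frozen=True)
class Isoform:
    """Domain composition of the titin isoform.

    The default is the rabbit psoas 3400-kDa isoform: 50 proximal Ig
    domains, 800 PEVK residues, 26 distal Ig domains.  ``n_prox_ig`` is the
    number N of unfoldable domains; the distal Ig domains form the
    end filament and do not unfold.
    """

    n_prox_ig: int = 50
    n_pevk_residues: int = 800
    n_dist_ig: int = 26

    def __post_init__(self) -> None:
        for name in ("n_prox_ig", "n_pevk_residues", "n_dist_ig"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValidationError(f"{name} must be a positive integer")


@dataclass(frozen=True)
class SegmentLengths:
    """Equilibrium lengths of the strand segments at one (l, i) state."""

    l_pevk: float
    l_folded_total: float
    l_unfolded_total: float
    l_end: float
    l_rest: float

    @property
    def total(self) -> float:
        return (self.l_pevk + self.l_folded_total + self.l_unfolded_total
                + self.l_end + self.l_rest)


# ---------------------------------------------------------------------------
# WLC primitives
# ---------------------------------------------------------------------------

def _wlc_phi(r):
    """Dimensionless WLC force phi = F*pl/kT as a function of r = x/cl."""
    return 0.25 / (1.0 - r) ** 2 - 0.25 + r


def _wlc_dphi(r):
    return 0.5 / (1.0 - r) ** 3 + 1.0


def _wlc_inverse(phi):
    """Invert the interpolation-formula WLC: r = x/cl from phi = F*pl/kT.

    Vectorised bisection on [0, 1 - 1e-9] followed by Newton polish.
    """
    phi = np.asarray(phi, dtype=float)
    lo = np.zeros_like(phi)
    hi = np.full_like(phi, 1.0 - _WLC_EPS)
    # 60 bisection steps bring the bracket below 1e-18; Newton then
    # converges to machine precision.
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = _wlc_phi(mid) < phi
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    r = 0.5 * (lo + hi)
    for _ in range(3):
        step = (_wlc_phi(r) - phi) / _wlc_dphi(r)
        r = np.clip(r - step, 0.0, 1.0 - _WLC_EPS)
    return np.where(phi <= 0.0, 0.0, r)


def wlc_force(x, pl: float, cl: float, temperature: float):
    """Entropic WLC force (interpolation formula) at end-to-end length x.

    F = (kT/pl) * [ 1/4 (1 - x/cl)^-2 - 1/4 + x/cl ].

    Diverges as x approaches the contour length cl.
    """
    x = np.asarray(x, dtype=float)
    if pl <= 0 or cl <= 0 or temperature <= 0:
        raise ValidationError("pl, cl and temperature must be positive")
    if np.any(x < 0):
        raise ValidationError("extension must be non-negative")
    if np.any(x >= cl):
        raise DomainError("extension must be below the contour length")
    out = (BOLTZMANN * temperature / pl) * _wlc_phi(x / cl)
    return out if out.ndim else float(out)


def modified_wlc_force(x, pl: float, cl: float, F0: float,
                       temperature: float, *, max_iter: int = 200):
    """Force of the modified WLC with stretch modulus F0 at extension x.

    Solves the implicit relation
    F = (kT/pl) * [ 1/4 (1 - x/cl + F/F0)^-2 - 1/4 + x/cl - F/F0 ]
    for F.  The substitution y = x/cl - F/F0 maps it onto the plain WLC,
    so x(F) = cl * (wlc_inverse(F*pl/kT) + F/F0) is strictly increasing and
    unbounded; the root is bracketed and found with Brent's method.
    Reduces to :func:`wlc_force` in the limit F0 -> infinity.
    """
    if F0 <= 0:
        raise ValidationError("F0 must be strictly positive")
    xs = float(x)
    if xs < 0:
        raise ValidationError("extension must be non-negative")
    if xs == 0.0:
        return 0.0
    kT = BOLTZMANN * temperature

    def g(F):
        return cl * (float(_wlc_inverse(F * pl / kT)) + F / F0) - xs

    hi = kT / pl
    for _ in range(max_iter):
        if g(hi) >= 0.0:
            break
        hi *= 2.0
    else:
        raise SolverError(
            f"modified WLC bracketing failed: x={xs!r}, cl={cl!r}, F0={F0!r}")
    return brentq(g, 0.0, hi, xtol=1e-30, rtol=8.9e-16, maxiter=300)


# ---------------------------------------------------------------------------
# Series elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WormLikeChain:
    pl: float
    cl: float
    temperature: float

    def length_at_force(self, F):
        F = np.asarray(F, dtype=float)
        r = _wlc_inverse(F * self.pl / (BOLTZMANN * self.temperature))
        out = self.cl * r
        return out if out.ndim else float(out)

    def force_at_length(self, x):
        return wlc_force(x, self.pl, self.cl, self.temperature)

    def compliance(self, F):
        """dx/dF at force F."""
        F = np.asarray(F, dtype=float)
        kT = BOLTZMANN * self.temperature
        r = _wlc_inverse(F * self.pl / kT)
        out = self.cl * (self.pl / kT) / _wlc_dphi(r)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModifiedWormLikeChain:
    pl: float
    cl: float
    F0: float
    temperature: float

    def length_at_force(self, F):
        F = np.asarray(F, dtype=float)
        kT = BOLTZMANN * self.temperature
        r = _wlc_inverse(F * self.pl / kT)
        out = self.cl * (r + F / self.F0)
        return out if out.ndim else float(out)

    def force_at_length(self, x):
        return modified_wlc_force(x, self.pl, self.cl, self.F0,
                                  self.temperature)

    def compliance(self, F):
        F = np.asarray(F, dtype=float)
        kT = BOLTZMANN * self.temperature
        r = _wlc_inverse(F * self.pl / kT)
        out = self.cl * ((self.pl / kT) / _wlc_dphi(r) + 1.0 / self.F0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class LinearSpring:
    k: float

    def length_at_force(self, F):
        F = np.asarray(F, dtype=float)
        out = F / self.k
        return out if out.ndim else float(out)

    def force_at_length(self, x):
        return self.k * float(x)

    def compliance(self, F):
        F = np.asarray(F, dtype=float)
        out = np.full_like(F, 1.0 / self.k)
        return out if out.ndim else float(out)


Element = WormLikeChain | ModifiedWormLikeChain | LinearSpring


def element_length_at_force(element: Element, F):
    """Extension of a series element at tension F (inverse constitutive law)."""
    if np.any(np.asarray(F, dtype=float) < 0):
        raise ValidationError("force must be non-negative")
    return element.length_at_force(F)


def strand_elements(params: MechanicalParams, isoform: Isoform,
                    n_unfolded: int) -> list[Element]:
    """Series elements of a strand with ``n_unfolded`` unfolded Ig domains.

    Order: PEVK, folded Ig chain, unfolded Ig chain, end filament,
    A-band/slack spring.  Chains with zero contour are omitted.
    """
    N = isoform.n_prox_ig
    if not 0 <= n_unfolded <= N:
        raise ValidationError(f"n_unfolded must be in [0, {N}]")
    T = params.temperature
    elements: list[Element] = [
        ModifiedWormLikeChain(
            params.pl_pevk,
            isoform.n_pevk_residues * params.cl_pevk_per_residue,
            params.F0, T),
    ]
    cl_folded = (N - n_unfolded) * params.folded_contour_per_domain
    if cl_folded > 0:
        elements.append(WormLikeChain(params.pl_ig, cl_folded, T))
    cl_unfolded = n_unfolded * (params.folded_contour_per_domain + params.d_u)
    if cl_unfolded > 0:
        elements.append(WormLikeChain(params.pl_ig, cl_unfolded, T))
    elements.append(LinearSpring(params.k_end))
    elements.append(LinearSpring(params.k_rest))
    return elements


def _chain_extension(elements: Sequence[Element], F):
    return sum(e.length_at_force(F) for e in elements)


def _chain_compliance(elements: Sequence[Element], F):
    return sum(e.compliance(F) for e in elements)


_F_CAP = 1e-2  # N; far beyond any physical titin force


def solve_strand(l: float, n_unfolded: int, params: MechanicalParams,
                 isoform: Isoform) -> tuple[float, SegmentLengths]:
    """Mechanical equilibrium of a strand at half-sarcomere length ``l``.

    Returns the common tension F and the segment lengths.  Equilibrium is
    the first-order condition of the convex series-chain energy: equal
    tension in every element with extensions summing to ``l``.  Below the
    slack length the constraint is inactive and F = 0.
    """
    if l < 0:
        raise ValidationError("length must be non-negative")
    elements = strand_elements(params, isoform, n_unfolded)
    ext = l - params.slack_length
    if ext <= 0:
        return 0.0, SegmentLengths(0.0, 0.0, 0.0, 0.0, l)

    def g(F):
        return _chain_extension(elements, F) - ext

    hi = 1e-15
    while g(hi) < 0.0:
        hi *= 4.0
        if hi > _F_CAP:
            raise DomainError(
                f"length {l!r} m exceeds the reachable extension at "
                f"n_unfolded={n_unfolded}")
    F = brentq(g, 0.0, hi, xtol=1e-30, rtol=8.9e-16, maxiter=300)
    # Newton polish to drive the force-balance residual to roundoff.
    for _ in range(8):
        res = g(F)
        F_new = F - res / _chain_compliance(elements, F)
        if not F_new > 0 or F_new == F:
            break
        F = F_new
    segs = _segment_lengths(elements, params, isoform, n_unfolded, F, l)
    return F, segs


def _segment_lengths(elements, params, isoform, n_unfolded, F, l):
    n_folded = isoform.n_prox_ig - n_unfolded
    it = iter(elements)
    l_pevk = next(it).length_at_force(F)
    l_folded = next(it).length_at_force(F) if n_folded > 0 else 0.0
    l_unfolded = next(it).length_at_force(F) if n_unfolded > 0 else 0.0
    l_end = next(it).length_at_force(F)
    l_rest = params.slack_length + next(it).length_at_force(F)
    return SegmentLengths(l_pevk, l_folded, l_unfolded, l_end, l_rest)


# ---------------------------------------------------------------------------
# Force-curve family
# ---------------------------------------------------------------------------

@dataclass
class ForceCurveFamily:
    """Tabulated equilibrium forces F_i(l) for i = 0..N unfolded domains.

    ``forces`` has one row per unfolding state (N+1 rows) on a strictly
    increasing ``length_grid``; linear interpolation between nodes.
    """

    length_grid: np.ndarray
    forces: np.ndarray
    params: MechanicalParams | None = None
    isoform: Isoform | None = None

    def __post_init__(self) -> None:
        self.length_grid = np.asarray(self.length_grid, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.length_grid.ndim != 1 or np.any(np.diff(self.length_grid) <= 0):
            raise ValidationError("length_grid must be strictly increasing 1-D")
        if self.forces.shape[1] != self.length_grid.size:
            raise ValidationError("forces must have one column per grid node")
        if np.any(self.forces < 0):
            raise ValidationError("forces must be non-negative")

    @property
    def n_states(self) -> int:
        return self.forces.shape[0]

    @property
    def n_domains(self) -> int:
        return self.n_states - 1

    def force_at(self, i: int, l) -> float | np.ndarray:
        """F_i at (scalar or array) length l, linear interpolation."""
        return np.interp(l, self.length_grid, self.forces[i])

    def forces_at(self, l: float) -> np.ndarray:
        """Vector (F_0(l), ..., F_N(l)) at a single length l."""
        grid = self.length_grid
        j = int(np.clip(np.searchsorted(grid, l), 1, grid.size - 1))
        w = (l - grid[j - 1]) / (grid[j] - grid[j - 1])
        w = min(max(w, 0.0), 1.0)
        return (1.0 - w) * self.forces[:, j - 1] + w * self.forces[:, j]

    def table(self, lengths: np.ndarray) -> np.ndarray:
        """Matrix of shape (len(lengths), N+1) with F_i at each length."""
        lengths = np.asarray(lengths, dtype=float)
        out = np.empty((lengths.size, self.n_states))
        for i in range(self.n_states):
            out[:, i] = np.interp(lengths, self.length_grid, self.forces[i])
        return out

    def to_csv(self, path) -> None:
        """Write the family as CSV: length in um, one F_i column in pN."""
        df = pd.DataFrame({"length_um": self.length_grid * 1e6})
        for i in range(self.n_states):
            df[f"F_{i}_pN"] = self.forces[i] * 1e12
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ForceCurveFamily":
        df = pd.read_csv(path)
        grid = df["length_um"].to_numpy() * 1e-6
        cols = [c for c in df.columns if c.startswith("F_")]
        forces = np.vstack([df[c].to_numpy() * 1e-12 for c in cols])
        return cls(grid, forces)


def build_force_curves(length_grid: np.ndarray,
                       params: MechanicalParams,
                       isoform: Isoform) -> ForceCurveFamily:
    """Tabulate F_i(l) for every unfolding state on a length grid.

    The equilibrium is inverted per state: the chain extension x_i(F) is
    tabulated on a dense geometric force grid, interpolated to the target
    extensions, and polished with Newton iterations on the force balance.
    """
    grid = np.asarray(length_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValidationError("length_grid must be strictly increasing 1-D")
    if grid[0] > params.slack_length:
        raise ValidationError(
            "length_grid must start at or below the slack length so the "
            "zero-force onset is captured")
    N = isoform.n_prox_ig
    ext = grid - params.slack_length
    taut = ext > 0
    forces = np.zeros((N + 1, grid.size))
    for i in range(N + 1):
        elements = strand_elements(params, isoform, i)
        if not np.any(taut):
            continue
        target = ext[taut]
        hi = 1e-12
        while _chain_extension(elements, hi) < target[-1]:
            hi *= 4.0
            if hi > _F_CAP:
                raise SolverError(
                    f"force bracket exhausted for state i={i} at "
                    f"l={grid[taut][-1]!r}")
        f_tab = np.concatenate(([0.0], np.geomspace(1e-16, hi, 3000)))
        x_tab = _chain_extension(elements, f_tab)
        F = np.interp(target, x_tab, f_tab)
        prev = None
        for _ in range(80):
            res = _chain_extension(elements, F) - target
            if np.all(np.abs(res) <= 1e-22 + 4e-16 * target):
                break
            step = res / _chain_compliance(elements, F)
            F = np.maximum(F - step, 0.5 * F)
            if prev is not None and np.array_equal(F, prev):
                break  # converged to fixed point at roundoff
            prev = F.copy()
        else:
            raise SolverError(f"Newton refinement stalled for state i={i}")
        forces[i, taut] = F
    return ForceCurveFamily(grid, forces, params=params, isoform=isoform)


def default_length_grid(l_min: float = 0.99e-6, l_max: float = 2.0e-6,
                        spacing: float = 1e-9) -> np.ndarray:
    """Default tabulation grid: 1 nm spacing over the protocol range."""
    n = int(round((l_max - l_min) / spacing))
    return l_min + spacing * np.arange(n + 1)
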