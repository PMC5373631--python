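"""Whole-cell kinetic model of actin turnover in podocyte foot processes.

Three actin pools are tracked: diffusible monomer ``Ga`` (G-actin, available
cell-wide), filaments ``Fa`` (F-actin) and crosslinked bundles ``Bu``
(stress-fiber-like), the latter two residing in the foot processes (FPs).
All concentrations are non-dimensional.  The reactions are

    dFa/dt = alpha_f*Ga*Fa^h/(Fa^h + k^h)        (feedback nucleation)
           + gamma_f*Ga*Fa + 2*n*Ga^2            (elongation + nucleation)
           - alpha_b*Fa*(2*Fa + Bu)              (loss to bundling)
           - beta_f*Fa                           (filament turnover)

    dBu/dt = alpha_b*Fa*(2*Fa + Bu)              (bundle formation/growth)
           + gamma_b*Ga*Bu                       (monomer addition to bundles)
           - beta_b*Bu                           (bundle turnover)

with the monomer pool closed by whole-cell mass conservation,

    total_actin = Ga + phi_fp*(Fa + Bu),

where ``phi_fp`` is the FP share of the cell volume (the reference cell
volume is normalised to 1).  ``alpha_f`` is the Rac1/nephrin-driven positive
feedback (active only in FPs), ``alpha_b`` the RhoA-driven bundling
coefficient, and ``beta_f``/``beta_b`` turnover rates that lump
depolymerisation and mechanical rupture.

The saturation constant ``k = 0.22`` and the regime anchors
``alpha_f in {0.32, 0.1}``, ``alpha_b in {0.03, 0.05}`` are fixed;
the remaining rates are calibrated (see :func:`calibrated_params`) so that
the healthy cell sits at a 1:2 monomer:polymerised equilibrium and the four
qualitative regimes (monostable healthy, bistable, oscillatory, collapse)
appear at those anchors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root
from scipy.signal import find_peaks


class ConservationError(ValueError):
    """Raised when a state is incompatible with the closed actin pool."""


# --------------------------------------------------------------------------
# parameters and state containers


@dataclass(frozen=True)
class KineticParams:
    """Rate constants for the three-pool actin model (arbitrary units)."""

    alpha_f: float = 0.32
    gamma_f: float = 0.002
    beta_f: float = 0.05
    k: float = 0.22
    alpha_b: float = 0.03
    gamma_b: float = 0.002
    beta_b: float = 0.01
    hill_h: float = 2.0
    #: separate nucleation coefficient; ``None`` ties it to ``gamma_f``
    nucleation_n: float | None = None
    total_actin: float = 0.4
    phi_fp: float = 0.2

    def __post_init__(self) -> None:
        for name in ("alpha_f", "gamma_f", "beta_f", "alpha_b", "gamma_b",
                     "beta_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if not 0 < self.phi_fp < 1:
            raise ValueError("phi_fp must lie in (0, 1)")
        if self.hill_h < 1:
            raise ValueError("hill_h must be >= 1")
        if self.total_actin <= 0:
            raise ValueError("total_actin must be > 0")

    @property
    def nucleation(self) -> float:
        return self.gamma_f if self.nucleation_n is None else self.nucleation_n

    def replace(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ActinState:
    """Local non-dimensional concentrations of the three actin pools."""

    Ga: float
    Fa: float
    Bu: float

    def __post_init__(self) -> None:
        if self.Ga < 0 or self.Fa < 0 or self.Bu < 0:
            raise ValueError("actin concentrations must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.Ga, self.Fa, self.Bu])


class RegimeLabel(enum.Enum):
    MONOSTABLE_HEALTHY = "monostable_healthy"
    BISTABLE = "bistable"
    OSCILLATORY = "oscillatory"
    COLLAPSE = "collapse"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class Equilibrium:
    state: ActinState
    eigenvalues: tuple[complex, complex]
    stability: str  # stable | unstable | saddle
    in_effacement_region: bool


# --------------------------------------------------------------------------
# calibration

#: fraction of the polymerised pool held as filaments at the healthy state
_HEALTHY_FA_FRACTION = 0.17


def calibrated_params(total_actin: float = 0.4,
                      fa_fraction: float = _HEALTHY_FA_FRACTION,
                      **overrides) -> KineticParams:
    """Baseline parameter set with turnover rates solved from the healthy state.

    The healthy podocyte holds monomeric and polymerised actin at a 1:2
    ratio, which pins ``Ga* = total_actin/3`` and
    ``Fa* + Bu* = (2/3)*total_actin/phi_fp``.  Given the printed anchors
    (``k``, ``alpha_f``, ``alpha_b``) and the calibrated ``gamma_f``,
    ``gamma_b`` and filament share ``fa_fraction``, the turnover rates
    ``beta_f`` and ``beta_b`` follow in closed form from requiring that the
    healthy state is an exact equilibrium.
    """
    base = KineticParams(total_actin=total_actin).replace(
        **{k: v for k, v in overrides.items() if k not in ("beta_f", "beta_b")})
    ga = base.total_actin / 3.0
    pool = (base.total_actin - ga) / base.phi_fp
    fa = fa_fraction * pool
    bu = pool - fa
    fbk = base.alpha_f * ga * fa**base.hill_h / (fa**base.hill_h + base.k**base.hill_h)
    bundling = base.alpha_b * fa * (2 * fa + bu)
    growth = base.gamma_f * ga * fa + 2 * base.nucleation * ga**2
    beta_f = (fbk + growth - bundling) / fa
    beta_b = (bundling + base.gamma_b * ga * bu) / bu
    if beta_f <= 0 or beta_b <= 0:
        raise ValueError("calibration infeasible: negative turnover rate")
    return base.replace(beta_f=beta_f, beta_b=beta_b)


def healthy_state(p: KineticParams,
                  fa_fraction: float = _HEALTHY_FA_FRACTION) -> ActinState:
    """The 1:2 monomer:polymer anchor state used for calibration."""
    ga = p.total_actin / 3.0
    pool = (p.total_actin - ga) / p.phi_fp
    fa = fa_fraction * pool
    return ActinState(ga, fa, pool - fa)


def default_effacement_threshold(p: KineticParams | None = None) -> float:
    """Bundle level below which an FP is considered effaced.

    10% of the healthy-equilibrium bundle concentration of the baseline set.
    """
    if p is None:
        p = calibrated_params()
    return 0.1 * healthy_state(p).Bu


# --------------------------------------------------------------------------
# right-hand side


def rhs(state: ActinState, p: KineticParams) -> tuple[float, float, float]:
    """Local reaction rates (dFa/dt, dBu/dt, dGa/dt) at an FP point.

    The three rates sum to zero (stoichiometric closure): every reaction
    moves actin between pools, never creates or destroys it.
    """
    dfa, dbu = reaction_rates(state.Fa, state.Bu, state.Ga, p)
    return float(dfa), float(dbu), float(-(dfa + dbu))


def reaction_rates(fa, bu, ga, p: KineticParams):
    """Vectorised (dFa/dt, dBu/dt) given local G-actin; arrays broadcast."""
    fa = np.asarray(fa, dtype=float)
    bu = np.asarray(bu, dtype=float)
    ga = np.asarray(ga, dtype=float)
    h = p.hill_h
    fah = np.power(np.maximum(fa, 0.0), h)
    feedback = p.alpha_f * ga * fah / (fah + p.k**h)
    growth = p.gamma_f * ga * fa + 2.0 * p.nucleation * ga * ga
    bundling = p.alpha_b * fa * (2.0 * fa + bu)
    dfa = feedback + growth - bundling - p.beta_f * fa
    dbu = bundling + p.gamma_b * ga * bu - p.beta_b * bu
    return dfa, dbu


def ga_from_conservation(fa, bu, p: KineticParams, *, strict: bool = True):
    """Monomer concentration implied by the closed whole-cell pool."""
    ga = p.total_actin - p.phi_fp * (np.asarray(fa, float) + np.asarray(bu, float))
    if strict and np.any(ga < -1e-12 * max(p.total_actin, 1.0)):
        raise ConservationError(
            "Fa + Bu exceeds the total actin pool; no feasible Ga")
    return np.clip(ga, 0.0, None)


def reduced_rhs(fa, bu, p: KineticParams):
    """(dFa/dt, dBu/dt) of the conservation-reduced two-variable system."""
    ga = ga_from_conservation(fa, bu, p, strict=False)
    return reaction_rates(fa, bu, ga, p)


# --------------------------------------------------------------------------
# simulation


@dataclass
class Trajectory:
    """Time course of the whole-cell model on a fixed output grid."""

    t: np.ndarray
    ga: np.ndarray
    fa: np.ndarray
    bu: np.ndarray

    def total_actin(self, p: KineticParams) -> np.ndarray:
        return self.ga + p.phi_fp * (self.fa + self.bu)

    def final_state(self) -> ActinState:
        return ActinState(float(self.ga[-1]), float(self.fa[-1]),
                          float(self.bu[-1]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.t, "Ga": self.ga, "Fa": self.fa, "Bu": self.bu})


def _modulated(p: KineticParams, protocol, t: float) -> KineticParams:
    if protocol is None:
        return p
    return protocol.apply(p, t)


def integrate_piecewise(f, t_end: float, y0, t_eval, breakpoints=(),
                        method: str = "LSODA", rtol: float = 1e-8,
                        atol: float = 1e-11, **kwargs) -> np.ndarray:
    """solve_ivp in segments split at protocol breakpoints.

    Restarting the integrator at the times where a protocol's profile is
    non-smooth keeps step-size control honest across the discontinuities.
    Returns the solution sampled at ``t_eval`` (shape (len(t_eval), n)).
    """
    t_eval = np.asarray(t_eval, float)
    cuts = sorted({float(b) for b in breakpoints if 0.0 < b < t_end})
    edges = [0.0] + cuts + [t_end]
    out = np.empty((len(t_eval), len(y0)))
    filled = np.zeros(len(t_eval), dtype=bool)
    y = np.asarray(y0, float)
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (~filled) & (t_eval <= b + 1e-12)
        pts = t_eval[sel]
        appended = len(pts) == 0 or pts[-1] < b - 1e-12
        if appended:
            pts = np.append(pts, b)  # always land exactly on the cut
        sol = solve_ivp(f, (a, b), y, method=method, rtol=rtol, atol=atol,
                        t_eval=pts, **kwargs)
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={sol.t[-1]:.4g}: {sol.message}")
        out[sel] = (sol.y[:, :-1] if appended else sol.y).T
        filled |= sel
        y = sol.y[:, -1]
    return out


def simulate(p: KineticParams,
             init: ActinState | None = None,
             t_end: float = 2000.0,
             protocol=None,
             rtol: float = 1e-8,
             atol: float = 1e-11,
             n_out: int = 800) -> Trajectory:
    """Integrate the reduced (Fa, Bu) system; Ga follows from conservation.

    ``protocol`` may be a :class:`podofp.protocols.StimulusProtocol` (or any
    object with ``apply(params, t) -> params``) modulating one rate in time.
    """
    if init is None:
        init = healthy_state(p)
    expect = init.Ga + p.phi_fp * (init.Fa + init.Bu)
    if abs(expect - p.total_actin) > 1e-6 * max(1.0, p.total_actin):
        raise ConservationError(
            f"initial state holds {expect:.6g} total actin, "
            f"parameters specify {p.total_actin:.6g}")

    def f(t, y):
        q = _modulated(p, protocol, t)
        dfa, dbu = reduced_rhs(y[0], y[1], q)
        return [dfa, dbu]

    t_eval = np.linspace(0.0, t_end, n_out)
    breaks = protocol.breakpoints() if protocol is not None else ()
    y = integrate_piecewise(f, t_end, [init.Fa, init.Bu], t_eval,
                            breakpoints=breaks, rtol=rtol, atol=atol)
    fa = np.clip(y[:, 0], 0.0, None)
    bu = np.clip(y[:, 1], 0.0, None)
    ga = ga_from_conservation(fa, bu, p, strict=False)
    return Trajectory(t_eval, ga, fa, bu)


# --------------------------------------------------------------------------
# phase-plane analysis


def _bu_roots(func: Callable[[float], float], grid: np.ndarray) -> list[float]:
    vals = np.array([func(b) for b in grid])
    roots = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(brentq(func, grid[i], grid[i + 1], xtol=1e-12))
    return roots


def nullclines(p: KineticParams,
               fa_range: tuple[float, float] | None = None,
               resolution: int = 400) -> dict[str, list[np.ndarray]]:
    """Nullcline branches of the reduced system in the (Fa, Bu) plane.

    Returns ``{"fa": [...], "bu": [...]}``; each entry is a list of (n, 2)
    arrays of points where dFa/dt = 0 (resp. dBu/dt = 0).  Multivalued
    curves appear as multiple branches, ordered by Bu.
    """
    bmax = p.total_actin / p.phi_fp
    if fa_range is None:
        fa_range = (0.0, bmax)
    if fa_range[1] <= fa_range[0] or resolution < 2:
        raise ValueError("need a positive Fa range and resolution >= 2")
    fa_grid = np.linspace(fa_range[0], fa_range[1], resolution)
    bu_grid = np.linspace(0.0, bmax, resolution)
    out: dict[str, list[np.ndarray]] = {}
    for key, idx in (("fa", 0), ("bu", 1)):
        branches: dict[int, list[tuple[float, float]]] = {}
        for fa in fa_grid:
            feasible = bu_grid[bu_grid <= bmax - fa + 1e-12]
            if len(feasible) < 2:
                continue
            roots = _bu_roots(lambda b: reduced_rhs(fa, b, p)[idx], feasible)
            for j, r in enumerate(sorted(roots)):
                branches.setdefault(j, []).append((fa, r))
        out[key] = [np.array(pts) for _, pts in sorted(branches.items())]
    return out


def _jacobian(fa: float, bu: float, p: KineticParams,
              eps: float = 1e-7) -> np.ndarray:
    J = np.zeros((2, 2))
    for i, (dfa, dbu) in enumerate(((eps, 0.0), (0.0, eps))):
        hi = reduced_rhs(fa + dfa, bu + dbu, p)
        lo = reduced_rhs(fa - dfa, bu - dbu, p)
        J[:, i] = (np.array(hi) - np.array(lo)) / (2 * eps)
    return J


def _classify_eigs(eigs: np.ndarray) -> str:
    re = np.real(eigs)
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_equilibria(p: KineticParams,
                    n_grid: int = 300,
                    threshold: float | None = None,
                    tol: float = 1e-10) -> list[Equilibrium]:
    """All equilibria of the reduced system in the feasible box.

    A dense sign-change scan over ``[0, total/phi]^2`` seeds a Newton
    polisher; duplicates are merged and the result is sorted by Fa.
    Stability comes from the eigenvalues of the reduced Jacobian.
    """
    if threshold is None:
        threshold = default_effacement_threshold()
    hi = p.total_actin / p.phi_fp
    grid = np.linspace(0.0, hi, n_grid)
    FF, BB = np.meshgrid(grid, grid, indexing="ij")
    feas = FF + BB <= hi + 1e-12
    dfa, dbu = reduced_rhs(FF, BB, p)
    sf, sb = np.sign(dfa), np.sign(dbu)
    cand = np.zeros_like(FF, dtype=bool)
    cand[:-1, :-1] = (
        ((sf[:-1, :-1] != sf[1:, :-1]) | (sf[:-1, :-1] != sf[:-1, 1:]))
        & ((sb[:-1, :-1] != sb[1:, :-1]) | (sb[:-1, :-1] != sb[:-1, 1:])))
    cand &= feas
    seeds = np.argwhere(cand)
    found: list[np.ndarray] = []
    for i, j in seeds:
        sol = root(lambda x: reduced_rhs(x[0], x[1], p), [FF[i, j], BB[i, j]],
                   method="hybr", tol=1e-13)
        if not sol.success:
            continue
        x = sol.x
        if x[0] < -1e-9 or x[1] < -1e-9 or x[0] + x[1] > hi + 1e-6:
            continue
        resid = np.hypot(*reduced_rhs(x[0], x[1], p))
        if resid > tol:
            continue
        x = np.clip(x, 0.0, None)
        if not any(np.hypot(*(x - y)) < 1e-6 * max(1.0, hi) for y in found):
            found.append(x)
    out = []
    for fa, bu in sorted(found, key=lambda x: x[0]):
        eigs = np.linalg.eigvals(_jacobian(fa, bu, p))
        ga = float(ga_from_conservation(fa, bu, p, strict=False))
        out.append(Equilibrium(
            state=ActinState(ga, float(fa), float(bu)),
            eigenvalues=(complex(eigs[0]), complex(eigs[1])),
            stability=_classify_eigs(eigs),
            in_effacement_region=bool(bu < threshold)))
    return out


def effacement_check(state: ActinState, threshold: float | None = None) -> bool:
    """True iff the bundle pool is below the effacement threshold."""
    if threshold is None:
        threshold = default_effacement_threshold()
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return state.Bu < threshold


def classify_regime(p: KineticParams,
                    threshold: float | None = None,
                    t_horizon: float | None = None) -> RegimeLabel:
    """Qualitative regime of a parameter set.

    - MONOSTABLE_HEALTHY: one stable equilibrium, outside the effacement
      region, and no other stable state.
    - BISTABLE: at least two stable equilibria, one inside the region.
    - OSCILLATORY: no stable equilibrium and a bounded attracting cycle that
      leaves the effacement region.
    - COLLAPSE: every trajectory from a standard initial grid ends inside
      the effacement region.
    """
    if threshold is None:
        threshold = default_effacement_threshold()
    eqs = find_equilibria(p, threshold=threshold)
    stable = [e for e in eqs if e.stability == "stable"]
    stable_out = [e for e in stable if not e.in_effacement_region]
    stable_in = [e for e in stable if e.in_effacement_region]
    if len(stable) >= 2:
        return RegimeLabel.BISTABLE if stable_in else RegimeLabel.UNRESOLVED
    if len(stable_out) == 1:
        return RegimeLabel.MONOSTABLE_HEALTHY
    if len(stable_in) == 1:
        return RegimeLabel.COLLAPSE
    # no stable equilibrium: long integration decides cycle vs collapse
    if t_horizon is None:
        rates = [p.beta_f, p.beta_b]
        slowest = min(r for r in rates if r > 0) if any(rates) else 1.0
        t_horizon = 50.0 / slowest
    pool = p.total_actin / p.phi_fp
    inits = [(0.2 * pool, 0.6 * pool), (0.05 * pool, 0.1 * pool),
             (0.3 * pool, 0.3 * pool)]
    any_osc = False
    all_collapse = True
    for fa0, bu0 in inits:
        ga0 = float(ga_from_conservation(fa0, bu0, p))
        traj = simulate(p, ActinState(ga0, fa0, bu0), t_end=t_horizon,
                        n_out=2000)
        tail = traj.bu[traj.t > 0.5 * t_horizon]
        amp = tail.max() - tail.min()
        if tail.max() >= threshold:
            all_collapse = False
        prominence = 0.01 * max(amp, 1e-12)
        peaks, _ = find_peaks(tail, prominence=prominence)
        if len(peaks) >= 3 and amp > 0.05 * healthy_state(p).Bu \
                and tail.max() >= threshold:
            any_osc = True
    if any_osc:
        return RegimeLabel.OSCILLATORY
    if all_collapse:
        return RegimeLabel.COLLAPSE
    return RegimeLabel.UNRESOLVED
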