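"""Two-compartment actin model with a shared, instantly mixed monomer pool.

The FP volume is split into two fractions, ``FP1`` (nominal positive
feedback ``alpha_f``) and ``FP2`` (``alpha_f + delta_alpha_f``); each
fraction follows the filament/bundle kinetics of :mod:`podofp.kinetics`
while the G-actin monomer diffuses infinitely fast, so both compartments
see the same ``Ga`` fixed by whole-cell conservation:

    Ga = total_actin - phi_fp*(frac1*(Fa1+Bu1) + frac2*(Fa2+Bu2)).

Because both compartments compete for one finite monomer pool, a localized
or transient boost of polymerisation in FP2 can permanently collapse the
bundles of either fraction: the system is tristable (symmetric recovery,
FP1 collapsed, or FP2 collapsed), the outcome selected by the stimulus
strength.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .kinetics import (ActinState, ConservationError, KineticParams,
                       default_effacement_threshold, healthy_state,
                       integrate_piecewise, reaction_rates)
from .protocols import StimulusProtocol, pulse_protocol


class TransientOutcome(enum.Enum):
    BOTH_RECOVER = "both_recover"
    FP1_COLLAPSES = "fp1_collapses"
    FP2_COLLAPSES = "fp2_collapses"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class TwoCompartmentParams:
    base: KineticParams
    frac_fp2: float = 0.5
    delta_alpha_f: float = 0.0  # sustained additive increment in FP2

    def __post_init__(self) -> None:
        if not 0 < self.frac_fp2 < 1:
            raise ValueError("frac_fp2 must lie in (0, 1)")
        if self.delta_alpha_f < 0:
            raise ValueError("delta_alpha_f must be >= 0")

    @property
    def frac_fp1(self) -> float:
        return 1.0 - self.frac_fp2

    def replace(self, **kwargs) -> "TwoCompartmentParams":
        return replace(self, **kwargs)


def shared_ga(y, p: TwoCompartmentParams, *, strict: bool = True):
    """Monomer concentration implied by conservation over both fractions."""
    fa1, bu1, fa2, bu2 = y
    b = p.base
    ga = b.total_actin - b.phi_fp * (p.frac_fp1 * (fa1 + bu1)
                                     + p.frac_fp2 * (fa2 + bu2))
    if strict and ga < -1e-12 * max(b.total_actin, 1.0):
        raise ConservationError("polymer exceeds the total actin pool")
    return max(ga, 0.0)


def rhs_two_compartment(y, p: TwoCompartmentParams, t: float = 0.0,
                        protocol: StimulusProtocol | None = None):
    """Derivatives (dFa1, dBu1, dFa2, dBu2); Ga eliminated by conservation.

    A protocol targeting ``alpha_f`` modulates compartment 2 only, on top of
    the sustained ``delta_alpha_f``.
    """
    if np.any(np.asarray(y) < -1e-9):
        raise ValueError("states must be non-negative")
    ga = shared_ga(y, p, strict=False)
    b = p.base
    delta = p.delta_alpha_f
    if protocol is not None:
        delta = delta + b.alpha_f * protocol.amplitude * protocol.profile(t)
    dfa1, dbu1 = reaction_rates(y[0], y[1], ga, b)
    dfa2, dbu2 = reaction_rates(y[2], y[3], ga,
                                b.replace(alpha_f=b.alpha_f + delta))
    return np.array([dfa1, dbu1, dfa2, dbu2])


@dataclass
class TwoCompartmentTrajectory:
    t: np.ndarray
    ga: np.ndarray
    fa1: np.ndarray
    bu1: np.ndarray
    fa2: np.ndarray
    bu2: np.ndarray

    def total_actin(self, p: TwoCompartmentParams) -> np.ndarray:
        b = p.base
        return self.ga + b.phi_fp * (p.frac_fp1 * (self.fa1 + self.bu1)
                                     + p.frac_fp2 * (self.fa2 + self.bu2))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.t, "Ga": self.ga,
                             "Fa1": self.fa1, "Bu1": self.bu1,
                             "Fa2": self.fa2, "Bu2": self.bu2})


def simulate_two(p: TwoCompartmentParams,
                 init: np.ndarray | None = None,
                 t_end: float = 6000.0,
                 protocol: StimulusProtocol | None = None,
                 rtol: float = 1e-8, atol: float = 1e-11,
                 n_out: int = 1200) -> TwoCompartmentTrajectory:
    """Integrate the coupled system from the symmetric healthy state."""
    if init is None:
        hs = healthy_state(p.base)
        init = np.array([hs.Fa, hs.Bu, hs.Fa, hs.Bu])
    t_eval = np.linspace(0.0, t_end, n_out)
    breaks = protocol.breakpoints() if protocol is not None else ()
    y = integrate_piecewise(
        lambda t, y: rhs_two_compartment(y, p, t, protocol), t_end,
        np.asarray(init, float), t_eval, breakpoints=breaks, rtol=rtol,
        atol=atol)
    fa1, bu1, fa2, bu2 = (np.clip(y[:, i], 0, None) for i in range(4))
    ga = np.array([shared_ga(s, p, strict=False)
                   for s in zip(fa1, bu1, fa2, bu2)])
    return TwoCompartmentTrajectory(t_eval, ga, fa1, bu1, fa2, bu2)


def _is_steady(y, p: TwoCompartmentParams, tol: float = 1e-8) -> bool:
    return bool(np.max(np.abs(rhs_two_compartment(y, p))) < tol)


def steady_response_surface(p_base: KineticParams,
                            delta_grid, frac_grid,
                            t_chunk: float = 4000.0, max_chunks: int = 6,
                            tol: float = 1e-8):
    """Steady bundle levels under a sustained feedback increment in FP2.

    ``delta_grid`` holds relative increments (delta_alpha_f/alpha_f) and
    ``frac_grid`` FP2 volume fractions.  Returns ``(Bu1, Bu2, converged)``
    arrays of shape ``(len(delta_grid), len(frac_grid))``; grid points
    still moving after the integration budget (e.g. oscillatory) are
    flagged unconverged, not reported as steady.
    """
    delta_grid = np.atleast_1d(np.asarray(delta_grid, float))
    frac_grid = np.atleast_1d(np.asarray(frac_grid, float))
    if delta_grid.size == 0 or frac_grid.size == 0:
        raise ValueError("grids must be non-empty")
    bu1 = np.zeros((delta_grid.size, frac_grid.size))
    bu2 = np.zeros_like(bu1)
    ok = np.zeros_like(bu1, dtype=bool)
    hs = healthy_state(p_base)
    for i, rel in enumerate(delta_grid):
        for j, frac in enumerate(frac_grid):
            p = TwoCompartmentParams(base=p_base, frac_fp2=float(frac),
                                     delta_alpha_f=rel * p_base.alpha_f)
            y = np.array([hs.Fa, hs.Bu, hs.Fa, hs.Bu])
            for _ in range(max_chunks):
                traj = simulate_two(p, init=y, t_end=t_chunk, n_out=40)
                y = np.array([traj.fa1[-1], traj.bu1[-1],
                              traj.fa2[-1], traj.bu2[-1]])
                if _is_steady(y, p, tol):
                    ok[i, j] = True
                    break
            bu1[i, j], bu2[i, j] = y[1], y[3]
    return bu1, bu2, ok


def classify_final(bu1: float, bu2: float,
                   threshold: float | None = None) -> TransientOutcome:
    if threshold is None:
        threshold = default_effacement_threshold()
    if bu1 >= threshold and bu2 >= threshold:
        return TransientOutcome.BOTH_RECOVER
    if bu1 < threshold <= bu2:
        return TransientOutcome.FP1_COLLAPSES
    if bu2 < threshold <= bu1:
        return TransientOutcome.FP2_COLLAPSES
    return TransientOutcome.UNRESOLVED


def transient_response(p_base: KineticParams,
                       protocol: StimulusProtocol | None = None,
                       frac_fp2: float = 0.5,
                       amplitude: float | None = None,
                       t_end: float = 8000.0,
                       threshold: float | None = None):
    """Response to a transient feedback pulse in FP2.

    Returns ``(trajectory, outcome)``.  The default protocol is the
    trapezoid pulse applied at t = 40; ``amplitude`` (peak
    delta_alpha_f/alpha_f) overrides the protocol's amplitude.
    """
    if protocol is None:
        protocol = pulse_protocol(
            "alpha_f", 1.0 if amplitude is None else amplitude)
    elif amplitude is not None:
        protocol = protocol.replace(amplitude=amplitude)
    if protocol.shape != "pulse":
        raise ValueError("transient_response requires a pulse protocol")
    p = TwoCompartmentParams(base=p_base, frac_fp2=frac_fp2)
    traj = simulate_two(p, t_end=t_end, protocol=protocol)
    y = np.array([traj.fa1[-1], traj.bu1[-1], traj.fa2[-1], traj.bu2[-1]])
    if not _is_steady(y, p, tol=1e-7):
        return traj, TransientOutcome.UNRESOLVED
    return traj, classify_final(y[1], y[3], threshold)


def outcome_boundary_scan(p_base: KineticParams,
                          frac_fp2: float = 0.5,
                          amplitude_range=(0.0, 3.0),
                          n_coarse: int = 13,
                          bisect_tol: float = 0.02,
                          t_end: float = 8000.0):
    """Final bundle levels vs pulse amplitude, with switching amplitudes.

    Scans a monotone amplitude grid, records final (Bu1, Bu2) and outcome
    per amplitude, then bisects the recover->FP1-collapse and
    FP1-collapse->FP2-collapse boundaries.
    """
    amps = np.linspace(*amplitude_range, n_coarse)
    if np.any(np.diff(amps) <= 0):
        raise ValueError("amplitude grid must be increasing")
    finals, outcomes = [], []
    for a in amps:
        traj, oc = transient_response(p_base, amplitude=float(a),
                                      frac_fp2=frac_fp2, t_end=t_end)
        finals.append((traj.bu1[-1], traj.bu2[-1]))
        outcomes.append(oc)

    def bisect(lo, hi, oc_lo):
        while hi - lo > bisect_tol:
            mid = 0.5 * (lo + hi)
            _, oc = transient_response(p_base, amplitude=mid,
                                       frac_fp2=frac_fp2, t_end=t_end)
            if oc == oc_lo:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    switches = {}
    for a_lo, a_hi, oc_lo, oc_hi in zip(amps[:-1], amps[1:], outcomes[:-1],
                                        outcomes[1:]):
        if oc_lo != oc_hi and (oc_lo, oc_hi) not in switches:
            switches[(oc_lo, oc_hi)] = bisect(a_lo, a_hi, oc_lo)
    return {"amplitude": amps, "bu1": np.array([f[0] for f in finals]),
            "bu2": np.array([f[1] for f in finals]),
            "outcome": outcomes, "switches": switches}
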