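"""Reaction-diffusion actin dynamics on the podocyte compartment network.

G-actin diffuses through every cell of the finite-volume network while the
filament/bundle reactions (and their Rac1-driven positive feedback) are
evaluated only inside FP cells, where nephrin signalling localises them.
Each FP is a single well-mixed cell coupled to its parent major process
through the narrow neck cross-section, so the whole cell body + major
process tree acts as a diffusion-limited monomer reservoir shared by 233
competing FPs.

After a destabilising perturbation (e.g. a global bundling increase), the
FPs — identical in parameters — desynchronise because their access to the
monomer pool differs with position along the tree.  Bundles then collapse
permanently in an irregular subset of FPs while survivors, absorbing the
released monomer, grow stronger: a deterministic but chaotic-looking
spatial pattern.  Scenario runners reproduce the global-bundling injury,
the localized transient feedback pulse, and the slow-bundle-turnover injury
with its three compensatory interventions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .geometry import FP, CompartmentNetwork
from .kinetics import KineticParams, default_effacement_threshold, \
    healthy_state, integrate_piecewise
from .protocols import StimulusProtocol, pulse_protocol, step_protocol

_MODULATABLE = ("alpha_f", "alpha_b", "beta_f", "beta_b", "gamma_f",
                "gamma_b")


@dataclass(frozen=True)
class SpatialParams:
    """Kinetics plus transport for the spatial model.

    ``phi_fp`` of the kinetic set is unused here: the geometry supplies
    actual volumes.  ``d_ga`` is the G-actin diffusivity in um^2 per model
    time unit; its default is set so that monomer redistribution across the
    ~40 um process tree competes with the bundle-cycle timescale, the
    regime in which the published desynchronisation develops between the
    perturbation at t = 40 and extensive collapse by t ~ 2400.
    """

    kinetics: KineticParams
    d_ga: float = 4.0

    def __post_init__(self) -> None:
        if self.d_ga <= 0:
            raise ValueError("d_ga must be > 0")

    def replace(self, **kwargs) -> "SpatialParams":
        return replace(self, **kwargs)


@dataclass
class SpatialTrajectory:
    """Field time course: Ga per cell, Fa/Bu per FP cell."""

    t: np.ndarray         # (nt,)
    ga: np.ndarray        # (nt, n_cells)
    fa: np.ndarray        # (nt, n_fp)
    bu: np.ndarray        # (nt, n_fp)
    fp_cells: np.ndarray  # cell index of each FP
    net: CompartmentNetwork

    @property
    def n_fp(self) -> int:
        return len(self.fp_cells)

    def total_actin(self) -> np.ndarray:
        v = self.net.volumes
        amount = self.ga @ v
        amount += (self.fa + self.bu) @ v[self.fp_cells]
        return amount


def uniform_healthy_field(net: CompartmentNetwork, p: SpatialParams):
    """Spatially uniform healthy steady state (exact for the calibrated set)."""
    hs = healthy_state(p.kinetics)
    fp_cells = net.fp_cell_ids()
    ga = np.full(net.n_cells, hs.Ga)
    fa = np.full(len(fp_cells), hs.Fa)
    bu = np.full(len(fp_cells), hs.Bu)
    return ga, fa, bu


def _normalise_protocols(protocols) -> list[StimulusProtocol]:
    if protocols is None:
        return []
    if isinstance(protocols, StimulusProtocol):
        return [protocols]
    return list(protocols)


def simulate_rd(net: CompartmentNetwork,
                p: SpatialParams,
                protocols=None,
                t_end: float = 2400.0,
                init=None,
                rtol: float = 1e-6,
                atol: float = 1e-9,
                n_out: int = 600) -> SpatialTrajectory:
    """Method-of-lines integration of the network reaction-diffusion model.

    ``dGa_i/dt = sum_j A_ij*D/(d_ij*V_i)*(Ga_j - Ga_i)`` everywhere, plus the
    local reaction source in FP cells; Fa and Bu integrate locally in FP
    cells.  The outer boundary is no-flux, so total actin is conserved to
    integrator tolerance.  ``protocols`` is a (list of)
    :class:`StimulusProtocol`; a protocol's ``region`` restricts it to the
    given FP indices.
    """
    if not net.is_connected():
        raise ValueError("network must be connected")
    protocols = _normalise_protocols(protocols)
    kin = p.kinetics
    for pr in protocols:
        if pr.param not in _MODULATABLE:
            raise ValueError(f"cannot modulate {pr.param!r}")
    fp_cells = net.fp_cell_ids()
    nf, nc = len(fp_cells), net.n_cells
    if init is None:
        ga0, fa0, bu0 = uniform_healthy_field(net, p)
    else:
        ga0, fa0, bu0 = (np.asarray(a, float).copy() for a in init)
    y0 = np.concatenate([ga0, fa0, bu0])

    M = net.exchange_matrix(p.d_ga)
    h = kin.hill_h
    kh = kin.k ** h
    base = {name: np.full(nf, getattr(kin, name)) for name in _MODULATABLE}
    nuc = kin.nucleation

    masks = []
    for pr in protocols:
        if pr.region is None:
            masks.append(np.ones(nf, dtype=bool))
        else:
            m = np.zeros(nf, dtype=bool)
            m[np.asarray(pr.region, int)] = True
            masks.append(m)

    def param_vectors(t: float) -> dict[str, np.ndarray]:
        vals = {k: v for k, v in base.items()}
        for pr, m in zip(protocols, masks):
            f = pr.profile(t)
            if f != 0.0:
                v = vals[pr.param].copy()
                v[m] = v[m] * (1.0 + pr.amplitude * f)
                vals[pr.param] = v
        return vals

    def rhs(t, y):
        ga = y[:nc]
        fa = y[nc:nc + nf]
        bu = y[nc + nf:]
        pv = param_vectors(t)
        gfp = ga[fp_cells]
        fac = np.maximum(fa, 0.0)
        fah = fac ** h
        feedback = pv["alpha_f"] * gfp * fah / (fah + kh)
        growth = pv["gamma_f"] * gfp * fa + 2.0 * nuc * gfp * gfp
        bundling = pv["alpha_b"] * fa * (2.0 * fa + bu)
        dfa = feedback + growth - bundling - pv["beta_f"] * fa
        dbu = bundling + pv["gamma_b"] * gfp * bu - pv["beta_b"] * bu
        dga = M @ ga
        np.add.at(dga, fp_cells, -(dfa + dbu))
        return np.concatenate([dga, dfa, dbu])

    # sparsity: Ga block from the exchange matrix; FP reactions couple the
    # local (Ga, Fa, Bu) triplet only
    S = sp.lil_matrix((nc + 2 * nf, nc + 2 * nf), dtype=np.int8)
    S[:nc, :nc] = (M != 0).astype(np.int8) + sp.eye(nc, dtype=np.int8)
    for j, c in enumerate(fp_cells):
        ifa, ibu = nc + j, nc + nf + j
        for a in (c, ifa, ibu):
            for b in (c, ifa, ibu):
                S[a, b] = 1

    t_eval = np.linspace(0.0, t_end, n_out)
    breaks = [b for pr in protocols for b in pr.breakpoints()]
    y = integrate_piecewise(rhs, t_end, y0, t_eval, breakpoints=breaks,
                            method="BDF", rtol=rtol, atol=atol,
                            jac_sparsity=S.tocsr())
    return SpatialTrajectory(
        t=t_eval, ga=y[:, :nc], fa=np.clip(y[:, nc:nc + nf], 0, None),
        bu=np.clip(y[:, nc + nf:], 0, None), fp_cells=fp_cells, net=net)


# --------------------------------------------------------------------------
# effacement detection and pattern statistics


@dataclass
class EffacementReport:
    status: np.ndarray          # "survived" | "effaced" | "unresolved"
    t_effaced: np.ndarray       # first crossing without recovery (nan else)
    threshold: float
    n_fp: int
    net_volume: float

    @property
    def n_effaced(self) -> int:
        return int(np.sum(self.status == "effaced"))

    @property
    def n_survived(self) -> int:
        return int(np.sum(self.status == "survived"))

    def summary(self) -> dict:
        return {"n_fp": self.n_fp, "effaced": self.n_effaced,
                "survived": self.n_survived, "threshold": self.threshold}


def detect_effacement(traj: SpatialTrajectory,
                      threshold: float | None = None,
                      persistence_window: float | None = None,
                      mode: str = "persistent") -> EffacementReport:
    """Classify each FP as effaced or survived from its bundle time course.

    In ``mode="persistent"`` an FP is effaced iff its Bu falls below
    ``threshold`` at some time t* and stays below it through
    t* + ``persistence_window`` and through the end of the record
    (permanent loss, not an oscillation trough).  In
    ``mode="irreversible"`` any sub-threshold stretch of at least the
    persistence window marks effacement even if bundle concentration later
    recovers: a foot process that lost its bundles for that long is taken
    to be morphologically resorbed, so later regrowth of bundled actin in
    the model volume does not restore it.  The window defaults to 10% of
    the record length.  Terminal sub-threshold stretches shorter than the
    window yield ``unresolved``, never a silent call.
    """
    if threshold is None:
        threshold = default_effacement_threshold()
    if mode not in ("persistent", "irreversible"):
        raise ValueError("mode must be 'persistent' or 'irreversible'")
    span = traj.t[-1] - traj.t[0]
    if persistence_window is None:
        persistence_window = 0.1 * span
    if threshold <= 0 or persistence_window <= 0:
        raise ValueError("threshold and persistence_window must be > 0")
    n = traj.n_fp
    status = np.empty(n, dtype=object)
    t_eff = np.full(n, np.nan)
    if span < persistence_window:
        status[:] = "unresolved"
        return EffacementReport(status, t_eff, threshold, n,
                                traj.net.geometry_volume)
    below = traj.bu < threshold  # (nt, nf)
    for i in range(n):
        b = below[:, i]
        status[i] = "survived"
        # runs of consecutive sub-threshold samples
        edges = np.flatnonzero(np.diff(np.concatenate(([0], b.view(np.int8),
                                                       [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            t_star = traj.t[start]
            t_stop = traj.t[min(stop, len(traj.t) - 1)]
            terminal = stop >= len(traj.t)
            long_enough = (t_stop if not terminal else traj.t[-1]) - t_star \
                >= persistence_window
            if mode == "persistent" and not terminal:
                continue
            if long_enough:
                status[i] = "effaced"
                t_eff[i] = t_star
                break
            if terminal:
                status[i] = "unresolved"
    return EffacementReport(status, t_eff, threshold, n,
                            traj.net.geometry_volume)


def survivor_mean_bu(traj: SpatialTrajectory,
                     report: EffacementReport) -> float:
    mask = report.status == "survived"
    if not mask.any():
        return float("nan")
    return float(traj.bu[-1, mask].mean())


def pattern_divergence(report_a: EffacementReport,
                       report_b: EffacementReport):
    """Fraction of FPs whose survived/effaced status differs.

    Returns ``(divergence, agreement_map)`` with divergence in [0, 1].
    """
    if report_a.n_fp != report_b.n_fp or not np.isclose(
            report_a.net_volume, report_b.net_volume):
        raise ValueError("reports come from different networks")
    agree = report_a.status == report_b.status
    return float(np.mean(~agree)), agree


def asynchrony_index(traj: SpatialTrajectory,
                     window: tuple[float, float] | None = None) -> float:
    """1 minus the mean pairwise correlation of FP bundle time courses,
    rescaled to [0, 1].  Identical courses give 0, anti-phase pairs 1;
    constant (degenerate) records are defined as perfectly synchronous.
    """
    if traj.n_fp < 2:
        raise ValueError("need at least two FPs")
    if window is None:
        sel = slice(None)
    else:
        sel = (traj.t >= window[0]) & (traj.t <= window[1])
    X = traj.bu[sel]
    sd = X.std(axis=0)
    live = sd > 1e-12 * max(X.max(), 1.0)
    if live.sum() < 2:
        return 0.0
    C = np.corrcoef(X[:, live].T)
    iu = np.triu_indices_from(C, k=1)
    rbar = float(C[iu].mean())
    return float(np.clip((1.0 - rbar) / 2.0, 0.0, 1.0))


# --------------------------------------------------------------------------
# scenario runners


def fp_region(net: CompartmentNetwork, path_ids: Iterable[int],
              arc_range: tuple[float, float]) -> np.ndarray:
    """FP indices lying on the given branch paths within an arclength band."""
    paths = set(path_ids)
    ids = [c.fp_id for c in net.cells
           if c.label == FP and c.path_id in paths
           and arc_range[0] <= c.arc <= arc_range[1]]
    return np.array(sorted(ids), dtype=int)


@dataclass
class ScenarioResult:
    name: str
    config: dict
    trajectory: SpatialTrajectory
    report: EffacementReport


_AB_STEP = 2.0 / 3.0      # alpha_b 0.03 -> 0.05
_BB_DROP = -0.5           # beta_b halved: weakened bundle turnover
_AB_COMP = -0.4           # compensatory bundling decrease
_AF_COMP = 0.5            # compensatory feedback increase

SCENARIO_NAMES = ("fig3_global_ab", "fig5_local_af_pulse", "fig6_bb_drop",
                  "fig6_bb_drop_restore", "fig6_bb_drop_ab_comp",
                  "fig6_bb_drop_af_comp")


def _scenario_protocols(name: str, net: CompartmentNetwork, cfg: dict):
    if name == "fig3_global_ab":
        cfg.setdefault("amplitude", _AB_STEP)
        cfg.setdefault("onset", 40.0)
        cfg.setdefault("t_end", 2400.0)
        return [step_protocol("alpha_b", cfg["amplitude"], cfg["onset"])]
    if name == "fig5_local_af_pulse":
        cfg.setdefault("amplitude", 2.0)
        cfg.setdefault("onset", 40.0)
        cfg.setdefault("rise", 10.0)
        cfg.setdefault("hold", 100.0)
        cfg.setdefault("fall", 50.0)
        cfg.setdefault("t_end", 2000.0)
        if "region" not in cfg:
            # distal band of the five longest branch paths
            reach = {}
            for c in net.cells:
                if c.path_id is not None:
                    reach[c.path_id] = max(reach.get(c.path_id, 0.0), c.arc)
            longest = sorted(reach, key=reach.get, reverse=True)[:5]
            cfg["region"] = fp_region(net, longest, (20.0, 34.0))
        return [pulse_protocol("alpha_f", cfg["amplitude"], cfg["onset"],
                               rise=cfg["rise"], hold=cfg["hold"],
                               fall=cfg["fall"], region=cfg["region"])]
    if name.startswith("fig6_bb_drop"):
        cfg.setdefault("amplitude", _BB_DROP)
        cfg.setdefault("t1", 500.0)
        cfg.setdefault("t_end", 2500.0)
        if name == "fig6_bb_drop":
            return [step_protocol("beta_b", cfg["amplitude"], onset=0.0)]
        if name == "fig6_bb_drop_restore":
            return [StimulusProtocol(param="beta_b", shape="step", onset=0.0,
                                     rise=0.0, fall=0.0,
                                     amplitude=cfg["amplitude"],
                                     offset=cfg["t1"])]
        if name == "fig6_bb_drop_ab_comp":
            cfg.setdefault("comp_amplitude", _AB_COMP)
            return [step_protocol("beta_b", cfg["amplitude"], onset=0.0),
                    step_protocol("alpha_b", cfg["comp_amplitude"],
                                  onset=cfg["t1"])]
        if name == "fig6_bb_drop_af_comp":
            cfg.setdefault("comp_amplitude", _AF_COMP)
            return [step_protocol("beta_b", cfg["amplitude"], onset=0.0),
                    step_protocol("alpha_f", cfg["comp_amplitude"],
                                  onset=cfg["t1"])]
    raise ValueError(f"unknown scenario {name!r}; known: {SCENARIO_NAMES}")


def run_scenario(name: str,
                 net: CompartmentNetwork,
                 p: SpatialParams,
                 threshold: float | None = None,
                 rtol: float = 1e-6,
                 atol: float = 1e-9,
                 **config) -> ScenarioResult:
    """Run a named perturbation scenario and report per-FP effacement.

    ``config`` overrides scenario defaults (``amplitude``, ``onset``,
    ``t1``, ``t_end``, ``region``, ``comp_amplitude``).
    """
    cfg = dict(config)
    cfg.setdefault("mode", "irreversible")
    protocols = _scenario_protocols(name, net, cfg)
    traj = simulate_rd(net, p, protocols=protocols, t_end=cfg["t_end"],
                       rtol=rtol, atol=atol)
    report = detect_effacement(traj, threshold=threshold, mode=cfg["mode"])
    log_cfg = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in cfg.items()}
    return ScenarioResult(name=name, config=log_cfg, trajectory=traj,
                          report=report)
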