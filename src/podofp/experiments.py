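"""End-to-end reproduction pipelines and the acceptance self-check.

``reproduce`` drives the other modules to regenerate each published result
at desk scale and returns a plain dict of the headline numbers; with an
output directory it also writes the run config (verbatim), CSV/JSON
artifacts and a short run log.  ``check_acceptance`` evaluates the shipped
target file against freshly computed values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import geometry as geo
from . import spatial as sp
from . import twocomp as tc
from .kinetics import classify_regime, default_effacement_threshold
from .presets import get_params, params_to_dict

FIGURE_IDS = ("table1_idealized", "fig1_stratify", "fig2", "fig3", "fig4",
              "fig5", "fig6")

_TARGETS_FILE = Path(__file__).parent / "data" / "acceptance_targets.json"


def _default_setup(seed: int | None):
    g = geo.build_idealized_podocyte(seed=seed)
    net = geo.to_network(g)
    p = sp.SpatialParams(kinetics=get_params("fig2C"))
    return g, net, p


def reproduce(figure_id: str, out_dir: str | Path | None = None,
              seed: int | None = 0, **overrides) -> dict:
    """Recompute one published result; returns its summary numbers."""
    t0 = time.time()
    if figure_id == "table1_idealized":
        g = geo.build_idealized_podocyte(seed=seed)
        m = geo.morphometrics(g)
        result = {k: (v if isinstance(v, int) else float(v))
                  for k, v in dataclasses.asdict(m).items()}
        artifact = m.to_table1_frame()
    elif figure_id == "fig1_stratify":
        g, net, _ = _default_setup(seed)
        strat = geo.stratify_cell_body(net, **overrides)
        cb = strat.min_over_label(net, geo.CB)
        result = {"min_cb_relative_conc": cb,
                  "max_mp_relative_conc":
                      float(strat.rel_conc[net.labels == geo.MP].max()),
                  "max_fp_relative_conc":
                      float(strat.rel_conc[net.labels == geo.FP].max()),
                  "n_cells_cb_labelled": int(strat.is_cb.sum())}
        artifact = None
        if out_dir is not None:
            import pandas as pd
            artifact = pd.DataFrame({
                "cell_id": [c.cell_id for c in net.cells],
                "label": [c.label for c in net.cells],
                "rel_conc": strat.rel_conc, "is_cb": strat.is_cb})
    elif figure_id == "fig2":
        result = {name: classify_regime(get_params(name)).value
                  for name in ("fig2C", "fig2D", "fig2E", "fig2F")}
        artifact = None
    elif figure_id == "fig4":
        kin = get_params("fig2C")
        result = {}
        for label, rel in (("small", 0.5), ("unit", 1.0), ("double", 2.0)):
            _, oc = tc.transient_response(kin, amplitude=rel, **overrides)
            result[label] = oc.value
        artifact = None
    elif figure_id in ("fig3", "fig5"):
        name = {"fig3": "fig3_global_ab", "fig5": "fig5_local_af_pulse"}
        g, net, p = _default_setup(seed)
        res = sp.run_scenario(name[figure_id], net, p, **overrides)
        result = dict(res.report.summary(),
                      survivor_mean_bu=sp.survivor_mean_bu(res.trajectory,
                                                           res.report))
        artifact = None
        if out_dir is not None:
            artifact = _timecourse_frame(res.trajectory)
    elif figure_id == "fig6":
        g, net, p = _default_setup(seed)
        result = {}
        for name in ("fig6_bb_drop", "fig6_bb_drop_restore",
                     "fig6_bb_drop_ab_comp", "fig6_bb_drop_af_comp"):
            if name == "fig6_bb_drop":
                res = sp.run_scenario(name, net, p, **overrides)
                result[name] = res.report.summary()
            else:
                for t1, tag in ((500.0, "early"), (1500.0, "late")):
                    res = sp.run_scenario(name, net, p, t1=t1, **overrides)
                    result[f"{name}_{tag}"] = res.report.summary()
        artifact = None
    else:
        raise ValueError(f"unknown figure id {figure_id!r}; "
                         f"known: {FIGURE_IDS}")

    result["_elapsed_s"] = round(time.time() - t0, 2)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = {"figure_id": figure_id, "seed": seed, "overrides":
               {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in overrides.items()},
               "params": params_to_dict(get_params("fig2C"))}
        (out / "config.json").write_text(json.dumps(cfg, indent=1))
        (out / "result.json").write_text(json.dumps(result, indent=1))
        if artifact is not None:
            artifact.to_csv(out / f"{figure_id}.csv")
        (out / "run.log").write_text(
            f"figure={figure_id} seed={seed} "
            f"config_sha1={hashlib.sha1(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]} "
            f"elapsed={result['_elapsed_s']}s\n")
    return result


def _timecourse_frame(traj: sp.SpatialTrajectory):
    import pandas as pd

    rows = []
    for j in range(traj.n_fp):
        rows.append(pd.DataFrame({"time": traj.t, "fp_id": j,
                                  "species": "Bu", "value": traj.bu[:, j]}))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# acceptance self-check


@dataclass
class TargetResult:
    target_id: str
    computed: float
    target: float
    cmp: str
    tolerance: float
    passed: bool


@dataclass
class AcceptanceReport:
    results: list[TargetResult]

    @property
    def n_passed(self) -> int:
        return sum(r.passed for r in self.results)

    def to_dict(self) -> dict:
        return {r.target_id: dataclasses.asdict(r) for r in self.results}


def compute_target(target_id: str, seed: int | None = 0) -> float:
    """Recompute one acceptance quantity from scratch."""
    if target_id == "t7":
        m = geo.morphometrics(geo.build_idealized_podocyte(seed=seed))
        return float(m.n_branches)
    if target_id == "t8":
        m = geo.morphometrics(geo.build_idealized_podocyte(seed=seed))
        return float(m.furthest_endpoint_distance)
    if target_id == "t11":
        g = geo.build_idealized_podocyte(seed=seed)
        net = geo.to_network(g)
        strat = geo.stratify_cell_body(net)
        return float(100.0 * strat.min_over_label(net, geo.CB))
    raise ValueError(f"unknown target {target_id!r}")


def check_acceptance(targets_file: str | Path | None = None,
                     seed: int | None = 0) -> AcceptanceReport:
    """Evaluate every target in the shipped (or given) target file."""
    path = Path(targets_file) if targets_file else _TARGETS_FILE
    targets = json.loads(path.read_text())
    results = []
    for t in targets:
        value = compute_target(t["id"], seed=seed)
        ref, cmp_, tol = t["value"], t["cmp"], t.get("tolerance", 0.0)
        if cmp_ == "eq":
            ok = abs(value - ref) <= tol
        elif cmp_ == "ge":
            ok = value >= ref - tol
        elif cmp_ == "le":
            ok = value <= ref + tol
        else:
            raise ValueError(f"unknown comparator {cmp_!r}")
        results.append(TargetResult(t["id"], value, ref, cmp_, tol, bool(ok)))
    return AcceptanceReport(results)
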