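"""Experiment harness: activity metrics, TIMP-2 sweeps, ensembles, presets.

The central observable is M14a, the weighted sum of the ECM-degradation-
competent MT1-MMP complexes (monomer and single-loaded dimer forms weight
1, the free dimer weight 2, summed over membrane pools).  Derived metrics
are its plateau after the initial transient (``M14a_steady``), the full
width at half maximum of the transient above that plateau
(``t_transient``), and, for degradation runs, the ECM half-degradation
time ``tau_H`` and the initial degradation rate.

Presets bundle the standard in-silico experiments: the no-turnover
transient and its TIMP-2 titration, the inactive-complex path-deletion
ladder, turnover-rate scaling, transient elimination, pulsatile insertion
(regular and random), the frequency/concentration trade-off at fixed
time-averaged delivery, and the spatial focal-degradation runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ecm as ecm_mod
from . import turnover as tv
from .kinetics import (
    CompiledModel,
    StateVector,
    Trajectory,
    compile_network,
    detect_steady_state,
    integrate_rk4,
)
from .network import (
    KineticParameters,
    ReactionNetwork,
    apply_path_deletions,
    build_core_network,
)

__all__ = [
    "M14aDefinition",
    "TransientMetrics",
    "compute_m14a",
    "half_width",
    "m14a_weights",
    "run_core",
    "run_turnover",
    "transient_metrics",
    "sweep_timp2",
    "run_to_half_ecm",
    "run_ensemble",
    "run_figure_preset",
    "PRESET_NAMES",
    "TIMP2_GRID",
]

#: default TIMP-2 titration grid (nM)
TIMP2_GRID = [0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0, 200.0, 300.0,
              400.0, 500.0]

#: turnover-rate scale factors for the rate-reduction sweep
TURNOVER_SCALES = [1.0, 0.3, 0.1, 0.03, 0.0]

#: frequency folds of the fixed-time-average insertion sweep (concentration
#: folds are the reciprocals)
FREQ_FOLDS = [100.0, 50.0, 20.0, 10.0, 5.0, 2.0, 1.0, 0.5, 0.2, 0.1, 0.05,
              0.02, 0.01]


@dataclass
class M14aDefinition:
    """Weights of the degradation-competent complexes.

    Defaults to activity weights per species as enumerated by the network
    (dimer 2, monomer and single-loaded dimer forms 1), which automatically
    sums pooled variants across X and D.
    """

    weights: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_network(cls, net: ReactionNetwork) -> "M14aDefinition":
        return cls({s.name: s.activity_weight for s in net.species
                    if s.activity_weight > 0})


@dataclass
class TransientMetrics:
    peak_value: float
    t_transient: float
    M14a_steady: float
    steady_reached_at: float | None = None


def m14a_weights(net: ReactionNetwork) -> dict[str, float]:
    return M14aDefinition.from_network(net).weights


def compute_m14a(
    traj: Trajectory, definition: M14aDefinition | Mapping[str, float] | None = None
) -> np.ndarray:
    """Weighted-sum M14a series of a trajectory."""
    if definition is None:
        weights = {n: 0.0 for n in traj.species}
        raise ValueError("an M14a definition (or weight mapping) is required")
    weights = (definition.weights if isinstance(definition, M14aDefinition)
               else dict(definition))
    missing = set(weights) - set(traj.species)
    if missing:
        raise KeyError(f"weights reference absent species: {sorted(missing)}")
    return traj.observable(weights)


def half_width(
    times: np.ndarray, series: np.ndarray, steady: float | None = None
) -> float:
    """FWHM of the transient above the steady baseline (s).

    The width runs from the first rise through half level to the last fall
    below it, linearly interpolated; a flat series has width 0.  A series
    already at its peak at t = 0 starts its width there.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(series, dtype=float)
    if steady is None:
        steady = float(y[-1])
    i_peak = int(np.argmax(y))
    peak = float(y[i_peak])
    scale = max(abs(peak), abs(steady), 1e-300)
    if peak - steady <= 1e-9 * scale:
        return 0.0
    half = steady + 0.5 * (peak - steady)

    def cross(i0: int, i1: int) -> float:
        # linear interpolation of the half-level crossing in [i0, i1]
        y0, y1 = y[i0], y[i1]
        f = (half - y0) / (y1 - y0)
        return float(t[i0] + f * (t[i1] - t[i0]))

    above = y >= half
    # first rise at or before the peak
    if above[0]:
        t_rise = float(t[0])
    else:
        i = i_peak
        while i > 0 and above[i - 1]:
            i -= 1
        t_rise = cross(i - 1, i)
    # last fall after the peak
    below_after = np.nonzero(~above[i_peak:])[0]
    if below_after.size == 0:
        t_fall = float(t[-1])
    else:
        j = i_peak + int(below_after[-1])  # last sample below half
        # walk back to the crossing into that final below-half stretch
        k = i_peak + int(below_after[0])
        t_fall = cross(k - 1, k)
        # if the series re-rises above half later, extend to the last fall
        last_above = np.nonzero(above[k:])[0]
        if last_above.size:
            m = k + int(last_above[-1])
            if m + 1 < len(y):
                t_fall = cross(m, m + 1)
            else:
                t_fall = float(t[-1])
    return max(t_fall - t_rise, 0.0)


# --------------------------------------------------------------------------
# run drivers
# --------------------------------------------------------------------------


def run_core(
    params: KineticParameters | None = None,
    timp2: float | None = None,
    include_m2: bool = True,
    include_ecm: bool = False,
    deletions: Sequence[int] = (),
    include_shedding: bool = False,
    t_end: float = 1500.0,
    dt: float = 0.01,
    record_every: float = 0.05,
) -> Trajectory:
    """Closed no-turnover model: surface expression of MT1-MMP at t = 0."""
    p = params or KineticParameters()
    net = build_core_network(p, include_ecm=include_ecm,
                             include_shedding=include_shedding, pools="single")
    if deletions:
        net = apply_path_deletions(net, deletions)
    model = compile_network(net)
    init = {"M14": p.M14_0,
            "T2": p.T2_0 if timp2 is None else float(timp2),
            "M2": p.M2_0 if include_m2 else 0.0}
    if include_ecm:
        init["ECM"] = p.ECM_0
    return integrate_rk4(model, model.initial_state(init), t_end, dt=dt,
                         record_every=record_every)


def run_turnover(
    params: KineticParameters | None = None,
    timp2: float | None = None,
    schedule: tv.InsertionSchedule | None = None,
    include_ecm: bool = False,
    eliminate_transient: bool = False,
    turnover_scale: float = 1.0,
    deletions: Sequence[int] = (),
    t_end: float = 1500.0,
    dt: float = 0.01,
    record_every: float = 0.1,
) -> tuple[CompiledModel, Trajectory]:
    """Two-pool turnover model, continuous or pulsatile insertion.

    With a pulsatile schedule the continuous insertion flux is switched off
    and delivery happens only through the pulse events; internalisation is
    unchanged.  ``turnover_scale`` rescales insertion and internalisation
    jointly; scale 0 freezes the pools (closed membrane).
    """
    p = params or KineticParameters()
    if timp2 is not None:
        p = dataclasses.replace(p, T2_0=float(timp2))
    pools = tv.default_pools(turnover_scale) if turnover_scale > 0 else [
        dataclasses.replace(pool, k_ins=0.0, k_int=0.0)
        for pool in tv.default_pools()
    ]
    pulsatile = schedule is not None and schedule.mode == "pulsatile"
    model, y0 = tv.build_turnover_model(
        p, pools=pools, include_ecm=include_ecm,
        eliminate_transient=eliminate_transient, deletions=deletions,
    )
    events = None
    if pulsatile:
        # pulses replace the continuous source; keep internalisation
        model = compile_network(
            _without_insertion(model.net),
            insertion_dists={pid: model.p_dist[i]
                             for i, pid in enumerate(model.pool_ids)},
            clamped=[model.species[i] for i in model.clamp_idx],
        )
        pool_map = {pool.pool_id: pool for pool in pools}
        pulse_events = tv.generate_schedule(schedule, pools, t_end)
        dists = {pid: model.p_dist[i] if eliminate_transient else None
                 for i, pid in enumerate(model.pool_ids)}
        dists = {k: v for k, v in dists.items() if v is not None}
        events = tv.pulse_events_to_operators(model, pulse_events,
                                              dists or None)
        if eliminate_transient:
            # start at the eliminated steady state; pulses keep feeding it
            y0 = StateVector(model.species, y0.conc.copy(), 0.0)
        else:
            # pulsatile delivery starts on an empty membrane: the first
            # (fold-scaled) vesicle at t = 0 is part of the regimen
            init = {s: y0.conc[model.index[s]] for s in ("T2", "M2")}
            if include_ecm:
                init["ECM"] = p.ECM_0
            y0 = model.initial_state(init)
        del pool_map
    traj = integrate_rk4(model, y0, t_end, dt=dt, events=events,
                         record_every=record_every)
    return model, traj


def _without_insertion(net: ReactionNetwork) -> ReactionNetwork:
    out = net.copy()
    cfg = {k: dict(v, k_ins=0.0)
           for k, v in out.metadata.get("pools_config", {}).items()}
    out.metadata = {**out.metadata, "pools_config": cfg}
    return out


def transient_metrics(
    traj: Trajectory,
    weights: Mapping[str, float],
    rel_tol: float = 1e-4,
    window: float = 500.0,
) -> TransientMetrics:
    series = compute_m14a(traj, weights)
    res = detect_steady_state(traj, series, rel_tol=rel_tol, window=window)
    steady = res.value
    return TransientMetrics(
        peak_value=float(np.max(series)),
        t_transient=half_width(traj.times, series, steady),
        M14a_steady=steady,
        steady_reached_at=res.reached_at if res.converged else None,
    )


# --------------------------------------------------------------------------
# sweeps and ensembles
# --------------------------------------------------------------------------


def sweep_timp2(
    values: Sequence[float] = tuple(TIMP2_GRID),
    variant: str = "core",
    params: KineticParameters | None = None,
    include_m2: bool = True,
    deletions: Sequence[int] = (),
    turnover_scale: float = 1.0,
    eliminate_transient: bool = False,
    t_end: float = 1500.0,
    dt: float = 0.01,
) -> pd.DataFrame:
    """One full simulation per TIMP-2 value; returns the metrics table."""
    if any(v < 0 for v in values):
        raise ValueError("TIMP-2 concentrations must be >= 0")
    rows = []
    for t2 in values:
        if variant == "core":
            traj = run_core(params, timp2=t2, include_m2=include_m2,
                            deletions=deletions, t_end=t_end, dt=dt)
            weights = m14a_weights(
                build_core_network(params or KineticParameters(),
                                   pools="single")
            )
            weights = {k: v for k, v in weights.items()
                       if k in traj.species}
        elif variant == "turnover":
            model, traj = run_turnover(
                params, timp2=t2, turnover_scale=turnover_scale,
                eliminate_transient=eliminate_transient, deletions=deletions,
                t_end=t_end, dt=dt,
            )
            weights = m14a_weights(model.net)
        else:
            raise ValueError(f"unknown sweep variant {variant!r}")
        m = transient_metrics(traj, weights)
        rows.append({"timp2": t2, "m14a_steady": m.M14a_steady,
                     "t_transient": m.t_transient, "peak": m.peak_value})
    return pd.DataFrame(rows)


def run_to_half_ecm(
    params: KineticParameters | None = None,
    timp2: float = 100.0,
    schedule: tv.InsertionSchedule | None = None,
    eliminate_transient: bool = False,
    t_start_horizon: float = 600.0,
    t_cap: float = 2.0e6,
    dt: float = 0.01,
    record_every: float = 0.1,
) -> tuple[float | None, Trajectory, float]:
    """tau_H with an adaptive horizon.

    Grows the simulated horizon (x4) until ECM crosses 50% or ``t_cap`` is
    reached; returns ``(tau_H or None, trajectory, horizon)`` — a ``None``
    tau_H means the crossing did not occur within the cap, so the cap is a
    lower bound.  Very long horizons coarsen the step (the chemistry left
    at that point is slow), up to dt = 0.02 s.
    """
    p = params or KineticParameters()
    horizon = t_start_horizon
    while True:
        stride = max(record_every, horizon / 20000.0)
        dt_eff = min(max(dt, horizon / 2.0e7), 0.02)
        _, traj = run_turnover(
            p, timp2=timp2, schedule=schedule,
            include_ecm=True, eliminate_transient=eliminate_transient,
            t_end=horizon, dt=dt_eff, record_every=stride,
        )
        tau = ecm_mod.tau_half(traj, p.ECM_0)
        if tau is not None:
            return tau, traj, horizon
        if horizon >= t_cap:
            return None, traj, horizon
        horizon = min(horizon * 4.0, t_cap)


def run_ensemble(
    timp2_values: Sequence[float] = (0.0, 200.0, 400.0),
    n_runs: int = 30,
    params: KineticParameters | None = None,
    interval_mode: str = "random",
    amount_mode: str = "regular",
    base_seed: int = 0,
    dt: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """tau_H ensembles over random pulsatile schedules.

    Returns ``(raw, stats)``: every (TIMP-2, seed, tau_H) realisation, and
    the per-TIMP-2 mean, SD and coefficient of variation.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    rows = []
    for t2 in timp2_values:
        for j in range(n_runs):
            sched = tv.InsertionSchedule(
                mode="pulsatile", interval_mode=interval_mode,
                amount_mode=amount_mode, seed=int(base_seed) * 1000 + j,
            )
            tau, _, _ = run_to_half_ecm(params, timp2=t2, schedule=sched,
                                        dt=dt)
            rows.append({"timp2": t2, "seed": sched.seed, "tau_H": tau})
    raw = pd.DataFrame(rows)
    stats = (
        raw.groupby("timp2")["tau_H"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    stats["cv"] = stats["sd"] / stats["mean"]
    return raw, stats


# --------------------------------------------------------------------------
# figure presets
# --------------------------------------------------------------------------


def _savefig(fig, outdir: Path | None, name: str) -> None:
    if outdir is None:
        return
    import matplotlib

    matplotlib.use("Agg", force=False)
    outdir.mkdir(parents=True, exist_ok=True)
    fig.savefig(outdir / name, dpi=120)


def _write(df: pd.DataFrame, outdir: Path | None, name: str) -> None:
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / name, index=False)


def _plot_series(outdir, name, xlabel, ylabel, curves):
    if outdir is None:
        return
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, x, y in curves:
        ax.plot(x, y, label=str(label), lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if len(curves) > 1:
        ax.legend(fontsize=7)
    fig.tight_layout()
    _savefig(fig, outdir, name)
    plt.close(fig)


def _preset_fig1(outdir, seed, params):
    traj = run_core(params, timp2=100.0)
    weights = m14a_weights(build_core_network(params, pools="single"))
    m14a = compute_m14a(traj, weights)
    sweep = sweep_timp2(params=params)
    ts = pd.DataFrame({"time": traj.times, "M14a": m14a})
    _write(ts, outdir, "fig1_m14a_timecourse.csv")
    _write(sweep, outdir, "fig1_timp2_sweep.csv")
    _plot_series(outdir, "fig1_m14a.png", "time (s)", "M14a (nM)",
                 [("T2=100", traj.times, m14a)])
    _plot_series(outdir, "fig1_sweep.png", "TIMP-2 (nM)", "M14a_steady (nM)",
                 [("", sweep["timp2"], sweep["m14a_steady"])])
    return {"timecourse": ts, "sweep": sweep}


def _preset_fig2(outdir, seed, params):
    traj = run_core(params, timp2=100.0)
    complexes = [n for n in traj.species if "M14" in n]
    ts = traj.to_wide()[["time"] + complexes]
    rows = []
    ladder = [(), (1,), (1, 2), (1, 2, 3), (1, 2, 3, 4), (1, 2, 3, 4, 5)]
    net0 = build_core_network(params, pools="single")
    for dels in ladder:
        tr = run_core(params, timp2=100.0, deletions=dels)
        weights = {k: v for k, v in m14a_weights(net0).items()
                   if k in tr.species}
        m = transient_metrics(tr, weights)
        rows.append({"n_deleted": len(dels),
                     "deletions": ",".join(map(str, dels)),
                     "m14a_steady": m.M14a_steady})
    ladder_df = pd.DataFrame(rows)
    _write(ts, outdir, "fig2_complex_timecourses.csv")
    _write(ladder_df, outdir, "fig2_deletion_ladder.csv")
    _plot_series(outdir, "fig2_ladder.png", "number of deleted complexes",
                 "M14a_steady (nM)",
                 [("", ladder_df["n_deleted"], ladder_df["m14a_steady"])])
    return {"timecourses": ts, "ladder": ladder_df}


def _preset_fig3(outdir, seed, params):
    rows = []
    for scale in TURNOVER_SCALES:
        t_end = max(3000.0, 8.0 * 259.0 / max(scale, 0.03))
        sw = sweep_timp2(params=params, variant="turnover",
                         turnover_scale=scale, t_end=t_end)
        base = sw.loc[sw["timp2"] == 0.0, "m14a_steady"].iloc[0]
        sw["scale"] = scale
        sw["m14a_steady_norm"] = sw["m14a_steady"] / base
        rows.append(sw)
    df = pd.concat(rows, ignore_index=True)
    _write(df, outdir, "fig3_turnover_scaling.csv")
    curves = [(s, g["timp2"], g["m14a_steady_norm"])
              for s, g in df.groupby("scale")]
    _plot_series(outdir, "fig3_scaling.png", "TIMP-2 (nM)",
                 "M14a_steady (normalised)", curves)
    return {"scaling": df}


def _preset_fig4(outdir, seed, params):
    rows = []
    for t2 in TIMP2_GRID:
        tau_p, _, _ = run_to_half_ecm(params, timp2=t2)
        tau_e, _, hor = run_to_half_ecm(params, timp2=t2,
                                        eliminate_transient=True)
        rows.append({"timp2": t2, "tau_H_present": tau_p,
                     "tau_H_eliminated": tau_e,
                     "eliminated_horizon": hor})
    df = pd.DataFrame(rows)
    _write(df, outdir, "fig4_tauH_vs_timp2.csv")
    _plot_series(outdir, "fig4_tauH.png", "TIMP-2 (nM)", "tau_H (s)",
                 [("present", df["timp2"], df["tau_H_present"]),
                  ("eliminated", df["timp2"], df["tau_H_eliminated"])])
    return {"tau_H": df}


def _preset_fig5(outdir, seed, params):
    out = {}
    for label, imode in (("regular", "regular"), ("random", "random")):
        sched = tv.InsertionSchedule(mode="pulsatile", interval_mode=imode,
                                     seed=seed)
        model, traj = run_turnover(params, timp2=100.0, schedule=sched,
                                   include_ecm=True, t_end=600.0)
        m14a = compute_m14a(traj, m14a_weights(model.net))
        integ = ecm_mod.integrated_active_ecm_complex(traj)
        out[label] = pd.DataFrame({
            "time": traj.times, "M14a": m14a, "ECM": traj.series("ECM"),
            "int_M14a_ECM": integ,
        })
        _write(out[label], outdir, f"fig5_{label}.csv")
    _plot_series(outdir, "fig5_integrated.png", "time (s)",
                 "integrated M14a.ECM (nM s)",
                 [(k, v["time"], v["int_M14a_ECM"]) for k, v in out.items()])
    return out


def _preset_fig6(outdir, seed, params, folds: Sequence[float] | None = None):
    rows = []
    for f in (folds if folds is not None else FREQ_FOLDS):
        sched = tv.InsertionSchedule(mode="pulsatile", freq_fold=f,
                                     conc_fold=1.0 / f, seed=seed)
        tau, traj, _ = run_to_half_ecm(params, timp2=100.0, schedule=sched)
        rate = ecm_mod.initial_degradation_rate(traj, window=10.0)
        rows.append({"freq_fold": f, "conc_fold": 1.0 / f, "tau_H": tau,
                     "initial_rate": rate})
    df = pd.DataFrame(rows)
    _write(df, outdir, "fig6_fold_sweep.csv")
    _plot_series(outdir, "fig6_tauH.png", "frequency fold", "tau_H (s)",
                 [("", df["freq_fold"], df["tau_H"])])
    return {"fold_sweep": df}


def _preset_fig7(outdir, seed, params):
    from . import spatial as sp

    grid = sp.build_grid()
    out = {}
    for regimen in ("continuous", "pulsatile-regular"):
        for mode in ("present", "eliminated"):
            res = sp.run_focal_degradation(
                grid, params, regimen=regimen, transient_mode=mode,
                timp2=200.0, t_end=120.0,
            )
            key = f"{regimen}_{mode}"
            out[key] = pd.DataFrame({
                "time": res.times, "ecm_center": res.ecm_center,
                "m14a": res.m14a,
            })
            _write(out[key], outdir, f"fig7_{key}.csv")
    _plot_series(outdir, "fig7_center_ecm.png", "time (s)",
                 "ECM at invadopodium (nM)",
                 [(k, v["time"], v["ecm_center"]) for k, v in out.items()])
    return out


def _preset_s5(outdir, seed, params):
    sweeps = {}
    for label, with_m2 in (("with_MMP2", True), ("without_MMP2", False)):
        sweeps[label] = sweep_timp2(params=params, include_m2=with_m2)
        _write(sweeps[label], outdir, f"s5_{label}.csv")
    return sweeps


def _preset_s10(outdir, seed, params):
    raw, stats = run_ensemble((0.0, 100.0, 200.0), n_runs=10, params=params,
                              interval_mode="regular", amount_mode="random",
                              base_seed=seed)
    _write(raw, outdir, "s10_raw.csv")
    _write(stats, outdir, "s10_stats.csv")
    return {"raw": raw, "stats": stats}


def _preset_s11(outdir, seed, params):
    p = params or KineticParameters()
    base_tau, _, _ = run_to_half_ecm(p, timp2=100.0,
                                     schedule=tv.InsertionSchedule(seed=seed))
    rows = []
    for fold in (1, 5, 10, 20):
        sched = tv.InsertionSchedule(mode="pulsatile", seed=seed)
        pools = tv.default_pools()
        horizon = max(4.0 * (base_tau or 600.0), 600.0)
        events = tv.generate_schedule(sched, pools, horizon)
        # one abrupt large vesicle at tau_H, per pool
        for pool in pools:
            events.append(tv.PulseEvent(base_tau or 300.0, pool.pool_id,
                                        fold * sched.pulse_amount(pool)))
        events.sort(key=lambda e: (e.time, e.pool_id))
        model, traj = _run_pulsatile_with_events(p, 100.0, events, horizon)
        rows.append({"fold": fold,
                     "tau_H": ecm_mod.tau_half(traj, p.ECM_0)})
    df = pd.DataFrame(rows)
    _write(df, outdir, "s11_abrupt_insertion.csv")
    return {"abrupt": df}


def _run_pulsatile_with_events(params, timp2, events, t_end, dt=0.01):
    p = dataclasses.replace(params, T2_0=float(timp2))
    model, y0 = tv.build_turnover_model(p, include_ecm=True)
    model = compile_network(
        _without_insertion(model.net),
        clamped=[model.species[i] for i in model.clamp_idx],
    )
    y = y0.conc.copy()
    ops = tv.pulse_events_to_operators(model, events)
    traj = integrate_rk4(model, StateVector(model.species, y), t_end, dt=dt,
                         events=ops, record_every=0.1)
    return model, traj


def _preset_s12(outdir, seed, params):
    from . import spatial as sp

    rows = []
    for n_inv in (1, 5):
        for D in (2e-11, 2e-15, 2e-19):
            grid = sp.build_grid(n_invadopodia=n_inv, timp2_diffusion=D)
            res = sp.run_focal_degradation(grid, params, regimen="continuous",
                                           transient_mode="present",
                                           timp2=20.0, t_end=30.0)
            m14a = np.asarray(res.m14a)
            steady = float(np.mean(m14a[-max(3, len(m14a) // 10):]))
            rows.append({"n_invadopodia": n_inv, "D": D,
                         "peak": float(np.max(m14a)), "steady": steady,
                         "peak_to_steady": float(np.max(m14a)) / steady})
    df = pd.DataFrame(rows)
    _write(df, outdir, "s12_diffusion_sweep.csv")
    return {"diffusion": df}


def _preset_s13(outdir, seed, params):
    p = params or KineticParameters()
    out = {}
    for label, shed in (("no_shedding", False), ("shedding", True)):
        traj = run_core(p, timp2=100.0, include_shedding=shed)
        weights = {k: v for k, v in m14a_weights(
            build_core_network(p, pools="single")).items()
            if k in traj.species}
        out[label] = pd.DataFrame({
            "time": traj.times, "M14a": compute_m14a(traj, weights),
        })
        _write(out[label], outdir, f"s13_{label}.csv")
    return out


_PRESETS = {
    "fig1": _preset_fig1, "fig2": _preset_fig2, "fig3": _preset_fig3,
    "fig4": _preset_fig4, "fig5": _preset_fig5, "fig6": _preset_fig6,
    "fig7": _preset_fig7, "s5": _preset_s5, "s10": _preset_s10,
    "s11": _preset_s11, "s12": _preset_s12, "s13": _preset_s13,
}
PRESET_NAMES = sorted(_PRESETS)


def run_figure_preset(
    name: str,
    outdir: str | Path | None = None,
    seed: int = 0,
    params: KineticParameters | None = None,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Run one bundled experiment; returns (and optionally writes) tables."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    p = params or KineticParameters()
    out = Path(outdir) if outdir is not None else None
    return _PRESETS[name](out, int(seed), p, **kwargs)
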