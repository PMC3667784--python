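"""Mass-action ODE assembly and fixed-step 4th-order Runge-Kutta integration.

A :class:`~invadosim.network.ReactionNetwork` is compiled to flat arrays
(reactant indices, effective rate constants, sparse stoichiometry) once, and
the classic RK4 scheme is then run in a numba-jitted kernel.  Membrane
insertion through docking pools is not plain mass action — the flux is
``k_ins * max(M_F0 - occupied, 0)`` where occupancy counts MT1-MMP monomer
equivalents docked in the pool — so pools are carried as a separate set of
compiled terms next to the reaction list.

Pulsatile insertion events are instantaneous state jumps applied between RK4
steps on an event-aligned grid, not stiff source terms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .network import Location, NetworkConfigError, ReactionNetwork

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


__all__ = [
    "StateVector",
    "Trajectory",
    "CompiledModel",
    "IntegrationError",
    "SteadyStateError",
    "SteadyStateResult",
    "compile_network",
    "mass_action_rhs",
    "integrate_rk4",
    "detect_steady_state",
]

#: small negative outputs are clamped to zero up to this magnitude (nM);
#: anything more negative trips the blow-up guard
NEG_TOLERANCE = 1e-3

#: default integration step (s); resolves the fast TIMP-2 binding transient
DEFAULT_DT = 1e-3


class IntegrationError(RuntimeError):
    def __init__(self, time: float, species: str, message: str | None = None):
        self.time = time
        self.species = species
        super().__init__(
            message
            or f"integration blew up near t={time:g} s (species {species!r})"
        )


class SteadyStateError(RuntimeError):
    """Steady state was not reached within the trajectory."""


@dataclass
class StateVector:
    """Ordered concentrations (nM) at one time point."""

    species: list[str]
    conc: np.ndarray
    time: float = 0.0

    @classmethod
    def from_dict(
        cls, net: ReactionNetwork, values: Mapping[str, float], time: float = 0.0
    ) -> "StateVector":
        names = net.species_names
        unknown = set(values) - set(names)
        if unknown:
            raise KeyError(f"unknown species in initial state: {sorted(unknown)}")
        conc = np.array([float(values.get(n, 0.0)) for n in names])
        return cls(names, conc, time)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.species, self.conc.tolist()))

    def copy(self) -> "StateVector":
        return StateVector(list(self.species), self.conc.copy(), self.time)


@dataclass
class Trajectory:
    """Time grid plus concentration series for every species."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    species: list[str]
    events: list[tuple] = field(default_factory=list)  # (time, pool, amount)

    def __post_init__(self) -> None:
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states row count must equal times length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def series(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def observable(self, weights: Mapping[str, float]) -> np.ndarray:
        out = np.zeros(len(self.times))
        for name, w in weights.items():
            if w:
                out += w * self.series(name)
        return out

    @property
    def final_state(self) -> StateVector:
        return StateVector(self.species, self.states[-1].copy(),
                           float(self.times[-1]))

    def to_wide(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=self.species)
        df.insert(0, "time", self.times)
        return df

    def to_tidy(self):
        return self.to_wide().melt(
            id_vars="time", var_name="species", value_name="concentration"
        )


# --------------------------------------------------------------------------
# compilation
# --------------------------------------------------------------------------

_POOL_LOCATION = {
    "X": Location.MEMBRANE_X,
    "D": Location.MEMBRANE_D,
    "M": Location.MEMBRANE,
}


@dataclass
class CompiledModel:
    """Flat-array form of a network, ready for the RK4 kernel."""

    net: ReactionNetwork
    species: list[str]
    index: dict[str, int]
    ri1: np.ndarray
    ri2: np.ndarray
    k_eff: np.ndarray
    sptr: np.ndarray
    sidx: np.ndarray
    scoef: np.ndarray
    pool_ids: list[str]
    p_k: np.ndarray
    p_mf0: np.ndarray
    p_occ: np.ndarray  # (n_pools, n_species) M14-equivalent site occupancy
    p_dist: np.ndarray  # (n_pools, n_species) insertion distribution
    clamp_idx: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species)

    def initial_state(self, values: Mapping[str, float]) -> StateVector:
        return StateVector.from_dict(self.net, values)

    def rhs(self, y: np.ndarray) -> np.ndarray:
        """Pure-python/numpy derivative (nM/s); mirror of the jitted kernel."""
        y = np.asarray(y, dtype=float)
        rates = self.k_eff * y[self.ri1]
        bi = self.ri2 >= 0
        rates[bi] *= y[self.ri2[bi]]
        dy = np.zeros_like(y)
        for j in range(len(rates)):
            for m in range(self.sptr[j], self.sptr[j + 1]):
                dy[self.sidx[m]] += self.scoef[m] * rates[j]
        for p in range(len(self.pool_ids)):
            free_sites = self.p_mf0[p] - float(self.p_occ[p] @ y)
            if free_sites > 0:
                dy += self.p_k[p] * free_sites * self.p_dist[p]
        dy[self.clamp_idx] = 0.0
        return dy

    def pool_free_sites(self, y: np.ndarray, pool_id: str) -> float:
        p = self.pool_ids.index(pool_id)
        return float(self.p_mf0[p] - self.p_occ[p] @ np.asarray(y, dtype=float))


def compile_network(
    net: ReactionNetwork,
    insertion_dists: Mapping[str, np.ndarray] | None = None,
    clamped: Sequence[str] = (),
) -> CompiledModel:
    """Compile a network (plus any turnover pools in its metadata).

    ``insertion_dists`` optionally replaces the default per-pool insertion
    target (a unit impulse on the pool's free MT1-MMP) with an arbitrary
    distribution vector over species — the transient-elimination mode.
    ``clamped`` species have their time derivative pinned to zero (an
    effectively infinite well-mixed reservoir, used for solution TIMP-2 and
    pro-MMP-2 in open turnover models).
    """
    net.validate()
    species = net.species_names
    index = {n: i for i, n in enumerate(species)}
    n_s = len(species)

    ri1, ri2, k_eff = [], [], []
    sidx, scoef, sptr = [], [], [0]
    for r in net.reactions:
        if r.tag == "insertion":
            continue  # handled through the pool terms
        delta: dict[int, float] = {}
        for n in r.reactants:
            delta[index[n]] = delta.get(index[n], 0.0) - 1.0
        for n in r.products:
            delta[index[n]] = delta.get(index[n], 0.0) + 1.0
        if len(r.reactants) == 1:
            ri1.append(index[r.reactants[0]])
            ri2.append(-1)
        elif len(r.reactants) == 2:
            ri1.append(index[r.reactants[0]])
            ri2.append(index[r.reactants[1]])
        else:
            raise NetworkConfigError(
                f"reaction '{r.label}' has no reactants and is not an insertion"
            )
        k_eff.append(r.rate_constant * r.multiplicity)
        for i, c in sorted(delta.items()):
            if c != 0.0:
                sidx.append(i)
                scoef.append(c)
        sptr.append(len(sidx))

    pools_cfg = net.metadata.get("pools_config", {})
    pool_ids, p_k, p_mf0 = [], [], []
    p_occ, p_dist = [], []
    for pid, cfg in pools_cfg.items():
        loc = _POOL_LOCATION[pid]
        occ = np.zeros(n_s)
        for s in net.species:
            if s.location is loc:
                occ[index[s.name]] = s.m14_content
        free_name = f"M14{pid}" if pid in ("X", "D") else "M14"
        dist = np.zeros(n_s)
        if insertion_dists and pid in insertion_dists:
            dist[:] = np.asarray(insertion_dists[pid], dtype=float)
        else:
            dist[index[free_name]] = 1.0
        pool_ids.append(pid)
        p_k.append(float(cfg["k_ins"]))
        p_mf0.append(float(cfg["M_F0"]))
        p_occ.append(occ)
        p_dist.append(dist)

    clamp_idx = np.array(sorted(index[n] for n in clamped), dtype=np.int64)
    return CompiledModel(
        net=net,
        species=species,
        index=index,
        ri1=np.array(ri1, dtype=np.int64),
        ri2=np.array(ri2, dtype=np.int64),
        k_eff=np.array(k_eff, dtype=np.float64),
        sptr=np.array(sptr, dtype=np.int64),
        sidx=np.array(sidx, dtype=np.int64),
        scoef=np.array(scoef, dtype=np.float64),
        pool_ids=pool_ids,
        p_k=np.array(p_k, dtype=np.float64),
        p_mf0=np.array(p_mf0, dtype=np.float64),
        p_occ=(np.array(p_occ) if p_occ else np.zeros((0, n_s))),
        p_dist=(np.array(p_dist) if p_dist else np.zeros((0, n_s))),
        clamp_idx=clamp_idx,
    )


def mass_action_rhs(
    net: ReactionNetwork | CompiledModel, state: StateVector | Mapping[str, float]
) -> dict[str, float]:
    """Derivative of every species (nM/s) at the given state.

    Pure function over the network; convenience wrapper around the compiled
    form for inspection and testing.
    """
    model = net if isinstance(net, CompiledModel) else compile_network(net)
    if isinstance(state, StateVector):
        y = np.asarray(state.conc, dtype=float)
    else:
        y = np.array([float(state.get(n, 0.0)) for n in model.species])
    dy = model.rhs(y)
    return dict(zip(model.species, dy.tolist()))


# --------------------------------------------------------------------------
# RK4 kernel
# --------------------------------------------------------------------------


@njit(cache=False)
def _rhs_kernel(y, ri1, ri2, k, sptr, sidx, scoef, p_k, p_mf0, p_occ, p_dist,
                clamp_idx, dy):  # pragma: no cover - jitted
    for i in range(y.size):
        dy[i] = 0.0
    for j in range(ri1.size):
        r = k[j] * y[ri1[j]]
        if ri2[j] >= 0:
            r *= y[ri2[j]]
        for m in range(sptr[j], sptr[j + 1]):
            dy[sidx[m]] += scoef[m] * r
    for p in range(p_k.size):
        occ = 0.0
        for i in range(y.size):
            w = p_occ[p, i]
            if w != 0.0:
                occ += w * y[i]
        free_sites = p_mf0[p] - occ
        if free_sites > 0.0:
            flux = p_k[p] * free_sites
            for i in range(y.size):
                d = p_dist[p, i]
                if d != 0.0:
                    dy[i] += flux * d
    for m in range(clamp_idx.size):
        dy[clamp_idx[m]] = 0.0


@njit(cache=False)
def _rk4_kernel(y, dt, n_steps, stride, ri1, ri2, k, sptr, sidx, scoef,
                p_k, p_mf0, p_occ, p_dist, clamp_idx, out,
                neg_tol):  # pragma: no cover - jitted
    n = y.size
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    rec = 0
    out[0, :] = y
    for step in range(n_steps):
        _rhs_kernel(y, ri1, ri2, k, sptr, sidx, scoef, p_k, p_mf0, p_occ,
                    p_dist, clamp_idx, k1)
        for i in range(n):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        _rhs_kernel(yt, ri1, ri2, k, sptr, sidx, scoef, p_k, p_mf0, p_occ,
                    p_dist, clamp_idx, k2)
        for i in range(n):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        _rhs_kernel(yt, ri1, ri2, k, sptr, sidx, scoef, p_k, p_mf0, p_occ,
                    p_dist, clamp_idx, k3)
        for i in range(n):
            yt[i] = y[i] + dt * k3[i]
        _rhs_kernel(yt, ri1, ri2, k, sptr, sidx, scoef, p_k, p_mf0, p_occ,
                    p_dist, clamp_idx, k4)
        for i in range(n):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if (step + 1) % stride == 0:
            rec += 1
            ok = True
            for i in range(n):
                if not np.isfinite(y[i]) or y[i] < -neg_tol:
                    ok = False
            out[rec, :] = y
            if not ok:
                return -(step + 1)
    return rec


def _run_segment(model: CompiledModel, y: np.ndarray, t0: float, t1: float,
                 dt: float, stride: int):
    """Integrate [t0, t1] in place; return (times, records) past t0."""
    span = t1 - t0
    if span <= 0:
        return np.empty(0), np.empty((0, y.size))
    n_steps = max(1, int(math.ceil(span / dt - 1e-9)))
    dt_eff = span / n_steps
    n_rec = n_steps // stride
    out = np.empty((n_rec + 1, y.size))
    rc = _rk4_kernel(
        y, dt_eff, n_steps, stride, model.ri1, model.ri2, model.k_eff,
        model.sptr, model.sidx, model.scoef, model.p_k, model.p_mf0,
        model.p_occ, model.p_dist, model.clamp_idx, out, NEG_TOLERANCE,
    )
    if rc < 0:
        bad_step = -rc
        row = out[min(bad_step // stride, n_rec)]
        bad = np.where(~np.isfinite(row) | (row < -NEG_TOLERANCE))[0]
        name = model.species[bad[0]] if bad.size else "<unknown>"
        raise IntegrationError(t0 + bad_step * dt_eff, name)
    times = t0 + dt_eff * stride * np.arange(1, n_rec + 1)
    recs = out[1 : n_rec + 1].copy()
    if n_rec == 0 or times[-1] < t1 - 1e-12:
        times = np.append(times, t1)
        recs = np.vstack([recs, y])
    return times, recs


def _stability_check(model: CompiledModel, y: np.ndarray, dt: float) -> None:
    decay = np.zeros_like(y)
    rates = model.k_eff * np.where(model.ri2 >= 0, y[model.ri2], 1.0)
    np.add.at(decay, model.ri1, rates)
    lam = float(np.max(decay)) if decay.size else 0.0
    if lam * dt > 2.0:
        warnings.warn(
            f"dt={dt:g} s likely exceeds the RK4 stability bound "
            f"(fastest local rate ~{lam:g}/s); consider dt < {2.0 / lam:g} s",
            RuntimeWarning,
            stacklevel=3,
        )


def integrate_rk4(
    model: CompiledModel | ReactionNetwork,
    y0: StateVector | Mapping[str, float],
    t_end: float,
    dt: float = DEFAULT_DT,
    events: Iterable[tuple[float, Callable[[np.ndarray], tuple]]] | None = None,
    record_every: float | None = None,
    t_start: float = 0.0,
) -> Trajectory:
    """Classic fixed-step RK4 over ``[t_start, t_end]``.

    ``events`` is a time-sorted iterable of ``(time, operator)`` pairs; each
    operator receives the raw state array at its event time and returns
    ``(new_state, log_entry_or_None)``.  The grid is aligned so every event
    time is hit exactly.  Output is sampled every ``record_every`` seconds
    (default: every step).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not isinstance(model, CompiledModel):
        model = compile_network(model)
    if isinstance(y0, StateVector):
        y = np.asarray(y0.conc, dtype=float).copy()
    else:
        y = StateVector.from_dict(model.net, y0).conc

    stride = 1 if record_every is None else max(1, int(round(record_every / dt)))
    _stability_check(model, y, dt)

    ev = sorted(events, key=lambda e: e[0]) if events else []
    if any(e[0] < t_start - 1e-12 for e in ev):
        raise ValueError("event before start of integration")

    times = [t_start]
    states = [y.copy()]
    applied: list[tuple] = []
    t_cursor = t_start
    for e_time, op in ev:
        if e_time > t_end + 1e-12:
            break
        seg_t, seg_s = _run_segment(model, y, t_cursor, min(e_time, t_end), dt,
                                    stride)
        times.extend(seg_t.tolist())
        states.extend(seg_s)
        t_cursor = max(t_cursor, min(e_time, t_end))
        y, entry = op(y)
        if entry is not None:
            applied.append(entry)
        states[-1] = y.copy()  # event jump replaces the boundary sample
    seg_t, seg_s = _run_segment(model, y, t_cursor, t_end, dt, stride)
    times.extend(seg_t.tolist())
    states.extend(seg_s)

    t_arr = np.array(times)
    s_arr = np.array(states)
    keep = np.concatenate([[True], np.diff(t_arr) > 1e-15])
    s_arr = np.where((s_arr > -NEG_TOLERANCE) & (s_arr < 0), 0.0, s_arr)
    return Trajectory(t_arr[keep], s_arr[keep], model.species, applied)


# --------------------------------------------------------------------------
# steady-state detection
# --------------------------------------------------------------------------


@dataclass
class SteadyStateResult:
    value: float
    reached_at: float
    converged: bool
    drift: float


def detect_steady_state(
    traj: Trajectory,
    observable: str | Mapping[str, float] | np.ndarray,
    rel_tol: float = 1e-4,
    window: float = 500.0,
) -> SteadyStateResult:
    """Plateau value of an observable once its drift falls below ``rel_tol``.

    The observable is declared steady at the earliest time where its total
    variation over the trailing ``window`` seconds is below ``rel_tol``
    relative to its level.  A trajectory that never satisfies the criterion
    yields ``converged=False`` (callers must not fall back silently to the
    last value).
    """
    if isinstance(observable, str):
        series = traj.series(observable)
    elif isinstance(observable, Mapping):
        series = traj.observable(observable)
    else:
        series = np.asarray(observable, dtype=float)
    t = traj.times
    if t[-1] - t[0] < window:
        raise ValueError("trajectory shorter than the steady-state window")
    scale = float(np.max(np.abs(series))) or 1.0
    start = np.searchsorted(t, t[0] + window)
    for i in range(start, len(t)):
        lo = np.searchsorted(t, t[i] - window)
        win = series[lo : i + 1]
        level = float(np.mean(win))
        spread = float(np.max(win) - np.min(win))
        ref = max(abs(level), 1e-12 * scale)
        if spread <= rel_tol * ref:
            return SteadyStateResult(level, float(t[i]), True, spread / ref)
    lo = np.searchsorted(t, t[-1] - window)
    win = series[lo:]
    level = float(np.mean(win))
    ref = max(abs(level), 1e-12 * scale)
    return SteadyStateResult(level, float(t[-1]), False,
                             float(np.max(win) - np.min(win)) / ref)
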