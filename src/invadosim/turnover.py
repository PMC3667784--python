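"""MT1-MMP delivery and removal through invadopodial membrane pools.

FRAP experiments on invadopodia resolve two kinetically distinct MT1-MMP
docking pools: a slow pool X (turnover time constant 259 s, 30 nM of docking
sites) and a fast pool D (26.0 s, 70 nM); together they carry the ~100 nM
surface expression of the invadopodial membrane.  Delivery is modelled
either as a continuous flux ``k_ins * M_F`` onto the free docking sites
``M_F = M_F0 - occupied`` or as discrete vesicular pulses whose interval is
chosen so the time-averaged delivery matches the continuous model's maximal
flux:

    t_int0 = PH / (k_ins * M_F0)

where ``PH`` is the amount delivered by a single vesicle.  With single vesicles
delivering 10% of the docking capacity (3 nM for X, 7 nM for D) this
gives 25.9 s for pool X and 2.6 s for pool D.  Internalisation removes every membrane species of a pool at
``k_int``; internalised material does not recycle.

The module also implements the transient-elimination insertion mode:
instead of arriving as fresh, TIMP-free enzyme, newly inserted MT1-MMP is
apportioned across the pool's complexes in their steady-state proportions,
which abolishes the sharp activity transient that otherwise follows every
insertion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .kinetics import (
    CompiledModel,
    StateVector,
    SteadyStateError,
    Trajectory,
    compile_network,
    detect_steady_state,
    integrate_rk4,
)
from .network import (
    KineticParameters,
    Location,
    Reaction,
    ReactionNetwork,
    build_core_network,
)

__all__ = [
    "PoolConfig",
    "InsertionSchedule",
    "PulseEvent",
    "pool_x",
    "pool_d",
    "single_pool",
    "continuous_turnover_reactions",
    "add_turnover",
    "pulse_interval",
    "generate_schedule",
    "apply_pulse",
    "steady_state_fractions",
    "insertion_distribution",
    "distribute_insertion",
    "build_turnover_model",
    "pulse_events_to_operators",
]

_POOL_LOC = {
    "X": Location.MEMBRANE_X,
    "D": Location.MEMBRANE_D,
    "M": Location.MEMBRANE,
}


@dataclass(frozen=True)
class PoolConfig:
    """One membrane docking pool.

    ``M_F0`` is the maximum docking-site concentration (nM); a docked
    complex occupies sites equal to its MT1-MMP monomer count.  ``k_ins``
    and ``k_int`` are the continuous insertion and internalisation rate
    constants (1/s); both default to the reciprocal FRAP time constant.
    """

    pool_id: str
    M_F0: float
    k_ins: float
    k_int: float

    def __post_init__(self) -> None:
        if self.M_F0 <= 0:
            raise ValueError("M_F0 must be positive")
        if self.pool_id not in _POOL_LOC:
            raise ValueError(f"pool_id must be one of {sorted(_POOL_LOC)}")

    @property
    def turnover_tau(self) -> float:
        return 1.0 / self.k_ins

    @property
    def location(self) -> Location:
        return _POOL_LOC[self.pool_id]

    @property
    def suffix(self) -> str:
        return self.pool_id if self.pool_id in ("X", "D") else ""

    def scaled(self, factor: float) -> "PoolConfig":
        """Scale the turnover rate (insertion and internalisation jointly)."""
        return replace(self, k_ins=self.k_ins * factor, k_int=self.k_int * factor)


def pool_x(scale: float = 1.0) -> PoolConfig:
    """Slow pool: tau = 259 s; 30 nM docking capacity (single vesicles
    deliver 10%, i.e. 3 nM)."""
    return PoolConfig("X", 30.0, 1.0 / 259.0, 1.0 / 259.0).scaled(scale)


def pool_d(scale: float = 1.0) -> PoolConfig:
    """Fast pool: tau = 26.0 s; 70 nM docking capacity (single vesicles
    deliver 10%, i.e. 7 nM)."""
    return PoolConfig("D", 70.0, 1.0 / 26.0, 1.0 / 26.0).scaled(scale)


def single_pool(M_F0: float = 10.0, tau: float = 100.0) -> PoolConfig:
    return PoolConfig("M", M_F0, 1.0 / tau, 1.0 / tau)


@dataclass
class PulseEvent:
    time: float
    pool_id: str
    amount: float  # requested, nM; clamping happens at application time

    def __post_init__(self) -> None:
        if self.time < 0 or self.amount < 0:
            raise ValueError("pulse time and amount must be non-negative")


@dataclass
class InsertionSchedule:
    """Description of the MT1-MMP delivery regimen.

    ``freq_fold`` and ``conc_fold`` rescale the pulse frequency and the
    single-pulse amount relative to the control regimen; sweeps that keep
    the time-averaged delivery fixed use reciprocal folds
    (``freq_fold * conc_fold = 1``).  Random intervals are exponential with
    the regular interval as mean; random amounts are uniform on
    ``[0, 2 PH]``.
    """

    mode: str = "pulsatile"  # or "continuous"
    interval_mode: str = "regular"  # or "random"
    amount_mode: str = "regular"  # or "random"
    PH: Mapping[str, float] = field(default_factory=dict)  # per pool, nM
    freq_fold: float = 1.0
    conc_fold: float = 1.0
    seed: int | None = None

    def pulse_amount(self, pool: PoolConfig) -> float:
        base = self.PH.get(pool.pool_id, 0.1 * pool.M_F0)
        return base * self.conc_fold

    def base_interval(self, pool: PoolConfig) -> float:
        base = self.PH.get(pool.pool_id, 0.1 * pool.M_F0)
        return pulse_interval(base, pool.k_ins, pool.M_F0) / self.freq_fold


def pulse_interval(PH: float, k_ins: float, M_F0: float) -> float:
    """Pulse interval making time-averaged pulsatile delivery equal the
    continuous model's maximal flux ``k_ins * M_F0``."""
    if PH <= 0 or k_ins <= 0 or M_F0 <= 0:
        raise ValueError("PH, k_ins and M_F0 must all be positive")
    return PH / (k_ins * M_F0)


def generate_schedule(
    sched: InsertionSchedule,
    pools: Sequence[PoolConfig],
    t_end: float,
) -> list[PulseEvent]:
    """Realise the pulse-event list for ``[0, t_end]``.

    Regular intervals emit pulses at ``0, t_int0, 2 t_int0, ...`` per pool.
    Random intervals draw exponential waiting times with mean ``t_int0``;
    random amounts draw uniformly on ``[0, 2 PH]``.  Either way the expected
    time-averaged delivery equals the regular schedule's.
    """
    if sched.mode != "pulsatile":
        return []
    randomised = "random" in (sched.interval_mode, sched.amount_mode)
    if randomised and sched.seed is None:
        raise ValueError("random schedules require a seed")
    events: list[PulseEvent] = []
    for k_pool, pool in enumerate(pools):
        rng = np.random.default_rng(
            None if sched.seed is None else [int(sched.seed), k_pool]
        )
        t_int0 = sched.base_interval(pool)
        amount = sched.pulse_amount(pool)
        t = 0.0
        while t <= t_end + 1e-9:
            if sched.amount_mode == "random":
                a = float(rng.uniform(0.0, 2.0 * amount))
            else:
                a = amount
            events.append(PulseEvent(min(t, t_end), pool.pool_id, a))
            if sched.interval_mode == "random":
                t += float(rng.exponential(t_int0))
            else:
                t += t_int0
    events.sort(key=lambda e: (e.time, e.pool_id))
    return events


# --------------------------------------------------------------------------
# continuous turnover
# --------------------------------------------------------------------------


def continuous_turnover_reactions(
    pool: PoolConfig, net: ReactionNetwork
) -> list[Reaction]:
    """Insertion and internalisation reactions for one pool.

    Insertion delivers free MT1-MMP at ``k_ins * M_F`` (saturating at zero
    once the docking sites are full); internalisation removes every
    membrane species of the pool at ``k_int``.  Internalising an ECM-engaged
    complex releases its bound ECM unit back to the matrix.
    """
    free_name = "M14" + pool.suffix
    rxns = [
        Reaction((), (free_name,), pool.k_ins, "insertion", 1, pool.pool_id)
    ]
    for s in net.species:
        if s.location is not pool.location:
            continue
        products = ("ECM",) * s.count("ECM")
        rxns.append(
            Reaction((s.name,), products, pool.k_int, "internalization", 1,
                     pool.pool_id)
        )
    return rxns


def add_turnover(
    net: ReactionNetwork, pools: Sequence[PoolConfig]
) -> ReactionNetwork:
    """Return a copy of the network with pool turnover attached."""
    out = net.copy()
    cfg = {}
    for pool in pools:
        if not out.has_species("M14" + pool.suffix):
            raise ValueError(
                f"network has no membrane species for pool {pool.pool_id!r}"
            )
        out.reactions.extend(continuous_turnover_reactions(pool, out))
        cfg[pool.pool_id] = {
            "M_F0": pool.M_F0,
            "k_ins": pool.k_ins,
            "k_int": pool.k_int,
        }
    out.metadata = {**out.metadata, "pools_config": cfg}
    out.validate()
    return out


# --------------------------------------------------------------------------
# pulse application
# --------------------------------------------------------------------------


def apply_pulse(
    model: CompiledModel,
    state: StateVector | np.ndarray,
    pool_id: str,
    amount: float,
    dist: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Add one vesicle's worth of MT1-MMP to a pool, limited by free sites.

    The docked amount is ``min(amount, M_F0) * M_F / M_F0``: delivery
    scales with the free docking sites, so a regular pulse train has
    exactly the continuous model's time-averaged insertion ``k_ins * M_F``
    at every occupancy, and nothing docks on a saturated pool.  Returns the
    new state array and the amount actually docked (nM of MT1-MMP monomer
    equivalents).  With ``dist`` the insertion is apportioned across
    complexes (transient-elimination mode) instead of arriving as free
    enzyme.
    """
    if amount < 0:
        raise ValueError("pulse amount must be non-negative")
    y = (state.conc if isinstance(state, StateVector) else
         np.asarray(state, dtype=float)).copy()
    p = model.pool_ids.index(pool_id)
    free_sites = model.p_mf0[p] - float(model.p_occ[p] @ y)
    applied = (min(amount, model.p_mf0[p]) / model.p_mf0[p]
               * max(free_sites, 0.0))
    if applied > 0:
        vec = model.p_dist[p] if dist is None else dist
        clamped = np.zeros(len(y), dtype=bool)
        clamped[model.clamp_idx] = True
        delta = applied * vec
        y = np.where(clamped, y, y + delta)
        neg = y < 0
        if np.any(neg):  # co-insertion drained a solution species dry
            warnings.warn(
                "insertion distribution exhausted a solution species; "
                "clamping at zero",
                RuntimeWarning,
                stacklevel=2,
            )
            y[neg] = 0.0
    return y, applied


def pulse_events_to_operators(
    model: CompiledModel,
    events: Sequence[PulseEvent],
    dists: Mapping[str, np.ndarray] | None = None,
):
    """Convert pulse events into integrator event operators."""
    ops = []
    for e in events:
        def op(y, _e=e):
            dist = dists.get(_e.pool_id) if dists else None
            y_new, applied = apply_pulse(model, y, _e.pool_id, _e.amount, dist)
            return y_new, (_e.time, _e.pool_id, applied)

        ops.append((e.time, op))
    return ops


# --------------------------------------------------------------------------
# transient elimination
# --------------------------------------------------------------------------


def _steady_fractions_multi(
    model: CompiledModel,
    y0: StateVector | Mapping[str, float] | np.ndarray,
    pool_ids: Sequence[str],
    t_max: float = 20000.0,
    dt: float = 0.02,
    rel_tol: float = 1e-4,
    window: float = 500.0,
) -> tuple[dict[str, dict[str, float]], np.ndarray]:
    """Fractions for several pools from a single steady-state run."""
    if isinstance(y0, np.ndarray):
        y0 = StateVector(model.species, y0.copy())
    traj = integrate_rk4(model, y0, t_max, dt=dt, record_every=max(dt, 1.0))
    out: dict[str, dict[str, float]] = {}
    y_steady = traj.states[-1]
    for pool_id in pool_ids:
        loc = _POOL_LOC[pool_id]
        occ_weights = {
            s.name: float(s.m14_content)
            for s in model.net.species
            if s.location is loc and s.m14_content > 0
        }
        res = detect_steady_state(traj, occ_weights, rel_tol=rel_tol,
                                  window=window)
        if not res.converged:
            raise SteadyStateError(
                f"pool {pool_id!r} occupancy still drifting at t={t_max:g} s "
                f"(relative drift {res.drift:.2e})"
            )
        i = min(int(np.searchsorted(traj.times, res.reached_at)),
                len(traj.times) - 1)
        y = traj.states[i]
        y_steady = y
        shares = {name: w * float(y[model.index[name]])
                  for name, w in occ_weights.items()}
        total = sum(shares.values())
        if total <= 0:
            raise SteadyStateError(f"pool {pool_id!r} is empty at steady state")
        out[pool_id] = {name: v / total for name, v in shares.items()}
    return out, y_steady


def steady_state_fractions(
    model: CompiledModel,
    y0: StateVector | Mapping[str, float],
    pool_id: str,
    t_max: float = 20000.0,
    dt: float = 0.02,
    rel_tol: float = 1e-4,
    window: float = 500.0,
) -> dict[str, float]:
    """Steady-state distribution of membrane MT1-MMP over a pool's complexes.

    Runs the continuous-turnover model to steady state and returns, per
    membrane species of the pool, its share of the docked MT1-MMP monomer
    equivalents (sums to 1).  Raises :class:`SteadyStateError` if the pool
    occupancy has not settled within ``t_max``.
    """
    fr, _ = _steady_fractions_multi(model, y0, [pool_id], t_max=t_max, dt=dt,
                                    rel_tol=rel_tol, window=window)
    return fr[pool_id]


def insertion_distribution(
    model: CompiledModel, fractions: Mapping[str, float]
) -> np.ndarray:
    """State-change vector per nM of inserted MT1-MMP monomer equivalents.

    Complexes receive ``fraction / (M14 content)`` moles each; the TIMP-2
    and pro-MMP-2 they carry are drawn from the bulk solution species so
    that solution totals stay physical.
    """
    vec = np.zeros(model.n_species)
    for name, frac in fractions.items():
        if frac < 0:
            raise ValueError("fractions must be non-negative")
        if frac == 0:
            continue
        sp = model.net.species_by_name(name)
        n14 = sp.m14_content
        if n14 <= 0:
            raise ValueError(f"{name!r} carries no MT1-MMP and cannot be "
                             "an insertion target")
        moles = frac / n14
        vec[model.index[name]] += moles
        if sp.count("T2"):
            vec[model.index["T2"]] -= moles * sp.count("T2")
        if sp.count("M2"):
            vec[model.index["M2"]] -= moles * sp.count("M2")
    return vec


def distribute_insertion(
    model: CompiledModel,
    state: StateVector | np.ndarray,
    pool_id: str,
    amount: float,
    fractions: Mapping[str, float],
) -> tuple[np.ndarray, float]:
    """Apportion one insertion across complexes in the given proportions."""
    dist = insertion_distribution(model, fractions)
    return apply_pulse(model, state, pool_id, amount, dist=dist)


# --------------------------------------------------------------------------
# high-level model assembly
# --------------------------------------------------------------------------


def default_pools(scale: float = 1.0) -> list[PoolConfig]:
    return [pool_x(scale), pool_d(scale)]


def build_turnover_model(
    params: KineticParameters | None = None,
    pools: Sequence[PoolConfig] | None = None,
    include_ecm: bool = False,
    include_shedding: bool = False,
    eliminate_transient: bool = False,
    clamp_solution: bool = True,
    deletions: Sequence[int] = (),
) -> tuple[CompiledModel, StateVector]:
    """Assemble the two-pool turnover model and its default initial state.

    The membrane starts with both pools fully docked with free MT1-MMP (the
    surface expression present at t = 0); solution TIMP-2 and pro-MMP-2 are
    clamped reservoirs by default, standing in for the large extracellular
    volume.  With ``eliminate_transient`` the continuous insertion flux (and
    any pulses built on this model) is distributed across each pool's
    complexes in their steady-state proportions.
    """
    from .network import apply_path_deletions  # local to avoid cycle noise

    p = params or KineticParameters()
    pools = list(pools) if pools is not None else default_pools()
    net = build_core_network(
        p, include_ecm=include_ecm, include_shedding=include_shedding,
        pools="XD",
    )
    if deletions:
        net = apply_path_deletions(net, deletions)
    net = add_turnover(net, pools)

    clamped = ("T2", "M2") if clamp_solution else ()
    model = compile_network(net, clamped=clamped)

    init = {"T2": p.T2_0, "M2": p.M2_0}
    for pool in pools:
        init["M14" + pool.suffix] = pool.M_F0
    if include_ecm:
        init["ECM"] = p.ECM_0
    y0 = model.initial_state(init)

    if eliminate_transient:
        # the complex distribution is taken from the insertion/inhibition
        # balance alone, so fractions are computed on the ECM-free variant
        if include_ecm:
            net_ne = build_core_network(p, include_ecm=False,
                                        include_shedding=include_shedding,
                                        pools="XD")
            if deletions:
                net_ne = apply_path_deletions(net_ne, deletions)
            net_ne = add_turnover(net_ne, pools)
            model_ne = compile_network(net_ne, clamped=clamped)
            y0_ne = model_ne.initial_state(
                {k: v for k, v in init.items() if k != "ECM"}
            )
        else:
            model_ne, y0_ne = model, y0
        fr, y_seed = _self_consistent_fractions(model_ne, y0_ne, pools,
                                                clamped)
        dists = {pid: insertion_distribution(model, fr[pid]) for pid in fr}
        model = compile_network(net, insertion_dists=dists, clamped=clamped)
        # start at the eliminated model's own steady state: every complex
        # is flat from t = 0, the hallmark of the eliminated regime
        y = model.initial_state(
            {"ECM": p.ECM_0} if include_ecm else {}
        ).conc
        for name in model_ne.species:
            y[model.index[name]] = y_seed[model_ne.index[name]]
        y0 = StateVector(model.species, y, 0.0)
    return model, y0


def _self_consistent_fractions(
    model: CompiledModel,
    y0: StateVector,
    pools: Sequence[PoolConfig],
    clamped: Sequence[str],
    max_iter: int = 12,
    tol: float = 1e-3,
) -> tuple[dict[str, dict[str, float]], np.ndarray]:
    """Fixed point of the transient-elimination insertion distribution.

    Inserted MT1-MMP must be apportioned in the steady-state proportions of
    the eliminated model itself, or the distributed state would still relax
    (a residual transient).  Iterate from the normal-insertion steady
    fractions until the fractions stop changing; returns the converged
    fractions and the eliminated model's steady state.
    """
    pool_ids = [pool.pool_id for pool in pools]
    net = model.net
    fr, y_seed = _steady_fractions_multi(model, y0, pool_ids)
    delta = math.inf
    for it in range(max_iter):
        dists = {pid: insertion_distribution(model, fr[pid])
                 for pid in pool_ids}
        model_e = compile_network(net, insertion_dists=dists, clamped=clamped)
        t_max = 20000.0 if it == 0 else 6000.0
        fr_new, y_seed = _steady_fractions_multi(model_e, y_seed, pool_ids,
                                                 t_max=t_max)
        delta = max(
            abs(fr_new[pid].get(k, 0.0) - fr[pid].get(k, 0.0))
            for pid in pool_ids
            for k in set(fr_new[pid]) | set(fr[pid])
        )
        fr = fr_new
        if delta < tol:
            break
    else:
        warnings.warn(
            f"transient-elimination fractions not fully converged "
            f"(last change {delta:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    return fr, y_seed
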