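"""ECM degradation by active MT1-MMP complexes and active MMP-2.

Degradation uses explicit enzyme-substrate complexes rather than a lumped
Michaelis-Menten rate, because the pool of engaged complexes (``M14a.ECM``)
is itself an observable of interest: its time integral is directly
proportional to the amount of degraded matrix.  Five enzyme classes attack
the ECM: the four degradation-competent MT1-MMP forms (monomer, free dimer,
and the two single-TIMP dimer forms) and soluble active MMP-2.

Metrics: ``tau_half`` is the time at which half of the initial ECM has been
degraded; the initial degradation rate is the least-squares slope of the
ECM loss over a short window at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .kinetics import Trajectory
from .network import (
    KineticParameters,
    Location,
    MolecularSpecies,
    NetworkConfigError,
    Reaction,
    ReactionNetwork,
)

__all__ = [
    "EcmParameters",
    "DegradationMetrics",
    "add_ecm_reactions",
    "tau_half",
    "integrated_active_ecm_complex",
    "initial_degradation_rate",
    "m14a_ecm_species",
]


@dataclass
class EcmParameters:
    """ECM binding/cleavage constants per enzyme class (nM, s units)."""

    ECM_0: float = 2000.0
    k_on_mt1: float = 1.0e-2
    k_off_mt1: float = 1.0e-2
    k_cat_mt1: float = 1.0e-1
    k_on_m2act: float = 1.0e-2
    k_off_m2act: float = 1.0e-2
    k_cat_m2act: float = 1.0e-1

    @classmethod
    def from_kinetic(cls, p: KineticParameters) -> "EcmParameters":
        return cls(
            ECM_0=p.ECM_0,
            k_on_mt1=p.k_on_ecm_mt1,
            k_off_mt1=p.k_off_ecm_mt1,
            k_cat_mt1=p.k_cat_mt1,
            k_on_m2act=p.k_on_ecm_m2act,
            k_off_m2act=p.k_off_ecm_m2act,
            k_cat_m2act=p.k_cat_m2act,
        )


@dataclass
class DegradationMetrics:
    tau_H: float | None  # None when ECM never falls below 50%
    initial_rate: float
    degraded_fraction: np.ndarray


def _mt1_enzyme_species(net: ReactionNetwork) -> list[MolecularSpecies]:
    """Degradation-competent membrane forms (activity weight > 0)."""
    return [s for s in net.species
            if s.location.is_membrane and s.activity_weight > 0]


def add_ecm_reactions(
    net: ReactionNetwork, p: EcmParameters | None = None
) -> ReactionNetwork:
    """Attach ECM species and degradation reactions to a network.

    For every enzyme class E: ``E + ECM <-> E.ECM -> E`` with the ECM unit
    consumed by the cleavage step.  MT1-ECM complexes stay in their membrane
    pool (and are internalisable once turnover is attached); dimer binding
    carries the statistical factor of its two free catalytic sites.
    """
    p = p or EcmParameters()
    out = net.copy()
    if not out.has_species("ECM"):
        out.species.append(MolecularSpecies("ECM", {"ECM": 1}, Location.SOLUTION))
    for v in ("k_on_mt1", "k_off_mt1", "k_cat_mt1", "k_on_m2act",
              "k_off_m2act", "k_cat_m2act"):
        if getattr(p, v) is None or getattr(p, v) < 0:
            raise NetworkConfigError(f"missing or negative ECM constant: {v}")

    def R(re, pr, k, tag, mult=1):
        out.reactions.append(Reaction(tuple(re), tuple(pr), k, tag, mult))

    for enz in _mt1_enzyme_species(out):
        cplx = enz.name + ".ECM"
        if not out.has_species(cplx):
            comp = dict(enz.composition)
            comp["ECM"] = 1
            out.species.append(MolecularSpecies(cplx, comp, enz.location))
        n_free = int(round(enz.activity_weight))
        R([enz.name, "ECM"], [cplx], p.k_on_mt1, "ecm_binding", n_free)
        R([cplx], [enz.name, "ECM"], p.k_off_mt1, "dissociation")
        R([cplx], [enz.name], p.k_cat_mt1, "ecm_cleavage")

    if out.has_species("M2act"):
        if not out.has_species("M2act.ECM"):
            out.species.append(
                MolecularSpecies("M2act.ECM", {"M2act": 1, "ECM": 1},
                                 Location.SOLUTION)
            )
        R(["M2act", "ECM"], ["M2act.ECM"], p.k_on_m2act, "ecm_binding")
        R(["M2act.ECM"], ["M2act", "ECM"], p.k_off_m2act, "dissociation")
        R(["M2act.ECM"], ["M2act"], p.k_cat_m2act, "ecm_cleavage")

    out.metadata = {**out.metadata, "include_ecm": True}
    out.validate()
    return out


def m14a_ecm_species(net_or_names) -> list[str]:
    """Names of the ECM-engaged degradation-competent MT1 complexes."""
    if isinstance(net_or_names, ReactionNetwork):
        return [s.name for s in net_or_names.species
                if s.count("ECM") and s.m14_content and "." in s.name]
    return [n for n in net_or_names if n.endswith(".ECM") and "M14" in n]


def _ecm_series(traj: Trajectory, total: bool = True) -> np.ndarray:
    """Free ECM; with ``total`` also the transiently enzyme-bound units."""
    ecm = traj.series("ECM").copy()
    if total:
        for n in traj.species:
            if n != "ECM" and n.endswith(".ECM"):
                ecm += traj.series(n)
    return ecm


def tau_half(
    traj: Trajectory | Sequence[float],
    ECM_0: float | None = None,
    times: Sequence[float] | None = None,
) -> float | None:
    """First time at which ECM falls to half of ``ECM_0``.

    Linearly interpolated between output samples; returns ``None`` if the
    trajectory never reaches 50% (callers must handle the not-reached case
    explicitly).  Enzyme-bound ECM units count as not-yet-degraded.
    """
    if isinstance(traj, Trajectory):
        series = _ecm_series(traj)
        t = traj.times
    else:
        series = np.asarray(traj, dtype=float)
        t = np.asarray(times, dtype=float)
    ecm0 = float(series[0]) if ECM_0 is None else float(ECM_0)
    target = ecm0 / 2.0
    below = np.nonzero(series <= target)[0]
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        return float(t[0])
    f = (series[i - 1] - target) / (series[i - 1] - series[i])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def integrated_active_ecm_complex(traj: Trajectory) -> np.ndarray:
    """Cumulative time integral of the summed M14a.ECM complexes (nM s).

    Directly proportional to the amount of ECM degraded through the MT1-MMP
    route; non-decreasing by construction.
    """
    names = [n for n in traj.species
             if n.endswith(".ECM") and "M14" in n]
    total = np.zeros(len(traj.times))
    for n in names:
        total += traj.series(n)
    return np.concatenate([[0.0], cumulative_trapezoid(total, traj.times)])


def initial_degradation_rate(
    traj: Trajectory, window: float = 10.0
) -> float:
    """Least-squares slope of ECM loss (nM/s) over ``[0, window]``."""
    series = _ecm_series(traj)
    t = traj.times
    mask = t <= t[0] + window
    if int(np.sum(mask)) < 2:
        raise ValueError("window must contain at least two samples")
    slope = np.polyfit(t[mask], series[mask], 1)[0]
    return float(-slope)


def degradation_metrics(
    traj: Trajectory, ECM_0: float, window: float = 10.0
) -> DegradationMetrics:
    series = _ecm_series(traj)
    return DegradationMetrics(
        tau_H=tau_half(traj, ECM_0),
        initial_rate=initial_degradation_rate(traj, window),
        degraded_fraction=1.0 - series / ECM_0,
    )
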