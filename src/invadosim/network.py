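"""Reaction-network construction for the MT1-MMP / TIMP-2 / MMP-2 system.

The membrane protease MT1-MMP (``M14``) is inhibited by soluble TIMP-2
(``T2``), which doubles as an adaptor that docks pro-MMP-2 (``M2``) onto the
membrane.  A second, TIMP-free MT1-MMP recruited by dimerisation through the
hemopexin domain processes the docked zymogen and releases active MMP-2
(``M2act``).  This module enumerates every complex that can be assembled from
these three players (plus optional ECM-bound and shed-fragment forms) and
emits the corresponding mass-action reaction list.

Complexes are named with the established dotted convention, e.g.
``M14.M14.T2.M2`` for the activation-competent quaternary complex and
``M14.T2.M2.M14.T2.M2`` for the fully inhibited double-loaded dimer.  In the
two-pool membrane variant every ``M14`` token carries the pool suffix
(``M14X``, ``M14D``).

ECM-degradation-competent ("M14a") species are the TIMP-free monomer, the
dimer (two free catalytic sites, activity weight 2) and the two
single-loaded dimer forms ``M14.M14.T2`` and ``M14.M14.T2.M2`` (one free
site each, weight 1).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Location",
    "MolecularSpecies",
    "Reaction",
    "KineticParameters",
    "ReactionNetwork",
    "NetworkConfigError",
    "enumerate_species",
    "build_core_network",
    "apply_path_deletions",
    "add_ectodomain_shedding",
    "conservation_totals",
    "PATH_DELETION_TARGETS",
]


class Location(str, Enum):
    """Where a species lives."""

    MEMBRANE = "membrane"
    MEMBRANE_X = "membrane_X"
    MEMBRANE_D = "membrane_D"
    SOLUTION = "solution"

    @property
    def is_membrane(self) -> bool:
        return self is not Location.SOLUTION


class NetworkConfigError(ValueError):
    """Raised when a network cannot be built from the given options."""


@dataclass
class MolecularSpecies:
    """A monomer or complex, identified by its canonical dotted name."""

    name: str
    composition: dict[str, int]
    location: Location
    activity_weight: float = 0.0

    def count(self, monomer: str) -> int:
        return int(self.composition.get(monomer, 0))

    @property
    def m14_content(self) -> int:
        return self.count("M14")


@dataclass
class Reaction:
    """An elementary (at most bimolecular) mass-action reaction.

    ``multiplicity`` is the statistical factor for equivalent binding sites
    (e.g. TIMP-2 binding either catalytic site of the free dimer carries
    multiplicity 2); the effective rate is ``multiplicity * rate_constant *
    [A] * [B]``.  For identical bimolecular reactants the "distinct pair"
    convention is used: the propensity is ``k [A]^2`` and two copies of A are
    consumed per event.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float
    tag: str
    multiplicity: int = 1
    pool_id: str | None = None  # only for insertion/internalization bookkeeping

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ValueError(f"negative rate constant in {self}")
        if len(self.reactants) > 2:
            raise ValueError("at most bimolecular reactions are supported")

    @property
    def label(self) -> str:
        lhs = " + ".join(self.reactants) if self.reactants else "0"
        rhs = " + ".join(self.products) if self.products else "0"
        return f"{lhs} -> {rhs}"


@dataclass
class KineticParameters:
    """Rate constants and initial concentrations.

    Units: bimolecular on-rates in 1/(nM s), unimolecular rates in 1/s,
    concentrations in nM.  The defaults reconstruct the published
    MT1-MMP/TIMP-2/MMP-2 activation-cascade lineage of this model family:
    tight, fast TIMP-2 binding to the MT1-MMP catalytic site, slower
    pro-MMP-2 docking onto bound TIMP-2, hemopexin-domain dimerisation with a
    ~10 nM dissociation constant, and essentially irreversible inhibition of
    active MMP-2 by TIMP-2.
    """

    # TIMP-2 <-> free MT1-MMP catalytic site
    k_on_t2: float = 2.74e-3
    k_off_t2: float = 2.0e-4
    # pro-MMP-2 <-> bound TIMP-2 (and solution T2+M2 pre-assembly)
    k_on_m2: float = 1.4e-4
    k_off_m2: float = 4.7e-3
    # hemopexin-domain dimerisation of membrane MT1-MMP units
    k_on_dim: float = 1.0e-3
    k_off_dim: float = 1.0e-2
    # processing of docked pro-MMP-2 by the TIMP-free partner
    k_act: float = 2.0e-2
    # TIMP-2 inhibition of active MMP-2
    k_on_t2_m2act: float = 5.9e-3
    k_off_t2_m2act: float = 2.0e-4
    # ECM engagement and cleavage
    k_on_ecm_mt1: float = 1.0e-2
    k_off_ecm_mt1: float = 1.0e-2
    k_cat_mt1: float = 1.0e-1
    k_on_ecm_m2act: float = 1.0e-2
    k_off_ecm_m2act: float = 1.0e-2
    k_cat_m2act: float = 1.0e-1
    # ectodomain shedding of membrane MT1-MMP
    k_shed: float = 1.0e-4
    # initial concentrations (nM)
    M14_0: float = 100.0
    T2_0: float = 100.0
    M2_0: float = 100.0
    ECM_0: float = 2000.0
    # whether a pre-assembled T2.M2 unit can dock directly onto a free site
    docking_preassembled: bool = True

    def require(self, *names: str) -> None:
        for n in names:
            v = getattr(self, n, None)
            if v is None:
                raise NetworkConfigError(f"missing rate constant: {n}")
            if isinstance(v, float) and v < 0:
                raise NetworkConfigError(f"negative rate constant: {n}")


@dataclass
class ReactionNetwork:
    """Species set plus mass-action reaction list."""

    species: list[MolecularSpecies]
    reactions: list[Reaction]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ValueError("duplicate species names in network")

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_by_name(self, name: str) -> MolecularSpecies:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def has_species(self, name: str) -> bool:
        return any(s.name == name for s in self.species)

    def validate(self) -> None:
        names = set(self.species_names)
        for r in self.reactions:
            for n in (*r.reactants, *r.products):
                if n not in names:
                    raise NetworkConfigError(
                        f"reaction '{r.label}' references unknown species {n!r}"
                    )

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(
            species=copy.deepcopy(self.species),
            reactions=copy.deepcopy(self.reactions),
            metadata=copy.deepcopy(self.metadata),
        )

    def to_table(self) -> "pandas.DataFrame":  # noqa: F821 - lazy import
        """Reviewable flat table of the generated reaction list."""
        import pandas as pd

        rows = [
            {
                "reactants": " + ".join(r.reactants) if r.reactants else "",
                "products": " + ".join(r.products) if r.products else "",
                "rate_constant": r.rate_constant,
                "multiplicity": r.multiplicity,
                "tag": r.tag,
                "pool": r.pool_id or "",
            }
            for r in self.reactions
        ]
        return pd.DataFrame(rows)

    def export_table(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    def replace_reactions_from_table(self, path_or_buf) -> "ReactionNetwork":
        """Swap in a hand-curated reaction table (TSV, columns as exported).

        Provided so the generated edge list can be audited and overridden
        without touching code; species not mentioned are kept.
        """
        import pandas as pd

        df = pd.read_csv(path_or_buf, sep="\t").fillna("")
        reactions = []
        for _, row in df.iterrows():
            reactants = tuple(x for x in str(row["reactants"]).split(" + ") if x)
            products = tuple(x for x in str(row["products"]).split(" + ") if x)
            reactions.append(
                Reaction(
                    reactants=reactants,
                    products=products,
                    rate_constant=float(row["rate_constant"]),
                    tag=str(row["tag"]),
                    multiplicity=int(row.get("multiplicity", 1)),
                    pool_id=str(row["pool"]) or None if "pool" in row else None,
                )
            )
        out = self.copy()
        out.reactions = reactions
        out.metadata = {**out.metadata, "reactions_overridden": True}
        out.validate()
        return out


# --------------------------------------------------------------------------
# species enumeration
# --------------------------------------------------------------------------

# a membrane complex is a multiset of "arms": an MT1-MMP unit that is either
# free (""), TIMP-2-loaded ("T") or TIMP-2+proMMP-2-loaded ("TM")
_ARM_ORDER = {"": 0, "T": 1, "TM": 2}

_MONOMER_NAME = {"": "M14", "T": "M14.T2", "TM": "M14.T2.M2"}

# canonical dotted names for dimers, keyed by sorted arm pair
_DIMER_NAME = {
    ("", ""): "M14.M14",
    ("", "T"): "M14.M14.T2",
    ("", "TM"): "M14.M14.T2.M2",
    ("T", "T"): "M14.T2.M14.T2",
    ("T", "TM"): "M14.T2.M14.T2.M2",
    ("TM", "TM"): "M14.T2.M2.M14.T2.M2",
}

_ACTIVITY_WEIGHT = {
    "M14": 1.0,
    "M14.M14": 2.0,
    "M14.M14.T2": 1.0,
    "M14.M14.T2.M2": 1.0,
}

# the four ECM-degradation-competent MT1 forms (arms with >=1 free site)
_M14A_ARMS = [("",), ("", ""), ("", "T"), ("", "TM")]


def _arm_composition(arms: Sequence[str]) -> dict[str, int]:
    comp = {"M14": len(arms)}
    comp["T2"] = sum(1 for a in arms if a in ("T", "TM"))
    comp["M2"] = sum(1 for a in arms if a == "TM")
    return comp


def membrane_name(arms: Sequence[str], suffix: str = "") -> str:
    arms = tuple(sorted(arms, key=_ARM_ORDER.__getitem__))
    base = _MONOMER_NAME[arms[0]] if len(arms) == 1 else _DIMER_NAME[arms]
    return base.replace("M14", "M14" + suffix) if suffix else base


def _pool_suffixes(pools: str) -> list[tuple[str, Location]]:
    if pools == "single":
        return [("", Location.MEMBRANE)]
    if pools == "XD":
        return [("X", Location.MEMBRANE_X), ("D", Location.MEMBRANE_D)]
    raise NetworkConfigError(f"unknown pools option {pools!r} (use 'single' or 'XD')")


def enumerate_species(
    include_ecm: bool = False,
    include_shedding: bool = False,
    pools: str = "single",
) -> list[MolecularSpecies]:
    """Closed species list of the complex-formation network.

    Solution side: the three monomers' soluble forms plus the pre-assembled
    inhibitor/zymogen complexes.  Membrane side: every monomer/dimer with
    arms drawn from {free, T2-loaded, T2.M2-loaded}; with ``include_ecm``,
    each degradation-competent form additionally in an ECM-engaged state.
    Order is deterministic.
    """
    out: list[MolecularSpecies] = []

    def add(name, comp, loc, w=0.0):
        out.append(MolecularSpecies(name, dict(comp), loc, w))

    add("T2", {"T2": 1}, Location.SOLUTION)
    add("M2", {"M2": 1}, Location.SOLUTION)
    add("M2act", {"M2act": 1}, Location.SOLUTION)
    add("T2.M2", {"T2": 1, "M2": 1}, Location.SOLUTION)
    add("T2.M2act", {"T2": 1, "M2act": 1}, Location.SOLUTION)

    arm_sets: list[tuple[str, ...]] = [("",), ("T",), ("TM",)]
    arm_sets += list(_DIMER_NAME.keys())

    for suffix, loc in _pool_suffixes(pools):
        for arms in arm_sets:
            name = membrane_name(arms, suffix)
            base = membrane_name(arms)
            add(name, _arm_composition(arms), loc, _ACTIVITY_WEIGHT.get(base, 0.0))
        if include_ecm:
            for arms in _M14A_ARMS:
                name = membrane_name(arms, suffix) + ".ECM"
                comp = _arm_composition(arms)
                comp["ECM"] = 1
                add(name, comp, loc)

    if include_ecm:
        add("ECM", {"ECM": 1}, Location.SOLUTION)
        add("M2act.ECM", {"M2act": 1, "ECM": 1}, Location.SOLUTION)

    if include_shedding:
        # shed ectodomain fragment: soluble, catalytically inert here, but a
        # TIMP-2 scavenger
        add("M14f", {"M14": 1}, Location.SOLUTION)
        add("M14f.T2", {"M14": 1, "T2": 1}, Location.SOLUTION)

    return out


# --------------------------------------------------------------------------
# reaction construction
# --------------------------------------------------------------------------


def _membrane_arm_sets(include_dimers: bool = True) -> list[tuple[str, ...]]:
    sets: list[tuple[str, ...]] = [("",), ("T",), ("TM",)]
    if include_dimers:
        sets += list(_DIMER_NAME.keys())
    return sets


def build_core_network(
    params: KineticParameters | None = None,
    include_ecm: bool = False,
    include_shedding: bool = False,
    pools: str = "single",
) -> ReactionNetwork:
    """Build the mass-action network for complex formation and activation.

    Reaction classes (all reversible unless noted):

    * TIMP-2 binding to any TIMP-free catalytic site,
    * pro-MMP-2 docking onto any bound, unloaded TIMP-2 (on the membrane and
      in solution),
    * optional direct docking of a pre-assembled ``T2.M2`` unit onto a free
      site,
    * within-pool dimerisation of any two MT1 units through the hemopexin
      domain, irrespective of their T2/M2 load,
    * irreversible processing ``M14.M14.T2.M2 -> M14.M14.T2 + M2act``,
    * TIMP-2 inhibition of active MMP-2,
    * with ``include_ecm``: explicit enzyme-substrate complexes and
      irreversible cleavage for the four competent MT1 forms and M2act,
    * with ``include_shedding``: see :func:`add_ectodomain_shedding`.
    """
    p = params or KineticParameters()
    p.require("k_on_t2", "k_off_t2", "k_on_m2", "k_off_m2", "k_on_dim",
              "k_off_dim", "k_act", "k_on_t2_m2act", "k_off_t2_m2act")
    species = enumerate_species(include_ecm, include_shedding, pools)
    rxns: list[Reaction] = []

    def R(reactants, products, k, tag, mult=1, pool=None):
        rxns.append(Reaction(tuple(reactants), tuple(products), k, tag, mult, pool))

    # solution-side assembly and inhibition
    R(["T2", "M2"], ["T2.M2"], p.k_on_m2, "binding")
    R(["T2.M2"], ["T2", "M2"], p.k_off_m2, "dissociation")
    R(["T2", "M2act"], ["T2.M2act"], p.k_on_t2_m2act, "inhibition")
    R(["T2.M2act"], ["T2", "M2act"], p.k_off_t2_m2act, "dissociation")

    for suffix, _loc in _pool_suffixes(pools):
        def mname(arms):
            return membrane_name(arms, suffix)

        for arms in _membrane_arm_sets():
            name = mname(arms)
            free = [i for i, a in enumerate(arms) if a == ""]
            bare_t = [i for i, a in enumerate(arms) if a == "T"]
            loaded = [i for i, a in enumerate(arms) if a == "TM"]

            # T2 association onto each free site
            if free:
                arms_t = list(arms)
                arms_t[free[0]] = "T"
                R([name, "T2"], [mname(arms_t)], p.k_on_t2, "binding", len(free))
            # bare T2 dissociation (T2 without a docked zymogen)
            if bare_t:
                arms_f = list(arms)
                arms_f[bare_t[0]] = ""
                R([name], [mname(arms_f), "T2"], p.k_off_t2, "dissociation",
                  len(bare_t))
            # pro-MMP-2 docking onto each bound, unloaded T2
            if bare_t:
                arms_m = list(arms)
                arms_m[bare_t[0]] = "TM"
                R([name, "M2"], [mname(arms_m)], p.k_on_m2, "binding", len(bare_t))
            if loaded:
                arms_u = list(arms)
                arms_u[loaded[0]] = "T"
                R([name], [mname(arms_u), "M2"], p.k_off_m2, "dissociation",
                  len(loaded))
                # the whole T2.M2 unit can leave when the T2-M14 bond breaks
                if p.docking_preassembled:
                    arms_f = list(arms)
                    arms_f[loaded[0]] = ""
                    R([name], [mname(arms_f), "T2.M2"], p.k_off_t2,
                      "dissociation", len(loaded))
            if free and p.docking_preassembled:
                arms_m = list(arms)
                arms_m[free[0]] = "TM"
                R([name, "T2.M2"], [mname(arms_m)], p.k_on_t2, "binding",
                  len(free))

        # dimerisation between any two monomeric units of the same pool
        units = ["", "T", "TM"]
        for i, a in enumerate(units):
            for b in units[i:]:
                dimer = mname((a, b))
                R([mname((a,)), mname((b,))], [dimer], p.k_on_dim, "binding")
                R([dimer], [mname((a,)), mname((b,))], p.k_off_dim,
                  "dissociation")

        # zymogen processing by the TIMP-free partner in the quaternary complex
        R([mname(("", "TM"))], [mname(("", "T")), "M2act"], p.k_act,
          "activation")

        if include_ecm:
            p.require("k_on_ecm_mt1", "k_off_ecm_mt1", "k_cat_mt1")
            for arms in _M14A_ARMS:
                enz = mname(arms)
                cplx = enz + ".ECM"
                n_free = sum(1 for a in arms if a == "")
                R([enz, "ECM"], [cplx], p.k_on_ecm_mt1, "ecm_binding", n_free)
                R([cplx], [enz, "ECM"], p.k_off_ecm_mt1, "dissociation")
                R([cplx], [enz], p.k_cat_mt1, "ecm_cleavage")

    if include_ecm:
        p.require("k_on_ecm_m2act", "k_off_ecm_m2act", "k_cat_m2act")
        R(["M2act", "ECM"], ["M2act.ECM"], p.k_on_ecm_m2act, "ecm_binding")
        R(["M2act.ECM"], ["M2act", "ECM"], p.k_off_ecm_m2act, "dissociation")
        R(["M2act.ECM"], ["M2act"], p.k_cat_m2act, "ecm_cleavage")

    net = ReactionNetwork(
        species=species,
        reactions=rxns,
        metadata={
            "pools": pools,
            "include_ecm": include_ecm,
            "include_shedding": include_shedding,
            "deletions": [],
            "shedding_rate": None,
        },
    )
    if include_shedding:
        net = add_ectodomain_shedding(net, p.k_shed, _in_place=True)
    net.validate()
    return net


# numbering follows the inactive-complex ladder of the path-deletion analysis
PATH_DELETION_TARGETS = {
    1: "M14.T2.M2.M14.T2.M2",
    2: "M14.T2.M2",
    3: "M14.T2.M14.T2.M2",
    4: "M14.T2.M14.T2",
    5: "M14.T2",
}


def apply_path_deletions(
    net: ReactionNetwork, deletions: Iterable[int]
) -> ReactionNetwork:
    """Remove inhibited-complex species (and every path to/from them).

    ``deletions`` indexes the five T2-carrying inactive complexes, ordered
    from the highest-order double-loaded dimer (1) down to the inhibited
    monomer (5).  The operation is idempotent and order-independent; the
    input network is left unmodified.
    """
    deletions = sorted(set(int(d) for d in deletions))
    bad = [d for d in deletions if d not in PATH_DELETION_TARGETS]
    if bad:
        raise NetworkConfigError(f"unknown path-deletion indices {bad}")
    out = net.copy()
    if not deletions:
        return out

    pools = net.metadata.get("pools", "single")
    doomed: set[str] = set()
    for d in deletions:
        base = PATH_DELETION_TARGETS[d]
        for suffix, _ in _pool_suffixes(pools):
            name = base.replace("M14", "M14" + suffix) if suffix else base
            doomed.add(name)
            doomed.add(name + ".ECM")  # ECM-engaged variant, if present

    out.species = [s for s in out.species if s.name not in doomed]
    out.reactions = [
        r
        for r in out.reactions
        if not (set(r.reactants) & doomed or set(r.products) & doomed)
    ]
    remaining = set(out.species_names)
    for r in out.reactions:
        for n in (*r.reactants, *r.products):
            if n not in remaining:  # pragma: no cover - internal consistency
                raise NetworkConfigError(
                    f"retained reaction '{r.label}' references deleted species"
                )
    out.metadata = {
        **out.metadata,
        "deletions": sorted(set(out.metadata.get("deletions", [])) | set(deletions)),
    }
    return out


def add_ectodomain_shedding(
    net: ReactionNetwork,
    k_shed: float,
    k_on_t2: float | None = None,
    k_off_t2: float | None = None,
    _in_place: bool = False,
) -> ReactionNetwork:
    """Add irreversible shedding of free membrane MT1-MMP.

    The shed ectodomain ``M14f`` diffuses in solution and binds TIMP-2
    reversibly, acting as a TIMP-2 scavenger.  Shedding removes the enzyme
    from the membrane without recycling.
    """
    if k_shed < 0:
        raise NetworkConfigError("k_shed must be >= 0")
    out = net if _in_place else net.copy()
    if not out.has_species("M14f"):
        out.species.append(
            MolecularSpecies("M14f", {"M14": 1}, Location.SOLUTION, 0.0)
        )
        out.species.append(
            MolecularSpecies("M14f.T2", {"M14": 1, "T2": 1}, Location.SOLUTION, 0.0)
        )
    kon = k_on_t2 if k_on_t2 is not None else KineticParameters().k_on_t2
    koff = k_off_t2 if k_off_t2 is not None else KineticParameters().k_off_t2
    pools = out.metadata.get("pools", "single")
    for suffix, _ in _pool_suffixes(pools):
        free = "M14" + suffix if suffix else "M14"
        out.reactions.append(
            Reaction((free,), ("M14f",), k_shed, "shedding", 1, None)
        )
    # scavenging of TIMP-2 by the shed fragment
    if not any(r.tag == "binding" and r.reactants == ("M14f", "T2")
               for r in out.reactions):
        out.reactions.append(Reaction(("M14f", "T2"), ("M14f.T2",), kon, "binding"))
        out.reactions.append(Reaction(("M14f.T2",), ("M14f", "T2"), koff,
                                      "dissociation"))
    out.metadata = {**out.metadata, "include_shedding": True,
                    "shedding_rate": k_shed}
    out.validate()
    return out


def conservation_totals(
    net: ReactionNetwork, concentrations: Mapping[str, float]
) -> dict[str, float]:
    """Monomer-equivalent totals (M14, T2, M2+M2act, ECM) of a state.

    In a closed network (no turnover, no shedding, no cleavage) the first
    three are conserved along any trajectory; cleavage consumes ECM only.
    """
    tot = {"M14": 0.0, "T2": 0.0, "M2": 0.0, "ECM": 0.0}
    for s in net.species:
        c = float(concentrations.get(s.name, 0.0))
        tot["M14"] += c * s.count("M14")
        tot["T2"] += c * s.count("T2")
        tot["M2"] += c * (s.count("M2") + s.count("M2act"))
        tot["ECM"] += c * s.count("ECM")
    return tot
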