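"""Carousel reaction networks: species, reactions, mass-action kinetics.

Three variants are supported:

``simplified``
    12 species, 19 reactions.  Eight receptor forms (free/ligand-bound x
    uncoupled/coupled to G, Gt or Gd) plus four free G-protein forms
    (heterotrimer G, GaGTP ``Gt``, GaGDP ``Gd``, free ``Gbg``).  GDP/GTP
    exchange together with trimer dissociation is a single irreversible
    step, as is GTP hydrolysis; binding, coupling and Gd+Gbg reassociation
    are reversible.

``extended``
    Receptor forms are duplicated into RGS-free and RGS-bound states with
    eight RGS association reactions; GAP-accelerated hydrolysis applies
    only to RGS-bound receptor-coupled GaGTP.

``two_pool``
    Adds a second receptor pool that cannot bind ligand (dominant-negative
    non-binder allele) but couples G protein normally.

The ligand L is a clamped external parameter, not a state variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import Abundances, ExtendedRGSParameters, KineticParameters, TwoPoolSpec

VARIANTS = ("simplified", "extended", "two_pool")

SIMPLIFIED_SPECIES = (
    "R", "LR", "RG", "LRG", "RGt", "LRGt", "RGd", "LRGd",
    "G", "Gt", "Gd", "Gbg",
)


@dataclass(frozen=True)
class Reaction:
    """One (possibly reversible) mass-action reaction.

    ``ligand_bound`` marks a forward flux additionally multiplied by the
    clamped ligand concentration [L].
    """

    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    kf: float
    kr: float | None = None   # None => irreversible
    ligand_bound: bool = False

    @property
    def reversible(self) -> bool:
        return self.kr is not None


@dataclass
class ReactionNetwork:
    variant: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    #: conservation-law name -> (coefficient vector over species, index of
    #: the species eliminated when reducing the steady-state system)
    conservation: dict[str, tuple[np.ndarray, int]]
    params: KineticParameters
    rgs: ExtendedRGSParameters | None = None
    pool2: TwoPoolSpec | None = None
    #: name -> species-index lists used by the analysis layer
    groups: dict[str, list[int]] = field(default_factory=dict)

    # compiled elementary-reaction arrays (filled by _compile)
    _k: np.ndarray = field(init=False, repr=False)
    _i1: np.ndarray = field(init=False, repr=False)
    _i2: np.ndarray = field(init=False, repr=False)
    _S: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._compile()

    # -- compilation ---------------------------------------------------
    def _compile(self) -> None:
        """Expand reversible reactions into elementary fluxes.

        Reactant slots use index n for the constant 1 and n+1 for [L].
        """
        n = len(self.species)
        sidx = {s: i for i, s in enumerate(self.species)}
        k, i1, i2, cols = [], [], [], []

        def add(rate: float, members: tuple[str, ...], ligand: bool,
                consumed: tuple[str, ...], produced: tuple[str, ...]) -> None:
            if len(members) > 2:
                raise ValueError("mass-action engine supports at most bimolecular steps")
            a = sidx[members[0]] if members else n
            b = sidx[members[1]] if len(members) > 1 else (n + 1 if ligand else n)
            if ligand and len(members) > 1:
                raise ValueError("ligand-multiplied flux must be unimolecular in species")
            k.append(rate)
            i1.append(a)
            i2.append(b)
            col = np.zeros(n)
            for s in consumed:
                col[sidx[s]] -= 1
            for s in produced:
                col[sidx[s]] += 1
            cols.append(col)

        for r in self.reactions:
            add(r.kf, r.reactants, r.ligand_bound, r.reactants, r.products)
            if r.kr is not None:
                add(r.kr, r.products, False, r.products, r.reactants)

        self._k = np.asarray(k)
        self._i1 = np.asarray(i1, dtype=np.intp)
        self._i2 = np.asarray(i2, dtype=np.intp)
        self._S = np.column_stack(cols) if cols else np.zeros((n, 0))

    # -- kinetics ------------------------------------------------------
    def fluxes(self, state: np.ndarray, L: float) -> np.ndarray:
        """Elementary mass-action fluxes (nM/s) at the given state."""
        c = np.empty(len(self.species) + 2)
        c[:-2] = state
        c[-2] = 1.0
        c[-1] = L
        return self._k * c[self._i1] * c[self._i2]

    def rhs(self, state: np.ndarray, L: float, *, validate: bool = False) -> np.ndarray:
        """Time derivatives d[state]/dt in nM/s."""
        state = np.asarray(state, dtype=float)
        if validate:
            if L < 0:
                raise ValueError("ligand concentration must be non-negative")
            if np.any(state < 0):
                raise ValueError("concentrations must be non-negative")
        return self._S @ self.fluxes(state, L)

    def jacobian(self, state: np.ndarray, L: float) -> np.ndarray:
        """d(rhs)/d(state), shape (n_species, n_species)."""
        n = len(self.species)
        c = np.empty(n + 2)
        c[:-2] = state
        c[-2] = 1.0
        c[-1] = L
        m = len(self._k)
        D = np.zeros((m, n))
        rows = np.arange(m)
        mask = self._i1 < n
        np.add.at(D, (rows[mask], self._i1[mask]), self._k[mask] * c[self._i2[mask]])
        mask = self._i2 < n
        np.add.at(D, (rows[mask], self._i2[mask]), self._k[mask] * c[self._i1[mask]])
        return self._S @ D

    # -- structure -----------------------------------------------------
    def conserved_totals(self, state: np.ndarray) -> dict[str, float]:
        state = np.asarray(state, dtype=float)
        return {name: float(vec @ state) for name, (vec, _) in self.conservation.items()}

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def naive_state(self, abundances: Abundances) -> np.ndarray:
        """All receptor free, all G protein as free heterotrimer."""
        x = np.zeros(len(self.species))
        x[self.species_index("R")] = abundances.R_tot
        x[self.species_index("G")] = abundances.G_tot
        if self.variant == "extended":
            x[self.species_index("RGS")] = self.rgs.RGS_tot_nM
        elif self.variant == "two_pool":
            x[self.species_index("R2")] = self.pool2.R_tot2
        return x


def _simplified_reactions(p: KineticParameters, *, prefix: str = "",
                          kH_RGt: float | None = None,
                          kH_LRGt: float | None = None) -> list[Reaction]:
    """The 19 reactions among one set of receptor forms + free G species.

    ``prefix`` renames receptor species (used for RGS-bound twins); the
    hydrolysis overrides support the extended variant's RGS-dependent rates.
    """
    kH_RGt = p.kH_RGt if kH_RGt is None else kH_RGt
    kH_LRGt = p.kH_LRGt if kH_LRGt is None else kH_LRGt
    P = lambda s: prefix + s  # noqa: E731
    rx: list[Reaction] = []
    # 4 reversible ligand-binding reactions
    for x in ("R", "RG", "RGt", "RGd"):
        rx.append(Reaction(f"L+{P(x)}", (P(x),), (P('L' + x),),
                           kf=p.kon_LR, kr=p.koff_LR, ligand_bound=True))
    # 6 reversible receptor-Ga coupling reactions
    for r in ("R", "LR"):
        for g in ("G", "Gt", "Gd"):
            rx.append(Reaction(f"{P(r)}+{g}", (P(r), g), (P(r + g),),
                               kf=p.kon_RG, kr=p.koff_RG))
    # 3 irreversible exchange reactions (GDP->GTP + Gbg release)
    rx.append(Reaction("exch_G", ("G",), ("Gt", "Gbg"), kf=p.kE_G))
    rx.append(Reaction(f"exch_{P('RG')}", (P("RG"),), (P("RGt"), "Gbg"), kf=p.kE_RG))
    rx.append(Reaction(f"exch_{P('LRG')}", (P("LRG"),), (P("LRGt"), "Gbg"), kf=p.kE_LRG))
    # 3 irreversible hydrolysis reactions
    rx.append(Reaction("hyd_Gt", ("Gt",), ("Gd",), kf=p.kH_Gt))
    rx.append(Reaction(f"hyd_{P('RGt')}", (P("RGt"),), (P("RGd"),), kf=kH_RGt))
    rx.append(Reaction(f"hyd_{P('LRGt')}", (P("LRGt"),), (P("LRGd"),), kf=kH_LRGt))
    # 3 reversible Gd+Gbg reassociation reactions
    rx.append(Reaction("reassoc_Gd", ("Gd", "Gbg"), ("G",),
                       kf=p.kA_Gd, kr=p.koff_GdGbg))
    rx.append(Reaction(f"reassoc_{P('RGd')}", (P("RGd"), "Gbg"), (P("RG"),),
                       kf=p.kA_Gd, kr=p.koff_GdGbg))
    rx.append(Reaction(f"reassoc_{P('LRGd')}", (P("LRGd"), "Gbg"), (P("LRG"),),
                       kf=p.kA_Gd, kr=p.koff_GdGbg))
    return rx


def _dedup_shared(rx: list[Reaction]) -> list[Reaction]:
    """Drop duplicate free-G-species reactions when receptor sets are merged."""
    seen: set[str] = set()
    out = []
    for r in rx:
        if r.name in seen:
            continue
        seen.add(r.name)
        out.append(r)
    return out


def build_network(variant: str, params: KineticParameters, *,
                  rgs: ExtendedRGSParameters | None = None,
                  pool2: TwoPoolSpec | None = None) -> ReactionNetwork:
    """Construct the carousel reaction network for one model variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")

    if variant == "simplified":
        species = SIMPLIFIED_SPECIES
        reactions = tuple(_simplified_reactions(params))
        idx = {s: i for i, s in enumerate(species)}
        n = len(species)

        def vec(names):
            v = np.zeros(n)
            for s in names:
                v[idx[s]] = 1.0
            return v

        conservation = {
            "receptor": (vec(["R", "LR", "RG", "LRG", "RGt", "LRGt", "RGd", "LRGd"]),
                         idx["R"]),
            "galpha": (vec(["RG", "LRG", "RGt", "LRGt", "RGd", "LRGd", "G", "Gt", "Gd"]),
                       idx["Gd"]),
            "gbg": (vec(["RG", "LRG", "G", "Gbg"]), idx["Gbg"]),
        }
        groups = {
            "receptor_occupied": [idx[s] for s in ("LR", "LRG", "LRGt", "LRGd")],
            "receptor_all": [idx[s] for s in species[:8]],
            "gbg_free": [idx["Gbg"]],
        }
        return ReactionNetwork(variant, species, reactions, conservation,
                               params, groups=groups)

    if variant == "extended":
        if rgs is None:
            raise ValueError("extended variant requires ExtendedRGSParameters")
        rec = ("R", "LR", "RG", "LRG", "RGt", "LRGt", "RGd", "LRGd")
        rec_s = tuple("s" + s for s in rec)  # RGS-bound twins
        species = rec + rec_s + ("G", "Gt", "Gd", "Gbg", "RGS")
        rx = _simplified_reactions(params, kH_RGt=rgs.kH_noRGS_RGt,
                                   kH_LRGt=rgs.kH_noRGS_RGt)
        rx += _simplified_reactions(params, prefix="s")
        rx = _dedup_shared(rx)
        # 8 RGS association reactions
        for s in rec:
            rx.append(Reaction(f"{s}+RGS", (s, "RGS"), ("s" + s,),
                               kf=rgs.kon_R_RGS, kr=rgs.koff_R_RGS))
        idx = {s: i for i, s in enumerate(species)}
        n = len(species)

        def vec(names):
            v = np.zeros(n)
            for s in names:
                v[idx[s]] = 1.0
            return v

        coupled = [s for s in rec + rec_s if s not in ("R", "LR", "sR", "sLR")]
        conservation = {
            "receptor": (vec(list(rec + rec_s)), idx["R"]),
            "galpha": (vec(coupled + ["G", "Gt", "Gd"]), idx["Gd"]),
            "gbg": (vec(["RG", "LRG", "sRG", "sLRG", "G", "Gbg"]), idx["Gbg"]),
            "rgs": (vec(list(rec_s) + ["RGS"]), idx["RGS"]),
        }
        groups = {
            "receptor_occupied": [idx[s] for s in species
                                  if s.startswith("LR") or s.startswith("sLR")],
            "receptor_all": [idx[s] for s in rec + rec_s],
            "gbg_free": [idx["Gbg"]],
        }
        return ReactionNetwork(variant, species, tuple(rx), conservation,
                               params, rgs=rgs, groups=groups)

    # two_pool
    if pool2 is None:
        raise ValueError("two_pool variant requires a TwoPoolSpec")
    species = SIMPLIFIED_SPECIES + ("R2", "R2G", "R2Gt", "R2Gd")
    rx = _simplified_reactions(params)
    p = params
    # pool-2 receptors: coupling + unoccupied-receptor cycle, no ligand binding
    for g in ("G", "Gt", "Gd"):
        rx.append(Reaction(f"R2+{g}", ("R2", g), ("R2" + g,),
                           kf=p.kon_RG, kr=p.koff_RG))
    rx.append(Reaction("exch_R2G", ("R2G",), ("R2Gt", "Gbg"), kf=p.kE_RG))
    rx.append(Reaction("hyd_R2Gt", ("R2Gt",), ("R2Gd",), kf=p.kH_RGt))
    rx.append(Reaction("reassoc_R2Gd", ("R2Gd", "Gbg"), ("R2G",),
                       kf=p.kA_Gd, kr=p.koff_GdGbg))
    idx = {s: i for i, s in enumerate(species)}
    n = len(species)

    def vec(names):
        v = np.zeros(n)
        for s in names:
            v[idx[s]] = 1.0
        return v

    conservation = {
        "receptor": (vec(["R", "LR", "RG", "LRG", "RGt", "LRGt", "RGd", "LRGd"]),
                     idx["R"]),
        "receptor2": (vec(["R2", "R2G", "R2Gt", "R2Gd"]), idx["R2"]),
        "galpha": (vec(["RG", "LRG", "RGt", "LRGt", "RGd", "LRGd",
                        "R2G", "R2Gt", "R2Gd", "G", "Gt", "Gd"]), idx["Gd"]),
        "gbg": (vec(["RG", "LRG", "R2G", "G", "Gbg"]), idx["Gbg"]),
    }
    groups = {
        "receptor_occupied": [idx[s] for s in ("LR", "LRG", "LRGt", "LRGd")],
        "receptor_all": [idx[s] for s in SIMPLIFIED_SPECIES[:8]],
        "gbg_free": [idx["Gbg"]],
    }
    return ReactionNetwork("two_pool", species, tuple(rx), conservation,
                           params, pool2=pool2, groups=groups)


def occupancy(network: ReactionNetwork, state: np.ndarray, R_tot: float) -> float:
    """Fractional receptor occupancy (ligand-bound receptors / total)."""
    if R_tot <= 0:
        return 0.0
    return float(np.sum(np.asarray(state)[network.groups["receptor_occupied"]]) / R_tot)
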