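"""Species/reaction network generation for ring-enzyme assembly pathways.

Hexamers form from monomers through one of three pathways (named by the
oligomer sizes visited):

* ``1236`` — monomer -> dimer -> trimer -> (trimer+trimer) ring closure,
* ``1246`` — monomer -> dimer -> tetramer -> (tetramer+dimer) ring closure,
* ``123456`` — strictly sequential monomer addition with a
  pentamer+monomer ring closure.

Every assembly step is reversible; ring closure is followed (irreversibly)
by catalysis, modelled as hexamer -> 6 monomers plus ADP release from each
wild-type subunit.  Reactions are enumerated exhaustively over all mixed
wild-type/mutant arrangements, with both attachment orientations ('left'
and 'right') counted as separate channels, and rates are shared between
reactions that create (or break) the same subunit interface: the rate of
``WW + MM -> WWMM`` equals that of ``MW + MM -> MWMM`` because the newly
formed contact is W-M in both.

The mass-action ODE right-hand side of the same network serves as the
deterministic mean-field oracle for the stochastic simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .inhibition import InhibitionScheme, classify_subunits
from .rings import (
    canonical_rotation,
    enumerate_linear_arrangements,
    enumerate_ring_configurations,
)

INTERFACE_KEYS = ("WW", "WM", "MW", "MM")
KIND_BY_SIZE = {1: "monomer", 2: "dimer", 3: "trimer", 4: "tetramer", 5: "pentamer", 6: "hexamer"}
PATHWAYS = ("1236", "1246", "123456")

__all__ = [
    "INTERFACE_KEYS",
    "PATHWAYS",
    "Species",
    "Reaction",
    "RateTable",
    "ReactionNetwork",
    "build_network",
    "rate_key",
    "catalytic_reaction",
    "ode_rhs",
]


@dataclass(frozen=True, order=True)
class Species:
    """A molecular species: an oligomer arrangement, or the ADP pool."""

    kind: str
    arrangement: str = ""

    @property
    def size(self) -> int:
        """Number of subunits (0 for ADP)."""
        return len(self.arrangement)

    @property
    def label(self) -> str:
        return self.arrangement or self.kind

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


ADP = Species("ADP")


def _species(arrangement: str) -> Species:
    return Species(KIND_BY_SIZE[len(arrangement)], arrangement)


_RATE_FIELDS = (
    "k12", "k23", "k24", "k34", "k45", "k36", "k46", "k56",
)


@dataclass(frozen=True)
class RateTable:
    """Interface-keyed rate constants, in per-particle units.

    Each assembly rate (``k12`` dimerization, ``k23`` trimerization, ``k24``
    dimer+dimer tetramerization, ``k36``/``k46``/``k56`` ring closures,
    ``k34``/``k45`` sequential additions) has a forward (``*_f``, bimolecular,
    1/(particle*s)) and reverse (``*_r``, unimolecular, 1/s) constant, given
    either as a single float shared by all four subunit interfaces or as a
    mapping ``{'WW': .., 'WM': .., 'MW': .., 'MM': ..}``.

    ``koff_mut_multiplier`` scales every reverse rate whose broken interface
    involves a mutant (the koffXM/koffMX scenarios); 0 means a mutant, once
    incorporated, can only leave an oligomer through full assembly and the
    catalytic step.
    """

    k12_f: float | Mapping[str, float] = 0.009
    k12_r: float | Mapping[str, float] = 3.5
    k23_f: float | Mapping[str, float] = 0.012
    k23_r: float | Mapping[str, float] = 3.0
    k24_f: float | Mapping[str, float] = 0.012
    k24_r: float | Mapping[str, float] = 3.0
    k34_f: float | Mapping[str, float] = 0.012
    k34_r: float | Mapping[str, float] = 3.0
    k45_f: float | Mapping[str, float] = 0.012
    k45_r: float | Mapping[str, float] = 3.0
    k36_f: float | Mapping[str, float] = 1.5
    k36_r: float | Mapping[str, float] = 0.05
    k46_f: float | Mapping[str, float] = 1.5
    k46_r: float | Mapping[str, float] = 0.05
    k56_f: float | Mapping[str, float] = 1.5
    k56_r: float | Mapping[str, float] = 0.05
    kcat_WW: float = 5.0
    kcat_WM: float = 0.05
    koff_mut_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in self.rate_names() + ["kcat_WW", "kcat_WM", "koff_mut_multiplier"]:
            value = getattr(self, name)
            values = value.values() if isinstance(value, Mapping) else [value]
            if any(v < 0 for v in values):
                raise ValueError(f"rate {name} must be non-negative")

    @staticmethod
    def rate_names() -> list[str]:
        return [f"{base}_{d}" for base in _RATE_FIELDS for d in ("f", "r")]

    @staticmethod
    def _select_key(keys: tuple[str, ...]) -> str:
        # Ring closures form two interfaces; the wild-type rate applies only
        # when both are W-W, otherwise the first mutant-containing interface
        # selects the (single) mutant override class.
        for key in keys:
            if "M" in key:
                return key
        return keys[0]

    def _lookup(self, name: str, keys: tuple[str, ...]) -> float:
        value = getattr(self, name)
        if isinstance(value, Mapping):
            return float(value[self._select_key(keys)])
        return float(value)

    def forward_rate(self, base: str, keys: tuple[str, ...]) -> float:
        return self._lookup(f"{base}_f", keys)

    def reverse_rate(self, base: str, keys: tuple[str, ...]) -> float:
        rate = self._lookup(f"{base}_r", keys)
        if any("M" in key for key in keys):
            rate *= self.koff_mut_multiplier
        return rate

    def scaled(self, multipliers: Mapping[str, float]) -> "RateTable":
        """A new table with named rates multiplied by the given factors.

        Keys are full field names (``'k12_f'``, ``'kcat_WW'``, ...).
        """
        changes = {}
        for name, factor in multipliers.items():
            value = getattr(self, name)
            if isinstance(value, Mapping):
                changes[name] = {k: v * factor for k, v in value.items()}
            else:
                changes[name] = value * factor
        return replace(self, **changes)


@dataclass(frozen=True)
class Reaction:
    """One reaction channel with its resolved rate constant.

    ``keys`` lists the subunit interface(s) newly formed by a forward
    assembly step or broken by the reverse step (one for a linear join, two
    for a ring closure); catalysis carries no interface key.
    """

    reactants: tuple[Species, ...]
    products: tuple[Species, ...]
    rate_name: str
    keys: tuple[str, ...]
    propensity_kind: str
    rate_constant: float
    adp_yield: int = 0
    tag: str = "assembly"

    def __post_init__(self) -> None:
        n_in = sum(s.size for s in self.reactants)
        n_out = sum(s.size for s in self.products)
        if n_in != n_out:
            raise ValueError(f"subunit count not conserved: {self}")


def rate_key(reaction: Reaction) -> tuple[str, ...]:
    """Interface key(s) formed (forward) or broken (reverse) by *reaction*."""
    if reaction.tag == "catalysis":
        raise ValueError("catalytic reactions carry no interface key")
    return reaction.keys


def catalytic_reaction(
    config, scheme: InhibitionScheme, rates: RateTable
) -> Reaction:
    """The irreversible catalytic channel of one hexamer configuration.

    The hexamer decays to its 6 monomers with per-hexamer rate constant
    ``(n_fast*kcat_WW + n_basal*kcat_WM)/n_W`` and releases ``n_W`` ADP,
    so its expected ADP production rate equals its census-weighted turnover
    contribution, and a pure wild-type ring fires at kcat_WW per hexamer.
    """
    pattern = classify_subunits(config, scheme)
    seq = config.canonical_sequence
    n_w = pattern.n_wildtype
    per_hexamer = (
        (pattern.n_fast * rates.kcat_WW + pattern.n_basal * rates.kcat_WM) / n_w
        if n_w > 0
        else 0.0
    )
    monomers = tuple(_species(c) for c in sorted(seq, reverse=True))  # W's first
    return Reaction(
        reactants=(_species(seq),),
        products=monomers + ((ADP,) if n_w else ()),
        rate_name="kcat",
        keys=(),
        propensity_kind="unimolecular",
        rate_constant=per_hexamer,
        adp_yield=n_w,
        tag="catalysis",
    )


def _join(
    left: str, right: str, base: str, rates: RateTable, close_ring: bool
) -> tuple[Reaction, Reaction]:
    """Forward and reverse channel for joining two linear arrangements.

    A linear join forms the single interface (left[-1], right[0]); a ring
    closure additionally forms (right[-1], left[0]) and maps the product
    through its canonical rotation.
    """
    keys: tuple[str, ...] = (left[-1] + right[0],)
    if close_ring:
        keys = keys + (right[-1] + left[0],)
        product = _species(canonical_rotation(left + right))
    else:
        product = _species(left + right)
    reactants = (_species(left), _species(right))
    kind = "bimolecular_identical" if left == right else "bimolecular_distinct"
    fwd = Reaction(reactants, (product,), f"{base}_f", keys, kind,
                   rates.forward_rate(base, keys))
    rev = Reaction((product,), reactants, f"{base}_r", keys, "unimolecular",
                   rates.reverse_rate(base, keys), tag="disassembly")
    return fwd, rev


class ReactionNetwork:
    """The generated species and reaction channels of one pathway."""

    def __init__(
        self,
        pathway: str,
        rates: RateTable,
        scheme: InhibitionScheme,
        species: list[Species],
        reactions: list[Reaction],
    ):
        self.pathway = pathway
        self.rates = rates
        self.scheme = scheme
        self.species = list(species)
        self.reactions = list(reactions)
        self.index = {s: i for i, s in enumerate(self.species)}
        self.subunit_size = np.array([s.size for s in self.species])
        self.wildtype_per_species = np.array(
            [s.arrangement.count("W") for s in self.species]
        )
        self._arrays: tuple | None = None

    # --- structural views --------------------------------------------------
    def species_of_kind(self, kind: str) -> list[Species]:
        return [s for s in self.species if s.kind == kind]

    def reactions_with(self, rate_name: str) -> list[Reaction]:
        return [r for r in self.reactions if r.rate_name == rate_name]

    @property
    def stoichiometry(self) -> np.ndarray:
        """Dense (n_species x n_reactions) stoichiometric matrix."""
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for s in rxn.reactants:
                S[self.index[s], j] -= 1
            for s in rxn.products:
                if s is not ADP and s.kind != "ADP":
                    S[self.index[s], j] += 1
            if rxn.adp_yield:
                S[self.index[ADP], j] += rxn.adp_yield
        return S

    def _rate_arrays(self):
        if self._arrays is None:
            R = len(self.reactions)
            r0 = np.empty(R, dtype=np.int64)
            r1 = np.full(R, -1, dtype=np.int64)
            kind = np.empty(R, dtype=np.int64)  # 0 uni, 1 distinct, 2 identical
            k = np.empty(R)
            codes = {"unimolecular": 0, "bimolecular_distinct": 1, "bimolecular_identical": 2}
            for j, rxn in enumerate(self.reactions):
                r0[j] = self.index[rxn.reactants[0]]
                if len(rxn.reactants) == 2:
                    r1[j] = self.index[rxn.reactants[1]]
                kind[j] = codes[rxn.propensity_kind]
                k[j] = rxn.rate_constant
            self._arrays = (r0, r1, kind, k, self.stoichiometry)
        return self._arrays

    def ode_event_rates(self, state: np.ndarray) -> np.ndarray:
        """Mass-action event rates: k*xA*xB, (k/2)*xA^2 or k*x per channel."""
        r0, r1, kind, k, _ = self._rate_arrays()
        x0 = state[r0]
        x1 = np.where(r1 >= 0, state[np.maximum(r1, 0)], 1.0)
        v = np.where(kind == 0, k * x0,
                     np.where(kind == 1, k * x0 * x1, 0.5 * k * x0 * x0))
        return v

    def ode_rhs(self, state: np.ndarray) -> np.ndarray:
        """Time derivative of all species counts (ADP included)."""
        _, _, _, _, S = self._rate_arrays()
        return S @ self.ode_event_rates(np.asarray(state, dtype=float))

    def initial_state(self, n_Wt: int, n_Mut: int) -> np.ndarray:
        """All-monomer initial condition."""
        state = np.zeros(len(self.species))
        state[self.index[Species("monomer", "W")]] = n_Wt
        state[self.index[Species("monomer", "M")]] = n_Mut
        return state

    def to_json(self) -> dict:
        """Machine-readable network dump (species, reactions, rate refs)."""
        return {
            "pathway": self.pathway,
            "scheme": self.scheme.name,
            "species": [{"kind": s.kind, "arrangement": s.arrangement} for s in self.species],
            "reactions": [
                {
                    "reactants": [s.label for s in r.reactants],
                    "products": [s.label for s in r.products],
                    "rate_name": r.rate_name,
                    "keys": list(r.keys),
                    "propensity_kind": r.propensity_kind,
                    "rate_constant": r.rate_constant,
                    "adp_yield": r.adp_yield,
                    "tag": r.tag,
                }
                for r in self.reactions
            ],
        }


def _pathway_steps(pathway: str) -> list[tuple[int, int, str, bool]]:
    """(left size, right size, rate base, closes ring) per assembly step."""
    if pathway == "1236":
        return [(1, 1, "k12", False), (2, 1, "k23", False), (3, 3, "k36", True)]
    if pathway == "1246":
        return [(1, 1, "k12", False), (2, 2, "k24", False), (4, 2, "k46", True)]
    if pathway == "123456":
        return [(1, 1, "k12", False), (2, 1, "k23", False), (3, 1, "k34", False),
                (4, 1, "k45", False), (5, 1, "k56", True)]
    raise ValueError(f"unknown pathway {pathway!r}; choose one of {PATHWAYS}")


def build_network(
    pathway: str, rates: RateTable, scheme: InhibitionScheme
) -> ReactionNetwork:
    """Enumerate all species and reaction channels of one assembly pathway.

    Bimolecular joins are enumerated over ordered reactant pairs; when the
    two partners differ in size, both attachment orientations (small
    partner on the left or on the right) are separate channels, matching
    the published channel counts (e.g. 16 forward trimerizations and 64
    forward ring closures on the 1-2-3-6 pathway, 128 on 1-2-4-6).  Every
    forward channel has a reverse channel keyed by the broken interface(s),
    and every hexamer configuration carries its catalytic channel.
    """
    steps = _pathway_steps(pathway)
    sizes = sorted({n for a, b, _, _ in steps for n in (a, b)} | {a + b for a, b, _, close in steps if not close})
    species: list[Species] = []
    for n in sorted(set(sizes)):
        species.extend(_species(a) for a in enumerate_linear_arrangements(n))
    hexamers = [
        _species(cfg.canonical_sequence) for cfg in enumerate_ring_configurations(6)
    ]
    species.extend(hexamers)
    species.append(ADP)

    reactions: list[Reaction] = []
    for left_size, right_size, base, close in steps:
        lefts = enumerate_linear_arrangements(left_size)
        rights = enumerate_linear_arrangements(right_size)
        for left in lefts:
            for right in rights:
                fwd, rev = _join(left, right, base, rates, close)
                reactions.append(fwd)
                reactions.append(rev)
                if left_size != right_size:
                    # opposite attachment orientation: small partner first
                    fwd2, rev2 = _join(right, left, base, rates, close)
                    reactions.append(fwd2)
                    reactions.append(rev2)
    for cfg in enumerate_ring_configurations(6):
        reactions.append(catalytic_reaction(cfg, scheme, rates))
    return ReactionNetwork(pathway, rates, scheme, species, reactions)


def ode_rhs(state: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Mass-action derivatives of *state* under *network* (module-level form)."""
    return network.ode_rhs(state)
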