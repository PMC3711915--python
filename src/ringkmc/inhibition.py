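"""Allosteric inhibition schemes for mixed wild-type/mutant rings.

A catalytically dead mutant subunit can force wild-type subunits in the same
ring from their fast turnover rate (k_cat,WW) down to a basal rate
(k_cat,WM).  Which wild-type subunits are affected depends on the allosteric
coupling model:

* ``scheme1_full_ring`` — concerted (MWC-like): one mutant anywhere forces
  every wild-type subunit in the ring to the basal rate.
* ``scheme2_both_neighbors`` — local coupling: a mutant inhibits both of its
  direct ring neighbours (offsets +1 and -1).
* ``scheme3_oriented_neighbor`` — directional coupling: a mutant inhibits
  one oriented neighbour only (offset +1).
* ``none`` — mutants have no allosteric influence.
* ``threshold`` — all wild-type subunits drop to basal once the ring
  contains at least ``threshold_t`` mutants.

Offsets are oriented ring positions relative to the mutant, modulo the ring
size; "+1" is the successor in a fixed ring direction.  The published
per-configuration activity table is invariant to which direction is chosen.
A ``per_mutant_type_offsets`` map generalizes the schemes to several mutant
species with distinct interaction ranges (e.g. an inhibitory mutant acting
on the second-next neighbour while another mutant allele is neutral).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .rings import RingConfiguration, enumerate_ring_configurations, validate_sequence

ALL_OFFSETS = "all"

__all__ = [
    "InhibitionScheme",
    "ActivityPattern",
    "classify_subunits",
    "activity_table",
    "hexamer_turnover",
    "kobs_mixed",
]


@dataclass(frozen=True)
class InhibitionScheme:
    """A rule mapping each mutant subunit to the ring offsets it inhibits."""

    name: str
    offsets: frozenset[int] | str = frozenset()
    threshold_t: int | None = None
    per_mutant_type_offsets: Mapping[str, frozenset[int] | str] | None = None

    def __post_init__(self) -> None:
        if isinstance(self.offsets, str) and self.offsets != ALL_OFFSETS:
            raise ValueError(f"offsets must be a set of ints or 'all': {self.offsets!r}")
        if not isinstance(self.offsets, (str, frozenset)):
            object.__setattr__(self, "offsets", frozenset(self.offsets))

    # --- the named schemes -------------------------------------------------
    @classmethod
    def scheme1(cls) -> "InhibitionScheme":
        return cls("scheme1_full_ring", ALL_OFFSETS)

    @classmethod
    def scheme2(cls) -> "InhibitionScheme":
        return cls("scheme2_both_neighbors", frozenset({+1, -1}))

    @classmethod
    def scheme3(cls) -> "InhibitionScheme":
        return cls("scheme3_oriented_neighbor", frozenset({+1}))

    @classmethod
    def none(cls) -> "InhibitionScheme":
        return cls("none", frozenset())

    @classmethod
    def threshold(cls, t: int) -> "InhibitionScheme":
        if t < 1:
            raise ValueError("threshold_t must be >= 1")
        return cls("threshold", frozenset(), threshold_t=t)

    @classmethod
    def from_name(cls, name: str) -> "InhibitionScheme":
        aliases = {
            "scheme1": cls.scheme1, "scheme1_full_ring": cls.scheme1, "1": cls.scheme1,
            "scheme2": cls.scheme2, "scheme2_both_neighbors": cls.scheme2, "2": cls.scheme2,
            "scheme3": cls.scheme3, "scheme3_oriented_neighbor": cls.scheme3, "3": cls.scheme3,
            "none": cls.none,
        }
        if name.startswith("threshold"):
            t = int(name.split(":", 1)[1]) if ":" in name else 2
            return cls.threshold(t)
        try:
            return aliases[name]()
        except KeyError:
            raise ValueError(f"unknown inhibition scheme: {name!r}") from None

    def offsets_for(self, label: str) -> frozenset[int] | str:
        """Offsets inhibited by a mutant of type *label*."""
        if self.per_mutant_type_offsets is not None:
            return self.per_mutant_type_offsets.get(label, frozenset())
        return self.offsets


@dataclass(frozen=True)
class ActivityPattern:
    """Per-configuration split of wild-type subunits into rate classes.

    ``n_fast`` wild-type subunits run at k_cat,WW, ``n_basal`` at k_cat,WM;
    their sum is the number of wild-type subunits in the ring.
    """

    config_id: int
    n_fast: int
    n_basal: int

    @property
    def n_wildtype(self) -> int:
        return self.n_fast + self.n_basal


def inhibited_positions(sequence: str, scheme: InhibitionScheme) -> set[int]:
    """Ring positions covered by some mutant's offset set.

    *sequence* may contain arbitrary non-``W`` labels when the scheme
    carries a ``per_mutant_type_offsets`` map; otherwise every non-``W``
    letter is treated as the single mutant kind ``M``.
    """
    n = len(sequence)
    hit: set[int] = set()
    for j, label in enumerate(sequence):
        if label == "W":
            continue
        offs = scheme.offsets_for(label)
        if offs == ALL_OFFSETS:
            hit.update((j + o) % n for o in range(1, n))
        else:
            hit.update((j + o) % n for o in offs)
    return hit


def classify_subunits(
    config: RingConfiguration | str, scheme: InhibitionScheme
) -> ActivityPattern:
    """Split a ring's wild-type subunits into fast and basal classes."""
    if isinstance(config, RingConfiguration):
        seq = config.canonical_sequence
        config_id = config.config_id
    else:
        # generalized interaction maps may carry extra mutant labels
        seq = config if scheme.per_mutant_type_offsets else validate_sequence(config)
        config_id = 0
        if not seq:
            raise ValueError("empty sequence")
    n_w = sum(1 for c in seq if c == "W")
    n_mut = len(seq) - n_w
    if scheme.name == "threshold":
        basal_all = n_mut >= (scheme.threshold_t or 1)
        return ActivityPattern(config_id, 0 if basal_all else n_w, n_w if basal_all else 0)
    hit = inhibited_positions(seq, scheme)
    n_basal = sum(1 for i, c in enumerate(seq) if c == "W" and i in hit)
    return ActivityPattern(config_id, n_w - n_basal, n_basal)


def activity_table(
    scheme: InhibitionScheme, ring_size: int = 6
) -> tuple[ActivityPattern, ...]:
    """Activity pattern for every ring configuration, in config_id order."""
    return tuple(
        classify_subunits(cfg, scheme)
        for cfg in enumerate_ring_configurations(ring_size)
    )


def hexamer_turnover(
    config: RingConfiguration | str,
    scheme: InhibitionScheme,
    kcat_WW: float,
    kcat_WM: float,
) -> float:
    """Expected ADP production rate of one ring (per hexamer, 1/time).

    ``n_fast * kcat_WW + n_basal * kcat_WM`` — the ring's contribution to
    the numerator of the census-weighted apparent turnover.
    """
    if kcat_WW < 0 or kcat_WM < 0:
        raise ValueError("catalytic constants must be non-negative")
    pat = classify_subunits(config, scheme)
    return pat.n_fast * kcat_WW + pat.n_basal * kcat_WM


def kobs_mixed(
    hexamer_census: Mapping[int, float],
    scheme: InhibitionScheme,
    kcat_WW: float,
    kcat_WM: float,
    n_Wt_total: float,
    ring_size: int = 6,
) -> float:
    """Apparent turnover per wild-type subunit from a hexamer census.

    *hexamer_census* maps config_id to the (possibly time-averaged) number
    of rings in that configuration; the result is the census-weighted ring
    turnover divided by the total number of wild-type subunits present in
    the simulation (hexameric or not).
    """
    if n_Wt_total <= 0:
        raise ValueError("n_Wt_total must be positive")
    configs = enumerate_ring_configurations(ring_size)
    total = 0.0
    for config_id, count in hexamer_census.items():
        cfg = configs[config_id - 1]
        total += count * hexamer_turnover(cfg, scheme, kcat_WW, kcat_WM)
    return total / n_Wt_total
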