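"""Combinatorics of wild-type/mutant subunit arrangements.

A AAA-ATPase protomer is either catalytically intact wild type (``W``) or an
ATPase-dead mutant (``M``).  Linear oligomers (assembly intermediates up to
the tetramer, plus pentamers on the strictly sequential pathway) are ordered
left-to-right and carry no symmetry: ``WM`` and ``MW`` are distinct species.
Closed hexameric rings are identified up to rotation only — the ring has a
distinct upper and lower face, so mirror images are *not* identified.

Sequences are plain strings over the alphabet ``{'W', 'M'}``.  The canonical
representative of a ring is its lexicographically minimal rotation, under
which the mutant letter sorts first (``'M' < 'W'`` in ASCII); the 14 hexamer
equivalence classes are numbered 1-14 by ascending mutant count and, within
a mutant count, by ascending canonical sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from math import gcd

SUBUNIT_KINDS = ("W", "M")

__all__ = [
    "SUBUNIT_KINDS",
    "RingConfiguration",
    "canonical_rotation",
    "enumerate_ring_configurations",
    "configurations_with_k_mutants",
    "enumerate_linear_arrangements",
    "validate_sequence",
]


def validate_sequence(sequence: str) -> str:
    """Check that *sequence* is a non-empty W/M string and return it."""
    if not sequence or any(c not in SUBUNIT_KINDS for c in sequence):
        raise ValueError(f"not a W/M subunit sequence: {sequence!r}")
    return sequence


@dataclass(frozen=True, order=True)
class RingConfiguration:
    """A rotation-equivalence class of ring arrangements.

    Attributes
    ----------
    canonical_sequence:
        Lexicographically minimal rotation ('M' sorts before 'W').
    mutant_count:
        Number of M subunits in the ring.
    multiplicity:
        Number of distinct rotations of the necklace; divides the ring size.
    config_id:
        1-based index in the fixed enumeration order (1 = all wild type,
        14 = all mutant for hexamers).
    """

    mutant_count: int
    canonical_sequence: str
    multiplicity: int
    config_id: int

    @property
    def ring_size(self) -> int:
        return len(self.canonical_sequence)

    @property
    def wildtype_count(self) -> int:
        return self.ring_size - self.mutant_count


def canonical_rotation(sequence: str, ring_size: int | None = None) -> str:
    """Return the lexicographically minimal cyclic rotation of *sequence*.

    ``'M'`` sorts before ``'W'``, so e.g. ``WWWWWM`` canonicalizes to
    ``MWWWWW``.  Idempotent.  If *ring_size* is given, a sequence of any
    other length raises ``ValueError``.
    """
    validate_sequence(sequence)
    if ring_size is not None and len(sequence) != ring_size:
        raise ValueError(
            f"expected ring of size {ring_size}, got length {len(sequence)}"
        )
    doubled = sequence + sequence
    n = len(sequence)
    return min(doubled[i : i + n] for i in range(n))


def _rotation_multiplicity(sequence: str) -> int:
    """Number of distinct rotations (ring size divided by the period)."""
    n = len(sequence)
    doubled = sequence + sequence
    return len({doubled[i : i + n] for i in range(n)})


@lru_cache(maxsize=None)
def enumerate_ring_configurations(ring_size: int = 6) -> tuple[RingConfiguration, ...]:
    """Enumerate all rotation-equivalence classes of W/M rings.

    One :class:`RingConfiguration` per binary necklace; the union of all
    rotations of the canonical representatives covers all ``2**ring_size``
    raw sequences, so multiplicities sum to ``2**ring_size``.
    """
    if ring_size < 1:
        raise ValueError("ring_size must be >= 1")
    canonical = {
        canonical_rotation("".join(seq))
        for seq in product(SUBUNIT_KINDS, repeat=ring_size)
    }
    ordered = sorted(canonical, key=lambda s: (s.count("M"), s))
    return tuple(
        RingConfiguration(
            mutant_count=s.count("M"),
            canonical_sequence=s,
            multiplicity=_rotation_multiplicity(s),
            config_id=i + 1,
        )
        for i, s in enumerate(ordered)
    )


def configuration_by_id(config_id: int, ring_size: int = 6) -> RingConfiguration:
    """Look up a ring configuration by its published 1-based index."""
    configs = enumerate_ring_configurations(ring_size)
    if not 1 <= config_id <= len(configs):
        raise ValueError(f"config_id {config_id} out of range 1..{len(configs)}")
    return configs[config_id - 1]


def ring_configuration_of(sequence: str, ring_size: int = 6) -> RingConfiguration:
    """Map a raw ring sequence to its rotation-equivalence class."""
    canon = canonical_rotation(sequence, ring_size)
    for cfg in enumerate_ring_configurations(ring_size):
        if cfg.canonical_sequence == canon:
            return cfg
    raise AssertionError("unreachable: every sequence has a class")


def configurations_with_k_mutants(k: int, ring_size: int = 6) -> int:
    """Count distinct necklaces with exactly *k* mutant subunits."""
    if not 0 <= k <= ring_size:
        raise ValueError(f"k={k} out of range 0..{ring_size}")
    return sum(
        1 for c in enumerate_ring_configurations(ring_size) if c.mutant_count == k
    )


def necklace_count(ring_size: int) -> int:
    """Burnside count of binary necklaces: (1/n) * sum over d|n of phi(d) 2^(n/d)."""
    n = ring_size
    total = 0
    for d in range(1, n + 1):
        if n % d == 0:
            phi = sum(1 for x in range(1, d + 1) if gcd(x, d) == 1)
            total += phi * 2 ** (n // d)
    return total // n


def enumerate_linear_arrangements(n: int) -> tuple[str, ...]:
    """All 2**n ordered linear W/M oligomers of length *n* (no symmetry).

    The left and right ends of a linear intermediate are distinct, so all
    ``2**n`` sequences are separate species (4 dimers, 8 trimers, 16
    tetramers, ...).
    """
    if not 1 <= n <= 5:
        raise ValueError(f"linear oligomer length must be 1..5, got {n}")
    return tuple("".join(seq) for seq in product(SUBUNIT_KINDS, repeat=n))
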