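"""Rotation-equivalence classes of subunit states on a cyclic ring.

A homotetrameric channel imaged by cryo-EM has no marked subunit: after C4
symmetry expansion and per-subunit classification, two per-tetramer state
vectors that differ only by a rotation of the ring describe the same
particle.  This module enumerates and canonicalizes those rotation classes
("necklaces" under the cyclic group Cn — reflections are excluded because
particles have fixed handedness).

For the two-state alphabet {A (activated), R (resting)} on a C4 ring there
are exactly six classes::

    4R0A, 3R1A, 2R2A_ortho, 2R2A_para, 1R3A, 0R4A

with orbit sizes 1, 4, 4, 2, 4, 1 summing to 2**4 = 16.  "ortho" denotes
the two activated subunits adjacent on the ring (related by a 90 degree
rotation), "para" the diagonal placement (180 degrees); this adjacency
convention is the package's own and every statistic that depends on it
(e.g. the ortho:para ratio that identifies nearest-neighbour coupling)
inherits it.

Labels are compared by their position in the declared alphabet; the
canonical representative of a class is its lexicographically minimal
rotation under that order, which makes tie-breaking deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidLabelError, RingSizeError

#: Canonical single-letter state codes.
RESTING = "R"
ACTIVATED = "A"
DISORDERED = "D"

#: Default two-state alphabet, in comparison order (A sorts before R).
TWO_STATE: tuple[str, ...] = (ACTIVATED, RESTING)
#: Extended alphabet including the disordered/broken label.
THREE_STATE: tuple[str, ...] = (ACTIVATED, DISORDERED, RESTING)

#: Guard against exhaustive enumeration of astronomically large state spaces.
MAX_ARRANGEMENTS = 10**6


def _validate(states: Sequence[str], alphabet: Sequence[str]) -> tuple[str, ...]:
    states = tuple(states)
    bad = [s for s in states if s not in alphabet]
    if bad:
        raise InvalidLabelError(
            f"state label(s) {sorted(set(bad))!r} not in alphabet {tuple(alphabet)!r}"
        )
    return states


def rotations(states: Sequence[str]) -> list[tuple[str, ...]]:
    """All n rotations of an arrangement (with repeats for symmetric ones)."""
    s = tuple(states)
    n = len(s)
    return [s[i:] + s[:i] for i in range(n)]


def orbit(states: Sequence[str]) -> set[tuple[str, ...]]:
    """The set of distinct rotations of an arrangement."""
    return set(rotations(states))


def canonicalize(
    states: Sequence[str], alphabet: Sequence[str] = TWO_STATE
) -> tuple[str, ...]:
    """Lexicographically minimal rotation under the alphabet order.

    Idempotent and invariant under any rotation of the input: two
    arrangements describe the same physical particle iff their canonical
    forms are equal.

    Parameters
    ----------
    states
        Per-subunit labels in ring order (position i adjacent to
        (i +/- 1) mod n).
    alphabet
        Ordered label set; labels compare by their index herein.
    """
    states = _validate(states, alphabet)
    rank = {label: i for i, label in enumerate(alphabet)}
    return min(rotations(states), key=lambda rot: tuple(rank[s] for s in rot))


@dataclass(frozen=True)
class CompositionClass:
    """One rotation-equivalence class of ring arrangements.

    Attributes
    ----------
    canonical
        Lexicographically minimal rotation, the class representative.
    orbit_size
        Number of distinct rotations (divides the ring size).
    active_count
        Number of subunits carrying the active label in any member.
    name
        Display name, e.g. ``"2R2A_ortho"``.
    """

    canonical: tuple[str, ...]
    orbit_size: int
    active_count: int
    name: str

    @property
    def n(self) -> int:
        return len(self.canonical)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def class_name(
    canonical: Sequence[str],
    active_label: str = ACTIVATED,
    resting_label: str = RESTING,
) -> str:
    """Display name for a composition class.

    Two-state rings are named ``xRyA`` (x resting, y activated subunits);
    on a C4 ring the two-activated case is disambiguated into
    ``2R2A_ortho`` (activated subunits adjacent) and ``2R2A_para``
    (diagonal).  Arrangements containing any other label fall back to the
    canonical label string, which is unambiguous for every alphabet.
    """
    canonical = tuple(canonical)
    n = len(canonical)
    labels = set(canonical)
    if not labels <= {active_label, resting_label}:
        return "".join(canonical)
    a = sum(1 for s in canonical if s == active_label)
    base = f"{n - a}R{a}A"
    if n == 4 and a == 2:
        i, j = (k for k in range(4) if canonical[k] == active_label)
        adjacent = (j - i) % 4 in (1, 3)
        return f"{base}_ortho" if adjacent else f"{base}_para"
    return base


def enumerate_classes(
    n: int,
    alphabet: Sequence[str] = TWO_STATE,
    active_label: str = ACTIVATED,
) -> list[CompositionClass]:
    """Exhaustively enumerate all rotation classes on a Cn ring.

    Returns the classes sorted by ``(active_count, canonical)``; orbit
    sizes always sum to ``k**n`` and the number of classes equals the
    Burnside necklace count ``(1/n) * sum_{d|n} phi(d) k**(n/d)``.

    Raises
    ------
    RingSizeError
        If ``n < 1``, the alphabet is empty, or ``k**n`` exceeds the
        exhaustive-enumeration guard (10**6 arrangements).
    """
    alphabet = tuple(alphabet)
    if n < 1:
        raise RingSizeError(f"ring size must be >= 1, got {n}")
    if len(alphabet) < 1:
        raise RingSizeError("alphabet must contain at least one label")
    if len(set(alphabet)) != len(alphabet):
        raise RingSizeError(f"alphabet has duplicate labels: {alphabet!r}")
    if len(alphabet) ** n > MAX_ARRANGEMENTS:
        raise RingSizeError(
            f"{len(alphabet)}**{n} arrangements exceed the enumeration guard "
            f"({MAX_ARRANGEMENTS})"
        )
    rank = {label: i for i, label in enumerate(alphabet)}
    seen: dict[tuple[str, ...], int] = {}
    for states in product(alphabet, repeat=n):
        canon = min(rotations(states), key=lambda r: tuple(rank[s] for s in r))
        seen[canon] = seen.get(canon, 0) + 1
    classes = [
        CompositionClass(
            canonical=canon,
            orbit_size=len(orbit(canon)),
            active_count=sum(1 for s in canon if s == active_label),
            name=class_name(canon, active_label=active_label),
        )
        for canon in seen
    ]
    # seen counts each class once per member arrangement; sanity-check the
    # orbit sizes against that tally.
    for cls in classes:
        assert seen[cls.canonical] == cls.orbit_size
    classes.sort(key=lambda c: (c.active_count, tuple(rank[s] for s in c.canonical)))
    return classes


def necklace_count(n: int, k: int) -> int:
    """Burnside/necklace count of rotation classes: (1/n) Σ_{d|n} φ(d) k^(n/d)."""
    total = sum(
        _euler_phi(d) * k ** (n // d) for d in range(1, n + 1) if n % d == 0
    )
    return total // n


def _euler_phi(m: int) -> int:
    return sum(1 for i in range(1, m + 1) if math.gcd(i, m) == 1)


def classify(
    states: Sequence[str],
    classes: Iterable[CompositionClass],
    alphabet: Sequence[str] = TWO_STATE,
) -> CompositionClass:
    """Map an arrangement to its composition class.

    Raises
    ------
    RingstateError
        If the canonical form matches none of the supplied classes, which
        signals a ring-size or alphabet mismatch between the arrangement
        and the enumeration.
    """
    canon = canonicalize(states, alphabet)
    index = {c.canonical: c for c in classes}
    try:
        return index[canon]
    except KeyError:
        raise RingSizeError(
            f"arrangement {tuple(states)!r} (canonical {canon!r}) matches none "
            "of the supplied classes; ring size or alphabet mismatch"
        ) from None


def class_table(classes: Iterable[CompositionClass]) -> pd.DataFrame:
    """Class metadata as a DataFrame (columns name, canonical, orbit_size,
    active_count), suitable for CSV export."""
    return pd.DataFrame(
        [
            {
                "name": c.name,
                "canonical": "".join(c.canonical),
                "orbit_size": c.orbit_size,
                "active_count": c.active_count,
            }
            for c in classes
        ]
    )
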