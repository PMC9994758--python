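"""Ordinal phenology stage scale and the metaclass label space.

Cotton growth in this package is discretised into six principal
phenological stages, ordered in time:

    RE (root establishment) < LD (leaf development) < S (squaring)
    < F (flowering) < BD (boll development) < BO (boll opening)

A field in transition between two adjacent stages carries two ranked
labels: a *primary* (prevailing) and a *secondary* stage.  Each single-
or two-label state is a *metaclass*; with k = 6 stages and the adjacency
constraint there are exactly 3k - 2 = 16 metaclasses, which form an
ordinal scale of their own:

    RE, (RE,LD), (LD,RE), LD, (LD,S), (S,LD), S, ..., (BO,BD), BO

Prediction error is measured as displacement along this 16-level scale.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Optional, Union

logger = logging.getLogger(__name__)

__all__ = [
    "PhenologyStage",
    "Metaclass",
    "enumerate_metaclasses",
    "enumerate_allowable_labels",
    "displacement",
    "N_STAGES",
    "N_METACLASSES",
]

N_STAGES = 6
N_METACLASSES = 3 * N_STAGES - 2  # 16


class PhenologyStage(enum.IntEnum):
    """Principal cotton growth stage; integer value is the ordinal (1..6)."""

    RE = 1  # root establishment: sowing to three formed leaves
    LD = 2  # leaf development: fourth leaf to first squares
    S = 3  # squaring: first squares to first flowers
    F = 4  # flowering
    BD = 5  # boll development
    BO = 6  # boll opening, until harvest

    @property
    def code(self) -> str:
        return self.name

    @classmethod
    def from_code(cls, code: str) -> "PhenologyStage":
        try:
            return cls[code.strip().upper()]
        except KeyError as exc:
            raise ValueError(f"unknown phenology stage code {code!r}") from exc

    def is_adjacent(self, other: "PhenologyStage") -> bool:
        return abs(int(self) - int(other)) == 1


@dataclass(frozen=True)
class Metaclass:
    """A single- or two-label growth state on the 16-level ordinal scale.

    Parameters
    ----------
    primary : PhenologyStage
        The prevailing stage.
    secondary : PhenologyStage or None
        The co-occurring stage during a transition; must be adjacent to
        ``primary`` on the stage scale.

    Raises
    ------
    ValueError
        If the secondary stage is present but not adjacent to the primary.
    """

    primary: PhenologyStage
    secondary: Optional[PhenologyStage] = None

    def __post_init__(self) -> None:
        if self.secondary is not None and not self.primary.is_adjacent(self.secondary):
            raise ValueError(
                f"secondary stage {self.secondary.code} is not adjacent to "
                f"primary {self.primary.code}; only transitions between "
                "neighbouring stages are representable"
            )

    @property
    def index(self) -> int:
        """Position on the 16-level ordinal metaclass scale (0..15).

        The scale interleaves unit sets with ordered adjacent pairs:
        unit λi sits at 3(i-1); the ascending pair (λi, λi+1) at
        3(i-1)+1; the descending pair (λi+1, λi) at 3i - 1.
        """
        p = int(self.primary)
        if self.secondary is None:
            return 3 * (p - 1)
        s = int(self.secondary)
        if s == p + 1:  # ascending transition, earlier stage still prevails
            return 3 * (p - 1) + 1
        return 3 * (s - 1) + 2  # descending: later stage prevails

    @classmethod
    def lenient(
        cls,
        primary: PhenologyStage,
        secondary: Optional[PhenologyStage],
    ) -> "Metaclass":
        """Build a metaclass, dropping a non-adjacent secondary with a log entry."""
        if secondary is not None and not primary.is_adjacent(secondary):
            logger.warning(
                "non-adjacent (primary=%s, secondary=%s) pair truncated to the "
                "unit metaclass",
                primary.code,
                secondary.code,
            )
            secondary = None
        return cls(primary, secondary)

    @classmethod
    def from_string(cls, text: str) -> "Metaclass":
        """Parse the serialized form ``"LD"`` or ``"S|LD"`` (primary|secondary)."""
        parts = [p for p in text.strip().split("|") if p]
        if not 1 <= len(parts) <= 2:
            raise ValueError(f"malformed metaclass string {text!r}")
        primary = PhenologyStage.from_code(parts[0])
        secondary = PhenologyStage.from_code(parts[1]) if len(parts) == 2 else None
        return cls(primary, secondary)

    def __str__(self) -> str:
        if self.secondary is None:
            return self.primary.code
        return f"{self.primary.code}|{self.secondary.code}"


def enumerate_metaclasses(k: int = N_STAGES) -> list:
    """Ordered metaclass scale for a ``k``-stage ordinal label set.

    Unit sets and adjacent ordered pairs are interleaved as
    λ1, (λ1,λ2), (λ2,λ1), λ2, (λ2,λ3), ...; the list has length 3k - 2.
    For ``k == 6`` the elements are :class:`Metaclass` objects; for any
    other ``k`` they are ``(primary_ordinal, secondary_ordinal | None)``
    tuples, since the stage enum is fixed at six levels.
    """
    if k < 1:
        raise ValueError(f"stage count must be >= 1, got {k}")
    seq: list = []
    for i in range(1, k):
        seq.append((i, None))
        seq.append((i, i + 1))
        seq.append((i + 1, i))
    seq.append((k, None))
    if k == N_STAGES:
        return [
            Metaclass(
                PhenologyStage(p),
                PhenologyStage(s) if s is not None else None,
            )
            for p, s in seq
        ]
    return seq


def enumerate_allowable_labels(k: int = N_STAGES, n: int = 2) -> set:
    """All label assignments of up to ``n`` ranked stages: k^2 for n = 2.

    These are the k unit sets plus the k(k-1) ordered 2-permutations —
    the raw annotation space before the adjacency constraint cuts it
    down to the 3k - 2 metaclasses.
    """
    if k < 1:
        raise ValueError(f"stage count must be >= 1, got {k}")
    if n != 2:
        raise NotImplementedError("only the two-ranked-label protocol is supported")
    labels: set = {(i,) for i in range(1, k + 1)}
    labels |= {(i, j) for i in range(1, k + 1) for j in range(1, k + 1) if i != j}
    return labels


def displacement(predicted: Metaclass, truth: Metaclass) -> int:
    """Absolute distance between two metaclasses on the 16-level scale."""
    return abs(predicted.index - truth.index)
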