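"""Shared containers: group compositions and winner-loser interaction matrices.

The :class:`InteractionMatrix` is the interchange format between the
agent-based simulator, the hierarchy metrics and the synthetic generator:
a square non-negative integer matrix whose entry ``[i, j]`` counts the
decided agonistic interactions that individual ``i`` won against ``j``,
together with the individual ids and their sexes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroupComposition", "InteractionMatrix", "make_ids"]

_LABEL_RE = re.compile(r"^(\d+)m(\d+)f$")


@dataclass(frozen=True)
class GroupComposition:
    """Adult composition of one group: ``n_males`` males and ``n_females`` females."""

    n_males: int
    n_females: int

    def __post_init__(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError("counts must be non-negative")
        # a single-agent "group" is allowed as a degenerate simulation case;
        # hierarchy metrics separately require at least two individuals
        if self.n_males + self.n_females < 1:
            raise ValueError("a group needs at least 1 adult")

    @property
    def n(self) -> int:
        return self.n_males + self.n_females

    @property
    def prop_males(self) -> float:
        return self.n_males / self.n

    @property
    def label(self) -> str:
        return f"{self.n_males}m{self.n_females}f"

    @classmethod
    def from_label(cls, label: str) -> "GroupComposition":
        m = _LABEL_RE.match(label.strip())
        if m is None:
            raise ValueError(f"composition label {label!r} is not of the form '<n>m<n>f'")
        return cls(int(m.group(1)), int(m.group(2)))


def make_ids(comp: GroupComposition) -> list[str]:
    """Individual ids for a composition: males first (``m1..``), then females (``f1..``)."""
    return [f"m{i + 1}" for i in range(comp.n_males)] + [
        f"f{i + 1}" for i in range(comp.n_females)
    ]


def sex_from_id(ident: str) -> str:
    head = ident.strip().lower()[:1]
    if head == "m":
        return "male"
    if head == "f":
        return "female"
    raise ValueError(f"cannot infer sex from id {ident!r}: expected 'm'/'f' prefix")


@dataclass
class InteractionMatrix:
    """Square winner x loser count matrix with per-individual sex labels."""

    ids: list[str]
    sexes: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.ids)
        if len(self.sexes) != n:
            raise ValueError("ids and sexes must have equal length")
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts must be {n}x{n} to match ids, got {self.counts.shape}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("diagonal (self-interactions) must be zero")
        bad = set(self.sexes) - {"male", "female"}
        if bad:
            raise ValueError(f"unknown sex labels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_males(self) -> int:
        return sum(s == "male" for s in self.sexes)

    @property
    def n_females(self) -> int:
        return sum(s == "female" for s in self.sexes)

    def male_mask(self) -> np.ndarray:
        return np.array([s == "male" for s in self.sexes])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.sexes == other.sexes
            and np.array_equal(self.counts, other.counts)
        )
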