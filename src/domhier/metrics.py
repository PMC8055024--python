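"""Dominance-hierarchy statistics from winner-loser interaction matrices.

The central quantities:

- **ADI** (average dominance index): per individual, the mean over its actual
  interaction partners of the fraction of fights won against that partner.
  Partners never interacted with are excluded from the mean; an individual
  with no interactions at all has an undefined ADI (NaN) and is left
  unranked.
- **FDI** (female dominance index): the average over females of the
  proportion of ranked males each female outranks; 0 when no female is above
  any male, 1 when all females are above all males.
- Unknown-relation proportion: fraction of unordered dyads with zero
  interactions in either direction.
- Sex-classed aggression fractions: male-male acts over all male-initiated
  acts, and female-to-male acts over all female-initiated acts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import InteractionMatrix

__all__ = [
    "HierarchySummary",
    "average_dominance_index",
    "average_dominance_index_exact",
    "rank_individuals",
    "female_dominance_index",
    "fdi_success_counts",
    "unknown_relation_proportion",
    "aggression_fractions",
    "summarize_hierarchy",
]

#: ADI values are compared after rounding to this many decimals when ranking.
ADI_TIE_DECIMALS = 9


def average_dominance_index(m: InteractionMatrix) -> np.ndarray:
    """Per-individual ADI; NaN where the individual had no interactions."""
    if m.n < 2:
        raise ValueError("need at least 2 individuals")
    c = m.counts.astype(float)
    totals = c + c.T
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, c / np.where(totals > 0, totals, 1.0), np.nan)
    np.fill_diagonal(frac, np.nan)
    n_partners = np.sum(~np.isnan(frac), axis=1)
    sums = np.nansum(frac, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        adi = np.where(n_partners > 0, sums / np.maximum(n_partners, 1), np.nan)
    return adi


def average_dominance_index_exact(m: InteractionMatrix) -> list[Optional[Fraction]]:
    """ADI as exact rationals (None where undefined); reference for tie handling."""
    if m.n < 2:
        raise ValueError("need at least 2 individuals")
    out: list[Optional[Fraction]] = []
    for i in range(m.n):
        fracs = []
        for j in range(m.n):
            if j == i:
                continue
            tot = int(m.counts[i, j]) + int(m.counts[j, i])
            if tot > 0:
                fracs.append(Fraction(int(m.counts[i, j]), tot))
        out.append(sum(fracs, Fraction(0)) / len(fracs) if fracs else None)
    return out


def rank_individuals(adi: Sequence[float]) -> np.ndarray:
    """Tie-aware competition ranks (1 = highest ADI); NaN for undefined ADI.

    ADI values are rounded to :data:`ADI_TIE_DECIMALS` decimals before
    comparison so that equal rationals computed in floating point tie
    exactly.  Tied individuals share the best rank of their block
    (1, 2, 2, 4 style).
    """
    adi = np.asarray(adi, dtype=float)
    defined = ~np.isnan(adi)
    if not defined.any():
        raise ValueError("all ADI values are undefined; nothing to rank")
    ranks = np.full(adi.shape, np.nan)
    vals = np.round(adi[defined], ADI_TIE_DECIMALS)
    ranks[defined] = rankdata(-vals, method="min")
    return ranks


def female_dominance_index(
    ranks: Sequence[float], sexes: Sequence[str], tie_weight: float = 0.0
) -> float:
    """Average over females of the proportion of ranked males below them.

    ``tie_weight`` is the credit a female receives for a male she ties with
    (0 by default: a tied male is not counted as dominated; 0.5 counts ties
    as half a success).
    """
    if not 0.0 <= tie_weight <= 1.0:
        raise ValueError("tie_weight must be in [0, 1]")
    ranks = np.asarray(ranks, dtype=float)
    sexes = list(sexes)
    male_ranks = np.array(
        [r for r, s in zip(ranks, sexes) if s == "male" and not math.isnan(r)]
    )
    female_ranks = np.array(
        [r for r, s in zip(ranks, sexes) if s == "female" and not math.isnan(r)]
    )
    if male_ranks.size == 0:
        raise ValueError("no ranked males: FDI undefined")
    if female_ranks.size == 0:
        raise ValueError("no ranked females: FDI undefined")
    props = [
        (np.sum(male_ranks > fr) + tie_weight * np.sum(male_ranks == fr))
        / male_ranks.size
        for fr in female_ranks
    ]
    return float(np.mean(props))


def fdi_success_counts(
    ranks: Sequence[float], sexes: Sequence[str]
) -> tuple[int, int]:
    """(successes, total) for the grouped-binomial view of female dominance.

    ``total`` is the product of the numbers of ranked males and females;
    ``successes`` is the summed number of males ranked strictly below each
    female.  ``successes / total`` equals the FDI with ``tie_weight = 0``.
    """
    ranks = np.asarray(ranks, dtype=float)
    sexes = list(sexes)
    male_ranks = np.array(
        [r for r, s in zip(ranks, sexes) if s == "male" and not math.isnan(r)]
    )
    female_ranks = np.array(
        [r for r, s in zip(ranks, sexes) if s == "female" and not math.isnan(r)]
    )
    if male_ranks.size == 0 or female_ranks.size == 0:
        raise ValueError("need at least one ranked male and one ranked female")
    successes = int(sum(np.sum(male_ranks > fr) for fr in female_ranks))
    return successes, int(male_ranks.size * female_ranks.size)


def unknown_relation_proportion(m: InteractionMatrix) -> float:
    """Fraction of unordered dyads with zero interactions in either direction."""
    if m.n < 2:
        raise ValueError("need at least 2 individuals")
    totals = m.counts + m.counts.T
    iu = np.triu_indices(m.n, k=1)
    return float(np.mean(totals[iu] == 0))


@dataclass(frozen=True)
class AggressionFractions:
    mm: Optional[float]  # male->male acts / all male-initiated acts
    fm: Optional[float]  # female->male acts / all female-initiated acts
    mm_excluded: bool  # True in single-male groups (no male-male dyad exists)


def aggression_fractions(
    acts: np.ndarray, sexes: Sequence[str]
) -> AggressionFractions:
    """Sex-classed fractions of directed aggressive acts.

    ``acts[i, j]`` counts acts directed by ``i`` at ``j``.  For simulated
    data these are initiator-attributed attacks; when only a winner-loser
    matrix is available its counts may be passed instead, attributing each
    won fight to the winner as aggressor.  The male-male fraction is marked
    excluded in single-male groups, where no male-male dyad exists.
    """
    acts = np.asarray(acts)
    sexes = list(sexes)
    male = np.array([s == "male" for s in sexes])
    if acts.shape != (len(sexes), len(sexes)):
        raise ValueError("acts must be square and match sexes")
    n_males = int(male.sum())
    male_total = int(acts[male].sum())
    female_total = int(acts[~male].sum())
    mm_excluded = n_males < 2
    mm = None
    if not mm_excluded and male_total > 0:
        mm = float(acts[np.ix_(male, male)].sum() / male_total)
    fm = None
    if female_total > 0:
        fm = float(acts[np.ix_(~male, male)].sum() / female_total)
    return AggressionFractions(mm=mm, fm=fm, mm_excluded=mm_excluded)


@dataclass
class HierarchySummary:
    """All hierarchy statistics for one group(-period)."""

    ids: list[str]
    sexes: list[str]
    adi: np.ndarray
    ranks: np.ndarray
    fdi: float
    fdi_successes: int
    fdi_total: int
    unknown_proportion: float
    mm_fraction: Optional[float]
    fm_fraction: Optional[float]
    mm_excluded: bool


def summarize_hierarchy(
    m: InteractionMatrix,
    acts: Optional[np.ndarray] = None,
    tie_weight: float = 0.0,
) -> HierarchySummary:
    """Compute the full set of hierarchy statistics for one matrix.

    ``acts`` carries initiator-attributed directed aggression counts; when
    omitted, the winner-loser counts stand in (winner-attributed).
    Individuals with undefined ADI are dropped before ranking and FDI, while
    the unknown-relation proportion is computed over the full set of dyads.
    """
    adi = average_dominance_index(m)
    ranks = rank_individuals(adi)
    fdi = female_dominance_index(ranks, m.sexes, tie_weight=tie_weight)
    succ, total = fdi_success_counts(ranks, m.sexes)
    frac = aggression_fractions(acts if acts is not None else m.counts, m.sexes)
    return HierarchySummary(
        ids=list(m.ids),
        sexes=list(m.sexes),
        adi=adi,
        ranks=ranks,
        fdi=fdi,
        fdi_successes=succ,
        fdi_total=total,
        unknown_proportion=unknown_relation_proportion(m),
        mm_fraction=frac.mm,
        fm_fraction=frac.fm,
        mm_excluded=frac.mm_excluded,
    )
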