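"""Independent brute-force oracles used by the tests.

These are written straight from the definitions, independently of the
package implementation, so that metric tests are genuine dual-route checks.
"""

from __future__ import annotations

import numpy as np


def oracle_adi(counts: np.ndarray) -> list[float | None]:
    """ADI by direct looping: mean winning fraction over interacted partners."""
    n = counts.shape[0]
    out = []
    for i in range(n):
        fracs = []
        for j in range(n):
            if i == j:
                continue
            tot = counts[i, j] + counts[j, i]
            if tot > 0:
                fracs.append(counts[i, j] / tot)
        out.append(sum(fracs) / len(fracs) if fracs else None)
    return out


def oracle_ranks(adi: list[float | None], decimals: int = 9) -> list[float | None]:
    """Competition ranks (1 = best) on rounded ADI; None stays unranked."""
    ranks: list[float | None] = []
    vals = [round(a, decimals) for a in adi if a is not None]
    for a in adi:
        if a is None:
            ranks.append(None)
        else:
            ranks.append(1 + sum(v > round(a, decimals) for v in vals))
    return ranks


def oracle_fdi(ranks, sexes, tie_weight: float = 0.0) -> float:
    male_ranks = [r for r, s in zip(ranks, sexes) if s == "male" and r is not None]
    female_ranks = [r for r, s in zip(ranks, sexes) if s == "female" and r is not None]
    props = []
    for fr in female_ranks:
        below = sum(mr > fr for mr in male_ranks)
        tied = sum(mr == fr for mr in male_ranks)
        props.append((below + tie_weight * tied) / len(male_ranks))
    return sum(props) / len(props)


def oracle_unknown(counts: np.ndarray) -> float:
    n = counts.shape[0]
    silent = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if counts[i, j] + counts[j, i] == 0
    )
    return silent / (n * (n - 1) / 2)
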