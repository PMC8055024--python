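"""Synthetic inputs with known ground truth for every analysis stage.

Two generators:

- latent-dominance interaction matrices: each individual gets a latent
  strength on a logit scale (sex-specific means), dyads meet a
  Poisson-distributed number of times, and each fight is won by the stronger
  with a logistic probability in the strength difference;
- grouped beta-binomial datasets with known regression coefficients,
  precision and random-intercept variances, for validating the fitting
  machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .core import GroupComposition, InteractionMatrix, make_ids

__all__ = ["LatentModelParams", "generate_interaction_matrix", "simulate_betabin_dataset"]


@dataclass(frozen=True)
class LatentModelParams:
    """Latent-hierarchy generator settings (logit-strength scale).

    The default sex means loosely mirror the simulator's 2:1 male:female
    initial-dominance ratio (log 2 apart); this is a test harness, not a
    biological claim.
    """

    female_mean: float = 0.0
    male_mean: float = 0.693
    female_sd: float = 1.0
    male_sd: float = 1.0
    encounter_rate: float = 2.0  # expected fights per dyad
    steepness: float = 1.0  # logistic slope on the latent difference

    def validate(self) -> None:
        if self.encounter_rate < 0:
            raise ValueError("encounter_rate must be >= 0")
        if self.female_sd < 0 or self.male_sd < 0:
            raise ValueError("latent SDs must be >= 0")


def generate_interaction_matrix(
    comp: GroupComposition,
    params: LatentModelParams = LatentModelParams(),
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> tuple[InteractionMatrix, np.ndarray]:
    """Draw a winner-loser count matrix from the latent-dominance model.

    Returns the matrix and the latent strengths (id order: males first).
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = make_ids(comp)
    sexes = ["male"] * comp.n_males + ["female"] * comp.n_females
    strengths = np.concatenate(
        [
            rng.normal(params.male_mean, params.male_sd, comp.n_males),
            rng.normal(params.female_mean, params.female_sd, comp.n_females),
        ]
    )
    n = comp.n
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            fights = rng.poisson(params.encounter_rate)
            if fights == 0:
                continue
            p_i = expit(params.steepness * (strengths[i] - strengths[j]))
            wins_i = rng.binomial(fights, p_i)
            counts[i, j] = wins_i
            counts[j, i] = fights - wins_i
    return InteractionMatrix(ids=ids, sexes=sexes, counts=counts), strengths


def simulate_betabin_dataset(
    beta,
    theta: float,
    X,
    n,
    grouping: dict | None = None,
    variance_components: dict | None = None,
    offset=None,
    seed: int | np.random.Generator = 0,
):
    """Draw grouped beta-binomial counts with known parameters.

    ``mu = logistic(X beta + offset + sum_f u_f)`` with ``u_f ~ N(0, sigma_f^2)``
    per level of each grouping factor, then ``p ~ Beta(mu theta, (1-mu) theta)``
    and ``k ~ Binomial(n, p)``.  Returns ``(k, mu)``.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta, dtype=float)
    n = np.asarray(n)
    eta = X @ beta
    if offset is not None:
        eta = eta + np.asarray(offset, dtype=float)
    grouping = grouping or {}
    variance_components = variance_components or {}
    for name, labels in grouping.items():
        sd = float(variance_components.get(name, 0.0)) ** 0.5
        levels, codes = np.unique(np.asarray(labels), return_inverse=True)
        u = rng.normal(0.0, sd, size=len(levels))
        eta = eta + u[codes]
    mu = expit(eta)
    p = rng.beta(mu * theta, (1.0 - mu) * theta)
    k = rng.binomial(n.astype(int), p)
    return k, mu
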