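"""Empirical-Bayes tuning of the stem-time fraction alpha.

alpha is the proportion of time from the tumor's earliest mutation to the
MRCA of the sampled cells — the only free parameter of the coalescent
prior. It is fitted by matching the model's marginal distribution of
observed genotype pairs

    p_ij = sum over relations of P((i, j) | relation) * P(relation)

against the relative frequency f_ij of observed genotype pairs pooled over
all site pairs of a genotype matrix, minimizing the squared distance
sum (p_ij - f_ij)^2 on a grid of alpha values. Common random numbers
across grid points keep the objective curve smooth in alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ErrorRates
from .genotypes import GenotypeMatrix
from .posterior import relation_tables
from .prior import CoalescentConfig, PriorTable, get_prior

DEFAULT_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


def observed_pair_freqs(m: GenotypeMatrix) -> np.ndarray:
    """3x3 relative frequencies of observed genotype pairs.

    Tallied over all ordered site pairs (x != y) and all cells with both
    sites observed; the ordered-pair tally makes f symmetric by
    construction.
    """
    if m.n_sites < 2:
        raise ValueError("need at least 2 sites")
    # Per cell k and genotype g, B[g, k] sites called g; summing
    # B[i, k] * B[j, k] over cells counts all ordered site pairs (s, t)
    # with calls (i, j), including s == t, which contributes B[i, k] to
    # the diagonal i == j only (one site has one call).
    B = np.stack([(m.calls == g).sum(axis=0) for g in (0, 1, 2)])
    counts = np.einsum("ik,jk->ij", B, B) - np.diag(B.sum(axis=1))
    total = counts.sum()
    if total == 0:
        raise ValueError("no site pair has a jointly observed cell")
    return counts / total


def model_marginals(prior: PriorTable, e: ErrorRates) -> np.ndarray:
    """3x3 model marginal p_ij of an observed genotype pair."""
    M = relation_tables(prior, e)
    return np.einsum("r,rij->ij", prior.order_prior, M)


@dataclass
class AlphaFit:
    """Grid-search fit of alpha.

    grid/objective trace the squared-distance curve; alpha_hat is the
    argmin. p_ij holds the model marginals per grid point, f_ij the
    observed frequencies.
    """

    grid: np.ndarray
    objective: np.ndarray
    alpha_hat: float
    p_ij: np.ndarray  # (len(grid), 3, 3)
    f_ij: np.ndarray  # (3, 3)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("alpha\tobjective\n")
            for a, o in zip(self.grid, self.objective):
                fh.write(f"{a}\t{o!r}\n")

    def to_json(self, path=None) -> str:
        text = json.dumps({"alpha_hat": self.alpha_hat,
                           "grid": self.grid.tolist(),
                           "objective": self.objective.tolist(),
                           "f_ij": self.f_ij.tolist()}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_alpha(m: GenotypeMatrix, grid=None, e: ErrorRates | None = None,
              b_tree: int = 1000, b_mut: int = 10000,
              seed: int = 0) -> AlphaFit:
    """Minimize sum (p_ij - f_ij)^2 over a grid of alpha values.

    One prior table per grid point is estimated at this matrix's sample
    count with a shared seed (common random numbers), then compared with
    the pooled observed pair frequencies of ``m``.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("alpha grid must have >= 2 points inside (0, 1)")
    e = ErrorRates() if e is None else e
    f = observed_pair_freqs(m)
    p = np.empty((grid.size, 3, 3))
    obj = np.empty(grid.size)
    for i, a in enumerate(grid):
        prior = get_prior(CoalescentConfig(m.n_samples, float(a),
                                           b_tree, b_mut, seed))
        p[i] = model_marginals(prior, e)
        obj[i] = ((p[i] - f) ** 2).sum()
    best = int(np.argmin(obj))
    return AlphaFit(grid, obj, float(grid[best]), p, f)
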