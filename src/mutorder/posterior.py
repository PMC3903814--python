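"""Bayesian classification of pairwise mutation order.

For each site pair (x, y) the likelihood of the observed genotype pairs is
computed under each order relation by mixing the relation-conditional true
genotype distribution (from the coalescent prior) through the
sequencing-error observation model, then combined with the relation prior
via Bayes' theorem. All arithmetic is in log space with explicit -inf
handling; cells missing at either site are excluded from that pair only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import ErrorRates, observation_probs
from .genotypes import MISSING, GenotypeMatrix
from .prior import OrderRelation, PriorTable

#: Tie-break preference among equal posteriors: refuse to invent a
#: direction without evidence.
_TIE_ORDER = (OrderRelation.INDEPENDENT, OrderRelation.FORWARD,
              OrderRelation.BACKWARD)


def relation_tables(prior: PriorTable, e: ErrorRates) -> np.ndarray:
    """(3, 3, 3) array ``M[rel][i, j]`` = P(observe (i, j) | relation).

    ``M[rel] = O^T C_rel O`` where O is the 2x3 observation table and
    C_rel the 2x2 conditional true-genotype table; every slice sums to 1.
    """
    O = observation_probs(e)
    return np.einsum("ai,rab,bj->rij", O, prior.cond_genotype, O)


def relation_cell_prob(obs_pair: tuple[int, int], relation: OrderRelation,
                       prior: PriorTable, e: ErrorRates) -> float:
    """P(observed genotype pair | order relation) for one cell."""
    i, j = obs_pair
    if i not in (0, 1, 2) or j not in (0, 1, 2):
        raise ValueError(f"observed genotypes must be 0/1/2, got {obs_pair}")
    return float(relation_tables(prior, e)[relation][i, j])


def _pair_counts(m: GenotypeMatrix, x: int, y: int) -> np.ndarray:
    """3x3 tally of observed genotype pairs over jointly observed cells."""
    gx, gy = m.calls[x], m.calls[y]
    ok = (gx != MISSING) & (gy != MISSING)
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (gx[ok], gy[ok]), 1)
    return counts


def _loglik_from_counts(counts: np.ndarray, logM: np.ndarray) -> np.ndarray:
    """(3,) log-likelihood per relation; 0 * -inf treated as 0."""
    ll = np.empty(3)
    with np.errstate(invalid="ignore"):
        for r in range(3):
            terms = counts * logM[r]
            ll[r] = -np.inf if np.any((counts > 0) & np.isneginf(logM[r])) \
                else terms[counts > 0].sum()
    return ll


def pair_loglik(m: GenotypeMatrix, x, y, relation: OrderRelation,
                prior: PriorTable, e: ErrorRates) -> float:
    """Log-likelihood of one site pair's data under one relation.

    Sums over cells with both sites observed; -inf when an observed
    genotype pair is impossible under the relation.
    """
    x, y = m.site_index(x), m.site_index(y)
    counts = _pair_counts(m, x, y)
    if counts.sum() == 0:
        raise ValueError(
            f"sites {m.site_labels[x]!r} and {m.site_labels[y]!r} share "
            "no jointly observed cells"
        )
    with np.errstate(divide="ignore"):
        logM = np.log(relation_tables(prior, e))
    return float(_loglik_from_counts(counts, logM)[relation])


@dataclass
class PairResult:
    x: str
    y: str
    loglik: np.ndarray          # (3,) indexed by OrderRelation, x-oriented
    posterior: np.ndarray       # (3,) normalized, or nan if unclassifiable
    n_used: int
    map_relation: OrderRelation | None
    tied: bool = False
    unclassifiable: bool = False


def _posterior_from_loglik(ll: np.ndarray, order_prior: np.ndarray):
    with np.errstate(divide="ignore"):
        logpost = ll + np.log(order_prior)
    if np.all(np.isneginf(logpost)):
        return np.full(3, np.nan), None, False
    post = np.exp(logpost - logsumexp(logpost))
    post /= post.sum()
    best = post.max()
    cands = [r for r in _TIE_ORDER if post[r] == best]
    return post, cands[0], len(cands) > 1


def pair_posterior(m: GenotypeMatrix, x, y, prior: PriorTable,
                   e: ErrorRates) -> PairResult:
    """Posterior over the three order relations for one site pair."""
    xi, yi = m.site_index(x), m.site_index(y)
    counts = _pair_counts(m, xi, yi)
    n_used = int(counts.sum())
    if n_used == 0:
        raise ValueError(
            f"sites {m.site_labels[xi]!r} and {m.site_labels[yi]!r} share "
            "no jointly observed cells"
        )
    with np.errstate(divide="ignore"):
        logM = np.log(relation_tables(prior, e))
    ll = _loglik_from_counts(counts, logM)
    post, map_rel, tied = _posterior_from_loglik(ll, prior.order_prior)
    return PairResult(m.site_labels[xi], m.site_labels[yi], ll, post, n_used,
                      map_rel, tied, unclassifiable=map_rel is None)


@dataclass
class PosteriorMatrix:
    """Pairwise order posteriors for all site pairs of a matrix.

    Results are stored once per unordered pair in the canonical
    orientation (site index x < y); :meth:`result` mirrors them for the
    opposite orientation, so posterior(x->y) == posterior(y<-x) always.
    """

    site_labels: list[str]
    pairs: dict[tuple[int, int], PairResult] = field(default_factory=dict)

    def result(self, x, y) -> PairResult:
        xi = self.site_labels.index(x) if isinstance(x, str) else int(x)
        yi = self.site_labels.index(y) if isinstance(y, str) else int(y)
        if xi == yi:
            raise KeyError("a site has no order relation with itself")
        if xi < yi:
            return self.pairs[(xi, yi)]
        r = self.pairs[(yi, xi)]
        perm = [OrderRelation.BACKWARD, OrderRelation.FORWARD,
                OrderRelation.INDEPENDENT]
        return PairResult(
            r.y, r.x, r.loglik[perm], r.posterior[perm], r.n_used,
            None if r.map_relation is None else r.map_relation.reverse(),
            r.tied, r.unclassifiable,
        )

    def posterior(self, x, y, relation: OrderRelation) -> float:
        return float(self.result(x, y).posterior[relation])

    def iter_canonical(self):
        for (xi, yi), r in sorted(self.pairs.items()):
            yield xi, yi, r

    def to_records(self) -> list[dict]:
        recs = []
        for _, _, r in self.iter_canonical():
            recs.append({
                "site_x": r.x, "site_y": r.y,
                "p_forward": None if r.unclassifiable else float(r.posterior[0]),
                "p_backward": None if r.unclassifiable else float(r.posterior[1]),
                "p_independent": None if r.unclassifiable else float(r.posterior[2]),
                "n_used": r.n_used,
                "map_relation": None if r.map_relation is None
                else r.map_relation.name,
                "tied": r.tied,
            })
        return recs

    def to_tsv(self, path) -> None:
        cols = ["site_x", "site_y", "p_forward", "p_backward",
                "p_independent", "n_used", "map_relation", "tied"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for rec in self.to_records():
                fh.write("\t".join("NA" if rec[c] is None else str(rec[c])
                                   for c in cols) + "\n")

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_records(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def classify_all_pairs(m: GenotypeMatrix, prior: PriorTable,
                       e: ErrorRates) -> PosteriorMatrix:
    """Posterior classification of every unordered site pair.

    Pairs with no jointly observed cells, or whose data are impossible
    under all three relations, are kept as flagged unclassifiable entries
    rather than dropped.
    """
    if m.n_sites < 2:
        raise ValueError("need at least 2 sites to classify pairs")
    with np.errstate(divide="ignore"):
        logM = np.log(relation_tables(prior, e))
    pm = PosteriorMatrix(list(m.site_labels))
    for xi in range(m.n_sites):
        for yi in range(xi + 1, m.n_sites):
            counts = _pair_counts(m, xi, yi)
            n_used = int(counts.sum())
            if n_used == 0:
                pm.pairs[(xi, yi)] = PairResult(
                    m.site_labels[xi], m.site_labels[yi],
                    np.full(3, np.nan), np.full(3, np.nan), 0, None,
                    unclassifiable=True)
                continue
            ll = _loglik_from_counts(counts, logM)
            post, map_rel, tied = _posterior_from_loglik(ll, prior.order_prior)
            pm.pairs[(xi, yi)] = PairResult(
                m.site_labels[xi], m.site_labels[yi], ll, post, n_used,
                map_rel, tied, unclassifiable=map_rel is None)
    return pm
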