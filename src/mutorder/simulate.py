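"""Forward simulator: genotype matrices with known mutation-order truth.

Runs the inference's own generative model forward: one coalescent
genealogy with a stem occupying fraction alpha of total time, one
mutation per site dropped branch-length-uniformly, leaf genotypes induced
by subtree membership, then FD/AD corruption and uniform random
missingness. Defaults mirror the essential-thrombocythemia study's
18-site tree dataset (58 cells, 45% missing calls); the 712-site preset
with 58% missingness emulates the full matrix the stem fraction was tuned
on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ErrorRates, observation_probs
from .genotypes import MISSING, GenotypeMatrix
from .prior import (GenealogySample, OrderRelation, _pair_relations,
                    _sample_mutations, sample_genealogy)

#: Missing-call fractions of the two real datasets the defaults emulate.
MISSING_RATE_18SITES = 0.45
MISSING_RATE_FULL = 0.58


@dataclass
class SimTruth:
    """Ground truth behind a simulated genotype matrix."""

    genealogy: GenealogySample
    site_nodes: np.ndarray        # (S,) lineage node of each site's mutation
    site_times: np.ndarray        # (S,) chronological key of each mutation
    true_relations: np.ndarray    # (S, S) OrderRelation values, diag -1
    clean_matrix: GenotypeMatrix  # error-free {0,1} calls

    def relation(self, x: int, y: int) -> OrderRelation:
        return OrderRelation(int(self.true_relations[x, y]))

    def to_newick(self) -> str:
        """Genealogy as Newick with branch lengths; the stem is the root
        branch (duration T_1)."""
        t = self.genealogy.topology
        T = self.genealogy.intervals

        def blen(u: int) -> float:
            return float(T[t.k_end[u] - 1:t.k_start[u]].sum())

        def rec(u: int) -> str:
            if t.children[u, 0] < 0:
                return f"c{u}:{blen(u)!r}"
            a, b = map(int, t.children[u])
            return f"({rec(a)},{rec(b)}):{blen(u)!r}"

        return rec(2 * self.genealogy.n - 2) + ";"

    def truth_json(self, path=None) -> str:
        text = json.dumps({
            "newick_with_stem": self.to_newick(),
            "stem_time": float(self.genealogy.intervals[0]),
            "alpha": self.genealogy.alpha,
            "site_nodes": self.site_nodes.tolist(),
        }, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def relations_tsv(self, path) -> None:
        labels = self.clean_matrix.site_labels
        with open(path, "w") as fh:
            fh.write("site_x\tsite_y\trelation\n")
            S = len(labels)
            for x in range(S):
                for y in range(x + 1, S):
                    fh.write(f"{labels[x]}\t{labels[y]}\t"
                             f"{self.relation(x, y).name}\n")


def simulate_dataset(n_cells: int = 58, n_sites: int = 18,
                     alpha: float = 0.92, e: ErrorRates | None = None,
                     missing_rate: float = MISSING_RATE_18SITES,
                     seed: int = 0) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate one genotype matrix and its ground truth.

    Parameters default to the real study's conditions: 58 cells, 18 sites,
    stem fraction 0.92, FD/AD at the published MDA error rates, and 45%
    of entries masked uniformly at random.
    """
    if n_cells < 2 or n_sites < 2:
        raise ValueError("need n_cells >= 2 and n_sites >= 2")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    e = ErrorRates() if e is None else e
    rng = np.random.default_rng(seed)
    g = sample_genealogy(n_cells, alpha, rng)
    t = g.topology

    nodes, times = _sample_mutations(g, n_sites, rng)
    rel = np.full((n_sites, n_sites), -1, dtype=np.int8)
    xi, yi = np.triu_indices(n_sites, k=1)
    r = _pair_relations(t, nodes[xi], nodes[yi], times[xi], times[yi])
    rel[xi, yi] = r
    rev = {int(OrderRelation.FORWARD): int(OrderRelation.BACKWARD),
           int(OrderRelation.BACKWARD): int(OrderRelation.FORWARD),
           int(OrderRelation.INDEPENDENT): int(OrderRelation.INDEPENDENT)}
    rel[yi, xi] = [rev[int(v)] for v in r]

    # leaf genotypes: cell below the site's lineage node carries the mutation
    pos = t.leaf_pos[np.newaxis, :]                      # (1, n)
    lo = t.node_lo[nodes][:, np.newaxis]
    hi = t.node_hi[nodes][:, np.newaxis]
    clean = ((pos >= lo) & (pos <= hi)).astype(np.int8)  # (S, n)

    P = observation_probs(e)
    cum = np.cumsum(P, axis=1)
    u = rng.random(clean.shape)
    obs = (u[..., np.newaxis] >= cum[clean][:, :, :-1]).sum(axis=2)
    obs = obs.astype(np.int8)
    obs[rng.random(clean.shape) < missing_rate] = MISSING

    labels = [f"site{s:03d}" for s in range(n_sites)]
    cells = [f"cell{k:03d}" for k in range(n_cells)]
    observed = GenotypeMatrix(labels, cells, obs)
    truth = SimTruth(g, nodes, times, rel,
                     GenotypeMatrix(list(labels), list(cells), clean))
    return observed, truth
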