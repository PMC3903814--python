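"""Monte-Carlo prior over pairwise mutation-order relations.

The prior is induced by a neutral-coalescent model of the sampled cells'
genealogy: a Kingman topology over ``n`` leaves, exponential coalescent
intervals ``T_k ~ Exp(k(k-1)/2)`` for ``k >= 2``, and a stem interval
``T_1`` (the single lineage from the tumor's earliest mutation down to the
MRCA) fixed so that ``T_1 / sum(T_k) = alpha``. Two mutations are dropped
onto the genealogy with probability proportional to branch length
(a lineage segment in interval ``k`` is hit with probability
``T_k / sum_i i*T_i``); the pair is in an ancestral relation when one
mutation's lineage contains the other's, independent when their carrier
sets are disjoint.

Tallying many such pairs over many genealogies yields

* the prior probability of each order relation (ancestral relations split
  evenly between the two directions), and
* the distribution of a random cell's true genotype pair conditional on
  each relation, tallied per leaf.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class OrderRelation(IntEnum):
    """Pairwise temporal relation of two mutations x and y."""

    FORWARD = 0      # x -> y : x ancestral to y on one lineage
    BACKWARD = 1     # x <- y : y ancestral to x
    INDEPENDENT = 2  # x <-/-> y : distinct lineages

    def reverse(self) -> "OrderRelation":
        if self is OrderRelation.FORWARD:
            return OrderRelation.BACKWARD
        if self is OrderRelation.BACKWARD:
            return OrderRelation.FORWARD
        return self


RELATIONS = (OrderRelation.FORWARD, OrderRelation.BACKWARD,
             OrderRelation.INDEPENDENT)


@dataclass(frozen=True)
class CoalescentConfig:
    """Monte-Carlo settings for prior estimation.

    n : number of sampled cells (leaves of each genealogy)
    alpha : stem-time fraction, in (0, 1)
    b_tree : number of genealogies
    b_mut : mutation pairs per genealogy
    seed : RNG seed
    """

    n: int
    alpha: float
    b_tree: int = 1000
    b_mut: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2 leaves, got {self.n}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.b_tree < 1 or self.b_mut < 1:
            raise ValueError("b_tree and b_mut must be >= 1")


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Rooted binary coalescent topology with n labelled leaves.

    Leaves are nodes 0..n-1; internal node n-1+e is created by the e-th
    coalescent event (the root is node 2n-2). Every node's leaf set is a
    contiguous block [lo, hi] of a canonical leaf ordering.
    """

    n: int
    children: np.ndarray      # (2n-1, 2), -1 for leaves
    node_lo: np.ndarray       # (2n-1,) first leaf position under the node
    node_hi: np.ndarray       # (2n-1,) last leaf position (inclusive)
    node_size: np.ndarray     # (2n-1,) number of leaves below
    k_start: np.ndarray       # (2n-1,) first (largest-k) interval of existence
    k_end: np.ndarray         # (2n-1,) last (smallest-k) interval of existence
    leaf_pos: np.ndarray      # (n,) position of leaf label i in the ordering
    seg_nodes: np.ndarray     # flat extant-lineage table, intervals k=1..n
    seg_off: np.ndarray       # (n+1,) seg_nodes[seg_off[k-1]:seg_off[k]] = interval k

    def leaves_below(self, node: int) -> np.ndarray:
        """Leaf labels carried by a mutation on ``node``'s lineage segment."""
        span = (self.leaf_pos >= self.node_lo[node]) & \
               (self.leaf_pos <= self.node_hi[node])
        return np.flatnonzero(span)


def sample_topology(n: int, rng: np.random.Generator) -> Topology:
    """Kingman topology: repeatedly merge a uniformly chosen lineage pair."""
    if n < 2:
        raise ValueError(f"need n >= 2 leaves, got {n}")
    total = 2 * n - 1
    children = np.full((total, 2), -1, dtype=np.int64)
    k_start = np.empty(total, dtype=np.int64)
    k_end = np.empty(total, dtype=np.int64)
    k_start[:n] = n
    # extant lineages, and the flat per-interval table (k = n down to 1)
    active = list(range(n))
    seg = np.empty(n * (n + 1) // 2, dtype=np.int64)
    seg_off = np.concatenate([[0], np.cumsum(np.arange(1, n + 1))])

    def record(k: int) -> None:
        seg[seg_off[k - 1]:seg_off[k]] = active

    record(n)
    for e in range(1, n):  # e-th coalescent event: k = n-e+1 -> n-e lineages
        k = n - e + 1
        i = int(rng.integers(len(active)))
        j = int(rng.integers(len(active) - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        new = n - 1 + e
        children[new] = (a, b)
        k_end[a] = k_end[b] = k
        k_start[new] = k - 1
        active = [x for x in active if x not in (a, b)] + [new]
        if k - 1 >= 1:
            record(k - 1)
    k_end[total - 1] = 1

    # leaf ordering + contiguous leaf ranges by iterative DFS from the root
    node_lo = np.empty(total, dtype=np.int64)
    node_hi = np.empty(total, dtype=np.int64)
    node_size = np.empty(total, dtype=np.int64)
    leaf_pos = np.empty(n, dtype=np.int64)
    pos = 0
    stack = [(total - 1, False)]
    order = []  # post-order
    while stack:
        node, done = stack.pop()
        if children[node, 0] < 0:
            leaf_pos[node] = pos
            node_lo[node] = node_hi[node] = pos
            node_size[node] = 1
            pos += 1
            continue
        if done:
            a, b = children[node]
            node_lo[node] = min(node_lo[a], node_lo[b])
            node_hi[node] = max(node_hi[a], node_hi[b])
            node_size[node] = node_size[a] + node_size[b]
        else:
            stack.append((node, True))
            stack.append((int(children[node, 1]), False))
            stack.append((int(children[node, 0]), False))
    return Topology(n, children, node_lo, node_hi, node_size,
                    k_start, k_end, leaf_pos, seg, seg_off)


def sample_intervals(n: int, alpha: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Coalescent interval durations T_1..T_n (index k-1 holds T_k).

    T_k ~ Exp(rate k(k-1)/2) independently for k >= 2; the stem T_1 is set
    deterministically so that T_1 / sum(T) = alpha.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    k = np.arange(2, n + 1)
    T = np.empty(n)
    T[1:] = rng.exponential(scale=2.0 / (k * (k - 1)))
    T[0] = alpha / (1.0 - alpha) * T[1:].sum()
    return T


@dataclass
class GenealogySample:
    """One simulated genealogy: topology plus interval durations."""

    topology: Topology
    intervals: np.ndarray  # T_1..T_n

    @property
    def n(self) -> int:
        return self.topology.n

    @property
    def alpha(self) -> float:
        return float(self.intervals[0] / self.intervals.sum())

    def branch_leafsets(self) -> list[frozenset[int]]:
        """Leaf set below every node (lineage), root last."""
        t = self.topology
        return [frozenset(map(int, t.leaves_below(u)))
                for u in range(2 * self.n - 1)]


def sample_genealogy(n: int, alpha: float,
                     rng: np.random.Generator) -> GenealogySample:
    return GenealogySample(sample_topology(n, rng),
                           sample_intervals(n, alpha, rng))


# ---------------------------------------------------------------------------
# Mutation placement
# ---------------------------------------------------------------------------

def _sample_mutations(g: GenealogySample, size: int,
                      rng: np.random.Generator):
    """Drop ``size`` mutations branch-length-uniformly on the genealogy.

    Returns (node ids, time keys); time keys order mutations chronologically
    within one lineage chain (interval index + uniform offset).
    """
    t = g.topology
    n = g.n
    w = np.arange(1, n + 1) * g.intervals  # total length of interval k
    cw = np.cumsum(w)
    k = np.searchsorted(cw, rng.random(size) * cw[-1], side="right") + 1
    k = np.minimum(k, n)
    idx = np.minimum((rng.random(size) * k).astype(np.int64), k - 1)
    nodes = t.seg_nodes[t.seg_off[k - 1] + idx]
    tkey = k + rng.random(size)
    return nodes, tkey


def _pair_relations(t: Topology, xn, yn, tx, ty):
    """Vectorized relation of mutation pairs given their lineage nodes.

    Leaf ranges of two nodes are nested (ancestral relation) or disjoint
    (independent); equal ranges mean the same lineage segment, ordered by
    the time keys.
    """
    lo, hi = t.node_lo, t.node_hi
    x_anc = (lo[xn] <= lo[yn]) & (hi[yn] <= hi[xn])
    y_anc = (lo[yn] <= lo[xn]) & (hi[xn] <= hi[yn])
    same = x_anc & y_anc
    forward = (x_anc & ~same) | (same & (tx < ty))
    rel = np.where(x_anc | y_anc,
                   np.where(forward, int(OrderRelation.FORWARD),
                            int(OrderRelation.BACKWARD)),
                   int(OrderRelation.INDEPENDENT))
    return rel


def place_mutation_pair(g: GenealogySample, rng: np.random.Generator):
    """Place one (x, y) mutation pair; return its relation and leaf genotypes.

    The leaf genotype pair of cell l is (1 if l descends from x's lineage
    else 0, likewise for y). Returns ``(OrderRelation, ndarray (n, 2))``.
    """
    t = g.topology
    (xn, yn), (tx, ty) = _sample_mutations(g, 2, rng)
    rel = OrderRelation(int(_pair_relations(t, np.array([xn]), np.array([yn]),
                                            np.array([tx]), np.array([ty]))[0]))
    geno = np.zeros((g.n, 2), dtype=np.int8)
    geno[t.leaves_below(int(xn)), 0] = 1
    geno[t.leaves_below(int(yn)), 1] = 1
    return rel, geno


# ---------------------------------------------------------------------------
# Prior estimation
# ---------------------------------------------------------------------------

@dataclass
class PriorTable:
    """Monte-Carlo prior for one (n, alpha).

    order_prior : (3,) probabilities indexed by OrderRelation; the two
        directed relations are equal by construction.
    cond_genotype : (3, 2, 2) ``cond_genotype[rel][i', j']`` = probability
        a random cell's true genotype pair is (i', j') given the relation.
    """

    order_prior: np.ndarray
    cond_genotype: np.ndarray
    config: CoalescentConfig
    mc_counts: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        obj = {
            "config": {"n": self.config.n, "alpha": self.config.alpha,
                       "b_tree": self.config.b_tree,
                       "b_mut": self.config.b_mut, "seed": self.config.seed},
            "order_prior": self.order_prior.tolist(),
            "cond_genotype": self.cond_genotype.tolist(),
            "mc_counts": self.mc_counts,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "PriorTable":
        try:
            obj = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                obj = json.load(fh)
        return cls(np.array(obj["order_prior"]),
                   np.array(obj["cond_genotype"]),
                   CoalescentConfig(**obj["config"]),
                   obj.get("mc_counts", {}))


def estimate_priors(cfg: CoalescentConfig) -> PriorTable:
    """Tally order relations and true genotype pairs over the MC ensemble.

    Per genealogy, ``b_mut`` mutation pairs are placed; every pair
    contributes one relation tally and ``n`` per-leaf genotype tallies.
    Ancestral ("same lineage") draws are pooled and split evenly between
    the two directions, so the directed priors are exactly equal and the
    backward conditional genotype table is the exact transpose of the
    forward one.
    """
    rng = np.random.default_rng(cfg.seed)
    n, b_mut = cfg.n, cfg.b_mut
    cnt_same = 0
    cnt_ind = 0
    # forward-oriented (ancestor = x) per-leaf tallies for ancestral pairs
    anc_11 = anc_10 = anc_00 = 0
    ind_mut = ind_00 = 0  # independent: single-carrier and no-carrier leaves
    for _ in range(cfg.b_tree):
        g = sample_genealogy(n, cfg.alpha, rng)
        t = g.topology
        xn, tx = _sample_mutations(g, b_mut, rng)
        yn, ty = _sample_mutations(g, b_mut, rng)
        rel = _pair_relations(t, xn, yn, tx, ty)
        sx = t.node_size[xn]
        sy = t.node_size[yn]
        ind = rel == int(OrderRelation.INDEPENDENT)
        fwd = rel == int(OrderRelation.FORWARD)
        nested = ~ind
        cnt_ind += int(ind.sum())
        cnt_same += int(nested.sum())
        s_anc = np.where(fwd, sx, sy)[nested]
        s_desc = np.where(fwd, sy, sx)[nested]
        anc_11 += int(s_desc.sum())
        anc_10 += int((s_anc - s_desc).sum())
        anc_00 += int((n - s_anc).sum())
        ind_mut += int((sx[ind] + sy[ind]).sum())
        ind_00 += int((n - sx[ind] - sy[ind]).sum())

    total = cfg.b_tree * b_mut
    p_fwd = 0.5 * cnt_same / total
    order_prior = np.array([p_fwd, p_fwd, 1.0 - 2.0 * p_fwd])

    cond = np.zeros((3, 2, 2))
    if cnt_same:
        denom = n * cnt_same
        cond[OrderRelation.FORWARD] = [[anc_00 / denom, 0.0],
                                       [anc_10 / denom, anc_11 / denom]]
        cond[OrderRelation.BACKWARD] = cond[OrderRelation.FORWARD].T
    if cnt_ind:
        denom = n * cnt_ind
        half = 0.5 * ind_mut / denom
        cond[OrderRelation.INDEPENDENT] = [[ind_00 / denom, half],
                                           [half, 0.0]]
    counts = {"n_pairs": total, "n_same_lineage": cnt_same,
              "n_independent": cnt_ind}
    return PriorTable(order_prior, cond, cfg, counts)


# Leave-one-out and grid tuning reuse identical (n, alpha) tables heavily.
_PRIOR_CACHE: dict[CoalescentConfig, PriorTable] = {}


def get_prior(cfg: CoalescentConfig) -> PriorTable:
    """Cached :func:`estimate_priors` keyed on the full configuration."""
    tab = _PRIOR_CACHE.get(cfg)
    if tab is None:
        tab = _PRIOR_CACHE[cfg] = estimate_priors(cfg)
    return tab
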