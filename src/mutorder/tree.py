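"""Mutation tree extraction from pairwise order posteriors.

Every site pair classified as directed contributes one edge x -> y with
weight -log P(x -> y | D); independent pairs contribute no edge. The
maximum-posterior mutation tree is the minimum-weight spanning
arborescence of this digraph (Chu-Liu/Edmonds), since total weight
minimization is posterior-product maximization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx

from .alpha import fit_alpha
from .errors import ErrorRates
from .genotypes import GenotypeMatrix, mutation_rate
from .posterior import PosteriorMatrix, classify_all_pairs
from .prior import CoalescentConfig, OrderRelation, PriorTable, get_prior


def build_digraph(pm: PosteriorMatrix) -> nx.DiGraph:
    """Directed order graph: one edge per pair whose MAP relation is directed.

    Edge x -> y carries weight -log P(x -> y | D) >= 0. Unclassifiable
    pairs and independent pairs contribute no edge.
    """
    g = nx.DiGraph()
    g.add_nodes_from(pm.site_labels)
    for _, _, r in pm.iter_canonical():
        if r.map_relation is OrderRelation.FORWARD:
            src, dst, p = r.x, r.y, float(r.posterior[OrderRelation.FORWARD])
        elif r.map_relation is OrderRelation.BACKWARD:
            src, dst, p = r.y, r.x, float(r.posterior[OrderRelation.BACKWARD])
        else:
            continue
        g.add_edge(src, dst, weight=-math.log(p), posterior=p)
    return g


def cycle_diagnostic(g: nx.DiGraph, limit: int = 50) -> list[list[str]]:
    """Directed cycles in the raw order graph (error-induced circular
    order relations); diagnostic only, capped at ``limit`` cycles."""
    out = []
    for cyc in nx.simple_cycles(g):
        out.append(cyc)
        if len(out) >= limit:
            break
    return out


@dataclass
class MutationTree:
    """Rooted arborescence over mutation sites."""

    root: str | None
    branches: list[tuple[str, str, float]]  # (parent, child, weight)
    excluded_sites: list[str] = field(default_factory=list)

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.branches))

    @property
    def nodes(self) -> list[str]:
        ns = {self.root} if self.root is not None else set()
        for p, c, _ in self.branches:
            ns.update((p, c))
        return sorted(ns)

    def children(self, node: str) -> list[str]:
        return sorted(c for p, c, _ in self.branches if p == node)

    @property
    def leaves(self) -> list[str]:
        parents = {p for p, _, _ in self.branches}
        return sorted(n for n in self.nodes if n not in parents)

    @property
    def internal_nodes(self) -> list[str]:
        """Non-root nodes that have children."""
        parents = {p for p, _, _ in self.branches}
        return sorted(n for n in parents if n != self.root)

    @property
    def branch_set(self) -> set[tuple[str, str]]:
        return {(p, c) for p, c, _ in self.branches}

    def to_json(self, path=None) -> str:
        text = json.dumps({
            "root": self.root,
            "branches": [{"parent": p, "child": c, "weight": w}
                         for p, c, w in self.branches],
            "total_weight": self.total_weight,
            "excluded_sites": self.excluded_sites,
        }, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("parent\tchild\tweight\n")
            for p, c, w in self.branches:
                fh.write(f"{p}\t{c}\t{w!r}\n")

    def to_dot(self, path=None, m: GenotypeMatrix | None = None,
               branch_labels: dict | None = None) -> str:
        """Graphviz DOT rendering; node labels carry mutation rates when a
        genotype matrix is supplied."""
        lines = ["digraph mutation_tree {", "  node [shape=box];"]
        for n in self.nodes:
            label = n
            if m is not None:
                label = f"{n}\\n{mutation_rate(m, n):.3f}"
            lines.append(f'  "{n}" [label="{label}"];')
        for p, c, w in self.branches:
            extra = ""
            if branch_labels and (p, c) in branch_labels:
                extra = f" ({branch_labels[(p, c)]})"
            lines.append(f'  "{p}" -> "{c}" [label="{w:.2f}{extra}"];')
        lines.append("}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _tree_from_branching(arb: nx.DiGraph, excluded: list[str]) -> MutationTree:
    roots = [n for n in arb.nodes if arb.in_degree(n) == 0]
    if len(roots) != 1:
        raise RuntimeError(f"arborescence has {len(roots)} roots")
    branches = sorted((p, c, float(d["weight"]))
                      for p, c, d in arb.edges(data=True))
    return MutationTree(roots[0], branches, sorted(excluded))


def min_arborescence(g: nx.DiGraph) -> MutationTree:
    """Minimum-total-weight spanning arborescence of the order digraph.

    Equivalent to trying every node as root and keeping the cheapest
    rooted spanning tree; with -log-posterior weights this is the
    maximum-posterior mutation tree. If no node reaches every other
    (graphs with many independent calls can disconnect), the arborescence
    is built over the largest root-reachable node set and the remaining
    sites are flagged as excluded.
    """
    if g.number_of_nodes() == 0:
        return MutationTree(None, [])
    if g.number_of_nodes() == 1:
        return MutationTree(next(iter(g.nodes)), [])
    reach = {n: {n} | nx.descendants(g, n) for n in g.nodes}
    best_cover = max(len(s) for s in reach.values())
    if best_cover == 1:
        # edgeless graph: a flagged empty tree rooted at the first site
        nodes = sorted(g.nodes)
        return MutationTree(nodes[0], [], excluded_sites=nodes[1:])
    if best_cover == g.number_of_nodes():
        sub, excluded = g, []
    else:
        root = min(n for n, s in reach.items() if len(s) == best_cover)
        sub = g.subgraph(reach[root]).copy()
        excluded = [n for n in g.nodes if n not in reach[root]]
    arb = nx.algorithms.tree.branchings.minimum_spanning_arborescence(
        sub, attr="weight", preserve_attrs=True)
    return _tree_from_branching(arb, excluded)


@dataclass
class PipelineResult:
    prior: PriorTable
    posteriors: PosteriorMatrix
    digraph: nx.DiGraph
    tree: MutationTree
    alpha_fit: object | None = None


def full_pipeline(m: GenotypeMatrix, e: ErrorRates | None = None,
                  alpha: float | None = None, b_tree: int = 1000,
                  b_mut: int = 10000, seed: int = 0,
                  tuning_matrix: GenotypeMatrix | None = None,
                  ) -> PipelineResult:
    """Priors at (n, alpha) -> pair posteriors -> digraph -> arborescence.

    When ``alpha`` is None it is first fitted by empirical Bayes on
    ``tuning_matrix`` (default: ``m`` itself). Deterministic given seed.
    """
    e = ErrorRates() if e is None else e
    fit = None
    if alpha is None:
        fit = fit_alpha(tuning_matrix if tuning_matrix is not None else m,
                        e=e, b_tree=b_tree, b_mut=b_mut, seed=seed)
        alpha = fit.alpha_hat
    prior = get_prior(CoalescentConfig(m.n_samples, float(alpha),
                                       b_tree, b_mut, seed))
    pm = classify_all_pairs(m, prior, e)
    g = build_digraph(pm)
    tree = min_arborescence(g)
    return PipelineResult(prior, pm, g, tree, fit)
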