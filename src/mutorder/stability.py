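"""Leave-one-out stability of the inferred mutation tree.

Replicates rerun the classification with one cell (or one site) removed
and tally how often the full-data tree's root and branches recur. The
coalescent prior depends only on the number of cells, so all sample-LOO
replicates share a single prior table estimated at n-1 leaves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import ErrorRates
from .genotypes import GenotypeMatrix
from .posterior import classify_all_pairs
from .prior import CoalescentConfig, get_prior
from .tree import MutationTree, build_digraph, min_arborescence


@dataclass
class StabilityReport:
    n_replicates: int
    root_counts: dict[str, int]
    branch_counts: dict[tuple[str, str], int]  # keyed by full-tree branch
    full_tree: MutationTree
    failures: list[str] = field(default_factory=list)

    @property
    def min_branch_recovery(self) -> int:
        return min(self.branch_counts.values()) if self.branch_counts else 0

    def to_json(self, path=None) -> str:
        text = json.dumps({
            "n_replicates": self.n_replicates,
            "root_counts": self.root_counts,
            "branch_counts": {f"{p}->{c}": v
                              for (p, c), v in self.branch_counts.items()},
            "failures": self.failures,
        }, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\titem\tcount\n")
            for site, v in sorted(self.root_counts.items()):
                fh.write(f"root\t{site}\t{v}\n")
            for (p, c), v in sorted(self.branch_counts.items()):
                fh.write(f"branch\t{p}->{c}\t{v}\n")


def _tally(report: StabilityReport, tree: MutationTree) -> None:
    if tree.root is not None:
        report.root_counts[tree.root] = \
            report.root_counts.get(tree.root, 0) + 1
    got = tree.branch_set
    for br in report.branch_counts:
        if br in got:
            report.branch_counts[br] += 1


def loo_samples(m: GenotypeMatrix, e: ErrorRates | None = None,
                alpha: float = 0.92, b_tree: int = 1000,
                b_mut: int = 10000, seed: int = 0,
                full_tree: MutationTree | None = None) -> StabilityReport:
    """One replicate per omitted cell, tallied against the full-data tree.

    ``full_tree`` may be passed in when the full pipeline has already run
    (it must come from the same settings); otherwise it is recomputed.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 cells for leave-one-out")
    e = ErrorRates() if e is None else e
    if full_tree is None:
        prior_full = get_prior(CoalescentConfig(m.n_samples, alpha,
                                                b_tree, b_mut, seed))
        full_tree = min_arborescence(
            build_digraph(classify_all_pairs(m, prior_full, e)))
    prior_loo = get_prior(CoalescentConfig(m.n_samples - 1, alpha,
                                           b_tree, b_mut, seed))
    report = StabilityReport(m.n_samples, {},
                             {br: 0 for br in full_tree.branch_set},
                             full_tree)
    for k in range(m.n_samples):
        try:
            sub = m.drop_sample(k)
            tree = min_arborescence(
                build_digraph(classify_all_pairs(sub, prior_loo, e)))
        except Exception as err:  # record, do not abort the replication
            report.failures.append(f"sample {m.sample_ids[k]}: {err}")
            continue
        _tally(report, tree)
    return report


def loo_sites(m: GenotypeMatrix, e: ErrorRates | None = None,
              alpha: float = 0.92, b_tree: int = 1000,
              b_mut: int = 10000, seed: int = 0,
              full_tree: MutationTree | None = None) -> StabilityReport:
    """One replicate per omitted site; branch recovery is tallied over
    full-tree branches not incident to the dropped site."""
    if m.n_sites < 3:
        raise ValueError("need at least 3 sites for leave-one-out")
    e = ErrorRates() if e is None else e
    prior = get_prior(CoalescentConfig(m.n_samples, alpha,
                                       b_tree, b_mut, seed))
    if full_tree is None:
        full_tree = min_arborescence(
            build_digraph(classify_all_pairs(m, prior, e)))
    report = StabilityReport(m.n_sites, {},
                             {br: 0 for br in full_tree.branch_set},
                             full_tree)
    for s, label in enumerate(m.site_labels):
        try:
            sub = m.drop_site(s)
            tree = min_arborescence(
                build_digraph(classify_all_pairs(sub, prior, e)))
        except Exception as err:
            report.failures.append(f"site {label}: {err}")
            continue
        if tree.root is not None:
            report.root_counts[tree.root] = \
                report.root_counts.get(tree.root, 0) + 1
        got = tree.branch_set
        for br in report.branch_counts:
            if label in br:
                continue  # branch incident to the dropped site
            if br in got:
                report.branch_counts[br] += 1
    return report
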