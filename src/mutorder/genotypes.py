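"""Genotype matrices of mutation sites by single cells.

Calls are integer-coded: 0 homozygous wildtype, 1 heterozygous mutation,
2 homozygous mutation. Missing calls (entries failing the upstream quality
criteria) are a distinct sentinel, never conflated with 0.

The packaged fixture is the 18-site x 58-cell essential-thrombocythemia
genotype table (single-cell exome sequencing, MDA-amplified), transcribed
from the published version of the dataset.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: Sentinel for a missing (quality-filtered) genotype call.
MISSING: int = -1

_VALID = frozenset({MISSING, 0, 1, 2})


@dataclass
class GenotypeMatrix:
    """Observed genotype calls for S mutation sites across n single cells.

    Attributes
    ----------
    site_labels : list of str
        Unique site identifiers, conventionally gene name plus base
        substitution, e.g. ``"DLEC1(T>C)"``.
    sample_ids : list of str
        Unique cell identifiers.
    calls : ndarray of shape (S, n), dtype int8
        Entries in {0, 1, 2, MISSING}.
    """

    site_labels: list[str]
    sample_ids: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array of sites x cells")
        if self.calls.shape != (len(self.site_labels), len(self.sample_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.site_labels)} sites x {len(self.sample_ids)} samples"
            )
        if len(set(self.site_labels)) != len(self.site_labels):
            raise ValueError("duplicate site labels")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype {self.calls[r, c]} at site "
                f"{self.site_labels[r]!r}, sample {self.sample_ids[c]!r}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def site_index(self, site: int | str) -> int:
        if isinstance(site, str):
            try:
                return self.site_labels.index(site)
            except ValueError:
                raise KeyError(f"unknown site {site!r}") from None
        return int(site)

    def drop_sample(self, k: int) -> "GenotypeMatrix":
        """Matrix with the k-th cell removed (leave-one-out replicate)."""
        ids = self.sample_ids[:k] + self.sample_ids[k + 1:]
        return GenotypeMatrix(list(self.site_labels), ids,
                              np.delete(self.calls, k, axis=1))

    def drop_site(self, s: int | str) -> "GenotypeMatrix":
        s = self.site_index(s)
        labels = self.site_labels[:s] + self.site_labels[s + 1:]
        return GenotypeMatrix(labels, list(self.sample_ids),
                              np.delete(self.calls, s, axis=0))


def read_matrix(path, *, rows: str = "sites", missing_token: str = "-",
                sep: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from tab- or comma-separated text.

    First row holds sample IDs, first column site labels (or the transpose
    with ``rows="cells"``). Unparseable tokens are reported with their
    row/column coordinates.
    """
    if rows not in ("sites", "cells"):
        raise ValueError(f"rows must be 'sites' or 'cells', got {rows!r}")
    with open(path) as fh:
        head = fh.readline()
    if sep is None:
        sep = "\t" if "\t" in head else ","
    header = [t.strip() for t in head.rstrip("\n").split(sep)[1:]]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate labels in header row")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    if df.size == 0:
        raise ValueError(f"{path}: empty genotype matrix")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate labels in first column")
    if rows == "cells":
        df = df.T
    site_labels = [str(s) for s in df.index]
    sample_ids = [str(s) for s in df.columns]
    calls = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for r in range(df.shape[0]):
        for c in range(df.shape[1]):
            tok = raw[r, c].strip()
            if tok == missing_token:
                calls[r, c] = MISSING
            elif tok in ("0", "1", "2"):
                calls[r, c] = int(tok)
            else:
                raise ValueError(
                    f"{path}: unparseable genotype {tok!r} at site "
                    f"{site_labels[r]!r}, sample {sample_ids[c]!r}"
                )
    return GenotypeMatrix(site_labels, sample_ids, calls)


def write_matrix(m: GenotypeMatrix, path, *, missing_token: str = "-",
                 sep: str = "\t") -> None:
    """Write ``m`` in the same dialect :func:`read_matrix` accepts."""
    with open(path, "w") as fh:
        fh.write("site" + sep + sep.join(m.sample_ids) + "\n")
        for r, label in enumerate(m.site_labels):
            toks = [missing_token if v == MISSING else str(v)
                    for v in m.calls[r]]
            fh.write(label + sep + sep.join(toks) + "\n")


def fixture_table1() -> GenotypeMatrix:
    """The packaged 18-site x 58-cell genotype table.

    Transcribed from the published table of the essential-thrombocythemia
    single-cell study; the transcription may differ from the journal
    original by single cells (per-site hand tallies of the two extreme
    mutation rates give 0.857/0.100 against the printed 0.864/0.122).
    """
    text = (resources.files("mutorder") / "data" / "hou2012_et_18sites.tsv").read_text()
    return _read_matrix_text(text)


def _read_matrix_text(text: str, *, missing_token: str = "-") -> GenotypeMatrix:
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    calls = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for r in range(df.shape[0]):
        for c in range(df.shape[1]):
            tok = raw[r, c].strip()
            calls[r, c] = MISSING if tok == missing_token else int(tok)
    return GenotypeMatrix([str(s) for s in df.index],
                          [str(s) for s in df.columns], calls)


def missing_count(m: GenotypeMatrix) -> int:
    """Number of missing entries in the matrix."""
    return int((m.calls == MISSING).sum())


def mutation_rate(m: GenotypeMatrix, site: int | str) -> float:
    """Mutated fraction among non-missing calls at one site.

    Both heterozygous (1) and homozygous (2) calls count as mutated.
    """
    row = m.calls[m.site_index(site)]
    obs = row != MISSING
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError(f"site {site!r} has no observed calls; "
                         "mutation rate undefined")
    return float((row[obs] > 0).sum() / n_obs)


def site_summaries(m: GenotypeMatrix) -> list[dict]:
    """Per-site observation and mutation tallies, JSON-serializable."""
    out = []
    for s, label in enumerate(m.site_labels):
        row = m.calls[s]
        obs = row != MISSING
        rec = {
            "site": label,
            "n_observed": int(obs.sum()),
            "n_missing": int((~obs).sum()),
            "n_het": int((row == 1).sum()),
            "n_hom": int((row == 2).sum()),
        }
        rec["mutation_rate"] = (
            (rec["n_het"] + rec["n_hom"]) / rec["n_observed"]
            if rec["n_observed"] else None
        )
        out.append(rec)
    return out


def write_site_summaries(m: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        json.dump(site_summaries(m), fh, indent=1)
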