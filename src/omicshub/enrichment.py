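"""Hypergeometric over-representation of a gene list against GMT sets.

A light-weight pathway/GO stand-in: for each user-supplied gene set the
upper-tail hypergeometric probability of observing at least the query's
overlap is computed against a background universe (defaulting, in the
pipeline, to all genes on the expression matrix rather than the genome),
followed by Benjamini-Hochberg correction across tested terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .differential import bh_adjust


@dataclass
class GeneSetCollection:
    """term_id -> (term_name, frozenset of member gene ids)."""

    sets: dict[str, tuple[str, frozenset]]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line, term id, description, then members.

    Member ids are upper-cased and whitespace-trimmed; terms with no
    members are dropped with a warning; a duplicated term id is an error.
    """
    sets: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (need term and description)")
            term, desc = parts[0].strip(), parts[1].strip()
            if not term:
                raise ValueError(f"{path}:{lineno}: empty term id")
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term!r}")
            members = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            if not members:
                warnings.warn(f"{path}:{lineno}: term {term!r} has no members; dropped")
                continue
            sets[term] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection:
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def enrich(
    query: set,
    background: set,
    collection: GeneSetCollection,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Over-represented terms at BH-adjusted P < p_max, sorted ascending.

    For a term with m members in the background, the P value is the
    hypergeometric upper tail of drawing >= k term members in |query|
    draws from the background without replacement. Terms with zero
    overlap are tested (P = 1) but never reported.
    """
    query = {g.upper() for g in query}
    background = {g.upper() for g in background}
    if not query <= background:
        raise ValueError("query must be a subset of the background universe")
    if not query:
        warnings.warn("empty query gene list; empty enrichment result")
        return _empty_table()
    big_n = len(background)
    n_query = len(query)
    rows = []
    for term, (name, members) in collection:
        in_bg = members & background
        k = len(members & query)
        if len(in_bg) == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, big_n, len(in_bg), n_query))
        rows.append((term, name, k, len(in_bg), n_query, big_n, p))
    if not rows:
        return _empty_table()
    table = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "overlap", "term_size", "query_size", "background_size", "p"],
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    hits = table[(table["p_adj"] < p_max) & (table["overlap"] > 0)]
    return hits.sort_values(["p_adj", "p", "term_id"]).reset_index(drop=True)


def empty_result() -> pd.DataFrame:
    """An enrichment table with the standard columns and no rows."""
    return pd.DataFrame(
        columns=["term_id", "term_name", "overlap", "term_size", "query_size", "background_size", "p", "p_adj"]
    )


_empty_table = empty_result
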