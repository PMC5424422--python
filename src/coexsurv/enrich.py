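"""Gene-set overrepresentation analysis.

A generic hypergeometric upper-tail test of a query gene list (e.g. one
co-expression module) against a user-supplied GMT collection and background
universe, with Benjamini–Hochberg FDR across sets and −log10(p) scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survassoc import benjamini_hochberg


@dataclass
class GeneSetCollection:
    """Named gene sets (deduplicated member symbols) with descriptions."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (set name, description, tab-separated members).
    Duplicate members within a set are collapsed; a line with fewer than
    3 fields is a hard error naming the line number."""
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno} has {len(fields)} fields (<3)")
            name, desc, *members = fields
            if not [m for m in members if m]:
                raise ValueError(f"GMT line {lineno}: set {name!r} is empty")
            sets[name] = frozenset(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def hypergeometric_enrich(query, collection: GeneSetCollection,
                          universe) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of ``query`` in each
    set of ``collection`` against the background ``universe``.

    p = P(overlap ≥ k) for a draw of |query| genes from the universe; BH
    FDR across sets; score = −log10(p).  The query must be a subset of the
    universe; set members outside the universe are ignored for counting.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    stray = query - universe
    if stray:
        raise ValueError(f"query gene not in universe: {sorted(stray)[0]!r}")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for name, members in collection.sets.items():
        in_universe = members & universe
        k = len(query & in_universe)
        set_size = len(in_universe)
        # P(X >= k), X ~ Hypergeom(N=universe, K=set, n=query)
        p = float(stats.hypergeom.sf(k - 1, n_universe, set_size, n_query))
        p = min(p, 1.0)
        rows.append({"set": name, "overlap": k, "set_size": set_size,
                     "p": p})
    out = pd.DataFrame(rows)
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
    out["neg_log10_p"] = -np.log10(out["p"])
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
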