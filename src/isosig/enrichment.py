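"""Gene-set over-representation and the cross-level counting rule.

Over-representation uses the upper-tail hypergeometric probability of
drawing the observed-or-larger overlap between a query gene list and a
gene set out of a finite universe.  The counting rule selects pathways
whose raw P is below alpha in *all* comparisons at one analysis level
while being >= alpha in *all* comparisons at the other level — pathways
visible only to isoform-level (or only to gene-level) signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .errors import DataError, ValidationError

LEVEL_NAMES = ("isoform", "gene")


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, set[str]] = field(repr=False)
    descriptions: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, set[str]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise DataError(f"malformed GMT line: {line[:60]!r}")
                name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
                if name in sets:
                    raise DataError(f"duplicate gene-set name {name!r}")
                sets[name] = set(members)
                descriptions[name] = desc
        return cls(sets, descriptions)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def hypergeom_test(query: set[str], target: set[str], universe: set[str]) -> dict:
    """Upper-tail hypergeometric over-representation of query in target.

    P = P(X >= overlap) with X ~ Hypergeom(N=|universe|, K=|target|,
    n=|query|).  Query and target must be subsets of the universe.
    """
    if not universe:
        raise ValidationError("empty universe")
    if not query <= universe or not target <= universe:
        raise ValidationError("query and target must be subsets of the universe")
    overlap = len(query & target)
    N, K, n = len(universe), len(target), len(query)
    p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
    return {
        "overlap": overlap,
        "set_size": K,
        "query_size": n,
        "universe_size": N,
        "p": min(max(p, 0.0), 1.0),
    }


def enrich_collection(
    query: Iterable[str], collection: GeneSetCollection, universe: Iterable[str]
) -> pd.DataFrame:
    """Hypergeometric test per gene set; rows sorted by P (raw, unadjusted)."""
    universe = set(universe)
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe dropped", stacklevel=2)
        query &= universe
    rows = []
    for name, members in collection.sets.items():
        row = hypergeom_test(query, members & universe, universe)
        row["set_name"] = name
        rows.append(row)
    df = pd.DataFrame(rows).set_index("set_name")
    return df.sort_values("p", kind="stable")


def counting_select(
    p_tables: Mapping[str, Mapping[str, Mapping[str, float]]], alpha: float = 0.05
) -> dict[str, list[str]]:
    """Cross-level discordant pathway selection on raw P values.

    ``p_tables[comparison][level][set_name]`` holds the raw enrichment P
    for each comparison and analysis level ("isoform" / "gene").  A
    pathway is isoform-discordant iff P < alpha at isoform level in all
    comparisons AND P >= alpha at gene level in all comparisons; the
    gene-discordant rule is symmetric.
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    if not p_tables:
        raise ValidationError("no comparisons supplied")
    name_sets = []
    for comp, levels in p_tables.items():
        for level in LEVEL_NAMES:
            if level not in levels:
                raise ValidationError(f"comparison {comp!r} missing level {level!r}")
            name_sets.append(frozenset(levels[level]))
    if len(set(name_sets)) != 1:
        raise ValidationError("gene-set collections differ across comparisons/levels")
    pathways = sorted(name_sets[0])
    out: dict[str, list[str]] = {"isoform": [], "gene": []}
    for pw in pathways:
        iso_all_sig = all(p_tables[c]["isoform"][pw] < alpha for c in p_tables)
        iso_all_ns = all(p_tables[c]["isoform"][pw] >= alpha for c in p_tables)
        gene_all_sig = all(p_tables[c]["gene"][pw] < alpha for c in p_tables)
        gene_all_ns = all(p_tables[c]["gene"][pw] >= alpha for c in p_tables)
        if iso_all_sig and gene_all_ns:
            out["isoform"].append(pw)
        if gene_all_sig and iso_all_ns:
            out["gene"].append(pw)
    return out
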