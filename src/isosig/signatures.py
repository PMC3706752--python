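"""Two-level gene classification and multi-comparison core sets.

A gene is differentially expressed at isoform level if at least one of
its isoforms is significant; it is counted once however many isoforms
are significant.  Genes with at least one significantly up- and one
significantly down-regulated isoform are flagged *opposing*: their
summed gene-level signal tends to cancel, which is exactly why they are
invisible to gene-level testing.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .matrix import AnnotationMap

CATEGORIES = ("both", "gene_only", "isoform_only", "neither")


def detect_opposing(iso_calls: pd.DataFrame, ann: AnnotationMap) -> set[str]:
    """Genes with >= 1 significant up AND >= 1 significant down isoform."""
    _require_calls(iso_calls)
    sig = iso_calls[iso_calls["significant"]]
    if sig.empty:
        return set()
    ann.check_covers(sig.index)
    genes = ann.mapping.reindex(sig.index)
    up = set(genes[sig["direction"] == "up"])
    down = set(genes[sig["direction"] == "down"])
    return up & down


def classify_genes(
    gene_calls: pd.DataFrame, iso_calls: pd.DataFrame, ann: AnnotationMap
) -> pd.DataFrame:
    """Combine gene- and isoform-level calls into per-gene categories.

    Returns a frame indexed by gene id with columns: ``gene_sig``,
    ``gene_direction``, ``iso_sig``, ``iso_directions`` (``up``, ``down``
    or ``up|down``), ``category`` (both / gene_only / isoform_only /
    neither), ``opposing`` and ``sig_isoforms`` (comma-joined ids).
    """
    _require_calls(gene_calls)
    _require_calls(iso_calls)
    ann.check_covers(iso_calls.index)

    iso_gene = ann.mapping.reindex(iso_calls.index)
    genes = sorted(set(gene_calls.index) | set(iso_gene))

    sig_iso = iso_calls[iso_calls["significant"]]
    sig_by_gene: dict[str, list[str]] = {}
    dirs_by_gene: dict[str, set[str]] = {}
    for iso_id, row in sig_iso.iterrows():
        g = iso_gene[iso_id]
        sig_by_gene.setdefault(g, []).append(iso_id)
        dirs_by_gene.setdefault(g, set()).add(row["direction"])

    rows = []
    for g in genes:
        g_sig = bool(gene_calls["significant"].get(g, False))
        g_dir = gene_calls["direction"].get(g, "none") if g_sig else "none"
        isoforms = sig_by_gene.get(g, [])
        dirs = dirs_by_gene.get(g, set())
        i_sig = len(isoforms) > 0
        opposing = {"up", "down"} <= dirs
        if g_sig and i_sig:
            category = "both"
        elif g_sig:
            category = "gene_only"
        elif i_sig:
            category = "isoform_only"
        else:
            category = "neither"
        rows.append(
            {
                "gene_id": g,
                "gene_sig": g_sig,
                "gene_direction": g_dir,
                "iso_sig": i_sig,
                "iso_directions": "|".join(sorted(dirs)),
                "category": category,
                "opposing": opposing,
                "sig_isoforms": ",".join(sorted(isoforms)),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def core_intersection(calls_by_comparison: Mapping[str, pd.DataFrame]) -> dict[str, set[str]]:
    """Features significant with the same direction in every comparison.

    Returns ``{"up": set, "down": set}``.  Comparisons with different
    feature universes are intersected with a warning.
    """
    if len(calls_by_comparison) < 2:
        raise ValidationError("core intersection needs >= 2 comparisons")
    universes = [set(c.index) for c in calls_by_comparison.values()]
    shared = set.intersection(*universes)
    if any(u != shared for u in universes):
        warnings.warn("feature universes differ across comparisons; using their intersection",
                      stacklevel=2)
    core: dict[str, set[str]] = {}
    for direction in ("up", "down"):
        sets = [
            set(c.index[(c["significant"]) & (c["direction"] == direction)]) & shared
            for c in calls_by_comparison.values()
        ]
        core[direction] = set.intersection(*sets)
    return core


def gene_direction_sets(
    classification: pd.DataFrame, opposing_in_both: bool = True
) -> dict[str, set[str]]:
    """Per-direction gene sets at isoform level from a classification.

    Opposing genes belong to both the up and the down set when
    ``opposing_in_both`` (the tally convention used here by default);
    otherwise each gene contributes only the directions listed.
    """
    up, down = set(), set()
    for g, row in classification.iterrows():
        dirs = set(row["iso_directions"].split("|")) if row["iso_directions"] else set()
        if not opposing_in_both and row["opposing"]:
            continue  # caller resolves via dominant direction separately
        if "up" in dirs:
            up.add(g)
        if "down" in dirs:
            down.add(g)
    return {"up": up, "down": down}


def venn_counts(sets_by_name: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts of a Venn diagram over named sets.

    Keys are sorted tuples of the set names a region belongs to; every
    element is counted in exactly one region, so the counts sum to the
    size of the union.
    """
    names = sorted(sets_by_name)
    if not names:
        raise ValidationError("venn_counts needs at least one set")
    union = set().union(*sets_by_name.values())
    counts: dict[tuple[str, ...], int] = {}
    for el in union:
        region = tuple(n for n in names if el in sets_by_name[n])
        counts[region] = counts.get(region, 0) + 1
    return counts


def _require_calls(df: pd.DataFrame) -> None:
    for col in ("significant", "direction"):
        if col not in df.columns:
            raise DataError(f"DE table missing column {col!r}")
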