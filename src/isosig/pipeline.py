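"""End-to-end orchestration: simulate -> normalize -> aggregate -> filter
-> cluster -> two-level DE -> classify -> core sets -> enrichment.

Every stochastic stage takes its seed from :class:`RunConfig`, and every
output file is re-derivable from config + seed: a manifest of SHA-256
hashes is written alongside the artifacts and is byte-identical on
rerun.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import clustering, differential, enrichment, expression, signatures
from .errors import DataError, ValidationError
from .matrix import AnnotationMap, ExpressionMatrix
from .simulate import SyntheticSpec, simulate_dataset


@dataclass
class Comparison:
    """A named case/control contrast over an optional sample subset."""

    name: str
    case: str
    control: str
    samples: list[str] | None = None  # None = all samples with either class


@dataclass
class RunConfig:
    keep_fraction: float = 0.76
    k: int = 2
    linkage: str = "complete"
    n_resamples: int = 200
    sample_frac: float = 0.8
    fc_cut: float = 2.0
    fdr_cut: float = 0.01
    alpha: float = 0.05
    seed: int = 0
    normalize: bool = True
    run_consensus: bool = False
    comparisons: list[Comparison] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.keep_fraction <= 1):
            raise ValidationError("keep_fraction must lie in (0, 1]")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not (0 < self.sample_frac <= 1):
            raise ValidationError("sample_frac must lie in (0, 1]")
        if self.fc_cut < 1:
            raise ValidationError("fc_cut must be >= 1")
        for name in ("fdr_cut", "alpha"):
            if not (0 < getattr(self, name) < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")
        self.comparisons = [
            c if isinstance(c, Comparison) else Comparison(**c) for c in self.comparisons
        ]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def prepare_levels(
    iso_linear: ExpressionMatrix,
    ann: AnnotationMap,
    keep_fraction: float = 0.76,
    normalize: bool = True,
) -> dict[str, ExpressionMatrix]:
    """Produce CV-filtered log2 matrices at both analysis levels."""
    if normalize:
        iso_linear = expression.loess_normalize(iso_linear)
    gene_linear = expression.aggregate_to_gene(iso_linear, ann)
    out = {}
    for level, mat in (("isoform", iso_linear), ("gene", gene_linear)):
        filtered = expression.cv_filter(mat, keep_fraction)
        out[level] = expression.log_transform(filtered)
    return out


def cluster_metrics(
    m_log2: ExpressionMatrix,
    labels: pd.Series,
    k: int = 2,
    linkage: str = "complete",
) -> dict:
    """Hierarchical clustering of one matrix plus purity and silhouette."""
    dist = clustering.euclidean_distances(m_log2)
    dend = clustering.hierarchical_cluster(dist, linkage)
    assignment = clustering.cut_to_k(dend, k)
    purity = clustering.cluster_purity(assignment, labels)
    sil = clustering.silhouette(dist, assignment) if k >= 2 else None
    return {
        "purity": purity,
        "silhouette_mean": None if sil is None else sil.overall_mean,
        "assignment": assignment,
        "dendrogram": dend,
        "distances": dist,
    }


def level_discrimination(
    spec: SyntheticSpec,
    seed: int,
    keep_fraction: float = 0.76,
    k: int = 2,
    linkage: str = "complete",
    normalize: bool = False,
) -> dict:
    """Simulate one synthetic study and score class discrimination at both
    levels.

    Returns isoform/gene purity and mean silhouette width.  Simulated
    matrices are already on a common scale, so normalization defaults to
    off here.
    """
    mat, ann, metadata, _ = simulate_dataset(spec, seed=seed)
    levels = prepare_levels(mat, ann, keep_fraction=keep_fraction, normalize=normalize)
    out = {}
    for level, m_log2 in levels.items():
        res = cluster_metrics(m_log2, metadata["class"], k=k, linkage=linkage)
        out[f"{level}_purity"] = res["purity"]
        out[f"{level}_silhouette"] = res["silhouette_mean"]
    return out


def _comparison_design(
    metadata: pd.DataFrame, comparison: Comparison
) -> tuple[differential.GroupDesign, pd.DataFrame]:
    meta = metadata if comparison.samples is None else metadata.loc[comparison.samples]
    present = set(meta["class"].unique())
    if not {comparison.case, comparison.control} <= present:
        raise DataError(
            f"comparison {comparison.name!r} subset lacks one of the classes "
            f"({comparison.case!r} vs {comparison.control!r})"
        )
    meta = meta[meta["class"].isin([comparison.case, comparison.control])]
    design = differential.GroupDesign.from_metadata(meta, comparison.case, comparison.control)
    return design, meta


def run_comparison(
    config: RunConfig,
    iso_linear: ExpressionMatrix,
    ann: AnnotationMap,
    metadata: pd.DataFrame,
    comparison: Comparison,
    outdir: Path | None = None,
) -> dict:
    """One case/control contrast: two-level DE, classification, clustering.

    Returns a report dict; when ``outdir`` is given, DE tables, the
    classification TSV and a JSON summary + manifest are written there.
    """
    design, meta = _comparison_design(metadata, comparison)
    sub = iso_linear.subset_samples(list(meta.index))
    levels = prepare_levels(sub, ann, keep_fraction=config.keep_fraction, normalize=config.normalize)

    de: dict[str, pd.DataFrame] = {}
    for level, m_log2 in levels.items():
        de[level] = differential.differential_expression(
            m_log2, design, fc_cut=config.fc_cut, fdr_cut=config.fdr_cut
        )
    classification = signatures.classify_genes(de["gene"], de["isoform"], ann)
    opposing = signatures.detect_opposing(de["isoform"], ann)

    metrics = {}
    for level, m_log2 in levels.items():
        res = cluster_metrics(m_log2, meta["class"], k=config.k, linkage=config.linkage)
        metrics[level] = {
            "purity": res["purity"],
            "silhouette_mean": res["silhouette_mean"],
        }
        if config.run_consensus:
            cons = clustering.consensus_cluster(
                m_log2,
                k=config.k,
                n_resamples=config.n_resamples,
                sample_frac=config.sample_frac,
                linkage=config.linkage,
                seed=config.seed,
            )
            cdf = clustering.consensus_cdf(cons)
            metrics[level]["consensus_cdf"] = cdf.to_dict(orient="list")

    report = {
        "comparison": comparison.name,
        "n_case": design.n_case,
        "n_control": design.n_control,
        "n_significant": {lvl: int(de[lvl]["significant"].sum()) for lvl in de},
        "category_counts": classification["category"].value_counts().to_dict(),
        "n_opposing": len(opposing),
        "cluster_metrics": metrics,
        "thresholds": {
            "fc_cut": config.fc_cut,
            "fdr_cut": config.fdr_cut,
            "keep_fraction": config.keep_fraction,
            "k": config.k,
            "linkage": config.linkage,
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}
        for level in de:
            path = outdir / f"{comparison.name}_de_{level}.tsv"
            differential.write_de_table(de[level], path)
            files[path.name] = path
        cpath = outdir / f"{comparison.name}_classification.tsv"
        classification.to_csv(cpath, sep="\t")
        files[cpath.name] = cpath
        spath = outdir / f"{comparison.name}_summary.json"
        spath.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        files[spath.name] = spath
        manifest = {name: _sha256(p) for name, p in sorted(files.items())}
        (outdir / f"{comparison.name}_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    report["de"] = de
    report["classification"] = classification
    report["opposing_genes"] = opposing
    return report


def run_full_study(
    config: RunConfig,
    iso_linear: ExpressionMatrix,
    ann: AnnotationMap,
    metadata: pd.DataFrame,
    gene_sets: enrichment.GeneSetCollection | None = None,
    outdir: Path | None = None,
) -> dict:
    """All configured comparisons + core sets + discordant pathways."""
    if len(config.comparisons) < 2:
        raise ValidationError("a full study needs >= 2 configured comparisons")
    reports = {}
    for comp in config.comparisons:
        try:
            reports[comp.name] = run_comparison(config, iso_linear, ann, metadata, comp, outdir)
        except (ValidationError, DataError) as err:
            raise type(err)(f"[comparison {comp.name}] {err}") from err

    core = {
        level: signatures.core_intersection(
            {name: rep["de"][level] for name, rep in reports.items()}
        )
        for level in ("isoform", "gene")
    }

    discordant = None
    if gene_sets is not None:
        universe = set(ann.gene_ids)
        p_tables: dict[str, dict[str, dict[str, float]]] = {}
        for name, rep in reports.items():
            cls = rep["classification"]
            queries = {
                "isoform": set(cls.index[cls["category"] == "isoform_only"]),
                "gene": set(cls.index[cls["category"] == "gene_only"]),
            }
            p_tables[name] = {
                level: enrichment.enrich_collection(q, gene_sets, universe)["p"].to_dict()
                for level, q in queries.items()
            }
        discordant = enrichment.counting_select(p_tables, alpha=config.alpha)

    summary = {
        "comparisons": {
            name: {k: v for k, v in rep.items() if k not in ("de", "classification", "opposing_genes")}
            for name, rep in reports.items()
        },
        "core_set_sizes": {
            level: {d: len(s) for d, s in dirs.items()} for level, dirs in core.items()
        },
        "discordant_pathways": discordant,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "study_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        core_rows = [
            {"level": level, "direction": d, "feature_id": f}
            for level, dirs in core.items()
            for d, members in dirs.items()
            for f in sorted(members)
        ]
        pd.DataFrame(core_rows, columns=["level", "direction", "feature_id"]).to_csv(
            outdir / "core_sets.tsv", sep="\t", index=False
        )

    return {"reports": reports, "core": core, "discordant": discordant, "summary": summary}


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
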