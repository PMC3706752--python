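"""Synthetic isoform-resolved expression data with known regulation structure.

The generator emulates a two-class (oncogenic vs non-oncogenic) cell-line
panel spread over several tissues of origin, with multi-isoform genes and
four gene-level regulation regimes:

* ``null`` — no class effect on any isoform;
* ``concordant`` — the same signed log2 effect on every isoform, so the
  gene-level (summed) signal carries the full effect;
* ``isoform_only`` — the effect on exactly one isoform of a multi-isoform
  gene, diluted in the gene-level sum;
* ``opposing`` — one isoform up and one down, with the down isoform's
  baseline abundance chosen so the linear-scale gene sums of the two
  classes are equal: the gene-level signal cancels exactly.

Expression is simulated on the log2 scale as

    baseline + class_effect + tissue_effect + N(0, noise_sd^2)

and returned on the linear scale (2^x, strictly positive).  Tissue random
effects are drawn per (gene, tissue) and shared by all isoforms of the
gene, so tissue structure never mimics isoform switching.  The class
effect is applied to the second entry of ``class_labels`` (the "case"
class); the first is baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ValidationError
from .matrix import AnnotationMap, ExpressionMatrix, validate_metadata

EFFECT_CLASSES = ("null", "concordant", "isoform_only", "opposing")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults describe the regime the analysis is designed for: ~3 isoforms
    per gene (truncated geometric), two classes of 40 samples over 4
    tissues, |log2 effect| ~ Uniform[1, 3] on 45% of genes split evenly
    between concordant, isoform-only and opposing regulation, unit
    log2-scale residual noise and half-unit tissue effects.
    """

    n_genes: int = 2000
    mean_isoforms: float = 3.0
    max_isoforms: int = 10
    n_samples_per_class: int = 40
    n_tissues: int = 4
    class_labels: tuple[str, str] = ("non-oncogenic", "oncogenic")
    effect_mix: tuple[float, float, float, float] = (0.55, 0.15, 0.15, 0.15)
    effect_low: float = 1.0
    effect_high: float = 3.0
    tissue_sd: float = 0.5
    noise_sd: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    cancellation_tol: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples_per_class", "n_tissues", "max_isoforms"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        self.effect_mix = tuple(float(p) for p in self.effect_mix)
        if len(self.effect_mix) != 4:
            raise ValidationError("effect_mix needs 4 proportions (null, concordant, isoform_only, opposing)")
        if any(p < 0 or p > 1 for p in self.effect_mix):
            raise ValidationError("effect_mix proportions must lie in [0, 1]")
        if abs(sum(self.effect_mix) - 1.0) > 1e-9:
            raise ValidationError("effect_mix must sum to 1")
        for name in ("tissue_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (1.0 <= self.mean_isoforms <= self.max_isoforms):
            raise ValidationError("mean_isoforms must lie in [1, max_isoforms]")
        if self.effect_low <= 0 or self.effect_high < self.effect_low:
            raise ValidationError("effect magnitudes need 0 < effect_low <= effect_high")
        if len(set(self.class_labels)) != 2:
            raise ValidationError("class_labels must be two distinct names")
        if self.cancellation_tol <= 0:
            raise ValidationError("cancellation_tol must be positive")

    @property
    def case_label(self) -> str:
        return self.class_labels[1]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_labels"] = list(self.class_labels)
        d["effect_mix"] = list(self.effect_mix)
        return d


@dataclass
class GroundTruth:
    """Per-gene regulation class and per-isoform baseline/effect truth.

    ``gene_class`` maps gene id -> regulation regime; ``iso_effect`` the
    signed true log2 class effect per transcript; ``baseline`` the true
    log2 baseline abundance per transcript.
    """

    gene_class: pd.Series = field(repr=False)
    iso_effect: pd.Series = field(repr=False)
    baseline: pd.Series = field(repr=False)

    def genes_in_class(self, effect_class: str) -> list[str]:
        if effect_class not in EFFECT_CLASSES:
            raise ValidationError(f"unknown effect class {effect_class!r}")
        return list(self.gene_class.index[self.gene_class == effect_class])

    def gene_log2fc(self, ann: AnnotationMap) -> pd.Series:
        """Truth-implied gene-level log2 fold change (case vs control).

        Computed from the noiseless linear-scale sums
        log2(sum_i 2^(b_i + e_i)) - log2(sum_i 2^(b_i)).
        """
        base_lin = np.power(2.0, self.baseline)
        case_lin = np.power(2.0, self.baseline + self.iso_effect)
        genes = ann.mapping.reindex(self.baseline.index)
        ctrl = base_lin.groupby(genes.to_numpy()).sum()
        case = case_lin.groupby(genes.to_numpy()).sum()
        return np.log2(case / ctrl)

    def to_tsv(self, path, ann: AnnotationMap) -> None:
        df = pd.DataFrame(
            {
                "gene_id": ann.mapping.reindex(self.iso_effect.index),
                "gene_class": self.gene_class.reindex(
                    ann.mapping.reindex(self.iso_effect.index)
                ).to_numpy(),
                "baseline_log2": self.baseline,
                "effect_log2": self.iso_effect,
            }
        )
        df.index.name = "transcript_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_class = df.groupby("gene_id")["gene_class"].first()
        return cls(gene_class, df["effect_log2"], df["baseline_log2"])


def _truncated_geometric_pmf(p: float, max_k: int) -> np.ndarray:
    k = np.arange(1, max_k + 1)
    pmf = (1 - p) ** (k - 1) * p
    return pmf / pmf.sum()


def _solve_geometric_p(mean: float, max_k: int) -> float:
    """Success probability making the {1..max_k}-truncated geometric mean equal `mean`."""
    if mean <= 1.0 + 1e-12:
        return 1.0 - 1e-12

    def gap(p):
        pmf = _truncated_geometric_pmf(p, max_k)
        return float(np.arange(1, max_k + 1) @ pmf) - mean

    # gap is decreasing in p; bracket between near-0 and near-1
    return optimize.brentq(gap, 1e-9, 1 - 1e-9, xtol=1e-12)


def isoform_count_distribution(spec: SyntheticSpec) -> np.ndarray:
    """PMF over isoform counts {1..max_isoforms} with the spec's mean."""
    p = _solve_geometric_p(spec.mean_isoforms, spec.max_isoforms)
    return _truncated_geometric_pmf(p, spec.max_isoforms)


def make_annotation(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> AnnotationMap:
    """Draw a transcript->gene map with geometric isoform counts."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pmf = isoform_count_distribution(spec)
    counts = rng.choice(np.arange(1, spec.max_isoforms + 1), size=spec.n_genes, p=pmf)
    width = len(str(spec.n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1)]
    transcripts, gene_of = [], []
    for g, c in zip(genes, counts):
        for j in range(1, c + 1):
            transcripts.append(f"{g}.T{j}")
            gene_of.append(g)
    return AnnotationMap(pd.Series(gene_of, index=pd.Index(transcripts, name="transcript_id")))


def _draw_magnitudes(spec: SyntheticSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.uniform(spec.effect_low, spec.effect_high, size=size)


def assign_effects(
    spec: SyntheticSpec, ann: AnnotationMap, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Assign regulation classes and true per-isoform baselines/effects.

    Class counts follow ``effect_mix`` exactly up to multinomial sampling;
    isoform_only and opposing classes are only ever placed on genes with
    >= 2 isoforms (category draws landing on single-isoform genes are
    swapped with multi-isoform null/concordant genes so the class
    fractions are preserved).

    For opposing genes both magnitudes are drawn from the effect
    distribution and the down isoform's baseline is set so the
    linear-scale class sums are equal, i.e. the truth-implied gene-level
    log2FC is 0 (well inside ``cancellation_tol``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    genes = ann.gene_ids
    iso_counts = ann.mapping.groupby(ann.mapping.to_numpy()).size().reindex(genes)
    multi = iso_counts >= 2

    cats = rng.choice(4, size=len(genes), p=list(spec.effect_mix))
    if (spec.effect_mix[2] > 0 or spec.effect_mix[3] > 0) and not multi.any():
        raise ValidationError(
            "effect_mix requires isoform-specific regulation but no gene has >= 2 isoforms"
        )
    # swap multi-isoform-only categories off single-isoform genes
    needs_multi = np.isin(cats, (2, 3)) & ~multi.to_numpy()
    can_give = np.isin(cats, (0, 1)) & multi.to_numpy()
    n_swap = int(needs_multi.sum())
    if n_swap:
        if n_swap > int(can_give.sum()):
            raise ValidationError(
                "not enough multi-isoform genes to host isoform_only/opposing effects"
            )
        givers = rng.choice(np.flatnonzero(can_give), size=n_swap, replace=False)
        takers = np.flatnonzero(needs_multi)
        cats[givers], cats[takers] = cats[takers].copy(), cats[givers].copy()

    baseline = pd.Series(
        rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(ann.mapping)),
        index=ann.mapping.index,
        dtype=float,
    )
    effect = pd.Series(0.0, index=ann.mapping.index)
    gene_class = pd.Series(
        [EFFECT_CLASSES[c] for c in cats], index=pd.Index(genes, name="gene_id")
    )

    iso_index: dict[str, list[str]] = {}
    for t, g in ann.mapping.items():
        iso_index.setdefault(g, []).append(t)
    for g, cat in zip(genes, cats):
        isos = iso_index[g]
        if cat == 1:  # concordant: one signed magnitude on all isoforms
            delta = _draw_magnitudes(spec, rng, 1)[0] * rng.choice((-1.0, 1.0))
            effect[isos] = delta
        elif cat == 2:  # isoform_only: one isoform of a multi-isoform gene
            target = isos[rng.integers(len(isos))]
            effect[target] = _draw_magnitudes(spec, rng, 1)[0] * rng.choice((-1.0, 1.0))
        elif cat == 3:  # opposing: +up / -down with exact linear cancellation
            up_idx, dn_idx = rng.choice(len(isos), size=2, replace=False)
            up, dn = isos[up_idx], isos[dn_idx]
            d_up, d_dn = _draw_magnitudes(spec, rng, 2)
            effect[up] = d_up
            effect[dn] = -d_dn
            # 2^b_dn (1 - 2^-d_dn) = 2^b_up (2^d_up - 1)
            baseline[dn] = baseline[up] + np.log2(
                (2.0**d_up - 1.0) / (1.0 - 2.0**-d_dn)
            )
    return GroundTruth(gene_class=gene_class, iso_effect=effect, baseline=baseline)


def make_metadata(spec: SyntheticSpec) -> pd.DataFrame:
    """Deterministic sample sheet: classes balanced round-robin over tissues."""
    rows = []
    for label in spec.class_labels:
        short = "".join(ch for ch in label if ch.isalnum())[:6] or "cls"
        for i in range(spec.n_samples_per_class):
            tissue = f"tissue{(i % spec.n_tissues) + 1}"
            rows.append((f"{short}_{i + 1:03d}", label, tissue))
    df = pd.DataFrame(rows, columns=["sample_id", "class", "tissue"]).set_index("sample_id")
    return validate_metadata(df)


def simulate_matrix(
    spec: SyntheticSpec,
    ann: AnnotationMap,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the linear-scale isoform-by-sample matrix plus metadata."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    metadata = make_metadata(spec)
    transcripts = ann.transcript_ids
    genes = ann.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    iso_gene_idx = np.array([gene_pos[g] for g in ann.mapping.to_numpy()])

    tissues = sorted(metadata["tissue"].unique())
    tissue_pos = {t: i for i, t in enumerate(tissues)}
    # per (gene, tissue) random effects, shared by all isoforms of the gene
    tissue_fx = rng.normal(0.0, spec.tissue_sd, size=(len(genes), len(tissues)))

    base = truth.baseline.reindex(transcripts).to_numpy()
    eff = truth.iso_effect.reindex(transcripts).to_numpy()
    is_case = (metadata["class"] == spec.case_label).to_numpy()
    tis_idx = np.array([tissue_pos[t] for t in metadata["tissue"]])

    log2x = (
        base[:, None]
        + np.outer(eff, is_case.astype(float))
        + tissue_fx[iso_gene_idx][:, tis_idx]
        + rng.normal(0.0, spec.noise_sd, size=(len(transcripts), len(metadata)))
    )
    data = pd.DataFrame(np.power(2.0, log2x), index=transcripts, columns=metadata.index)
    return ExpressionMatrix(data, level="isoform", scale="linear"), metadata


def simulate_dataset(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[ExpressionMatrix, AnnotationMap, pd.DataFrame, GroundTruth]:
    """Run the three generator stages with a single seed; fully deterministic."""
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    ann = make_annotation(spec, rng)
    truth = assign_effects(spec, ann, rng)
    mat, metadata = simulate_matrix(spec, ann, truth, rng)
    return mat, ann, metadata, truth
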