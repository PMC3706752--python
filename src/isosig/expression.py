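"""Expression-matrix processing: gene aggregation, loess normalization,
log transform, coefficient-of-variation filtering and the qPCR
2^-ddCt fold-change utility.

Gene-level expression is defined as the linear-scale sum of a gene's
isoform expressions, so aggregation is always performed before the log
transform and per-sample totals are conserved exactly.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import DataError, ValidationError
from .matrix import AnnotationMap, ExpressionMatrix

_MEAN_FLOOR = 1e-8


def aggregate_to_gene(iso: ExpressionMatrix, ann: AnnotationMap) -> ExpressionMatrix:
    """Sum isoform rows to one row per gene (linear scale).

    Gene rows are ordered by gene id; sample order is preserved.  Raises
    :class:`DataError` listing offenders if any transcript is missing
    from the annotation.
    """
    if iso.level != "isoform":
        raise ValidationError("aggregate_to_gene expects an isoform-level matrix")
    if iso.scale != "linear":
        raise ValidationError("aggregate_to_gene expects a linear-scale matrix")
    ann.check_covers(iso.feature_ids)
    genes = ann.mapping.reindex(iso.data.index)
    gene_data = iso.data.groupby(genes.to_numpy(), sort=True).sum()
    gene_data.index.name = "feature_id"
    return ExpressionMatrix(gene_data, level="gene", scale="linear")


def loess_normalize(m: ExpressionMatrix, span: float = 0.4) -> ExpressionMatrix:
    """Normalize each sample against a median pseudo-reference by loess.

    For each sample a loess curve of M = log2(sample/ref) on
    A = (log2 sample + log2 ref)/2 is fitted (features where either value
    is zero are excluded from the fit and passed through unchanged) and
    subtracted; output stays on the linear scale.  The reference — the
    per-feature median across samples — is computed once.
    """
    if m.scale != "linear":
        raise ValidationError("loess_normalize expects a linear-scale matrix")
    if m.n_samples < 2:
        raise ValidationError("loess normalization needs at least 2 samples")
    X = m.data.to_numpy(dtype=float)
    ref = np.median(X, axis=1)
    out = X.copy()
    ok_ref = ref > 0
    log_ref = np.where(ok_ref, np.log2(np.where(ok_ref, ref, 1.0)), 0.0)
    for j in range(X.shape[1]):
        x = X[:, j]
        ok = ok_ref & (x > 0)
        if ok.sum() < 10:
            continue
        log_x = np.log2(x[ok])
        a = 0.5 * (log_x + log_ref[ok])
        mm = log_x - log_ref[ok]
        spread = float(a.max() - a.min())
        if spread <= 0:  # all intensities equal: trend is the constant mean
            fit = np.full(mm.shape, mm.mean())
        else:
            fit = lowess(mm, a, frac=span, delta=0.01 * spread, return_sorted=False)
        out[ok, j] = x[ok] / np.power(2.0, fit)
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(df, level=m.level, scale="linear")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1); the +1 offset keeps zeros finite and maps 0 -> 0."""
    if m.scale != "linear":
        raise ValidationError("log_transform expects a linear-scale matrix")
    values = m.data.to_numpy(dtype=float)
    if (values < 0).any():
        raise DataError("negative values cannot be log-transformed")
    df = pd.DataFrame(np.log2(values + 1.0), index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(df, level=m.level, scale="log2")


def cv_filter(m: ExpressionMatrix, keep_fraction: float) -> ExpressionMatrix:
    """Keep the ceil(keep_fraction * n) features with largest CV.

    CV = sample SD (n-1 denominator) / mean on linear values; features
    with mean below 1e-8 get CV 0.  Ties are broken by lexicographic
    feature id; surviving rows keep their input order.
    """
    if not (0 < keep_fraction <= 1):
        raise ValidationError("keep_fraction must lie in (0, 1]")
    if m.n_samples < 2:
        raise ValidationError("CV undefined with a single sample")
    X = m.data.to_numpy(dtype=float)
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    cv = np.where(mean < _MEAN_FLOOR, 0.0, sd / np.where(mean < _MEAN_FLOOR, 1.0, mean))
    k = math.ceil(keep_fraction * m.n_features)
    ranking = sorted(
        range(m.n_features), key=lambda i: (-cv[i], m.data.index[i])
    )
    keep = sorted(ranking[:k])  # original row order among survivors
    return ExpressionMatrix(m.data.iloc[keep].copy(), level=m.level, scale=m.scale)


def ddct_fold(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR fold change 2^-ddCt.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValidationError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
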