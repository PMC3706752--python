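"""Two-group differential expression with empirical-Bayes moderated
t-statistics, Benjamini-Hochberg FDR adjustment, and the fold-change /
FDR selection rule.

The moderation follows the standard empirical-Bayes formulation: the
per-feature residual variances s_g^2 are modelled as scaled chi-square
draws around a common prior s0^2 with d0 prior degrees of freedom, the
hyperparameters are fitted by moment matching on log variances
(digamma/trigamma inversion), and the posterior variance

    s~_g^2 = (d0 * s0^2 + df * s_g^2) / (d0 + df)

replaces s_g^2 in the t-statistic, which is referred to a t distribution
with df + d0 degrees of freedom (normal limit when d0 is infinite).

Fold changes are reported in the signed linear convention: FC = 2^log2FC
when log2FC >= 0 and -2^(-log2FC) otherwise, so FC = -5.6 means 5.6-fold
down and |FC| >= 1 always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ValidationError
from .matrix import ExpressionMatrix


@dataclass
class GroupDesign:
    """Case/control assignment of samples for a two-group comparison."""

    groups: pd.Series = field(repr=False)  # sample_id -> "case" | "control"
    case: str = "case"
    control: str = "control"

    def __post_init__(self) -> None:
        levels = set(self.groups.unique())
        if levels != {self.case, self.control}:
            raise ValidationError(
                f"design must contain exactly the groups {self.case!r} and {self.control!r}"
            )
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError("both groups need at least 2 samples")

    @property
    def n_case(self) -> int:
        return int((self.groups == self.case).sum())

    @property
    def n_control(self) -> int:
        return int((self.groups == self.control).sum())

    @property
    def df(self) -> int:
        return self.n_case + self.n_control - 2

    @classmethod
    def from_metadata(cls, metadata: pd.DataFrame, case_label: str, control_label: str) -> "GroupDesign":
        sub = metadata[metadata["class"].isin([case_label, control_label])]
        groups = sub["class"].map({case_label: "case", control_label: "control"})
        return cls(groups)


@dataclass
class ModerationResult:
    """Fitted prior df d0, prior variance s0^2, and posterior variances."""

    d0: float
    s0_sq: float
    posterior_var: np.ndarray = field(repr=False)


def fit_groups(m: ExpressionMatrix, design: GroupDesign) -> pd.DataFrame:
    """Per-feature group means and pooled residual variance.

    Returns a frame with ``mean_case``, ``mean_control``, ``log2FC`` and
    ``s2`` columns; the residual df (n1 + n2 - 2) is in ``frame.attrs["df"]``.
    """
    if m.scale != "log2":
        raise ValidationError("fit_groups expects a log2-scale matrix")
    samples = design.groups.index
    missing = [s for s in samples if s not in m.data.columns]
    if missing:
        raise DataError(f"design samples absent from matrix: {missing[:5]}")
    if design.df < 1:
        raise ValidationError("zero residual degrees of freedom")
    X = m.data[list(samples)].to_numpy(dtype=float)
    case_mask = (design.groups == design.case).to_numpy()
    n1, n2 = design.n_case, design.n_control
    mean_case = X[:, case_mask].mean(axis=1)
    mean_ctrl = X[:, ~case_mask].mean(axis=1)
    ss_case = ((X[:, case_mask] - mean_case[:, None]) ** 2).sum(axis=1)
    ss_ctrl = ((X[:, ~case_mask] - mean_ctrl[:, None]) ** 2).sum(axis=1)
    s2 = (ss_case + ss_ctrl) / (n1 + n2 - 2)
    out = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "log2FC": mean_case - mean_ctrl,
            "s2": s2,
        },
        index=m.data.index,
    )
    out.attrs["df"] = design.df
    out.attrs["n_case"] = n1
    out.attrs["n_control"] = n2
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the log scale)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return y


def moderate_variances(
    s2: np.ndarray,
    df: int,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> ModerationResult:
    """Fit (d0, s0^2) by moment matching on log variances and shrink.

    With ``d0=0`` forced the posterior equals the raw variances; when the
    observed log-variance dispersion does not exceed the chi-square
    sampling dispersion (e.g. all variances identical), d0 is infinite
    and the posterior collapses to s0^2 = exp(mean(log s^2)).
    """
    s2 = np.asarray(s2, dtype=float)
    if d0 is None and s2.size < 10:
        raise ValidationError("need >= 10 features to fit moderation hyperparameters")
    if df < 1:
        raise ValidationError("df must be >= 1")
    if (s2 < 0).any():
        raise DataError("negative variances")
    if d0 is not None:
        if d0 == 0:
            return ModerationResult(0.0, float(s0_sq) if s0_sq else float(np.median(s2)), s2.copy())
        if math.isinf(d0):
            s0 = float(s0_sq) if s0_sq is not None else float(np.exp(np.mean(np.log(np.maximum(s2, 1e-300)))))
            return ModerationResult(math.inf, s0, np.full_like(s2, s0))
        if s0_sq is None:
            raise ValidationError("finite forced d0 requires s0_sq")
        post = (d0 * s0_sq + df * s2) / (d0 + df)
        return ModerationResult(float(d0), float(s0_sq), post)

    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        d0_hat = math.inf
        s0_hat = float(np.exp(np.mean(z)))
        post = np.full_like(s2, s0_hat)
    else:
        d0_hat = 2.0 * _trigamma_inverse(evar)
        s0_hat = float(np.exp(np.mean(e) + special.digamma(d0_hat / 2.0) - math.log(d0_hat / 2.0)))
        post = (d0_hat * s0_hat + df * s2) / (d0_hat + df)
    return ModerationResult(d0_hat, s0_hat, post)


def moderated_t(fit: pd.DataFrame, moderation: ModerationResult) -> pd.DataFrame:
    """Add moderated t statistics and two-sided P values to a group fit."""
    if len(moderation.posterior_var) != len(fit):
        raise ValidationError("moderation result does not match fit dimensions")
    df = fit.attrs["df"]
    n1, n2 = fit.attrs["n_case"], fit.attrs["n_control"]
    post = moderation.posterior_var
    scale = 1.0 / n1 + 1.0 / n2
    log2fc = fit["log2FC"].to_numpy()
    degenerate = post <= 0
    se = np.sqrt(np.where(degenerate, 1.0, post) * scale)
    t = log2fc / se
    total_df = df + moderation.d0
    if math.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    with np.errstate(invalid="ignore"):
        t = np.where(
            degenerate & (log2fc == 0), 0.0, np.where(degenerate, np.sign(log2fc) * np.inf, t)
        )
        p = np.where(degenerate & (log2fc == 0), 1.0, np.where(degenerate, 0.0, p))
    out = fit.copy()
    out["posterior_var"] = post
    out["t"] = t
    out["p"] = p
    out["degenerate"] = degenerate
    out.attrs.update(fit.attrs)
    out.attrs["d0"] = moderation.d0
    out.attrs["s0_sq"] = moderation.s0_sq
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise DataError("NaN in P values")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _signed_fc(log2fc: np.ndarray) -> np.ndarray:
    return np.where(log2fc >= 0, np.power(2.0, log2fc), -np.power(2.0, -log2fc))


def call_significant(result: pd.DataFrame, fc_cut: float = 2.0, fdr_cut: float = 0.01) -> pd.DataFrame:
    """Apply the selection rule: |FC| > fc_cut AND adjusted P < fdr_cut."""
    if "adj_p" not in result.columns:
        raise ValidationError("call_significant requires an 'adj_p' column")
    out = result.copy()
    log2fc = out["log2FC"].to_numpy()
    out["FC"] = _signed_fc(log2fc)
    out["significant"] = (np.abs(out["FC"]) > fc_cut) & (out["adj_p"] < fdr_cut)
    out["direction"] = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    out.attrs.update(result.attrs)
    return out


def differential_expression(
    m: ExpressionMatrix,
    design: GroupDesign,
    fc_cut: float = 2.0,
    fdr_cut: float = 0.01,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Full per-feature DE table: fit, moderate, test, adjust, call.

    With ``d0=0`` this reduces exactly to the classical two-sample
    pooled-variance t-test followed by BH adjustment.
    """
    fit = fit_groups(m, design)
    mod = moderate_variances(fit["s2"].to_numpy(), fit.attrs["df"], d0=d0, s0_sq=s0_sq)
    res = moderated_t(fit, mod)
    res["adj_p"] = bh_adjust(res["p"].to_numpy())
    res = call_significant(res, fc_cut=fc_cut, fdr_cut=fdr_cut)
    res.index.name = "feature_id"
    return res


DE_COLUMNS = [
    "mean_case",
    "mean_control",
    "log2FC",
    "FC",
    "t",
    "p",
    "adj_p",
    "significant",
    "direction",
]


def write_de_table(result: pd.DataFrame, path) -> None:
    result[DE_COLUMNS].to_csv(path, sep="\t")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
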