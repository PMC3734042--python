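"""Two-group differential expression on log2 matrices.

Two statistical paths are provided, mirroring the two array platforms of a
case/control T-cell study design:

* small-RNA path — detection filter (probe kept only if detected in strictly
  more than half of the cases AND of the controls) followed by an ordinary
  pooled two-sample Student t-test;
* mRNA path — empirical-Bayes moderated t-test, where every gene's sample
  variance is shrunk toward a prior (d0, s0^2) estimated from all genes, with
  Storey q-values for multiple-testing correction.

The variance prior assumes per-gene true variances follow a scaled inverse
chi-square distribution: s_g^2 | sigma_g^2 ~ sigma_g^2 * chi2(df)/df with
sigma_g^2 ~ s0^2 * d0 / chi2(d0).  Hyperparameters are estimated by the
method of moments on log sample variances, and the moderated statistic

    t_g = (mean_case - mean_control) / sqrt(s~_g^2 (1/n1 + 1/n2)),
    s~_g^2 = (d0 s0^2 + df s_g^2) / (d0 + df)

is referred to a t distribution on d0 + df degrees of freedom.  d0 = 0
recovers the ordinary t-test exactly; d0 = infinity uses s0^2 for every gene
(a normal-reference limit).

Fold changes are geometric-mean ratios: 2^(difference of log2 group means).
An arithmetic-mean ratio is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq

from .errors import EstimationError, InputError
from .io import DetectionMatrix, ExpressionMatrix

__all__ = [
    "VariancePrior",
    "detection_filter",
    "group_stats",
    "student_t_test",
    "fit_variance_prior",
    "inverse_trigamma",
    "moderated_t_test",
    "qvalues",
    "de_table",
]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class VariancePrior:
    """Hyperparameters of the scaled inverse chi-square variance prior."""

    d0: float  # prior degrees of freedom; 0 = no moderation, may be math.inf
    s0_sq: float  # prior variance scale

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise EstimationError("prior degrees of freedom must be non-negative")
        if not (self.s0_sq > 0):
            raise EstimationError("prior scale must be positive")


def detection_filter(det: DetectionMatrix, groups: Mapping[str, str]) -> set[str]:
    """Features detected in strictly more than 50% of each group.

    The per-group reading is the stricter interpretation of "detected in
    more than 50% of the patients and controls"; a pooled-cohort variant is
    easy to apply externally but is not the default contract here.
    """
    case_cols = np.array([i for i, s in enumerate(det.sample_ids) if groups.get(s) == "case"])
    ctrl_cols = np.array([i for i, s in enumerate(det.sample_ids) if groups.get(s) == "control"])
    if case_cols.size == 0 or ctrl_cols.size == 0:
        raise InputError("both groups must be non-empty for the detection filter")
    case_frac = det.detected[:, case_cols].mean(axis=1)
    ctrl_frac = det.detected[:, ctrl_cols].mean(axis=1)
    keep = (case_frac > 0.5) & (ctrl_frac > 0.5)
    return {f for f, k in zip(det.feature_ids, keep) if k}


def group_stats(expr: ExpressionMatrix, arithmetic_ratio: bool = False) -> pd.DataFrame:
    """Per-feature group means, fold change, and pooled variance.

    Returns a DataFrame indexed by feature with columns ``mean_case``,
    ``mean_control``, ``log2_fc``, ``fold_change``, ``s_sq``, ``df``,
    ``n_case``, ``n_control``.  ``fold_change`` is case/control.  Features
    with zero variance in both groups are retained (the t statistic handles
    the degeneracy downstream).
    """
    ci, ki = expr.case_columns, expr.control_columns
    n1, n2 = ci.size, ki.size
    if n1 < 2 or n2 < 2:
        raise InputError("need at least two samples per group")
    x1 = expr.values[:, ci]
    x2 = expr.values[:, ki]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    s_sq = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    log2_fc = m1 - m2
    if arithmetic_ratio:
        fold = (2.0**x1).mean(axis=1) / (2.0**x2).mean(axis=1)
    else:
        fold = 2.0**log2_fc
    return pd.DataFrame(
        {
            "mean_case": m1,
            "mean_control": m2,
            "log2_fc": log2_fc,
            "fold_change": fold,
            "s_sq": s_sq,
            "df": float(df),
            "n_case": n1,
            "n_control": n2,
        },
        index=pd.Index(expr.feature_ids, name="feature_id"),
    )


def _t_from_stats(stats_df: pd.DataFrame, var: np.ndarray, df_test: float | np.ndarray):
    n1 = stats_df["n_case"].to_numpy(float)
    n2 = stats_df["n_control"].to_numpy(float)
    diff = stats_df["log2_fc"].to_numpy(float)
    se = np.sqrt(var * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(diff)
    p = np.ones_like(diff)
    degenerate = np.zeros(diff.shape, dtype=bool)
    ok = se > 0
    t[ok] = diff[ok] / se[ok]
    if np.isscalar(df_test) and np.isinf(df_test):
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        dfv = np.broadcast_to(np.asarray(df_test, float), diff.shape)
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), dfv[ok])
    # zero pooled variance: identical groups -> t=0, p=1; different means is
    # a 0-variance separation whose p has no finite-sample meaning
    sep = (~ok) & (diff != 0)
    t[sep] = np.sign(diff[sep]) * np.inf
    p[sep] = _TINY
    degenerate[sep] = True
    p = np.clip(p, _TINY, 1.0)
    return t, p, degenerate


def student_t_test(expr: ExpressionMatrix) -> pd.DataFrame:
    """Equal-variance two-sample t-test, two-sided, per feature."""
    gs = group_stats(expr)
    t, p, degenerate = _t_from_stats(gs, gs["s_sq"].to_numpy(float), gs["df"].iloc[0])
    out = gs.copy()
    out["t"] = t
    out["p_value"] = p
    out["degenerate"] = degenerate
    return out


def inverse_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is monotone decreasing)."""
    if y <= 0:
        raise EstimationError("inverse trigamma requires a positive argument")
    trigamma = lambda x: float(special.polygamma(1, x))
    lo, hi = 1e-8, 1.0
    while trigamma(hi) > y:
        hi *= 2.0
        if hi > 1e12:
            break
    return float(brentq(lambda x: trigamma(x) - y, lo, hi, xtol=1e-12, rtol=1e-12))


def fit_variance_prior(s_sq: np.ndarray, df: np.ndarray | float) -> VariancePrior:
    """Method-of-moments estimate of (d0, s0^2) from sample variances.

    Works on log variances: with e_g = log s_g^2 - digamma(df_g/2) +
    log(df_g/2), the excess of var(e) over mean(trigamma(df_g/2)) identifies
    d0 through the trigamma function; the mean of e identifies s0^2.  When
    the observed spread does not exceed what sampling alone explains, the
    prior is degenerate (d0 = infinity) at the geometric-mean variance.
    """
    s_sq = np.asarray(s_sq, float)
    df = np.broadcast_to(np.asarray(df, float), s_sq.shape)
    pos = s_sq > 0
    if not pos.any():
        raise EstimationError("all sample variances are zero")
    if pos.sum() < 10:
        raise EstimationError("need at least 10 positive sample variances")
    s_sq, df = s_sq[pos], df[pos]
    half_df = df / 2.0
    e = np.log(s_sq) - special.digamma(half_df) + np.log(half_df)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, half_df).mean())
    if excess <= 0:
        return VariancePrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * inverse_trigamma(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t_test(stats_df: pd.DataFrame, prior: VariancePrior) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test from :func:`group_stats` output.

    Accepts d0 = 0 (no moderation; reduces exactly to the ordinary t-test)
    and d0 = infinity (all genes share s0^2; normal reference).
    """
    s_sq = stats_df["s_sq"].to_numpy(float)
    df = stats_df["df"].to_numpy(float)
    if np.isinf(prior.d0):
        s_tilde = np.full_like(s_sq, prior.s0_sq)
        df_total: float | np.ndarray = np.inf
    else:
        s_tilde = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
        df_total = prior.d0 + df
    t, p, degenerate = _t_from_stats(stats_df, s_tilde, df_total)
    out = stats_df.copy()
    out["s_tilde_sq"] = s_tilde
    out["t"] = t
    out["p_value"] = p
    out["degenerate"] = degenerate
    return out


def qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-point pi0 estimate at ``lam``.

    pi0 = min(1, #{p > lam} / (m (1 - lam))); q for the i-th order statistic
    is the cumulative minimum from the largest p of pi0 * m * p_(j) / j.
    With pi0 = 1 (e.g. lam = 0) this is exactly Benjamini-Hochberg.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        raise InputError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    if not 0 <= lam < 1:
        raise InputError("lambda must lie in [0, 1)")
    m = p.size
    pi0 = min(1.0, float((p > lam).sum()) / (m * (1.0 - lam))) if lam > 0 else 1.0
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return np.clip(q, _TINY, 1.0)


def de_table(
    expr: ExpressionMatrix,
    method: str = "student",
    detection: DetectionMatrix | None = None,
    add_qvalues: bool = False,
    qvalue_lambda: float = 0.5,
) -> pd.DataFrame:
    """One-call differential expression table.

    ``method`` is ``"student"`` or ``"moderated"`` (the latter fits the
    variance prior from the data).  If ``detection`` is given, the strict
    per-group >50% detection filter is applied first.
    """
    if detection is not None:
        expr = expr.subset_features(sorted(detection_filter(detection, expr.groups)))
    if method == "student":
        out = student_t_test(expr)
    elif method == "moderated":
        gs = group_stats(expr)
        prior = fit_variance_prior(gs["s_sq"].to_numpy(), gs["df"].to_numpy())
        out = moderated_t_test(gs, prior)
        out.attrs["variance_prior"] = prior
    else:
        raise InputError(f"unknown method {method!r}")
    if add_qvalues:
        out["q_value"] = qvalues(out["p_value"].to_numpy(), lam=qvalue_lambda)
    return out
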