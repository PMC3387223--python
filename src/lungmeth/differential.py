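"""Per-CpG differential methylation testing.

The workhorse is the empirical-Bayes moderated t-statistic: per-probe pooled
variances are shrunk toward a scaled inverse-chi-square prior whose
parameters (prior df ``d0`` and prior variance ``s0_sq``) are estimated from
the observed variance distribution by matching the mean and spread of the
log-variances against their digamma/trigamma expectations. The moderated
statistic gains ``d0`` degrees of freedom over the ordinary pooled t:

    s2_tilde_g = (d0 * s0_sq + d_g * s2_g) / (d0 + d_g)
    t_g = delta_beta_g / (s_tilde_g * sqrt(1/n_A + 1/n_B)),  df = d0 + d_g

Calling combines an FDR threshold on Benjamini-Hochberg q-values with the
absolute beta-difference cutoff |delta_beta| >= 0.136.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .dataio import ValidationError

__all__ = [
    "ModerationParams",
    "fit_moderation",
    "moderated_t_test",
    "bh_fdr",
    "call_differential",
    "count_cpgs_and_genes",
    "covariate_regression",
    "Q_THRESHOLD",
    "DELTA_THRESHOLD",
]

#: default significance and effect-size cutoffs of the differential screen
Q_THRESHOLD = 0.05
DELTA_THRESHOLD = 0.136


@dataclass(frozen=True)
class ModerationParams:
    """Scaled inverse-chi-square variance prior: df ``d0`` (may be inf) and
    scale ``s0_sq``."""

    d0: float
    s0_sq: float

    def shrink(self, s2: np.ndarray, dg: float) -> np.ndarray:
        """Posterior (shrunken) variances given observed variances at df dg."""
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s2, dtype=float), self.s0_sq)
        return (self.d0 * self.s0_sq + dg * np.asarray(s2, dtype=float)) / (self.d0 + dg)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_moderation(variances: np.ndarray, dg: float) -> ModerationParams:
    """Method-of-moments fit of the variance prior from per-probe sample
    variances observed at residual df *dg*.

    Matches mean and variance of log(s^2) against their theoretical values
    under s^2 ~ s0^2 * chisq(dg)/dg scaled by an inv-chisq(d0) prior. When the
    observed spread of log-variances does not exceed the chi-square sampling
    spread, the prior df is infinite (complete shrinkage).
    """
    v = np.asarray(variances, dtype=float)
    if np.all(v == 0):
        raise ValidationError("all per-probe variances are zero", code="degenerate")
    v = v[v > 0]
    if len(v) < 10:
        raise ValidationError(
            f"need >= 10 probes with positive variance, got {len(v)}", code="too-few"
        )
    z = np.log(v)
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    emean = float(np.mean(e))
    if np.ptp(z) == 0.0:
        # exactly constant variances: the prior is a point mass at that value
        return ModerationParams(d0=np.inf, s0_sq=float(v[0]))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, dg / 2.0))
    if evar <= 0:
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def _t_sf2(t: np.ndarray, df: float) -> np.ndarray:
    """Two-sided p from a t distribution, tolerating df = inf."""
    t = np.abs(np.asarray(t, dtype=float))
    if np.isinf(df):
        return 2.0 * stats.norm.sf(t)
    return 2.0 * stats.t.sf(t, df)


def moderated_t_test(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    group_a: str,
    group_b: str,
    params: ModerationParams | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t-test of group A vs group B per probe.

    *labels* aligns with the matrix columns; samples with other labels are
    ignored. ``delta_beta = mean_A - mean_B``. With ``params=None`` the
    variance prior is fitted from the pooled per-probe variances; pass
    ``ModerationParams(0, 1)`` for the ordinary pooled t.
    Returns a DataFrame indexed by probe with columns mean_beta_A,
    mean_beta_B, delta_beta, t_mod, df_total, p.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=matrix.columns)
    a_cols = labels.index[labels == group_a]
    b_cols = labels.index[labels == group_b]
    n_a, n_b = len(a_cols), len(b_cols)
    if n_a < 2 or n_b < 2:
        raise ValidationError(
            f"each group needs >= 2 samples (got {group_a}: {n_a}, {group_b}: {n_b})",
            code="group-size",
        )
    xa = matrix[a_cols].to_numpy(dtype=float)
    xb = matrix[b_cols].to_numpy(dtype=float)
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    delta = mean_a - mean_b
    dg = n_a + n_b - 2
    ss = xa.var(axis=1, ddof=1) * (n_a - 1) + xb.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / dg
    if params is None:
        params = fit_moderation(s2, dg)
    s2_tilde = params.shrink(s2, dg)
    se = np.sqrt(s2_tilde * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    df_total = params.d0 + dg
    p = _t_sf2(t, df_total)
    p[(se == 0) & (delta == 0)] = 1.0
    return pd.DataFrame(
        {
            "mean_beta_A": mean_a,
            "mean_beta_B": mean_b,
            "delta_beta": delta,
            "t_mod": t,
            "df_total": df_total,
            "p": p,
        },
        index=matrix.index,
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be one-dimensional", code="shape")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]", code="range")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_differential(
    stats_df: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
    q_threshold: float = Q_THRESHOLD,
    delta_threshold: float = DELTA_THRESHOLD,
) -> pd.DataFrame:
    """Attach q-values and hyper/hypo/none calls to per-probe test results.

    hyper: q < q_threshold and delta_beta >= delta_threshold;
    hypo:  q < q_threshold and delta_beta <= -delta_threshold.
    The effect cutoff is inclusive ("at least" 0.136). If a *manifest* is
    given, gene symbols are merged in.
    """
    out = stats_df.copy()
    if "q" not in out.columns:
        out["q"] = bh_fdr(out["p"].to_numpy())
    call = np.full(len(out), "none", dtype=object)
    sig = out["q"].to_numpy() < q_threshold
    delta = out["delta_beta"].to_numpy()
    call[sig & (delta >= delta_threshold)] = "hyper"
    call[sig & (delta <= -delta_threshold)] = "hypo"
    out["call"] = call
    if manifest is not None:
        out.insert(0, "gene", manifest["gene"].reindex(out.index))
    return out


def count_cpgs_and_genes(records: pd.DataFrame) -> dict:
    """Count called CpGs and unique genes per direction.

    Returns n_hyper_cpgs / n_hyper_genes / n_hypo_cpgs / n_hypo_genes plus
    ``overlap_genes``: genes carrying CpGs in both directions.
    """
    if "gene" not in records.columns:
        raise ValidationError("records lack a 'gene' column", code="columns")
    hyper = records[records["call"] == "hyper"]
    hypo = records[records["call"] == "hypo"]
    hyper_genes = set(hyper["gene"])
    hypo_genes = set(hypo["gene"])
    return {
        "n_hyper_cpgs": len(hyper),
        "n_hyper_genes": len(hyper_genes),
        "n_hypo_cpgs": len(hypo),
        "n_hypo_genes": len(hypo_genes),
        "overlap_genes": sorted(hyper_genes & hypo_genes),
    }


def covariate_regression(
    matrix: pd.DataFrame,
    covariate: pd.Series | np.ndarray,
    params: ModerationParams | None = None,
) -> pd.DataFrame:
    """Per-probe simple linear regression of beta on a continuous covariate
    (e.g. pack-years), with empirical-Bayes moderated residual variance and
    BH q-values. Samples with a missing covariate are excluded.
    """
    x = pd.Series(np.asarray(covariate, dtype=float), index=matrix.columns)
    keep = x.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} samples with missing covariate", stacklevel=2)
    x = x[keep]
    y = matrix.loc[:, keep.index[keep]].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("need >= 3 samples with a covariate value", code="too-few")
    xv = x.to_numpy()
    if np.ptp(xv) == 0:
        raise ValidationError("covariate is constant", code="degenerate")
    xc = xv - xv.mean()
    sxx = float(np.sum(xc**2))
    slope = (y @ xc) / sxx
    intercept = y.mean(axis=1) - slope * xv.mean()
    resid = y - (intercept[:, None] + np.outer(slope, xv))
    dg = n - 2
    s2 = np.sum(resid**2, axis=1) / dg
    if params is None:
        params = fit_moderation(s2, dg)
    s2_tilde = params.shrink(s2, dg)
    se = np.sqrt(s2_tilde / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, 0.0)
    p = _t_sf2(t, params.d0 + dg)
    p[(se == 0) & (slope == 0)] = 1.0
    return pd.DataFrame(
        {"slope": slope, "t_mod": t, "p": p, "q": bh_fdr(p)}, index=matrix.index
    )
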