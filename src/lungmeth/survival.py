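"""Survival-marker screens over per-CpG methylation.

Two screens, mirroring a two-pronged prognostic-marker search:

1. **Kaplan-Meier screen** — discretize each CpG's beta values into low
   [0, 0.25), medium [0.25, 0.75) and high [0.75, 1] methylation groups,
   keep CpGs where every non-empty group has more than ``min_group``
   patients (and >= 2 groups exist), run a k-group log-rank test, and
   control FDR across tested CpGs with Benjamini-Hochberg.

2. **Cox + Wilcoxon screen** — contrast short-term (1-24 months survival,
   death observed) vs long-term (>= 60 months) survivors: per CpG a
   single-covariate Cox proportional-hazards fit on continuous beta over all
   included patients, a Wilcoxon rank-sum test of beta between the strata,
   and a beta-difference cutoff; a marker is called when both tests give
   p < 0.05 and |delta_beta| >= 0.136.

Patients surviving <= 1 month are excluded from both screens (post-operative
deaths). All estimators are written against their textbook definitions:
product-limit Kaplan-Meier, hypergeometric log-rank, Newton-maximized Cox
partial likelihood with Breslow tie handling, and an exact small-sample
Wilcoxon null distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ValidationError
from .differential import bh_fdr

__all__ = [
    "exclude_early_deaths",
    "discretize_beta",
    "discretize_beta_array",
    "kaplan_meier",
    "logrank_test",
    "km_screen",
    "cox_fit",
    "wilcoxon_rank_sum",
    "cox_wilcoxon_screen",
    "km_curves",
]

GROUP_NAMES = ("low", "medium", "high")


def exclude_early_deaths(sheet: pd.DataFrame, min_months: float = 1.0):
    """Drop tumor patients surviving up to *min_months* (inclusive).

    Returns ``(filtered_sheet, n_removed)``; normals are kept untouched.
    """
    surv = pd.to_numeric(sheet["survival_months"], errors="coerce")
    early = (sheet["tissue"] == "tumor") & (surv <= min_months)
    return sheet.loc[~early].copy(), int(early.sum())


def discretize_beta(beta: float) -> str:
    """Map a beta value to the low / medium / high methylation group."""
    if not 0.0 <= beta <= 1.0:
        raise ValidationError(f"beta {beta!r} outside [0, 1]", code="range")
    if beta < 0.25:
        return "low"
    if beta < 0.75:
        return "medium"
    return "high"


def discretize_beta_array(beta: np.ndarray) -> np.ndarray:
    """Vectorized discretization to integer codes 0=low, 1=medium, 2=high."""
    b = np.asarray(beta, dtype=float)
    if ((b < 0) | (b > 1)).any():
        raise ValidationError("beta outside [0, 1]", code="range")
    return np.digitize(b, [0.25, 0.75])


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns the step function as a table of event times with the number at
    risk, events, and S(t). At tied times events precede censorings, so
    censored subjects at an event time still count in that risk set.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValidationError("empty survival data", code="too-few")
    if len(t) != len(e):
        raise ValidationError("times/events length mismatch", code="shape")
    if (t < 0).any():
        raise ValidationError("negative survival time", code="range")
    event_times = np.unique(t[e])
    s = 1.0
    rows = []
    for ti in event_times:
        n_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & e))
        s *= 1.0 - d / n_risk
        rows.append({"time": ti, "n_risk": n_risk, "n_events": d, "survival": s})
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "survival"])


def logrank_test(times, events, groups) -> dict:
    """k-group log-rank test.

    Sums per-event-time observed-minus-expected events against the
    multivariate hypergeometric variance; chi-square with k-1 df.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = np.unique(g)
    k = len(labels)
    if k < 2:
        raise ValidationError("log-rank needs >= 2 non-empty groups", code="group-size")
    gi = np.searchsorted(labels, g)

    event_times = np.unique(t[e])
    omeE = np.zeros(k - 1)
    V = np.zeros((k - 1, k - 1))
    for ti in event_times:
        at_risk = t >= ti
        n = int(at_risk.sum())
        d = int(np.sum((t == ti) & e))
        if n <= 1 or d == 0:
            continue
        n_j = np.bincount(gi[at_risk], minlength=k).astype(float)
        d_j = np.bincount(gi[(t == ti) & e], minlength=k).astype(float)
        exp_j = d * n_j / n
        omeE += (d_j - exp_j)[: k - 1]
        frac = n_j / n
        hyper = d * (n - d) / (n - 1)
        V += hyper * (np.diag(frac[: k - 1]) - np.outer(frac[: k - 1], frac[: k - 1]))
    if not np.any(V):
        chi2 = 0.0
    else:
        chi2 = float(omeE @ np.linalg.pinv(V) @ omeE)
    p = float(stats.chi2.sf(chi2, k - 1))
    return {"chi2": chi2, "df": k - 1, "p": p}


@dataclass
class CoxResult:
    beta: float
    se: float
    p: float
    converged: bool
    n_events: int


def cox_fit(times, events, covariate, max_iter: int = 50, tol: float = 1e-9) -> CoxResult:
    """Single-covariate Cox proportional-hazards fit.

    Newton-Raphson maximization of the Breslow partial likelihood; Wald
    two-sided p. Degenerate inputs (constant covariate, < 2 events, or
    non-convergence) are flagged rather than raised so screens can skip them.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    n_events = int(e.sum())
    if n_events < 2 or np.ptp(x) == 0:
        return CoxResult(np.nan, np.nan, np.nan, converged=False, n_events=n_events)
    # sort descending by time so risk sets are cumulative prefixes
    order = np.argsort(-t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    xs = x - x.mean()  # center for numerical stability; slope is unaffected

    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * xs)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * xs)
        s2 = np.cumsum(w * xs * xs)
        # risk set of an event at time ti = all with t >= ti: because times are
        # sorted descending, that's the prefix up to the last index sharing ti
        last = np.searchsorted(-t, -t, side="right") - 1
        r0, r1, r2 = s0[last], s1[last], s2[last]
        ev = np.flatnonzero(e)
        mean_x = r1[ev] / r0[ev]
        score = float(np.sum(xs[ev] - mean_x))
        info = float(np.sum(r2[ev] / r0[ev] - mean_x**2))
        if info <= 0:
            return CoxResult(np.nan, np.nan, np.nan, converged=False, n_events=n_events)
        step = score / info
        # dampen absurd steps (monotone likelihood / separation)
        if abs(step) > 5.0:
            step = np.sign(step) * 5.0
        beta += step
        if abs(step) < tol:
            se = 1.0 / np.sqrt(info)
            p = 2.0 * stats.norm.sf(abs(beta) / se)
            return CoxResult(float(beta), float(se), float(p), True, n_events)
        if abs(beta) > 50:
            break
    return CoxResult(np.nan, np.nan, np.nan, converged=False, n_events=n_events)


def cox_score_test(times, events, covariate) -> dict:
    """Score test of beta = 0 in the Cox model (equals log-rank for a binary
    covariate without tied event times)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    order = np.argsort(-t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    xs = x - x.mean()
    s0 = np.cumsum(np.ones_like(xs))
    s1 = np.cumsum(xs)
    s2 = np.cumsum(xs * xs)
    last = np.searchsorted(-t, -t, side="right") - 1
    ev = np.flatnonzero(e)
    mean_x = s1[last][ev] / s0[last][ev]
    score = float(np.sum(xs[ev] - mean_x))
    info = float(np.sum(s2[last][ev] / s0[last][ev] - mean_x**2))
    chi2 = score**2 / info if info > 0 else 0.0
    return {"chi2": chi2, "p": float(stats.chi2.sf(chi2, 1))}


def _wilcoxon_exact_sf(n1: int, n2: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic by dynamic programming."""
    # count[u] = #subsets; recurrence over items of group 1
    max_u = n1 * n2
    counts = np.zeros(max_u + 1, dtype=float)
    counts[0] = 1.0
    # DP over the generating function prod_{i=1..n1} (1-x^{n2+i})/(1-x^i)
    for i in range(1, n1 + 1):
        new = np.zeros_like(counts)
        for u in range(max_u + 1):
            new[u] = counts[u] + (new[u - i] if u >= i else 0.0)
        counts = new
        hi = n2 + i
        new = counts.copy()
        new[hi:] -= counts[: max_u + 1 - hi]
        counts = new
    return counts / counts.sum()


def wilcoxon_rank_sum(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when min(n1, n2) <= 8 and there are no ties;
    otherwise the normal approximation with tie correction and continuity
    correction. Returns the U statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("empty group", code="too-few")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(n1, n2) <= 8 and not has_ties:
        pmf = _wilcoxon_exact_sf(n1, n2)
        ui = int(round(u))
        lo = pmf[: ui + 1].sum()
        hi = pmf[ui:].sum()
        p = min(1.0, 2.0 * min(lo, hi))
        return {"U": float(u), "p": float(p), "exact": True}
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 == 0:
        return {"U": float(u), "p": 1.0, "exact": False}
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    return {"U": float(u), "p": float(2.0 * stats.norm.sf(z)), "exact": False}


# ---------------------------------------------------------------------------
# screens


def _tumor_survival(sheet: pd.DataFrame):
    tum = sheet[(sheet["tissue"] == "tumor") & sheet["survival_months"].notna()]
    times = tum["survival_months"].to_numpy(dtype=float)
    events = np.array([bool(e) for e in tum["event"]])
    return tum.index, times, events


def km_screen(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    min_group: int = 5,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-CpG Kaplan-Meier / log-rank screen over discretized methylation.

    Expects early deaths to be excluded already. CpGs are tested only when
    every non-empty methylation group holds more than *min_group* patients
    and at least two groups are non-empty; BH FDR across tested CpGs.
    """
    ids, times, events = _tumor_survival(sheet)
    values = beta[list(ids)].to_numpy(dtype=float)
    rows = []
    for cpg, b in zip(beta.index, values):
        codes = discretize_beta_array(b)
        sizes = np.bincount(codes, minlength=3)
        nonempty = sizes[sizes > 0]
        if len(nonempty) < 2 or (nonempty <= min_group).any():
            continue
        res = logrank_test(times, events, codes)
        rows.append(
            {
                "cpg_id": cpg,
                "n_low": int(sizes[0]),
                "n_medium": int(sizes[1]),
                "n_high": int(sizes[2]),
                "logrank_chi2": res["chi2"],
                "logrank_df": res["df"],
                "logrank_p": res["p"],
            }
        )
    if not rows:
        warnings.warn("no CpG passed the group-size rule", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "n_low", "n_medium", "n_high", "logrank_chi2", "logrank_df",
                "logrank_p", "logrank_q", "significant",
            ]
        )
    out = pd.DataFrame(rows).set_index("cpg_id")
    out["logrank_q"] = bh_fdr(out["logrank_p"].to_numpy())
    out["significant"] = out["logrank_q"] < q_threshold
    return out


def cox_wilcoxon_screen(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    short_range: tuple[float, float] = (1.0, 24.0),
    long_min: float = 60.0,
    p_threshold: float = 0.05,
    delta_threshold: float = 0.136,
) -> pd.DataFrame:
    """Short- vs long-survivor differential methylation screen.

    short stratum: survival in [short_range] with the death observed;
    long stratum: survival >= long_min (dead or censored). Per CpG: Cox fit
    of continuous beta on all included patients, Wilcoxon rank-sum of beta
    short vs long, delta = mean beta(short) - mean beta(long). combined_call
    requires both p < p_threshold and |delta| >= delta_threshold; direction
    is the sign of delta (methylation state in the poor-survival group).
    """
    ids, times, events = _tumor_survival(sheet)
    short = (times >= short_range[0]) & (times <= short_range[1]) & events
    long_ = times >= long_min
    if short.sum() < 3 or long_.sum() < 3:
        raise ValidationError(
            f"strata too small (short {int(short.sum())}, long {int(long_.sum())})",
            code="group-size",
        )
    values = beta[list(ids)].to_numpy(dtype=float)
    rows = []
    for cpg, b in zip(beta.index, values):
        cox = cox_fit(times, events, b)
        wil = wilcoxon_rank_sum(b[short], b[long_])
        delta = float(b[short].mean() - b[long_].mean())
        called = (
            cox.converged
            and cox.p < p_threshold
            and wil["p"] < p_threshold
            and abs(delta) >= delta_threshold
        )
        rows.append(
            {
                "cpg_id": cpg,
                "n_short": int(short.sum()),
                "n_long": int(long_.sum()),
                "cox_beta": cox.beta,
                "cox_p": cox.p,
                "cox_converged": cox.converged,
                "wilcoxon_U": wil["U"],
                "wilcoxon_p": wil["p"],
                "delta_short_long": delta,
                "combined_call": bool(called),
                "direction": "hyper" if delta > 0 else ("hypo" if delta < 0 else "none"),
            }
        )
    return pd.DataFrame(rows).set_index("cpg_id")


def km_curves(beta_row: pd.Series, sheet: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier step coordinates per methylation group for one CpG."""
    ids, times, events = _tumor_survival(sheet)
    codes = discretize_beta_array(beta_row.loc[ids].to_numpy(dtype=float))
    frames = []
    for code, name in enumerate(GROUP_NAMES):
        mask = codes == code
        if not mask.any():
            continue
        km = kaplan_meier(times[mask], events[mask])
        km.insert(0, "group", name)
        frames.append(km)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
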