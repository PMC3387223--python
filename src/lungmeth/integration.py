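"""Methylation-expression integration.

For each differentially methylated CpG, correlate its beta values with the
median expression of its gene (median across the gene's expression probes,
per sample) and attach a permutation p-value: sample labels of the gene's
expression-probe block are permuted jointly, the median profile recomputed,
and the correlation with the fixed beta vector re-evaluated. Because the
permutation moves whole sample columns, the recomputed median profile equals
the original median profile under the same relabeling, which the
implementation exploits for speed; the definition is unchanged.

perm_p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1), two-sided on |r|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, ValidationError

__all__ = [
    "gene_level_expression",
    "pearson_r",
    "permutation_pvalue",
    "correlation_screen",
    "inverse_fraction",
    "strongest_per_gene",
]


def gene_level_expression(expr: ExpressionMatrix, gene: str) -> pd.Series:
    """Per-sample median expression over the gene's expression probes."""
    probes = expr.gene_probes(gene)
    if len(probes) == 0:
        raise ValidationError(f"gene {gene!r} has no expression probes", code="unmapped")
    return expr.values.loc[probes].median(axis=0)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("length mismatch", code="shape")
    if len(x) < 3:
        raise ValidationError("need >= 3 paired values", code="too-few")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for constant vector", code="degenerate")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def permutation_pvalue(
    beta_vec,
    expr_probes: pd.DataFrame | np.ndarray,
    n_perm: int,
    seed: int | np.random.Generator,
) -> dict:
    """Permutation p-value for the CpG-beta vs median-gene-expression
    correlation.

    *expr_probes* holds the gene's expression-probe block (probes x samples,
    aligned with *beta_vec*). Each round permutes the block's sample labels
    jointly and recomputes the median expression profile and its correlation
    with the fixed beta vector.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1", code="config")
    b = np.asarray(beta_vec, dtype=float)
    e = np.asarray(expr_probes, dtype=float)
    if e.ndim == 1:
        e = e[None, :]
    if e.shape[1] != len(b):
        raise ValidationError("sample mismatch between beta and expression", code="shape")
    if len(b) < 4:
        raise ValidationError("need >= 4 shared samples", code="too-few")
    med = np.median(e, axis=0)
    r_obs = pearson_r(b, med)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(b)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    med_perm = med[perms]  # jointly permuted columns leave the median map intact
    bc = b - b.mean()
    mc = med_perm - med_perm.mean(axis=1, keepdims=True)
    num = mc @ bc
    den = np.sqrt((bc @ bc) * np.sum(mc**2, axis=1))
    r_perm = num / den
    exceed = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    return {"r_obs": r_obs, "perm_p": (1 + exceed) / (n_perm + 1), "n_perm": n_perm}


def correlation_screen(
    records: pd.DataFrame,
    beta: pd.DataFrame,
    expr: ExpressionMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlate every called CpG with its gene's median expression.

    Only CpGs with call != none and a gene present on the expression array
    enter the census. Returns cpg_id-indexed records with gene, pearson_r,
    perm_p, n_samples and the inverse flag (pearson_r < 0).
    """
    called = records[records["call"] != "none"]
    samples = [s for s in beta.columns if s in set(expr.samples)]
    if len(samples) < 4:
        raise ValidationError("need >= 4 samples shared with expression", code="too-few")
    rng = np.random.default_rng(seed)
    rows = []
    gene_blocks: dict[str, np.ndarray] = {}
    for cpg, rec in called.iterrows():
        gene = rec["gene"]
        if gene not in gene_blocks:
            probes = expr.gene_probes(gene)
            gene_blocks[gene] = (
                expr.values.loc[probes, samples].to_numpy() if len(probes) else None
            )
        block = gene_blocks[gene]
        if block is None:
            continue
        b = beta.loc[cpg, samples].to_numpy(dtype=float)
        res = permutation_pvalue(b, block, n_perm=n_perm, seed=rng)
        rows.append(
            {
                "cpg_id": cpg,
                "gene": gene,
                "call": rec["call"],
                "pearson_r": res["r_obs"],
                "perm_p": res["perm_p"],
                "n_samples": len(samples),
                "inverse": res["r_obs"] < 0,
            }
        )
    return pd.DataFrame(rows).set_index("cpg_id") if rows else pd.DataFrame(
        columns=["gene", "call", "pearson_r", "perm_p", "n_samples", "inverse"]
    )


def inverse_fraction(records: pd.DataFrame | None = None, n_inverse: int | None = None,
                     n_total: int | None = None) -> dict:
    """Census of inversely correlated CpGs; percent to one decimal.

    Accepts either a correlation-record table or explicit counts.
    """
    if records is not None:
        n_total = len(records)
        n_inverse = int(records["inverse"].sum())
    if not n_total:
        raise ValidationError("empty census", code="too-few")
    return {
        "n_inverse": int(n_inverse),
        "n_total": int(n_total),
        "percent": round(100.0 * n_inverse / n_total, 1),
    }


def strongest_per_gene(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only each gene's strongest (most negative / largest |r|) CpG."""
    if records.empty:
        return records
    order = records["pearson_r"].abs().sort_values(ascending=False)
    best = records.loc[order.index].groupby("gene", sort=False).head(1)
    return best.sort_index()
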