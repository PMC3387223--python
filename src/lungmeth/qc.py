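"""Quality control and unsupervised structure.

Technical-replicate concordance, selection of the top differential CpGs,
row-standardized (z-score) hierarchical clustering of probes and samples,
and flagging of samples whose cluster disagrees with their tissue label
(the audit trail for purity-driven exclusions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .dataio import ValidationError

__all__ = [
    "ClusterResult",
    "replicate_concordance",
    "select_top_cpgs",
    "cluster_heatmap",
    "flag_discordant_samples",
]


@dataclass
class ClusterResult:
    """Ordered z-matrix plus the linkage trees and a 2-cluster sample cut."""

    zmatrix: pd.DataFrame  # rows/columns in dendrogram order
    probe_order: list[str]
    sample_order: list[str]
    sample_linkage: np.ndarray
    probe_linkage: np.ndarray
    sample_clusters: pd.Series  # 2-cluster cut labels, original sample ids
    constant_probes: list[str] = field(default_factory=list)
    metric: str = "euclidean"
    linkage_method: str = "average"


def replicate_concordance(matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.Series:
    """Pearson correlation over all probes for each technical replicate pair.

    Groups of size > 2 contribute every within-group pair. Indexed by
    ``"<id1>|<id2>"``.
    """
    groups = sheet["replicate_group"].dropna()
    groups = groups[groups.astype(str) != ""]
    if groups.empty:
        raise ValidationError("no replicate groups in sample sheet", code="no-replicates")
    out = {}
    for _, members in groups.groupby(groups):
        ids = [s for s in members.index if s in matrix.columns]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a = matrix[ids[i]].to_numpy(dtype=float)
                b = matrix[ids[j]].to_numpy(dtype=float)
                r = np.corrcoef(a, b)[0, 1]
                out[f"{ids[i]}|{ids[j]}"] = float(r)
    if not out:
        raise ValidationError("replicate groups have no samples in matrix", code="no-replicates")
    return pd.Series(out, name="pearson_r")


def select_top_cpgs(records: pd.DataFrame, k: int = 100, q_threshold: float = 0.05) -> list[str]:
    """The k largest-|delta_beta| CpGs among q-significant records.

    Ties on |delta_beta| break by smaller q, then lexicographic CpG id.
    Returns all qualifying CpGs (with a warning) when fewer than k qualify.
    """
    sig = records[records["q"] < q_threshold].copy()
    if len(sig) < k:
        warnings.warn(f"only {len(sig)} CpGs pass q < {q_threshold}; returning all",
                      stacklevel=2)
    sig["_absd"] = sig["delta_beta"].abs()
    sig["_id"] = sig.index.astype(str)
    sig = sig.sort_values(by=["_absd", "q", "_id"], ascending=[False, True, True],
                          kind="stable")
    return sig["_id"].head(k).tolist()


def _zscore_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (values - mean) / sd
    z[constant] = 0.0
    return z, constant


def cluster_heatmap(
    matrix: pd.DataFrame,
    probe_ids: list[str] | None = None,
    sheet: pd.DataFrame | None = None,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Row z-score then agglomerative clustering of probes and samples.

    Constant probes are z-scored to all-zero rows (with a warning) and
    reported in ``constant_probes``. Leaf order is scipy's deterministic
    dendrogram order; sample cluster labels come from a 2-cluster cut.
    """
    sub = matrix.loc[probe_ids] if probe_ids is not None else matrix
    if sub.shape[1] < 2:
        raise ValidationError("need >= 2 samples to cluster", code="too-few")
    if sub.shape[0] < 2:
        raise ValidationError("need >= 2 probes to cluster", code="too-few")
    values = sub.to_numpy(dtype=float)
    z, constant = _zscore_rows(values)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant probes z-scored to 0", stacklevel=2)
    zdf = pd.DataFrame(z, index=sub.index, columns=sub.columns)

    probe_link = hierarchy.linkage(pdist(z, metric=metric), method=method)
    sample_link = hierarchy.linkage(pdist(z.T, metric=metric), method=method)
    probe_order = [sub.index[i] for i in hierarchy.leaves_list(probe_link)]
    sample_order = [sub.columns[i] for i in hierarchy.leaves_list(sample_link)]
    cut = hierarchy.fcluster(sample_link, t=2, criterion="maxclust")
    return ClusterResult(
        zmatrix=zdf.loc[probe_order, sample_order],
        probe_order=probe_order,
        sample_order=sample_order,
        sample_linkage=sample_link,
        probe_linkage=probe_link,
        sample_clusters=pd.Series(cut, index=sub.columns, name="cluster"),
        constant_probes=[str(p) for p in sub.index[constant]],
        metric=metric,
        linkage_method=method,
    )


def flag_discordant_samples(result: ClusterResult, sheet: pd.DataFrame) -> list[str]:
    """Samples whose 2-cluster assignment disagrees with the majority tissue
    label of their cluster. An all-one-tissue cohort flags nothing."""
    clusters = result.sample_clusters
    tissue = sheet["tissue"].reindex(clusters.index)
    if tissue.nunique() < 2:
        return []
    flags = []
    majority = {}
    for c in np.unique(clusters):
        members = tissue[clusters == c]
        majority[c] = members.mode().iloc[0]
    for sid in clusters.index:
        if tissue[sid] is not None and tissue[sid] != majority[clusters[sid]]:
            flags.append(sid)
    return flags
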