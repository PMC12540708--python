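"""Differential-expression filtering and k-means time-course clustering.

Genes passing the significance filter (FDR < 0.05, |log2FC| > 1 at any
timepoint, max group mean > 1, protein-coding) are scaled per gene by
min–max over the five timepoints {0, 2, 4, 6, 8} h (the 0-h point anchors
the fold change at 0) and clustered per condition by Euclidean k-means,
with k chosen from silhouette score, the elbow (within-cluster SS) and
cluster-size dispersion.  Downstream operations assign JNK-dependent genes
(anisomycin vs. anisomycin + JNK-inhibitor contrast) to clusters, compute
overlaps between cluster gene sets across conditions, and cross-reference
clusters against published mRNA half-life tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .fitting import minmax_scale

__all__ = [
    "PROFILE_TIMES",
    "ClusterSet",
    "TimecourseKMeans",
    "filter_degs",
    "build_profile_matrix",
    "choose_k",
    "cluster_genes",
    "jnk_dependent_genes",
    "cluster_overlap",
    "crossref_halflives",
]

PROFILE_TIMES = (0.0, 2.0, 4.0, 6.0, 8.0)
DEG_TIMEPOINTS = (2, 4, 6, 8)

_REQUIRED_COLS = ("gene_id", "biotype", "fdr", "max_group_mean")


def _fc_columns(table: pd.DataFrame) -> list[str]:
    cols = [f"log2fc_{t}h" for t in DEG_TIMEPOINTS if f"log2fc_{t}h" in table.columns]
    if not cols:
        raise ValueError(
            "table has no log2fc_{2,4,6,8}h columns"
        )
    return cols


def _check_columns(table: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"DEG table is missing required columns: {missing}")


def filter_degs(
    table: pd.DataFrame,
    condition: str | None = None,
    fdr_max: float = 0.05,
    log2fc_min: float = 1.0,
    min_group_mean: float = 1.0,
    biotype: str = "protein_coding",
) -> set[str]:
    """Significantly regulated genes for one condition.

    A gene passes with FDR < 0.05, |log2FC| > 1 at ≥ 1 timepoint, max
    group mean > 1, and a protein-coding biotype.  The filter is
    idempotent and order-independent.
    """
    _check_columns(table)
    if condition is not None and "condition" in table.columns:
        table = table[table["condition"] == condition]
    if table.empty:
        return set()
    fc = table[_fc_columns(table)].abs().max(axis=1)
    keep = (
        (table["fdr"] < fdr_max)
        & (fc > log2fc_min)
        & (table["max_group_mean"] > min_group_mean)
        & (table["biotype"] == biotype)
    )
    return set(table.loc[keep, "gene_id"])


def build_profile_matrix(
    table: pd.DataFrame,
    genes: set[str] | list[str],
    condition: str | None = None,
) -> pd.DataFrame:
    """Per-gene min–max-scaled profiles at {0, 2, 4, 6, 8} h.

    The 0-h column is the control-relative fold change 0 prior to scaling;
    each row is then scaled to [0, 1] (constant rows map to zeros).
    """
    _check_columns(table)
    if condition is not None and "condition" in table.columns:
        table = table[table["condition"] == condition]
    table = table.set_index("gene_id")
    genes = sorted(genes)
    missing = [g for g in genes if g not in table.index]
    if missing:
        raise KeyError(f"genes absent from table: {missing[:5]}")
    fc_cols = _fc_columns(table)
    raw = np.column_stack(
        [np.zeros(len(genes))] + [table.loc[genes, c].to_numpy(float) for c in fc_cols]
    )
    scaled = np.vstack([minmax_scale(row) for row in raw])
    return pd.DataFrame(scaled, index=pd.Index(genes, name="gene_id"),
                        columns=list(PROFILE_TIMES))


@dataclass
class ClusterSet:
    """K-means cluster assignments plus per-cluster mean profiles.

    Labels run 1..k and are renumbered by descending peak time of the
    cluster-mean profile (late-peaking/sustained clusters first), a stable
    documented ordering.
    """

    condition: str
    k: int
    assignments: pd.Series  # gene_id -> label in 1..k
    profiles: pd.DataFrame  # label x timepoint mean scaled profile
    sds: pd.DataFrame
    sizes: pd.Series
    seed: int

    def genes(self, label: int) -> set[str]:
        return set(self.assignments.index[self.assignments == label])

    def gene_sets(self) -> dict[int, set[str]]:
        return {int(lb): self.genes(int(lb)) for lb in self.profiles.index}


class TimecourseKMeans(ClusterMixin, BaseEstimator):
    """Euclidean k-means on scaled time-course profiles.

    k-means++ initialisation, best of ``n_restarts`` by within-cluster sum
    of squares, deterministic for a given ``random_state``.  Fitted labels
    are renumbered 1..k by descending peak time of the cluster mean
    (ties: larger cluster first).
    """

    def __init__(self, n_clusters: int = 5, random_state: int = 0, n_restarts: int = 10):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.n_restarts = n_restarts

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.n_clusters > X.shape[0]:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds number of rows {X.shape[0]}"
            )
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=self.n_restarts,
            random_state=self.random_state,
        ).fit(X.to_numpy(float))
        raw = km.labels_
        times = np.asarray(X.columns, dtype=float)
        order = []
        for lb in range(self.n_clusters):
            members = X.to_numpy(float)[raw == lb]
            # duplicate points can leave a centroid without members
            peak = times[int(np.argmax(members.mean(axis=0)))] if members.size else -np.inf
            order.append((-peak, -members.shape[0], lb))
        relabel = {old: new + 1 for new, (_, _, old) in enumerate(sorted(order))}
        self.labels_ = np.array([relabel[lb] for lb in raw])
        self.inertia_ = float(km.inertia_)
        self.feature_times_ = times
        self.index_ = X.index
        return self

    def to_cluster_set(self, X, condition: str) -> ClusterSet:
        """Package fitted labels as a :class:`ClusterSet` for ``X``."""
        X = pd.DataFrame(X)
        labels = pd.Series(self.labels_, index=X.index, name="cluster")
        prof = X.groupby(labels).mean()
        sds = X.groupby(labels).std(ddof=0)
        sizes = labels.value_counts().sort_index()
        return ClusterSet(
            condition=condition,
            k=self.n_clusters,
            assignments=labels,
            profiles=prof,
            sds=sds,
            sizes=sizes,
            seed=self.random_state,
        )


def choose_k(
    matrix: pd.DataFrame,
    k_range: range = range(2, 11),
    seed: int = 0,
    n_restarts: int = 10,
    min_cluster_frac: float = 0.05,
):
    """Cluster-number diagnostics and a recommendation.

    For each k: silhouette score, within-cluster SS (elbow) and the
    coefficient of variation of cluster sizes.  Recommended k maximises
    the silhouette among k whose smallest cluster holds at least
    ``min_cluster_frac`` of genes; the recommendation is advisory.

    Returns ``(recommended_k, diagnostics_frame)``.
    """
    X = matrix.to_numpy(float)
    ks = list(k_range)
    if X.shape[0] < max(ks) + 1:
        raise ValueError(
            f"need at least {max(ks) + 1} rows to scan k up to {max(ks)}"
        )
    degenerate = bool(np.all(X == X[0]))
    rows = []
    for k in ks:
        est = TimecourseKMeans(k, random_state=seed, n_restarts=n_restarts).fit(matrix)
        sizes = np.bincount(est.labels_)[1:]
        sil = np.nan
        if not degenerate and len(np.unique(est.labels_)) > 1:
            sil = float(silhouette_score(X, est.labels_))
        rows.append(
            {
                "k": k,
                "silhouette": sil,
                "within_ss": est.inertia_,
                "size_cv": float(np.std(sizes) / np.mean(sizes)),
                "min_cluster_frac": float(sizes.min() / X.shape[0]),
            }
        )
    diag = pd.DataFrame(rows)
    diag.attrs["degenerate"] = degenerate
    if degenerate or diag["silhouette"].isna().all():
        return ks[0], diag
    ok = diag[diag["min_cluster_frac"] >= min_cluster_frac]
    pool = ok if not ok.empty else diag
    rec = int(pool.loc[pool["silhouette"].idxmax(), "k"])
    return rec, diag


def cluster_genes(
    matrix: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    condition: str = "custom",
) -> ClusterSet:
    """K-means clustering of the scaled profile matrix for one condition."""
    est = TimecourseKMeans(k, random_state=seed, n_restarts=n_restarts).fit(matrix)
    return est.to_cluster_set(matrix, condition)


def jnk_dependent_genes(
    contrast: pd.DataFrame,
    cluster_set: ClusterSet | None = None,
    log2fc_min: float = 1.0,
    signed: bool = False,
):
    """Genes differing between stimulated and kinase-inhibited conditions.

    ``contrast`` holds per-gene log2 fold changes (sustained vs. JNK
    inhibitor) per timepoint; a gene qualifies with |log2FC| > 1 at ≥ 1
    timepoint (``signed=True`` requires upregulation instead).  With a
    cluster set, also reports how many such genes fall in each cluster.

    Returns ``genes`` or ``(genes, per_cluster_counts)``.
    """
    if "gene_id" not in contrast.columns:
        raise ValueError("contrast table must have a gene_id column")
    fc = contrast[_fc_columns(contrast)]
    hit = (fc > log2fc_min) if signed else (fc.abs() > log2fc_min)
    genes = set(contrast.loc[hit.any(axis=1), "gene_id"])
    if cluster_set is None:
        return genes
    counts = {
        lb: len(genes & members) for lb, members in cluster_set.gene_sets().items()
    }
    return genes, pd.Series(counts, name="n_jnk_dependent").sort_index()


def cluster_overlap(set_a: set[str], set_b: set[str]) -> dict:
    """Overlap metrics between two gene sets.

    Reports the intersection size, Jaccard index, both directional
    fractions, and — as the headline figure — the shared fraction of the
    smaller set.
    """
    if not set_a or not set_b:
        raise ValueError("overlap of an empty gene set is undefined")
    inter = len(set_a & set_b)
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_intersection": inter,
        "jaccard": inter / len(set_a | set_b),
        "frac_a": inter / len(set_a),
        "frac_b": inter / len(set_b),
        "shared_frac_smaller": inter / min(len(set_a), len(set_b)),
    }


def crossref_halflives(
    cluster_set: ClusterSet,
    halflife_tables: pd.DataFrame,
) -> pd.DataFrame:
    """Mean measured mRNA half-life per (cluster, study), with coverage.

    ``halflife_tables`` is tidy with columns study_id, gene_id,
    half_life_h.  Genes absent from a study are counted, never imputed; a
    (cluster, study) cell with no matched genes reports a missing mean.
    """
    for c in ("study_id", "gene_id", "half_life_h"):
        if c not in halflife_tables.columns:
            raise ValueError(f"half-life table is missing column {c!r}")
    if (halflife_tables["half_life_h"] <= 0).any():
        raise ValueError("half-lives must be positive")
    rows = []
    for study, sub in halflife_tables.groupby("study_id"):
        hl = sub.set_index("gene_id")["half_life_h"]
        for lb, members in cluster_set.gene_sets().items():
            matched = hl.index.intersection(sorted(members))
            rows.append(
                {
                    "cluster": lb,
                    "study_id": study,
                    "mean_half_life_h": float(hl.loc[matched].mean())
                    if len(matched)
                    else np.nan,
                    "n_matched": int(len(matched)),
                    "n_unmatched": int(len(members) - len(matched)),
                }
            )
    return pd.DataFrame(rows).sort_values(["cluster", "study_id"]).reset_index(drop=True)
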