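"""Cluster the selected genes into tissue-phenotype pattern groups.

The selected genes are grouped into ``k`` clusters (default 3) either by
k-means (Euclidean, 50 restarts) or by hierarchical clustering (Euclidean,
average linkage, tree cut at k). The default feature space is each gene's
4-vector of fitted coefficients (beta_mg, beta_mf, beta_ig, beta_if), which
makes the recovered clusters directly interpretable as sign patterns;
concatenated z-scored expression across both tissues is available as an
alternative feature space.

Cluster labels are renumbered by descending mean likelihood score of their
members so the labelling is deterministic and independent of input order.
Each cluster is tagged with the nearest of three canonical sign patterns:

* ``cluster-1-like`` — (+, -, +, -): expression rises with insulin
  sensitivity (GIR) and falls with fasting glucose in both tissues.
* ``cluster-2-like`` — (+, -, -, +): muscle as above, IMAT opposing.
* ``cluster-3-like`` — (-, +, 0, 0): muscle falls with GIR and rises with
  FG; no IMAT effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import ConsistencyError, InvalidParameterError
from .regression import BETA_NAMES, GeneModelFit

CANONICAL_PATTERNS = {
    "cluster-1-like": np.array([1, -1, 1, -1]),
    "cluster-2-like": np.array([1, -1, -1, 1]),
    "cluster-3-like": np.array([-1, 1, 0, 0]),
}


@dataclass
class GeneClusterAssignment:
    labels: pd.Series          # gene_id -> cluster label in 1..k
    k: int
    method: str
    feature_space: str
    seed: int
    silhouette: float | None = None

    def sizes(self) -> dict:
        return self.labels.value_counts().to_dict()

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def beta_features(fits) -> pd.DataFrame:
    """Gene x 4 matrix of fitted coefficients, the default feature space."""
    return pd.DataFrame(
        [f.beta_dict() for f in fits],
        index=[f.gene_id for f in fits],
        columns=list(BETA_NAMES),
    )


def expression_features(muscle, imat, gene_ids) -> pd.DataFrame:
    """Concatenated per-gene z-scored expression across both tissues."""
    blocks = []
    for mat in (muscle, imat):
        sub = mat.values.loc[list(gene_ids)]
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
        z.columns = [f"{mat.tissue}:{c}" for c in z.columns]
        blocks.append(z)
    return pd.concat(blocks, axis=1)


def cluster_genes(features: pd.DataFrame, k: int = 3, method: str = "kmeans",
                  scores: pd.Series | None = None, seed: int = 0,
                  feature_space: str = "beta") -> GeneClusterAssignment:
    """Assign each gene to one of ``k`` clusters.

    ``scores`` (gene_id -> likelihood score) drives the deterministic
    renumbering: cluster 1 has the highest mean member score. Without scores,
    clusters are renumbered by descending size (ties by first member id).
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if k > len(features):
        raise InvalidParameterError(f"k={k} exceeds the {len(features)} genes provided")
    X = features.to_numpy(float)
    if not np.isfinite(X).all():
        raise InvalidParameterError("features must be finite")

    if k == 1:
        raw = np.zeros(len(features), dtype=int)
    elif method == "kmeans":
        km = KMeans(n_clusters=k, n_init=50, random_state=seed)
        raw = km.fit_predict(X)
    elif method == "hierarchical":
        raw = fcluster(linkage(X, method="average", metric="euclidean"),
                       t=k, criterion="maxclust") - 1
    else:
        raise InvalidParameterError(f"unknown clustering method '{method}'")

    labels = pd.Series(raw, index=features.index)
    # deterministic renumbering: by descending mean member score, else by size
    if scores is not None:
        keyfun = lambda c: (-scores.loc[labels.index[labels == c]].mean(),
                            sorted(labels.index[labels == c])[0])
    else:
        keyfun = lambda c: (-(labels == c).sum(), sorted(labels.index[labels == c])[0])
    order = sorted(labels.unique(), key=keyfun)
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = labels.map(remap)

    sil = None
    if 1 < k < len(features) and len(np.unique(raw)) > 1:
        sil = float(silhouette_score(X, raw, metric="euclidean"))
    return GeneClusterAssignment(labels=labels, k=k, method=method,
                                 feature_space=feature_space, seed=seed,
                                 silhouette=sil)


def _nearest_pattern(mean_beta: np.ndarray) -> str:
    """Tag a mean-beta vector with the closest canonical sign pattern.

    Entries below a quarter of the largest magnitude count as zero; a
    canonical zero matches a zeroed entry exactly and costs half a point
    against a nonzero one.
    """
    scale = np.max(np.abs(mean_beta))
    signs = np.sign(mean_beta)
    if scale > 0:
        signs[np.abs(mean_beta) < 0.25 * scale] = 0
    best, best_score = None, -np.inf
    for tag, pattern in CANONICAL_PATTERNS.items():
        score = 0.0
        for s, p in zip(signs, pattern):
            if s == p:
                score += 1.0
            elif s == 0 or p == 0:
                score += 0.5
        if score > best_score:
            best, best_score = tag, score
    return best


@dataclass
class ClusterPatternSummary:
    table: pd.DataFrame  # one row per cluster: mean betas, consensus, tag

    def tag_of(self, cluster: int) -> str:
        return self.table.set_index("cluster").loc[cluster, "pattern_tag"]


def summarize_cluster_patterns(assignment: GeneClusterAssignment,
                               fits) -> ClusterPatternSummary:
    """Per-cluster mean beta vector, per-entry sign consensus and pattern tag."""
    by_gene = {f.gene_id: f for f in fits}
    missing = [g for g in assignment.labels.index if g not in by_gene]
    if missing:
        raise ConsistencyError(f"no fit for assigned gene(s): {missing[:5]}")
    rows = []
    for cluster in sorted(assignment.labels.unique()):
        members = assignment.members(cluster)
        betas = np.array([[by_gene[g].beta_dict()[name] for name in BETA_NAMES]
                          for g in members])
        mean_beta = betas.mean(axis=0)
        signs = np.sign(betas)
        consensus = []
        for col in range(4):
            s = signs[:, col]
            majority = max((np.sum(s == v) for v in (-1.0, 0.0, 1.0)))
            consensus.append(majority / len(members))
        row = {"cluster": cluster, "n_genes": len(members)}
        row.update({f"mean_{n}": v for n, v in zip(BETA_NAMES, mean_beta)})
        row.update({f"consensus_{n}": c for n, c in zip(BETA_NAMES, consensus)})
        row["pattern_tag"] = _nearest_pattern(mean_beta)
        rows.append(row)
    return ClusterPatternSummary(pd.DataFrame(rows))


def pair_counting_ari(labels_a, labels_b) -> float:
    """Adjusted Rand index by explicit all-pairs counting.

    Quadratic in the number of items; kept as a transparent, formula-level
    implementation for verifying clustering recovery.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise InvalidParameterError("label vectors differ in length")
    n = len(a)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    s_a, s_b = same_a[iu], same_b[iu]
    n11 = np.sum(s_a & s_b)
    n00 = np.sum(~s_a & ~s_b)
    n10 = np.sum(s_a & ~s_b)
    n01 = np.sum(~s_a & s_b)
    total = n11 + n00 + n10 + n01
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0
    return float((n11 - expected) / (max_index - expected))
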