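"""Participant k-nearest-neighbour networks and expression-based classification.

One directed network is built per (tissue, gene cluster): each participant
points to its k most similar participants (Euclidean distance over the
cluster's z-scored genes, default k=3). A participant's predictive
classification score in a network is the largest class fraction among its
direct out-neighbours, and the attained class is the expression-based call.
Scores are then averaged — per tissue across the three cluster networks,
and overall across both tissues — and compared with the clinical labels to
flag participants whose molecular neighbourhood contradicts their clinical
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix
from .errors import ConsistencyError, InvalidParameterError

AMBIGUOUS = "ambiguous"


@dataclass
class NetworkSpec:
    k: int = 3
    zscore_features: bool = True  # z-score each gene across participants

    def validate(self, n_participants: int) -> None:
        if not 1 <= self.k < n_participants:
            raise InvalidParameterError(
                f"k={self.k} requires at least k+1={self.k + 1} participants, "
                f"have {n_participants}"
            )


@dataclass
class NeighborNetwork:
    graph: nx.DiGraph
    tissue: str
    cluster: object
    k: int

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    def neighbors_of(self, pid: str) -> list[str]:
        return list(self.graph.successors(pid))

    def edge_frame(self) -> pd.DataFrame:
        rows = [(u, v, d["distance"], self.tissue, self.cluster)
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "distance",
                                           "tissue", "cluster"])


def build_knn_network(expr_subset: ExpressionMatrix, spec: NetworkSpec,
                      cluster: object = None) -> NeighborNetwork:
    """Directed kNN graph over participants from one tissue/cluster gene set.

    Distance ties are broken by participant-id lexicographic order so the
    graph is fully deterministic.
    """
    pids = expr_subset.participant_ids
    spec.validate(len(pids))
    X = expr_subset.values.to_numpy(float).T  # participants x genes
    if not np.isfinite(X).all():
        raise InvalidParameterError("expression features must be finite")
    if spec.zscore_features:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))

    g = nx.DiGraph()
    g.add_nodes_from(pids)
    for a, pid in enumerate(pids):
        order = sorted((i for i in range(len(pids)) if i != a),
                       key=lambda i: (dist[a, i], pids[i]))
        for i in order[:spec.k]:
            g.add_edge(pid, pids[i], distance=float(dist[a, i]))
    return NeighborNetwork(graph=g, tissue=expr_subset.tissue,
                           cluster=cluster, k=spec.k)


@dataclass
class ClassificationScore:
    """Per-participant class fractions, score and predicted label."""

    fractions: pd.DataFrame       # participants x classes, rows sum to 1
    level: str                    # "cluster", "tissue" or "overall"
    tissue: str | None = None
    cluster: object = None
    meta: dict = field(default_factory=dict)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def score(self) -> pd.Series:
        return self.fractions.max(axis=1)

    @property
    def predicted(self) -> pd.Series:
        frac = self.fractions
        best = frac.max(axis=1)
        # count classes attaining the max; an exact tie is ambiguous
        ties = frac.eq(best, axis=0).sum(axis=1)
        pred = frac.idxmax(axis=1).where(ties == 1, AMBIGUOUS)
        if self.level != "cluster":
            # for averaged levels a call requires a strict majority
            pred = pred.where(best > 0.5, AMBIGUOUS)
        return pred.rename("predicted")

    def as_frame(self) -> pd.DataFrame:
        out = self.fractions.copy()
        out["score"] = self.score
        out["predicted"] = self.predicted
        out.insert(0, "level", self.level)
        out.insert(1, "tissue", self.tissue or "both")
        out.insert(2, "cluster", self.cluster if self.cluster is not None else "all")
        return out.rename_axis("participant_id").reset_index()


def classification_score(net: NeighborNetwork, labels: pd.Series,
                         classes=None) -> ClassificationScore:
    """Class fractions of each participant's direct out-neighbours."""
    missing = [p for p in net.participant_ids if p not in labels.index]
    if missing:
        raise ConsistencyError(f"unlabelled participant(s): {missing[:5]}")
    if classes is None:
        classes = sorted(labels.unique())
    rows = {}
    for pid in net.participant_ids:
        neigh = net.neighbors_of(pid)
        counts = labels.loc[neigh].value_counts()
        rows[pid] = [counts.get(c, 0) / len(neigh) for c in classes]
    fractions = pd.DataFrame.from_dict(rows, orient="index", columns=list(classes))
    return ClassificationScore(fractions=fractions, level="cluster",
                               tissue=net.tissue, cluster=net.cluster)


def average_scores(scores, level: str) -> ClassificationScore:
    """Average class fractions across networks (per tissue, or overall)."""
    if not scores:
        raise InvalidParameterError("no scores to average")
    ref = scores[0].fractions
    for s in scores[1:]:
        if sorted(s.fractions.index) != sorted(ref.index):
            raise ConsistencyError("scores cover different participant sets")
        if list(s.fractions.columns) != list(ref.columns):
            raise ConsistencyError("scores cover different classes")
    stacked = [s.fractions.loc[ref.index] for s in scores]
    mean = sum(stacked) / len(stacked)
    tissues = {s.tissue for s in scores}
    return ClassificationScore(
        fractions=mean, level=level,
        tissue=tissues.pop() if len(tissues) == 1 else None,
        meta={"n_networks": len(scores)},
    )


def compare_to_clinical(per_cluster: dict, per_tissue: dict,
                        overall: ClassificationScore,
                        clin: ClinicalTable) -> pd.DataFrame:
    """Discordance report against the clinical classification.

    ``per_cluster`` maps (tissue, cluster) to a cluster-level score;
    ``per_tissue`` maps tissue to its cluster-averaged score. A participant
    is *non-unique* in a tissue when its three cluster-level calls disagree,
    and *discordant* at a level when the call differs from the clinical
    label (ambiguous calls count as discordant).
    """
    labels = clin.labels()
    pids = overall.participant_ids
    missing = [p for p in pids if p not in labels.index]
    if missing:
        raise ConsistencyError(f"participants without clinical label: {missing[:5]}")

    rows = []
    for pid in pids:
        row = {"participant_id": pid, "clinical": labels[pid]}
        for tissue, tscore in sorted(per_tissue.items()):
            calls = [sc.predicted[pid] for (t, _), sc in sorted(per_cluster.items())
                     if t == tissue]
            row[f"{tissue}_non_unique"] = len(set(calls)) > 1
            row[f"{tissue}_predicted"] = tscore.predicted[pid]
            row[f"{tissue}_discordant"] = tscore.predicted[pid] != labels[pid]
        row["overall_predicted"] = overall.predicted[pid]
        row["overall_score"] = overall.score[pid]
        row["overall_discordant"] = overall.predicted[pid] != labels[pid]
        rows.append(row)
    return pd.DataFrame(rows)


def run_network_stage(muscle: ExpressionMatrix, imat: ExpressionMatrix,
                      assignment, clin: ClinicalTable, spec: NetworkSpec):
    """Build all (tissue x cluster) networks and the score hierarchy.

    Returns ``(networks, per_cluster, per_tissue, overall, report)`` where
    networks maps (tissue, cluster) to its :class:`NeighborNetwork`.
    """
    labels = clin.labels()
    classes = sorted(labels.unique())
    networks, per_cluster = {}, {}
    for mat in (muscle, imat):
        for cluster in sorted(assignment.labels.unique()):
            genes = assignment.members(cluster)
            net = build_knn_network(mat.subset_genes(genes), spec, cluster=cluster)
            networks[(mat.tissue, cluster)] = net
            per_cluster[(mat.tissue, cluster)] = classification_score(
                net, labels, classes=classes)
    per_tissue = {
        tissue: average_scores(
            [sc for (t, _), sc in per_cluster.items() if t == tissue], "tissue")
        for tissue in ("muscle", "imat")
    }
    overall = average_scores(list(per_cluster.values()), "overall")
    report = compare_to_clinical(per_cluster, per_tissue, overall, clin)
    return networks, per_cluster, per_tissue, overall, report
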