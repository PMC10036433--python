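"""Participant kNN networks and expression-based classification."""

import numpy as np
import pandas as pd
import pytest

import imatnet as im
from imatnet.datatypes import ExpressionMatrix
from imatnet.errors import ConsistencyError, InvalidParameterError
from imatnet.knn import (AMBIGUOUS, ClassificationScore, NetworkSpec,
                         average_scores, build_knn_network,
                         classification_score, run_network_stage)

from conftest import truth_labels


def matrix_from_coords(coords, tissue="muscle"):
    """One-gene expression matrix placing participants at 1-D coordinates."""
    pids = [f"P{i}" for i in range(len(coords))]
    return ExpressionMatrix(tissue, pd.DataFrame([coords], index=["g1"], columns=pids))


def frac_score(fractions, classes=("obesity", "type2diabetes"), level="cluster"):
    frame = pd.DataFrame(fractions, columns=list(classes),
                         index=[f"P{i}" for i in range(len(fractions))])
    return ClassificationScore(fractions=frame, level=level)


class TestBuildNetwork:
    def test_four_participants_k3_complete(self):
        mat = matrix_from_coords([0.0, 1.0, 2.0, 3.0])
        net = build_knn_network(mat, NetworkSpec(k=3, zscore_features=False))
        for pid in net.participant_ids:
            assert len(net.neighbors_of(pid)) == 3
            assert pid not in net.neighbors_of(pid)
        assert net.graph.number_of_edges() == 12

    def test_line_coordinates_match_bruteforce(self):
        coords = [0.0, 1.0, 2.0, 10.0, 11.0]
        mat = matrix_from_coords(coords)
        net = build_knn_network(mat, NetworkSpec(k=2, zscore_features=False))
        # exhaustive pairwise-distance oracle
        pids = mat.participant_ids
        for a, pid in enumerate(pids):
            dists = sorted((abs(coords[a] - coords[b]), pids[b])
                           for b in range(len(pids)) if b != a)
            expected = {p for _, p in dists[:2]}
            assert set(net.neighbors_of(pid)) == expected
        assert set(net.neighbors_of("P0")) == {"P1", "P2"}

    def test_distance_ties_break_lexicographically(self):
        mat = matrix_from_coords([0.0, 1.0, -1.0, 5.0])  # P1 and P2 tie for P0
        net = build_knn_network(mat, NetworkSpec(k=1, zscore_features=False))
        assert net.neighbors_of("P0") == ["P1"]

    def test_too_few_participants_rejected(self):
        mat = matrix_from_coords([0.0, 1.0, 2.0])
        with pytest.raises(InvalidParameterError):
            build_knn_network(mat, NetworkSpec(k=3))


class TestClassificationScore:
    @pytest.fixture()
    def labelled_net(self):
        mat = matrix_from_coords([0.0, 0.1, 0.2, 5.0])
        net = build_knn_network(mat, NetworkSpec(k=3, zscore_features=False))
        labels = pd.Series(["obesity", "obesity", "obesity", "type2diabetes"],
                           index=["P0", "P1", "P2", "P3"])
        return net, labels

    def test_unanimous_neighbours(self, labelled_net):
        net, labels = labelled_net
        score = classification_score(net, labels)
        # P3's three neighbours are all obesity
        assert score.fractions.loc["P3", "obesity"] == 1.0
        assert score.score["P3"] == 1.0
        assert score.predicted["P3"] == "obesity"

    def test_two_thirds_majority(self, labelled_net):
        net, labels = labelled_net
        score = classification_score(net, labels)
        # P0 sees (P1: OB, P2: OB, P3: T2D) -> hand-enumerated (2/3, 1/3)
        assert score.fractions.loc["P0", "obesity"] == pytest.approx(2 / 3)
        assert score.fractions.loc["P0", "type2diabetes"] == pytest.approx(1 / 3)
        assert score.score["P0"] == pytest.approx(2 / 3)
        assert score.predicted["P0"] == "obesity"

    def test_k3_binary_scores_in_two_thirds_or_one(self, labelled_net):
        net, labels = labelled_net
        score = classification_score(net, labels)
        assert set(np.round(score.score, 10)) <= {round(2 / 3, 10), 1.0}
        np.testing.assert_allclose(score.fractions.sum(axis=1), 1.0)

    def test_even_k_tie_is_ambiguous(self):
        mat = matrix_from_coords([0.0, 1.0, 2.0, 3.0, 4.0])
        net = build_knn_network(mat, NetworkSpec(k=4, zscore_features=False))
        labels = pd.Series(["obesity", "obesity", "x", "type2diabetes", "type2diabetes"],
                           index=[f"P{i}" for i in range(5)])
        labels["P2"] = "obesity"  # P2's 4 neighbours: 2 OB, 2 T2D
        score = classification_score(net, labels)
        assert score.predicted["P2"] == AMBIGUOUS

    def test_unlabelled_node_rejected(self, labelled_net):
        net, labels = labelled_net
        with pytest.raises(ConsistencyError, match="P3"):
            classification_score(net, labels.drop("P3"))


class TestAverageScores:
    def test_unanimous_networks(self):
        s = frac_score([[1.0, 0.0]] * 3)
        avg = average_scores([s, s, s], level="overall")
        assert avg.predicted["P0"] == "obesity"
        assert avg.score["P0"] == 1.0

    def test_mean_fraction_two_thirds(self):
        parts = [frac_score([[1 - f, f]]) for f in (1 / 3, 2 / 3, 1.0)]
        avg = average_scores(parts, level="tissue")
        assert avg.fractions.loc["P0", "type2diabetes"] == pytest.approx(2 / 3)
        assert avg.predicted["P0"] == "type2diabetes"

    def test_boundary_half_is_ambiguous(self):
        parts = [frac_score([[1 - f, f]]) for f in (1 / 3, 2 / 3, 1 / 2)]
        avg = average_scores(parts, level="overall")
        assert avg.fractions.loc["P0", "type2diabetes"] == pytest.approx(0.5)
        assert avg.predicted["P0"] == AMBIGUOUS

    def test_mismatched_participants_rejected(self):
        a = frac_score([[1.0, 0.0]])
        b = frac_score([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ConsistencyError):
            average_scores([a, b], level="overall")


@pytest.fixture(scope="module")
def stage():
    cohort = im.generate_cohort(im.CohortSpec(seed=51))
    spec = im.GeneSpec(n_null=0, noise_sd=0.2, seed=52)
    muscle, imat, truth = im.generate_expression(cohort, spec)
    assignment = im.GeneClusterAssignment(
        labels=truth_labels(truth), k=3, method="kmeans",
        feature_space="beta", seed=0)
    return cohort, run_network_stage(muscle, imat, assignment, cohort,
                                     NetworkSpec(k=3))


class TestNetworkStage:
    def test_six_networks_emitted(self, stage):
        _, (networks, per_cluster, per_tissue, overall, _) = stage
        assert len(networks) == 6
        assert {t for t, _ in networks} == {"muscle", "imat"}
        assert len(per_cluster) == 6 and set(per_tissue) == {"muscle", "imat"}

    def test_out_degree_and_no_self_edges(self, stage):
        _, (networks, *_rest) = stage
        for net in networks.values():
            for pid in net.participant_ids:
                assert len(net.neighbors_of(pid)) == 3
                assert pid not in net.neighbors_of(pid)

    def test_separated_cohort_mostly_concordant(self, stage):
        _, (*_unused, report) = stage
        assert (~report["overall_discordant"]).mean() >= 0.8

    def test_report_covers_both_tissue_levels(self, stage):
        _, (*_unused, report) = stage
        for col in ("muscle_predicted", "imat_predicted", "muscle_non_unique",
                    "overall_predicted", "overall_discordant"):
            assert col in report.columns

    def test_planted_mislabel_flagged_discordant(self):
        cohort = im.generate_cohort(im.CohortSpec(seed=53))
        target = cohort.frame.query("group == 'obesity'")["participant_id"].iloc[2]
        spec = im.GeneSpec(n_null=0, noise_sd=0.2, seed=54)
        muscle, imat, truth = im.generate_expression(cohort, spec,
                                                     mislabeled=(target,))
        assignment = im.GeneClusterAssignment(
            labels=truth_labels(truth), k=3, method="kmeans",
            feature_space="beta", seed=0)
        *_unused, report = run_network_stage(muscle, imat, assignment, cohort,
                                             NetworkSpec(k=3))
        row = report.set_index("participant_id").loc[target]
        assert row["overall_discordant"]
        assert row["overall_predicted"] == "type2diabetes"

    def test_non_unique_definition(self):
        """Disagreeing cluster-level calls mark a participant non-unique."""
        fractions = [frac_score([[1.0, 0.0], [1.0, 0.0]]),
                     frac_score([[0.0, 1.0], [1.0, 0.0]]),
                     frac_score([[1.0, 0.0], [1.0, 0.0]])]
        for s, c in zip(fractions, (1, 2, 3)):
            s.tissue, s.cluster = "muscle", c
        per_cluster = {("muscle", c): s for c, s in zip((1, 2, 3), fractions)}
        per_tissue = {"muscle": average_scores(fractions, "tissue")}
        overall = average_scores(fractions, "overall")
        clin = im.ClinicalTable(pd.DataFrame({
            "participant_id": ["P0", "P1"],
            "group": ["obesity", "obesity"],
            "GIR": [5.0, 6.0], "FG": [4.5, 5.0]}))
        report = im.compare_to_clinical(per_cluster, per_tissue, overall, clin)
        report = report.set_index("participant_id")
        assert report.loc["P0", "muscle_non_unique"]
        assert not report.loc["P1", "muscle_non_unique"]
        assert not report.loc["P0", "overall_discordant"]  # 2/3 still obesity
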