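import numpy as np
import pandas as pd
import pytest

import imatnet as im

CLUSTER_TO_LABEL = {"cluster1": 1, "cluster2": 2, "cluster3": 3}


@pytest.fixture(scope="session")
def cohort():
    """Default cross-sectional cohort (10 obesity + 6 type 2 diabetes)."""
    return im.generate_cohort(im.CohortSpec(seed=11))


@pytest.fixture(scope="session")
def planted(cohort):
    """Signal-only expression matrices with the default 14/23/22 planting."""
    spec = im.GeneSpec(n_null=0, noise_sd=0.3, seed=13)
    muscle, imat, truth = im.generate_expression(cohort, spec)
    return muscle, imat, truth


@pytest.fixture(scope="session")
def planted_fits(cohort, planted):
    muscle, imat, _ = planted
    m, pheno = im.align(muscle, cohort)
    i, _ = im.align(imat, cohort)
    return im.fit_all_genes(m, i, pheno)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def truth_labels(truth: pd.DataFrame) -> pd.Series:
    """Planted template labels as integer cluster ids, indexed by gene."""
    return truth.set_index("gene_id")["template"].map(CLUSTER_TO_LABEL)


def joint_fit_oracle(x_m, x_i, y_g, y_f):
    """Independent normal-equations oracle: explicit 2x2 matrix inversion,
    one response at a time (valid because both responses share X)."""
    z = lambda v: (np.asarray(v, float) - np.mean(v)) / np.std(v)
    X = np.column_stack([z(x_m), z(x_i)])
    G = X.T @ X
    det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
    Ginv = np.array([[G[1, 1], -G[0, 1]], [-G[1, 0], G[0, 0]]]) / det
    beta = np.empty((2, 2))
    for col, y in enumerate((z(y_g), z(y_f))):
        beta[:, col] = Ginv @ (X.T @ y)
    return beta


def score_oracle(x_m, x_i, y_g, y_f):
    """Likelihood-ratio score from residual covariance determinants only."""
    z = lambda v: (np.asarray(v, float) - np.mean(v)) / np.std(v)
    X = np.column_stack([z(x_m), z(x_i)])
    Y = np.column_stack([z(y_g), z(y_f)])
    n = len(Y)
    beta = joint_fit_oracle(x_m, x_i, y_g, y_f)
    E = Y - X @ beta
    s1 = E.T @ E / n
    s0 = Y.T @ Y / n
    det2 = lambda S: S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    return 0.5 * n * np.log(det2(s0) / det2(s1))
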