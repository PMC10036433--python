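"""Per-gene joint two-response regression and likelihood-ratio gene scoring.

For each gene j the model links the two insulin-resistance responses, GIR
(g) and fasting glucose (f), to the gene's expression in muscle (m) and
IMAT (i):

    Y = X_j B + E

with Y the n x 2 response matrix, X_j the n x 2 predictor matrix (muscle
and IMAT expression of gene j) and B the 2 x 2 coefficient matrix with
entries beta_mg, beta_mf, beta_ig, beta_if. All four coefficients are
estimated jointly by least squares, which is also the Gaussian maximum
likelihood solution under an unrestricted 2 x 2 residual covariance.

Every variable is z-scored (population SD) before fitting and the model
carries no intercept, so beta values are comparable across genes. Genes are
scored by the log-likelihood ratio of the full model against the
intercept-only (here: zero, since responses are centred) null:

    score = loglik_full - loglik_null = (n / 2) * ln(det S0 / det S1)

where S0 and S1 are the ML residual covariance matrices of the null and
full models. The score is >= 0 because the full model nests the null.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, PhenotypeVector
from .errors import CollinearityError, DegenerateInputError, InvalidParameterError

log = logging.getLogger("imatnet.regression")

#: condition-number ceiling on the 2x2 predictor Gram matrix
CONDITION_LIMIT = 1e8

BETA_NAMES = ("beta_mg", "beta_mf", "beta_ig", "beta_if")


def standardize(values) -> np.ndarray:
    """z-score a vector with the population SD (mean 0, SD 1)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise InvalidParameterError("standardize expects a vector of length >= 2")
    sd = v.std()
    if sd == 0:
        raise DegenerateInputError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


@dataclass
class GeneModelFit:
    """Fit result for one gene's joint two-response regression."""

    gene_id: str
    beta: np.ndarray            # 2x2, rows = (muscle, imat), cols = (GIR, FG)
    resid_cov: np.ndarray       # 2x2 ML residual covariance S1
    resid_cov_det: float
    loglik_full: float
    loglik_null: float
    n_used: int

    @property
    def score(self) -> float:
        return self.loglik_full - self.loglik_null

    def beta_dict(self) -> dict:
        b = self.beta
        return {"beta_mg": b[0, 0], "beta_mf": b[0, 1],
                "beta_ig": b[1, 0], "beta_if": b[1, 1]}


def _gaussian_loglik(n: int, cov: np.ndarray) -> float:
    """Bivariate Gaussian ML log-likelihood given the ML covariance.

    A numerically singular covariance means a perfect fit; the likelihood
    diverges and is reported as +inf (the score stays well ordered).
    """
    p = cov.shape[0]
    det = float(np.linalg.det(cov))
    if det <= 1e-300:
        return math.inf
    return -0.5 * n * (p * math.log(2 * math.pi) + math.log(det) + p)


def fit_gene_model(x_m, x_i, y_g, y_f, gene_id: str = "gene") -> GeneModelFit:
    """Jointly estimate the four tissue-phenotype coefficients for one gene.

    Inputs are standardised internally; a pairwise-complete mask drops
    participants with any missing value among the four vectors.
    """
    arrs = [np.asarray(v, dtype=float) for v in (x_m, x_i, y_g, y_f)]
    n_all = len(arrs[0])
    if any(len(a) != n_all for a in arrs):
        raise InvalidParameterError("all four vectors must have equal length")
    mask = ~np.any([np.isnan(a) for a in arrs], axis=0)
    if mask.sum() < n_all:
        log.info("gene %s: dropped %d participant(s) with missing values",
                 gene_id, n_all - mask.sum())
    arrs = [a[mask] for a in arrs]
    n = int(mask.sum())
    if n < 4:
        raise InvalidParameterError(f"gene {gene_id}: need >= 4 complete participants, have {n}")

    try:
        zx_m, zx_i, zy_g, zy_f = (standardize(a) for a in arrs)
    except DegenerateInputError as exc:
        raise DegenerateInputError(f"gene {gene_id}: {exc}") from exc

    X = np.column_stack([zx_m, zx_i])
    Y = np.column_stack([zy_g, zy_f])

    gram = X.T @ X
    cond = np.linalg.cond(gram)
    if cond > CONDITION_LIMIT:
        raise CollinearityError(
            f"gene {gene_id}: muscle and IMAT predictors are collinear "
            f"(Gram condition number {cond:.3g})"
        )

    beta = np.linalg.solve(gram, X.T @ Y)
    resid = Y - X @ beta
    s1 = resid.T @ resid / n
    s0 = Y.T @ Y / n
    if np.linalg.det(s0) <= 1e-300:
        raise DegenerateInputError(f"gene {gene_id}: responses are collinear")
    fit = GeneModelFit(
        gene_id=gene_id,
        beta=beta,
        resid_cov=s1,
        resid_cov_det=float(np.linalg.det(s1)),
        loglik_full=_gaussian_loglik(n, s1),
        loglik_null=_gaussian_loglik(n, s0),
        n_used=n,
    )
    if fit.score < -1e-8:
        raise DegenerateInputError(f"gene {gene_id}: negative likelihood-ratio score")
    return fit


def score_gene(fit: GeneModelFit) -> float:
    """Likelihood-ratio score: loglik_full - loglik_null."""
    return fit.score


def fit_all_genes(muscle: ExpressionMatrix, imat: ExpressionMatrix,
                  pheno: PhenotypeVector) -> list[GeneModelFit]:
    """Fit every gene shared by the two tissue matrices, in muscle-matrix order."""
    shared = [g for g in muscle.gene_ids if g in set(imat.gene_ids)]
    if not shared:
        raise InvalidParameterError("no genes shared between tissues")
    mus = muscle.values.loc[shared, pheno.participant_ids].to_numpy(float)
    ima = imat.values.loc[shared, pheno.participant_ids].to_numpy(float)
    fits = []
    for row, gid in enumerate(shared):
        fits.append(fit_gene_model(mus[row], ima[row], pheno.gir, pheno.fg, gene_id=gid))
    return fits


@dataclass
class GeneRanking:
    """Genes ordered by likelihood-ratio score (descending)."""

    table: pd.DataFrame  # gene_id, score, rank, selected
    n_selected: int

    @property
    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "gene_id"])


def rank_and_select(fits, n_top: int = 59) -> GeneRanking:
    """Rank genes by score (ties broken by gene_id) and flag the top ``n_top``."""
    if n_top < 1:
        raise InvalidParameterError("n_top must be >= 1")
    if n_top > len(fits):
        warnings.warn(
            f"requested top {n_top} of {len(fits)} genes; selecting all",
            stacklevel=2,
        )
        n_top = len(fits)
    rows = sorted(((f.gene_id, f.score) for f in fits), key=lambda t: (-t[1], t[0]))
    table = pd.DataFrame(rows, columns=["gene_id", "score"])
    table["rank"] = np.arange(1, len(table) + 1)
    table["selected"] = table["rank"] <= n_top
    return GeneRanking(table=table, n_selected=n_top)


def fits_to_frame(fits, ranking: GeneRanking | None = None) -> pd.DataFrame:
    """Flatten fits (and optionally ranking flags) into one result table."""
    rows = []
    for f in fits:
        row = {"gene_id": f.gene_id, **f.beta_dict(),
               "loglik_full": f.loglik_full, "loglik_null": f.loglik_null,
               "score": f.score, "n_used": f.n_used}
        rows.append(row)
    frame = pd.DataFrame(rows)
    if ranking is not None:
        frame = frame.merge(ranking.table[["gene_id", "rank", "selected"]], on="gene_id")
        frame = frame.sort_values("rank").reset_index(drop=True)
    return frame
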