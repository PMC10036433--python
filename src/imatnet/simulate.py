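"""Synthetic cohort generator.

The analysis was developed against cohorts whose raw data are not public, so
this module fabricates cohorts with the statistical structure the pipeline
assumes, calibrated to the published participant-demographics tables (which
print group means +/- SEM; group SD is reconstructed as SEM*sqrt(n)).

Three generators cover the two study designs:

* :func:`generate_cohort` — a cross-sectional cohort (obesity vs type 2
  diabetes) with clinical variables drawn per group.
* :func:`generate_expression` — paired muscle/IMAT expression with planted
  gene-phenotype coupling. A latent "health score" ``h`` per participant is
  the standardised first principal direction of ``(z(GIR), -z(FG))`` — high
  for insulin-sensitive, normoglycaemic participants — and each signal
  gene's expression in tissue ``t`` is ``w_t * h + noise``. The three
  template sign patterns mirror the gene clusters the regression stage is
  meant to recover.
* :func:`generate_intervention_cohort` — a longitudinal pre/post cohort with
  paired clinical draws and qPCR Ct values for a candidate-gene panel, with
  optional planted baseline-expression ~ response correlations.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` children, one per stage, so any stage can be
re-run in isolation and reproduce its slice of the simulation bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix
from .errors import DegenerateInputError, InvalidParameterError

# ---------------------------------------------------------------------------
# printed cohort tables (mean, SEM) used to parameterise the generator

#: cross-sectional cohort: group -> (n, {variable: (mean, sem)})
TABLE1_GROUPS = {
    "obesity": (10, {
        "Age": (40.5, 2.4), "BMI": (36.7, 1.6), "BW": (116.8, 7.4),
        "FFM": (71.9, 4.8), "FG": (4.9, 0.2), "Insulin": (122.2, 22.9),
        "Glucagon": (70.6, 9.7), "Height": (1.8, 0.04), "GIR": (5.1, 1.0),
        "RelFat": (38.2, 2.6),
    }),
    "type2diabetes": (6, {
        "Age": (45.7, 2.5), "BMI": (34.8, 1.7), "BW": (101.4, 6.4),
        "FFM": (63.0, 4.5), "FG": (10.2, 0.9), "Insulin": (173.6, 27.8),
        "Glucagon": (87.7, 10.1), "Height": (1.7, 0.03), "GIR": (1.7, 0.7),
        "RelFat": (37.8, 2.7),
    }),
}

#: longitudinal cohort (n=17): variable -> ((pre_mean, pre_sem), (post_mean, post_sem) | None)
TABLE2_VARIABLES = {
    "Age": ((46.5, 2.2), None),
    "BMI": ((34.7, 1.0), (30.7, 1.0)),
    "BW": ((96.9, 2.7), (85.9, 2.6)),
    "FFM": ((56.7, 1.8), (52.9, 1.5)),
    "FG": ((5.2, 0.1), (5.0, 0.1)),
    "Insulin": ((110.4, 9.7), (78.5, 9.7)),
    "Glucagon": ((82.2, 4.0), (71.4, 3.7)),
    "GIR": ((3.5, 0.4), (5.4, 0.5)),
    "RelFat": ((41.3, 1.5), (38.0, 1.8)),
    "VO2peak": ((2.2, 0.1), (2.5, 0.1)),
    "RelVO2peak": ((23.2, 1.0), (29.6, 1.4)),
}
TABLE2_N = 17

#: qPCR candidate panel validated in the longitudinal cohort, plus reference
CANDIDATE_GENES = (
    "AASS", "ARF1", "BCAT2", "DBNDD1", "LDHD", "NAPB", "PDK4", "PIGA",
    "POLR3GL", "SIN3A", "SNAP23", "SPCS2", "SSU72", "ST3GAL2", "UBTD1",
)
REFERENCE_GENE = "TBP"

#: template sign patterns (w_muscle, w_imat) against the latent health score.
#: h tracks +GIR / -FG, so e.g. cluster1 genes rise with insulin sensitivity
#: in both tissues (positive GIR association, negative FG association).
TEMPLATES = {
    "cluster1": (1.0, 1.0),
    "cluster2": (1.0, -1.0),
    "cluster3": (-1.0, 0.0),
}


def sem_to_sd(sem: float, n: int) -> float:
    """Reconstruct a group SD from a printed standard error of the mean."""
    if sem <= 0:
        raise InvalidParameterError(f"sem must be > 0, got {sem}")
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    return sem * math.sqrt(n)


# ---------------------------------------------------------------------------
# specs


@dataclass
class CohortSpec:
    """Cross-sectional cohort description: per-group variable means and SEMs."""

    groups: dict = field(default_factory=lambda: {g: (n, dict(v)) for g, (n, v) in TABLE1_GROUPS.items()})
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise InvalidParameterError("cohort spec has no groups")
        for g, (n, variables) in self.groups.items():
            if n < 2:
                raise InvalidParameterError(f"group '{g}': n must be >= 2, got {n}")
            for var, (mean, sem) in variables.items():
                if sem <= 0:
                    raise InvalidParameterError(f"group '{g}', variable '{var}': SEM must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        groups = {g: (int(n), {v: tuple(ms) for v, ms in vars_.items()})
                  for g, (n, vars_) in d["groups"].items()}
        return cls(groups=groups, seed=int(d.get("seed", 0)))


@dataclass
class GeneSpec:
    """Planted gene-phenotype coupling for the expression generator.

    ``n_per_template`` maps template name to the number of signal genes with
    that sign pattern; ``loading`` scales all tissue loadings; ``noise_sd``
    is the per-tissue expression noise SD (same units as the loadings, which
    apply to a unit-variance latent score).
    """

    n_per_template: dict = field(default_factory=lambda: {"cluster1": 14, "cluster2": 23, "cluster3": 22})
    n_null: int = 500
    loading: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.n_per_template) - set(TEMPLATES)
        if unknown:
            raise InvalidParameterError(f"unknown templates: {sorted(unknown)}")
        if self.noise_sd <= 0:
            raise InvalidParameterError("noise_sd must be > 0")
        if self.n_null < 0 or any(c < 0 for c in self.n_per_template.values()):
            raise InvalidParameterError("gene counts must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneSpec":
        out = cls()
        for k, v in d.items():
            if not hasattr(out, k):
                raise InvalidParameterError(f"unknown GeneSpec field '{k}'")
            setattr(out, k, v)
        return out


@dataclass
class InterventionSpec:
    """Longitudinal pre/post cohort and qPCR panel description."""

    n: int = TABLE2_N
    variables: dict = field(default_factory=lambda: {v: t for v, t in TABLE2_VARIABLES.items()})
    pre_post_corr: float = 0.8
    genes: tuple = CANDIDATE_GENES
    reference_gene: str = REFERENCE_GENE
    ref_ct_mean: float = 26.0
    ref_ct_sd: float = 0.5
    dct_mean: float = 5.0
    dct_sd: float = 1.0
    #: gene -> (target clinical variable, correlation of baseline log2 level with its delta-%)
    planted_predictive: dict = field(default_factory=lambda: {"ST3GAL2": ("FG", -0.9)})
    #: gene -> planted pre-to-post log2 expression shift
    planted_de: dict = field(default_factory=lambda: {"ARF1": -1.0})
    within_gene_noise_sd: float = 0.3
    #: (n_pre_dropped, n_post_dropped) Ct samples failing QC, or None
    dropout: tuple | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise InvalidParameterError("intervention cohort needs n >= 2")
        if not -1.0 < self.pre_post_corr < 1.0:
            raise InvalidParameterError("|pre_post_corr| must be < 1")
        for gene, (var, r) in self.planted_predictive.items():
            if abs(r) >= 1.0:
                raise InvalidParameterError(f"planted r for {gene} must satisfy |r| < 1")
            if var not in self.variables:
                raise InvalidParameterError(f"planted gene {gene} targets unknown variable '{var}'")
        if self.ref_ct_sd < 0:
            raise InvalidParameterError("reference Ct SD must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "InterventionSpec":
        out = cls()
        for k, v in d.items():
            if not hasattr(out, k):
                raise InvalidParameterError(f"unknown InterventionSpec field '{k}'")
            if k == "planted_predictive":
                v = {g: (t[0], float(t[1])) for g, t in v.items()}
            if k in ("genes",) and isinstance(v, list):
                v = tuple(v)
            if k == "dropout" and v is not None:
                v = tuple(v)
            setattr(out, k, v)
        return out


# ---------------------------------------------------------------------------
# generators


def _positive_mean(mu, sd):
    """Mean of Normal(mu, sd) truncated to (0, inf)."""
    from scipy import stats

    a = -mu / sd
    return float(stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd))


@lru_cache(maxsize=None)
def _truncated_location(target, sd):
    """Location mu such that Normal(mu, sd) truncated to (0, inf) has mean
    ``target``. Truncation inflates the mean, so mu <= target; for variables
    many SDs above zero the correction is numerically nil and skipped.
    """
    from scipy.optimize import brentq

    if target / sd > 6.0:
        return target
    return brentq(lambda mu: _positive_mean(mu, sd) - target,
                  target - 12 * sd, target, xtol=1e-12 * max(1.0, abs(target)))


@lru_cache(maxsize=None)
def _truncated_locations_bivariate(m1, m2, sd1, sd2, rho, iters=60):
    """Locations (a, b) such that a bivariate normal with SDs (sd1, sd2) and
    correlation rho, truncated to the positive quadrant, has marginal means
    (m1, m2). Uses the closed-form first moments of the quadrant-truncated
    bivariate normal inside a damped fixed-point iteration.
    """
    from scipy import stats
    from scipy.special import ndtr

    if m1 / sd1 > 6.0 and m2 / sd2 > 6.0:
        return m1, m2
    t = math.sqrt(1 - rho ** 2)
    biv = stats.multivariate_normal(mean=[0.0, 0.0],
                                    cov=[[1.0, rho], [rho, 1.0]])
    phi = stats.norm.pdf

    def truncated_means(a, b):
        alpha, beta = -a / sd1, -b / sd2
        L = float(biv.cdf([-alpha, -beta]))  # P(u > alpha, v > beta)
        eu = (phi(alpha) * ndtr(-(beta - rho * alpha) / t)
              + rho * phi(beta) * ndtr(-(alpha - rho * beta) / t)) / L
        ev = (phi(beta) * ndtr(-(alpha - rho * beta) / t)
              + rho * phi(alpha) * ndtr(-(beta - rho * alpha) / t)) / L
        return a + sd1 * eu, b + sd2 * ev

    a, b = m1, m2
    for _ in range(iters):
        e1, e2 = truncated_means(a, b)
        a_next, b_next = a - (e1 - m1), b - (e2 - m2)
        if abs(a_next - a) < 1e-12 and abs(b_next - b) < 1e-12:
            return a_next, b_next
        a, b = a_next, b_next
    return a, b


def _truncated_normal(rng, mean, sd, size, max_rounds=1000, calibrated=True):
    """Positive draws with mean exactly ``mean``: resample Normal(mu, sd)
    conditioned on > 0, with mu solved so the truncated mean equals the
    target (plain resampling would inflate the mean of high-CV variables).
    """
    mu = _truncated_location(mean, sd) if calibrated else mean
    out = rng.normal(mu, sd, size)
    for _ in range(max_rounds):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mu, sd, bad.sum())
    raise InvalidParameterError(
        f"could not draw positive values from Normal({mu}, {sd})"
    )


def generate_cohort(spec: CohortSpec) -> ClinicalTable:
    """Draw a cross-sectional cohort from per-group Normal(mean, SEM*sqrt(n))."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    rows = []
    pid = 1
    for group, (n, variables) in spec.groups.items():
        draws = {var: _truncated_normal(rng, mean, sem_to_sd(sem, n), n)
                 for var, (mean, sem) in variables.items()}
        sexes = rng.choice(["F", "M"], size=n)
        for i in range(n):
            row = {"participant_id": f"Pb{pid:03d}", "group": group, "sex": sexes[i]}
            row.update({var: draws[var][i] for var in variables})
            rows.append(row)
            pid += 1
    return ClinicalTable(pd.DataFrame(rows))


def latent_health_score(cohort: ClinicalTable) -> pd.Series:
    """Standardised first principal direction of (z(GIR), -z(FG)).

    High scores mark insulin-sensitive, normoglycaemic participants. The sign
    is fixed so the score correlates positively with GIR.
    """
    gir = cohort.frame["GIR"].to_numpy(float)
    fg = cohort.frame["FG"].to_numpy(float)
    if gir.std() == 0 or fg.std() == 0:
        raise DegenerateInputError("GIR and FG must vary to define a latent score")
    z = lambda v: (v - v.mean()) / v.std()
    M = np.column_stack([z(gir), -z(fg)])
    _, _, vt = np.linalg.svd(M - M.mean(axis=0), full_matrices=False)
    h = M @ vt[0]
    if np.corrcoef(h, gir)[0, 1] < 0:
        h = -h
    h = (h - h.mean()) / h.std()
    return pd.Series(h, index=cohort.participant_ids, name="health_score")


def generate_expression(cohort: ClinicalTable, spec: GeneSpec,
                        mislabeled: tuple = ()):
    """Plant template-patterned expression on a cohort's latent health score.

    Returns ``(muscle, imat, truth)`` where truth is a DataFrame with one row
    per gene: template label (or "null") and the tissue loadings used.

    ``mislabeled`` lists participants whose expression is generated from the
    opposite group's typical latent score (their clinical rows are untouched),
    emulating individuals whose molecular state contradicts their clinical
    classification.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    h = latent_health_score(cohort)

    if len(mislabeled):
        labels = cohort.labels()
        h = h.copy()
        for pid in mislabeled:
            other = labels[labels != labels[pid]].index
            h[pid] = h[other].mean()

    n = len(h)
    gene_rows, muscle_rows, imat_rows = [], [], []
    idx = 1
    for template, count in spec.n_per_template.items():
        wm, wi = (spec.loading * w for w in TEMPLATES[template])
        for _ in range(count):
            gid = f"gene_{idx:04d}"
            idx += 1
            muscle_rows.append(wm * h.to_numpy() + rng.normal(0, spec.noise_sd, n))
            imat_rows.append(wi * h.to_numpy() + rng.normal(0, spec.noise_sd, n))
            gene_rows.append({"gene_id": gid, "template": template,
                              "w_muscle": wm, "w_imat": wi})
    for _ in range(spec.n_null):
        gid = f"gene_{idx:04d}"
        idx += 1
        muscle_rows.append(rng.normal(0, 1.0, n))
        imat_rows.append(rng.normal(0, 1.0, n))
        gene_rows.append({"gene_id": gid, "template": "null",
                          "w_muscle": 0.0, "w_imat": 0.0})

    truth = pd.DataFrame(gene_rows)
    gene_ids = truth["gene_id"].tolist()
    cols = cohort.participant_ids
    muscle = ExpressionMatrix("muscle", pd.DataFrame(muscle_rows, index=gene_ids, columns=cols))
    imat = ExpressionMatrix("imat", pd.DataFrame(imat_rows, index=gene_ids, columns=cols))
    return muscle, imat, truth


def generate_intervention_cohort(spec: InterventionSpec):
    """Draw the longitudinal cohort: paired clinical rows, Ct table, truth.

    Returns ``(ClinicalTable, ct_table, truth)``. The clinical table is long
    format (group column = timepoint); the Ct table is long format with one
    row per (participant, timepoint, gene) including the reference gene. The
    truth table records each candidate gene's planted screen correlation and
    differential-expression shift.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng_clin = np.random.default_rng(ss[0])
    rng_ct = np.random.default_rng(ss[2])
    n = spec.n
    pids = [f"Pi{i + 1:03d}" for i in range(n)]
    rho = spec.pre_post_corr

    pre_rows = {"participant_id": pids, "group": ["pre"] * n}
    post_rows = {"participant_id": pids, "group": ["post"] * n}
    delta_pct = {}
    for var, (pre_ms, post_ms) in spec.variables.items():
        mu0, sem0 = pre_ms
        sd0 = sem_to_sd(sem0, n)
        if post_ms is None:
            pre = _truncated_normal(rng_clin, mu0, sd0, n)
            post = pre.copy()
        else:
            mu1, sem1 = post_ms
            sd1 = sem_to_sd(sem1, n)
            # locations calibrated so the positive-quadrant-truncated means
            # equal the printed means
            a, b = _truncated_locations_bivariate(mu0, mu1, sd0, sd1, rho)
            pre = np.empty(n)
            post = np.empty(n)
            todo = np.ones(n, dtype=bool)
            for _ in range(1000):  # joint truncation at 0 by resampling
                m = todo.sum()
                if m == 0:
                    break
                z0 = rng_clin.normal(size=m)
                z1 = rng_clin.normal(size=m)
                p0 = a + sd0 * z0
                p1 = b + sd1 * (rho * z0 + math.sqrt(1 - rho ** 2) * z1)
                pre[todo], post[todo] = p0, p1
                todo[todo] = (p0 <= 0) | (p1 <= 0)
        pre_rows[var] = pre
        post_rows[var] = post
        delta_pct[var] = 100.0 * (post - pre) / pre

    clinical = ClinicalTable(pd.concat(
        [pd.DataFrame(pre_rows), pd.DataFrame(post_rows)], ignore_index=True))

    # --- qPCR panel -------------------------------------------------------
    ref_pre = rng_ct.normal(spec.ref_ct_mean, spec.ref_ct_sd, n)
    ref_post = rng_ct.normal(spec.ref_ct_mean, spec.ref_ct_sd, n)
    ct_rows = []
    truth_rows = []
    for gene in spec.genes:
        if gene in spec.planted_predictive:
            var, r = spec.planted_predictive[gene]
            s = delta_pct[var]
            s = (s - s.mean()) / s.std()
            level = r * s + math.sqrt(1 - r ** 2) * rng_ct.normal(size=n)
        else:
            var, r = None, 0.0
            level = rng_ct.normal(size=n)
        dct_pre = spec.dct_mean - spec.dct_sd * level
        shift = spec.planted_de.get(gene, 0.0)
        dct_post = dct_pre - shift + rng_ct.normal(0, spec.within_gene_noise_sd, n)
        for i, pid in enumerate(pids):
            ct_rows.append((pid, "pre", gene, ref_pre[i] + dct_pre[i]))
            ct_rows.append((pid, "post", gene, ref_post[i] + dct_post[i]))
        truth_rows.append({"gene": gene, "target_variable": var,
                           "planted_r": r, "de_log2_shift": shift})
    for i, pid in enumerate(pids):
        ct_rows.append((pid, "pre", spec.reference_gene, ref_pre[i]))
        ct_rows.append((pid, "post", spec.reference_gene, ref_post[i]))

    ct = pd.DataFrame(ct_rows, columns=["participant_id", "timepoint", "gene", "Ct"])

    if spec.dropout is not None:
        n_pre, n_post = spec.dropout
        drop_pre = set(rng_ct.choice(pids, size=n_pre, replace=False))
        drop_post = set(rng_ct.choice(pids, size=n_post, replace=False))
        keep = ~(
            (ct["timepoint"].eq("pre") & ct["participant_id"].isin(drop_pre))
            | (ct["timepoint"].eq("post") & ct["participant_id"].isin(drop_post))
        )
        ct = ct[keep].reset_index(drop=True)

    return clinical, ct, pd.DataFrame(truth_rows)
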