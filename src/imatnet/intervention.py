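"""Longitudinal intervention-response analysis.

Four steps mirror the published validation stage:

1. paired t tests on each clinical variable's pre/post values, and the
   relative change Delta% = 100*(post - pre)/pre per participant;
2. qPCR relative quantification against the reference gene *TBP*:
   dCt = Ct_target - Ct_ref, ddCt relative to a calibrator (default the
   pre-intervention group-mean dCt per gene), and the reported level
   log2(2^-ddCt) = -ddCt;
3. pre vs post differential expression by one-way (two-group) ANOVA on the
   log2 relative levels, tolerating unpaired groups after sample dropout;
4. the headline screen: Pearson correlation of each gene's baseline (pre)
   relative expression with each clinical variable's Delta%, with per-test
   significance at a configurable alpha and Benjamini-Hochberg q-values
   reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ClinicalTable
from .errors import (ConsistencyError, InfiniteStatisticError,
                     InvalidParameterError, UndefinedChangeError)

log = logging.getLogger("imatnet.intervention")

SCREEN_VARIABLES = ("BMI", "BW", "FFM", "FG", "GIR", "RelFat")


def relative_change(pre: float, post: float) -> float:
    """Relative pre-to-post change in percent: 100*(post - pre)/pre."""
    if pre == 0:
        raise UndefinedChangeError("relative change undefined for pre = 0")
    return 100.0 * (post - pre) / pre


def paired_frame(clin: ClinicalTable, variables=None) -> pd.DataFrame:
    """Long table of (participant, variable, pre, post, delta_pct)."""
    f = clin.frame
    if not {"pre", "post"} <= set(f["group"].unique()):
        raise InvalidParameterError("clinical table is not a paired pre/post cohort")
    pre = f[f["group"] == "pre"].set_index("participant_id")
    post = f[f["group"] == "post"].set_index("participant_id")
    shared = [p for p in pre.index if p in post.index]
    variables = list(variables) if variables is not None else clin.variables
    rows = []
    for pid in shared:
        for var in variables:
            a, b = pre.loc[pid, var], post.loc[pid, var]
            if pd.isna(a) or pd.isna(b):
                continue
            rows.append({"participant_id": pid, "variable": var, "pre": a,
                         "post": b, "delta_pct": relative_change(a, b)})
    return pd.DataFrame(rows)


def paired_change_test(pre, post):
    """Classical paired t test on post - pre differences (df = n - 1).

    Returns ``(t, p, mean_difference)``.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise InvalidParameterError("pre and post must have equal length")
    mask = ~(np.isnan(pre) | np.isnan(post))
    pre, post = pre[mask], post[mask]
    n = len(pre)
    if n < 2:
        raise InvalidParameterError("paired t test needs >= 2 complete pairs")
    diff = post - pre
    if np.allclose(diff, 0):
        return 0.0, 1.0, 0.0
    if diff.std(ddof=1) == 0:
        raise InfiniteStatisticError("zero-variance differences with nonzero mean")
    t, p = stats.ttest_rel(post, pre)
    return float(t), float(p), float(diff.mean())


def change_test_table(clin: ClinicalTable, variables=None) -> pd.DataFrame:
    """Paired t test per clinical variable of a pre/post cohort."""
    paired = paired_frame(clin, variables=variables)
    rows = []
    for var, sub in paired.groupby("variable", sort=False):
        t, p, mean_diff = paired_change_test(sub["pre"], sub["post"])
        rows.append({"variable": var, "n": len(sub), "t": t, "p": p,
                     "mean_difference": mean_diff,
                     "mean_delta_pct": sub["delta_pct"].mean()})
    return pd.DataFrame(rows)


def relative_expression(ct: pd.DataFrame, reference_gene: str = "TBP",
                        calibrator: str = "pre-group-mean",
                        calibrator_sample: str | None = None) -> pd.DataFrame:
    """ddCt relative quantification of a long-format Ct table.

    Rows missing a matching reference-gene Ct for their (participant,
    timepoint) are dropped and logged. ``calibrator`` is either
    ``"pre-group-mean"`` (per-gene mean pre-intervention dCt) or
    ``"named-sample"`` with ``calibrator_sample`` giving the participant id
    whose pre dCt calibrates that gene.

    Returns one row per (participant, timepoint, gene) with dCt, ddCt and
    ``log2_level`` = -ddCt.
    """
    ref = (ct[ct["gene"] == reference_gene]
           .set_index(["participant_id", "timepoint"])["Ct"])
    targets = ct[ct["gene"] != reference_gene].copy()
    key = list(zip(targets["participant_id"], targets["timepoint"]))
    have_ref = [k in ref.index for k in key]
    n_dropped = len(targets) - sum(have_ref)
    if n_dropped:
        log.warning("relative_expression: dropped %d row(s) lacking reference Ct",
                    n_dropped)
    targets = targets[have_ref]
    targets["dCt"] = targets["Ct"].to_numpy() - ref.loc[
        list(zip(targets["participant_id"], targets["timepoint"]))].to_numpy()

    out = []
    for gene, sub in targets.groupby("gene", sort=False):
        if calibrator == "pre-group-mean":
            pre = sub.loc[sub["timepoint"] == "pre", "dCt"]
            if pre.empty:
                log.warning("gene %s: no pre samples; calibrating on all samples", gene)
                cal = sub["dCt"].mean()
            else:
                cal = pre.mean()
        elif calibrator == "named-sample":
            if calibrator_sample is None:
                raise InvalidParameterError("named-sample calibrator needs a sample id")
            row = sub[(sub["participant_id"] == calibrator_sample)
                      & (sub["timepoint"] == "pre")]
            if row.empty:
                raise ConsistencyError(
                    f"gene {gene}: calibrator sample '{calibrator_sample}' absent")
            cal = float(row["dCt"].iloc[0])
        else:
            raise InvalidParameterError(f"unknown calibrator '{calibrator}'")
        sub = sub.copy()
        sub["ddCt"] = sub["dCt"] - cal
        sub["log2_level"] = -sub["ddCt"]
        out.append(sub)
    cols = ["participant_id", "timepoint", "gene", "Ct", "dCt", "ddCt", "log2_level"]
    return pd.concat(out, ignore_index=True)[cols]


def differential_expression_anova(group_pre, group_post):
    """One-way two-group ANOVA (equivalently F = t^2 of the unpaired t)."""
    a = np.asarray(group_pre, dtype=float)
    b = np.asarray(group_post, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("each group needs >= 2 values")
    if np.var(a) == 0 and np.var(b) == 0 and np.isclose(a.mean(), b.mean()):
        return 0.0, 1.0
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)


def differential_expression_table(rel: pd.DataFrame,
                                  paired: bool = False) -> pd.DataFrame:
    """Pre vs post test per gene on log2 relative levels.

    Default is the unpaired one-way ANOVA, which tolerates the partially
    unpaired groups left by sample dropout. ``paired=True`` instead runs a
    paired t test on participants measured at both timepoints (F reported
    as t^2 so the two modes share one output scale).
    """
    rows = []
    for gene, sub in rel.groupby("gene", sort=False):
        pre = sub.loc[sub["timepoint"] == "pre", "log2_level"]
        post = sub.loc[sub["timepoint"] == "post", "log2_level"]
        if paired:
            pre_s = sub[sub["timepoint"] == "pre"].set_index("participant_id")["log2_level"]
            post_s = sub[sub["timepoint"] == "post"].set_index("participant_id")["log2_level"]
            shared = pre_s.index.intersection(post_s.index)
            t, p, _ = paired_change_test(pre_s.loc[shared], post_s.loc[shared])
            f = t ** 2
        else:
            f, p = differential_expression_anova(pre, post)
        rows.append({"gene": gene, "n_pre": len(pre), "n_post": len(post),
                     "mean_log2_pre": pre.mean(), "mean_log2_post": post.mean(),
                     "F": f, "p": p})
    return pd.DataFrame(rows)


@dataclass
class ScreenConfig:
    alpha: float = 0.05
    method: str = "pearson"  # or "spearman"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha must be in (0, 1)")
        if self.method not in ("pearson", "spearman"):
            raise InvalidParameterError(f"unknown correlation method '{self.method}'")


def correlation_screen(baseline_expr: pd.DataFrame, delta_clinical: pd.DataFrame,
                       config: ScreenConfig | None = None) -> pd.DataFrame:
    """Correlate baseline expression with relative clinical change.

    ``baseline_expr``: genes x participants (pre-intervention log2 levels);
    ``delta_clinical``: participants x variables (Delta% values). Cells are
    pairwise-complete; a (gene, variable) pair with fewer than 3 complete
    pairs is reported with missing statistics. Significance is flagged per
    test at ``alpha`` (unadjusted); Benjamini-Hochberg q-values over all
    computed tests are reported alongside.
    """
    config = config or ScreenConfig()
    config.validate()
    corr = stats.pearsonr if config.method == "pearson" else stats.spearmanr
    shared = [p for p in delta_clinical.index if p in baseline_expr.columns]
    if not shared:
        raise ConsistencyError("no participants shared between expression and changes")
    rows = []
    for gene in baseline_expr.index:
        expr = baseline_expr.loc[gene, shared].astype(float)
        for var in delta_clinical.columns:
            delta = delta_clinical.loc[shared, var].astype(float)
            mask = expr.notna() & delta.notna()
            n = int(mask.sum())
            if n < 3:
                log.warning("screen: gene %s vs %s has %d pairs; reported missing",
                            gene, var, n)
                rows.append({"gene": gene, "variable": var, "n": n,
                             "r": np.nan, "p": np.nan})
                continue
            r, p = corr(expr[mask], delta[mask])
            rows.append({"gene": gene, "variable": var, "n": n,
                         "r": float(r), "p": float(p)})
    table = pd.DataFrame(rows)
    computed = table["p"].notna()
    table["q"] = np.nan
    if computed.any():
        table.loc[computed, "q"] = multipletests(
            table.loc[computed, "p"], method="fdr_bh")[1]
    table["significant"] = computed & (table["p"] < config.alpha)
    return table


def delta_matrix(clin: ClinicalTable, variables=SCREEN_VARIABLES) -> pd.DataFrame:
    """Participants x variables matrix of Delta% from a paired cohort."""
    paired = paired_frame(clin, variables=variables)
    return paired.pivot(index="participant_id", columns="variable",
                        values="delta_pct")


def baseline_matrix(rel: pd.DataFrame) -> pd.DataFrame:
    """Genes x participants matrix of pre-intervention log2 relative levels."""
    pre = rel[rel["timepoint"] == "pre"]
    return pre.pivot(index="gene", columns="participant_id", values="log2_level")
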