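"""Core in-memory containers.

All containers are thin, validated wrappers around pandas objects so that
every analysis stage can hand tables around without re-checking invariants.
Clinical tables hold one participant per row (or one participant x timepoint
row for paired designs); expression matrices are genes x participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

#: units of the clinical variables, as reported with the cohorts
VARIABLE_UNITS = {
    "Age": "years",
    "BMI": "kg/m^2",
    "BW": "kg",
    "FFM": "kg",
    "FG": "mmol/l",
    "Insulin": "pmol/l",
    "Glucagon": "ng/l",
    "Height": "m",
    "GIR": "mg kg^-1 min^-1",
    "RelFat": "%",
    "VO2peak": "l/min",
    "RelVO2peak": "ml/kg min^-1",
}

CROSS_SECTIONAL_GROUPS = ("obesity", "type2diabetes")
TIMEPOINT_GROUPS = ("pre", "post")
SEXES = ("F", "M", "unknown")

#: fasting glucose band (mmol/l) used to label impaired fasting glucose
IMPAIRED_FG_BAND = (5.6, 7.0)


@dataclass
class ClinicalTable:
    """Participant-level phenotypes.

    ``frame`` columns: ``participant_id``, ``group``, ``sex`` plus one
    numeric column per clinical variable. For paired (pre/post) cohorts the
    ``group`` column holds the timepoint and participant ids are unique
    within each timepoint only.
    """

    frame: pd.DataFrame
    units: dict = field(default_factory=lambda: dict(VARIABLE_UNITS))

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("participant_id", "group"):
            if col not in f.columns:
                raise ValidationError(f"clinical table lacks required column '{col}'")
        if "sex" not in f.columns:
            f = f.copy()
            f["sex"] = "unknown"
            self.frame = f
        groups = set(f["group"].unique())
        if not (groups <= set(CROSS_SECTIONAL_GROUPS) or groups <= set(TIMEPOINT_GROUPS)):
            raise ValidationError(f"unrecognised group labels: {sorted(groups)}")
        bad_sex = set(f["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unrecognised sex labels: {sorted(bad_sex)}")
        # ids unique within timepoint (trivially the whole table if unpaired)
        for tp, sub in f.groupby("group"):
            dup = sub["participant_id"][sub["participant_id"].duplicated()]
            if len(dup):
                raise ValidationError(
                    f"duplicate participant_id '{dup.iloc[0]}' within group '{tp}'"
                )
        if "GIR" in f.columns and (pd.to_numeric(f["GIR"]).dropna() < 0).any():
            raise ValidationError("GIR must be >= 0")
        if "FG" in f.columns and (pd.to_numeric(f["FG"]).dropna() <= 0).any():
            raise ValidationError("FG must be > 0")

    @property
    def participant_ids(self) -> list[str]:
        return list(self.frame["participant_id"])

    @property
    def variables(self) -> list[str]:
        reserved = {"participant_id", "group", "sex"}
        return [c for c in self.frame.columns if c not in reserved]

    def group_counts(self) -> dict:
        return self.frame["group"].value_counts().to_dict()

    def labels(self) -> pd.Series:
        """group label per participant, indexed by participant_id."""
        return self.frame.set_index("participant_id")["group"]

    def impaired_fg_flags(self) -> pd.Series:
        """Flag participants whose FG falls in the impaired band."""
        lo, hi = IMPAIRED_FG_BAND
        fg = self.frame.set_index("participant_id")["FG"]
        return (fg >= lo) & (fg <= hi)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ExpressionMatrix:
    """Genes x participants expression values for one tissue."""

    tissue: str
    values: pd.DataFrame  # index: gene_id, columns: participant_id

    def __post_init__(self) -> None:
        if self.tissue not in ("muscle", "imat"):
            raise ValidationError(f"unknown tissue '{self.tissue}'")
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene_id '{dup}'")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate participant ids in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.tissue, self.values.loc[list(gene_ids)])


@dataclass
class PhenotypeVector:
    """The two regression responses, GIR (g) and FG (f), participant-aligned."""

    participant_ids: list
    gir: np.ndarray
    fg: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.participant_ids)
        self.gir = np.asarray(self.gir, dtype=float)
        self.fg = np.asarray(self.fg, dtype=float)
        if self.gir.shape != (n,) or self.fg.shape != (n,):
            raise ValidationError("phenotype vectors must match participant count")

    def __len__(self) -> int:
        return len(self.participant_ids)


def align(expr: ExpressionMatrix, clin: ClinicalTable):
    """Restrict an expression matrix and a clinical table to shared participants.

    Returns ``(ExpressionMatrix, PhenotypeVector)`` with identical participant
    ordering (the clinical table's row order restricted to the intersection).
    Participants present on only one side are dropped and counted in the log.
    """
    import logging

    log = logging.getLogger("imatnet.io")
    clin_ids = clin.participant_ids
    expr_ids = set(expr.participant_ids)
    shared = [p for p in clin_ids if p in expr_ids]
    if not shared:
        raise AlignmentError("no participants shared between expression and clinical table")
    dropped = (len(clin_ids) - len(shared)) + (len(expr_ids) - len(shared))
    if dropped:
        log.warning("align: dropped %d unmatched participant(s)", dropped)
    sub = clin.frame.set_index("participant_id").loc[shared]
    pheno = PhenotypeVector(shared, sub["GIR"].to_numpy(float), sub["FG"].to_numpy(float))
    aligned = ExpressionMatrix(expr.tissue, expr.values[shared])
    return aligned, pheno
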