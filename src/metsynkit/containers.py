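"""Shared data containers for cohort-level analyses.

The central in-memory objects are thin wrappers around pandas structures:
a :class:`MetaboliteTable` pairs a samples × metabolites abundance matrix
(``NaN`` marks a value censored below the detection limit) with Metabolon-style
two-level pathway annotations, and :class:`ClinicalRecord` carries the
per-subject covariates needed for HOMA-IR and Framingham risk scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MetaboliteTable", "ClinicalRecord", "clinical_frame", "records_from_frame"]

ANNOTATION_COLUMNS = ("biochemical_name", "subpathway", "superpathway")


@dataclass
class MetaboliteTable:
    """Samples × metabolites abundance matrix with pathway annotations.

    Parameters
    ----------
    abundances
        DataFrame indexed by sample id, one column per metabolite id.
        Missing (below detection limit) cells are ``NaN``; all observed
        abundances must be non-negative.
    annotations
        DataFrame indexed by metabolite id with columns
        ``biochemical_name``, ``subpathway``, ``superpathway``. A metabolite
        without a biochemical assignment carries ``"unannotated"``.
    """

    abundances: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.abundances.columns.equals(self.annotations.index):
            raise ValueError(
                "annotation index must match abundance columns "
                f"({len(self.abundances.columns)} metabolites vs "
                f"{len(self.annotations.index)} annotations)"
            )
        missing_cols = set(ANNOTATION_COLUMNS) - set(self.annotations.columns)
        if missing_cols:
            raise ValueError(f"annotations lack columns: {sorted(missing_cols)}")
        values = self.abundances.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("negative abundances are not allowed")
        if self.annotations["superpathway"].isna().any():
            raise ValueError("every metabolite needs a superpathway (use 'unannotated')")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.abundances.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.abundances.isna()

    def subset_metabolites(self, metabolite_ids) -> "MetaboliteTable":
        ids = list(metabolite_ids)
        unknown = set(ids) - set(self.abundances.columns)
        if unknown:
            raise KeyError(f"unknown metabolites: {sorted(unknown)[:5]}")
        return MetaboliteTable(self.abundances[ids], self.annotations.loc[ids])

    def subset_samples(self, sample_ids) -> "MetaboliteTable":
        ids = list(sample_ids)
        return MetaboliteTable(self.abundances.loc[ids], self.annotations)

    def lipid_family(self) -> "MetaboliteTable":
        """Restrict to the Lipid superpathway (the paper-style lipid family)."""
        ids = self.annotations.index[self.annotations["superpathway"] == "Lipid"]
        if len(ids) == 0:
            raise ValueError("no metabolites in the Lipid superpathway")
        return self.subset_metabolites(ids)

    # -- plain-text round trip -------------------------------------------------

    def to_tsv(self, abundance_path: str | Path, annotation_path: str | Path) -> None:
        self.abundances.rename_axis("sample_id").to_csv(abundance_path, sep="\t")
        self.annotations.rename_axis("metabolite_id").to_csv(annotation_path, sep="\t")

    @classmethod
    def from_tsv(
        cls, abundance_path: str | Path, annotation_path: str | Path
    ) -> "MetaboliteTable":
        ab = pd.read_csv(abundance_path, sep="\t", index_col="sample_id")
        ann = pd.read_csv(annotation_path, sep="\t", index_col="metabolite_id")
        return cls(ab, ann)


@dataclass
class ClinicalRecord:
    """Per-subject demographics, anthropometry, lipids and glycemia.

    Concentrations follow the units routine in European clinical labs:
    glucose / lipids in mmol/L, insulin in pmol/L, HbA1c in mmol/mol.
    ``rd`` is the clamp rate of glucose disposal in μmol·kg⁻¹·min⁻¹ when
    available (it drives the insulin-resistance classification).
    """

    subject_id: str
    age: float
    sex: str
    bmi: float
    weight: float
    sbp: float
    dbp: float
    fasting_glucose: float
    fasting_insulin: float
    hba1c: float
    total_chol: float
    ldl: float
    hdl: float
    triglycerides: float
    smoker: bool
    diabetes: bool
    bp_treated: bool
    rd: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.sbp <= self.dbp:
            raise ValueError("systolic pressure must exceed diastolic")
        for name in (
            "bmi", "weight", "fasting_glucose", "fasting_insulin",
            "hba1c", "total_chol", "ldl", "hdl", "triglycerides",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame indexed by subject id."""
    cols = [f.name for f in fields(ClinicalRecord)]
    df = pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)
    return df.set_index("subject_id")


def records_from_frame(df: pd.DataFrame) -> list[ClinicalRecord]:
    """Inverse of :func:`clinical_frame` (index = subject_id)."""
    out = []
    for sid, row in df.iterrows():
        kwargs = {k: row[k] for k in row.index if k in {f.name for f in fields(ClinicalRecord)}}
        for flag in ("smoker", "diabetes", "bp_treated"):
            kwargs[flag] = bool(kwargs[flag])
        out.append(ClinicalRecord(subject_id=str(sid), **kwargs))
    return out
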