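"""Labeled per-observation feature tables shared by every pipeline stage.

An :class:`OmicsTable` holds one modality's measurements: one row per
observation (nodule for radiomics, patient for metabolomics) with four
metadata columns (``sample_id``, ``patient_id``, ``cohort``, ``label``)
followed by numeric feature columns.  ``malignant`` is the positive class
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

META_COLUMNS: tuple[str, ...] = ("sample_id", "patient_id", "cohort", "label")
BENIGN = "benign"
MALIGNANT = "malignant"


@dataclass
class OmicsTable:
    """A rectangular, labeled feature table for one modality.

    Parameters
    ----------
    data:
        DataFrame whose first columns are :data:`META_COLUMNS` and whose
        remaining columns are numeric features.
    modality:
        Free-form modality tag, conventionally ``"radiomics"`` or
        ``"metabolomics"``.
    """

    data: pd.DataFrame
    modality: str = "unknown"

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            dupes = self.data["sample_id"][self.data["sample_id"].duplicated()]
            raise ValueError(f"duplicate sample_id values: {sorted(set(dupes))[:5]}")
        bad = set(self.data["label"].dropna()) - {BENIGN, MALIGNANT}
        if bad or self.data["label"].isna().any():
            raise ValueError(f"labels must be '{BENIGN}' or '{MALIGNANT}', got {bad}")
        # keep metadata first, features after, in a stable order
        feats = [c for c in self.data.columns if c not in META_COLUMNS]
        self.data = self.data[list(META_COLUMNS) + feats].reset_index(drop=True)

    # ------------------------------------------------------------------ views
    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        """Feature matrix as float64, rows in table order."""
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Binary labels with malignant = 1."""
        return (self.data["label"] == MALIGNANT).to_numpy(dtype=int)

    @property
    def labels(self) -> pd.Series:
        return self.data["label"]

    @property
    def patient_ids(self) -> pd.Series:
        return self.data["patient_id"]

    def patient_labels(self) -> pd.Series:
        """Patient-level labels: malignant if *any* of the patient's rows is.

        A screening participant can carry benign and malignant nodules at the
        same time; the patient counts as malignant as soon as one nodule is.
        """
        is_mal = self.data["label"] == MALIGNANT
        agg = is_mal.groupby(self.data["patient_id"]).any()
        return agg.map({True: MALIGNANT, False: BENIGN}).rename("label")

    # -------------------------------------------------------------- subsetting
    def select_features(self, names: Sequence[str]) -> "OmicsTable":
        unknown = [n for n in names if n not in self.data.columns]
        if unknown:
            raise KeyError(f"unknown features: {unknown[:5]}")
        cols = list(META_COLUMNS) + list(names)
        return OmicsTable(self.data[cols].copy(), self.modality)

    def subset_rows(self, mask: np.ndarray) -> "OmicsTable":
        return OmicsTable(self.data.loc[np.asarray(mask)].copy(), self.modality)

    def for_patients(self, patient_ids: Iterable[str]) -> "OmicsTable":
        wanted = set(patient_ids)
        mask = self.data["patient_id"].isin(wanted).to_numpy()
        return self.subset_rows(mask)

    # --------------------------------------------------------------------- io
    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, modality: str = "unknown") -> "OmicsTable":
        return cls(pd.read_csv(path), modality)
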