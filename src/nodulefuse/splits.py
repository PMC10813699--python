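"""Patient-grouped, class-stratified random splits.

Radiomics tables carry several rows (nodules) per patient; putting a
patient's nodules on both sides of a split would leak information, so all
splitting happens at the patient level, stratified by the patient-level
label (malignant if any of the patient's rows is malignant).
"""

from __future__ import annotations

import logging

import numpy as np

from .tables import MALIGNANT, OmicsTable

log = logging.getLogger(__name__)


def stratified_patient_split(
    table: OmicsTable, train_frac: float, rng: np.random.Generator, max_resample: int = 100
) -> tuple[OmicsTable, OmicsTable]:
    """Split rows into (train, valid) by patient, stratified by patient label.

    If a side ends up single-class (possible with few patients of a class),
    the split is redrawn, up to ``max_resample`` times.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    plabels = table.patient_labels()
    patients = plabels.index.to_numpy()
    is_mal = (plabels == MALIGNANT).to_numpy()
    for attempt in range(max_resample):
        train_pat: list[str] = []
        for cls_mask in (is_mal, ~is_mal):
            grp = patients[cls_mask]
            n_train = int(round(train_frac * grp.size))
            n_train = min(max(n_train, 1), grp.size - 1) if grp.size > 1 else grp.size
            train_pat.extend(rng.choice(grp, size=n_train, replace=False))
        train_set = set(train_pat)
        tr = table.for_patients(train_set)
        va = table.for_patients(set(patients) - train_set)
        if tr.labels.nunique() == 2 and va.labels.nunique() == 2:
            if attempt:
                log.info("split redrawn %d time(s) to get both classes on each side", attempt)
            return tr, va
    raise RuntimeError("could not draw a split with both classes on each side")
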