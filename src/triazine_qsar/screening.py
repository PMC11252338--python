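"""Apply a fitted model to designed candidate compounds and rank them.

Each candidate gets a predicted activity, a leverage value against the
training data's descriptor space, and an in-domain flag; candidates carry no
observed activity, so the domain check is leverage-only.  When a reference
equation (e.g. the study's printed model) is supplied, its predictions are
reported side by side so coefficient discrepancies surface per compound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import DATA_NOTES, CompoundRecord, ModelSpec, QSARDataset
from .domain import leverages, warning_leverage

__all__ = ["ScreeningResult", "screen"]


@dataclass(frozen=True)
class ScreeningResult:
    """Ranked candidate table; ordering is descending predicted activity."""

    table: pd.DataFrame  # columns: label, pic50_pred, [pic50_pred_reference,]
    #                      leverage, in_domain, [pic50_pred_published, flag_note]
    h_star: float

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.table["label"])

    def top(self, n: int = 5) -> pd.DataFrame:
        return self.table.head(n)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def screen(
    model: ModelSpec,
    candidates: Sequence[CompoundRecord],
    train: QSARDataset,
    reference_model: ModelSpec | None = None,
    ad_reference: str = "all",
) -> ScreeningResult:
    """Predict, attach leverage flags, and sort candidates by predicted pIC50.

    Sorting is stable with ties broken by label.  ``ad_reference`` selects the
    hat-basis rows as in :func:`triazine_qsar.domain.assess_domain`.  Rows with
    data-provenance notes (see :data:`triazine_qsar.data_model.DATA_NOTES`)
    carry the note in a ``flag_note`` column.
    """
    names = model.descriptor_names
    if ad_reference == "all":
        ref_records = [*train.train, *train.test]
    elif ad_reference == "train":
        ref_records = list(train.train)
    else:
        raise ValueError(f"unknown ad_reference {ad_reference!r}")
    h_star = warning_leverage(model.n_descriptors, len(ref_records))

    if not candidates:
        cols = ["label", "pic50_pred", "leverage", "in_domain"]
        return ScreeningResult(table=pd.DataFrame(columns=cols), h_star=h_star)

    ref_X = np.array([[1.0, *r.descriptor_vector(names)] for r in ref_records])
    cand_X = np.array([[1.0, *r.descriptor_vector(names)] for r in candidates])
    h = leverages(ref_X, cand_X)

    rows = []
    for record, hi in zip(candidates, h):
        row = {
            "label": record.label,
            "pic50_pred": model.predict_record(record),
            "leverage": float(hi),
            "in_domain": bool(hi < h_star),
        }
        if reference_model is not None:
            row["pic50_pred_reference"] = reference_model.predict_record(record)
        published_pred = record.extra.get("pic50_pred_published")
        if published_pred is not None:
            row["pic50_pred_published"] = float(published_pred)
        note = DATA_NOTES.get(record.label)
        if note is not None:
            row["flag_note"] = note
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["pic50_pred", "label"], ascending=[False, True], kind="mergesort"
    )
    return ScreeningResult(table=table.reset_index(drop=True), h_star=h_star)
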