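"""Leverage-based applicability domain (Williams plot).

A prediction is trusted only for compounds structurally similar to the data
the model was built on.  Similarity is measured by leverage — the diagonal of
the hat matrix of the reference design — against the warning threshold
h* = 3(k+1)/n, and (where an observed activity exists) by the standardized
residual against a fixed band.  The Williams plot is the scatter of the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import CompoundRecord, ModelSpec, QSARDataset

__all__ = [
    "DomainAssessment",
    "leverages",
    "warning_leverage",
    "standardized_residuals",
    "assess_domain",
]


def leverages(train_X: np.ndarray, query_X: np.ndarray) -> np.ndarray:
    """h_i = x_i^T (X^T X)^{-1} x_i with X the intercept-augmented reference design.

    Both arguments must already carry the intercept column.  The query may be
    the reference rows themselves (then sum(h) = number of fitted
    coefficients), a test set, or designed candidates.
    """
    train_X = np.asarray(train_X, dtype=float)
    query_X = np.asarray(query_X, dtype=float)
    if np.linalg.matrix_rank(train_X) < train_X.shape[1]:
        raise np.linalg.LinAlgError("X^T X is singular: reference design is rank-deficient")
    G = np.linalg.inv(train_X.T @ train_X)
    return np.einsum("ij,jk,ik->i", query_X, G, query_X)


def warning_leverage(k: int, n: int) -> float:
    """Warning threshold h* = 3 (k+1)/n for k descriptors and n reference rows."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 3.0 * (k + 1) / n


def standardized_residuals(obs: Sequence[float], pred: Sequence[float]) -> np.ndarray:
    """SDR_i = (obs_i - pred_i) / sqrt(mean of squared residuals).

    The n-denominator root-mean-square normalization makes the SDR series have
    RMS exactly 1.  Raises if every residual is zero.
    """
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if len(o) < 2:
        raise ValueError("need at least two residuals")
    resid = o - p
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms == 0.0:
        raise ZeroDivisionError("all residuals are zero; SDR undefined")
    return resid / rms


@dataclass(frozen=True)
class DomainAssessment:
    """Per-compound leverage/SDR flags plus the global thresholds."""

    labels: tuple[str, ...]
    leverage: tuple[float, ...]
    sdr: tuple[float | None, ...]  # None where no observed activity
    in_domain: tuple[bool, ...]
    h_star: float
    sdr_limit: float

    @property
    def n_outliers(self) -> int:
        return sum(not f for f in self.in_domain)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "leverage": self.leverage,
                "sdr": [s if s is not None else float("nan") for s in self.sdr],
                "in_domain": self.in_domain,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def williams_plot(self, path) -> None:
        """Render the leverage/SDR scatter with the h* and +-SDR-limit lines."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = self.to_frame()
        with_sdr = frame.dropna(subset=["sdr"])
        no_sdr = frame[frame["sdr"].isna()]
        fig, ax = plt.subplots(figsize=(6, 4.5))
        ax.scatter(with_sdr["leverage"], with_sdr["sdr"], c="black", s=25, label="with activity")
        if len(no_sdr):
            ax.scatter(no_sdr["leverage"], [0.0] * len(no_sdr), c="tab:red", s=25,
                       marker="^", label="candidates (leverage only)")
        ax.axvline(self.h_star, ls="--", c="tab:blue")
        ax.axhline(self.sdr_limit, ls="--", c="tab:gray")
        ax.axhline(-self.sdr_limit, ls="--", c="tab:gray")
        ax.set_xlabel("leverage h")
        ax.set_ylabel("standardized residual")
        ax.set_title(f"Williams plot (h* = {self.h_star:.2f})")
        ax.legend(loc="best", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _augmented(records: Sequence[CompoundRecord], names: Sequence[str]) -> np.ndarray:
    return np.array([[1.0, *r.descriptor_vector(names)] for r in records])


def assess_domain(
    dataset: QSARDataset,
    model: ModelSpec,
    candidates: Sequence[CompoundRecord] = (),
    sdr_limit: float = 3.0,
    reference: str = "all",
) -> DomainAssessment:
    """Williams-plot domain assessment of the dataset plus optional candidates.

    ``reference`` selects the rows defining the hat basis, h* and the SDR
    normalization: "all" (train + test, the source study's convention — its
    printed h* uses the full 32-compound dataset) or "train".  Compounds
    without an observed activity (designed candidates) are assessed on
    leverage alone.  A compound is in-domain iff h < h* and |SDR| <= sdr_limit
    (or SDR is undefined).
    """
    if reference == "all":
        ref_records = [*dataset.train, *dataset.test]
    elif reference == "train":
        ref_records = list(dataset.train)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    names = model.descriptor_names
    ref_X = _augmented(ref_records, names)
    h_star = warning_leverage(model.n_descriptors, len(ref_records))

    assessed = [*dataset.train, *dataset.test, *candidates]
    query_X = _augmented(assessed, names)
    h = leverages(ref_X, query_X)

    ref_obs = np.array([float(r.observed_pic50) for r in ref_records])
    ref_pred = np.array([model.predict_record(r) for r in ref_records])
    rms = float(np.sqrt(np.mean((ref_obs - ref_pred) ** 2)))
    if rms == 0.0:
        raise ZeroDivisionError("all reference residuals are zero; SDR undefined")

    sdr: list[float | None] = []
    flags: list[bool] = []
    for record, hi in zip(assessed, h):
        if record.observed_pic50 is None:
            s = None
        else:
            s = (float(record.observed_pic50) - model.predict_record(record)) / rms
        sdr.append(s)
        flags.append(bool(hi < h_star and (s is None or abs(s) <= sdr_limit)))
    return DomainAssessment(
        labels=tuple(r.label for r in assessed),
        leverage=tuple(map(float, h)),
        sdr=tuple(sdr),
        in_domain=tuple(flags),
        h_star=h_star,
        sdr_limit=sdr_limit,
    )
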