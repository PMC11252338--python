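"""Ordinary-least-squares engine: fitting, backward elimination, prediction, VIF.

statsmodels provides the underlying OLS machinery (coefficients, standard
errors, per-coefficient p-values); this module wraps it behind the package's
domain types and adds the descriptor-selection loop used to build the model:
iterative removal of the least significant descriptor, followed by a variance
-inflation-factor screen against multicollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.linalg import qr as _qr

from .data_model import CompoundRecord, ModelSpec, PredictionSet, QSARDataset

__all__ = [
    "FitDiagnostics",
    "VIFTable",
    "SingularFitError",
    "EmptyModelError",
    "fit_ols",
    "backward_eliminate",
    "predict",
    "predict_dataset",
    "vif",
    "design_matrix",
]

_RANK_RTOL = 1e-10


class SingularFitError(np.linalg.LinAlgError):
    """Design matrix is rank-deficient; carries the offending column names."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank-deficient in columns: {self.columns}")


class EmptyModelError(RuntimeError):
    """Backward elimination removed every descriptor."""


@dataclass(frozen=True)
class FitDiagnostics:
    """Inference output of one OLS fit, keyed like the model's coefficients."""

    std_errors: Mapping[str, float]  # includes "intercept"
    p_values: Mapping[str, float]
    dof: int  # residual degrees of freedom, N - p - 1

    def __post_init__(self) -> None:
        if self.dof < 1:
            raise ValueError("residual degrees of freedom must be >= 1")


@dataclass(frozen=True)
class VIFTable:
    """Per-descriptor variance inflation factors, 1/(1 - R_j^2)."""

    values: Mapping[str, float]

    def worst(self) -> tuple[str, float]:
        name = max(self.values, key=lambda n: self.values[n])
        return name, self.values[name]


def design_matrix(
    dataset: QSARDataset, descriptor_names: Sequence[str], subset: str = "train"
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Intercept-augmented design matrix, response vector, and row labels."""
    rows = dataset.subset(subset)
    X = np.array([[1.0, *r.descriptor_vector(descriptor_names)] for r in rows])
    y = np.array([float(r.observed_pic50) for r in rows])
    return X, y, [r.label for r in rows]


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X, tol=_RANK_RTOL * np.linalg.norm(X, 2))
    if rank < X.shape[1]:
        # identify dependent columns by rank-revealing QR pivoting
        _, _, piv = _qr(X, pivoting=True)
        bad = sorted(piv[rank:].tolist())
        cols = ["intercept", *names]
        raise SingularFitError([cols[j] for j in bad])


def fit_ols(
    dataset: QSARDataset,
    descriptor_names: Sequence[str],
    subset: str = "train",
) -> tuple[ModelSpec, FitDiagnostics]:
    """Least-squares fit of observed pIC50 on the named descriptors.

    The intercept is always included.  Requires N > p + 1 rows and a
    full-column-rank design; a rank-deficient design raises
    :class:`SingularFitError` naming the collinear columns.
    """
    names = list(descriptor_names)
    X, y, _ = design_matrix(dataset, names, subset)
    n, p1 = X.shape
    if n <= p1:
        raise ValueError(f"need N > p + 1 rows, got N={n}, p={p1 - 1}")
    _check_rank(X, names)
    res = sm.OLS(y, X).fit()
    keys = ["intercept", *names]
    model = ModelSpec(
        descriptor_names=tuple(names),
        intercept=float(res.params[0]),
        slopes={n_: float(b) for n_, b in zip(names, res.params[1:])},
        n_train=n,
        n_descriptors=len(names),
    )
    diag = FitDiagnostics(
        std_errors=dict(zip(keys, map(float, res.bse))),
        p_values=dict(zip(keys, map(float, res.pvalues))),
        dof=int(res.df_resid),
    )
    return model, diag


def predict(model: ModelSpec, record: CompoundRecord) -> float:
    """intercept + sum(slope_j * x_j); raises KeyError naming a missing descriptor."""
    return model.predict_record(record)


def predict_dataset(
    model: ModelSpec, dataset: QSARDataset, subset: str | None = None
) -> PredictionSet:
    rows = dataset.records if subset is None else dataset.subset(subset)
    return PredictionSet(
        labels=tuple(r.label for r in rows),
        predicted=tuple(model.predict_record(r) for r in rows),
        observed=tuple(r.observed_pic50 for r in rows),
    )


def vif(
    dataset: QSARDataset, descriptor_names: Sequence[str], subset: str = "train"
) -> VIFTable:
    """Variance inflation factors from auxiliary regressions with intercept.

    VIF_j = 1/(1 - R_j^2) where R_j^2 is the determination coefficient of the
    OLS regression of descriptor j on the remaining descriptors.  A perfectly
    collinear descriptor is reported as ``inf`` rather than raising.
    """
    names = list(descriptor_names)
    if len(names) < 2:
        raise ValueError("VIF needs at least two descriptors")
    rows = dataset.subset(subset)
    cols = {n: np.array([float(r.descriptors[n]) for r in rows]) for n in names}
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        others = [n for n in names if n != name]
        A = np.column_stack([np.ones(len(rows))] + [cols[n] for n in others])
        yj = cols[name]
        beta, *_ = np.linalg.lstsq(A, yj, rcond=None)
        rss = float(np.sum((yj - A @ beta) ** 2))
        tss = float(np.sum((yj - yj.mean()) ** 2))
        if tss == 0.0:
            out[name] = float("inf")
            continue
        ratio = rss / tss  # = 1 - R_j^2
        # below numerical resolution the column is effectively collinear
        out[name] = float("inf") if ratio <= 1e-12 else 1.0 / ratio
    return VIFTable(values=out)


def backward_eliminate(
    dataset: QSARDataset,
    all_descriptors: Sequence[str],
    alpha: float = 0.05,
    vif_cap: float = 10.0,
    subset: str = "train",
) -> ModelSpec:
    """Descendant descriptor selection: drop-worst-p-value, then a VIF screen.

    While any slope's p-value exceeds ``alpha``, the descriptor with the
    largest p-value is removed and the model refit (ties broken by descriptor
    order).  Afterwards, while any VIF exceeds ``vif_cap``, the worst offender
    is removed, refitting each time.  The intercept is never a candidate.
    Removals are recorded in the returned model's ``removal_log``.
    """
    names = list(all_descriptors)
    if len(names) < 2:
        raise ValueError("need at least two candidate descriptors")
    log: list[str] = []

    def _fit(current: list[str]) -> tuple[ModelSpec, FitDiagnostics]:
        return fit_ols(dataset, current, subset)

    model, diag = _fit(names)
    while names:
        pvals = [diag.p_values[n] for n in names]
        worst = max(pvals)
        if worst <= alpha:
            break
        drop = names[pvals.index(worst)]  # first occurrence: tie-break by order
        log.append(f"p-value: removed {drop} (p={worst:.4g} > {alpha})")
        names.remove(drop)
        if not names:
            raise EmptyModelError("significance screening removed every descriptor")
        model, diag = _fit(names)

    while len(names) >= 2:
        table = vif(dataset, names, subset)
        name, value = table.worst()
        if value <= vif_cap:
            break
        log.append(f"VIF: removed {name} (VIF={value:.4g} > {vif_cap})")
        names.remove(name)
        if not names:
            raise EmptyModelError("VIF screening removed every descriptor")
        model, diag = _fit(names)

    return ModelSpec(
        descriptor_names=model.descriptor_names,
        intercept=model.intercept,
        slopes=model.slopes,
        n_train=model.n_train,
        n_descriptors=model.n_descriptors,
        removal_log=tuple(log),
    )
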