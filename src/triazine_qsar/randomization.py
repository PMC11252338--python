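"""Y-randomization (response-scrambling) robustness test.

The training responses are permuted uniformly at random, the model is refit on
the unchanged descriptors, and the fit/cross-validation statistics of the
scrambled models are averaged.  A genuine structure-activity relationship
must score far above its scrambled versions; the cRp^2 statistic summarizes
the margin and is conventionally required to exceed 0.5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import QSARDataset
from .mlr import design_matrix

__all__ = ["RandomizationResult", "run_y_randomization", "crp2"]


@dataclass(frozen=True)
class RandomizationResult:
    """Per-iteration scrambled-model statistics and their averages."""

    n_iterations: int
    r_rand: tuple[float, ...]
    r2_rand: tuple[float, ...]
    q2_rand: tuple[float, ...]
    seed: int
    skipped: tuple[int, ...] = ()

    @property
    def mean_r_rand(self) -> float:
        return float(np.mean(self.r_rand))

    @property
    def mean_r2_rand(self) -> float:
        return float(np.mean(self.r2_rand))

    @property
    def mean_q2_rand(self) -> float:
        return float(np.mean(self.q2_rand))

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "mean_r_rand": self.mean_r_rand,
            "mean_r2_rand": self.mean_r2_rand,
            "mean_q2_rand": self.mean_q2_rand,
            "r_rand": list(self.r_rand),
            "r2_rand": list(self.r2_rand),
            "q2_rand": list(self.q2_rand),
            "skipped": list(self.skipped),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def run_y_randomization(
    dataset: QSARDataset,
    descriptor_names: Sequence[str],
    n_iterations: int = 100,
    seed: int = 0,
) -> RandomizationResult:
    """Scramble training responses ``n_iterations`` times and refit each time.

    Each iteration permutes the observed training activities without
    replacement (descriptors and the train/test split untouched), refits OLS,
    and records R, R2 and leave-one-out Q2 of the scrambled model.  Fully
    reproducible from ``seed``.  An iteration whose permuted refit is
    rank-deficient is recorded in ``skipped`` (the descriptor matrix is fixed,
    so in practice this only occurs for degenerate designs).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    X, y, _ = design_matrix(dataset, descriptor_names, "train")
    n, p1 = X.shape
    if n <= p1 + 1:
        raise ValueError("need N > p + 2 training rows")
    if np.linalg.matrix_rank(X) < p1:
        raise np.linalg.LinAlgError("rank-deficient training design")
    G = np.linalg.pinv(X.T @ X)
    H = X @ G @ X.T
    h = np.diag(H).copy()
    rng = np.random.default_rng(seed)

    r_list: list[float] = []
    r2_list: list[float] = []
    q2_list: list[float] = []
    skipped: list[int] = []
    for it in range(n_iterations):
        yp = rng.permutation(y)
        fitted = H @ yp
        resid = yp - fitted
        tss = float(np.sum((yp - yp.mean()) ** 2))
        if tss == 0.0 or np.any(h >= 1.0 - 1e-12):
            skipped.append(it)
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / tss
        press = float(np.sum((resid / (1.0 - h)) ** 2))
        r_list.append(math.sqrt(max(r2, 0.0)))
        r2_list.append(r2)
        q2_list.append(1.0 - press / tss)
    return RandomizationResult(
        n_iterations=n_iterations,
        r_rand=tuple(r_list),
        r2_rand=tuple(r2_list),
        q2_rand=tuple(q2_list),
        seed=seed,
        skipped=tuple(skipped),
    )


def crp2(r: float, r2: float, mean_r_rand: float) -> float:
    """cRp^2 = r * sqrt(r2 - mean_r_rand^2); must exceed 0.5 to pass.

    Raises on a negative radicand (scrambled models as good as the real one).
    """
    radicand = r2 - mean_r_rand**2
    if radicand < 0:
        raise ValueError(
            f"negative radicand: R2={r2} < (mean R_rand)^2={mean_r_rand**2:.4f}; "
            "the scrambled models explain as much variance as the real model"
        )
    return r * math.sqrt(radicand)
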