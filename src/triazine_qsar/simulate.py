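"""Seedable generator of QSAR-like datasets with known ground truth.

The generator emulates the statistical shape of the study panel — a small
training set, bounded continuous descriptors, categorical hydrogen-bond and
indicator columns, and a linear response with Gaussian noise — so that
parameter recovery, descriptor selection, randomization nulls and
applicability-domain flagging can be tested against a known truth.  It makes
no attempt to simulate chemistry: descriptors are draws from ranges, not
properties of structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import CompoundRecord, QSARDataset

__all__ = ["GeneratorConfig", "generate", "inject_outlier"]

#: Default truth mirrors the published equation; descriptor ranges span the
#: study's training and designed compounds; the noise level matches the
#: residual spread of the published fit (sigma ~ 0.24).
_DEFAULT_SLOPES = {
    "chi": 1.64,
    "TE": -5.69e-05,
    "NHD": 1.48,
    "LogS": -1.37,
    "I_shape": -0.36,
}
_DEFAULT_DISTRIBUTIONS: Mapping[str, tuple] = {
    "chi": ("uniform", 2.9, 4.1),
    "TE": ("uniform", -106000.0, -22000.0),
    "NHD": ("categorical", (1, 2, 3, 4, 5, 6)),
    "LogS": ("uniform", -5.2, -2.7),
    "I_shape": ("categorical", (0, 1)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to regenerate a synthetic dataset bit-for-bit.

    ``descriptor_distributions`` maps name -> ("uniform", low, high) or
    ("categorical", (levels...)).  ``nuisance_descriptors`` adds that many
    uninformative columns, each correlated at ``nuisance_rho`` with a randomly
    chosen informative continuous descriptor (0 for independent noise).
    """

    n_train: int = 27
    n_test: int = 5
    true_intercept: float = -10.12
    true_slopes: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SLOPES))
    descriptor_distributions: Mapping[str, tuple] = field(
        default_factory=lambda: dict(_DEFAULT_DISTRIBUTIONS)
    )
    nuisance_descriptors: int = 0
    nuisance_rho: float = 0.0
    noise_sd: float = 0.24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not -1.0 < self.nuisance_rho < 1.0:
            raise ValueError("nuisance_rho must lie in (-1, 1)")
        missing = [n for n in self.true_slopes if n not in self.descriptor_distributions]
        if missing:
            raise ValueError(f"no distribution given for slope descriptors: {missing}")


def _draw(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    kind = dist[0]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=n)
    if kind == "categorical":
        return rng.choice(np.asarray(dist[1], dtype=float), size=n)
    raise ValueError(f"unknown distribution kind {kind!r}")


def generate(config: GeneratorConfig) -> QSARDataset:
    """Draw descriptors, build the linear response, split train/test by permutation."""
    rng = np.random.default_rng(config.seed)
    n = config.n_train + config.n_test
    names = list(config.descriptor_distributions)
    columns = {name: _draw(rng, config.descriptor_distributions[name], n) for name in names}

    # correlated nuisance columns: Cholesky-style mixing on standardized
    # informative continuous columns, rescaled to a comparable range
    continuous = [
        name
        for name in names
        if config.descriptor_distributions[name][0] == "uniform" and name in config.true_slopes
    ]
    for j in range(config.nuisance_descriptors):
        noise = rng.standard_normal(n)
        rho = config.nuisance_rho
        if rho != 0.0 and continuous:
            base = columns[continuous[j % len(continuous)]]
            z = (base - base.mean()) / base.std()
            mixed = rho * z + np.sqrt(1.0 - rho**2) * noise
        else:
            mixed = noise
        columns[f"nuisance_{j}"] = mixed

    y = np.full(n, config.true_intercept)
    for name, slope in config.true_slopes.items():
        y = y + slope * columns[name]
    y = y + rng.normal(0.0, config.noise_sd, size=n)

    order = rng.permutation(n)
    subsets = np.empty(n, dtype=object)
    subsets[order[: config.n_train]] = "train"
    subsets[order[config.n_train:]] = "test"

    records = [
        CompoundRecord(
            label=f"syn{i + 1}",
            descriptors={name: float(columns[name][i]) for name in columns},
            observed_pic50=float(y[i]),
            subset=str(subsets[i]),
        )
        for i in range(n)
    ]
    return QSARDataset.from_records(records, descriptor_names=list(columns))


def inject_outlier(dataset: QSARDataset, sigma_multiplier: float) -> QSARDataset:
    """Append one designed-subset compound far from the training centroid.

    The new compound sits ``sigma_multiplier`` standard deviations from the
    centroid along the first principal direction of the (standardized)
    training descriptors, then is mapped back to descriptor units.
    """
    if sigma_multiplier <= 0:
        raise ValueError("sigma_multiplier must be > 0")
    names = dataset.descriptor_names
    X = np.array([[float(r.descriptors[n]) for n in names] for r in dataset.train])
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0.0):
        degenerate = [n for n, s in zip(names, sd) if s == 0.0]
        raise ValueError(f"zero-variance descriptors: {degenerate}")
    Z = (X - mean) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    direction = vt[0]
    point = mean + sigma_multiplier * direction * sd
    outlier = CompoundRecord(
        label="injected_outlier",
        descriptors={n: float(v) for n, v in zip(names, point)},
        observed_pic50=None,
        subset="designed",
    )
    return QSARDataset(
        records=(*dataset.records, outlier), descriptor_names=dataset.descriptor_names
    )
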