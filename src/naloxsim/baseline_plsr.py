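"""Partial-least-squares regression baseline.

Maps the same concatenated feature vector the black-box network sees to the
flattened occupancy trajectory.  The number of latent components is chosen
by k-fold cross-validation (default 15 folds) minimizing mean squared
prediction error; features are standardized by the PLS fit itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .scenarios import EmulatorDataset

__all__ = ["PLSRConfig", "FittedPLSR", "fit_plsr", "predict_plsr"]


@dataclass(frozen=True)
class PLSRConfig:
    max_components: int = 10
    folds: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")


@dataclass
class FittedPLSR:
    model: PLSRegression
    n_components: int
    cv_errors: np.ndarray  # MSE per candidate component count (index 0 -> 1 comp.)
    config: PLSRConfig = field(default=None)

    @property
    def cv_error(self) -> float:
        return float(self.cv_errors[self.n_components - 1])


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, EmulatorDataset):
        return dataset.inputs_concat, dataset.targets
    x, y = dataset
    return np.asarray(x), np.asarray(y)


def fit_plsr(dataset, config: PLSRConfig | None = None) -> FittedPLSR:
    """Select the component count (1..max) by cross-validated MSE and refit
    on the full data.  Candidate counts above the feature rank are capped
    with a warning."""
    config = config or PLSRConfig()
    x, y = _as_xy(dataset)
    n = x.shape[0]
    if n < config.folds:
        raise ValueError(f"need at least {config.folds} records for "
                         f"{config.folds}-fold cross-validation, got {n}")
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
    max_comp = min(config.max_components, max(rank, 1))
    if max_comp < config.max_components:
        warnings.warn(
            f"max_components capped at feature rank {max_comp}", stacklevel=2)
    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    splits = list(kf.split(x))
    cv_errors = np.empty(max_comp)
    for k in range(1, max_comp + 1):
        sse = 0.0
        count = 0
        for tr, te in splits:
            m = PLSRegression(n_components=k, scale=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(x[tr], y[tr])
            pred = m.predict(x[te])
            sse += float(np.sum((pred - y[te]) ** 2))
            count += y[te].size
        cv_errors[k - 1] = sse / count
    best = int(np.argmin(cv_errors)) + 1
    final = PLSRegression(n_components=best, scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(x, y)
    return FittedPLSR(model=final, n_components=best, cv_errors=cv_errors,
                      config=config)


def predict_plsr(fitted: FittedPLSR, inputs) -> np.ndarray:
    """Predict occupancy trajectories, clipped to [0, 1] so the PD map
    stays in range."""
    if isinstance(inputs, EmulatorDataset):
        x = inputs.inputs_concat
    else:
        x = np.atleast_2d(np.asarray(inputs))
    if x.shape[1] != fitted.model.x_loadings_.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match the fitted model "
            f"({fitted.model.x_loadings_.shape[0]})")
    pred = fitted.model.predict(x)
    return np.clip(pred, 0.0, 1.0)
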