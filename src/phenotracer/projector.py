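"""Neural-network projection of new samples onto the reference map.

A single-hidden-layer regressor (6 markers -> H sigmoidal hidden units ->
2 linear outputs, H = 11 by default) is trained to reproduce the reference
embedding coordinates from min-max-normalized marker values. Trained on a
90% split; the 10% holdout reports generalization error and, together
with 10-fold cross-validation, the stability of the predicted positions.
Projection of a new sample is a pure forward pass using the stored
training normalization ranges (out-of-range inputs are clipped, never
rescaled, so there is no leakage of the new sample's own distribution),
followed by nearest-center state assignment for per-state composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, train_test_split
from sklearn.neural_network import MLPRegressor

from .datatypes import CellMatrix, PhenoMap, ProjectionResult, Projector
from .phenomap import assign_region

DEFAULT_HIDDEN = 11
DEFAULT_TRAIN_FRACTION = 0.9
DEFAULT_CV_FOLDS = 10


@dataclass
class TrainingReport:
    """Holdout error and cross-validation stability of a trained projector."""

    holdout_mse: float
    train_mse: float
    cv_prediction_sd: float
    coordinate_sd: float
    hidden_size: int
    n_train: int
    n_holdout: int
    hidden_sweep: dict[int, float] | None = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        if d["hidden_sweep"] is not None:
            d["hidden_sweep"] = {str(k): v for k, v in d["hidden_sweep"].items()}
        return d


def _fit_mlp(X, Y, hidden_size, seed, max_iter=3000):
    mlp = MLPRegressor(
        hidden_layer_sizes=(hidden_size,),
        activation="logistic",
        solver="lbfgs",
        alpha=1e-4,
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lbfgs max-iter warnings
        mlp.fit(X, Y)
    return mlp


def _forward(proj: Projector, X01: np.ndarray) -> np.ndarray:
    h = 1.0 / (1.0 + np.exp(-(X01 @ proj.w_hidden + proj.b_hidden)))
    return h @ proj.w_out + proj.b_out


def train_projector(
    matrix6: CellMatrix,
    coords: np.ndarray,
    hidden_size: int = DEFAULT_HIDDEN,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    cv_folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    labels: np.ndarray | None = None,
    hidden_sweep: tuple[int, ...] | None = None,
) -> tuple[Projector, TrainingReport]:
    """Train the 6 -> hidden -> 2 regressor on the reference embedding.

    Inputs are min-max scaled to [0, 1] using ranges computed on the
    training split only (stored in the returned :class:`Projector`).
    The split is stratified by state label when ``labels`` is given.
    The report carries the holdout MSE, the cross-validation stability
    (mean SD of the fold models' predictions on the holdout cells), and
    optionally a hidden-size sweep of holdout MSEs.
    """
    X = matrix6.values
    Y = np.asarray(coords, dtype=float)
    if X.shape[1] != 6:
        raise ValueError(f"expected exactly 6 markers, got {X.shape[1]}")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("matrix and coords row counts differ")
    if X.shape[0] < 100:
        raise ValueError("need at least 100 cells to train")

    idx = np.arange(X.shape[0])
    tr, ho = train_test_split(
        idx,
        train_size=train_fraction,
        random_state=seed,
        stratify=None if labels is None else np.asarray(labels),
    )
    lo = X[tr].min(axis=0)
    hi = X[tr].max(axis=0)
    degenerate = np.flatnonzero(hi <= lo)
    if degenerate.size:
        names = [matrix6.marker_names[i] for i in degenerate]
        raise ValueError(f"degenerate marker range (min == max): {names}")

    def scale(A):
        return np.clip((A - lo) / (hi - lo), 0.0, 1.0)

    Xtr, Xho = scale(X[tr]), scale(X[ho])
    Ytr, Yho = Y[tr], Y[ho]

    sweep = None
    if hidden_sweep:
        sweep = {}
        for h in hidden_sweep:
            m = _fit_mlp(Xtr, Ytr, h, seed)
            sweep[int(h)] = float(np.mean((m.predict(Xho) - Yho) ** 2))

    mlp = _fit_mlp(Xtr, Ytr, hidden_size, seed)
    projector = Projector(
        marker_order=list(matrix6.marker_names),
        input_min=lo,
        input_max=hi,
        w_hidden=mlp.coefs_[0],
        b_hidden=mlp.intercepts_[0],
        w_out=mlp.coefs_[1],
        b_out=mlp.intercepts_[1],
        activation="logistic",
    )
    holdout_mse = float(np.mean((_forward(projector, Xho) - Yho) ** 2))
    train_mse = float(np.mean((_forward(projector, Xtr) - Ytr) ** 2))

    # CV stability: train one model per fold-complement, compare their
    # predictions on the common holdout cells
    preds = []
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for fold_i, (keep, _) in enumerate(kf.split(Xtr)):
        m = _fit_mlp(Xtr[keep], Ytr[keep], hidden_size, seed + fold_i + 1)
        preds.append(m.predict(Xho))
    preds = np.stack(preds)  # folds x holdout x 2
    cv_sd = float(np.mean(preds.std(axis=0)))
    report = TrainingReport(
        holdout_mse=holdout_mse,
        train_mse=train_mse,
        cv_prediction_sd=cv_sd,
        coordinate_sd=float(Y.std(axis=0).mean()),
        hidden_size=hidden_size,
        n_train=len(tr),
        n_holdout=len(ho),
        hidden_sweep=sweep,
    )
    return projector, report


def project(projector: Projector, new_matrix6: CellMatrix) -> np.ndarray:
    """Project a new sample onto the reference map (pure forward pass).

    Markers are reordered to the training order; inputs are scaled by the
    stored training ranges with out-of-range values clipped to [0, 1]. A
    warning is raised when more than half of all values clip, which
    signals a transform/domain mismatch with the training data.
    """
    mat = new_matrix6.select_markers(projector.marker_order)
    X = mat.values
    lo, hi = projector.input_min, projector.input_max
    X01 = (X - lo) / (hi - lo)
    clipped = (X01 < 0) | (X01 > 1)
    if clipped.mean() > 0.5:
        warnings.warn(
            f"{clipped.mean():.0%} of input values fall outside the training "
            "ranges; the sample is likely on a different scale than the "
            "training data"
        )
    return _forward(projector, np.clip(X01, 0.0, 1.0))


def score_sample(
    coords: np.ndarray, pheno_map: PhenoMap, k: int = 1
) -> ProjectionResult:
    """Per-state composition of a projected sample.

    Each cell is assigned by k-NN on the partition centers; fractions are
    cell shares per state (cells outside the boundary are flagged but
    included in the denominators).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    state_ids, out = assign_region(coords, pheno_map, k=k)
    K = len(pheno_map.state_ids)
    counts = np.bincount(state_ids, minlength=K + 1)[1:]
    return ProjectionResult(
        coords=coords,
        state_ids=state_ids,
        state_fractions=counts / counts.sum(),
        out_of_map=out,
        state_names=list(pheno_map.state_names),
    )
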