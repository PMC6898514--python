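"""Sparse Markov transition inference from aggregate state fractions.

The estimation problem: cell-state occupancy fractions f_t are observed at
T discrete (possibly nonuniform) time points, individual cells are not
tracked, and the number of states K is large relative to T. Modelling the
population as a time-homogeneous Markov chain within a phase, the K x K
row-stochastic transition matrix P is estimated by penalized least squares

    minimize_P  sum_t || f_{t+1} - f_t P ||_2^2  +  lambda * sum_{j != k} p_jk
    subject to  p_jk >= 0,  sum_k p_jk = 1 for every row j.

Off-diagonal entries carry an L1 penalty (linear under the nonnegativity
constraints) while self-transitions are free: staying in a state costs
nothing, switching is discouraged. The problem is a convex quadratic
program over a product of probability simplices (see ``_qp``).

The sparsity level is chosen by cell-level cross-validation with the
one-standard-error rule (largest lambda whose CV error is within one SE of
the minimum); uncertainty is quantified by a multinomial bootstrap of the
per-time-point counts; the representative network of a bootstrap ensemble
is its medoid under entry-wise L1 distance; and hysteresis between two
phases is read off the per-edge bootstrap support frequencies.

A caution that shapes several defaults here: aggregate fractions only
constrain the NET occupancy flow, so with few time points the penalized
objective identifies the minimum-switching explanation of the data, not
necessarily the generating matrix. Support selection is the fragile step;
magnitudes on a correct support are well determined (see the debiasing
refit in :func:`fit_transitions_cv`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._qp import solve_restricted_ls, solve_row_stochastic
from .datatypes import (
    BootstrapEnsemble,
    SparsityPath,
    StateFractionSeries,
    TransitionMatrix,
)

DEFAULT_LAMBDA_GRID = np.logspace(-4, 0, 30)
NONZERO_TOL = 1e-6
#: minimum probability treated as a real edge when reading support off a fit
SUPPORT_TOL = 0.01


def _penalty_mask(active: np.ndarray, K: int) -> np.ndarray:
    """No penalty on self-transitions; unit penalty elsewhere."""
    mask = np.ones((active.size, K))
    mask[np.arange(active.size), active] = 0.0
    return mask


def _variance_weights(counts: np.ndarray) -> np.ndarray:
    """Inverse-multinomial-variance weights (normalized to mean 1)."""
    n = counts.sum(axis=1, keepdims=True)
    f = (counts + 0.5) / (n + 1.0)
    w = 1.0 / (f * (1.0 - f) / n)
    return w / w.mean()


def fit_transition_matrix(
    series: StateFractionSeries | np.ndarray,
    lam: float,
    phase: str = "",
    state_names: list[str] | None = None,
    weights: np.ndarray | None = None,
    P0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 3000,
) -> TransitionMatrix:
    """Fit one row-stochastic transition matrix to a fraction series.

    Rows for states never occupied at any predictor time point contribute
    nothing to the data term and are unidentified; they are resolved to the
    identity row (the penalty-consistent choice) and flagged in
    ``unidentified_rows``.

    Parameters
    ----------
    series : StateFractionSeries or (T, K) array of fractions
    lam : nonnegative off-diagonal sparsity penalty
    weights : optional (T-1, K) loss weights (e.g. inverse-variance);
        default is the plain squared Euclidean error on fractions
    P0 : optional warm start (K x K)
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if isinstance(series, StateFractionSeries):
        fractions = series.fractions
        phase = phase or series.phase
        state_names = state_names or list(series.state_names)
    else:
        fractions = np.asarray(series, dtype=float)
    T, K = fractions.shape
    if T < 2:
        raise ValueError("need at least two time points")
    F, G = fractions[:-1], fractions[1:]

    occupied = F.sum(axis=0) > 0.0
    active = np.flatnonzero(occupied)
    P = np.eye(K)
    if active.size:
        mask = _penalty_mask(active, K)
        P_act = solve_row_stochastic(
            F[:, active],
            G,
            lam,
            mask,
            W=None if weights is None else weights,
            P0=P0[active] if P0 is not None else None,
            tol=tol,
            maxit=max_iter,
        )
        P[active] = P_act
    resid = G - F @ P
    full_mask = np.ones((K, K)) - np.eye(K)
    return TransitionMatrix(
        np.clip(P, 0.0, 1.0),
        phase=phase,
        state_names=state_names,
        objective=float(np.sum(resid * resid) + lam * np.sum(full_mask * P)),
        lam=lam,
        unidentified_rows=[int(j) for j in np.flatnonzero(~occupied)],
    )


# ---------------------------------------------------------------------------
# Cross-validation and the 1-SE rule


def one_se_select(
    lambda_grid: np.ndarray, cv_error: np.ndarray, cv_se: np.ndarray
) -> tuple[float, float]:
    """Apply the one-standard-error rule to a CV curve.

    Returns (lambda_min, lambda_1se): the error-minimizing lambda and the
    largest lambda whose error is within one standard error of the minimum.
    With a flat error curve this selects the largest lambda on the grid.
    """
    lambda_grid = np.asarray(lambda_grid, float)
    cv_error = np.asarray(cv_error, float)
    cv_se = np.asarray(cv_se, float)
    i_min = int(np.argmin(cv_error))
    threshold = cv_error[i_min] + cv_se[i_min]
    within = np.flatnonzero(cv_error <= threshold)
    return float(lambda_grid[i_min]), float(lambda_grid[within.max()])


def _split_counts(
    counts: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Partition each time point's cells uniformly at random into folds."""
    T, K = counts.shape
    out = np.zeros((n_folds, T, K), dtype=int)
    for t in range(T):
        cells = np.repeat(np.arange(K), counts[t])
        rng.shuffle(cells)
        for i, chunk in enumerate(np.array_split(cells, n_folds)):
            out[i, t] = np.bincount(chunk, minlength=K)
    return out


def cross_validate_lambda(
    counts: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_folds: int = 2,
    n_repeats: int = 8,
    seed: int | np.random.Generator = 0,
) -> SparsityPath:
    """Select the sparsity penalty by repeated K-fold cell-level CV.

    Cells at each time point are partitioned uniformly at random into
    ``n_folds`` folds, ``n_repeats`` times. For each held-out fold, the
    matrix is fit on the pooled remaining folds' fractions across the
    lambda grid (warm-started from large to small lambda) and scored by
    mean squared one-step prediction error on the held-out fractions.
    ``cv_error``/``cv_se`` are the mean and standard error over all
    ``n_folds * n_repeats`` fold errors; ``lambda_1se`` implements the
    one-SE rule. Repetition matters: with a single 2-fold split the SE is
    estimated from two numbers and the rule intermittently selects a
    lambda large enough to delete dominant real transitions.
    """
    counts = np.asarray(counts, dtype=int)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size > 1 and np.any(np.diff(lambda_grid) <= 0):
        raise ValueError("lambda grid must be strictly ascending")
    if np.any(counts.sum(axis=1) < n_folds):
        raise ValueError("each time point needs at least n_folds cells")
    if lambda_grid.size == 1:
        warnings.warn("lambda grid of length 1: returning it trivially")
        lam = float(lambda_grid[0])
        return SparsityPath(lambda_grid, np.zeros(1), np.zeros(1), lam, lam)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_lam = lambda_grid.size
    errors = np.empty((n_folds * n_repeats, n_lam))
    row = 0
    for _ in range(n_repeats):
        folds = _split_counts(counts, n_folds, rng)
        totals = folds.sum(axis=2, keepdims=True)
        for i in range(n_folds):
            train = counts - folds[i]
            f_train = train / train.sum(axis=1, keepdims=True)
            f_held = folds[i] / totals[i]
            P_warm = None
            for g in range(n_lam - 1, -1, -1):
                fit = fit_transition_matrix(
                    f_train, lambda_grid[g], P0=P_warm, tol=1e-8, max_iter=2000
                )
                P_warm = fit.P
                pred = f_held[:-1] @ fit.P
                errors[row, g] = float(np.mean((f_held[1:] - pred) ** 2))
            row += 1
    cv_error = errors.mean(axis=0)
    cv_se = errors.std(axis=0, ddof=1) / np.sqrt(errors.shape[0])
    lam_min, lam_1se = one_se_select(lambda_grid, cv_error, cv_se)
    return SparsityPath(lambda_grid, cv_error, cv_se, lam_min, lam_1se)


def fit_transitions_cv(
    series: StateFractionSeries,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_folds: int = 2,
    n_repeats: int = 8,
    debias: bool = True,
    seed: int | np.random.Generator = 0,
) -> tuple[TransitionMatrix, SparsityPath]:
    """CV-selected fit for one phase: select lambda, fit, optionally debias.

    With ``debias`` (default), the penalized fit is used only for support
    selection (entries above ``SUPPORT_TOL``); magnitudes are re-estimated
    by least squares restricted to that support, removing the L1 shrinkage
    toward the diagonal. The refit is iterated once so entries that fall
    below the support tolerance after debiasing are dropped.
    """
    path = cross_validate_lambda(
        series.counts, lambda_grid, n_folds=n_folds, n_repeats=n_repeats, seed=seed
    )
    emp = series.counts / series.counts.sum(axis=1, keepdims=True)
    fit = fit_transition_matrix(
        emp, path.lambda_1se, phase=series.phase, state_names=list(series.state_names)
    )
    if debias:
        F, G = emp[:-1], emp[1:]
        P = fit.P
        for _ in range(2):
            P = solve_restricted_ls(F, G, P > SUPPORT_TOL)
        fit = TransitionMatrix(
            P,
            phase=series.phase,
            state_names=list(series.state_names),
            objective=float(np.sum((G - F @ P) ** 2)),
            lam=path.lambda_1se,
            unidentified_rows=fit.unidentified_rows,
        )
    return fit, path


# ---------------------------------------------------------------------------
# Bootstrap, summaries, medoid, phase comparison


def bootstrap_transitions(
    series: StateFractionSeries,
    n_per_timepoint: int = 10_000,
    B: int = 100,
    lambda_policy: str = "per-replicate-cv",
    lam: float | None = None,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_folds: int = 2,
    cv_repeats: int = 3,
    seed: int = 0,
) -> BootstrapEnsemble:
    """Multinomial bootstrap of the fitted transition matrix.

    For each replicate, cell counts at every time point are redrawn
    independently as Multinomial(n_per_timepoint, observed fractions). The
    sparsity penalty is re-selected per replicate by cross-validation on
    the resampled counts (``lambda_policy="per-replicate-cv"``, the
    default) or held fixed (``"fixed"`` with an explicit ``lam``); the
    matrix is then fit to the full resampled fractions. ``cv_repeats`` is
    kept modest by default since replicate-to-replicate lambda variability
    is itself integrated over the ensemble.
    """
    if B < 1:
        raise ValueError("need B >= 1 replicates")
    if lambda_policy not in ("per-replicate-cv", "fixed"):
        raise ValueError("lambda_policy must be 'per-replicate-cv' or 'fixed'")
    if lambda_policy == "fixed" and lam is None:
        raise ValueError("fixed lambda policy requires lam")
    rng = np.random.default_rng(seed)
    T, K = series.fractions.shape
    all_counts = np.empty((B, T, K), dtype=int)
    matrices = []
    for b in range(B):
        counts_b = np.empty((T, K), dtype=int)
        for t in range(T):
            counts_b[t] = rng.multinomial(n_per_timepoint, series.fractions[t])
        all_counts[b] = counts_b
        fractions_b = counts_b / counts_b.sum(axis=1, keepdims=True)
        if lambda_policy == "per-replicate-cv":
            path = cross_validate_lambda(
                counts_b, lambda_grid, n_folds=n_folds, n_repeats=cv_repeats, seed=rng
            )
            lam_b = path.lambda_1se
        else:
            lam_b = float(lam)
        matrices.append(
            fit_transition_matrix(
                fractions_b,
                lam_b,
                phase=series.phase,
                state_names=list(series.state_names),
            )
        )
    return BootstrapEnsemble(
        matrices=matrices,
        counts=all_counts,
        n_per_timepoint=n_per_timepoint,
        phase=series.phase,
        state_names=list(series.state_names),
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass
class EdgeSummary:
    """Box-plot statistics of the bootstrap distribution of every edge."""

    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    whisker_lo: np.ndarray
    whisker_hi: np.ndarray
    nonzero_frequency: np.ndarray
    state_names: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        K = self.median.shape[0]
        j, k = np.divmod(np.arange(K * K), K)
        return pd.DataFrame(
            {
                "source": [self.state_names[a] for a in j],
                "target": [self.state_names[a] for a in k],
                "median": self.median.ravel(),
                "q25": self.q25.ravel(),
                "q75": self.q75.ravel(),
                "whisker_lo": self.whisker_lo.ravel(),
                "whisker_hi": self.whisker_hi.ravel(),
                "nonzero_frequency": self.nonzero_frequency.ravel(),
            }
        )


def ensemble_summary(ensemble: BootstrapEnsemble) -> EdgeSummary:
    """Per-edge box-plot statistics across bootstrap replicates.

    Medians and hinges use the linear-interpolation percentile convention;
    whiskers extend to the most extreme replicate value no further than
    1.5 x IQR from the hinges; ``nonzero_frequency`` is the share of
    replicates where the edge exceeds 1e-6.
    """
    if ensemble.B < 2:
        raise ValueError("need at least 2 replicates to summarize")
    A = ensemble.stack()  # B x K x K
    q25, med, q75 = np.percentile(A, [25, 50, 75], axis=0)
    iqr = q75 - q25
    lo_lim, hi_lim = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    whisk_lo = np.where(A >= lo_lim[None], A, np.inf).min(axis=0)
    whisk_hi = np.where(A <= hi_lim[None], A, -np.inf).max(axis=0)
    return EdgeSummary(
        median=med,
        q25=q25,
        q75=q75,
        whisker_lo=whisk_lo,
        whisker_hi=whisk_hi,
        nonzero_frequency=ensemble.nonzero_frequency(NONZERO_TOL),
        state_names=list(ensemble.state_names),
    )


def medoid_network(ensemble: BootstrapEnsemble) -> TransitionMatrix:
    """The replicate minimizing mean entry-wise L1 distance to the others.

    Ties are broken by the lowest replicate index; the medoid is always an
    ensemble member.
    """
    A = ensemble.stack()
    B = A.shape[0]
    if B == 1:
        return ensemble.matrices[0]
    D = np.abs(A[:, None] - A[None, :]).sum(axis=(2, 3))
    mean_dist = D.sum(axis=1) / (B - 1)
    return ensemble.matrices[int(np.argmin(mean_dist))]


@dataclass
class HysteresisReport:
    """Edge-support comparison between the two phase ensembles."""

    freq_emt: np.ndarray
    freq_met: np.ndarray
    support_threshold: float
    emt_only_edges: list[tuple[str, str]]
    met_only_edges: list[tuple[str, str]]
    n_supported_emt: int
    n_supported_met: int
    bidirectional_pairs: list[tuple[str, str]]
    state_names: list[str]

    def phase_unique_edges(self) -> dict[str, list[tuple[str, str]]]:
        return {"EMT": self.emt_only_edges, "MET": self.met_only_edges}

    def to_dict(self) -> dict:
        return {
            "support_threshold": self.support_threshold,
            "n_supported_emt": self.n_supported_emt,
            "n_supported_met": self.n_supported_met,
            "emt_only_edges": [list(e) for e in self.emt_only_edges],
            "met_only_edges": [list(e) for e in self.met_only_edges],
            "bidirectional_pairs": [list(e) for e in self.bidirectional_pairs],
        }


def compare_phases(
    emt: BootstrapEnsemble,
    met: BootstrapEnsemble,
    support_threshold: float = 0.5,
) -> HysteresisReport:
    """Compare off-diagonal edge support between EMT and MET ensembles.

    An edge j -> k is "supported" in a phase when the share of bootstrap
    replicates with p_jk above tolerance reaches ``support_threshold``.
    Reports edges supported in exactly one phase (the hysteresis
    signature), per-phase supported-edge counts, and bidirectional pairs
    (j -> k supported under EMT with k -> j supported under MET).
    """
    if emt.state_names != met.state_names:
        raise ValueError("ensembles have mismatched state names/ordering")
    K = emt.K
    off = ~np.eye(K, dtype=bool)
    f_emt = emt.nonzero_frequency(NONZERO_TOL)
    f_met = met.nonzero_frequency(NONZERO_TOL)
    sup_emt = (f_emt >= support_threshold) & off
    sup_met = (f_met >= support_threshold) & off
    names = emt.state_names

    def _edges(mask):
        return [(names[j], names[k]) for j, k in zip(*np.nonzero(mask))]

    bidir = [
        (names[j], names[k])
        for j, k in zip(*np.nonzero(sup_emt & sup_met.T))
        if j != k
    ]
    return HysteresisReport(
        freq_emt=f_emt,
        freq_met=f_met,
        support_threshold=support_threshold,
        emt_only_edges=_edges(sup_emt & ~sup_met),
        met_only_edges=_edges(sup_met & ~sup_emt),
        n_supported_emt=int(sup_emt.sum()),
        n_supported_met=int(sup_met.sum()),
        bidirectional_pairs=bidir,
        state_names=list(names),
    )
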