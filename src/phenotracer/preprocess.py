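"""Cytometry preprocessing: loading, transforms, filtering, state fractions.

The steps here are the standard mass-cytometry path from raw ion counts to
analysis-ready matrices: arcsinh variance stabilization, removal of
non-viable (cisplatin-positive) and apoptotic (cleaved-PARP / cleaved-
Caspase-3-positive) cells, density-dependent downsampling ahead of
clustering, pruning of rare states (< 1% prevalence by default), and
conversion of per-cell state labels into per-time-point occupancy
fractions for transition inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from . import fcs
from .datatypes import CellMatrix, StateFractionSeries, StateLabeling

#: cofactor conventional for CyTOF ion counts; an alternative published
#: value of 552 is supported via the ``cofactor`` argument.
DEFAULT_COFACTOR = 5.0


def read_expression_table(
    path,
    fmt: str | None = None,
    markers: list[str] | None = None,
) -> CellMatrix:
    """Read a raw cells x channels table from FCS or delimited text.

    ``fmt`` is inferred from the suffix when omitted (".fcs" vs anything
    else); ``markers`` optionally restricts and orders the channels. Values
    are returned untransformed, row order as stored.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fcs" if path.suffix.lower() == ".fcs" else "delimited"
    if fmt == "fcs":
        values, names, _ = fcs.read_fcs(path)
        mat = CellMatrix(values, names, transformed=False)
    elif fmt == "delimited":
        df = pd.read_csv(path, sep=None, engine="python")
        extra = {}
        for col in ("time", "phase", "state"):
            if col in df.columns:
                extra[col] = df.pop(col).to_numpy()
        mat = CellMatrix(
            df.to_numpy(dtype=float),
            list(df.columns),
            time_label=extra.get("time"),
            phase=extra.get("phase"),
            transformed=False,
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if markers is not None:
        mat = mat.select_markers(markers)
    return mat


def arcsinh_transform(matrix: CellMatrix, cofactor: float = DEFAULT_COFACTOR) -> CellMatrix:
    """Apply x -> asinh(x / cofactor) entrywise; marks the matrix transformed."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if matrix.transformed:
        raise ValueError("matrix is already arcsinh-transformed")
    return CellMatrix(
        np.arcsinh(matrix.values / cofactor),
        list(matrix.marker_names),
        time_label=matrix.time_label,
        phase=matrix.phase,
        transformed=True,
    )


@dataclass
class FilterReport:
    """Counts removed by each viability/apoptosis rule."""

    n_input: int
    n_retained: int
    n_cisplatin_positive: int
    n_apoptotic: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def viability_filter(
    matrix: CellMatrix,
    cisplatin_channel: str,
    cparp_channel: str,
    caspase_channel: str,
    thresholds: dict[str, float],
) -> tuple[CellMatrix, FilterReport]:
    """Remove non-viable and apoptotic cells.

    A cell is retained when its cisplatin signal is at or below threshold
    AND neither cleaved-PARP nor cleaved-Caspase-3 exceeds its threshold
    (apoptosis is an OR over the two cleavage channels). Thresholds are
    user-supplied per channel; gates are dataset-specific and cannot be
    defaulted.
    """
    cis = matrix.values[:, matrix.marker_index(cisplatin_channel)]
    parp = matrix.values[:, matrix.marker_index(cparp_channel)]
    casp = matrix.values[:, matrix.marker_index(caspase_channel)]
    dead = cis > thresholds[cisplatin_channel]
    apop = (parp > thresholds[cparp_channel]) | (casp > thresholds[caspase_channel])
    keep = ~dead & ~apop
    report = FilterReport(
        n_input=matrix.n_cells,
        n_retained=int(keep.sum()),
        n_cisplatin_positive=int(dead.sum()),
        n_apoptotic=int((apop & ~dead).sum()),
    )
    if report.n_retained == 0:
        warnings.warn("viability filter removed every cell")
    return matrix.subset(keep), report


def density_dependent_downsample(
    matrix: CellMatrix,
    target_size: int,
    neighborhood: float | None = None,
    seed: int = 0,
) -> CellMatrix:
    """Thin dense regions so the retained sample is more uniformly spread.

    Local density of each cell is the number of cells within ``neighborhood``
    (Euclidean, over all columns; default radius = 5 x the median
    nearest-neighbor distance). Each cell is kept independently with
    probability min(1, c / density), with c calibrated by bisection so the
    expected number retained equals ``target_size``. Dense regions are
    thinned more than sparse ones; the procedure is order-independent and
    seeded.
    """
    n = matrix.n_cells
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    if target_size > n:
        raise ValueError("target_size exceeds the number of cells")
    if target_size == n:
        return matrix.subset(np.ones(n, dtype=bool))

    X = matrix.values
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    if neighborhood is None:
        d1 = nn.kneighbors(X)[0][:, 1]
        neighborhood = 5.0 * float(np.median(d1))
    density = np.array(
        [len(idx) for idx in nn.radius_neighbors(X, radius=neighborhood)[0]],
        dtype=float,
    )  # includes the cell itself -> >= 1

    def expected(c):
        return np.minimum(1.0, c / density).sum()

    lo, hi = 0.0, float(density.max())
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if expected(mid) < target_size:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    rng = np.random.default_rng(seed)
    keep = rng.random(n) < np.minimum(1.0, c / density)
    return matrix.subset(keep)


@dataclass
class PruneReport:
    """Which states were dropped by the prevalence filter, and how many cells."""

    min_fraction: float
    n_cells: int
    dropped: dict[str, int] = field(default_factory=dict)
    kept: dict[str, int] = field(default_factory=dict)
    renumbering: dict[int, int] = field(default_factory=dict)  # old -> new id

    def to_dict(self) -> dict:
        return {
            "min_fraction": self.min_fraction,
            "n_cells": self.n_cells,
            "dropped": self.dropped,
            "kept": self.kept,
            "renumbering": {str(k): v for k, v in self.renumbering.items()},
        }


def prune_rare_states(
    labeling: StateLabeling, min_fraction: float = 0.01
) -> tuple[StateLabeling, PruneReport]:
    """Drop states holding less than ``min_fraction`` of all cells (inclusive
    at the boundary: a state at exactly the threshold is retained).

    Cells of dropped states become unassigned (label 0); survivors are
    renumbered 1..K' preserving the original order.
    """
    if not (0 < min_fraction < 1):
        raise ValueError("min_fraction must lie in (0, 1)")
    labels = labeling.labels
    n = labels.size
    counts = np.bincount(labels, minlength=labeling.K + 1)[1:]
    keep = counts / n >= min_fraction
    if not keep.any():
        raise ValueError("prevalence filter would drop every state")
    renum = {}
    new_id = 0
    for old in range(labeling.K):
        if keep[old]:
            new_id += 1
            renum[old + 1] = new_id
    new_labels = np.array([renum.get(l, 0) for l in labels])
    new_names = [labeling.state_names[k] for k in range(labeling.K) if keep[k]]
    report = PruneReport(
        min_fraction=min_fraction,
        n_cells=n,
        dropped={
            labeling.state_names[k]: int(counts[k])
            for k in range(labeling.K)
            if not keep[k]
        },
        kept={
            labeling.state_names[k]: int(counts[k])
            for k in range(labeling.K)
            if keep[k]
        },
        renumbering=renum,
    )
    return StateLabeling(new_labels, new_names, len(new_names)), report


def fractions_from_labels(
    labeling: StateLabeling,
    time_label: np.ndarray,
    phase: str,
    times: np.ndarray | None = None,
) -> StateFractionSeries:
    """Per-time-point state occupancy fractions from per-cell labels.

    Unassigned cells (label 0) are excluded from the denominators. Time
    points are sorted ascending; a time point with no assigned cells is an
    error.
    """
    time_label = np.asarray(time_label, dtype=float)
    if time_label.shape[0] != labeling.n_cells:
        raise ValueError("every cell needs a time label")
    uniq = np.unique(time_label) if times is None else np.asarray(times, float)
    K = labeling.K
    counts = np.zeros((uniq.size, K), dtype=int)
    for i, t in enumerate(uniq):
        sel = labeling.labels[time_label == t]
        sel = sel[sel > 0]
        if sel.size == 0:
            raise ValueError(f"no assigned cells at time point {t}")
        counts[i] = np.bincount(sel, minlength=K + 1)[1:]
    fractions = counts / counts.sum(axis=1, keepdims=True)
    return StateFractionSeries(
        phase=phase,
        times=uniq,
        fractions=fractions,
        counts=counts,
        state_names=list(labeling.state_names),
    )
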