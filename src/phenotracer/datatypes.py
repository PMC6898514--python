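"""Shared container types for cytometry matrices, fraction series and fits.

These are deliberately light dataclasses around numpy arrays: validation
happens at construction, and each type knows how to serialize itself to the
plain-text formats the pipeline exchanges (delimited tables and JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SIMPLEX_ATOL = 1e-12
ROW_STOCHASTIC_ATOL = 1e-8

#: The six clustering markers of the EMT/MET panel, in canonical order.
DEFAULT_MARKERS = ("E-Cadherin", "Vimentin", "CD44", "CD24", "MUC1", "Twist")


def _as_2d(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D array, got shape {arr.shape}")
    return arr


@dataclass
class CellMatrix:
    """Cells x markers expression table with optional per-cell annotations.

    ``transformed`` distinguishes raw ion counts (nonnegative) from
    arcsinh-scale values (any sign).
    """

    values: np.ndarray
    marker_names: list[str]
    time_label: np.ndarray | None = None  # per-cell time, days
    phase: np.ndarray | None = None  # per-cell "EMT" | "MET" | "none"
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = _as_2d(self.values)
        self.marker_names = [str(m) for m in self.marker_names]
        if len(self.marker_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.marker_names)} marker names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain NaN/Inf")
        if not self.transformed and np.any(self.values < 0):
            raise ValueError("raw expression values must be nonnegative")
        for name in ("time_label", "phase"):
            ann = getattr(self, name)
            if ann is not None:
                ann = np.asarray(ann)
                if ann.shape[0] != self.n_cells:
                    raise ValueError(f"{name} length != number of cells")
                setattr(self, name, ann)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not found; available: {self.marker_names}"
            ) from None

    def select_markers(self, names: Sequence[str]) -> "CellMatrix":
        idx = [self.marker_index(n) for n in names]
        return CellMatrix(
            self.values[:, idx],
            [self.marker_names[i] for i in idx],
            time_label=self.time_label,
            phase=self.phase,
            transformed=self.transformed,
        )

    def subset(self, mask: np.ndarray) -> "CellMatrix":
        return CellMatrix(
            self.values[mask],
            list(self.marker_names),
            time_label=None if self.time_label is None else self.time_label[mask],
            phase=None if self.phase is None else self.phase[mask],
            transformed=self.transformed,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.marker_names)
        if self.time_label is not None:
            df["time"] = self.time_label
        if self.phase is not None:
            df["phase"] = self.phase
        return df


@dataclass
class StateLabeling:
    """Per-cell state assignment, states numbered 1..K; 0 marks unassigned."""

    labels: np.ndarray
    state_names: list[str]
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.K < 2:
            raise ValueError("need K >= 2 states")
        if len(self.state_names) != self.K:
            raise ValueError("state_names length must equal K")
        assigned = self.labels[self.labels != 0]
        if assigned.size and (assigned.min() < 1 or assigned.max() > self.K):
            raise ValueError("labels must lie in 1..K (0 = unassigned)")

    @property
    def n_cells(self) -> int:
        return self.labels.shape[0]


@dataclass
class StateFractionSeries:
    """Per-state occupancy fractions at ordered time points for one phase."""

    phase: str
    times: np.ndarray
    fractions: np.ndarray  # T x K, rows on the simplex
    counts: np.ndarray  # T x K nonnegative integers
    state_names: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = _as_2d(self.fractions)
        self.counts = np.asarray(self.counts)
        if self.fractions.shape != self.counts.shape:
            raise ValueError("fractions and counts shapes differ")
        if self.times.shape[0] != self.fractions.shape[0]:
            raise ValueError("times length != number of fraction rows")
        if self.fractions.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.fractions < -SIMPLEX_ATOL):
            raise ValueError("fractions must be nonnegative")
        if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError("each time point needs a positive total count")

    @property
    def K(self) -> int:
        return self.fractions.shape[1]

    @property
    def T(self) -> int:
        return self.fractions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, columns=self.state_names)
        df.insert(0, "phase", self.phase)
        df.insert(1, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class TransitionMatrix:
    """K x K row-stochastic matrix of state-transition probabilities."""

    P: np.ndarray
    phase: str = ""
    state_names: list[str] | None = None
    objective: float | None = None
    lam: float | None = None
    unidentified_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.P = _as_2d(self.P)
        K = self.P.shape[0]
        if self.P.shape[1] != K:
            raise ValueError("transition matrix must be square")
        if np.any(self.P < -ROW_STOCHASTIC_ATOL) or np.any(
            self.P > 1 + ROW_STOCHASTIC_ATOL
        ):
            raise ValueError("entries must lie in [0, 1]")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=ROW_STOCHASTIC_ATOL):
            raise ValueError("rows must sum to 1 (row-stochastic)")
        if self.state_names is None:
            self.state_names = [f"S{k + 1}" for k in range(K)]

    @property
    def K(self) -> int:
        return self.P.shape[0]

    def offdiagonal_mass(self) -> float:
        return float(self.P.sum() - np.trace(self.P))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.state_names, columns=self.state_names)

    def edge_list(self, tol: float = 1e-6) -> pd.DataFrame:
        """Long-format (source, target, probability) rows for entries > tol."""
        src, tgt = np.nonzero(self.P > tol)
        return pd.DataFrame(
            {
                "source": [self.state_names[j] for j in src],
                "target": [self.state_names[k] for k in tgt],
                "probability": self.P[src, tgt],
            }
        )


@dataclass
class SparsityPath:
    """Cross-validation curve over a sparsity (lambda) grid."""

    lambda_grid: np.ndarray
    cv_error: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.cv_error = np.asarray(self.cv_error, dtype=float)
        self.cv_se = np.asarray(self.cv_se, dtype=float)
        if not (
            self.lambda_grid.shape == self.cv_error.shape == self.cv_se.shape
        ):
            raise ValueError("grid, cv_error and cv_se must have equal length")
        if self.lambda_1se < self.lambda_min:
            raise ValueError("lambda_1se must be >= lambda_min")


@dataclass
class BootstrapEnsemble:
    """B bootstrap replicates of a fitted transition matrix."""

    matrices: list[TransitionMatrix]
    counts: np.ndarray  # B x T x K resampled counts
    n_per_timepoint: int
    phase: str
    state_names: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.matrices) < 1:
            raise ValueError("need at least one replicate")

    @property
    def B(self) -> int:
        return len(self.matrices)

    @property
    def K(self) -> int:
        return self.matrices[0].K

    def stack(self) -> np.ndarray:
        """B x K x K array of replicate matrices."""
        return np.stack([m.P for m in self.matrices])

    def nonzero_frequency(self, tol: float = 1e-6) -> np.ndarray:
        return (self.stack() > tol).mean(axis=0)


@dataclass
class PhenoMap:
    """Segmented 2D reference map: coordinates, centers, regions, boundary.

    ``regions`` and ``boundary`` are shapely polygons; regions are Voronoi
    cells of the centers clipped to the boundary.
    """

    coords: np.ndarray  # reference cells x 2
    centers: np.ndarray  # K x 2
    state_ids: np.ndarray  # K ints (1-based state ids of the centers)
    regions: list  # shapely Polygon per state
    boundary: object  # shapely Polygon
    state_names: list[str]
    marker_names: list[str]
    embedding_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = _as_2d(self.coords)
        self.centers = _as_2d(self.centers)
        self.state_ids = np.asarray(self.state_ids, dtype=int)
        if self.centers.shape[0] != self.state_ids.shape[0]:
            raise ValueError("one state id per center required")

    def save(self, directory) -> None:
        from .phenomap import save_map

        save_map(self, directory)

    @staticmethod
    def load(directory) -> "PhenoMap":
        from .phenomap import load_map

        return load_map(directory)


@dataclass
class Projector:
    """Trained 6 -> hidden -> 2 regressor with stored min-max input ranges."""

    marker_order: list[str]
    input_min: np.ndarray  # per-marker training minimum
    input_max: np.ndarray  # per-marker training maximum
    w_hidden: np.ndarray  # 6 x H
    b_hidden: np.ndarray  # H
    w_out: np.ndarray  # H x 2
    b_out: np.ndarray  # 2
    activation: str = "logistic"

    def __post_init__(self) -> None:
        self.input_min = np.asarray(self.input_min, dtype=float)
        self.input_max = np.asarray(self.input_max, dtype=float)
        if np.any(self.input_max <= self.input_min):
            bad = [
                m
                for m, lo, hi in zip(
                    self.marker_order, self.input_min, self.input_max
                )
                if hi <= lo
            ]
            raise ValueError(f"degenerate marker range (min == max): {bad}")
        n_in = len(self.marker_order)
        H = self.w_hidden.shape[1]
        if self.w_hidden.shape != (n_in, H) or self.w_out.shape != (H, 2):
            raise ValueError("inconsistent weight shapes")

    @property
    def hidden_size(self) -> int:
        return self.w_hidden.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "marker_order": self.marker_order,
            "input_min": self.input_min.tolist(),
            "input_max": self.input_max.tolist(),
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
            "activation": self.activation,
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def from_json(path) -> "Projector":
        d = json.loads(Path(path).read_text())
        return Projector(
            marker_order=d["marker_order"],
            input_min=np.array(d["input_min"]),
            input_max=np.array(d["input_max"]),
            w_hidden=np.array(d["w_hidden"]),
            b_hidden=np.array(d["b_hidden"]),
            w_out=np.array(d["w_out"]),
            b_out=np.array(d["b_out"]),
            activation=d["activation"],
        )


@dataclass
class ProjectionResult:
    """Per-cell map placement and the per-state composition of one sample."""

    coords: np.ndarray
    state_ids: np.ndarray
    state_fractions: np.ndarray
    out_of_map: np.ndarray
    state_names: list[str]

    def __post_init__(self) -> None:
        total = float(np.sum(self.state_fractions))
        if abs(total - 1.0) > SIMPLEX_ATOL * max(1, len(self.state_fractions)):
            raise ValueError("state fractions must sum to 1")

    def composition(self) -> dict[str, float]:
        return {
            name: float(f)
            for name, f in zip(self.state_names, self.state_fractions)
        }
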