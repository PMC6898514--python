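"""Synthetic mass-cytometry-like time courses with known Markov dynamics.

The generator emulates the structure of a TGFβ addition/withdrawal EMT–MET
experiment: K latent cell states with state-conditional Gaussian marker
expression on the arcsinh scale, cross-sectional samples of ~10,000 cells at
each of seven time points (four during EMT induction, three during
withdrawal/MET), and phase-specific sparse row-stochastic transition
matrices. One state ("MET") is reachable only during the withdrawal phase,
encoding hysteresis. Because every quantity is known exactly, the simulator
provides ground truth for the transition-inference and map-projection
stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import (
    DEFAULT_MARKERS,
    CellMatrix,
    StateFractionSeries,
    TransitionMatrix,
)

PHASES = ("EMT", "MET")


@dataclass
class StateProfile:
    """State-conditional marker distribution: a Gaussian on the arcsinh scale."""

    state_id: int
    mean: np.ndarray  # 6 marker means
    covariance: np.ndarray  # 6 x 6 symmetric PSD

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("state mean must be finite")
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape must match mean length")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigs = np.linalg.eigvalsh(self.covariance)
        if eigs.min() < -1e-10:
            raise ValueError("covariance must be positive semidefinite")


def _check_row_stochastic(P: np.ndarray, name: str) -> None:
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError(f"{name} is not row-stochastic")


@dataclass
class SimulationScenario:
    """Full specification of a two-phase simulated time course."""

    states: list[StateProfile]
    initial_distribution: np.ndarray
    transitions_emt: np.ndarray  # K x K row-stochastic
    transitions_met: np.ndarray
    times_emt: np.ndarray  # measured days during induction (incl. day 0)
    times_met: np.ndarray  # measured withdrawal days (t0 = end of EMT)
    cells_per_timepoint: int = 10_000
    seed: int = 0
    state_names: list[str] = field(default_factory=list)
    marker_names: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))

    def __post_init__(self) -> None:
        K = len(self.states)
        if K < 2:
            raise ValueError("need at least 2 states")
        self.initial_distribution = np.asarray(self.initial_distribution, float)
        if abs(self.initial_distribution.sum() - 1.0) > 1e-12 or np.any(
            self.initial_distribution < 0
        ):
            raise ValueError("initial_distribution must be a probability vector")
        self.transitions_emt = np.asarray(self.transitions_emt, float)
        self.transitions_met = np.asarray(self.transitions_met, float)
        for name, P in (
            ("transitions_emt", self.transitions_emt),
            ("transitions_met", self.transitions_met),
        ):
            if P.shape != (K, K):
                raise ValueError(f"{name} must be {K}x{K}")
            _check_row_stochastic(P, name)
        self.times_emt = np.asarray(self.times_emt, float)
        self.times_met = np.asarray(self.times_met, float)
        for name, t in (("times_emt", self.times_emt), ("times_met", self.times_met)):
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.cells_per_timepoint <= 0:
            raise ValueError("cells_per_timepoint must be positive")
        if not self.state_names:
            self.state_names = [f"S{k + 1}" for k in range(K)]

    @property
    def K(self) -> int:
        return len(self.states)

    def transition_matrix(self, phase: str) -> np.ndarray:
        if phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
        return self.transitions_emt if phase == "EMT" else self.transitions_met

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "states": [
                {
                    "state_id": s.state_id,
                    "mean": s.mean.tolist(),
                    "covariance": s.covariance.tolist(),
                }
                for s in self.states
            ],
            "initial_distribution": self.initial_distribution.tolist(),
            "transitions_emt": self.transitions_emt.tolist(),
            "transitions_met": self.transitions_met.tolist(),
            "times_emt": self.times_emt.tolist(),
            "times_met": self.times_met.tolist(),
            "cells_per_timepoint": self.cells_per_timepoint,
            "seed": self.seed,
            "state_names": self.state_names,
            "marker_names": self.marker_names,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def from_json(path) -> "SimulationScenario":
        d = json.loads(Path(path).read_text())
        return SimulationScenario(
            states=[
                StateProfile(s["state_id"], np.array(s["mean"]), np.array(s["covariance"]))
                for s in d["states"]
            ],
            initial_distribution=np.array(d["initial_distribution"]),
            transitions_emt=np.array(d["transitions_emt"]),
            transitions_met=np.array(d["transitions_met"]),
            times_emt=np.array(d["times_emt"]),
            times_met=np.array(d["times_met"]),
            cells_per_timepoint=d["cells_per_timepoint"],
            seed=d["seed"],
            state_names=d["state_names"],
            marker_names=d["marker_names"],
        )


def propagate_fractions(pi0: np.ndarray, P: np.ndarray, n_steps: int) -> np.ndarray:
    """Exact occupancy fractions pi0 @ P^t for t = 0..n_steps (closed form)."""
    out = np.empty((n_steps + 1, pi0.size))
    out[0] = pi0
    for t in range(n_steps):
        out[t + 1] = out[t] @ P
    return out


def _phase_start(scenario: SimulationScenario, phase: str) -> tuple[np.ndarray, np.ndarray]:
    """Initial distribution and measurement times for one phase.

    The MET phase starts from the exact end-of-EMT distribution (the day-10
    TGFβ sample serves as its t0, at withdrawal day 0).
    """
    if phase == "EMT":
        return scenario.initial_distribution, scenario.times_emt
    n_emt_steps = len(scenario.times_emt) - 1
    pi0 = propagate_fractions(
        scenario.initial_distribution, scenario.transitions_emt, n_emt_steps
    )[-1]
    times = np.concatenate([[0.0], scenario.times_met])
    if np.any(np.diff(times) <= 0):
        raise ValueError("times_met must be positive withdrawal days")
    return pi0, times


def simulate_state_series(
    scenario: SimulationScenario, phase: str
) -> tuple[StateFractionSeries, list[np.ndarray]]:
    """Propagate true fractions and draw per-cell state labels for one phase.

    One Markov step is taken per observed interval (the model's discrete
    clock is the measurement schedule, not calendar days). Returns the
    exact (noise-free) fraction series together with multinomially sampled
    per-cell labels (state ids 1..K) for each time point; counts in the
    series are the sampled counts.
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    P = scenario.transition_matrix(phase)
    pi0, times = _phase_start(scenario, phase)
    true_fr = propagate_fractions(pi0, P, len(times) - 1)

    rng = np.random.default_rng([scenario.seed, PHASES.index(phase)])
    n = scenario.cells_per_timepoint
    counts = np.empty_like(true_fr, dtype=int)
    labels = []
    for t in range(len(times)):
        counts[t] = rng.multinomial(n, true_fr[t])
        labels.append(np.repeat(np.arange(1, scenario.K + 1), counts[t]))
    series = StateFractionSeries(
        phase=phase,
        times=times,
        fractions=true_fr,
        counts=counts,
        state_names=list(scenario.state_names),
    )
    return series, labels


def simulate_marker_expression(
    labels: np.ndarray, states: list[StateProfile], seed: int
) -> CellMatrix:
    """Draw each cell's 6-marker vector from its state's Gaussian profile."""
    labels = np.asarray(labels, dtype=int)
    by_id = {s.state_id: s for s in states}
    missing = sorted(set(labels.tolist()) - set(by_id))
    if missing:
        raise KeyError(f"no StateProfile for state id(s) {missing}")
    n_markers = states[0].mean.size
    out = np.empty((labels.size, n_markers))
    rng = np.random.default_rng(seed)
    # per-state block draws keep this O(K) calls instead of O(cells)
    for sid in sorted(by_id):
        mask = labels == sid
        if not mask.any():
            continue
        prof = by_id[sid]
        # cholesky of a PSD matrix via eigen-decomposition (handles zeros)
        w, V = np.linalg.eigh(prof.covariance)
        A = V * np.sqrt(np.clip(w, 0, None))
        z = rng.standard_normal((int(mask.sum()), n_markers))
        out[mask] = prof.mean + z @ A.T
    return CellMatrix(out, list(DEFAULT_MARKERS[:n_markers]), transformed=True)


# ---------------------------------------------------------------------------
# Default hysteresis scenario


_STATE_NAMES = ["E1", "E2", "E3", "pEMT1", "pEMT2", "pEMT3", "M", "MET"]

# arcsinh-scale marker means per state, columns:
# E-Cadherin, Vimentin, CD44, CD24, MUC1, Twist.
# Epithelial states are E-Cadherin/CD24/MUC1-high; partial-EMT states
# co-express epithelial and mesenchymal markers; M is Vimentin/CD44/Twist-
# high; the MET state is a distinct hybrid (epithelial-leaning with
# residual Vimentin) rather than a revisited E state.
_STATE_MEANS = np.array(
    [
        [5.0, 0.5, 0.8, 4.5, 4.0, 0.5],  # E1
        [4.5, 0.8, 1.2, 4.0, 3.0, 0.8],  # E2
        [4.0, 1.2, 1.5, 3.5, 2.5, 1.2],  # E3
        [3.5, 2.5, 2.5, 2.5, 2.0, 2.0],  # pEMT1
        [2.5, 3.5, 3.0, 2.0, 1.5, 2.8],  # pEMT2
        [1.5, 4.0, 3.8, 1.5, 1.0, 3.2],  # pEMT3
        [0.5, 5.0, 4.5, 0.8, 0.5, 4.0],  # M
        [3.0, 2.0, 1.5, 3.8, 3.5, 1.0],  # MET
    ]
)

_MARKER_SD = 0.4  # within-state spread on the arcsinh scale

# Induction-phase transitions. Two epithelial pools drain at well-separated
# rates: the most plastic pool E1 converts into pEMT1/pEMT2, E3 converts
# into pEMT3; E2 and the partial/mesenchymal pools persist on this time
# scale. The MET state has no inbound mass at all during induction.
#
# The drain->sink (bipartite) flux structure with distinct decay constants
# is deliberate: aggregate fractions only constrain net occupancy flow, so
# balanced pass-through flux (e.g. a serial chain near quasi-stationarity)
# is invisible to any estimator working from state fractions alone. The
# defaults keep the ground truth inside the regime where transition
# inference from aggregate data is identifiable at all.
_P_EMT = np.array(
    [
        [0.45, 0, 0, 0.35, 0.20, 0, 0, 0],
        [0, 1.00, 0, 0, 0, 0, 0, 0],
        [0, 0, 0.75, 0, 0, 0.25, 0, 0],
        [0, 0, 0, 1.00, 0, 0, 0, 0],
        [0, 0, 0, 0, 1.00, 0, 0, 0],
        [0, 0, 0, 0, 0, 1.00, 0, 0],
        [0, 0, 0, 0, 0, 0, 1.00, 0],
        [0, 0, 0, 0, 0, 0, 0, 1.00],
    ]
)

# Withdrawal-phase transitions: pEMT3 relaxes back to E3 (the reverse of
# the induction edge E3 -> pEMT3), while the mesenchymal pool M exits
# through the distinct MET state — the hysteresis edge, absent under
# induction. pEMT1/pEMT2 persist after withdrawal.
_P_MET = np.array(
    [
        [1.00, 0, 0, 0, 0, 0, 0, 0],
        [0, 1.00, 0, 0, 0, 0, 0, 0],
        [0, 0, 1.00, 0, 0, 0, 0, 0],
        [0, 0, 0, 1.00, 0, 0, 0, 0],
        [0, 0, 0, 0, 1.00, 0, 0, 0],
        [0, 0, 0.40, 0, 0, 0.60, 0, 0],
        [0, 0, 0, 0, 0, 0, 0.38, 0.62],
        [0, 0, 0, 0, 0, 0, 0, 1.00],
    ]
)

# Baseline (day 0) state mix: mostly epithelial with pre-existing partial
# and mesenchymal pools, no MET-state cells.
_INITIAL = np.array([0.22, 0.20, 0.18, 0.10, 0.08, 0.08, 0.14, 0.0])

M_STATE = 7  # 1-based id 7 ("M") is index 6
MET_STATE = 8  # 1-based id 8 ("MET") is index 7


def make_hysteresis_scenario(seed: int = 0) -> SimulationScenario:
    """Default 8-state scenario with an MET-phase-only state transition.

    Measurement schedule mirrors the canonical design: TGFβ days 0/2/6/10
    during induction, withdrawal days 2/6/10 afterwards (the day-10
    induction sample is the withdrawal t0), 10,000 cells per time point.
    """
    states = [
        StateProfile(k + 1, _STATE_MEANS[k], np.eye(6) * _MARKER_SD**2)
        for k in range(8)
    ]
    return SimulationScenario(
        states=states,
        initial_distribution=_INITIAL.copy(),
        transitions_emt=_P_EMT.copy(),
        transitions_met=_P_MET.copy(),
        times_emt=np.array([0.0, 2.0, 6.0, 10.0]),
        times_met=np.array([2.0, 6.0, 10.0]),
        cells_per_timepoint=10_000,
        seed=seed,
        state_names=list(_STATE_NAMES),
    )


def simulate_experiment(scenario: SimulationScenario) -> dict:
    """Simulate the full two-phase experiment with a shared anchor sample.

    The end-of-induction sample appears as the last EMT time point and the
    first MET time point (same physical sample, so identical labels). Marker
    expression is drawn for every unique sample. Returns a dict with both
    label lists, empirical fraction series, per-phase cell matrices and the
    true transition matrices.
    """
    from .preprocess import fractions_from_labels
    from .datatypes import StateLabeling

    emt_series, emt_labels = simulate_state_series(scenario, "EMT")
    met_series, met_labels = simulate_state_series(scenario, "MET")
    # shared anchor: the withdrawal t0 is physically the last induction sample
    met_labels = [emt_labels[-1]] + met_labels[1:]

    def _empirical(labels, times, phase):
        lab = np.concatenate(labels)
        tim = np.concatenate(
            [np.full(len(l), t) for l, t in zip(labels, times)]
        )
        labeling = StateLabeling(lab, list(scenario.state_names), scenario.K)
        return fractions_from_labels(labeling, tim, phase)

    emt_emp = _empirical(emt_labels, emt_series.times, "EMT")
    met_emp = _empirical(met_labels, met_series.times, "MET")

    cells = {}
    for phase, labels, times in (
        ("EMT", emt_labels, emt_series.times),
        ("MET", met_labels, met_series.times),
    ):
        all_labels = np.concatenate(labels)
        expr = simulate_marker_expression(
            all_labels, scenario.states, seed=scenario.seed * 4 + 2 + PHASES.index(phase)
        )
        expr.time_label = np.concatenate(
            [np.full(len(l), t) for l, t in zip(labels, times)]
        )
        expr.phase = np.full(all_labels.size, phase)
        cells[phase] = (expr, all_labels)

    return {
        "scenario": scenario,
        "emt_true": emt_series,
        "met_true": met_series,
        "emt_series": emt_emp,
        "met_series": met_emp,
        "cells": cells,
        "true_matrices": {
            "EMT": TransitionMatrix(
                scenario.transitions_emt, "EMT", list(scenario.state_names)
            ),
            "MET": TransitionMatrix(
                scenario.transitions_met, "MET", list(scenario.state_names)
            ),
        },
    }
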