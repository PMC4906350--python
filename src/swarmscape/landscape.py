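"""Transition-probability estimation and free-energy landscape.

From a discrete state sequence: residential probabilities ``P_i`` (occupancy),
a row-stochastic lag transition matrix ``P_ij``, and the jointly normalised
matrix ``Q_ij`` (all transition counts divided by their grand total, so the
whole matrix sums to one).  State energies follow ``F_i = -ln P_i`` and
barriers invert the escape rate Eyring-style; the default energy unit is
k_B*T (dimensionless) so no physical temperature has to be assumed, with a
joules mode using CODATA constants for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Boltzmann as K_B
from scipy.constants import Planck as PLANCK_H

__all__ = [
    "TransitionModel",
    "EnergyLandscape",
    "estimate_transition_model",
    "state_free_energy",
    "barrier_free_energy",
    "energy_landscape",
    "stability_flags",
]


@dataclass
class TransitionModel:
    """Estimated Markov model over K states (labels 1..K)."""

    K: int
    P_i: np.ndarray  # residential (occupancy) probabilities, sums to 1
    P: np.ndarray  # K x K row-stochastic transition matrix
    Q: np.ndarray  # K x K jointly normalised matrix, sums to 1
    counts: np.ndarray  # raw transition counts
    lag: int
    absorbing_fixups: np.ndarray  # states whose empty count row was replaced by identity

    def __post_init__(self) -> None:
        assert abs(self.P_i.sum() - 1.0) < 1e-9
        assert np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9)
        assert abs(self.Q.sum() - 1.0) < 1e-9


@dataclass
class EnergyLandscape:
    """Per-state energies and inter-state barriers.

    ``units`` is ``"kbt"`` (dimensionless multiples of k_B*T) or
    ``"joules"``; ``temperature`` and ``lag_time`` only matter in joules
    mode.  Infinite entries mark zero-probability states/transitions.
    """

    F_i: np.ndarray
    F_ij: np.ndarray
    units: str
    temperature: float | None = None
    lag_time: float | None = None


def estimate_transition_model(labels: np.ndarray, lag: int = 1) -> TransitionModel:
    """Count lag-``lag`` ordered label pairs and normalise.

    ``P_i`` is occupancy over the whole sequence; ``P`` row-normalises the
    counts; ``Q`` divides by the grand total.  A state with no outgoing
    transitions (possible only at the sequence end) gets an identity row in
    ``P`` and is flagged in ``absorbing_fixups``.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1 or len(labels) < lag + 1:
        raise ValueError("label sequence must be 1-D with length >= lag + 1")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    K = int(labels.max())
    if labels.min() < 1:
        raise ValueError("labels must be 1-based")

    src = labels[:-lag] - 1
    dst = labels[lag:] - 1
    counts = np.zeros((K, K))
    np.add.at(counts, (src, dst), 1.0)

    row_sums = counts.sum(axis=1)
    P = np.empty_like(counts)
    fixups = row_sums == 0
    for i in range(K):
        if fixups[i]:
            P[i] = np.eye(K)[i]
        else:
            P[i] = counts[i] / row_sums[i]

    total = counts.sum()
    Q = counts / total

    occupancy = np.bincount(labels - 1, minlength=K).astype(float)
    P_i = occupancy / occupancy.sum()

    return TransitionModel(
        K=K, P_i=P_i, P=P, Q=Q, counts=counts, lag=lag, absorbing_fixups=np.flatnonzero(fixups)
    )


def state_free_energy(
    P_i: np.ndarray | float, mode: str = "kbt", T: float = 300.0
) -> np.ndarray | float:
    """State energy from occupancy: ``-ln P_i`` in k_B*T units, or
    ``-k_B T ln P_i`` in joules.  Zero probability maps to +inf."""
    p = np.asarray(P_i, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        f = -np.log(p)
    if mode == "kbt":
        out = f
    elif mode == "joules":
        out = K_B * T * f
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if np.isscalar(P_i) else out


def barrier_free_energy(
    P_ij: np.ndarray | float,
    mode: str = "kbt",
    T: float = 300.0,
    lag_time: float = 1.0,
) -> np.ndarray | float:
    """Barrier from a transition probability via the escape rate
    ``k_ij = P_ij / lag_time``.

    kbt mode: ``-ln P_ij`` (dimensionless, independent of h and lag_time).
    joules mode: Eyring inversion ``-k_B T ln(h k_ij / (k_B T))``.
    Zero probability maps to +inf.
    """
    p = np.asarray(P_ij, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if mode == "kbt":
        with np.errstate(divide="ignore"):
            out = -np.log(p)
    elif mode == "joules":
        if lag_time <= 0:
            raise ValueError("lag_time must be positive in joules mode")
        with np.errstate(divide="ignore"):
            rate = p / lag_time
            out = -K_B * T * np.log(PLANCK_H * rate / (K_B * T))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if np.isscalar(P_ij) else out


def energy_landscape(
    model: TransitionModel,
    mode: str = "kbt",
    T: float = 300.0,
    lag_time: float = 1.0,
) -> EnergyLandscape:
    """Full landscape for an estimated model: state energies from occupancy,
    barriers from the lag transition probabilities (diagonal retained)."""
    F_i = state_free_energy(model.P_i, mode=mode, T=T)
    F_ij = barrier_free_energy(model.P, mode=mode, T=T, lag_time=lag_time)
    return EnergyLandscape(
        F_i=np.asarray(F_i),
        F_ij=np.asarray(F_ij),
        units=mode,
        temperature=T if mode == "joules" else None,
        lag_time=lag_time if mode == "joules" else None,
    )


def stability_flags(model: TransitionModel, threshold: float = 0.5) -> np.ndarray:
    """Boolean per-state flags: a state is "stable" when its self-transition
    probability is at least ``threshold`` (long expected dwell), else
    "transient"."""
    return np.diag(model.P) >= threshold
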