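"""Information-theoretic measures over a transition model.

Missing information is Shannon entropy in bits: per state, the entropy of
that state's outgoing transition row; globally, the entropy of the jointly
normalised matrix Q.  From the normalised per-state values the module derives
emergence, self-organization, and complexity (``C = 4 E S``) under two
conventions:

``paper-relative`` (default)
    Quantities are referenced to the lowest-uncertainty state r:
    ``E_i = Ihat_r / Ihat_i`` (1 where Ihat_i = 0), ``S_i = 1 - Ihat_i``,
    ``dS_i = Ihat_i - Ihat_r``, ``C_i = 4 E_i S_i``.  Predictable,
    diagonal-dominant states score high on all three.

``gershenson``
    The standard entropy-ratio triple: ``E_i = Ihat_i``,
    ``S_i = 1 - Ihat_i``, ``C_i = 4 E_i S_i``.

Every report records which convention produced it; both are always computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import TransitionModel

__all__ = [
    "CONVENTIONS",
    "ComplexityReport",
    "state_missing_information",
    "global_missing_information",
    "normalized_missing_information",
    "complexity_report",
]

CONVENTIONS = ("paper-relative", "gershenson")


def _entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0 log 0 = 0 convention."""
    p = np.asarray(p, dtype=float).ravel()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def state_missing_information(P_row: np.ndarray) -> float:
    """Entropy (bits) of one state's outgoing transition row."""
    row = np.asarray(P_row, dtype=float)
    if abs(row.sum() - 1.0) > 1e-9:
        raise ValueError("transition row must sum to 1")
    if np.any(row < 0):
        raise ValueError("probabilities must be non-negative")
    return _entropy_bits(row)


def global_missing_information(Q: np.ndarray) -> float:
    """Entropy (bits) of the jointly normalised transition matrix."""
    Q = np.asarray(Q, dtype=float)
    if abs(Q.sum() - 1.0) > 1e-9:
        raise ValueError("Q must sum to 1 overall")
    if np.any(Q < 0):
        raise ValueError("probabilities must be non-negative")
    return _entropy_bits(Q)


def normalized_missing_information(I_i: np.ndarray, K: int) -> np.ndarray:
    """Per-state entropy normalised to [0, 1] by its maximum log2 K
    (defined as 0 when K == 1)."""
    I_i = np.asarray(I_i, dtype=float)
    if K <= 1:
        return np.zeros_like(I_i)
    return I_i / np.log2(K)


@dataclass
class ComplexityReport:
    """Per-state and global information measures for one transition model.

    Arrays are indexed by state (0-based position for state label i+1).
    ``reference_state`` is the 1-based label of the reference state r.
    """

    convention: str
    K: int
    I_i: np.ndarray  # per-state missing information, bits
    I_hat: np.ndarray  # normalised to [0, 1]
    I_global: float  # bits, entropy of Q
    reference_state: int
    E: np.ndarray
    S: np.ndarray
    dS: np.ndarray  # I_hat - I_hat[r]  (zero vector under "gershenson")
    C: np.ndarray
    C_rel: np.ndarray  # C / C[r]
    degenerate: bool = False  # K == 1


def complexity_report(model: TransitionModel, convention: str = "paper-relative") -> ComplexityReport:
    """Compute the emergence / self-organization / complexity triple.

    The reference state r is the state with minimal normalised missing
    information (ties broken toward the lowest label).
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    K = model.K
    I_i = np.array([state_missing_information(model.P[i]) for i in range(K)])
    I_hat = normalized_missing_information(I_i, K)
    I_global = global_missing_information(model.Q)
    r = int(np.argmin(I_hat))  # argmin returns the first (lowest-label) minimiser

    if K == 1:
        E = np.ones(1)
        S = np.ones(1)
        dS = np.zeros(1)
        C = 4.0 * E * S
        return ComplexityReport(
            convention=convention, K=1, I_i=I_i, I_hat=I_hat, I_global=I_global,
            reference_state=1, E=E, S=S, dS=dS, C=C, C_rel=np.ones(1), degenerate=True,
        )

    if convention == "paper-relative":
        with np.errstate(divide="ignore", invalid="ignore"):
            E = np.where(I_hat > 0, I_hat[r] / np.where(I_hat > 0, I_hat, 1.0), 1.0)
        S = 1.0 - I_hat
        dS = I_hat - I_hat[r]
    else:  # gershenson
        E = I_hat.copy()
        S = 1.0 - I_hat
        dS = np.zeros(K)
    C = 4.0 * E * S
    C_r = C[r]
    with np.errstate(divide="ignore", invalid="ignore"):
        C_rel = C / C_r if C_r != 0 else np.full(K, np.nan)

    return ComplexityReport(
        convention=convention, K=K, I_i=I_i, I_hat=I_hat, I_global=I_global,
        reference_state=r + 1, E=E, S=S, dS=dS, C=C, C_rel=C_rel,
    )
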