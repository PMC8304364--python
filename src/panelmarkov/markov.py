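"""Three-state continuous-time Markov chain core.

State space, generator (intensity) matrix algebra, and the closed-form
derived quantities: interval transition probabilities ``P(t) = expm(Qt)``,
embedded jump-chain probabilities, mean sojourn times and the stationary
distribution. All rates are per week.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "N_STATES",
    "TRANSITIONS",
    "StateSpace",
    "IntensityMatrix",
    "TransitionTable",
    "SojournTimes",
    "transition_probability_matrix",
    "jump_chain_probabilities",
    "mean_sojourn_times",
    "stationary_distribution",
    "reconstruct_intensity",
    "expm_stack",
]

N_STATES = 3

#: The six off-diagonal transitions, in reporting order.
TRANSITIONS = ((0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1))

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class StateSpace:
    """Ordered labels for the three severity states.

    Indices are 0-based internally; user-facing reports print 1-based
    indices alongside the labels.
    """

    labels: tuple[str, str, str] = ("normal", "mild", "severe")

    def __post_init__(self) -> None:
        if len(self.labels) != N_STATES:
            raise ValueError(f"exactly {N_STATES} state labels required, got {len(self.labels)}")
        if len(set(self.labels)) != N_STATES:
            raise ValueError("state labels must be distinct")

    def index(self, label: str) -> int:
        return self.labels.index(label)


DEFAULT_STATES = StateSpace()


@dataclass(frozen=True)
class IntensityMatrix:
    """A 3x3 generator matrix: non-negative off-diagonals, zero row sums.

    Units are events per week throughout the package.
    """

    q: np.ndarray
    states: StateSpace = DEFAULT_STATES

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (N_STATES, N_STATES):
            raise ValueError(f"intensity matrix must be {N_STATES}x{N_STATES}, got {q.shape}")
        off = q[~np.eye(N_STATES, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal intensities must be non-negative")
        if np.any(np.diag(q) > _ROW_SUM_TOL):
            raise ValueError("diagonal intensities must be non-positive")
        if np.any(np.abs(q.sum(axis=1)) > 1e-9 * max(1.0, float(np.abs(q).max()))):
            raise ValueError("generator rows must sum to zero")
        object.__setattr__(self, "q", q)

    @classmethod
    def from_rates(cls, rates, states: StateSpace = DEFAULT_STATES) -> "IntensityMatrix":
        """Build from the six off-diagonal rates in :data:`TRANSITIONS` order."""
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (len(TRANSITIONS),):
            raise ValueError(f"expected {len(TRANSITIONS)} rates, got {rates.shape}")
        q = np.zeros((N_STATES, N_STATES))
        for rate, (i, j) in zip(rates, TRANSITIONS):
            q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        return cls(q, states)

    @property
    def rates(self) -> np.ndarray:
        """The six off-diagonal rates in :data:`TRANSITIONS` order."""
        return np.array([self.q[i, j] for i, j in TRANSITIONS])

    def __array__(self, dtype=None, copy=None):
        return np.array(self.q, dtype=dtype)


@dataclass(frozen=True)
class TransitionTable:
    """3x3 table of counts or probabilities indexed from-state x to-state."""

    values: np.ndarray
    kind: str = "probabilities"
    jump: bool = False
    states: StateSpace = DEFAULT_STATES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_STATES, N_STATES):
            raise ValueError(f"transition table must be {N_STATES}x{N_STATES}")
        if self.kind not in ("counts", "probabilities"):
            raise ValueError(f"kind must be 'counts' or 'probabilities', got {self.kind!r}")
        if np.any(values < -1e-12):
            raise ValueError("transition table entries must be non-negative")
        if self.kind == "counts":
            if not np.allclose(values, np.round(values)):
                raise ValueError("count tables must hold integers")
            if self.jump:
                raise ValueError("jump tables hold probabilities, not counts")
            values = np.round(values)
        else:
            row_sums = values.sum(axis=1)
            if np.any(np.abs(row_sums - 1.0) > 1e-6):
                raise ValueError(f"probability rows must sum to 1, got {row_sums}")
            if self.jump and np.any(np.abs(np.diag(values)) > 1e-12):
                raise ValueError("jump-chain tables have an empty diagonal")
        object.__setattr__(self, "values", values)

    def __array__(self, dtype=None, copy=None):
        return np.array(self.values, dtype=dtype)

    def total(self) -> float:
        return float(self.values.sum())

    def to_text(self, title: str | None = None, percent_of_total: bool = False) -> str:
        """Aligned-text rendering with 1-based state labels."""
        lines = []
        if title:
            lines.append(title)
        labels = self.states.labels
        header = "from \\ to".ljust(14) + "".join(f"{lab:>16}" for lab in labels)
        lines.append(header)
        total = self.total() if self.kind == "counts" else None
        for i, lab in enumerate(labels):
            cells = []
            for j in range(N_STATES):
                v = self.values[i, j]
                if self.kind == "counts":
                    cell = f"{int(v)}"
                    if percent_of_total and total:
                        cell += f" ({100.0 * v / total:.1f}%)"
                elif self.jump and i == j:
                    cell = "-"
                else:
                    cell = f"{v:.3f}"
                cells.append(f"{cell:>16}")
            lines.append(f"{i + 1} {lab}".ljust(14) + "".join(cells))
        return "\n".join(lines)


@dataclass(frozen=True)
class SojournTimes:
    """Mean dwell time per state before any transition, in weeks."""

    weeks: np.ndarray
    states: StateSpace = DEFAULT_STATES

    def __post_init__(self) -> None:
        weeks = np.asarray(self.weeks, dtype=float)
        if weeks.shape != (N_STATES,):
            raise ValueError(f"expected {N_STATES} sojourn times")
        if np.any(weeks <= 0) or not np.all(np.isfinite(weeks)):
            raise ValueError("sojourn times must be positive and finite")
        object.__setattr__(self, "weeks", weeks)

    def __array__(self, dtype=None, copy=None):
        return np.array(self.weeks, dtype=dtype)


_TAYLOR_THETA = 0.5
_TAYLOR_TERMS = 13  # remainder < 0.5^14 / 14! ~ 7e-16 at theta = 0.5


def expm_stack(mats: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of small square matrices.

    Batched scaling-and-squaring with a Horner-evaluated truncated Taylor
    series: every operation is a polynomial in the input, so the routine is
    analytic and safe for complex-step differentiation (unlike
    eigendecomposition-based exponentials, whose LAPACK internals conjugate).
    """
    mats = np.asarray(mats)
    n = mats.shape[-1]
    if mats.ndim < 2 or mats.shape[-2] != n:
        raise ValueError("expected a stack of square matrices")
    norm = np.abs(mats).sum(axis=-1).max(axis=-1)  # infinity norm per slice
    max_norm = float(np.max(norm)) if norm.size else 0.0
    if not np.isfinite(max_norm):
        raise ValueError("matrix stack contains non-finite entries")
    s = 0
    if max_norm > _TAYLOR_THETA:
        s = min(int(np.ceil(np.log2(max_norm / _TAYLOR_THETA))), 1024)
    a = mats / (2.0**s)
    eye = np.broadcast_to(np.eye(n, dtype=a.dtype), a.shape)
    out = eye + a / _TAYLOR_TERMS
    for k in range(_TAYLOR_TERMS - 1, 0, -1):
        out = eye + (a @ out) / k
    for _ in range(s):
        out = out @ out
    return out


def transition_probability_matrix(q: IntensityMatrix, t: float) -> TransitionTable:
    """Interval transition probabilities ``P(t) = expm(Q t)``.

    ``t`` is in weeks; the result is row-stochastic and satisfies the
    Chapman-Kolmogorov semigroup property.
    """
    if t < 0:
        raise ValueError(f"elapsed time must be non-negative, got {t}")
    p = scipy.linalg.expm(q.q * float(t))
    p = np.clip(p, 0.0, 1.0)
    p /= p.sum(axis=1, keepdims=True)
    return TransitionTable(p, kind="probabilities", states=q.states)


def jump_chain_probabilities(q: IntensityMatrix) -> TransitionTable:
    """Embedded jump-chain probabilities ``q_ij / (-q_ii)``.

    Entry (i, j) is the probability that the next transition out of state i
    lands in state j, conditional on a transition occurring.
    """
    diag = np.diag(q.q)
    zero = np.flatnonzero(diag >= -1e-300)
    if zero.size:
        names = ", ".join(q.states.labels[i] for i in zero)
        raise ValueError(f"state(s) with zero exit rate have no jump distribution: {names}")
    probs = q.q / (-diag)[:, None]
    np.fill_diagonal(probs, 0.0)
    return TransitionTable(probs, kind="probabilities", jump=True, states=q.states)


def mean_sojourn_times(q: IntensityMatrix) -> SojournTimes:
    """Mean sojourn time per state, ``-1 / q_ii``, in weeks."""
    diag = np.diag(q.q)
    zero = np.flatnonzero(diag >= -1e-300)
    if zero.size:
        names = ", ".join(q.states.labels[i] for i in zero)
        raise ValueError(f"state(s) with zero exit rate have infinite sojourn: {names}")
    return SojournTimes(-1.0 / diag, states=q.states)


def stationary_distribution(q: IntensityMatrix) -> np.ndarray:
    """Long-run occupancy probabilities solving ``pi Q = 0``, ``sum pi = 1``."""
    ns = scipy.linalg.null_space(q.q.T)
    if ns.shape[1] != 1:
        raise ValueError("generator is reducible; stationary distribution is not unique")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi <= 0):
        raise ValueError("generator is reducible; stationary distribution has zero mass")
    return pi


def reconstruct_intensity(jump: TransitionTable, sojourn: SojournTimes) -> IntensityMatrix:
    """Invert (jump probabilities, sojourn times) back into a generator.

    ``q_ii = -1/sojourn_i`` and ``q_ij = jump_ij * (-q_ii)``; exact inverse of
    (:func:`jump_chain_probabilities`, :func:`mean_sojourn_times`).
    """
    if not jump.jump:
        raise ValueError("expected a jump-chain table (empty diagonal)")
    if jump.states.labels != sojourn.states.labels:
        raise ValueError("jump table and sojourn times use different state spaces")
    exit_rates = 1.0 / sojourn.weeks
    q = jump.values * exit_rates[:, None]
    np.fill_diagonal(q, -exit_rates)
    return IntensityMatrix(q, states=jump.states)
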