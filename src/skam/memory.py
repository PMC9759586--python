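"""Recurrent binary attractor network: learning rules and dynamics.

Binarized structure vectors are stored as fixed points of a Hopfield-type
network of N +-1 units evolving under sigma_i(t) = sign(sum_j J_ij
sigma_j(t-1)).  Three prescriptions for the couplings are provided:

* pseudo-inverse: J = sigma^T C^-1 sigma / N with C the pattern overlap
  matrix; every stored pattern is an exact fixed point for load alpha = P/N
  below one.
* Hebb: plain outer-product sum, J = sigma^T sigma / N.
* Storkey: the order-sensitive sequential recursion with a local-field
  correction term.

All rules force J_ii = 0.  Updates run in parallel (all units at once) or
serially (one unit at a time in a fresh seeded random permutation per
sweep), with the sign(0) = +1 convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vsa import hard_sign

__all__ = [
    "Trajectory",
    "WeightMatrix",
    "overlap",
    "train_hebb",
    "train_pseudoinverse",
    "train_storkey",
    "update",
    "update_batch",
]

#: condition-number guard for the pseudo-inverse overlap matrix
MAX_CONDITION = 1e12

#: default number of update steps used in retrieval
DEFAULT_T = 20


@dataclass
class WeightMatrix:
    J: np.ndarray
    rule: str
    n_patterns: int

    @property
    def n_units(self) -> int:
        return self.J.shape[0]


@dataclass
class Trajectory:
    """States visited by the dynamics, including the initial state."""

    states: np.ndarray  # (steps+1, N)
    converged: bool
    steps_to_fixed_point: int | None

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


def _as_patterns(patterns) -> np.ndarray:
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim == 1:
        patterns = patterns[None, :]
    if patterns.ndim != 2:
        raise ValueError("patterns must form a (P, N) matrix")
    if not np.all(np.abs(patterns) == 1.0):
        raise ValueError("patterns must be +-1")
    return patterns


def train_pseudoinverse(patterns) -> WeightMatrix:
    """Pseudo-inverse couplings; stored patterns are exact fixed points.

    Requires P < N.  The overlap-matrix inverse is applied through a linear
    solve; a near-singular overlap matrix (e.g. duplicated patterns) raises.
    """
    patterns = _as_patterns(patterns)
    P, N = patterns.shape
    if P >= N:
        raise ValueError(f"pseudo-inverse rule requires P < N (got P={P}, N={N})")
    C = patterns @ patterns.T / N
    if np.linalg.cond(C) > MAX_CONDITION:
        raise np.linalg.LinAlgError(
            "pattern overlap matrix is numerically singular (degenerate patterns?)"
        )
    J = patterns.T @ np.linalg.solve(C, patterns) / N
    np.fill_diagonal(J, 0.0)
    return WeightMatrix(J=J, rule="pseudoinverse", n_patterns=P)


def train_hebb(patterns) -> WeightMatrix:
    """Hebbian outer-product couplings."""
    patterns = _as_patterns(patterns)
    P, N = patterns.shape
    J = patterns.T @ patterns / N
    np.fill_diagonal(J, 0.0)
    return WeightMatrix(J=J, rule="hebb", n_patterns=P)


def train_storkey(patterns) -> WeightMatrix:
    """Storkey sequential rule.

    Patterns are presented in row order starting from J = 0; each step
    applies the recursion

        J^mu = (N+1)/(N-1) J^{mu-1}
               + (sigma sigma^T - I)/(N-1)
               - (sigma h^T + h sigma^T)/(N-1),   h = J^{mu-1} sigma,

    with the diagonal forced to zero after every step (so h is computed
    with the zero-diagonal couplings of the previous step).  The result
    depends on presentation order.
    """
    patterns = _as_patterns(patterns)
    P, N = patterns.shape
    if N < 2:
        raise ValueError("Storkey rule needs N >= 2")
    J = np.zeros((N, N))
    for mu in range(P):
        sigma = patterns[mu]
        h = J @ sigma
        J = (
            (N + 1) / (N - 1) * J
            + (np.outer(sigma, sigma) - np.eye(N)) / (N - 1)
            - (np.outer(sigma, h) + np.outer(h, sigma)) / (N - 1)
        )
        np.fill_diagonal(J, 0.0)
    return WeightMatrix(J=J, rule="storkey", n_patterns=P)


def _as_J(weights) -> np.ndarray:
    J = weights.J if isinstance(weights, WeightMatrix) else np.asarray(weights, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("couplings must be a square matrix")
    return J


def update(
    weights,
    sigma0: np.ndarray,
    mode: str = "parallel",
    T: int = DEFAULT_T,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Run the network dynamics from an initial +-1 state.

    Parallel mode applies one synchronous update per step; serial mode
    performs N single-unit updates per step in a seeded random permutation
    (a fresh permutation each sweep).  Stops early at a fixed point: a
    repeated state in parallel mode, a flip-free sweep in serial mode.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    J = _as_J(weights)
    state = hard_sign(np.asarray(sigma0, dtype=float))
    if state.shape[0] != J.shape[0]:
        raise ValueError("initial state length does not match couplings")
    states = [state.copy()]
    converged = False
    steps = None

    if mode == "parallel":
        for t in range(1, T + 1):
            new = hard_sign(J @ state)
            states.append(new.copy())
            if np.array_equal(new, state):
                converged = True
                steps = t - 1
                break
            state = new
    elif mode == "serial":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        for t in range(1, T + 1):
            flipped = False
            for i in rng.permutation(J.shape[0]):
                new_i = 1.0 if J[i] @ state >= 0 else -1.0
                if new_i != state[i]:
                    state[i] = new_i
                    flipped = True
            states.append(state.copy())
            if not flipped:
                converged = True
                steps = t - 1
                break
    else:
        raise ValueError(f"unknown update mode {mode!r}")
    return Trajectory(states=np.array(states), converged=converged, steps_to_fixed_point=steps)


def update_batch(weights, states: np.ndarray, T: int = DEFAULT_T) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parallel dynamics applied to a batch of initial states (rows).

    Returns ``(final_states, steps, converged)`` where ``steps`` counts the
    updates applied to each row before it stopped changing (T if it never
    froze).  Equivalent row-by-row to :func:`update` in parallel mode.
    """
    J = _as_J(weights)
    S = hard_sign(np.asarray(states, dtype=float))
    if S.ndim != 2 or S.shape[1] != J.shape[0]:
        raise ValueError("states must be (n, N) matching the couplings")
    n = S.shape[0]
    steps = np.full(n, T, dtype=int)
    active = np.ones(n, dtype=bool)
    for t in range(1, T + 1):
        new = hard_sign(S[active] @ J.T)
        frozen = np.all(new == S[active], axis=1)
        S[active] = new
        idx = np.flatnonzero(active)
        steps[idx[frozen]] = t - 1
        active[idx[frozen]] = False
        if not active.any():
            break
    return S, steps, ~active


def overlap(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized overlap m = (1/N) sum_i x_i y_i between two +-1 patterns."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pattern length mismatch")
    return float(np.mean(x * y))
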