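"""Experiment pipelines: storage/retrieval of structures, basin-of-attraction
diagnostics, the outside-basin SNR theory, sequence retrieval, and the
classical sequence-attractor baseline.

The central quantities:

* ``m0``    initial overlap of the binarized cue with the stored pattern;
  for a cue of ``L0`` of ``L`` pairs, ``m0 = (2/pi) arctan(sqrt(r/(1-r)))``
  with ``r = L0/L``  (equivalently ``(2/pi) arcsin(sqrt(r))``).
* ``m_min(alpha)``  the basin edge: the smallest m0 from which the dynamics
  still converge to the stored pattern, estimated from a pseudo-inverse
  network storing random patterns via a logistic fit of the perfect-recall
  probability ``p1(m0) ~ 1/(1 + exp(-sqrt(N)(m0 - m_min)))``.
* ``l_c``   the critical cue fraction: the L0/L whose mean cue overlap
  equals m_min, i.e. the inverse of the m0 relation.
* ``f(alpha)``  the out-of-basin amplification: fixed points reached from
  m0 below m_min have overlap ``m* ~ f(alpha) m0``.
* outside the basin the unbinding SNR follows
  ``SNR(m) ~ (2c/pi) m^2 N / L`` and, after substituting ``m* = f m0`` and
  the small-cue form ``m0 ~ (2/pi) sqrt(L0/L)``,
  ``SNR ~ (8 c f^2 / pi^3) N L0 / L^2`` with ``c ~ 0.65``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .cleanup import snr_from_overlaps
from .memory import (
    DEFAULT_T,
    train_hebb,
    train_pseudoinverse,
    train_storkey,
    update,
    update_batch,
)
from .vsa import hard_sign

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "FEstimate",
    "MminEstimate",
    "OverlapStats",
    "RetrievalResult",
    "SequenceResult",
    "SnrFit",
    "SnrTheoryParams",
    "TransitionModelParams",
    "TransitionResult",
    "estimate_f",
    "estimate_mmin",
    "fit_snr_constant",
    "fresh_structure_snr",
    "lc_from_mmin",
    "lc_small_cue",
    "m0_small_cue",
    "m0_theory",
    "overlap_distribution",
    "run_retrieval_experiment",
    "run_sequence_experiment",
    "run_transition_baseline",
    "snr_outside_basin",
    "snr_theory",
]

_RULES = {"pseudoinverse": train_pseudoinverse, "hebb": train_hebb, "storkey": train_storkey}

#: refuse to materialize clean-up dictionaries larger than this many floats
_MAX_DICT_FLOATS = 1 << 26


class ConfigError(ValueError):
    """Invalid experiment configuration; message lists all violations."""


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class ExperimentConfig:
    """Parameters of a structure storage/retrieval experiment.

    ``alpha`` and ``n_patterns`` (P) are redundant; give either.  The
    dictionary size ``dict_size`` defaults to L*N.  ``n_trials`` counts
    independent networks.  ``cleanup_mode`` is ``"full"`` (materialize the
    dictionary and decode by argmax; needed for error rates) or
    ``"snr_only"`` (sample ``distractor_sample`` fresh distractors per
    structure; enough for SNR measurements and far cheaper at large L*N).
    """

    n_units: int
    n_pairs: int
    cue_size: int
    alpha: float | None = None
    n_patterns: int | None = None
    dict_size: int | None = None
    T: int = DEFAULT_T
    rule: str = "pseudoinverse"
    update_mode: str = "parallel"
    n_trials: int = 1
    seed: int = 0
    attribute_sharing: bool = True
    cue_random: bool = False
    cleanup_mode: str = "full"
    distractor_sample: int = 300

    def __post_init__(self) -> None:
        errors = []
        if self.n_units < 2:
            errors.append("n_units must be >= 2")
        if self.n_pairs < 1:
            errors.append("n_pairs must be >= 1")
        if not (1 <= self.cue_size <= self.n_pairs):
            errors.append(f"cue_size must be in [1, n_pairs={self.n_pairs}]")
        if self.alpha is None and self.n_patterns is None:
            errors.append("give alpha or n_patterns")
        if self.n_patterns is None and self.alpha is not None:
            self.n_patterns = int(round(self.alpha * self.n_units))
        if self.n_patterns is not None:
            if self.n_patterns < 1:
                errors.append("n_patterns must be >= 1")
            if self.alpha is None:
                self.alpha = self.n_patterns / self.n_units
        if self.rule not in _RULES:
            errors.append(f"unknown rule {self.rule!r}")
        elif self.rule == "pseudoinverse" and self.n_patterns is not None and self.n_patterns >= self.n_units:
            errors.append("pseudoinverse rule requires P < N (alpha < 1)")
        if self.update_mode not in ("parallel", "serial"):
            errors.append(f"unknown update_mode {self.update_mode!r}")
        if self.cleanup_mode not in ("full", "snr_only"):
            errors.append(f"unknown cleanup_mode {self.cleanup_mode!r}")
        if self.T < 1:
            errors.append("T must be >= 1")
        if self.n_trials < 1:
            errors.append("n_trials must be >= 1")
        if self.distractor_sample < 1:
            errors.append("distractor_sample must be >= 1")
        if self.dict_size is None:
            self.dict_size = self.n_pairs * self.n_units
        if self.dict_size < self.n_pairs:
            errors.append("dict_size must be at least n_pairs")
        if errors:
            raise ConfigError("; ".join(errors))


@dataclass
class OverlapStats:
    """Decomposition of the final-overlap distribution into a delta at
    m = 1 (weight p1, tolerance one flipped bit) and an m < 1 mode."""

    p1: float
    m_star: float
    sigma_m: float
    n_samples: int


def overlap_distribution(m_samples: Sequence[float], n_units: int) -> OverlapStats:
    m = np.asarray(m_samples, dtype=float)
    if m.size < 1:
        raise ValueError("no overlap samples")
    exact = m >= 1.0 - 2.0 / n_units
    rest = m[~exact]
    return OverlapStats(
        p1=float(exact.mean()),
        m_star=float(rest.mean()) if rest.size else float("nan"),
        sigma_m=float(rest.std(ddof=1)) if rest.size > 1 else float("nan"),
        n_samples=int(m.size),
    )


# ---------------------------------------------------------------------------
# closed forms


def m0_theory(cue_size: int, n_pairs: int) -> float:
    """Mean binarized-cue overlap for a cue of L0 of L pairs (large N)."""
    if not (0 < cue_size <= n_pairs):
        raise ValueError("need 0 < L0 <= L")
    if cue_size == n_pairs:
        return 1.0  # continuity limit of the arctan form
    r = cue_size / n_pairs
    return float(2.0 / np.pi * np.arctan(np.sqrt(r / (1.0 - r))))


def m0_small_cue(cue_size: int, n_pairs: int) -> float:
    """Small-cue expansion m0 ~ (2/pi) sqrt(L0/L)."""
    if not (0 < cue_size <= n_pairs):
        raise ValueError("need 0 < L0 <= L")
    return float(2.0 / np.pi * np.sqrt(cue_size / n_pairs))


def lc_from_mmin(m_min: float) -> float:
    """Critical cue fraction: the L0/L at which the mean cue overlap equals
    the basin edge, l_c = sin^2((pi/2) m_min) (exact inverse of m0_theory)."""
    if not (0.0 <= m_min < 1.0):
        raise ValueError("m_min must be in [0, 1)")
    return float(np.sin(np.pi / 2.0 * m_min) ** 2)


def lc_small_cue(m_min: float) -> float:
    """Quadratic small-m_min expansion of :func:`lc_from_mmin`."""
    if not (0.0 <= m_min < 1.0):
        raise ValueError("m_min must be in [0, 1)")
    return float((np.pi / 2.0 * m_min) ** 2)


@dataclass(frozen=True)
class SnrTheoryParams:
    """Constants of the outside-basin SNR prediction."""

    c: float = 0.65
    f_alpha: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.c <= 1.0):
            raise ValueError("c must be in (0, 1]")


def snr_theory(m: float, n_units: int, n_pairs: int, c: float = 0.65) -> float:
    """SNR of unbinding from a state with overlap m: (2c/pi) m^2 N / L."""
    return float(2.0 * c / np.pi * m**2 * n_units / n_pairs)


def snr_outside_basin(n_units: int, n_pairs: int, cue_size: int, f_alpha: float, c: float = 0.65) -> float:
    """Deep outside-basin SNR: (8 c f^2 / pi^3) N L0 / L^2 (for L0 << L).

    Equals :func:`snr_theory` composed with m* = f(alpha) m0 and the
    small-cue m0.
    """
    return float(8.0 * c * f_alpha**2 / np.pi**3 * n_units * cue_size / n_pairs**2)


def fresh_structure_snr(
    n_units: int,
    n_pairs: int,
    n_trials: int = 2000,
    binarized: bool = False,
    distractor_sample: int = 20,
    seed: int | np.random.SeedSequence = 0,
    chunk: int = 128,
) -> float:
    """Empirical unbinding SNR of freshly encoded structures (no storage).

    Each trial encodes one structure of L pairs from fresh Gaussian items,
    optionally binarizes it, unbinds the last pair's object with its
    attribute, and records the overlap with the correct item plus
    ``distractor_sample`` fresh distractor overlaps.  The leading-order
    expectation is N/L (exactly N/(L+1) at finite L, since the queried
    pair's own binding contributes unit self-noise); binarization lowers it
    by a further factor 2/pi.
    """
    N, L = n_units, n_pairs
    scale = 1.0 / np.sqrt(N)
    rng = np.random.default_rng(_as_seedseq(seed))
    correct, distract = [], []
    done = 0
    while done < n_trials:
        c = min(chunk, n_trials - done)
        A = rng.normal(0.0, scale, (c, L, N))
        B = rng.normal(0.0, scale, (c, L, N))
        S = np.fft.irfft((np.fft.rfft(A, axis=2) * np.fft.rfft(B, axis=2)).sum(axis=1), n=N, axis=1)
        if binarized:
            S = hard_sign(S)
        est = np.fft.irfft(
            np.conj(np.fft.rfft(B[:, L - 1, :], axis=1)) * np.fft.rfft(S, axis=1), n=N, axis=1
        )
        correct.append(np.einsum("ij,ij->i", est, A[:, L - 1, :]))
        d = rng.normal(0.0, scale, (c, distractor_sample, N))
        distract.append(np.einsum("ij,ikj->ik", est, d).ravel())
        done += c
    return snr_from_overlaps(np.concatenate(correct), np.concatenate(distract))


# ---------------------------------------------------------------------------
# structure retrieval


@dataclass
class RetrievalResult:
    config: ExperimentConfig
    records: pd.DataFrame
    snr: float
    p_error: float | None
    baseline_snr: float
    baseline_p_error: float | None
    stats: OverlapStats


def _encode_network(rng: np.random.Generator, cfg: ExperimentConfig):
    """Encode P structures and their cues for one network.

    Returns (sigma, sigma0, a_query, b_query_conj_fft, obj_dict or None,
    target_idx or None).  Objects are rows of the clean-up dictionary in
    full mode, or freshly drawn Gaussian items in snr_only mode (identical
    in distribution).  Attributes are shared across structures when
    ``cfg.attribute_sharing`` (the default stated world).
    """
    N, L, L0, P = cfg.n_units, cfg.n_pairs, cfg.cue_size, cfg.n_patterns
    scale = 1.0 / np.sqrt(N)

    obj_dict = None
    target_idx = None
    if cfg.cleanup_mode == "full":
        if cfg.dict_size * N > _MAX_DICT_FLOATS:
            raise ConfigError(
                f"dict_size*N = {cfg.dict_size * N} too large to materialize; "
                "use cleanup_mode='snr_only' or a smaller dict_size"
            )
        obj_dict = rng.normal(0.0, scale, (cfg.dict_size, N))
        target_idx = np.empty(P, dtype=int)

    B = rng.normal(0.0, scale, (L, N)) if cfg.attribute_sharing else None
    FB = np.fft.rfft(B, axis=1) if B is not None else None

    sigma = np.empty((P, N))
    sigma0 = np.empty((P, N))
    a_query = np.empty((P, N))
    fb_query = np.empty((P, N // 2 + 1), dtype=complex)

    for mu in range(P):
        if obj_dict is not None:
            idx = rng.choice(cfg.dict_size, size=L, replace=False)
            A = obj_dict[idx]
        else:
            A = rng.normal(0.0, scale, (L, N))
        Bmu = B if B is not None else rng.normal(0.0, scale, (L, N))
        FBmu = FB if FB is not None else np.fft.rfft(Bmu, axis=1)
        prod = np.fft.rfft(A, axis=1) * FBmu
        if cfg.cue_random:
            cue_pos = rng.choice(L - 1, size=L0, replace=False) if L > 1 else np.array([0])
        else:
            cue_pos = np.arange(L0)
        sigma[mu] = hard_sign(np.fft.irfft(prod.sum(axis=0), n=N))
        sigma0[mu] = hard_sign(np.fft.irfft(prod[cue_pos].sum(axis=0), n=N))
        # decode query: the last pair, guaranteed outside the (prefix or
        # random-from-first-L-1) cue
        a_query[mu] = A[L - 1]
        fb_query[mu] = np.conj(FBmu[L - 1])
        if obj_dict is not None:
            target_idx[mu] = idx[L - 1]
    return sigma, sigma0, a_query, fb_query, obj_dict, target_idx


def _decode_states(states, a_query, fb_query, obj_dict, target_idx, cfg, rng):
    """Unbind the held-out pair's object from each state and clean up.

    Returns (overlap_correct, distractor_mean_sq, correct or None).
    """
    N = cfg.n_units
    est = np.fft.irfft(fb_query * np.fft.rfft(states, axis=1), n=N, axis=1)
    ov_correct = np.einsum("ij,ij->i", est, a_query)
    if obj_dict is not None:
        overlaps = est @ obj_dict.T
        best = np.argmax(overlaps, axis=1)
        correct = best == target_idx
        P, D = overlaps.shape
        mask = np.ones((P, D), dtype=bool)
        mask[np.arange(P), target_idx] = False
        k = min(cfg.distractor_sample, D - 1)
        d_sq = np.empty(P)
        for mu in range(P):
            d = overlaps[mu][mask[mu]]
            if k < d.size:
                d = rng.choice(d, size=k, replace=False)
            d_sq[mu] = np.mean(d**2)
    else:
        correct = None
        d = rng.normal(0.0, 1.0 / np.sqrt(N), (cfg.distractor_sample, N))
        d_sq = np.mean((est @ d.T) ** 2, axis=1)
    return ov_correct, d_sq, correct


def run_retrieval_experiment(cfg: ExperimentConfig) -> RetrievalResult:
    """Store P binarized structures, cue each with L0 pairs, run the
    dynamics, decode the held-out pair, and aggregate error/SNR.

    The pre-storage decode of the binarized structure itself is recorded as
    the baseline (the "original structure" error).  Deterministic for a
    given config and seed.
    """
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    for net, child in enumerate(root.spawn(cfg.n_trials)):
        rng = np.random.default_rng(child)
        sigma, sigma0, a_query, fb_query, obj_dict, target_idx = _encode_network(rng, cfg)
        J = _RULES[cfg.rule](sigma)
        if cfg.update_mode == "parallel":
            retrieved, steps, _ = update_batch(J, sigma0, T=cfg.T)
        else:
            retrieved = np.empty_like(sigma0)
            steps = np.empty(cfg.n_patterns, dtype=int)
            for mu in range(cfg.n_patterns):
                traj = update(J, sigma0[mu], mode="serial", T=cfg.T, rng=rng)
                retrieved[mu] = traj.final
                steps[mu] = traj.steps_to_fixed_point if traj.converged else cfg.T
        m0 = np.mean(sigma0 * sigma, axis=1)
        m = np.mean(retrieved * sigma, axis=1)
        ov, d_sq, correct = _decode_states(retrieved, a_query, fb_query, obj_dict, target_idx, cfg, rng)
        ov_b, d_sq_b, correct_b = _decode_states(sigma, a_query, fb_query, obj_dict, target_idx, cfg, rng)
        for mu in range(cfg.n_patterns):
            rows.append(
                dict(
                    network=net,
                    mu=mu,
                    m0=m0[mu],
                    m=m[mu],
                    steps=steps[mu],
                    overlap_correct=ov[mu],
                    distractor_mean_sq=d_sq[mu],
                    correct=(None if correct is None else bool(correct[mu])),
                    baseline_overlap_correct=ov_b[mu],
                    baseline_distractor_mean_sq=d_sq_b[mu],
                    baseline_correct=(None if correct_b is None else bool(correct_b[mu])),
                )
            )
    records = pd.DataFrame(rows)
    snr = float(records.overlap_correct.mean() ** 2 / records.distractor_mean_sq.mean())
    baseline_snr = float(
        records.baseline_overlap_correct.mean() ** 2 / records.baseline_distractor_mean_sq.mean()
    )
    if cfg.cleanup_mode == "full":
        p_error = float(1.0 - records.correct.mean())
        baseline_p_error = float(1.0 - records.baseline_correct.mean())
    else:
        p_error = baseline_p_error = None
    stats = overlap_distribution(records.m.to_numpy(), cfg.n_units)
    return RetrievalResult(
        config=cfg,
        records=records,
        snr=snr,
        p_error=p_error,
        baseline_snr=baseline_snr,
        baseline_p_error=baseline_p_error,
        stats=stats,
    )


# ---------------------------------------------------------------------------
# basin diagnostics on random-pattern networks


def _random_pattern_basin(alpha, n_units, m0_values, n_trials, T, rng, rule="pseudoinverse"):
    """Final overlaps of one random-pattern network initialized at each m0.

    Initial states flip ceil(N(1-m0)/2) uniformly chosen bits of a randomly
    selected stored pattern.  Returns {m0: array of final overlaps}.
    """
    N = n_units
    P = int(round(alpha * N))
    sigma = hard_sign(rng.random((P, N)) - 0.5)
    J = _RULES[rule](sigma)
    out = {}
    for m0 in m0_values:
        n_flip = int(np.ceil(N * (1.0 - m0) / 2.0))
        targets = rng.integers(0, P, n_trials)
        S = sigma[targets].copy()
        for t in range(n_trials):
            S[t, rng.choice(N, n_flip, replace=False)] *= -1.0
        final, _, _ = update_batch(J, S, T=T)
        out[float(m0)] = np.mean(final * sigma[targets], axis=1)
    return out


@dataclass
class MminEstimate:
    m_min: float
    width: float
    m0_grid: np.ndarray
    p1: np.ndarray


def estimate_mmin(
    alpha: float,
    n_units: int,
    m0_grid: Sequence[float] | None = None,
    n_trials: int = 60,
    n_networks: int = 1,
    T: int = DEFAULT_T,
    seed: int = 0,
) -> MminEstimate:
    """Basin edge m_min(alpha) from the perfect-recall probability p1(m0).

    Fits the logistic p1 = 1/(1 + exp(-k (m0 - m_min))); the crossing must
    be bracketed by the grid or a range error is raised.  ``width`` = 1/k
    shrinks like 1/sqrt(N).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1) for the pseudo-inverse network")
    grid = np.asarray(m0_grid if m0_grid is not None else np.arange(0.10, 0.51, 0.025), dtype=float)
    root = _as_seedseq(seed)
    pooled = {float(m0): [] for m0 in grid}
    for child in root.spawn(n_networks):
        rng = np.random.default_rng(child)
        res = _random_pattern_basin(alpha, n_units, grid, n_trials, T, rng)
        for m0, m in res.items():
            pooled[m0].append(m)
    p1 = np.array(
        [np.mean(np.concatenate(pooled[float(m0)]) >= 1.0 - 2.0 / n_units) for m0 in grid]
    )
    if p1.min() > 0.5 or p1.max() < 0.5:
        raise ValueError("p1 does not cross 1/2 inside the m0 grid; widen the grid")
    mid = grid[int(np.argmin(np.abs(p1 - 0.5)))]

    def logistic(m0, k, m_min):
        return 1.0 / (1.0 + np.exp(-k * (m0 - m_min)))

    popt, _ = curve_fit(
        logistic, grid, p1, p0=[np.sqrt(n_units), mid], bounds=([1e-3, 0.0], [np.inf, 1.0]), maxfev=10000
    )
    return MminEstimate(m_min=float(popt[1]), width=float(1.0 / popt[0]), m0_grid=grid, p1=p1)


@dataclass
class FEstimate:
    f_alpha: float
    m0_grid: np.ndarray
    m_star: np.ndarray
    m_min: float | None


#: default f(alpha) grid, as fractions of m_min spanning the out-of-basin range
_F_GRID_FRACTIONS = (0.40, 0.55, 0.70, 0.85)


def estimate_f(
    alpha: float,
    n_units: int,
    m0_grid: Sequence[float] | None = None,
    n_trials: int = 150,
    n_networks: int = 3,
    T: int = DEFAULT_T,
    seed: int = 0,
    m_min: float | None = None,
) -> FEstimate:
    """Out-of-basin amplification f(alpha): slope through the origin of the
    mean final overlap m* (excluding exact retrievals) against m0.

    The default grid spans the out-of-basin range, m0 = (0.40 ... 0.85) x
    m_min; if m_min is not supplied it is estimated first.  Raises if any
    grid point turns out to lie inside the basin (majority of trials
    retrieved exactly).
    """
    root = _as_seedseq(seed)
    mmin_seed, basin_root = root.spawn(2)
    if m0_grid is None:
        if m_min is None:
            m_min = estimate_mmin(alpha, n_units, seed=mmin_seed).m_min
        grid = np.asarray(_F_GRID_FRACTIONS) * m_min
    else:
        grid = np.asarray(m0_grid, dtype=float)
    xs, ys = [], []
    m_star_by_point = {float(m0): [] for m0 in grid}
    for child in basin_root.spawn(n_networks):
        rng = np.random.default_rng(child)
        res = _random_pattern_basin(alpha, n_units, grid, n_trials, T, rng)
        for m0, m in res.items():
            exact = m >= 1.0 - 2.0 / n_units
            if exact.mean() > 0.5:
                raise ValueError(
                    f"m0 = {m0:.3f} lies inside the basin (exact-retrieval fraction "
                    f"{exact.mean():.2f}); all grid points must be outside"
                )
            m_star_by_point[m0].extend(m[~exact])
            xs.extend([m0] * int((~exact).sum()))
            ys.extend(m[~exact])
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    f = float(xs @ ys / (xs @ xs))
    m_star = np.array([np.mean(m_star_by_point[float(m0)]) for m0 in grid])
    return FEstimate(f_alpha=f, m0_grid=grid, m_star=m_star, m_min=m_min)


# ---------------------------------------------------------------------------
# outside-basin SNR fit


@dataclass
class SnrFit:
    c: float
    slope: float
    r_squared: float
    f_alpha: float
    m_min: float
    l_c: float
    points: pd.DataFrame


def fit_snr_constant(
    alpha: float = 0.1,
    n_units: int = 2000,
    L_values: Sequence[int] = (70, 90, 110, 130),
    L0_values: Sequence[int] = (2, 3, 4),
    n_networks: int = 10,
    distractor_sample: int = 300,
    T: int = DEFAULT_T,
    seed: int = 0,
    deep_factor: float = 3.0,
    x_max: float = 4.3,
) -> SnrFit:
    """Measure the proportionality constant c of the outside-basin SNR law.

    Runs retrieval experiments over an (L, L0) grid restricted to the deep
    outside-basin regime (L >= deep_factor * L0 / l_c, and x = L^2/(N L0)
    <= x_max to keep the SNR measurable), measures f(alpha) separately on
    random patterns, and fits 1/SNR = slope * x through the origin; then
    c = pi^3 / (8 f^2 slope).
    """
    root = _as_seedseq(seed)
    s_mmin, s_f, s_runs = root.spawn(3)
    mmin = estimate_mmin(
        alpha, n_units, m0_grid=np.arange(0.10, 0.36, 0.025), n_trials=60,
        seed=s_mmin,
    )
    l_c = lc_from_mmin(mmin.m_min)
    grid = [
        (L, L0)
        for L0 in L0_values
        for L in L_values
        if L >= deep_factor * L0 / l_c and L * L / (n_units * L0) <= x_max
    ]
    if len(grid) < 2:
        raise ValueError("fewer than two grid points survive the deep-regime filter")
    fest = estimate_f(alpha, n_units, seed=s_f, m_min=mmin.m_min)

    xs, ys = [], []
    run_seeds = s_runs.spawn(len(grid))
    for (L, L0), child in zip(grid, run_seeds):
        cfg = ExperimentConfig(
            n_units=n_units,
            n_pairs=L,
            cue_size=L0,
            alpha=alpha,
            T=T,
            n_trials=n_networks,
            seed=int(child.generate_state(1)[0] % (2**31)),
            cleanup_mode="snr_only",
            distractor_sample=distractor_sample,
        )
        res = run_retrieval_experiment(cfg)
        xs.append(L * L / (n_units * L0))
        ys.append(1.0 / res.snr)
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    slope = float(xs @ ys / (xs @ xs))
    resid = ys - slope * xs
    r2 = float(1.0 - (resid**2).sum() / ((ys - ys.mean()) ** 2).sum())
    c = float(np.pi**3 / (8.0 * fest.f_alpha**2 * slope))
    points = pd.DataFrame(
        dict(L=[g[0] for g in grid], L0=[g[1] for g in grid], x=xs, inv_snr=ys)
    )
    return SnrFit(
        c=c,
        slope=slope,
        r_squared=r2,
        f_alpha=fest.f_alpha,
        m_min=mmin.m_min,
        l_c=l_c,
        points=points,
    )


# ---------------------------------------------------------------------------
# sequences


@dataclass
class SequenceResult:
    accuracy_by_position: np.ndarray  # index 0 = position 1 (the cue, always 1)
    records: pd.DataFrame
    retrieval_overlap: np.ndarray


def _make_chain_indices(rng, n_sequences, seq_len, shared_items, dict_size):
    """Item indices for a chain of sequences, neighbors sharing a block.

    Sequence mu+1 starts with the last ``shared_items`` items of sequence
    mu; all other items are distinct draws from the dictionary.
    """
    fresh_needed = seq_len + (n_sequences - 1) * (seq_len - shared_items)
    if fresh_needed > dict_size:
        raise ValueError("dictionary too small for the requested chain")
    pool = rng.choice(dict_size, size=fresh_needed, replace=False)
    pos = 0
    seqs = []
    for mu in range(n_sequences):
        if mu == 0:
            idx = list(pool[pos : pos + seq_len])
            pos += seq_len
        else:
            idx = list(seqs[-1][seq_len - shared_items :]) + list(
                pool[pos : pos + seq_len - shared_items]
            )
            pos += seq_len - shared_items
        seqs.append(idx)
    return seqs


def run_sequence_experiment(
    n_units: int,
    seq_len: int,
    n_sequences: int = 1,
    shared_items: int = 0,
    dict_size: int | None = None,
    T: int = DEFAULT_T,
    n_trials: int = 10,
    seed: int = 0,
    include_first_item: bool = False,
) -> SequenceResult:
    """Store sequences holistically and decode them position by position.

    Each sequence is encoded as a chain of asymmetric bindings, binarized
    and stored in a pseudo-inverse network.  The cue is the first relation
    (a1, a2).  After retrieval, decoding queries the retrieved state with
    the (cleaned-up) previous item and cleans the estimate against the
    dictionary, so errors can accumulate along the sequence.
    """
    if seq_len < 2:
        raise ValueError("sequences need at least two items")
    if not (0 <= shared_items < seq_len):
        raise ValueError("shared_items must be in [0, seq_len)")
    N = n_units
    D = dict_size if dict_size is not None else seq_len * n_units
    scale = 1.0 / np.sqrt(N)
    root = np.random.SeedSequence(seed)
    rows = []
    m_final = []
    for trial, child in enumerate(root.spawn(n_trials)):
        rng = np.random.default_rng(child)
        items = rng.normal(0.0, scale, (D, N))
        seqs = _make_chain_indices(rng, n_sequences, seq_len, shared_items, D)
        sigma = np.empty((n_sequences, N))
        cues = np.empty((n_sequences, N))
        for mu, idx in enumerate(seqs):
            F = np.fft.rfft(items[idx], axis=1)
            # asymmetric binding: circ_corr(earlier, later)
            terms = np.conj(F[:-1]) * F[1:]
            vec = np.fft.irfft(terms.sum(axis=0), n=N)
            if include_first_item:
                vec = vec + items[idx[0]]
            sigma[mu] = hard_sign(vec)
            cues[mu] = hard_sign(np.fft.irfft(terms[0], n=N))
        J = train_pseudoinverse(sigma)
        retrieved, _, _ = update_batch(J, cues, T=T)
        m_final.extend(np.mean(retrieved * sigma, axis=1))
        FS = np.fft.rfft(retrieved, axis=1)
        for mu, idx in enumerate(seqs):
            q = items[idx[0]]
            for pos in range(1, seq_len):
                est = np.fft.irfft(FS[mu] * np.fft.rfft(q), n=N)  # conv(s, q)
                best = int(np.argmax(items @ est))
                rows.append(dict(trial=trial, seq=mu, position=pos + 1, correct=best == idx[pos]))
                q = items[best]
    records = pd.DataFrame(rows)
    acc = np.ones(seq_len)
    by_pos = records.groupby("position").correct.mean()
    for pos, val in by_pos.items():
        acc[pos - 1] = val
    return SequenceResult(
        accuracy_by_position=acc, records=records, retrieval_overlap=np.asarray(m_final)
    )


# ---------------------------------------------------------------------------
# classical sequence-attractor baseline


@dataclass(frozen=True)
class TransitionModelParams:
    """Delayed-asymmetric-coupling sequence model: ``tau`` is the synaptic
    trace time constant (in update steps), ``lam`` the relative strength of
    the successor couplings."""

    tau: float = 8.0
    lam: float = 2.5

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.lam <= 0:
            raise ValueError("tau and lam must be positive")


@dataclass
class TransitionResult:
    overlaps: np.ndarray  # (n_trials, T+1, n_patterns)
    mean_overlaps: np.ndarray  # (T+1, n_patterns)
    patterns: np.ndarray


def run_transition_baseline(
    sequences: Sequence[Sequence[int]],
    n_units: int,
    params: TransitionModelParams | None = None,
    T: int = 80,
    n_trials: int = 20,
    seed: int = 0,
    init_pattern: int = 0,
    init_overlap: float = 0.9,
) -> TransitionResult:
    """Classical sequence-attractor scheme: every event is its own attractor.

    Each distinct pattern id in ``sequences`` becomes a random +-1 pattern
    stored with symmetric Hebb couplings; each consecutive pair within a
    sequence adds an asymmetric coupling of strength lam from the earlier
    to the later pattern, driven through an exponentially filtered trace of
    the network state with time constant tau.  Because the transition rule
    is Markovian in the current attractor, the model cannot disambiguate
    sequences that share an event.

    Returns the overlap of the state with every stored pattern at each
    parallel update, per trial and trial-averaged.
    """
    params = params or TransitionModelParams()
    n_patterns = max(max(s) for s in sequences) + 1
    for s in sequences:
        if len(s) < 2 or min(s) < 0:
            raise ValueError("each sequence needs >= 2 valid pattern ids")
    N = n_units
    root = _as_seedseq(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    xi = hard_sign(rng.random((n_patterns, N)) - 0.5)
    J_sym = xi.T @ xi / N
    np.fill_diagonal(J_sym, 0.0)
    J_asym = np.zeros((N, N))
    for s in sequences:
        for cur, nxt in zip(s[:-1], s[1:]):
            J_asym += np.outer(xi[nxt], xi[cur])
    J_asym *= params.lam / N

    n_flip = int(round(N * (1.0 - init_overlap) / 2.0))
    overlaps = np.empty((n_trials, T + 1, n_patterns))
    for trial, child in enumerate(root.spawn(n_trials)):
        trng = np.random.default_rng(child)
        state = xi[init_pattern].copy()
        if n_flip:
            state[trng.choice(N, n_flip, replace=False)] *= -1.0
        trace = state.copy()
        overlaps[trial, 0] = xi @ state / N
        for t in range(1, T + 1):
            prev = state
            state = hard_sign(J_sym @ state + J_asym @ trace)
            # the trace filters the *previous* state so the asymmetric
            # drive lags the transition; updating it with the new state
            # instead leaves the chain stuck in a terminal mixture
            trace += (prev - trace) / params.tau
            overlaps[trial, t] = xi @ state / N
    return TransitionResult(
        overlaps=overlaps, mean_overlaps=overlaps.mean(axis=0), patterns=xi
    )
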