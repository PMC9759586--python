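"""Dictionary clean-up and the closed-form decoding-error theory.

Unbinding returns a noisy estimate of a stored item.  Clean-up is maximum
likelihood decoding against the dictionary: pick the item with the largest
dot product.  For Gaussian item statistics the error probability of this
decoder depends only on a signal-to-noise ratio

    SNR = <a_hat . a_d>^2 / <(a_hat . a_d')^2>,     d' != d,

the squared mean overlap with the correct item over the mean squared overlap
with incorrect ones.  The error of decoding against ``D`` incorrect
alternatives is

    P_err = Integral Dz [1 - Phi(z + sqrt(SNR))^D],

with ``Dz`` the standard Gaussian measure, and for SNR >> 1

    P_err ~ sqrt(2 / (pi SNR)) * D * exp(-SNR / 4).

Convention: the exponent counts *incorrect* items, so pass ``D - 1`` for a
D-item dictionary containing the target (negligible for large D, but fixed).
To leading order the unbinding SNR of a fresh structure of L pairs is N/L;
the exact finite-L value is N/(L+1) because the queried pair's own binding
contributes unit self-noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.special import log_ndtr

from .encoding import Dictionary

__all__ = [
    "DecodeResult",
    "asymptotic_error",
    "cleanup",
    "empirical_snr",
    "leading_snr",
    "snr_from_overlaps",
    "theoretical_error",
]


@dataclass
class DecodeResult:
    """Outcome of one clean-up operation."""

    estimator: np.ndarray
    best_index: int
    correct: bool | None
    overlap_correct: float | None
    distractor_mean: float | None
    distractor_mean_sq: float | None
    n_distractors: int


def cleanup(
    estimator: np.ndarray,
    dictionary: Dictionary,
    target_index: int | None = None,
    distractor_indices: Sequence[int] | None = None,
) -> DecodeResult:
    """Maximum-likelihood clean-up of a noisy item estimate.

    Returns the argmax dictionary index (ties broken to the lowest index).
    If ``target_index`` is given, correctness and the correct/distractor
    overlap statistics are recorded; ``distractor_indices`` restricts the
    distractor summary to a subsample (the argmax always uses the full
    dictionary).
    """
    estimator = np.asarray(estimator, dtype=float)
    if estimator.shape[0] != dictionary.n_units:
        raise ValueError("estimator length does not match dictionary items")
    overlaps = dictionary.items @ estimator
    best = int(np.argmax(overlaps))  # first occurrence == lowest index

    correct = None
    overlap_correct = None
    d_mean = d_mean_sq = None
    n_d = 0
    if target_index is not None:
        if not (0 <= target_index < dictionary.n_items):
            raise IndexError("target_index outside dictionary")
        correct = best == target_index
        overlap_correct = float(overlaps[target_index])
        if distractor_indices is None:
            mask = np.ones(dictionary.n_items, dtype=bool)
            mask[target_index] = False
            d = overlaps[mask]
        else:
            d = overlaps[np.asarray(distractor_indices, dtype=int)]
        if d.size:
            d_mean = float(d.mean())
            d_mean_sq = float((d**2).mean())
            n_d = int(d.size)
    return DecodeResult(
        estimator=estimator,
        best_index=best,
        correct=correct,
        overlap_correct=overlap_correct,
        distractor_mean=d_mean,
        distractor_mean_sq=d_mean_sq,
        n_distractors=n_d,
    )


def snr_from_overlaps(correct: np.ndarray, distractor: np.ndarray) -> float:
    """Empirical SNR from pooled overlap samples.

    ``correct``: per-trial overlaps with the true item; ``distractor``:
    pooled overlaps with incorrect items (or per-trial mean squares, see
    :func:`empirical_snr`).  Raises if the denominator vanishes.
    """
    correct = np.asarray(correct, dtype=float)
    distractor = np.asarray(distractor, dtype=float)
    denom = float(np.mean(distractor**2))
    if denom == 0.0:
        raise ZeroDivisionError("undefined SNR: distractor overlaps are all zero")
    return float(np.mean(correct) ** 2 / denom)


def empirical_snr(results: Sequence[DecodeResult]) -> float:
    """SNR from clean-up trials: (mean correct overlap)^2 over the pooled
    mean squared distractor overlap (distractors weighted by sample count)."""
    if len(results) < 2:
        raise ValueError("need at least two decode trials")
    num = [r.overlap_correct for r in results if r.overlap_correct is not None]
    if len(num) < 2:
        raise ValueError("decode trials lack correct-item overlaps")
    sq_sum = 0.0
    n = 0
    for r in results:
        if r.distractor_mean_sq is not None and r.n_distractors > 0:
            sq_sum += r.distractor_mean_sq * r.n_distractors
            n += r.n_distractors
    if n == 0 or sq_sum == 0.0:
        raise ZeroDivisionError("undefined SNR: no nonzero distractor overlaps")
    return float(np.mean(num) ** 2 / (sq_sum / n))


def theoretical_error(snr: float, n_distractors: int) -> float:
    """Gaussian-model ML decoding error against ``n_distractors`` incorrect
    items, by adaptive quadrature (absolute tolerance 1e-8)."""
    if not np.isfinite(snr) or snr < 0:
        raise ValueError("snr must be finite and >= 0")
    n_distractors = int(n_distractors)
    if n_distractors < 1:
        raise ValueError("n_distractors must be >= 1")
    root = np.sqrt(snr)

    def integrand(z: float) -> float:
        # 1 - Phi(z + sqrt(SNR))^D, computed in log space for stability
        return -np.expm1(n_distractors * log_ndtr(z + root)) * np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)

    val, _ = quad(integrand, -12.0, 12.0, epsabs=1e-10, limit=200)
    return float(min(max(val, 0.0), 1.0))


def asymptotic_error(snr: float, n_distractors: int) -> float:
    """Large-SNR approximation sqrt(2/(pi SNR)) D exp(-SNR/4), clipped to 1."""
    if not np.isfinite(snr) or snr <= 0:
        raise ValueError("snr must be finite and > 0")
    if n_distractors < 1:
        raise ValueError("n_distractors must be >= 1")
    val = np.sqrt(2.0 / (np.pi * snr)) * n_distractors * np.exp(-snr / 4.0)
    return float(min(val, 1.0))


def leading_snr(n_units: int, n_pairs: int) -> float:
    """Leading-order unbinding SNR, N/L."""
    if n_units < 1 or n_pairs < 1:
        raise ValueError("N and L must be >= 1")
    return n_units / n_pairs
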