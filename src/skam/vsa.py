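"""Quadratic binding and unbinding operators.

A binding operation maps a pair of activity patterns ``a, b`` (real vectors of
length ``N``) to a single vector ``g(a, b)`` through a quadratic form
``g_k = a^T G^k b``, one fixed ``N x N`` matrix per output component.  The
holographic reduced representation (HRR) is the special case in which binding
is circular convolution and unbinding is circular correlation; both are
``O(N log N)`` via the FFT, and the explicit stacked-matrix form is kept as a
slow reference for small ``N``.

Conventions
-----------
``circ_conv(a, b)_k = sum_j a_j b_{(k-j) mod N}`` (commutative) and
``circ_corr(x, y)_k = sum_j x_j y_{(j+k) mod N}`` (not commutative).

Unbinding must approximately invert binding.  For circular convolution the
inverting operation is correlation with the probe in the *first* slot,
``unbind(s, b) = circ_corr(b, s)``, which equals convolution of ``s`` with the
index-reversed probe (the standard HRR involution).  Correlating in the other
order returns the index-mirrored item and decodes to noise, so ``unbind`` is
deliberately not ``circ_corr(s, b)``.

For temporal sequences the binding must be asymmetric: binding and unbinding
switch roles, ``bind(a, b) = circ_corr(a, b)`` with the *earlier* element
first, and ``unbind(s, q) = circ_conv(s, q)``.  Querying a bound pair with the
earlier element returns the later one; the reverse query does not invert,
which is what makes the operation order-aware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BindingScheme",
    "bind",
    "circ_conv",
    "circ_conv_direct",
    "circ_corr",
    "circ_corr_direct",
    "hard_sign",
    "hrr_matrices",
    "unbind",
]

#: largest N for which the explicit G/F matrix stacks may be materialized
EXPLICIT_MATRIX_MAX_N = 256

_MODES = ("hrr_symmetric", "hrr_asymmetric", "explicit_matrices")


def hard_sign(x: np.ndarray) -> np.ndarray:
    """Element-wise sign with the fixed convention ``sign(0) = +1``."""
    return np.where(np.asarray(x) >= 0, 1.0, -1.0)


def _as_equal_vectors(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("binding operands must be one-dimensional vectors")
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"operand length mismatch: {a.shape[0]} != {b.shape[0]}"
        )
    if a.shape[0] < 1:
        raise ValueError("operands must have length >= 1")
    return a, b


def circ_conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular convolution, ``g_k = sum_j a_j b_{(k-j) mod N}``.

    Commutative and associative; conserves the product of component sums,
    ``sum(g) = sum(a) * sum(b)``.
    """
    a, b = _as_equal_vectors(a, b)
    n = a.shape[0]
    return np.fft.irfft(np.fft.rfft(a) * np.fft.rfft(b), n=n)


def circ_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Circular correlation, ``r_k = sum_j x_j y_{(j+k) mod N}``."""
    x, y = _as_equal_vectors(x, y)
    n = x.shape[0]
    return np.fft.irfft(np.conj(np.fft.rfft(x)) * np.fft.rfft(y), n=n)


def circ_conv_direct(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """O(N^2) double-sum evaluation of :func:`circ_conv` (test oracle)."""
    a, b = _as_equal_vectors(a, b)
    n = a.shape[0]
    j = np.arange(n)
    return np.array([a @ b[(k - j) % n] for k in range(n)])


def circ_corr_direct(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """O(N^2) double-sum evaluation of :func:`circ_corr` (test oracle)."""
    x, y = _as_equal_vectors(x, y)
    n = x.shape[0]
    j = np.arange(n)
    return np.array([x @ y[(j + k) % n] for k in range(n)])


def hrr_matrices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Explicit binding/unbinding matrix stacks ``G, F`` of shape (N, N, N).

    ``G[k, i, j] = 1`` iff ``(i + j) mod N == k`` so that ``a^T G^k b``
    reproduces circular convolution, and ``F[k, i, j] = 1`` iff
    ``(i - j) mod N == k`` so that ``s^T F^k b`` reproduces
    ``circ_corr(b, s)``, the inverting unbinding.

    Refuses ``n > EXPLICIT_MATRIX_MAX_N`` (the stacks are N^3 floats).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > EXPLICIT_MATRIX_MAX_N:
        raise ValueError(
            f"explicit matrices are limited to N <= {EXPLICIT_MATRIX_MAX_N}; "
            "use an hrr_* mode for larger N"
        )
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    G = np.zeros((n, n, n))
    F = np.zeros((n, n, n))
    G[(i + j) % n, i, j] = 1.0
    F[(i - j) % n, i, j] = 1.0
    return G, F


@dataclass(frozen=True)
class BindingScheme:
    """Choice of binding/unbinding operators.

    Parameters
    ----------
    mode:
        ``"hrr_symmetric"`` (circular convolution / correlation),
        ``"hrr_asymmetric"`` (roles switched; for ordered relations), or
        ``"explicit_matrices"`` (the quadratic-form reference, equal to the
        symmetric mode).
    G, F:
        Stacked binding/unbinding matrices, required only for
        ``explicit_matrices``.
    """

    mode: str = "hrr_symmetric"
    G: np.ndarray | None = None
    F: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(
                f"unknown binding mode {self.mode!r}; expected one of {_MODES}"
            )
        if self.mode == "explicit_matrices" and (self.G is None or self.F is None):
            raise ValueError("explicit_matrices mode requires both G and F")

    @classmethod
    def symmetric(cls) -> "BindingScheme":
        return cls(mode="hrr_symmetric")

    @classmethod
    def asymmetric(cls) -> "BindingScheme":
        return cls(mode="hrr_asymmetric")

    @classmethod
    def explicit(cls, n: int) -> "BindingScheme":
        G, F = hrr_matrices(n)
        return cls(mode="explicit_matrices", G=G, F=F)


def bind(a: np.ndarray, b: np.ndarray, scheme: BindingScheme | None = None) -> np.ndarray:
    """Bind two items into an association vector.

    In ``hrr_asymmetric`` mode the order matters: ``a`` is the earlier
    element of the relation.
    """
    scheme = scheme or BindingScheme.symmetric()
    if scheme.mode == "hrr_symmetric":
        return circ_conv(a, b)
    if scheme.mode == "hrr_asymmetric":
        return circ_corr(a, b)
    a, b = _as_equal_vectors(a, b)
    return np.einsum("i,kij,j->k", a, scheme.G, b)


def unbind(s: np.ndarray, probe: np.ndarray, scheme: BindingScheme | None = None) -> np.ndarray:
    """Query a (summed) association vector ``s`` with one item of a pair.

    Symmetric mode returns a noisy estimate of the probe's partner;
    asymmetric mode returns the *successor* of the probe (querying with the
    later element does not invert, by construction).
    """
    scheme = scheme or BindingScheme.symmetric()
    if scheme.mode == "hrr_symmetric":
        return circ_corr(probe, s)
    if scheme.mode == "hrr_asymmetric":
        return circ_conv(s, probe)
    s, probe = _as_equal_vectors(s, probe)
    return np.einsum("i,kij,j->k", s, scheme.F, probe)
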