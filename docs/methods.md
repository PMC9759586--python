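# Methods

This note records the model conventions, measurement protocols, numerical
choices and known limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Binding and unbinding conventions

`circ_conv(a, b)_k = Σ_j a_j b_{(k−j) mod N}` and
`circ_corr(x, y)_k = Σ_j x_j y_{(j+k) mod N}`, subscripts modulo N. Fast
paths use the real FFT; `circ_conv_direct` / `circ_corr_direct` keep the
O(N²) double sums as test oracles (agreement required to 1e−10 relative).

Correlation is not symmetric in its operands, and only one operand order
inverts convolution: `circ_corr(b, conv(a, b)) ≈ a`, while
`circ_corr(conv(a, b), b)` returns the index-mirrored item `a_{−k}` (we
verified the round-trip overlap drops from ≈ 1.0 to ≈ N^{−1/2} when the
operands are swapped). The package therefore fixes:

* symmetric scheme — `bind(a, b) = circ_conv(a, b)`,
  `unbind(s, probe) = circ_corr(probe, s)` (equivalently convolution with
  the index-reversed probe, the standard HRR involution). The explicit
  matrix form uses `G^k_{ij} = δ_{k,(i+j) mod N}` and
  `F^k_{ij} = δ_{k,(i−j) mod N}`, which reproduces the FFT path exactly.
* asymmetric scheme (sequences) — `bind(a, b) = circ_corr(a, b)` with the
  *earlier* element first, `unbind(s, q) = circ_conv(s, q)`. Querying
  with the earlier element returns its successor; the reverse query does
  not invert, which is precisely what makes the encoding order-aware.
  Sequence decoding therefore unrolls forward: clean `a_ℓ`, query, clean
  `a_{ℓ+1}`, and so on.

Explicit G/F stacks are N³ floats and are refused above N = 256.

`sgn(0) = +1` everywhere (binarization and network updates). Zeros have
measure zero for generic float inputs, but the fixed convention makes
runs bit-reproducible.

Structure encodings sum pair bindings in canonical (sorted) order so that
reordering the pair list yields a bit-identical vector (floating-point
addition is not associative).

## Decoding error theory

`theoretical_error(snr, n_distractors)` evaluates
`∫ Dz [1 − Φ(z + √SNR)^D]` by adaptive quadrature on z ∈ [−12, 12]
(`log_ndtr` for stability, absolute tolerance 1e−8). The exponent counts
*incorrect* items: pass `D − 1` for a D-item dictionary containing the
target. Monte-Carlo ML decoding of Gaussian-calibrated estimators
(`â = g·a_target + η` with `g` chosen so the overlap SNR is exact)
reproduces the integral within binomial error at SNR ∈ {9, 16, 25, 36},
D = 1000.

`asymptotic_error` implements the large-SNR form
`√(2/(π·SNR))·D·exp(−SNR/4)` exactly as usually printed, clipped to 1.
Beware: the exact large-SNR limit of the integral is
`D·exp(−SNR/4)/√(π·SNR)`, so the printed form overshoots by √2 even
asymptotically, and by ~2.8× at SNR = 40, D = 1000 where rare noise draws
still saturate the inner probability. The tests document this ratio; use
the integral for quantitative work.

The unbinding SNR of a fresh structure is N/(L+1), not N/L: the queried
pair's own binding contributes unit self-noise to the estimator. N/L is
the correct leading order and `leading_snr` returns it, but at L = 5 the
difference is 17% — tests that pin "within 10% of N/L" at such small L
are testing the approximation, not the simulation.

## Memory network

Pseudo-inverse couplings solve `C x = σ` rather than inverting C, with a
condition-number guard at 1e12 (duplicated patterns raise). Diagonal
forced to zero for all rules. The Storkey recursion uses the
zero-diagonal J of the previous step when computing the local fields
`h = Jσ`, and zeroes the diagonal after every pattern; the
`(N+1)/(N−1)` growth factor makes the result presentation-order
dependent, which is tested against an independent line-by-line
transcription.

Parallel updates are synchronous; serial updates sweep the units in a
fresh seeded random permutation per sweep. Both stop early at a fixed
point (repeated state / flip-free sweep). T = 20 parallel updates is the
default for retrieval throughout.

## Measurement protocols

**Cue overlap.** `m0_theory(L0, L) = (2/π)·arctan(√(r/(1−r)))`,
`r = L0/L` (equivalently `(2/π)·arcsin √r`), with `m0_theory(L, L) = 1`
by continuity. The critical cue fraction inverts this relation exactly:
`lc_from_mmin(m) = sin²((π/2)·m)`, so that a cue of fraction l_c has mean
overlap exactly m_min; its quadratic expansion is `(π m/2)²`.

**Basin edge m_min(α).** A pseudo-inverse network stores αN random ±1
patterns; initial states flip ⌈N(1−m0)/2⌉ uniformly chosen bits of a
stored pattern. The perfect-recall probability p1(m0) (tolerance: final
overlap ≥ 1 − 2/N, i.e. at most one flipped bit) is fitted with the
logistic `1/(1 + e^{−k(m0 − m_min)})`; the grid must bracket the ½
crossing. The width 1/k shrinks with network size (≈ 1/√N), which is what
makes the basin edge sharp in the large-N limit.

**Amplification f(α).** The slope through the origin of the mean
non-exact final overlap m* against m0, pooled over networks. The default
m0 grid spans the *full* out-of-basin range — fractions
(0.40, 0.55, 0.70, 0.85) of m_min — because f is a property of the
energy landscape, not of any particular cue length. This choice matters:
m*/m0 rises from ≈ 2.1 near m0 = 0.08 to ≈ 2.5 near the basin edge at
α = 0.1, N = 2000, so a grid restricted to very small m0 yields a
smaller f and (since the SNR law divides by f²) a correspondingly larger
fitted c. Grid points where most trials retrieve exactly are rejected as
in-basin.

**Outside-basin SNR constant c.** Retrieval experiments over an (L, L0)
grid restricted to the deep regime (L ≥ 3·L0/l_c, and x = L²/(N·L0) ≤ 4.3
to keep the SNR measurable), with 10 independent networks per point;
1/SNR is fitted through the origin against x, and
`c = π³/(8 f(α)² slope)`. At α = 0.1, N = 2000 this yields c ≈ 0.59–0.66
across seeds (R² ≥ 0.95), consistent with the theory value ≈ 0.65. The
result is insensitive to N (checked at N = 2000–4000) but, as noted
above, sensitive to the f protocol.

**Empirical SNR.** Numerator: squared mean overlap of the estimator with
the correct item, pooled over structures and networks. Denominator: mean
squared overlap with incorrect items. Full clean-up runs use a
materialized dictionary (refused above 2²⁶ floats — use `snr_only` mode
instead, which samples fresh Gaussian distractors; identical in
distribution since dictionary items are i.i.d.).

**Sequences.** A sequence of L events encodes to L−1 asymmetric bindings;
the retrieval cue is the first relation (a1, a2), equivalent to L0 = 2.
Decoding queries the retrieved state with the cleaned-up previous item,
so errors can accumulate along the sequence. Chains of sequences share a
contiguous block: sequence μ+1 begins with the last L_s items of
sequence μ.

**Transition-model baseline.** Every event is stored as its own attractor
(symmetric Hebb couplings); each consecutive pair adds an asymmetric
coupling of strength λ from the earlier to the later pattern, driven by
an exponentially filtered trace of the *previous* network state with time
constant τ (defaults λ = 2.5, τ = 8 parallel steps). Filtering the
previous state (rather than the freshly updated one) lets the drive lag
each transition; with the un-lagged variant the chain terminates in a
mixture state. Because the transition rule is Markovian in the current
attractor, two sequences sharing an event receive identical forward drive
there — the model cannot select the correct continuation, which is the
behavior the comparison tests assert. This implementation is
contract-level (order of peaks, failure at shared events), not a
quantitative reproduction of any particular trace model.

## Synthetic data

All inputs are synthetic by construction: dictionaries are i.i.d.
Normal(0, 1/N) item vectors from seeded generators, structures draw
object indices uniformly without replacement within a structure, and one
attribute set is shared across structures by default (toggleable). The
generator reproduces the stated world of the model — it does not emulate
correlated or sparse item statistics, semantically structured
dictionaries, or noisy neurons, so green tests establish the internal
consistency of the theory and simulation, not biological validity.

Every pipeline draws all randomness from one root `SeedSequence`; per
network and per target the streams are spawned independently, so runs are
bit-reproducible for a given config and seed.

## Scale and limitations

Reference figures in this line of work use N = 8000–12000 with 10,000
stored structures; the default protocols here run at N = 500–4000 so that
the full suite completes in minutes on one CPU. Consequences: p(m) modes
are broader (σ_m ≈ 1/√N), the perfect-recall transition is softer, and
out-of-basin error rates at small N are noticeably above their large-N
values even though the SNR scaling collapse already holds. The m* vs m0
relation is only approximately linear, so f(α) — and through it c —
carries a protocol dependence of order ±10–15%; both protocols are fixed
a priori and documented above.
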