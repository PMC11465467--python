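# Methods

This note records the model conventions, numerical choices and defaults
behind `spinsse`, and what the synthetic inputs do and do not emulate.

## Hilbert space and operators

The basis is electron 1 ⊗ electron 2 ⊗ nuclei of radical 1 (declaration
order) ⊗ nuclei of radical 2, with magnetic quantum numbers descending
from +I within each site; the nuclear subspace (dimension Z = Π(2I_k+1))
is therefore contiguous.  Singlet/triplet states are defined in the
two-electron product basis as |T₊₁⟩ = |αα⟩, |T₀⟩,|S⟩ = (|αβ⟩ ± |βα⟩)/√2,
|T₋₁⟩ = |ββ⟩, which fixes the projector matrices bit-for-bit.  All
operators are stored sparse (CSR); the Hamiltonian is never densified
during assembly or large-system propagation.  Only I = 1/2 and I = 1 are
supported — these cover ¹H and ¹⁴N, the nuclei of every system the
package ships — and anything else is rejected loudly rather than silently
truncated.

## Units and couplings

Public APIs use mT for fields, MHz for tensors, µs⁻¹ for rates and ns for
times; internally every Hamiltonian is an angular frequency in rad µs⁻¹
(MHz × 2π, mT × g μ_B/ℏ with g = 2.0023 per radical by default, constants
from CODATA via `scipy.constants`).  Unit round-trips agree to one part
in 10⁹.

The exchange term is H_ex = −J(2**Ŝ**₁·**Ŝ**₂ + ½), so the singlet sits
2J above the triplet (in angular-frequency units, 2π·2J).  Because the
molecular-wire literature quotes the *splitting* 2J, configurations accept
explicit `j_MHz`, `j_mT`, `two_j_MHz` or `two_j_mT` keys — the classic
factor-of-two trap is resolved by making the convention explicit, never by
guessing.  A combined electron–electron tensor **C** = **D** − 2J·**1**
may replace the separate terms; the two assemblies differ only by a
multiple of the identity (a global energy offset with no observable
consequence), which is covered by a test.

## Reaction kinetics

K̂ = Σ_Θ (k_Θ/2) P̂_Θ + (k_f/2)·**1**.  The factor ½ lives inside K̂ so
that the anticommutator −{K̂, ρ̂} gives total population decay e^(−kt)
for a uniform rate — the physical contract the tests enforce.  `k_f` is a
spin-independent escape channel: it removes population uniformly but does
not contribute to the spin-selective yields Φ_Θ.  In the driven model the
singlet backward recombination k_b(t) is the singlet's selective rate
while k_f applies to all four states.

## Propagation

The SSE generator Ω = −iĤ − K̂ is held piecewise constant over each step
(first-order Magnus, time-ordering neglected within a step).  Ω is
evaluated at the step start by default — the same zero-order-hold
convention as tensor trajectories — giving global first-order accuracy in
δt for time-dependent problems; a midpoint rule (`time_sampling =
"midpoint"`) upgrades this to second order and is verified by a
step-halving test.  Default δt = 1 ns; 4 ns is a typical production
choice for the large flavin/tryptophan systems.

Four step methods share one contract (relative error controlled by ε,
default 10⁻⁶; norms never renormalized):

* `expm_action`: scipy's accuracy-controlled `expm_multiply`.
* `krylov_arnoldi`: adaptive Arnoldi iteration with the standard
  a-posteriori error estimate h_{m+1,m}·|[e^{H_m}]_{m,0}|; on reaching the
  subspace cap (default 64) the step is split recursively.
* `krylov_lanczos`: Hermitian Lanczos with full reorthogonalization.  The
  Lanczos recurrence needs a Hermitian operator, so this method requires
  the Hermitian part of Ω to be a uniform multiple of the identity (no
  reaction, or a uniform decay, which is factored out analytically as
  e^(−γt/2)); other generators are refused with a pointer to Arnoldi.
* `auto` (default): for static generators of dimension ≤ 600 the step
  propagator e^{Ωδt} is built densely once and applied as a matrix
  product (exact to machine precision, and much faster for the batched
  small-system runs used in tests); larger or time-dependent problems
  fall back to `expm_action`.

The ε ≈ 0.5 sometimes quoted for production trace-sampling runs trades
accuracy for speed in a solver-specific way; its precise semantics are
implementation-defined and no attempt is made to match it numerically.

## Yields

Direct mode propagates all Z nuclear basis states; stochastic mode
propagates M sampled SU(Z) coherent states (Gaussian complex vectors
normalized to the unit hypersphere — exactly the δ(|**Z**|−1) density).
Samples are keyed by (seed, sample index) through
`numpy.random.SeedSequence`, so sample m is identical regardless of how
many samples run or in what order; orientation scans reuse the same seeds
at every grid point so Monte-Carlo noise does not roughen the curve.  The
reported standard error is the sample standard deviation of the M
per-sample yields over √M (the estimator is verified unbiased, and its
error verified ∝ 1/√M, by tests).  For small systems M must be
comparable to Z for reliable results, which forfeits the stochastic gain
— requesting M > Z warns and the direct cap (Z ≤ 8192 by default) points
users to the stochastic mode instead.

Quadrature is the trapezoid rule on the propagation grid (observables are
already sampled every step; the error is dominated by δt).  The
correction factor for symmetric rates,
Φ_Θ(∞) ≈ [k ∫₀ᵀ e^(−kt) p_Θ(t) dt] / (1 − e^(−kT)) with p_Θ from a
reaction-free run, completes the truncated integral with the k-weighted
average accumulated so far.  Numerator and denominator use the same
trapezoid rule, so it is exact for constant p at any step size and
conserves Σ_Θ Φ_Θ = 1 to machine precision.  An endpoint-based tail term
e^(−kT)p(T) was considered and rejected: for oscillatory p it carries an
O(amplitude)·e^(−kT) error (measured ~0.14 on the one-proton pair at
T = 1/k), whereas the averaged form agrees with a 10×-longer uncorrected
run to ~2×10⁻⁴.  The factor is refused for asymmetric rates or a nonzero
k_f, where the underlying factorization ρ = e^(−kt)ρ₀ does not hold.

MARY scans report the survival-based relative yield
Φ_RP(B, t)/Φ_RP(0, t) = Tr ρ̂(t)|_B / Tr ρ̂(t)|₀ at a fixed observation
time, and minima are located by grid argmin with the grid step reported
as the resolution — no interpolation, no hidden optimizer.  The relative
anisotropy is χ = (Φ_∥ − Φ_⊥)/((Φ_∥ + Φ_⊥)/2), zero iff the two
orientations give equal yields and antisymmetric under swapping them.
Orientation scans rotate **B** in the molecular z–x plane with all
tensors fixed.

## Time-dependent interactions

Tensor trajectories are uniform time series (tab/comma-separated text,
`time_ns` column plus `<tag>.xx … <tag>.zz` in MHz) applied with a
zero-order hold; times beyond the final sample raise rather than
extrapolate, and a propagation longer than the trajectory is refused
before it starts.  Tagged interactions are assembled once into component
operators S_a I_b so the per-step update is a 9-term sparse sum, verified
against full re-assembly.  Per-interaction static/dynamic flags reproduce
the usual scenario set (all static, static without dipolar, only dipolar
fluctuating, only hyperfines fluctuating, all dynamic).

The driven geometry modulates the inter-radical distance as
r(t) = r₀ + (Δ_d/2)(1 − cos 2πv_d t): an oscillation of peak-to-peak
amplitude Δ_d away from the contact distance r₀, where recombination is
fastest and the exchange largest.  J(t) and k_b(t) share the exponential
distance law e^(−β(r−r₀)), so J/J₀ = k_b/k_b0 at all times and
max/min = e^(βΔ_d) over a period.  The outward convention was chosen
because it reproduces the expected physics of a driven pair: with
J₀ = 10 MHz the static exchange quenches the directional response
(χ ≈ 0.004), while driving at v_d = 5 MHz periodically switches the
exchange off and restores it (χ ≈ 0.12).  Defaults r₀ = 17.8 Å,
Δ_d = 3 Å, β = 1.4 Å⁻¹, k_b0 = 2 µs⁻¹, k_f = 0.5 µs⁻¹.

## Synthetic data

The Ornstein–Uhlenbeck tensor generator is the minimal stationary
Gaussian stand-in for MD/QC tensor time series: per-component exact OU
updates around a mean tensor, one correlation time τ, sampled every 50 ps
by default, initial sample from the stationary distribution.  It captures
the amplitude and memory of real tensor fluctuations but none of their
cross-component correlations, multi-timescale structure or anharmonicity;
a passing relaxation test therefore demonstrates the machinery
(fluctuations → relaxation → reduced orientation-scan amplitude), not a
quantitative prediction for any real protein.  Relaxation-test defaults
(σ = 10 MHz per component, τ = 200 ps) were chosen once as a realistic
fluctuation scale for flavin-like hyperfine tensors with a correlation
time safely above the 50 ps sampling step.

The `fad_trp_12`/`fad_trp_14` builtins carry the correct nucleus rosters
(Hilbert dimensions 55,296 and 221,184) but synthetic hyperfine tensors
and a synthetic electron–electron coupling, as documented in their
docstrings; real studies must supply literature tensors via the
`tensors` argument or a tensor file.  No shipped test depends on the
synthetic values beyond qualitative orderings.

## Problem sizes

The dense Liouville oracle (DOP853 on the density matrix, rtol 10⁻¹⁰,
yields on the same grid/quadrature as the SSE path so the comparison
isolates propagation error) is capped at dimension 256 and used for
cross-validation at dimensions ≤ 64, where direct-SSE yields agree with
it to better than 10⁻⁶.  The test suite and the acceptance script run
desk-scale versions of each study: the wire scan uses a 3-proton reduced
model (dim 32, 65 field points, 50 ns each), the driven comparison the
single-nitrogen pair (dim 12, 12 µs), the relaxation comparison a
2-nucleus pair (dim 24, 1 µs, 13 orientations), and the
trace-sampling statistics a 4-proton pair (Z = 16).  The 55,296- and
21,233,664-dimensional rosters are exercised for their dimension
arithmetic; propagating them is a cluster-scale exercise the package
supports through the same sparse/stochastic code paths but is not part
of the test suite.

## Known limitations

Two electrons only; no g-tensor anisotropy or quadrupolar interactions;
Haberkorn kinetics only (no Lindblad dephasing or Jones–Hore scheme); no
spin-coherent-state sampling (SU(Z) states need fewer samples and are
unitarily invariant); zero-order-hold or midpoint Magnus only (no
higher-order Magnus or adaptive stepping); mixed initial electronic
states are handled by combining runs of pure states.
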