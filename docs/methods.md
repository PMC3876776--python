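# Methods

## Model and assumptions

The single-neuron model is a binding neuron with instantaneous feedback.
Impulses arrive as a renewal stream: inter-arrival times Z are i.i.d. with
density f_Z, independent of everything else. Each stored impulse persists
for a lifetime drawn from an independent law G_τ (deterministic τ as the
step-CDF special case) and is lost exactly at the end of its lifetime; when
an arrival and an expiry coincide (probability zero for continuous laws,
possible for user-supplied discrete laws) the expiry is processed first.
The neuron fires when the stored count reaches the threshold K, the store is
cleared, and — because of feedback — one fresh impulse with a newly drawn
lifetime is reinstated immediately. All closed-form results assume K = 2;
the simulator supports any K ≥ 2 and feedback on or off.

Under K = 2 with feedback, each inter-arrival is an independent Bernoulli
round with success probability q = P(Z ≤ τ) = ∫ f_Z Ḡ_τ dt, so the
interspike interval is a geometric compound

T = Σ_{i<N} X_i + Y_N, with N − 1 ~ geometric(q) on {0, 1, 2, ...},
X ~ (Z | Z > τ) with density f_Z G_τ / p, and Y ~ (Z | Z ≤ τ) with density
f_Z Ḡ_τ / q. The wasted-impulse count per interval is N − 1 itself; its
geometric law is verified against the simulator by a chi-square fit. (The
count is taken on {0, 1, 2, ...} with mean p/q; an interval can contain zero
wasted impulses.)

Moments come from the decomposition rather than from symbolic
differentiation of the transform:

- E(T) = E(Z)/q (exact for every law),
- Var(T) = (p/q) Var(X) + (p/q²) E(X)² + Var(Y),

with closed-form branch moments for the built-in cases and quadrature
otherwise. For exponential(λ) input with deterministic τ this reproduces
Var(T) = (1 + 2λτe^{−λτ}) / (λ²(1 − e^{−λτ})²); for exponential lifetimes it
gives E(T) = (λ+μ)/λ² and Var(T) = ((2λ+μ)² − 3λ²)/λ⁴, which equal the
transform derivatives of the rational Laplace transform
λ(s+λ)/(s² + s(2λ+μ) + λ²); for uniform(a, b) input with a < τ < b it gives
E(T) = (b² − a²)/(2(τ − a)). The package computes the uniform-case CV from
these moments, not from any printed closed form, and a test checks all three
routes against central finite differences of L_h at 0.

## Density evaluation routes

- **Exponential input, deterministic τ** — term-wise inversion of the
  expanded geometric series of the transform gives a *finite* series,
  h(t) = e^{−λt} Σ_{n≥1} λⁿ/(n−1)! [(t−(n−1)τ)^{n−1} 𝟙{t>(n−1)τ} −
  (t−nτ)^{n−1} 𝟙{t>nτ}], terminating at n = ⌊t/τ⌋ + 1. Factorials are kept
  in log space, so large λt is safe. The CDF is the matching sum of shifted,
  e^{−λc}-weighted regularized incomplete gamma functions. The density has
  a genuine jump at t = τ (from λe^{−λτ} down to ≈ 0): an interval shorter
  than τ is a single input gap, while an interval just above τ requires a
  wasted round and a near-zero successful round, which has vanishing
  probability density.
- **Exponential input, exponential lifetime** — bi-exponential density
  h(t) = λ[(λ+r₁)e^{r₁t} − (λ+r₂)e^{r₂t}]/(r₁−r₂) with r₁, r₂ the real
  negative roots of s² + s(2λ+μ) + λ² = 0 (discriminant μ(4λ+μ) > 0, so the
  roots are always distinct; Vieta gives r₁r₂ = λ², r₁+r₂ = −(2λ+μ), which
  is asserted to 1e−10).
- **Anything else** (uniform input, custom laws) — numerical inversion of
  the transform; see below.

## Numerical Laplace inversion

`invert_laplace` implements the Abate–Whitt Euler-summation algorithm:
Bromwich–Fourier discretization with parameter A (aliasing error ≈ e^{−A}
for densities bounded by 1) and binomial (Euler) averaging of the last
partial sums of the alternating series. The generic default is A = 18.4
with 31 transform evaluations and averaging over the last 12 partial sums,
which achieves ≤ 1e−7 on the smooth validation pairs
(L = 1/(s+1) ↔ e^{−t}; L = (1−e^{−s})/s ↔ 𝟙_{(0,1)} at interior points).

Plain Euler summation degrades badly near discontinuities of the target
(Gibbs error ~1e−2 near the exp/deterministic density's jump at τ, measured
with the 31-term budget). The ISI density route therefore uses
**singularity subtraction**: the only discontinuous piece of h is the first
renewal term f_Z(t)Ḡ_τ(t), whose transform is known and whose time-domain
form is directly evaluable; it is subtracted from the transform and added
back exactly, and the continuous remainder
L[fḠ]·L[fG]/(1 − L[fG]) is inverted with a larger budget (A = 25, 641
terms, averaging over the last 41). The remainder is continuous but only
piecewise smooth (derivative kinks at multiples of τ), which is why the
bigger budget is needed; measured max error is ≈ 1e−6 on a (0, 5] grid for
λ = 1, τ = 1. Comparison grids avoid exact multiples of τ because the
density value at a jump point is a convention (the series uses the
left-limit convention; any Fourier-type inversion converges to the jump
midpoint). The numeric CDF route inverts L_h(s)/s with the default budget —
the CDF is continuous, and the ~1e−4 accuracy is ample for the
Kolmogorov–Smirnov comparisons it serves.

Quadratures use absolute tolerance 1e−10 / relative 1e−8 with upper limits
at the 1 − 1e−12 quantile of the input law (a fixed generous cut-off of
80 time units, ≈ 40 mean intervals, for the normalization checks; the ISI
tail decays at least geometrically with rate p per mean round, so the
truncated mass is far below the 1e−6 tolerance).

## Monte-Carlo simulator

Two independent algorithms: a general event-driven store (list of expiry
times, any K, feedback optional, pure-Python) and a vectorized fast path
for K = 2 with feedback that draws (Z, τ) rounds in blocks and segments them
at successes. They consume randomness differently and are compared
statistically in tests (two-sample KS, means within joint standard errors) —
a deliberate dual-route check. One seed expands into separate input and
lifetime sub-streams via `numpy.random.SeedSequence.spawn`, so identical
(spec, n, seed) give byte-identical trains. A cap of 1e7 input events per
interval converts never-firing configurations (q = 0) into a clear error.
`summarize` reports the sample mean, variance and CV with the SE of the mean
s/√n and a delta-method SE for the CV using empirical third and fourth
central moments (no normality assumption).

## Hourglass network

Discrete-time update with step dt: every X_i decreases by dt; any neuron at
zero (tolerance dt·1e−6, far above accumulated float error, far below one
step) fires. The firing neuron's hourglass becomes U_i − dt (the literal
update convention, which makes the effective period U − dt under mean
refill); inhibited targets gain w_ij; excited targets lose w_ij with a floor
at zero. Eligibility to fire is fixed immediately after the decrement:
an inhibitory kick from an earlier firer (row-major processing order) can
lift a not-yet-processed neuron off zero, while an excitatory kick that
lands a neuron on zero takes effect at the next step's test — this matches
the stated update equations, under which an excited neuron's new value is
max{0, X_j − w_ij − dt}, not a refill. A regression test pins both
tie-break behaviours.

Refill policies: `mean` (U_i = E(T) of the neuron's ISI law — the default,
matching a refill with the expected firing time) and `sampled` (a fresh
draw from the ISI law). Initial state: X_i(0) from the active refill
policy; the staggered-start option adds i.i.d. uniform(0, E(T)) phase
jitter, because identical mean-refill starts are perfectly synchronized and
the jitter is what makes multi-seed averages meaningful.

### Study conditions of the grid experiment

`grid_experiment` fixes the reference conditions: a 10×10 grid, purely
inhibitory lateral coupling, neurons with exponential(λ = 15) input and
deterministic lifetime τ, mean refill, staggered start. All time-like
quantities are expressed in multiples of E(T): dt = E(T)/20,
horizon = 300·E(T), w given as w_rel·E(T). The horizon is chosen so that an
uncoupled neuron fires ≈ 300 times and lands in the high-activity class
(> 200 spikes), which keeps the silent (≤ 5) / medium (6–200) / high (> 200)
classification informative; the boundary count of exactly 5 is classified
silent. Literal (τ, w) pairs in seconds are not used because λ = 15 s⁻¹
combined with unit steps and w up to 30 mixes incompatible scales; the
relative-units formulation is the internally consistent reading.

Two consequences of these conditions are worth stating plainly. First,
with λ = 15 every stated τ ∈ {1, 5, 7} gives q = 1 − e^{−λτ} ≈ 1 and
E(T) ≈ 1/15 up to ~3e−7 relative, so the silent-neuron count is flat in τ
in the relative-units experiment — the monotone-in-τ property holds as
equality. Second, because mean refill makes the network deterministic after
the initial jitter, lateral inhibition produces winner-take-all lock-in:
suppressed neurons stay suppressed, silent neurons appear already at
w = 0.5·E(T), and the silent count saturates once every "loser" is fully
locked out (hence identical counts at w_rel = 3 and 15). The interior
(4 inhibitory neighbours) ends up less active than the border ring
(≤ 3 neighbours) on multi-seed averages, though the margin at the smallest
sweep weight is modest (~4 spikes on ~150).

## What the synthetic conditions do and do not show

All inputs are generated by the package itself under the stated laws;
passing tests show internal consistency of the analytics, the simulator and
the network dynamics under exactly these renewal/lifetime assumptions. They
do not speak to autocorrelated input streams, time-varying rates,
heavy-tailed laws, refractoriness or biophysical membrane dynamics, none of
which are modelled. Monte-Carlo checks use 1e5 intervals (3-SE bands,
KS and chi-square at significance 0.01); the grid sweep averages 5 seeds —
the same problem sizes the acceptance script reports.

## Known limitations

- Closed-form ISI analytics exist only for K = 2; larger thresholds are
  simulation-only.
- The numeric density route needs the transform of f_Z·G_τ; for custom laws
  this falls back to oscillatory quadrature per evaluation point, which is
  slow and is intended for spot checks rather than dense grids.
- Density values exactly at jump points (t = nτ in the exp/deterministic
  case) follow the series' left-limit convention and differ from the
  midpoint value any Fourier-type inversion returns there.
- The uniform-input route requires a < τ (otherwise q = 0 and the neuron
  never fires; τ ≥ b degenerates to T ≡ Z, where the inversion of the
  discontinuous uniform density is inaccurate at the support edges).
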