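# Methods

## Model

A single rate neuron receives N inputs x = (x_1 … x_N) ≥ 0 through
plastic excitatory weights v_i and a parallel fixed feed-forward
inhibitory pathway of uniform strength u that pools the same inputs.
The net drive is h = Σ_i (v_i − u) x_i, so the dynamics can be written
in *effective* weights w_i = v_i − u, bounded below by −u when the
excitatory weights are non-negative.  The activity is y = g(h) with g
linear, rectified-linear, or the saturating "bi-sigmoid"
y = σ₋ tanh(h/σ₋) for h < 0 and σ₊ tanh(h/σ₊) for h ≥ 0
(defaults σ₋ = 0.01, σ₊ = 50).

Learning follows the BCM rule with a sliding modification threshold:

    τ_w dw_i/dt = x_i F(y),      F(y) = y (y − θ)
    τ_θ dθ/dt   = −θ + y²

Potentiation occurs for y > θ, depression for 0 < y < θ, and θ tracks
the running average of y², which stabilises learning without weight
bounds.  The *weight-dependent* (soft-bound) variant multiplies the
depression branch by the excitatory weight:

    τ_w dw_i/dt = (w_i + u) x_i F(y)   when the synapse depresses,

leaving potentiation unchanged.  The relative depression Δv/v is then
weight-independent and the relative potentiation decreases with v, as
observed in plasticity experiments.  Because the depression factor
vanishes at v = 0, weights cannot cross into negative excitatory
strength: the soft bound replaces hard clipping.

Which branch applies is decided per synapse by the sign of its own
Hebbian drive x_i F.  For non-negative stimuli this is exactly the sign
of F — all synapses of a pattern potentiate or depress together — but
it generalises safely to signed inputs (the zero-mean image ensemble),
where branching on F alone would let (w_i + u) x_i F grow |v|
exponentially for synapses with x_i < 0.

With slow time constants (1/K ≪ τ_θ ≪ τ_w) the threshold can be
replaced by its stimulus average θ(w) = (1/K) Σ_k y_k², reducing
learning to an N-dimensional dynamical system in w.  All fixed-point
analysis operates on this mean-field system; the simulator integrates
the full online dynamics.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| u | feed-forward inhibition (negative = excitation) | 0 | drive per unit Σx |
| τ_w | weight time constant | 200 | presentations |
| τ_θ | threshold time constant | 20 | presentations |
| σ_y | s.d. of Gaussian output noise | 0 | activity |
| dt | integration step | 1 | presentations |
| ω | triangular tuning width fraction | 0.5 | — |
| φ | two-stimulus angle parameter | 0.4 | radians |

`default_config` sets τ_θ = 10·max(N, K) and τ_w = 10·τ_θ, the regime
in which the threshold averages the whole ensemble while weights move
slowly; the fixed points do not depend on the time constants provided
the system is stable.  The constructor warns (without failing) when
τ_w < τ_θ, where the sliding-threshold stabilisation can break down and
the divergence guard (|w| > 10⁶ or non-finite) may trip.

## Numerical integration

Stimuli arrive one per unit time in a randomly permuted, fixed sequence
that is re-used every epoch.  Within a presentation the activity is
constant, so the threshold ODE is linear with an exact solution; the
default integrator relaxes θ exponentially towards ỹ² over the interval
and feeds the *interval-averaged* threshold into the single weight
update.  This reproduces the continuous-time periodic orbit at one step
per presentation.  The distinction matters: a plain Euler step of size
dt biases the equilibrium winner response to exactly 2 − dt/τ_θ on the
two-stimulus task (2.5 % at τ_θ = 20), whereas the exponential
integrator lands within 2·10⁻⁴ of the continuous value 2.  A pure Euler
mode (`integrator="euler"`) is kept for comparison, and both plain
Euler primitives are exposed as `step_threshold` / `step_weights`.

The threshold is updated before the weights within a presentation and
both see the same activity sample; a single Gaussian noise value per
presentation perturbs the activity used in both updates, while recorded
responses are always noise-free.

A depression step multiplies v by (1 + dt/τ_w · x_i F); if that factor
would turn negative (a step large enough to jump v across zero) it is
clamped at zero and the event logged, preserving the continuous-time
invariant v ≥ 0.

Initial weights are w_i ~ Uniform(0, 0.1) (seedable), θ = 0.
Convergence is declared when the *epoch-summed* weight change falls
below 10⁻⁹·(1 + max|w|): at weight-dependent fixed points the
per-pattern updates are nonzero and cancel pairwise, so only the net
change over an epoch is meaningful.

## Equilibrium estimation and noise

Noiseless equilibria are read off the converged state.  Under output
noise the weights wander around the fixed point with an autocorrelation
time of order τ_w presentations, so equilibrium statistics are
time-averaged with `tail_average`: the run is continued seamlessly
(same permutation — a junction that re-presents a pattern twice excites
a ~τ_w transient), responses and θ are averaged over a window of many
τ_w, and standard errors come from batch means with batches longer than
the correlation time.

The analytic noisy fixed points for the mirrored unit-norm pair are
y = 1 ± √(1 − σ_y²) with θ = 2 for σ_y < 1, collapsing to y₁ = y₂ = 1,
θ = 1 + σ_y² for σ_y ≥ 1.  These hold in the mean-field limit
τ_θ → ∞; at finite τ_θ the simulated orbit carries a systematic offset
of order θ/τ_θ that no amount of averaging removes, which the validation
suite accounts for explicitly alongside the stochastic error.

## Fixed points and stability

For K = N linearly independent patterns, standard BCM has the
winner-take-all points w = K·(X⁻¹)_{:,m} (response K to pattern m, zero
to the rest, θ = K), plus the unstable origin and the symmetric point
with all responses equal to θ = 1.  For two stimuli the weight-dependent
rule adds a mirror pair of partially selective points found by the
determinant-line reduction: a fixed point with nonzero drive on both
patterns must lie on the line x₁⁽¹⁾x₂⁽²⁾(w₁+u) = x₁⁽²⁾x₂⁽¹⁾(w₂+u)
(or its mirror), reducing the search to a one-dimensional root problem,
scanned for sign changes on [−u+ε, 3·max|w_std|] and resolved by Brent's
method.  Roots are kept only when the assumed depression/potentiation
case holds; only the two single-depressor cases are solved, as the
all-depress and all-potentiate regions contain no null-clines.  For
N > 2 the case enumeration becomes non-linear in w and fixed points are
located by simulation only.

Stability uses Jacobians of the stimulus-averaged update (θ treated as
the mean-field function of w), by central finite differences with
relative step 10⁻⁶.  At the winner-take-all points the update is not
differentiable — they sit exactly on the branch switch — so every
branch assignment for patterns with vanishing drive is evaluated, and a
point is stable only if all branch Jacobians have eigenvalue real parts
below −10⁻⁸.  Where the linearisation is entirely marginal (the origin,
whose drive is quadratic) a direct probe checks for outward drive on a
small circle of perturbations.

The critical inhibition levels are closed-form in two dimensions:
u*, above which the winner-take-all points are stable and the
weight-dependent pair has merged into them, and u** < 0, at and below
which (under feed-forward *excitation*) the equilibrium pins at
w = (−u, −u) and the neuron is unselective.  Both are evaluated per
fixed point; for the mirrored parametrization they coincide and reduce
to u*(φ) = 2 sin 2φ / (cos φ + cos 3φ + sin φ − sin 3φ) and
u**(φ) = −1/(√2 sin(φ + π/4)).

Null-cline curves are extracted as zero contours of the two update
components on a (w₁, w₂) grid.  Intersections are *counted* by locating
grid cells in which both components change sign and refining each with
a two-dimensional root solve: at the winner-take-all points the two
null-clines meet in a corner of the piecewise field and discretised
contour polylines can fail to cross there, so intersection of the
polylines themselves is not reliable.  The origin never appears as a
crossing because the drive is quadratic there (no sign change); it is
reported separately.

## Stimulus ensembles and the synthetic image source

* **Mirrored pair**: x⁽¹⁾ = (cos φ, sin φ), x⁽²⁾ = (sin φ, cos φ) —
  unit vectors at angle π/2 − 2φ; φ = 0 orthogonal, φ = π/4 singular.
* **Triangular / von Mises**: circulant tuning curves over N inputs
  with periodic boundaries; circular distance is
  min(|i−k|, N−|i−k|), indices 0-based.  Note that the even-N,
  ω = 0.5 triangular matrix is *exactly* singular (its Nyquist-mode
  circulant eigenvalue vanishes), so inverse-based analysis raises a
  singularity error there; simulation is unaffected, and odd N gives a
  well-conditioned instance.
* **Image patches**: images are filtered with a balanced
  Difference-of-Gaussians kernel (isotropic Gaussians of σ = 1 and 3
  pixels — "width" is read as the standard deviation — truncated at
  4σ of the surround, each normalised to unit sum before subtraction,
  so the kernel sums to zero and annihilates constants).  Circular
  patches of exactly `patch_pixels` pixels (default 400) are cut at
  uniform random positions: the smallest disc holding at least that
  many pixels is trimmed deterministically (largest radius first,
  raster order on ties).  The whole ensemble is mapped to [0, 1] by a
  *single* affine map — per-patch scaling would destroy relative
  contrast between patches — and the zero-mean variant additionally
  shifts the scaled ensemble so its grand mean is zero (preserving the
  learning-relevant input scale).

The synthetic image generator produces greyscale noise images with a
1/f amplitude spectrum and Gaussian Fourier coefficients, matching the
second-order statistic of natural scenes that drives the DoG/whitening
pipeline.  It deliberately does *not* reproduce higher-order structure
(edges, occlusions, sparse oriented contours) of real photographs, so
image-based results are validated directionally only: the
weight-dependent rule yields a smaller weight spread on [0, 1] inputs
and a positively skewed weight distribution on zero-mean inputs.
Gabor-likeness of receptive fields is not quantified.

## Metrics

Selectivity s = max_k y_k / Σ_l y_l ∈ [1/K, 1]; negative responses
(possible transiently with a linear neuron) are clipped to zero first,
ties broken by lowest pattern index, and all-zero responses return NaN
with a warning.  The E/I imbalance m = (max_k E_k − I)/max_k E_k uses
the excitatory current E_k = Σ_i v_i x_i⁽ᵏ⁾ (v = w + u) and inhibitory
current I = u Σ_i x_i⁽ᵏ⁾, evaluated at the pattern maximising E; m = 1
at u = 0 and falls towards 0 as inhibition cancels excitation.  Weight
histograms use Freedman–Diaconis bins and adjusted Fisher–Pearson
sample skewness.  The phase diagram classifies each (φ, u) cell
analytically via u*(φ), u**(φ) and the determinant-line root search;
rows at singular φ (π/4) are masked.

## Validation problem sizes

The test-suite and the reproduction script run at desk scale: two-input
runs use 40 000–60 000 presentations (τ_θ = 20, τ_w = 200); noisy
equilibria average 8 000 two-pattern epochs in 16 batches; the
triangular experiment (N = K = 20, τ_θ = 200, τ_w = 2000) runs
1.2 × 10⁶ presentations for standard BCM (winner-take-all competition
develops slowly in high dimension) and 3 × 10⁵ per inhibition level for
the weight-dependent sweep; image experiments use 1 000 patches of 100
pixels from six 128-pixel synthetic images, rather than the 40 000
patches of 400 pixels of the full-scale configuration, which remains
the default of the image pipeline.

## Limitations

* Spike-timing-based formulations, inhibitory plasticity and recurrent
  or multi-neuron circuits are out of scope; the model is a single
  feed-forward neuron.
* The analytic weight-dependent fixed-point machinery is strictly
  two-dimensional; higher dimensions rely on simulation.
* Oscillatory/chaotic regimes at fast τ_θ are detected only by the
  divergence guard, not characterised.
* The accessibility of fixed points (all v ≥ 0) is reported per point
  rather than summarised by a closed-form threshold in u.
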