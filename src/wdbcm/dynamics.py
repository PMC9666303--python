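"""BCM learning dynamics: standard and weight-dependent rules.

The neuron computes y = g(w . x) where w are *effective* weights, the
plastic excitatory weights v minus a fixed feed-forward inhibition u
(w_i = v_i - u, hence w_i >= -u whenever v_i >= 0).  Weights follow

    tau_w dw_i/dt = x_i y (y - theta)                 (standard)
    tau_w dw_i/dt = (w_i + u) x_i y (y - theta)       (weight-dependent,
                                                       depression only)

and the modification threshold slides with the running average of the
squared activity, tau_theta dtheta/dt = -theta + y^2.  In the
weight-dependent rule depression is proportional to the excitatory
weight v_i = w_i + u (soft bound at v = 0); potentiation is unchanged.
Should v_i turn negative the same product makes the drive positive, so
the synapse only potentiates and recovers — no hard bound is needed.

Stimuli arrive one per unit time.  Within a presentation the activity
is constant, so the threshold ODE is linear and is integrated exactly
(exponential relaxation towards y^2); the weight update then uses the
time-averaged threshold over the presentation interval.  This
"exponential" integrator reproduces the continuous-time periodic orbit
at one step per presentation, where a plain Euler step of the same size
biases equilibrium responses by O(dt / tau_theta).  A pure Euler
integrator is available for comparison (``integrator="euler"``), and
both updates are exposed as the primitives :func:`step_threshold` and
:func:`step_weights`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .stimuli import StimulusEnsemble

logger = logging.getLogger(__name__)


class Rule(str, Enum):
    STANDARD = "standard"
    WEIGHT_DEPENDENT = "weight_dependent"


class ThresholdMode(str, Enum):
    ONLINE = "online"
    MEAN_FIELD = "mean_field"


@dataclass(frozen=True)
class TransferSpec:
    """Input-output transfer function of the neuron.

    ``linear`` is y = h, ``rectified`` is y = max(0, h), and
    ``bi_sigmoid`` is the saturating sigmoid used for receptive-field
    development: y = sigma_minus * tanh(h / sigma_minus) for h < 0 and
    y = sigma_plus * tanh(h / sigma_plus) otherwise, so the neuron is
    linear for small drive but saturates within (-sigma_minus,
    sigma_plus).
    """

    kind: str = "linear"
    sigma_minus: float = 0.01
    sigma_plus: float = 50.0

    def __post_init__(self):
        if self.kind not in ("linear", "rectified", "bi_sigmoid"):
            raise ValueError(f"unknown transfer kind {self.kind!r}")
        if self.sigma_minus <= 0 or self.sigma_plus <= 0:
            raise ValueError("saturation levels must be positive")


def transfer(h, spec: TransferSpec):
    """Apply the transfer function elementwise to the net input h."""
    h = np.asarray(h, dtype=float)
    if spec.kind == "linear":
        y = h
    elif spec.kind == "rectified":
        y = np.maximum(h, 0.0)
    else:
        y = np.where(
            h < 0,
            spec.sigma_minus * np.tanh(h / spec.sigma_minus),
            spec.sigma_plus * np.tanh(h / spec.sigma_plus),
        )
    return y if y.ndim else float(y)


def bcm_drive(y, theta):
    """BCM modification function F(y) = y (y - theta).

    Negative (depression) for 0 < y < theta, positive (potentiation)
    for y > theta.
    """
    return y * (y - theta)


@dataclass(frozen=True)
class PlasticityConfig:
    """Parameters of a BCM learning run.

    Time constants are in units of stimulus presentations.  The usual
    stable regime has 1/K << tau_theta << tau_w; the constructor warns
    (but does not fail) outside tau_theta >= K and tau_w >= tau_theta.
    ``sigma_y`` is the standard deviation of zero-mean Gaussian noise
    added to the post-synaptic activity once per presentation.
    """

    rule: Rule = Rule.STANDARD
    u: float = 0.0
    tau_w: float = 200.0
    tau_theta: float = 20.0
    sigma_y: float = 0.0
    transfer: TransferSpec = field(default_factory=TransferSpec)
    dt: float = 1.0
    threshold_mode: ThresholdMode = ThresholdMode.ONLINE
    integrator: str = "exponential"
    rng_seed: int = 0

    def __post_init__(self):
        if isinstance(self.rule, str):
            object.__setattr__(self, "rule", Rule(self.rule))
        if isinstance(self.threshold_mode, str):
            object.__setattr__(self, "threshold_mode", ThresholdMode(self.threshold_mode))
        if self.tau_w <= 0 or self.tau_theta <= 0:
            raise ValueError("time constants must be positive")
        if self.sigma_y < 0:
            raise ValueError("sigma_y must be non-negative")
        if self.integrator not in ("exponential", "euler"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.tau_w < self.tau_theta:
            warnings.warn(
                "tau_w < tau_theta: weights adapt faster than the threshold; "
                "the sliding-threshold stabilisation may fail",
                stacklevel=2,
            )


def default_config(ensemble: StimulusEnsemble, **overrides) -> PlasticityConfig:
    """Config with tau_theta = 10 max(N, K) and tau_w = 10 tau_theta."""
    tau_theta = 10.0 * max(ensemble.n_inputs, ensemble.n_patterns)
    base = dict(tau_theta=tau_theta, tau_w=10.0 * tau_theta)
    base.update(overrides)
    return PlasticityConfig(**base)


@dataclass
class NeuronState:
    """Effective weights w and sliding threshold theta.

    The excitatory weights are recoverable as v = w + u.
    """

    w: np.ndarray
    theta: float = 0.0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)

    def excitatory_weights(self, u: float) -> np.ndarray:
        return self.w + u

    def copy(self) -> "NeuronState":
        return NeuronState(self.w.copy(), self.theta)


@dataclass
class Trajectory:
    """Sampled time course of a learning run.

    ``responses`` holds the noise-free response to every pattern at each
    sample time (noise only enters the plasticity, not the reporting).
    """

    times: np.ndarray
    w_samples: np.ndarray
    theta_samples: np.ndarray
    responses: np.ndarray
    converged: bool
    final_state: NeuronState
    perm: np.ndarray | None = None

    def save(self, path) -> None:
        """One row per sample: time, theta, w..., y... (tab-separated)."""
        table = np.column_stack(
            [self.times, self.theta_samples, self.w_samples, self.responses]
        )
        n_w = self.w_samples.shape[1]
        n_y = self.responses.shape[1]
        header = "time\ttheta\t" + "\t".join(
            [f"w{i}" for i in range(n_w)] + [f"y{k}" for k in range(n_y)]
        )
        np.savetxt(path, table, delimiter="\t", header=header, comments="")

    def save_npz(self, path) -> None:
        """Compact binary container for long runs."""
        np.savez_compressed(
            path,
            times=self.times,
            w_samples=self.w_samples,
            theta_samples=self.theta_samples,
            responses=self.responses,
            converged=self.converged,
            final_w=self.final_state.w,
            final_theta=self.final_state.theta,
        )


class DivergenceError(RuntimeError):
    """Raised when the weights blow up or turn non-finite."""


def step_threshold(state: NeuronState, y_tilde: float, cfg: PlasticityConfig) -> NeuronState:
    """One Euler step of the sliding threshold towards y_tilde^2."""
    state.theta += (cfg.dt / cfg.tau_theta) * (y_tilde**2 - state.theta)
    return state


def step_weights(
    state: NeuronState,
    x: np.ndarray,
    cfg: PlasticityConfig,
    y_tilde: float | None = None,
) -> NeuronState:
    """One Euler step of the weight update for a single presentation.

    If ``y_tilde`` is None the noise-free activity transfer(w . x) is
    used (no noise drawn here; ``simulate`` handles noise draws so that
    the threshold and weight updates share the same sample).

    For the weight-dependent rule a depression step multiplies the
    excitatory weight v = w + u by (1 + dt/tau_w * x_i * F); if that
    factor would turn negative it is clamped at zero so v cannot jump
    across zero within one Euler step (the continuous-time rule keeps
    v >= 0), and the event is logged.
    """
    if y_tilde is None:
        y_tilde = transfer(float(state.w @ x), cfg.transfer)
    return _apply_weight_update(state, x, cfg, y_tilde, state.theta)


def _apply_weight_update(
    state: NeuronState,
    x: np.ndarray,
    cfg: PlasticityConfig,
    y_tilde: float,
    theta_eff: float,
) -> NeuronState:
    F = bcm_drive(y_tilde, theta_eff)
    if not np.isfinite(F):
        raise DivergenceError("non-finite activity in weight update")
    scale = cfg.dt / cfg.tau_w
    if cfg.rule is Rule.WEIGHT_DEPENDENT:
        # a synapse depresses when its own Hebbian drive x_i F is
        # negative; for non-negative stimuli this is simply F < 0 (the
        # post-synaptic activity alone sets the sign), but it
        # generalises safely to signed inputs (zero-mean image patches)
        depressing = x * F < 0
        if np.any(depressing):
            v = state.w + cfg.u
            factor = 1.0 + scale * x * F
            if np.any(factor[depressing] < 0):
                logger.warning(
                    "depression step clamped: dt/tau_w * x * |F| >= 1 "
                    "(F=%g); consider a smaller dt", F,
                )
                factor = np.maximum(factor, 0.0)
            state.w = np.where(depressing, v * factor - cfg.u, state.w + scale * x * F)
        else:
            state.w = state.w + scale * x * F
    else:
        state.w = state.w + scale * x * F
    return state


def _present(state: NeuronState, x: np.ndarray, y_tilde: float, cfg: PlasticityConfig) -> None:
    """Advance state by one presentation of pattern x with activity y_tilde.

    The exponential integrator relaxes theta exactly towards y_tilde^2
    over the interval dt and feeds the interval-averaged threshold into
    the weight update; the Euler integrator applies the two plain Euler
    primitives in sequence (threshold first).
    """
    if cfg.integrator == "euler":
        step_threshold(state, y_tilde, cfg)
        _apply_weight_update(state, x, cfg, y_tilde, state.theta)
        return
    r = cfg.dt / cfg.tau_theta
    decay = np.exp(-r)
    target = y_tilde**2
    theta_bar = target + (state.theta - target) * (1.0 - decay) / r
    state.theta = target + (state.theta - target) * decay
    _apply_weight_update(state, x, cfg, y_tilde, theta_bar)


def mean_field_theta(responses, sigma_y: float = 0.0) -> float:
    """Stimulus-averaged threshold theta = (1/K) sum_k y_k^2 (+ sigma_y^2).

    The ``sigma_y`` term is the mean-field correction for Gaussian
    post-synaptic noise, E[y_tilde^2] = y^2 + sigma_y^2.
    """
    responses = np.asarray(responses, dtype=float)
    return float(np.mean(responses**2) + sigma_y**2)


def initial_state(n_inputs: int, seed: int) -> NeuronState:
    """Small random initial weights w_i ~ Uniform(0, 0.1), theta = 0."""
    rng = np.random.default_rng(seed)
    return NeuronState(rng.uniform(0.0, 0.1, size=n_inputs), 0.0)


def simulate(
    ensemble: StimulusEnsemble,
    cfg: PlasticityConfig,
    init: NeuronState | int | None = None,
    n_presentations: int = 50_000,
    record_every: int = 50,
    convergence_tol: float = 1e-9,
) -> Trajectory:
    """Run BCM learning on an ensemble of stimuli.

    Stimuli are presented in a randomly permuted, fixed sequence: one
    permutation of the K patterns is drawn up front and cycled every
    epoch.  Convergence is declared when the epoch-summed weight change
    satisfies max_i |sum-over-epoch dw_i| < tol * (1 + max_i |w_i|)
    (summing over the epoch matters for weight-dependent fixed points,
    where per-pattern updates are nonzero but cancel pairwise).

    ``init`` may be a NeuronState, an integer seed for the default small
    random initialisation, or None (uses cfg.rng_seed).
    """
    X = ensemble.patterns
    K, N = X.shape
    if n_presentations < K:
        raise ValueError("need at least one full epoch of presentations")
    rng = np.random.default_rng(cfg.rng_seed)
    if init is None:
        state = initial_state(N, cfg.rng_seed)
    elif isinstance(init, (int, np.integer)):
        state = initial_state(N, int(init))
    else:
        state = init.copy()

    perm = rng.permutation(K)
    noisy = cfg.sigma_y > 0
    mean_field = cfg.threshold_mode is ThresholdMode.MEAN_FIELD

    times, w_samples, theta_samples, responses = [], [], [], []
    converged = False
    w_epoch_start = state.w.copy()

    for t in range(n_presentations):
        k = perm[t % K]
        x = X[k]
        h = float(state.w @ x)
        y = transfer(h, cfg.transfer)
        y_tilde = y + rng.normal(0.0, cfg.sigma_y) if noisy else y
        if mean_field:
            state.theta = mean_field_theta(
                transfer(X @ state.w, cfg.transfer), cfg.sigma_y
            )
            _apply_weight_update(state, x, cfg, y_tilde, state.theta)
        else:
            _present(state, x, y_tilde, cfg)

        if not np.all(np.isfinite(state.w)) or np.max(np.abs(state.w)) > 1e6:
            raise DivergenceError(
                f"weights diverged at presentation {t} "
                f"(rule={cfg.rule.value}, u={cfg.u}, tau_w={cfg.tau_w}, "
                f"tau_theta={cfg.tau_theta}): |w| exceeded bound or is non-finite"
            )
        if t % record_every == 0:
            times.append(t)
            w_samples.append(state.w.copy())
            theta_samples.append(state.theta)
            responses.append(transfer(X @ state.w, cfg.transfer))
        if (t + 1) % K == 0:
            dw = np.max(np.abs(state.w - w_epoch_start))
            if dw < convergence_tol * (1.0 + np.max(np.abs(state.w))):
                converged = True
            w_epoch_start = state.w.copy()

    return Trajectory(
        times=np.asarray(times),
        w_samples=np.asarray(w_samples),
        theta_samples=np.asarray(theta_samples),
        responses=np.asarray(responses),
        converged=converged,
        final_state=state,
        perm=perm,
    )


def tail_average(
    ensemble: StimulusEnsemble,
    cfg: PlasticityConfig,
    state: NeuronState | Trajectory,
    n_epochs: int = 10,
    n_batches: int = 1,
) -> dict:
    """Continue a run for ``n_epochs`` epochs and time-average it.

    Time-averages the noise-free responses and the threshold over the
    window and estimates standard errors by the batch-means method:
    the window is split into ``n_batches`` contiguous blocks and the SE
    is the spread of the block means (with ``n_batches=1`` the epoch
    means themselves are the blocks).  Under noise the weights wander
    around the fixed point with an autocorrelation time of order tau_w
    presentations, so the window should span several tau_w and batches
    should be longer than the correlation time for the SE to be honest.

    Passing the Trajectory itself (rather than its final state)
    continues with the *same* presentation permutation, keeping the
    periodic orbit seamless; a fresh permutation at the junction can
    re-present the same pattern twice in a row and excite a transient
    of duration ~tau_w that biases short averaging windows.

    Returns the means, SEs, the per-epoch means (for derived
    statistics) and the continued final state.
    """
    X = ensemble.patterns
    K = ensemble.n_patterns
    cfg_cont = replace(cfg, rng_seed=cfg.rng_seed + 1)
    rng = np.random.default_rng(cfg_cont.rng_seed)
    if isinstance(state, Trajectory):
        perm = state.perm if state.perm is not None else rng.permutation(K)
        st = state.final_state.copy()
    else:
        perm = rng.permutation(K)
        st = state.copy()
    epoch_resp = np.empty((n_epochs, K))
    epoch_theta = np.empty(n_epochs)
    for e in range(n_epochs):
        resp_acc = np.zeros(K)
        theta_acc = 0.0
        for j in range(K):
            x = X[perm[j]]
            y = transfer(float(st.w @ x), cfg_cont.transfer)
            y_tilde = y + rng.normal(0.0, cfg_cont.sigma_y) if cfg_cont.sigma_y > 0 else y
            _present(st, x, y_tilde, cfg_cont)
            resp_acc += transfer(X @ st.w, cfg_cont.transfer)
            theta_acc += st.theta
        epoch_resp[e] = resp_acc / K
        epoch_theta[e] = theta_acc / K
    n_batches = max(1, min(n_batches, n_epochs))
    blocks = np.array_split(epoch_resp, n_batches) if n_batches > 1 else [
        epoch_resp[e : e + 1] for e in range(n_epochs)
    ]
    batch_means = np.array([b.mean(axis=0) for b in blocks])
    theta_blocks = np.array_split(epoch_theta, n_batches) if n_batches > 1 else [
        epoch_theta[e : e + 1] for e in range(n_epochs)
    ]
    theta_means = np.array([b.mean() for b in theta_blocks])
    nb = batch_means.shape[0]
    resp_se = batch_means.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.zeros(K)
    theta_se = float(theta_means.std(ddof=1) / np.sqrt(nb)) if nb > 1 else 0.0
    return {
        "responses": epoch_resp.mean(axis=0),
        "responses_se": resp_se,
        "batch_means": batch_means,
        "epoch_means": epoch_resp,
        "theta": float(epoch_theta.mean()),
        "theta_se": theta_se,
        "final_state": st,
    }
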