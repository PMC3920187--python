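"""Rate-coded competitive network of the intermediate superior colliculus (SC).

The model is a one-dimensional field of ``N`` leaky rate nodes.  The left half
of the field represents the left SC and receives a stimulus-driven *reactive*
input (the prosaccade command); the right half represents the right SC and
receives a stronger, later *planned* input (the volitional antisaccade
command).  All nodes interact through a distance-dependent lateral kernel —
short-range excitation, long-range (including cross-hemifield) inhibition —
which makes the two input pools compete: whichever pool approaches the firing
threshold first suppresses the other.

Node dynamics
-------------
The internal state ``x_i`` of node ``i`` evolves as

    dx_i/dt = tau_i * ( -x_i + sum_j w_ij A_j + I_ext,i(t) + I_n,i )

where ``tau_i`` is a per-node integration *rate* (ms^-1), ``w_ij`` the lateral
kernel, ``I_ext`` the external input and ``I_n`` Gaussian background noise.
The activity (mean firing rate) is a shifted logistic of the state,

    A_i = 1 / (1 + exp(-beta * x_i)) - theta,

bounded in the open interval ``(-theta, 1 - theta)``.  Under the default
``tau_semantics="rate"`` a *larger* tau integrates *faster* (implied membrane
time constants 1/tau of roughly 60-250 ms); the alternative
``"time_constant"`` semantics divides by tau instead.

The lateral kernel is a shifted Gaussian of inter-node distance,

    w_ij = B * ( g(|i-j| * dx) - C ),      dx = 2*pi/N,

where ``g`` is a Gaussian of spatial width ``sigma``.  Two normalizations are
available: ``kernel_norm="paper"`` scales the Gaussian by ``1/(4*pi*sigma)``
(with the default parameters this makes *every* weight inhibitory and no node
can ever reach threshold), while ``"unnormalized"`` drops that factor so that
near-neighbour weights are excitatory and the winner-take-all competition the
architecture calls for can actually arise.  See
:mod:`saccade_race.experiment` for the one-time amplitude calibration.

Two conventions deserve a note because the equations alone underdetermine
them (see docs/methods.md for the full account):

* **Rectified transmission** (``lateral_rectify``, default on): activities
  entering the lateral sum are clipped at zero, ``max(A, 0) @ W``.  With the
  shifted sigmoid, suppressed nodes would otherwise transmit *negative*
  activity through the constant inhibitory surround — i.e. excite their
  competitors — and the hemifield activity sums cancel, neutralizing the
  competition entirely.  Firing rates are non-negative; the readout and the
  state dynamics are unchanged.
* **Noise granularity** (``noise_mode``, default ``"per_trial"``): the
  background current I_n is drawn once per node per trial and held for the
  whole trial.  Under fixed-step Euler a fresh per-step draw (the
  ``"per_step"`` option) averages to state fluctuations of order 1e-4 and
  the noise would play no dynamical role.

Integration is fixed-step explicit Euler with no sqrt(dt) noise rescaling,
which keeps trials exactly reproducible from a seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .exceptions import NumericalInstabilityError, ParameterError

#: 1-based labels of the nodes driven by the reactive (stimulus) input, in the
#: left SC, and by the planned (antisaccade) input, in the right SC.
REACTIVE_NODES = (18, 19, 20, 21, 22)
PLANNED_NODES = (78, 79, 80, 81, 82)

#: Central node of each pool: the node whose activity is read out against the
#: decision threshold.  Node 20 encodes the error prosaccade, node 80 the
#: (correct) antisaccade.
ERROR_NODE = 20
CORRECT_NODE = 80


def node_index(label: int) -> int:
    """0-based array index of a 1-based node label."""
    return label - 1


@dataclasses.dataclass(frozen=True)
class NetworkParams:
    """Full specification of one simulation condition.

    Defaults are the control-condition values of the model's parameter table.
    The patient (schizophrenia) condition differs only in the four
    integration-rate distribution parameters; see
    :func:`saccade_race.experiment.patient_condition`.
    """

    n_nodes: int = 100
    beta: float = 0.5
    theta: float = 0.5
    threshold: float = 0.1791
    kernel_amplitude: float = 1.0
    kernel_offset: float = 0.35
    kernel_sigma: float = 2.0 * math.pi / 10.0
    kernel_norm: str = "paper"  # "paper" | "unnormalized"
    input_reactive: float = 1.0
    input_planned: float = 1.5
    tau_mean_left: float = 0.01685
    tau_sd_left: float = 0.003
    tau_mean_right: float = 0.0065
    tau_sd_right: float = 0.0016
    tau_semantics: str = "rate"  # "rate" | "time_constant"
    tau_granularity: str = "per_hemisphere"  # "per_hemisphere" | "per_node"
    noise_mean: float = 0.0
    noise_sd: float = 0.05
    noise_mode: str = "per_trial"  # "per_trial" | "per_step"
    lateral_rectify: bool = True
    planned_delay_ms: float = 50.0
    planned_onset_mode: str = "relative"  # "relative" | "absolute"
    reactive_onset_ms: float = 50.0
    input_duration_ms: float = 600.0
    sim_duration_ms: float = 650.0
    dt_ms: float = 0.5
    efferent_delay_ms: float = 30.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        p = self
        if p.n_nodes <= 0 or p.n_nodes % 2 != 0:
            raise ParameterError(f"n_nodes must be a positive even integer, got {p.n_nodes}")
        if p.kernel_sigma <= 0:
            raise ParameterError(f"kernel_sigma must be > 0, got {p.kernel_sigma}")
        if p.kernel_norm not in ("paper", "unnormalized"):
            raise ParameterError(f"kernel_norm must be 'paper' or 'unnormalized', got {p.kernel_norm!r}")
        if p.tau_semantics not in ("rate", "time_constant"):
            raise ParameterError(f"tau_semantics must be 'rate' or 'time_constant', got {p.tau_semantics!r}")
        if p.tau_granularity not in ("per_node", "per_hemisphere"):
            raise ParameterError(
                f"tau_granularity must be 'per_node' or 'per_hemisphere', got {p.tau_granularity!r}"
            )
        if p.noise_mode not in ("per_trial", "per_step"):
            raise ParameterError(f"noise_mode must be 'per_trial' or 'per_step', got {p.noise_mode!r}")
        if p.planned_onset_mode not in ("relative", "absolute"):
            raise ParameterError(f"planned_onset_mode must be 'relative' or 'absolute', got {p.planned_onset_mode!r}")
        # I_p > I_r is the architecture's premise; I_p == 0 is permitted so the
        # planned pathway can be disabled in lesion-style runs.
        if p.input_planned != 0 and p.input_planned <= p.input_reactive:
            raise ParameterError(
                f"input_planned must exceed input_reactive (or be 0 to disable), "
                f"got I_p={p.input_planned} <= I_r={p.input_reactive}"
            )
        for name in ("tau_sd_left", "tau_sd_right", "noise_sd"):
            if getattr(p, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(p, name)}")
        for name in ("tau_mean_left", "tau_mean_right"):
            if getattr(p, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(p, name)}")
        if p.dt_ms <= 0:
            raise ParameterError(f"dt_ms must be > 0, got {p.dt_ms}")
        if p.sim_duration_ms < p.reactive_onset_ms + p.planned_delay_ms:
            raise ParameterError(
                "sim_duration_ms must cover reactive_onset_ms + planned_delay_ms"
            )
        if not 0 < p.threshold < 1 - p.theta:
            raise ParameterError(
                f"threshold must lie in (0, 1-theta) = (0, {1 - p.theta}), got {p.threshold}"
            )

    # -- derived geometry ---------------------------------------------------

    @property
    def node_spacing(self) -> float:
        """Radians per node, dx = 2*pi/N."""
        return 2.0 * math.pi / self.n_nodes

    @property
    def planned_onset_ms(self) -> float:
        """Trial time at which the planned input switches on."""
        if self.planned_onset_mode == "relative":
            return self.reactive_onset_ms + self.planned_delay_ms
        return self.planned_delay_ms

    @property
    def n_steps(self) -> int:
        return int(round(self.sim_duration_ms / self.dt_ms))

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times 0, dt, ..., sim_duration."""
        return np.arange(self.n_steps + 1) * self.dt_ms

    def replace(self, **changes) -> "NetworkParams":
        return dataclasses.replace(self, **changes)

    def left_nodes(self) -> np.ndarray:
        """0-based indices of the left SC (first half of the field)."""
        return np.arange(self.n_nodes // 2)

    def right_nodes(self) -> np.ndarray:
        return np.arange(self.n_nodes // 2, self.n_nodes)


@dataclasses.dataclass(frozen=True)
class LateralKernel:
    """N x N matrix of synaptic efficacies w_ij (dimensionless)."""

    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclasses.dataclass(frozen=True)
class NetworkState:
    """Network state at one instant: time, internal states, activities."""

    t_ms: float
    x: np.ndarray
    a: np.ndarray


def build_kernel(params: NetworkParams) -> LateralKernel:
    """Construct the lateral-interaction kernel.

    Distances are linear (non-wrapped) multiples of the node spacing; the
    matrix is symmetric and translation invariant, and for large distances the
    Gaussian term vanishes so w -> -B*C (constant long-range inhibition).
    """
    n = params.n_nodes
    sig = params.kernel_sigma
    if sig <= 0:
        raise ParameterError(f"kernel_sigma must be > 0, got {sig}")
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]) * params.node_spacing
    gauss = np.exp(-(d ** 2) / (4.0 * sig ** 2))
    if params.kernel_norm == "paper":
        gauss = gauss / (4.0 * math.pi * sig)
    w = params.kernel_amplitude * (gauss - params.kernel_offset)
    return LateralKernel(weights=w)


def activation(x: np.ndarray, beta: float, theta: float) -> np.ndarray:
    """Shifted logistic activity A = 1/(1 + exp(-beta*x)) - theta.

    Strictly increasing in x, saturating in (-theta, 1-theta); evaluated in a
    form that never overflows for large |x|.
    """
    x = np.asarray(x, dtype=float)
    # scipy.special.expit semantics without the import cost in the hot loop
    out = np.empty_like(x)
    pos = x >= 0
    np.exp(-beta * x, where=pos, out=out)
    out[pos] = 1.0 / (1.0 + out[pos])
    ex = np.exp(beta * x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out - theta


def external_input(params: NetworkParams, t_ms: float) -> np.ndarray:
    """External input vector at trial time ``t_ms``.

    The reactive input drives nodes 18-22 (left SC) with strength I_r from
    ``reactive_onset_ms``; the planned input drives the mirror pool 78-82
    (right SC) with strength I_p from ``planned_onset_ms``.  Each input stays
    on for ``input_duration_ms``.
    """
    if params.n_nodes < PLANNED_NODES[-1]:
        raise ParameterError(
            f"input geometry requires n_nodes >= {PLANNED_NODES[-1]}, got {params.n_nodes}"
        )
    vec = np.zeros(params.n_nodes)
    t0 = params.reactive_onset_ms
    if t0 <= t_ms < t0 + params.input_duration_ms:
        vec[[node_index(k) for k in REACTIVE_NODES]] = params.input_reactive
    t1 = params.planned_onset_ms
    if t1 <= t_ms < t1 + params.input_duration_ms:
        vec[[node_index(k) for k in PLANNED_NODES]] = params.input_planned
    return vec


def input_time_course(params: NetworkParams) -> np.ndarray:
    """(n_steps, n_nodes) external input evaluated at the left edge of each step."""
    steps = np.arange(params.n_steps) * params.dt_ms
    out = np.zeros((params.n_steps, params.n_nodes))
    r_idx = [node_index(k) for k in REACTIVE_NODES]
    p_idx = [node_index(k) for k in PLANNED_NODES]
    t0, t1 = params.reactive_onset_ms, params.planned_onset_ms
    dur = params.input_duration_ms
    out[np.ix_((steps >= t0) & (steps < t0 + dur), r_idx)] = params.input_reactive
    out[np.ix_((steps >= t1) & (steps < t1 + dur), p_idx)] = params.input_planned
    return out


def rate_vector(params: NetworkParams, tau_left, tau_right) -> np.ndarray:
    """Per-node integration rate (ms^-1) from the hemispheric draws.

    ``tau_left``/``tau_right`` are scalars (per-hemisphere draws) or length
    n_nodes/2 arrays (per-node draws).
    """
    tau_left = np.asarray(tau_left, dtype=float)
    tau_right = np.asarray(tau_right, dtype=float)
    if np.any(tau_left <= 0) or np.any(tau_right <= 0):
        raise ParameterError("integration-rate draws must be strictly positive")
    half = params.n_nodes // 2
    vec = np.empty(params.n_nodes)
    if params.tau_semantics == "rate":
        vec[:half], vec[half:] = tau_left, tau_right
    else:
        vec[:half], vec[half:] = 1.0 / tau_left, 1.0 / tau_right
    return vec


def step_state(
    state: NetworkState,
    kernel: LateralKernel,
    params: NetworkParams,
    tau_vector: np.ndarray,
    noise_draw: np.ndarray,
    dt_ms: float | None = None,
) -> NetworkState:
    """Advance the state by one explicit Euler step.

    ``tau_vector`` is the per-node rate (ms^-1, already converted per
    ``tau_semantics``); ``noise_draw`` is the per-node noise current held
    constant over the step.
    """
    dt = params.dt_ms if dt_ms is None else dt_ms
    if dt <= 0:
        raise ParameterError(f"dt_ms must be > 0, got {dt}")
    i_ext = external_input(params, state.t_ms)
    a_out = np.maximum(state.a, 0.0) if params.lateral_rectify else state.a
    drive = a_out @ kernel.weights + i_ext + noise_draw - state.x
    x_new = state.x + dt * np.asarray(tau_vector) * drive
    if not np.all(np.isfinite(x_new)):
        raise NumericalInstabilityError(
            f"non-finite state after Euler step of dt_ms={dt}"
        )
    return NetworkState(t_ms=state.t_ms + dt, x=x_new, a=activation(x_new, params.beta, params.theta))


def initial_state(params: NetworkParams) -> NetworkState:
    """Baseline state x(0) = 0 (the rise-to-threshold starting level S_0)."""
    x0 = np.zeros(params.n_nodes)
    return NetworkState(t_ms=0.0, x=x0, a=activation(x0, params.beta, params.theta))


_FINITE_CHECK_EVERY = 64


def integrate_batch(
    params: NetworkParams,
    kernel: LateralKernel,
    rates: np.ndarray,
    noise: np.ndarray,
    record_nodes: Sequence[int] = (ERROR_NODE, CORRECT_NODE),
) -> np.ndarray:
    """Integrate ``m`` independent trials at once and record selected nodes.

    Parameters
    ----------
    rates : (m, n_nodes) per-node integration rates (ms^-1).
    noise : (n_steps, m, n_nodes) noise currents per node per step, or
        (1, m, n_nodes) for a per-trial constant noise current.
    record_nodes : 1-based labels of nodes whose activity traces to keep.

    Returns
    -------
    traces : (n_steps + 1, m, len(record_nodes)) activity at each sample time.
    """
    n_steps = params.n_steps
    m = rates.shape[0]
    if noise.shape not in ((n_steps, m, params.n_nodes), (1, m, params.n_nodes)):
        raise ParameterError(
            f"noise must have shape {(n_steps, m, params.n_nodes)} or "
            f"{(1, m, params.n_nodes)}, got {noise.shape}"
        )
    static_noise = noise.shape[0] == 1
    w = kernel.weights
    beta, theta = params.beta, params.theta
    dt = params.dt_ms
    dtr = dt * rates
    i_ext = input_time_course(params)
    rec = [node_index(k) for k in record_nodes]
    x = np.zeros((m, params.n_nodes))
    traces = np.empty((n_steps + 1, m, len(rec)))
    rectify = params.lateral_rectify
    # divergence is detected and reported; suppress the intermediate
    # overflow warnings it would otherwise spray
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n_steps):
            a = activation(x, beta, theta)
            traces[k] = a[:, rec]
            drive = (np.maximum(a, 0.0) if rectify else a) @ w
            drive += i_ext[k]
            drive += noise[0] if static_noise else noise[k]
            drive -= x
            x += dtr * drive
            if k % _FINITE_CHECK_EVERY == 0 and not np.all(np.isfinite(x)):
                raise NumericalInstabilityError(
                    f"non-finite state near t={k * dt:.1f} ms with dt_ms={dt}"
                )
    if not np.all(np.isfinite(x)):
        raise NumericalInstabilityError(f"non-finite final state with dt_ms={dt}")
    traces[n_steps] = activation(x, beta, theta)[:, rec]
    return traces
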