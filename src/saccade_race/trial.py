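"""Single-trial engine: threshold crossings, outcome classes, reaction times.

One antisaccade trial draws an integration rate per hemisphere (the
LATER-style trial-to-trial rate variability that is the model's stochastic
core), integrates the network for the full trial duration, and reads out the
first threshold crossing of the error-encoding node (node 20, reactive input)
and of the correct-encoding node (node 80, planned input).

Outcome classes
---------------
* ``antisaccade`` — only the correct node crossed.
* ``error_prosaccade_uncorrected`` — only the error node crossed.
* ``corrected_antisaccade`` — the error node crossed and the correct node
  crossed afterwards (an error prosaccade followed by a corrective
  antisaccade).
* ``no_response`` — neither node reached threshold within the trial.

Reaction times are stimulus-locked (crossing time minus reactive-input onset)
plus a 30 ms efferent delay for the eye-muscle conduction time; the corrected
antisaccade latency is the bare interval between the two crossings (the
efferent delays cancel).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from . import network
from .exceptions import InvalidInputError, ParameterError
from .network import CORRECT_NODE, ERROR_NODE, LateralKernel, NetworkParams

OUTCOME_ANTI = "antisaccade"
OUTCOME_ERROR = "error_prosaccade_uncorrected"
OUTCOME_CORRECTED = "corrected_antisaccade"
OUTCOME_NONE = "no_response"
OUTCOMES = (OUTCOME_ANTI, OUTCOME_ERROR, OUTCOME_CORRECTED, OUTCOME_NONE)

_MAX_TAU_REDRAWS = 1000


@dataclasses.dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated antisaccade trial."""

    outcome: str
    t_cross_error_ms: Optional[float]
    t_cross_correct_ms: Optional[float]
    rt_error_ms: Optional[float]
    rt_anti_ms: Optional[float]
    rt_corrected_ms: Optional[float]
    tau_left: float
    tau_right: float
    seed: int
    tau_redraws: int = 0

    @property
    def rt_corrected_total_ms(self) -> Optional[float]:
        """Stimulus-locked corrected-antisaccade latency (inter-crossing
        interval plus the error-prosaccade latency); the alternative
        convention used in some summaries of the delay sweep."""
        if self.rt_corrected_ms is None or self.rt_error_ms is None:
            return None
        return self.rt_corrected_ms + self.rt_error_ms


def detect_crossing(times_ms, trace, threshold) -> Optional[float]:
    """First time the trace reaches ``threshold`` (>= comparison).

    Linearly interpolates between the bracketing samples; returns None if the
    trace never reaches threshold.
    """
    trace = np.asarray(trace, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if trace.size == 0:
        raise InvalidInputError("empty trace")
    if trace.shape != times_ms.shape:
        raise InvalidInputError("times and trace must have equal length")
    above = trace >= threshold
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return float(times_ms[0])
    y0, y1 = trace[k - 1], trace[k]
    frac = (threshold - y0) / (y1 - y0)
    return float(times_ms[k - 1] + frac * (times_ms[k] - times_ms[k - 1]))


def classify(t_cross_error: Optional[float], t_cross_correct: Optional[float]) -> str:
    """Outcome label from the pair of (possibly absent) crossing times."""
    if t_cross_error is None and t_cross_correct is None:
        return OUTCOME_NONE
    if t_cross_error is None:
        return OUTCOME_ANTI
    if t_cross_correct is None:
        return OUTCOME_ERROR
    return OUTCOME_CORRECTED


def draw_tau(rng: np.random.Generator, mean: float, sd: float) -> tuple[float, int]:
    """Draw a strictly positive integration rate, rejecting non-positive values.

    Returns (value, number_of_redraws).
    """
    if sd == 0:
        if mean <= 0:
            raise ParameterError("tau mean must be > 0 when sd == 0")
        return float(mean), 0
    redraws = 0
    while True:
        value = rng.normal(mean, sd)
        if value > 0:
            return float(value), redraws
        redraws += 1
        if redraws > _MAX_TAU_REDRAWS:
            raise ParameterError(
                f"could not draw a positive rate from Normal({mean}, {sd})"
            )


def draw_tau_vector(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> tuple[np.ndarray, int]:
    """Vector of strictly positive rate draws with per-element rejection."""
    if sd == 0:
        if mean <= 0:
            raise ParameterError("tau mean must be > 0 when sd == 0")
        return np.full(size, float(mean)), 0
    values = rng.normal(mean, sd, size=size)
    redraws = 0
    bad = values <= 0
    while bad.any():
        n_bad = int(bad.sum())
        redraws += n_bad
        if redraws > _MAX_TAU_REDRAWS * size:
            raise ParameterError(
                f"could not draw positive rates from Normal({mean}, {sd})"
            )
        values[bad] = rng.normal(mean, sd, size=n_bad)
        bad = values <= 0
    return values, redraws


def build_trial_result(
    t_cross_error: Optional[float],
    t_cross_correct: Optional[float],
    params: NetworkParams,
    tau_left: float,
    tau_right: float,
    seed: int = 0,
    tau_redraws: int = 0,
) -> TrialResult:
    """Assemble RTs and the outcome label from the two crossing times."""
    outcome = classify(t_cross_error, t_cross_correct)
    onset = params.reactive_onset_ms
    eff = params.efferent_delay_ms
    rt_error = None if t_cross_error is None else t_cross_error - onset + eff
    rt_anti = (
        t_cross_correct - onset + eff if outcome == OUTCOME_ANTI else None
    )
    rt_corrected = (
        t_cross_correct - t_cross_error if outcome == OUTCOME_CORRECTED else None
    )
    return TrialResult(
        outcome=outcome,
        t_cross_error_ms=t_cross_error,
        t_cross_correct_ms=t_cross_correct,
        rt_error_ms=rt_error,
        rt_anti_ms=rt_anti,
        rt_corrected_ms=rt_corrected,
        tau_left=tau_left,
        tau_right=tau_right,
        seed=seed,
        tau_redraws=tau_redraws,
    )


def draw_trial_inputs(params: NetworkParams, rng: np.random.Generator):
    """Draw everything stochastic for one trial, in a fixed stream order.

    Order: left rate (with rejections), right rate (with rejections), then the
    noise currents — one (n_nodes,) draw held for the whole trial under
    ``noise_mode="per_trial"``, or an (n_steps, n_nodes) matrix under
    ``"per_step"``.  Both the scalar trial runner and the vectorized ensemble
    runner consume the stream identically.  Returns the noise with a leading
    step axis of length 1 (per-trial) or n_steps (per-step).
    """
    half = params.n_nodes // 2
    if params.tau_granularity == "per_node":
        tau_left, redraws_l = draw_tau_vector(
            rng, params.tau_mean_left, params.tau_sd_left, half
        )
        tau_right, redraws_r = draw_tau_vector(
            rng, params.tau_mean_right, params.tau_sd_right, half
        )
    else:
        tau_left, redraws_l = draw_tau(rng, params.tau_mean_left, params.tau_sd_left)
        tau_right, redraws_r = draw_tau(rng, params.tau_mean_right, params.tau_sd_right)
    n_rows = 1 if params.noise_mode == "per_trial" else params.n_steps
    noise = params.noise_mean + params.noise_sd * rng.standard_normal(
        (n_rows, params.n_nodes)
    )
    return tau_left, tau_right, redraws_l + redraws_r, noise


def run_trial(
    params: NetworkParams,
    kernel: LateralKernel,
    rng: np.random.Generator,
    seed: int = 0,
) -> TrialResult:
    """Run one full trial and classify its outcome.

    ``seed`` is recorded in the result for provenance; the randomness itself
    comes from ``rng``.
    """
    tau_left, tau_right, redraws, noise = draw_trial_inputs(params, rng)
    rates = network.rate_vector(params, tau_left, tau_right)[None, :]
    traces = network.integrate_batch(
        params, kernel, rates, noise[:, None, :], record_nodes=(ERROR_NODE, CORRECT_NODE)
    )
    times = params.times_ms
    t_err = detect_crossing(times, traces[:, 0, 0], params.threshold)
    t_corr = detect_crossing(times, traces[:, 0, 1], params.threshold)
    return build_trial_result(
        t_err,
        t_corr,
        params,
        float(np.mean(tau_left)),
        float(np.mean(tau_right)),
        seed=seed,
        tau_redraws=redraws,
    )


def first_crossings_batch(times_ms: np.ndarray, traces: np.ndarray, threshold: float):
    """Vectorized first-crossing detection for a (n_samples, m) trace array.

    Returns an object array of crossing times (None where never crossed).
    """
    n_samples, m = traces.shape
    above = traces >= threshold
    crossed = above.any(axis=0)
    k = above.argmax(axis=0)
    out = np.empty(m, dtype=object)
    out[:] = None
    for j in np.nonzero(crossed)[0]:
        kj = k[j]
        if kj == 0:
            out[j] = float(times_ms[0])
        else:
            y0, y1 = traces[kj - 1, j], traces[kj, j]
            frac = (threshold - y0) / (y1 - y0)
            out[j] = float(times_ms[kj - 1] + frac * (times_ms[kj] - times_ms[kj - 1]))
    return out
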