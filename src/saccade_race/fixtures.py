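"""Deterministic small inputs for tests and demos."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import ndtri

from .exceptions import FixtureError
from .experiment import control_condition, run_ensemble

FIXTURE_KINDS = ("tiny-ensemble", "recinormal-rts", "degenerate")


@dataclasses.dataclass(frozen=True)
class RecinormalRTs:
    """RTs whose reciprocals follow an exact (stratified) normal sample.

    1/RT takes the values m + s * probit(p_k) on a shuffled midpoint grid of
    probabilities, so the theoretical median ``median_ms`` = 1/m is recovered
    exactly in the large-n limit.
    """

    rts: np.ndarray
    median_ms: float
    rate_mean: float
    rate_sd: float


def make_fixture(kind: str, seed: int = 0, n: int = 10_000):
    """Build one of the named deterministic fixtures.

    * ``tiny-ensemble`` — a 20-trial control ensemble.
    * ``recinormal-rts`` — n RTs with exact recinormal structure (median 300 ms).
    * ``degenerate`` — 50 identical RTs (flat distribution, CV = 0).
    """
    if kind == "tiny-ensemble":
        return run_ensemble(control_condition(), ntrials=20, master_seed=seed)
    if kind == "recinormal-rts":
        median_ms = 300.0
        m = 1.0 / median_ms
        s = m / 5.0
        rng = np.random.default_rng(seed)
        p = (np.arange(n) + 0.5) / n
        rng.shuffle(p)
        rates = m + s * ndtri(p)
        return RecinormalRTs(
            rts=1.0 / rates, median_ms=median_ms, rate_mean=m, rate_sd=s
        )
    if kind == "degenerate":
        return np.full(50, 250.0)
    raise FixtureError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
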