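"""Trial-record CSV serialization (RFC 4180, '.' decimals, UTF-8).

One row per trial; absent values are empty fields, never 0.  Reals are
written with 17 significant digits so the round-trip is bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .experiment import ConditionSpec, Ensemble
from .trial import OUTCOMES, TrialResult

COLUMNS = [
    "trial",
    "condition",
    "seed",
    "outcome",
    "t_cross_error_ms",
    "t_cross_correct_ms",
    "rt_error_ms",
    "rt_anti_ms",
    "rt_corrected_ms",
    "tau_left",
    "tau_right",
    "tau_redraws",
    "master_seed",
]

_FLOAT_COLS = [
    "t_cross_error_ms",
    "t_cross_correct_ms",
    "rt_error_ms",
    "rt_anti_ms",
    "rt_corrected_ms",
    "tau_left",
    "tau_right",
]


def ensemble_frame(ensemble: Ensemble) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(ensemble.trials):
        rows.append(
            {
                "trial": i,
                "condition": ensemble.condition.name,
                "seed": t.seed,
                "outcome": t.outcome,
                "t_cross_error_ms": t.t_cross_error_ms,
                "t_cross_correct_ms": t.t_cross_correct_ms,
                "rt_error_ms": t.rt_error_ms,
                "rt_anti_ms": t.rt_anti_ms,
                "rt_corrected_ms": t.rt_corrected_ms,
                "tau_left": t.tau_left,
                "tau_right": t.tau_right,
                "tau_redraws": t.tau_redraws,
                "master_seed": ensemble.master_seed,
            }
        )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_ensemble(ensemble: Ensemble, path) -> None:
    df = ensemble_frame(ensemble)
    df.to_csv(path, index=False, float_format="%.17g")


def read_ensemble(path) -> Ensemble:
    """Read a trial CSV back into an Ensemble.

    The condition is reconstructed by name only (parameter overrides are not
    serialized in trial records).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {missing}")
    trials = []
    for _, row in df.iterrows():
        outcome = row["outcome"]
        if outcome not in OUTCOMES:
            raise FormatError(f"unknown outcome label {outcome!r}")
        vals = {c: (None if pd.isna(row[c]) else float(row[c])) for c in _FLOAT_COLS}
        trials.append(
            TrialResult(
                outcome=outcome,
                t_cross_error_ms=vals["t_cross_error_ms"],
                t_cross_correct_ms=vals["t_cross_correct_ms"],
                rt_error_ms=vals["rt_error_ms"],
                rt_anti_ms=vals["rt_anti_ms"],
                rt_corrected_ms=vals["rt_corrected_ms"],
                tau_left=vals["tau_left"],
                tau_right=vals["tau_right"],
                seed=int(row["seed"]),
                tau_redraws=int(row["tau_redraws"]),
            )
        )
    condition = ConditionSpec(str(df["condition"].iloc[0]), {})
    master_seed = int(df["master_seed"].iloc[0])
    return Ensemble(condition=condition, trials=trials, master_seed=master_seed, params=None)


def read_rt_table(path, column: str = "rt_ms") -> np.ndarray:
    """Read a plain per-subject RT table (CSV with an ``rt_ms`` column)."""
    df = pd.read_csv(path)
    if column not in df.columns:
        raise FormatError(f"missing column(s): ['{column}']")
    return df[column].dropna().to_numpy(dtype=float)
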