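"""Calibration experiments: does the analysis recover what the simulator put in?

Each function runs a battery of simulated experiments under stated study
conditions and measures how well the corresponding estimator or test
recovers the generating parameter.  They are the package's own
verification instruments, shared by the test suite and the reproduction
script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .response import ExperimentDesign, ResponseParams, ScheduleGeometry, simulate_experiment
from .stats import fit_poisson_glm_irls, habituation_trend, permutation_condition_test

__all__ = [
    "RECOVERY_GEOMETRY",
    "estimate_condition_log_ratio",
    "reversal_recovery",
    "habituation_recovery",
    "permutation_type1_error",
]

#: Session geometry used by the calibration batteries: eight 6.4 s songs
#: per playback (51.2 s of song exposure per session), with shortened
#: inter-song silences and pre/post windows — song exposure is what powers
#: the estimators; silence lengths only add simulation time.
RECOVERY_GEOMETRY = ScheduleGeometry(
    n_songs=8, song_duration_s=6.4, inter_song_silence_s=10.0, pre_s=10.0, post_s=10.0
)


def estimate_condition_log_ratio(
    table: pd.DataFrame,
    condition: str,
    reference: str,
    *,
    window: str = "within_song",
    include_session: bool = True,
) -> float:
    """Fixed-effects Poisson estimate of log(rate[condition]/rate[reference]).

    Bird fixed intercepts absorb the random bird offsets; an optional linear
    session covariate absorbs habituation so the condition contrast is not
    confounded by presentation order.
    """
    sub = table[(table["window"] == window) & (table["exposure_s"] > 0)]
    sub = sub[sub["condition"].isin([condition, reference])]
    birds = sorted(sub["subject"].unique())
    cols = [(sub["subject"] == b).to_numpy(float) for b in birds]
    names = [f"bird[{b}]" for b in birds]
    cond_idx = len(names)
    cols.append((sub["condition"] == condition).to_numpy(float))
    names.append(f"condition[{condition}]")
    if include_session and sub["session"].nunique() > 1:
        cols.append(sub["session"].to_numpy(float) - 1.0)
        names.append("session")
    fit = fit_poisson_glm_irls(
        sub["count"].to_numpy(float),
        np.column_stack(cols),
        np.log(sub["exposure_s"].to_numpy(float)),
        names=names,
    )
    return float(fit.coefficients[cond_idx])


def reversal_recovery(
    n_reps: int = 200,
    seed: int = 0,
    *,
    n_birds: int = 8,
    base_rate: float = 0.5,
    reversal_multiplier: float = 0.1,
    habituation: float = 0.65,
    bird_sd: float = 0.5,
) -> np.ndarray:
    """Per-replicate GLM estimates of the REVERSAL/FIXED log rate ratio.

    Each replicate simulates a counterbalanced two-condition experiment
    (four sessions, each condition heard twice, order alternating across
    birds) and refits; the estimates should centre on
    ``log(reversal_multiplier)``.
    """
    design = ExperimentDesign(
        n_birds=n_birds,
        n_sessions=4,
        condition_orders=(
            ("FIXED", "REVERSAL", "FIXED", "REVERSAL"),
            ("REVERSAL", "FIXED", "REVERSAL", "FIXED"),
        ),
        geometry=RECOVERY_GEOMETRY,
    )
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) & 0x7FFFFFFF
    estimates = np.empty(n_reps)
    for i in range(n_reps):
        params = ResponseParams(
            base_rate=base_rate,
            condition_multipliers={"REVERSAL": reversal_multiplier},
            habituation=habituation,
            bird_sd=bird_sd,
            seed=int(seeds[i]),
        )
        table = simulate_experiment(design, params)
        estimates[i] = estimate_condition_log_ratio(table, "REVERSAL", "FIXED")
    return estimates


def habituation_recovery(
    n_reps: int = 200,
    seed: int = 0,
    *,
    n_birds: int = 8,
    n_sessions: int = 4,
    base_rate: float = 0.5,
    habituation: float = 0.65,
    bird_sd: float = 0.5,
) -> np.ndarray:
    """Per-replicate session-trend slopes; should centre on log(habituation)."""
    design = ExperimentDesign(
        n_birds=n_birds,
        n_sessions=n_sessions,
        condition_orders=(("FIXED",) * n_sessions,),
        geometry=RECOVERY_GEOMETRY,
    )
    seeds = np.random.SeedSequence([seed, 1]).generate_state(n_reps) & 0x7FFFFFFF
    slopes = np.empty(n_reps)
    for i in range(n_reps):
        params = ResponseParams(
            base_rate=base_rate,
            habituation=habituation,
            bird_sd=bird_sd,
            seed=int(seeds[i]),
        )
        table = simulate_experiment(design, params)
        slopes[i] = habituation_trend(table).coef("session")
    return slopes


def permutation_type1_error(
    n_reps: int = 2000,
    seed: int = 0,
    *,
    n_birds: int = 8,
    alpha: float = 0.05,
    base_rate: float = 0.5,
    bird_sd: float = 0.5,
) -> float:
    """Rejection rate of the within-bird permutation test under the null.

    All condition multipliers are 1 (no effect), so rejections at level
    ``alpha`` should occur with probability ~``alpha``.
    """
    design = ExperimentDesign.counterbalanced(
        n_birds, ["FIXED", "REVERSAL"], RECOVERY_GEOMETRY
    )
    seeds = np.random.SeedSequence([seed, 2]).generate_state(n_reps) & 0x7FFFFFFF
    rejections = 0
    for i in range(n_reps):
        params = ResponseParams(base_rate=base_rate, bird_sd=bird_sd, seed=int(seeds[i]))
        table = simulate_experiment(design, params)
        p = permutation_condition_test(table, ("FIXED", "REVERSAL"))
        rejections += p <= alpha
    return rejections / n_reps
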