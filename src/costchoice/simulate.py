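"""Synthetic sessions and Poisson-spiking neurons.

The session generator draws choices from the logistic choice model so that
every downstream stage — behavioral fitting, task-relatedness screening,
ANCOVA tuning classification, variable selection — can run without recorded
data. Offer types repeat in shuffled blocks and the eight cost-by-side
configurations (cost assignment x offer side x target side) are
counterbalanced in shuffled blocks of eight, emulating the pseudo-random
counterbalanced design of the task. Hysteresis terms are computed from the
realized choice sequence.

Neurons follow the additive structure the tuning analysis assumes: the
windowed firing rate is linear in a single decision variable plus an
ipsi/contra location offset, and spike counts are Poisson on
rate x window duration. This mirrors the parallel-lines model; it omits
features of real spike trains (autocorrelation, drift, mixed tuning) that
the analysis does not assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior, task
from .task import HIGH, LEFT, LOW, RIGHT, VARIABLES
from .windows import COVARIATE_BY_WINDOW, WINDOW_DURATION, WINDOWS

#: Default offer types (qA, qB): quantity ratios 0.5-6 around a relative
#: value of ~2, the regime where choices are informative about both rho and
#: the action cost.
DEFAULT_OFFER_TYPES = (
    (2, 1),
    (1, 1),
    (2, 3),
    (1, 2),
    (2, 5),
    (1, 3),
    (1, 4),
    (1, 6),
)

#: Target angles by hemifield (degrees from azimuth).
LEFT_ANGLES = (157.5, 202.5)
RIGHT_ANGLES = (22.5, 337.5)


@dataclass
class SessionConfig:
    """Generating parameters for one synthetic behavioral session.

    The normalized parameters default to the across-session medians of the
    recorded behavior (action cost ``xi`` midway between the two animals'
    medians); the steepness ``a0`` is a generator choice giving realistic
    choice stochasticity near indifference.
    """

    session_id: str = "sim"
    n_trials: int = 250
    offer_types: tuple = DEFAULT_OFFER_TYPES
    a0: float = 2.0
    rho: float = 2.0
    xi: float = 0.22
    eta: float = 0.16
    phi: float = -0.008
    delta: float = -0.03
    epsilon: float = 0.017
    hemisphere: str = "left"
    seed: int = 0

    @property
    def coefficients(self) -> np.ndarray:
        """Raw a0..a6 implied by the normalized parameters."""
        return self.a0 * np.array(
            [1.0, self.rho, self.xi, self.eta, self.phi, self.delta, self.epsilon]
        )


@dataclass
class NeuronSpec:
    """Generative tuning of one synthetic neuron.

    ``tuned_variable`` is a decision-variable name (see
    :data:`costchoice.task.VARIABLES`) or ``None`` for an untuned cell;
    ``slope`` is in spikes/s per unit of the variable, ``baseline`` and
    ``location_offset`` in spikes/s. The location offset is added whenever
    the window's covariate (chosen offer/target location) is contralateral.
    """

    neuron_id: str
    tuned_variable: str | None = None
    slope: float = 0.0
    baseline: float = 10.0
    location_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.tuned_variable is not None and self.tuned_variable not in VARIABLES.values():
            raise ValueError(f"unknown tuned_variable {self.tuned_variable!r}")
        if self.tuned_variable is None and self.slope != 0.0:
            raise ValueError("untuned neurons must have slope = 0")


def _balanced_sequence(items: list, n: int, rng: np.random.Generator) -> list:
    """n draws cycling through shuffled blocks of ``items`` (counts within +/-1)."""
    out = []
    while len(out) < n:
        block = list(items)
        rng.shuffle(block)
        out.extend(block)
    return out[:n]


def generate_session(config: SessionConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one session of choices from the logistic choice model.

    Returns the canonical trial table with indicator columns appended.
    Reproducible given ``config.seed`` (or an explicit ``rng``).
    """
    if len(config.offer_types) == 0:
        raise ValueError("offer_types must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trials
    if n == 0:
        return task.add_indicators(pd.DataFrame(columns=task.TRIAL_COLUMNS))
    a = config.coefficients

    offers = _balanced_sequence(list(config.offer_types), n, rng)
    # eight counterbalanced configurations: A low cost? x A left? x target A left?
    configs = _balanced_sequence(
        [(c, o, t) for c in (0, 1) for o in (0, 1) for t in (0, 1)], n, rng
    )

    rows = []
    prev_juice: str | None = None
    prev_cost: str | None = None
    for i in range(n):
        qa, qb = offers[i]
        a_low, a_left, ta_left = configs[i]
        cost_a = LOW if a_low else HIGH
        cost_b = HIGH if a_low else LOW
        d_cost = (0 if a_low else 1) - (1 if a_low else 0)
        d_hyst = (1 if prev_juice == "B" else 0) - (1 if prev_juice == "A" else 0)
        if prev_cost is None:
            d_costhyst = 0
        else:
            d_costhyst = int(cost_b == prev_cost) - int(cost_a == prev_cost)
        d_offer = (0 if a_left else 1) - (1 if a_left else 0)
        d_target = (0 if ta_left else 1) - (1 if ta_left else 0)
        x = (
            a[0] * qb
            - a[1] * qa
            + a[2] * d_cost
            + a[3] * d_hyst
            + a[4] * d_costhyst
            + a[5] * d_offer
            + a[6] * d_target
        )
        p_b = 1.0 / (1.0 + np.exp(-x)) if x < 50 else 1.0
        chosen = "B" if rng.random() < p_b else "A"
        ta_side = LEFT if ta_left else RIGHT
        angle_pool = LEFT_ANGLES if ta_left else RIGHT_ANGLES
        rows.append(
            {
                "session_id": config.session_id,
                "trial_index": i + 1,
                "qA": qa,
                "qB": qb,
                "costA": cost_a,
                "costB": cost_b,
                "offerA_side": LEFT if a_left else RIGHT,
                "targetA_side": ta_side,
                "chosen_juice": chosen,
                "chosen_side": "",  # filled by add_indicators
                "target_angle_deg": angle_pool[int(rng.integers(2))],
            }
        )
        prev_juice = chosen
        prev_cost = cost_a if chosen == "A" else cost_b
    df = pd.DataFrame(rows, columns=task.TRIAL_COLUMNS)
    return task.add_indicators(df)


def generate_events(trials: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Per-trial event times (s, within-trial clock) matching the task timing.

    Offers appear 1.5 s after fixation and last 1 s; targets appear 1 s
    later; the go signal follows a uniform 0.6-1.2 s delay; juice is
    delivered after the saccade (~0.2 s) plus 0.75 s of peripheral fixation.
    """
    n = len(trials)
    offer_on = np.full(n, 1.5)
    offer_off = offer_on + 1.0
    target_on = offer_off + 1.0
    go = target_on + rng.uniform(0.6, 1.2, size=n)
    juice = go + 0.2 + 0.75
    return pd.DataFrame(
        {
            "trial_index": trials["trial_index"].to_numpy(),
            "offer_on": offer_on,
            "offer_off": offer_off,
            "target_on": target_on,
            "go": go,
            "juice": juice,
        }
    )


def generate_neuron(
    spec: NeuronSpec,
    trials: pd.DataFrame,
    variables: pd.DataFrame,
    rng: np.random.Generator,
    duration: float = WINDOW_DURATION,
) -> pd.DataFrame:
    """Poisson spike counts per trial per window for one synthetic neuron.

    The mean count in a window is ``max(0, baseline + slope*variable +
    location_offset*covariate) * duration``; the returned rate is
    count/duration.
    """
    if duration <= 0:
        raise ValueError("window duration must be positive")
    v = (
        np.nan_to_num(variables[spec.tuned_variable].to_numpy(float))
        if spec.tuned_variable is not None
        else np.zeros(len(trials))
    )
    frames = []
    for w in WINDOWS:
        cov = variables[COVARIATE_BY_WINDOW[w]].to_numpy(float)
        rate = np.maximum(0.0, spec.baseline + spec.slope * v + spec.location_offset * cov)
        counts = rng.poisson(rate * duration)
        frames.append(
            pd.DataFrame(
                {
                    "neuron_id": spec.neuron_id,
                    "trial_index": trials["trial_index"].to_numpy(),
                    "window_id": w,
                    "count": counts,
                    "rate": counts / duration,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_population(
    recipe: list[tuple[NeuronSpec, int]],
    config: SessionConfig,
    rng: np.random.Generator | None = None,
) -> dict:
    """Simulate a session plus a labeled neuron population.

    ``recipe`` lists (template spec, count) pairs; each generated neuron gets
    a unique id derived from the template. Returns a dict with the trial
    table, the behavioral fit used for variable construction (fitted, as in
    the real pipeline), the long rate table, and a ground-truth table for
    recovery scoring.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    trials = generate_session(config, rng)
    fit = behavior.fit_session(trials)
    variables = task.variable_table(trials, rho=fit.rho, xi=fit.xi, hemisphere=config.hemisphere)

    rates, truth = [], []
    i = 0
    for spec, count in recipe:
        for _ in range(count):
            label = spec.tuned_variable or ("loc_only" if spec.location_offset else "untuned")
            nid = f"n{i:04d}_{label}"
            s = replace(spec, neuron_id=nid)
            rates.append(generate_neuron(s, trials, variables, rng))
            truth.append(
                {
                    "neuron_id": nid,
                    "tuned_variable": s.tuned_variable,
                    "slope": s.slope,
                    "baseline": s.baseline,
                    "location_offset": s.location_offset,
                }
            )
            i += 1
    return {
        "trials": trials,
        "fit": fit,
        "variables": variables,
        "rates": pd.concat(rates, ignore_index=True) if rates else pd.DataFrame(),
        "truth": pd.DataFrame(truth),
    }


def five_signal_recipe(
    n_per_class: int = 12,
    n_untuned: int = 0,
    value_slope: float = 3.0,
    binary_slope: float = 8.0,
    location_offset: float = 8.0,
    baseline: float = 6.0,
) -> list[tuple[NeuronSpec, int]]:
    """Population recipe with the five signals dominant in the recorded area.

    Chosen value, chosen cost and chosen juice cells, plus location-only
    cells driven purely by the chosen offer/target side, plus optional
    untuned cells.
    """
    return [
        (NeuronSpec("cv", "chosen_value", slope=value_slope, baseline=baseline), n_per_class),
        (NeuronSpec("cc", "chosen_cost", slope=binary_slope, baseline=baseline), n_per_class),
        (NeuronSpec("cj", "chosen_juice", slope=binary_slope, baseline=baseline), n_per_class),
        (
            NeuronSpec("col", None, baseline=baseline, location_offset=location_offset),
            n_per_class,
        ),
        (NeuronSpec("untuned", None, baseline=baseline), n_untuned),
    ]
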