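import numpy as np
import pandas as pd
import pytest

import costchoice as cc
from costchoice import simulate, task


@pytest.fixture(scope="session")
def sim_session():
    """A moderately sized simulated session with its ML behavioral fit."""
    cfg = cc.SessionConfig(session_id="sess", n_trials=400, seed=101)
    trials = cc.generate_session(cfg)
    fit = cc.fit_session(trials)
    return cfg, trials, fit


@pytest.fixture(scope="session")
def five_signal_population():
    """Labeled population with the five dominant signals plus untuned cells.

    Session-scoped: several tests reuse the same dataset (classification
    recovery, variable selection, report consistency).
    """
    cfg = cc.SessionConfig(session_id="pop", n_trials=400, seed=202)
    recipe = simulate.five_signal_recipe(n_per_class=12, n_untuned=8)
    return simulate.generate_population(recipe, cfg)


@pytest.fixture(scope="session")
def population_pipeline(five_signal_population):
    """Full pipeline run on the five-signal population."""
    data = five_signal_population
    return cc.run_pipeline(data["trials"], data["rates"])


def random_trials(rng: np.random.Generator, n: int = 40, session_id: str = "r") -> pd.DataFrame:
    """A structurally valid random trial table for property tests."""
    rows = []
    for i in range(n):
        a_low = bool(rng.integers(2))
        rows.append(
            {
                "session_id": session_id,
                "trial_index": i + 1,
                "qA": int(rng.integers(0, 4)),
                "qB": int(rng.integers(0, 7)),
                "costA": task.LOW if a_low else task.HIGH,
                "costB": task.HIGH if a_low else task.LOW,
                "offerA_side": task.LEFT if rng.integers(2) else task.RIGHT,
                "targetA_side": task.LEFT if rng.integers(2) else task.RIGHT,
                "chosen_juice": "A" if rng.integers(2) else "B",
                "chosen_side": "",
                "target_angle_deg": 22.5,
            }
        )
    return task.add_indicators(pd.DataFrame(rows, columns=task.TRIAL_COLUMNS))
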