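"""Event-aligned rates and the task-relatedness ANOVA screen."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols

from costchoice import simulate, task, windows
from costchoice.simulate import NeuronSpec, SessionConfig
from costchoice.windows import WINDOWS, anova3_pvalues, screen_task_related, window_rates


def simple_events(n_trials):
    return pd.DataFrame(
        {
            "trial_index": np.arange(1, n_trials + 1),
            "offer_on": 1.5,
            "offer_off": 2.5,
            "target_on": 3.5,
            "go": 4.4,
            "juice": 5.35,
        }
    )


class TestWindowRates:
    def test_no_spikes_gives_zero_everywhere(self):
        events = simple_events(2)
        spikes = pd.DataFrame({"trial_index": [], "time": []})
        rates = window_rates(spikes, events)
        assert (rates["rate"] == 0).all()
        assert len(rates) == 2 * len(WINDOWS)

    def test_count_over_duration(self):
        events = simple_events(1)
        spikes = pd.DataFrame({"trial_index": [1] * 5, "time": [1.51, 1.6, 1.7, 1.8, 1.99]})
        rates = window_rates(spikes, events).set_index("window_id")
        assert rates.loc["post_offer", "rate"] == 10.0

    def test_half_open_boundaries(self):
        events = simple_events(1)
        # spike exactly at window start counts, exactly at end does not
        spikes = pd.DataFrame({"trial_index": [1, 1], "time": [1.5, 2.0]})
        rates = window_rates(spikes, events).set_index("window_id")
        assert rates.loc["post_offer", "count"] == 1
        assert rates.loc["late_delay", "count"] == 1  # the 2.0 spike starts late-delay

    def test_manual_count_oracle(self):
        events = simple_events(3)
        events.loc[1, "go"] = 4.9  # jittered go on trial 2
        rng = np.random.default_rng(0)
        spikes = pd.DataFrame(
            {
                "trial_index": np.repeat([1, 2, 3], 40),
                "time": rng.uniform(0.0, 6.5, 120),
            }
        )
        rates = window_rates(spikes, events)
        for _, row in rates.iterrows():
            ev = events.set_index("trial_index").loc[row["trial_index"]]
            event, lo, hi = windows.WINDOW_DEFS[row["window_id"]]
            st = spikes[spikes["trial_index"] == row["trial_index"]]["time"]
            manual = int(((st >= ev[event] + lo) & (st < ev[event] + hi)).sum())
            assert row["count"] == manual

    def test_missing_event_excludes_trial(self):
        events = simple_events(3)
        events.loc[2, "juice"] = np.nan
        spikes = pd.DataFrame({"trial_index": [1], "time": [1.6]})
        with pytest.warns(UserWarning, match="missing event"):
            rates = window_rates(spikes, events)
        assert set(rates["trial_index"]) == {1, 2}

    def test_window_set_is_fixed(self):
        assert len(WINDOWS) == 9
        for w, (event, lo, hi) in windows.WINDOW_DEFS.items():
            assert hi - lo == pytest.approx(0.5)


class TestAnova:
    def test_matches_statsmodels_type2(self):
        """Main-effects type II p-values equal statsmodels anova_lm."""
        rng = np.random.default_rng(1)
        n = 120
        df = pd.DataFrame(
            {
                "tt": rng.choice([f"t{i}" for i in range(6)], n),
                "f2": rng.choice(["L", "R"], n),
                "f3": rng.choice(["L", "R"], n),
            }
        )
        df["y"] = (
            rng.normal(size=n)
            + (df["tt"] == "t3") * 1.5
            + (df["f2"] == "L") * 0.8
        )
        ours = anova3_pvalues(df["y"].to_numpy(), {c: df[c].to_numpy() for c in ("tt", "f2", "f3")})
        lm = ols("y ~ C(tt) + C(f2) + C(f3)", data=df).fit()
        ref = sm.stats.anova_lm(lm, typ=2)
        assert ours["tt"] == pytest.approx(ref.loc["C(tt)", "PR(>F)"], rel=1e-8)
        assert ours["f2"] == pytest.approx(ref.loc["C(f2)", "PR(>F)"], rel=1e-8)
        assert ours["f3"] == pytest.approx(ref.loc["C(f3)", "PR(>F)"], rel=1e-8)

    def test_balanced_two_by_two_by_two_closed_form(self):
        """On a balanced 2x2x2 design the type II F equals the textbook
        between/within mean-square ratio."""
        rng = np.random.default_rng(2)
        reps = 6
        levels = [(a, b, c) for a in "xy" for b in "uv" for c in "pq"]
        df = pd.DataFrame(levels * reps, columns=["A", "B", "C"])
        df["y"] = rng.normal(size=len(df)) + np.where(df["A"] == "x", 1.0, 0.0)
        ours = anova3_pvalues(df["y"].to_numpy(), {c: df[c].to_numpy() for c in "ABC"})
        n = len(df)
        grand = df["y"].mean()
        resid_full = df["y"] - df.groupby("A")["y"].transform("mean") \
            - df.groupby("B")["y"].transform("mean") - df.groupby("C")["y"].transform("mean") + 2 * grand
        rss_full = (resid_full**2).sum()
        from scipy import stats as sps

        for f in "ABC":
            ss_f = sum(
                len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby(f)
            )
            F = (ss_f / 1) / (rss_full / (n - 4))
            p = sps.f.sf(F, 1, n - 4)
            assert ours[f] == pytest.approx(p, rel=1e-10)

    def test_constant_factor_gets_p_one(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        factors = {
            "tt": rng.choice(["a", "b"], 40),
            "f2": np.array(["L"] * 40),
            "f3": rng.choice(["L", "R"], 40),
        }
        with pytest.warns(UserWarning, match="constant"):
            p = anova3_pvalues(y, factors)
        assert p["f2"] == 1.0


@pytest.fixture(scope="module")
def screened(five_signal_population):
    data = five_signal_population
    screen = screen_task_related(data["rates"], data["trials"])
    return data, screen


class TestScreen:
    def test_strong_effect_is_flagged(self, screened):
        data, screen = screened
        tuned = data["truth"][data["truth"]["tuned_variable"] == "chosen_value"]["neuron_id"]
        sub = screen[screen["neuron_id"].isin(tuned)]
        flagged = sub.groupby("neuron_id")["task_related"].any()
        assert flagged.all()

    def test_rescaling_invariance(self, five_signal_population):
        data = five_signal_population
        one = data["truth"]["neuron_id"].iloc[0]
        rates = data["rates"][data["rates"]["neuron_id"] == one]
        a = screen_task_related(rates, data["trials"])
        scaled = rates.assign(rate=rates["rate"] * 3.7)
        b = screen_task_related(scaled, data["trials"])
        for c in [c for c in a.columns if c.startswith("p_")]:
            assert np.allclose(a[c], b[c], rtol=1e-9)

    def test_factor_count_table_consistency(self, screened):
        """Count-table cells equal direct recomputation from the screen table."""
        _, screen = screened
        table = windows.factor_count_table(screen)
        for w in WINDOWS:
            sub = screen[screen["window_id"] == w]
            for f in windows.SCREEN_FACTORS:
                assert table.loc[w, f] == (sub[f"p_{f}"] < 0.001).sum()
        # "at least 1" row is a union over windows, not a sum
        for f in windows.SCREEN_FACTORS:
            by_neuron = screen.groupby("neuron_id")[f"p_{f}"].min() < 0.001
            assert table.loc["at_least_1", f] == by_neuron.sum()
        assert table.loc["at_least_1", "any_factor"] == (
            screen.groupby("neuron_id")["task_related"].any().sum()
        )

    def test_task_related_definition(self, screened):
        _, screen = screened
        pcols = [c for c in screen.columns if c.startswith("p_")]
        assert (screen["task_related"] == (screen[pcols].min(axis=1) < 0.001)).all()
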