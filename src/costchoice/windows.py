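"""Event-aligned time windows, firing rates, and the task-relatedness screen.

Neuronal activity is analyzed in nine 0.5 s windows aligned to behavioral
events: pre-offer, post-offer, late-delay (0.5-1.0 s after offer onset),
mem-delay (after offer offset), pre-target, post-target, pre-go, pre-juice,
and post-juice. A "response" is one neuron's firing rate in one window as a
function of the trial.

Task-relatedness is screened with two 3-way ANOVAs on trial-level rates
(factors trial type x offer A location x target A location, and trial type x
chosen offer location x chosen target location), main effects only, type II
sums of squares. A response is task related if any factor reaches p < 0.001
in either ANOVA.

The ANOVA is computed by projection onto precomputed orthonormal bases of
the full and drop-one-factor design matrices, which lets one session's
factor structure be reused across all neurons and windows; it agrees with
statsmodels ``anova_lm(typ=2)`` on main-effects models (see tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task import add_indicators, trial_type_key

#: The nine analysis windows, in trial order.
WINDOWS = (
    "pre_offer",
    "post_offer",
    "late_delay",
    "mem_delay",
    "pre_target",
    "post_target",
    "pre_go",
    "pre_juice",
    "post_juice",
)

#: window -> (aligning event, start offset s, end offset s); all 0.5 s long.
WINDOW_DEFS = {
    "pre_offer": ("offer_on", -0.5, 0.0),
    "post_offer": ("offer_on", 0.0, 0.5),
    "late_delay": ("offer_on", 0.5, 1.0),
    "mem_delay": ("offer_off", 0.0, 0.5),
    "pre_target": ("target_on", -0.5, 0.0),
    "post_target": ("target_on", 0.0, 0.5),
    "pre_go": ("go", -0.5, 0.0),
    "pre_juice": ("juice", -0.5, 0.0),
    "post_juice": ("juice", 0.0, 0.5),
}

WINDOW_DURATION = 0.5

#: Windows whose ANCOVA covariate is the chosen *offer* location (before
#: target onset; pre-offer follows the early convention) vs the chosen
#: *target* location (from target onset on).
EARLY_COVARIATE_WINDOWS = ("pre_offer", "post_offer", "late_delay", "mem_delay", "pre_target")
LATE_COVARIATE_WINDOWS = ("post_target", "pre_go", "pre_juice", "post_juice")

COVARIATE_BY_WINDOW = {
    **{w: "chosen_offer_contra" for w in EARLY_COVARIATE_WINDOWS},
    **{w: "chosen_target_contra" for w in LATE_COVARIATE_WINDOWS},
}

#: Trial epochs for the dimensional-integration analysis: windows after
#: offer presentation but before target onset vs windows from target onset
#: on. The pre-offer window belongs to neither epoch.
EARLY_EPOCH_WINDOWS = ("post_offer", "late_delay", "mem_delay", "pre_target")
LATE_EPOCH_WINDOWS = ("post_target", "pre_go", "pre_juice", "post_juice")

EVENT_COLUMNS = ("offer_on", "offer_off", "target_on", "go", "juice")

#: ANOVA factor names in report order.
SCREEN_FACTORS = (
    "trial_type",
    "offer_A_location",
    "target_A_location",
    "chosen_offer_location",
    "chosen_target_location",
)


def window_rates(spikes: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Spike counts and rates per trial per window.

    ``spikes`` has columns ``trial_index`` and ``time`` (seconds on the same
    clock as the event times); ``events`` has one row per trial with columns
    ``trial_index`` and the five alignment events. Windows are half-open
    ``[start, end)``. Trials with a missing (NaN) event are excluded with a
    warning.
    """
    missing = events[list(EVENT_COLUMNS)].isna().any(axis=1)
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} trial(s) with missing event times",
            stacklevel=2,
        )
        events = events[~missing]
    by_trial = {t: np.sort(g["time"].to_numpy(float)) for t, g in spikes.groupby("trial_index")}
    rows = []
    for _, ev in events.iterrows():
        t = ev["trial_index"]
        st = by_trial.get(t, np.empty(0))
        for w in WINDOWS:
            event, lo, hi = WINDOW_DEFS[w]
            start = ev[event] + lo
            end = ev[event] + hi
            count = int(np.searchsorted(st, end, side="left") - np.searchsorted(st, start, side="left"))
            rows.append(
                {"trial_index": t, "window_id": w, "count": count, "rate": count / (hi - lo)}
            )
    return pd.DataFrame(rows, columns=["trial_index", "window_id", "count", "rate"])


def _dummies(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Full-rank treatment-coded dummy block for a factor (first level dropped)."""
    levels = pd.unique(labels)
    if len(levels) < 2:
        return np.empty((len(labels), 0)), len(levels)
    block = np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])
    return block, len(levels)


@dataclass
class _AnovaDesign:
    """Precomputed orthonormal bases for a main-effects ANOVA."""

    factor_names: tuple[str, ...]
    q_full: np.ndarray
    rank_full: int
    q_reduced: dict  # factor -> (Q, rank)
    n: int
    constant: tuple[str, ...]  # factors with a single level

    @classmethod
    def build(cls, factors: dict[str, np.ndarray]) -> "_AnovaDesign":
        n = len(next(iter(factors.values())))
        blocks, constant = {}, []
        for name, labels in factors.items():
            block, nlev = _dummies(np.asarray(labels))
            if nlev < 2:
                constant.append(name)
            blocks[name] = block
        intercept = np.ones((n, 1))

        def basis(cols: list[np.ndarray]) -> tuple[np.ndarray, int]:
            X = np.hstack([intercept] + cols)
            q, r = np.linalg.qr(X)
            keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(r).max())
            return q[:, keep], int(keep.sum())

        names = tuple(factors)
        q_full, rank_full = basis([blocks[f] for f in names])
        q_reduced = {}
        for f in names:
            q_reduced[f] = basis([blocks[g] for g in names if g != f])
        return cls(names, q_full, rank_full, q_reduced, n, tuple(constant))

    def pvalues(self, Y: np.ndarray) -> dict[str, np.ndarray]:
        """Type II main-effect p-values for each column of Y (trials x responses)."""
        tot = np.sum(Y * Y, axis=0)
        proj_full = self.q_full.T @ Y
        rss_full = tot - np.sum(proj_full * proj_full, axis=0)
        df_resid = self.n - self.rank_full
        out = {}
        for f in self.factor_names:
            if f in self.constant:
                out[f] = np.ones(Y.shape[1])
                continue
            q_red, rank_red = self.q_reduced[f]
            proj = q_red.T @ Y
            rss_red = tot - np.sum(proj * proj, axis=0)
            df1 = self.rank_full - rank_red
            if df1 <= 0 or df_resid <= 0:
                out[f] = np.ones(Y.shape[1])
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                fstat = ((rss_red - rss_full) / df1) / (rss_full / df_resid)
            p = stats.f.sf(fstat, df1, df_resid)
            out[f] = np.where(np.isfinite(fstat), p, 1.0)
        return out


def anova3_pvalues(y: np.ndarray, factors: dict[str, np.ndarray]) -> dict[str, float]:
    """Main-effects 3-way ANOVA (type II) p-values for a single response."""
    design = _AnovaDesign.build(factors)
    if design.constant:
        warnings.warn(
            f"factor(s) {design.constant} constant; p set to 1", stacklevel=2
        )
    res = design.pvalues(np.asarray(y, float).reshape(-1, 1))
    return {f: float(p[0]) for f, p in res.items()}


def screen_task_related(
    rates: pd.DataFrame,
    trials: pd.DataFrame,
    alpha: float = 0.001,
    min_trials_per_type: int = 2,
) -> pd.DataFrame:
    """Task-relatedness screen for every (neuron, window) response.

    ``rates`` is a long table (``neuron_id, trial_index, window_id, rate``)
    from one session; ``trials`` the session's trial table. Each response
    enters two 3-way ANOVAs; the trial-type factor appears in both and its
    smaller p-value is kept. Returns one row per response with the five
    factor p-values and the ``task_related`` flag (any p < ``alpha``).

    Trial types with fewer than ``min_trials_per_type`` trials are dropped
    from the ANOVA. A factor constant over the retained trials gets p = 1.
    """
    df = trials if "chosen_side" in trials.columns else add_indicators(trials)
    df = df.set_index("trial_index")
    tt = trial_type_key(df)
    keep_types = tt.value_counts()
    keep_idx = df.index[tt.isin(keep_types[keep_types >= min_trials_per_type].index)]

    fac = pd.DataFrame(
        {
            "trial_type": tt,
            "offer_A_location": df["offerA_side"],
            "target_A_location": df["targetA_side"],
            "chosen_offer_location": df["chosen_side"],
            "chosen_target_location": df["chosen_target_side"],
        }
    ).loc[keep_idx]

    designs = None
    rows = []
    for window_id, wdf in rates.groupby("window_id", sort=False):
        Y = wdf.pivot_table(index="trial_index", columns="neuron_id", values="rate")
        Y = Y.reindex(keep_idx).dropna(axis=0)
        if designs is None or not Y.index.equals(designs[2]):
            f = fac.loc[Y.index]
            d1 = _AnovaDesign.build(
                {k: f[k].to_numpy() for k in ("trial_type", "offer_A_location", "target_A_location")}
            )
            d2 = _AnovaDesign.build(
                {
                    k: f[k].to_numpy()
                    for k in ("trial_type", "chosen_offer_location", "chosen_target_location")
                }
            )
            designs = (d1, d2, Y.index)
        d1, d2, _ = designs
        arr = Y.to_numpy(float)
        p1 = d1.pvalues(arr)
        p2 = d2.pvalues(arr)
        p_tt = np.minimum(p1["trial_type"], p2["trial_type"])
        for j, neuron_id in enumerate(Y.columns):
            pvals = {
                "trial_type": p_tt[j],
                "offer_A_location": p1["offer_A_location"][j],
                "target_A_location": p1["target_A_location"][j],
                "chosen_offer_location": p2["chosen_offer_location"][j],
                "chosen_target_location": p2["chosen_target_location"][j],
            }
            rows.append(
                {
                    "neuron_id": neuron_id,
                    "window_id": window_id,
                    **{f"p_{k}": v for k, v in pvals.items()},
                    "task_related": bool(min(pvals.values()) < alpha),
                }
            )
    return pd.DataFrame(rows)


def factor_count_table(screen: pd.DataFrame, alpha: float = 0.001) -> pd.DataFrame:
    """Per-window counts of responses significant for each screen factor.

    Rows are the nine windows plus an ``at_least_1`` row counting, per
    factor, the neurons significant in at least one window; the final
    column counts responses (or neurons) significant for at least one
    factor.
    """
    out = []
    for w in WINDOWS:
        sub = screen[screen["window_id"] == w]
        row = {"window_id": w}
        any_sig = np.zeros(len(sub), bool)
        for f in SCREEN_FACTORS:
            sig = sub[f"p_{f}"].to_numpy() < alpha
            row[f] = int(sig.sum())
            any_sig |= sig
        row["any_factor"] = int(any_sig.sum())
        out.append(row)
    row = {"window_id": "at_least_1"}
    per_neuron = screen.groupby("neuron_id")
    for f in SCREEN_FACTORS:
        row[f] = int((per_neuron[f"p_{f}"].min() < alpha).sum())
    row["any_factor"] = int(per_neuron["task_related"].any().sum())
    out.append(row)
    return pd.DataFrame(out).set_index("window_id")
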