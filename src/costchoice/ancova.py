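"""ANCOVA tuning classification of neuronal responses.

Each task-related response (one neuron, one window) is regressed on every
candidate decision variable with the *parallel lines* model: rate ~
variable + chosen-location group, no interaction. The group is the chosen
offer location for windows before target onset and the chosen target
location from target onset on, coded 1 = contralateral. A variable
*explains* the response if its slope is significant (p < 0.05); the recorded
R2 is the total R2 of the two-regressor model, and is set to 0 when the
variable does not explain the response.

The two location-only variables are assessed instead with the *horizontal
lines* model (group only). Because that model is nested in every parallel
model sharing its group, its R2 is lower than the R2 of any variable that
explains the response; a location-only variable can therefore provide the
best fit only when it provides the sole explanation. Each location-only
variable is assessed in the windows where its location is the covariate
(chosen offer location before target onset, chosen target location after).

Data points default to per-(trial type x group) mean rates, each cell
requiring at least two trials — the granularity at which tuning is usually
displayed; trial-level fitting is available via ``level="trials"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import LOCATION_ONLY, VARIABLES
from .windows import COVARIATE_BY_WINDOW, WINDOWS
from .task import trial_type_key

EXPLAIN_ALPHA = 0.05

#: window -> the location-only variable assessable in that window.
LOCATION_ONLY_BY_WINDOW = {
    w: (20 if cov == "chosen_offer_contra" else 21) for w, cov in COVARIATE_BY_WINDOW.items()
}


@dataclass
class AncovaFit:
    """One (response, variable) regression result."""

    neuron_id: str
    window_id: str
    variable_id: int
    model: str  # "parallel" or "horizontal"
    r2: float  # total R2, set to 0 when the variable does not explain
    p_factor: float
    p_group: float
    explains: bool
    slope_sign: int
    n_points: int

    def to_row(self) -> dict:
        return {
            "neuron_id": self.neuron_id,
            "window_id": self.window_id,
            "variable_id": self.variable_id,
            "variable": VARIABLES[self.variable_id],
            "model": self.model,
            "r2": self.r2,
            "p_factor": self.p_factor,
            "p_group": self.p_group,
            "explains": self.explains,
            "slope_sign": self.slope_sign,
            "n_points": self.n_points,
        }


@dataclass
class ResponseClassification:
    """Explained set and best-fitting variable for one response."""

    neuron_id: str
    window_id: str
    explained: frozenset
    best_variable: int | None
    best_r2: float


def aggregate_points(
    rates: pd.Series,
    trial_types: pd.Series,
    group: pd.Series,
    x: pd.Series | None,
    level: str = "means",
    min_per_cell: int = 2,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Assemble (y, x, g) data points for one ANCOVA.

    ``level="means"`` averages rates (and the variable) within each
    (trial type x group) cell, dropping cells with fewer than
    ``min_per_cell`` trials; ``level="trials"`` uses individual trials.
    Trials where the variable is undefined (NaN) are dropped pairwise.
    """
    df = pd.DataFrame({"y": rates, "tt": trial_types, "g": group})
    df["x"] = x if x is not None else 0.0
    df = df.dropna(subset=["y", "x"])
    if level == "trials":
        return df["y"].to_numpy(), df["x"].to_numpy(), df["g"].to_numpy()
    if level != "means":
        raise ValueError("level must be 'means' or 'trials'")
    cells = df.groupby(["tt", "g"], observed=True).agg(
        y=("y", "mean"), x=("x", "mean"), n=("y", "size")
    )
    cells = cells[cells["n"] >= min_per_cell]
    g = cells.index.get_level_values("g").to_numpy(float)
    return cells["y"].to_numpy(), cells["x"].to_numpy(), g


def _ols(y: np.ndarray, cols: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares fit with intercept: (coefficients, two-sided t p-values, R2)."""
    X = np.column_stack([np.ones_like(y)] + cols)
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    df = n - p
    if df <= 0:
        return beta, np.ones(p), r2
    sigma2 = rss / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    # a perfect fit has zero residual variance: the slope t-statistic
    # diverges, so p -> 0 for nonzero coefficients
    tol = 1e-12 * max(1.0, float(np.abs(y).max()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > tol, beta / np.where(se > tol, se, 1.0), np.where(np.abs(beta) > tol, np.inf, 0.0))
    pvals = 2.0 * sps.t.sf(np.abs(t), df)
    return beta, pvals, r2


def fit_parallel(
    y: np.ndarray, x: np.ndarray, g: np.ndarray, *, neuron_id="", window_id="", variable_id=0
) -> AncovaFit:
    """Parallel-lines ANCOVA: rate ~ variable + group (no interaction)."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    g = np.asarray(g, float)
    n = len(y)
    degenerate = n < 4 or np.ptp(x) == 0
    if degenerate:
        return AncovaFit(neuron_id, window_id, variable_id, "parallel", 0.0, 1.0, 1.0, False, 0, n)
    cols = [x] + ([g] if np.ptp(g) > 0 else [])
    beta, pvals, r2_raw = _ols(y, cols)
    p_factor = float(pvals[1])
    p_group = float(pvals[2]) if len(cols) == 2 else 1.0
    explains = bool(p_factor < EXPLAIN_ALPHA)
    r2 = r2_raw if explains else 0.0
    return AncovaFit(
        neuron_id,
        window_id,
        variable_id,
        "parallel",
        r2,
        p_factor,
        p_group,
        explains,
        int(np.sign(beta[1])),
        n,
    )


def fit_horizontal(
    y: np.ndarray, g: np.ndarray, *, neuron_id="", window_id="", variable_id=0
) -> AncovaFit:
    """Horizontal-lines ANCOVA: rate ~ group only."""
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    n = len(y)
    if n < 3 or np.ptp(g) == 0:
        return AncovaFit(
            neuron_id, window_id, variable_id, "horizontal", 0.0, np.nan, 1.0, False, 0, n
        )
    beta, pvals, r2_raw = _ols(y, [g])
    p_group = float(pvals[1])
    explains = bool(p_group < EXPLAIN_ALPHA)
    r2 = r2_raw if explains else 0.0
    return AncovaFit(
        neuron_id,
        window_id,
        variable_id,
        "horizontal",
        r2,
        np.nan,
        p_group,
        explains,
        int(np.sign(beta[1])),
        n,
    )


def analyze_response(
    rates: pd.Series,
    trials: pd.DataFrame,
    variables: pd.DataFrame,
    window_id: str,
    neuron_id: str = "",
    level: str = "means",
    min_per_cell: int = 2,
) -> list[AncovaFit]:
    """Fit all candidate variables against one response.

    ``rates`` is indexed by trial_index; ``trials`` and ``variables`` are the
    session's trial table and decision-variable table (same index as
    ``rates``). Variables 1-19 use the parallel model; the window-applicable
    location-only variable uses the horizontal model, and the other
    location-only variable is recorded as not assessable (explains False).
    """
    tt = trial_type_key(trials)
    cov_name = COVARIATE_BY_WINDOW[window_id]
    group = variables[cov_name]
    var_names = [VARIABLES[v] for v in VARIABLES if v not in LOCATION_ONLY]

    # one aggregation shared by every variable without missing values;
    # variables with NaNs (value ratio on zero chosen value) re-aggregate
    # pairwise below
    df = pd.DataFrame({"y": np.asarray(rates, float), "tt": np.asarray(tt), "g": np.asarray(group)})
    for name in var_names:
        df[name] = np.asarray(variables[name], float)
    df = df.dropna(subset=["y"])
    if level == "means":
        cells = df.groupby(["tt", "g"], observed=True).agg(
            {**{c: "mean" for c in ["y"] + var_names}, "tt": "size"}
        ).rename(columns={"tt": "n"})
        cells = cells[cells["n"] >= min_per_cell]
        y = cells["y"].to_numpy()
        g = cells.index.get_level_values("g").to_numpy(float)
        xcols = {name: cells[name].to_numpy() for name in var_names}
    elif level == "trials":
        y = df["y"].to_numpy()
        g = df["g"].to_numpy(float)
        xcols = {name: df[name].to_numpy() for name in var_names}
    else:
        raise ValueError("level must be 'means' or 'trials'")

    fits = []
    for vid, vname in VARIABLES.items():
        if vid in LOCATION_ONLY:
            if vid == LOCATION_ONLY_BY_WINDOW[window_id]:
                fits.append(
                    fit_horizontal(y, g, neuron_id=neuron_id, window_id=window_id, variable_id=vid)
                )
            else:
                fits.append(
                    AncovaFit(
                        neuron_id, window_id, vid, "horizontal", 0.0, np.nan, np.nan, False, 0, 0
                    )
                )
            continue
        x = xcols[vname]
        if np.isnan(variables[vname].to_numpy(float)).any():
            yv, x, gv = aggregate_points(
                rates, tt, group, variables[vname], level, min_per_cell
            )
            fits.append(
                fit_parallel(yv, x, gv, neuron_id=neuron_id, window_id=window_id, variable_id=vid)
            )
            continue
        fits.append(
            fit_parallel(y, x, g, neuron_id=neuron_id, window_id=window_id, variable_id=vid)
        )
    return fits


def classify_response(fits: list[AncovaFit]) -> ResponseClassification:
    """Pick the best-fitting variable from one response's 21 fits.

    Best = highest recorded R2 among explaining variables; a location-only
    variable is eligible only when no other variable explains the response.
    Ties break by variable index.
    """
    explained = frozenset(f.variable_id for f in fits if f.explains)
    candidates = [f for f in fits if f.explains and f.variable_id not in LOCATION_ONLY]
    if not candidates:
        candidates = [f for f in fits if f.explains]
    if not candidates:
        any_fit = fits[0]
        return ResponseClassification(any_fit.neuron_id, any_fit.window_id, explained, None, 0.0)
    best = max(candidates, key=lambda f: (f.r2, -f.variable_id))
    return ResponseClassification(
        best.neuron_id, best.window_id, explained, best.variable_id, best.r2
    )


def analyze_population(
    rates: pd.DataFrame,
    trials: pd.DataFrame,
    variables: pd.DataFrame,
    responses: pd.DataFrame | None = None,
    level: str = "means",
    min_per_cell: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANCOVA fits and classifications for a set of responses.

    ``rates`` is the long rate table for one session; ``responses``
    optionally restricts the analysis to given (neuron_id, window_id) pairs
    (typically the task-related set from the screen). Returns a long fit
    table (one row per response x variable) and a classification table (one
    row per response).
    """
    trials_ix = trials.set_index("trial_index") if trials.index.name != "trial_index" else trials
    vars_ix = variables.set_index(trials_ix.index) if not variables.index.equals(trials_ix.index) else variables
    wanted = None
    if responses is not None:
        wanted = set(map(tuple, responses[["neuron_id", "window_id"]].to_numpy()))
    fit_rows, cls_rows = [], []
    for (nid, wid), sub in rates.groupby(["neuron_id", "window_id"], sort=False):
        if wanted is not None and (nid, wid) not in wanted:
            continue
        r = sub.set_index("trial_index")["rate"].reindex(trials_ix.index)
        fits = analyze_response(
            r, trials_ix, vars_ix, wid, neuron_id=nid, level=level, min_per_cell=min_per_cell
        )
        fit_rows.extend(f.to_row() for f in fits)
        c = classify_response(fits)
        cls_rows.append(
            {
                "neuron_id": c.neuron_id,
                "window_id": c.window_id,
                "explained": ",".join(str(v) for v in sorted(c.explained)),
                "best_variable": c.best_variable,
                "best_r2": c.best_r2,
            }
        )
    return pd.DataFrame(fit_rows), pd.DataFrame(cls_rows)


def count_matrices(classifications: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window x variable count matrices of explained and best-fit responses.

    In the explained matrix a response contributes to every variable in its
    explained set; in the best-fit matrix to at most one.
    """
    explained = pd.DataFrame(0, index=list(WINDOWS), columns=list(VARIABLES.values()))
    best = explained.copy()
    for _, row in classifications.iterrows():
        w = row["window_id"]
        if row["explained"]:
            for v in str(row["explained"]).split(","):
                explained.loc[w, VARIABLES[int(v)]] += 1
        bv = row["best_variable"]
        if pd.notna(bv) and bv is not None:
            best.loc[w, VARIABLES[int(bv)]] += 1
    return explained, best


def group_significance_split(
    fits: pd.DataFrame, variable_id: int, alpha: float = EXPLAIN_ALPHA
) -> pd.DataFrame:
    """Per-window counts of responses explained by a variable, split by
    whether the location group was also significant (conjunctive coding)."""
    sub = fits[(fits["variable_id"] == variable_id) & fits["explains"]]
    rows = []
    for w in WINDOWS:
        wsub = sub[sub["window_id"] == w]
        both = int((wsub["p_group"] < alpha).sum())
        rows.append(
            {
                "window_id": w,
                "n_explained": len(wsub),
                "n_with_group": both,
                "n_without_group": len(wsub) - both,
            }
        )
    return pd.DataFrame(rows)
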